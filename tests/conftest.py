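import hypothesis
import numpy as np
import pandas as pd
import pytest

from hdxdiff import EffectRegion, SimulationConfig, simulate_dataset

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def effect_dataset():
    """Two ~150-residue subunits, one protected region, default noise."""
    cfg = SimulationConfig(
        n_proteins=2, protein_length=150, seed=11,
        effect_regions=[EffectRegion("SUB1", 40, 70, "protected", 30.0)])
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """Small two-condition dataset with no true effects."""
    cfg = SimulationConfig(n_proteins=2, protein_length=120, seed=5)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Deterministic kinetics: no replicate noise, no centroid jitter."""
    cfg = SimulationConfig(
        n_proteins=1, protein_length=100, seed=3,
        sigma_rep=0.0, centroid_jitter_da=0.0, layout="tiling")
    return simulate_dataset(cfg)


def make_rdu_records(group_sds, center=0.3, exposure=0.5, state="alone"):
    """Long RDU table of triplicate groups {c-d, c, c+d}: each group's
    sample SD is exactly d, so the dataset mean replicate SD is
    mean(group_sds)."""
    rows = []
    for i, d in enumerate(group_sds):
        for r, val in enumerate([center - d, center, center + d]):
            rows.append({
                "protein": "P1", "start": 10 * i + 1, "end": 10 * i + 10,
                "sequence": "ACDEFGHIKL", "state": state,
                "exposure": exposure, "replicate": f"R{r + 1}",
                "rdu": val, "n_exchangeable": 9,
            })
    return pd.DataFrame(rows)
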