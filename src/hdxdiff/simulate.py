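"""Synthetic ion-level HDX-MS datasets with known ground truth.

The generator emulates the statistical structure of a differential HDX
experiment on multi-subunit complexes: several ~25 kDa protein chains
digested into overlapping pepsin-like peptides, deuterated for a grid of
exposure times (default 0, 0.5, 1, 5, 10, 30 min) in triplicate under
two conditions (protein alone vs. in complex).

Exchange follows the Linderstrom-Lang model in the EX2 limit: residue
``j`` exchanges with rate ``k_int,j / PF_j`` where ``k_int`` is an
intrinsic rate drawn log-uniformly over a configurable span and ``PF``
is a per-residue, per-condition protection factor (>= 1). The true
fractional uptake of a peptide at exposure ``t`` is

    u(t) = beta * f_D * (1/N) * sum_j [1 - exp(-(k_int,j / PF_j) * t)]

over its ``N`` exchangeable amides (first residue and prolines
excluded), with ``f_D`` the deuterium fraction of the labelling buffer
and ``beta`` a uniform back-exchange retention factor. Condition
effects are localized: residue intervals whose protection factor is
multiplied by ``fold`` in one condition.

Replicate noise is Gaussian at the peptide-RDU level (the statistics
operate on RDU, keeping the generator's truth analytic); optional
per-ion centroid jitter (in Da) exercises the intensity-weighted
averaging. Intensities are split across 2-3 charge states by a
Dirichlet draw. Identical (config, seed) yields byte-identical CSV
output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import CANONICAL_COLUMNS, ProteinSequence, write_fasta, write_ion_table
from .uptake import count_exchangeable_amides

_AA_NO_P = "ACDEFGHIKLMNQRSTVWY"


@dataclass(frozen=True)
class EffectRegion:
    """A residue interval whose protection differs between conditions.

    ``protected`` multiplies the protection factor in the treatment
    condition by ``fold`` (uptake decreases in the complex, deltaRDU < 0);
    ``deprotected`` multiplies it in the reference condition instead
    (uptake increases in the complex, deltaRDU > 0).
    """

    protein_id: str
    start: int
    end: int
    direction: str = "protected"
    fold: float = 20.0

    def __post_init__(self) -> None:
        if self.direction not in ("protected", "deprotected"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")


@dataclass
class SimulationConfig:
    """Parameters of one simulated experiment. Defaults mirror the
    acquisition design the pipeline targets: 6 exposures, triplicates,
    two conditions, ~230-residue subunits, replicate noise of 0.4% RDU
    (so the default x4 effect threshold sits near 1.6%), 95% D2O."""

    proteins: Optional[list[tuple[str, str]]] = None  # (id, sequence); generated if None
    n_proteins: int = 4
    protein_length: int = 230
    proline_fraction: float = 0.04
    exposures: tuple[float, ...] = (0.0, 0.5, 1.0, 5.0, 10.0, 30.0)
    replicates: int = 3
    conditions: tuple[str, str] = ("alone", "complex")   # (reference, treatment)
    peptides_per_protein: Optional[int] = None           # default ~2.5x length/mean_length
    peptide_mean_length: float = 12.0
    peptide_sd_length: float = 4.0
    peptide_min_length: int = 6
    layout: str = "random"                               # 'random' or 'tiling'
    k_min: float = 1e-2                                  # intrinsic rate span, min^-1
    k_max: float = 1e1
    effect_regions: list[EffectRegion] = field(default_factory=list)
    sigma_rep: float = 0.004                             # replicate noise, RDU fraction
    d2o_fraction: float = 0.95
    back_exchange: float = 1.0                           # retention factor beta in (0, 1]
    charge_states: tuple[int, ...] = (2, 3)
    charge_alpha: float = 2.0                            # Dirichlet concentration
    centroid_jitter_da: float = 0.02                     # per-ion jitter, Da (0 disables)
    base_intensity: float = 1e5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.d2o_fraction <= 1):
            raise ValueError("d2o_fraction must be in (0, 1]")
        if not (0 < self.back_exchange <= 1):
            raise ValueError("back_exchange must be in (0, 1]")
        if self.sigma_rep < 0 or self.centroid_jitter_da < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.k_min <= 0 or self.k_max < self.k_min:
            raise ValueError("need 0 < k_min <= k_max")
        if self.layout not in ("random", "tiling"):
            raise ValueError(f"unknown peptide layout {self.layout!r}")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect_regions"] = [dataclasses.asdict(r) for r in self.effect_regions]
        return d


@dataclass
class RegionTruth:
    """An effect region with its true mean deltaRDU profile (fraction,
    treatment minus reference, per exposure, averaged over the region's
    non-proline residues)."""

    region: EffectRegion
    delta_profile: dict[float, float]


@dataclass
class GroundTruth:
    """Designated true-effect regions of a simulated dataset."""

    regions: list[RegionTruth]

    def regions_for(self, protein_id: str) -> list[RegionTruth]:
        return [r for r in self.regions if r.region.protein_id == protein_id]

    def to_json(self, path: str | Path) -> None:
        payload = [{
            "protein": rt.region.protein_id,
            "start": rt.region.start,
            "end": rt.region.end,
            "direction": rt.region.direction,
            "fold": rt.region.fold,
            "delta_profile": {f"{t:g}": v for t, v in rt.delta_profile.items()},
        } for rt in self.regions]
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SimulatedDataset:
    """Everything the generator knows about one simulated experiment."""

    ions: pd.DataFrame                 # canonical ion table
    truth: GroundTruth
    proteins: dict[str, ProteinSequence]
    peptide_truth: pd.DataFrame        # noise-free per-peptide uptake and delta
    config: SimulationConfig


def random_proteins(rng: np.random.Generator, n: int, length: int,
                    proline_fraction: float) -> list[tuple[str, str]]:
    """Random amino-acid sequences with a controlled proline content."""
    out = []
    for i in range(n):
        seq = rng.choice(list(_AA_NO_P), size=length)
        is_pro = rng.random(length) < proline_fraction
        is_pro[0] = False  # keep position 1 informative for the amide count
        seq[is_pro] = "P"
        out.append((f"SUB{i + 1}", "".join(seq)))
    return out


def _peptide_layout(rng: np.random.Generator, length: int,
                    cfg: SimulationConfig) -> list[tuple[int, int]]:
    """Peptide intervals (1-based inclusive) for one protein."""
    if cfg.layout == "tiling":
        L = int(cfg.peptide_mean_length)
        step = max(L // 2, 1)
        peps = [(s, min(s + L - 1, length))
                for s in range(1, length - cfg.peptide_min_length + 2, step)]
        # nested half-length peptides so the shortest-peptide rule is exercised
        half = max(L // 2, cfg.peptide_min_length)
        peps += [(s, min(s + half - 1, length))
                 for s in range(1, length - half + 2, L)]
        return sorted(set(peps))
    n_pep = cfg.peptides_per_protein or max(
        10, round(2.5 * length / cfg.peptide_mean_length))
    peps = set()
    while len(peps) < n_pep:
        ln = int(np.clip(round(rng.normal(cfg.peptide_mean_length, cfg.peptide_sd_length)),
                         cfg.peptide_min_length, length))
        start = int(rng.integers(1, length - ln + 2))
        peps.add((start, start + ln - 1))
    return sorted(peps)


def _true_uptake(k_eff: np.ndarray, t: float, beta: float, f_d: float) -> float:
    """Closed-form mean fractional uptake over exchangeable residues."""
    if t == 0:
        return 0.0
    return float(beta * f_d * np.mean(1.0 - np.exp(-k_eff * t)))


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the ion table and ground truth for one experiment."""
    rng = np.random.default_rng(config.seed)
    ref, treat = config.conditions

    prot_defs = config.proteins or random_proteins(
        rng, config.n_proteins, config.protein_length, config.proline_fraction)
    proteins = {pid: ProteinSequence(pid, seq) for pid, seq in prot_defs}

    for region in config.effect_regions:
        if region.protein_id not in proteins:
            raise ValueError(f"effect region references unknown protein "
                             f"{region.protein_id!r}")
        prot = proteins[region.protein_id]
        if not prot.contains_interval(region.start, region.end):
            raise ValueError(f"effect region {region.start}-{region.end} outside "
                             f"protein {region.protein_id!r}")

    rows: list[tuple] = []
    truth_regions: list[RegionTruth] = []
    pep_truth_rows: list[dict] = []
    nonzero = [t for t in config.exposures if t > 0]

    for pid, seq in prot_defs:
        L = len(seq)
        log_k = rng.uniform(np.log10(config.k_min), np.log10(config.k_max), L)
        k_int = 10.0 ** log_k
        pf = {ref: np.ones(L), treat: np.ones(L)}
        for region in config.effect_regions:
            if region.protein_id != pid:
                continue
            sl = slice(region.start - 1, region.end)
            cond = treat if region.direction == "protected" else ref
            pf[cond][sl] *= region.fold
            non_pro = np.array([seq[i] != "P" and i >= region.start - 1
                                for i in range(region.start - 1, region.end)])
            idx = np.arange(region.start - 1, region.end)[non_pro]
            profile = {}
            for t in config.exposures:
                ut = _true_uptake(k_int[idx] / pf[treat][idx], t,
                                  config.back_exchange, config.d2o_fraction)
                ur = _true_uptake(k_int[idx] / pf[ref][idx], t,
                                  config.back_exchange, config.d2o_fraction)
                profile[t] = ut - ur
            truth_regions.append(RegionTruth(region, profile))

        for (p_start, p_end) in _peptide_layout(rng, L, config):
            pep_seq = seq[p_start - 1:p_end]
            n_exch = count_exchangeable_amides(pep_seq)
            if n_exch < 1:
                continue
            # exchangeable residue indices (0-based in protein coordinates)
            exch_idx = np.array([
                p_start - 1 + j for j in range(1, len(pep_seq))
                if pep_seq[j] != "P"])
            n_charge = int(rng.choice(config.charge_states))
            charges = list(range(1, n_charge + 1)) if n_charge <= 1 else \
                list(range(2, 2 + n_charge))
            weights = rng.dirichlet(np.full(n_charge, config.charge_alpha))
            u_by_cond = {}
            for cond in (ref, treat):
                k_eff = k_int[exch_idx] / pf[cond][exch_idx]
                u_by_cond[cond] = {t: _true_uptake(
                    k_eff, t, config.back_exchange, config.d2o_fraction)
                    for t in config.exposures}
            for t in config.exposures:
                pep_truth_rows.append({
                    "protein": pid, "start": p_start, "end": p_end,
                    "sequence": pep_seq, "exposure": t,
                    "u_ref": u_by_cond[ref][t], "u_treat": u_by_cond[treat][t],
                    "delta": u_by_cond[treat][t] - u_by_cond[ref][t],
                })
            for cond in (ref, treat):
                for t in config.exposures:
                    u = u_by_cond[cond][t]
                    for r in range(config.replicates):
                        if t == 0:
                            rdu_obs = 0.0
                        else:
                            rdu_obs = float(np.clip(
                                u + rng.normal(0.0, config.sigma_rep), 0.0, 1.0))
                        uptake_da = rdu_obs * n_exch
                        total_int = config.base_intensity * float(
                            rng.lognormal(0.0, 0.3))
                        for ci, (z, w) in enumerate(zip(charges, weights)):
                            ion_uptake = uptake_da
                            if t > 0 and config.centroid_jitter_da > 0:
                                ion_uptake = max(0.0, uptake_da + float(
                                    rng.normal(0.0, config.centroid_jitter_da)))
                            rows.append((pid, p_start, p_end, pep_seq, z, cond,
                                         t, f"R{r + 1}", total_int * w, ion_uptake))

    ions = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    return SimulatedDataset(
        ions=ions,
        truth=GroundTruth(truth_regions),
        proteins=proteins,
        peptide_truth=pd.DataFrame(pep_truth_rows),
        config=config,
    )


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the canonical CSV, FASTA, ground-truth JSON and config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ions": out / "ions.csv",
        "fasta": out / "proteins.fasta",
        "truth": out / "ground_truth.json",
        "config": out / "sim_config.json",
    }
    write_ion_table(dataset.ions, paths["ions"])
    write_fasta(dataset.proteins, paths["fasta"])
    dataset.truth.to_json(paths["truth"])
    paths["config"].write_text(json.dumps(dataset.config.to_dict(), indent=1))
    return paths


def benchmark_recovery(
    truth: GroundTruth,
    consolidations: dict[str, "ResidueConsolidation"],
    boundary_margin: int = 0,
) -> dict:
    """Residue-level confusion of regulated calls against ground truth.

    Residues with consolidated status ``no-data`` are excluded (they are
    undetectable by construction). A residue is truth-positive when it
    lies inside an effect region, predicted-positive when its status is
    ``value`` (i.e. a regulated peptide supplied it). Sign accuracy is
    the fraction of true positives whose sign matches the region
    direction (protected -> negative deltaRDU).

    Peptide-level signal bleeds past region edges by up to one peptide
    length: a peptide overlapping a region by a single residue carries a
    genuinely non-zero deltaRDU and, once called, paints its whole
    extent. ``boundary_margin`` excludes residues within that many
    positions outside a region from the negative set (they are neither
    false nor true negatives); set it to the maximum peptide length to
    score region recovery itself rather than edge resolution.
    """
    from .consolidate import STATUS_NO_DATA, STATUS_VALUE

    known = set(consolidations)
    for rt in truth.regions:
        if rt.region.protein_id not in known:
            raise ValueError(f"no consolidation for protein "
                             f"{rt.region.protein_id!r} named in the truth")
    tp = fp = fn = tn = 0
    sign_ok = sign_total = 0
    for pid, cons in consolidations.items():
        truth_mask = np.zeros(cons.length, dtype=bool)
        shoulder = np.zeros(cons.length, dtype=bool)
        direction = np.zeros(cons.length)
        for rt in truth.regions_for(pid):
            i0 = rt.region.start - cons.numbering_offset
            i1 = rt.region.end - cons.numbering_offset + 1
            truth_mask[i0:i1] = True
            if boundary_margin > 0:
                shoulder[max(i0 - boundary_margin, 0):i0] = True
                shoulder[i1:i1 + boundary_margin] = True
        shoulder &= ~truth_mask
        detectable = cons.status != STATUS_NO_DATA
        predicted = cons.status == STATUS_VALUE
        negatives = detectable & ~truth_mask & ~shoulder
        tp += int((detectable & truth_mask & predicted).sum())
        fn += int((detectable & truth_mask & ~predicted).sum())
        fp += int((negatives & predicted).sum())
        tn += int((negatives & ~predicted).sum())
        for rt in truth.regions_for(pid):
            sl = slice(rt.region.start - cons.numbering_offset,
                       rt.region.end - cons.numbering_offset + 1)
            direction[sl] = -1.0 if rt.region.direction == "protected" else 1.0
        hits = detectable & truth_mask & predicted
        sign_total += int(hits.sum())
        sign_ok += int((np.sign(cons.values[hits]) == direction[hits]).sum())
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "false_positive_rate": fp / (fp + tn) if fp + tn else float("nan"),
        "sign_accuracy": sign_ok / sign_total if sign_total else float("nan"),
    }
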