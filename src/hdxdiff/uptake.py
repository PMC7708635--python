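"""Relative deuterium uptake (RDU) computation and kinetic curves.

The measured deuterium uptake of each ion (in Da) is normalized by the
peptide's theoretical maximum — the number of exchangeable backbone
amides, i.e. every residue except prolines and the peptide's first
residue — after intensity-weighted averaging over the charge states
observed for that peptide/condition/exposure/replicate. RDU is stored
as a fraction in [0, 1]; reports and thresholds use percent.

No back-exchange correction is applied: RDU is relative to the
all-exchanged theoretical maximum. ``d2o_fraction`` defaults to 1.0
accordingly and exists for simulator round-trips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PEPTIDE_KEY

#: Weighted relative uptake above 1 by more than this factor indicates an
#: inconsistent theoretical maximum and is an error; values within the
#: band are clamped to 1 with a warning.
RDU_CLAMP_BAND = 0.05


@dataclass(frozen=True)
class MaxUptake:
    """Theoretical maximum uptake of a peptide: its count of exchangeable
    backbone amides."""

    sequence: str
    n_exchangeable: int


def count_exchangeable_amides(sequence: str, n_term_exclusions: int = 1) -> int:
    """Number of exchangeable backbone amides of a peptide.

    Prolines (no amide hydrogen) and the first ``n_term_exclusions``
    residues (fast back exchange at the free N-terminus) do not count.

    >>> count_exchangeable_amides("ADSRATAGAY")
    9
    >>> count_exchangeable_amides("PEPTIDE")
    5
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    if n_term_exclusions < 1:
        raise ValueError("n_term_exclusions must be >= 1")
    tail = sequence[n_term_exclusions:].upper()
    return max(len(tail) - tail.count("P"), 0)


def max_uptake(sequence: str, n_term_exclusions: int = 1) -> MaxUptake:
    return MaxUptake(sequence, count_exchangeable_amides(sequence, n_term_exclusions))


def peptide_rdu(
    uptakes_da: Sequence[float],
    intensities: Sequence[float],
    n_exchangeable: int,
    d2o_fraction: float = 1.0,
) -> float:
    """Intensity-weighted relative deuterium uptake of one
    peptide/condition/exposure/replicate from its ion observations.

    rdu = sum(I_i * u_i) / sum(I_i) / (N_exch * f_D)

    Invariant under uniform rescaling of the intensities; reduces to the
    simple mean of per-ion relative uptakes when intensities are equal.
    """
    u = np.asarray(uptakes_da, dtype=float)
    w = np.asarray(intensities, dtype=float)
    if u.size == 0:
        raise ValueError("no ions supplied")
    total = w.sum()
    if total <= 0:
        raise ValueError("total ion intensity must be > 0")
    if n_exchangeable <= 0:
        raise ValueError("peptide has no exchangeable amides")
    rdu = float((u * w).sum() / total / (n_exchangeable * d2o_fraction))
    if rdu > 1 + RDU_CLAMP_BAND:
        raise ValueError(
            f"relative uptake {rdu:.3f} exceeds theoretical maximum by more "
            f"than {RDU_CLAMP_BAND:.0%}: inconsistent n_exchangeable?"
        )
    if rdu > 1:
        warnings.warn(f"relative uptake {rdu:.4f} clamped to 1", stacklevel=2)
        rdu = 1.0
    return rdu


def compute_rdu_table(
    ions: pd.DataFrame,
    d2o_fraction: float = 1.0,
    n_term_exclusions: int = 1,
) -> pd.DataFrame:
    """Collapse a canonical ion table to per-peptide RDU records.

    Groups ions by peptide/state/exposure/replicate, averages their
    deuterium uptake weighted by intensity and divides by the theoretical
    maximum. Returns a long table with columns
    ``protein,start,end,sequence,state,exposure,replicate,rdu,n_exchangeable``.
    """
    if ions.empty:
        raise ValueError("empty ion table")
    keys = PEPTIDE_KEY + ["state", "exposure", "replicate"]
    df = ions.copy()
    n_exch = df["sequence"].map(
        lambda s: count_exchangeable_amides(s, n_term_exclusions))
    if (n_exch <= 0).any():
        bad = df.loc[n_exch <= 0, "sequence"].unique()
        raise ValueError(f"peptides with no exchangeable amides: {list(bad)[:5]}")
    df["_n_exch"] = n_exch
    df["_wu"] = df["uptake"] * df["intensity"]
    g = df.groupby(keys, sort=True, as_index=False).agg(
        _wu=("_wu", "sum"),
        _w=("intensity", "sum"),
        _n_exch=("_n_exch", "first"),
    )
    if (g["_w"] <= 0).any():
        raise ValueError("group with zero total intensity")
    rdu = g["_wu"] / g["_w"] / (g["_n_exch"] * d2o_fraction)
    over = rdu > 1 + RDU_CLAMP_BAND
    if over.any():
        raise ValueError(
            f"{int(over.sum())} peptide groups exceed the theoretical maximum "
            f"by more than {RDU_CLAMP_BAND:.0%}"
        )
    clamped = rdu > 1
    if clamped.any():
        warnings.warn(
            f"{int(clamped.sum())} relative uptakes in (1, 1+{RDU_CLAMP_BAND}] "
            "clamped to 1", stacklevel=2)
        rdu = rdu.clip(upper=1.0)
    out = g[keys].copy()
    out["rdu"] = rdu
    out["n_exchangeable"] = g["_n_exch"]
    return out


def build_kinetics(records: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean kinetic curves from a long RDU table.

    Returns one row per peptide/state/exposure with ``mean_rdu``,
    ``sd_rdu`` (sample SD, n-1 denominator; NaN for singleton groups,
    which are flagged in the ``singleton`` column) and ``n_rep``.
    """
    keys = PEPTIDE_KEY + ["state", "exposure", "replicate"]
    if records.duplicated(subset=keys).any():
        dup = records[records.duplicated(subset=keys, keep=False)]
        raise ValueError(
            f"duplicate (peptide, state, exposure, replicate) keys: "
            f"{dup[keys].head(3).to_dict('records')}"
        )
    gkeys = PEPTIDE_KEY + ["state", "exposure"]
    g = records.groupby(gkeys, sort=True, as_index=False).agg(
        mean_rdu=("rdu", "mean"),
        sd_rdu=("rdu", lambda x: x.std(ddof=1)),
        n_rep=("rdu", "size"),
    )
    g["singleton"] = g["n_rep"] == 1
    return g


def sum_rdu(curve: Mapping[float, float] | pd.DataFrame, exclude_t0: bool = True) -> float:
    """Sum of mean RDU (or mean deltaRDU) over exposure times.

    ``curve`` maps exposure (min) to the replicate-mean value, or is a
    kinetic-curve frame with ``exposure`` and ``mean_rdu`` columns for
    one peptide/state. The T0 reference (exposure 0) is excluded by
    default; it is identically zero by construction so this only matters
    for differential curves with asymmetric T0 handling.
    """
    if isinstance(curve, pd.DataFrame):
        items = list(zip(curve["exposure"], curve["mean_rdu"]))
    else:
        items = list(curve.items())
    if not any(t > 0 for t, _ in items):
        raise ValueError("curve has no non-zero exposure")
    return float(sum(v for t, v in items if (t > 0 or not exclude_t0)))
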