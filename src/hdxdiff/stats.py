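"""Per-peptide differential statistics for two-condition HDX kinetics.

A peptide is called regulated between two conditions when it passes both
of two criteria:

1. the Benjamini-Hochberg-corrected p-value of the condition main effect
   in a two-factor ANOVA (condition x categorical exposure, type-III
   condition effect under sum-to-zero contrasts) is <= ``alpha``
   (default 0.01), and
2. the absolute difference of replicate-mean RDU between the conditions
   exceeds an effect-size threshold at ``k`` successive exposure times
   (default 3), with a consistent sign across that window.

The effect-size threshold is data driven: ``multiplier`` (default 4)
times the dataset-wide mean replicate dispersion of RDU. With the
default estimator the dispersion is the mean over all
(peptide, condition, exposure > 0) groups of the replicate sample SD;
the mean pairwise absolute difference is available as an alternative
estimator and both are echoed in run reports.

The T0 reference (exposure 0, RDU identically 0, zero variance) is
excluded from the ANOVA and from the persistence rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .io import PEPTIDE_KEY

#: Residual sums of squares below this are treated as an exact fit
#: (noise-free data): the condition p-value degenerates to 0 or 1.
_SS_EPS = 1e-24


@dataclass
class ThresholdSpec:
    """The dual significance thresholds of a differential comparison."""

    alpha: float = 0.01            # corrected-p cutoff (inclusive)
    multiplier: float = 4.0        # effect threshold = multiplier * dispersion
    dispersion: float = 0.0        # dataset mean replicate dispersion of RDU (fraction)
    k_successive: int = 3          # required run length of exceeding exposures
    effect_threshold: float = 0.0  # fraction RDU
    estimator: str = "sd"          # 'sd' or 'pairwise_mad'
    dispersion_sd: float = float("nan")           # both estimators, for the run report
    dispersion_pairwise_mad: float = float("nan")

    @property
    def effect_threshold_percent(self) -> float:
        return 100.0 * self.effect_threshold

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "multiplier": self.multiplier,
            "dispersion_fraction": self.dispersion,
            "dispersion_sd_fraction": self.dispersion_sd,
            "dispersion_pairwise_mad_fraction": self.dispersion_pairwise_mad,
            "k_successive": self.k_successive,
            "effect_threshold_fraction": self.effect_threshold,
            "effect_threshold_percent": self.effect_threshold_percent,
            "estimator": self.estimator,
        }


def _pairwise_mad(x: np.ndarray) -> float:
    """Mean absolute difference over all unordered replicate pairs."""
    n = len(x)
    diffs = [abs(x[i] - x[j]) for i in range(n) for j in range(i + 1, n)]
    return float(np.mean(diffs))


def effect_size_threshold(
    records: pd.DataFrame,
    multiplier: float = 4.0,
    alpha: float = 0.01,
    k_successive: int = 3,
    estimator: str = "sd",
) -> ThresholdSpec:
    """Dataset-wide effect-size threshold for differential calls.

    ``records`` is a long RDU table (one row per
    peptide/state/exposure/replicate, ``rdu`` column). The dispersion is
    the mean replicate spread over all groups with >= 2 replicates at
    non-zero exposure; the threshold is ``multiplier`` times that.
    """
    if estimator not in ("sd", "pairwise_mad"):
        raise ValueError(f"unknown dispersion estimator {estimator!r}")
    df = records[records["exposure"] > 0]
    groups = df.groupby(PEPTIDE_KEY + ["state", "exposure"])["rdu"]
    sds, mads = [], []
    for _, x in groups:
        if len(x) >= 2:
            arr = x.to_numpy(dtype=float)
            sds.append(arr.std(ddof=1))
            mads.append(_pairwise_mad(arr))
    if not sds:
        raise ValueError("no group with >= 2 replicates at exposure > 0")
    sd_disp = float(np.mean(sds))
    mad_disp = float(np.mean(mads))
    dispersion = sd_disp if estimator == "sd" else mad_disp
    return ThresholdSpec(
        alpha=alpha,
        multiplier=multiplier,
        dispersion=dispersion,
        k_successive=k_successive,
        effect_threshold=multiplier * dispersion,
        estimator=estimator,
        dispersion_sd=sd_disp,
        dispersion_pairwise_mad=mad_disp,
    )


def _balanced_condition_p(arr: np.ndarray) -> float:
    """Condition main-effect p of a balanced two-way layout.

    ``arr`` has shape (2 conditions, n_exposures, n_replicates) with no
    missing cells. On a balanced design the classical two-way ANOVA
    partition equals the type-III test under sum-to-zero contrasts.
    """
    a, b, n = arr.shape
    grand = arr.mean()
    mean_a = arr.mean(axis=(1, 2))
    mean_b = arr.mean(axis=(0, 2))
    mean_ab = arr.mean(axis=2)
    ss_a = b * n * ((mean_a - grand) ** 2).sum()
    ss_e = ((arr - mean_ab[:, :, None]) ** 2).sum()
    df_e = a * b * (n - 1)
    if df_e <= 0:
        return float("nan")
    if ss_e < _SS_EPS:
        return 0.0 if ss_a > _SS_EPS else 1.0
    f = (ss_a / (a - 1)) / (ss_e / df_e)
    return float(sps.f.sf(f, a - 1, df_e))


def _balanced_condition_p_batch(arr: np.ndarray) -> np.ndarray:
    """Vectorized :func:`_balanced_condition_p` over axis 0 of an array
    with shape (n_peptides, 2, n_exposures, n_replicates)."""
    _, a, b, n = arr.shape
    grand = arr.mean(axis=(1, 2, 3))
    mean_a = arr.mean(axis=(2, 3))
    mean_ab = arr.mean(axis=3)
    ss_a = b * n * ((mean_a - grand[:, None]) ** 2).sum(axis=1)
    ss_e = ((arr - mean_ab[..., None]) ** 2).sum(axis=(1, 2, 3))
    df_e = a * b * (n - 1)
    p = np.full(arr.shape[0], np.nan)
    exact = ss_e < _SS_EPS
    p[exact] = np.where(ss_a[exact] > _SS_EPS, 0.0, 1.0)
    ok = ~exact
    with np.errstate(invalid="ignore"):
        f = (ss_a[ok] / (a - 1)) / (ss_e[ok] / df_e)
    p[ok] = sps.f.sf(f, a - 1, df_e)
    return p


def anova_condition_effect(observations: pd.DataFrame) -> Optional[float]:
    """Raw p-value of the condition effect for one peptide.

    ``observations`` holds replicate RDU values for one peptide in two
    conditions, columns ``state``, ``exposure``, ``rdu``. The model is
    RDU ~ condition + exposure(categorical) + condition:exposure with
    sum-to-zero contrasts; the type-III p of the condition main effect is
    returned. T0 rows are dropped. Returns ``None`` when the peptide is
    untestable (< 2 shared non-zero exposures with >= 2 replicates each
    per condition, or no residual degrees of freedom).
    """
    df = observations[observations["exposure"] > 0]
    states = sorted(df["state"].unique())
    if len(states) != 2:
        return None
    counts = df.groupby(["state", "exposure"])["rdu"].size().unstack("state")
    shared = counts.dropna()
    shared = shared[(shared >= 2).all(axis=1)]
    if len(shared) < 2:
        return None
    df = df[df["exposure"].isin(shared.index)]
    n_cells = df.groupby(["state", "exposure"]).size()
    if df.shape[0] - 2 * len(shared.index) <= 0:
        return None
    if n_cells.nunique() == 1:
        n = int(n_cells.iloc[0])
        exposures = sorted(shared.index)
        arr = np.empty((2, len(exposures), n))
        for i, s in enumerate(states):
            for j, t in enumerate(exposures):
                arr[i, j, :] = df.loc[
                    (df["state"] == s) & (df["exposure"] == t), "rdu"
                ].to_numpy()
        return _balanced_condition_p(arr)
    return _typ3_condition_p(df)


def _typ3_condition_p(df: pd.DataFrame) -> Optional[float]:
    """Type-III condition p via OLS with sum contrasts (unbalanced path).

    Rank deficiency is tolerated: aliased terms are absorbed by the
    pseudo-inverse fit, mirroring ``singular.ok`` behaviour.
    """
    data = df.copy()
    data["exposure_cat"] = data["exposure"].astype(str)
    model = ols("rdu ~ C(state, Sum) * C(exposure_cat, Sum)", data=data).fit()
    if model.df_resid <= 0:
        return None
    table = anova_lm(model, typ=3)
    return float(table.loc["C(state, Sum)", "PR(>F)"])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order preserving.

    NaN entries (untestable peptides) are passed through and do not
    count toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    finite = ~np.isnan(p)
    if finite.any() and ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def successive_exceedance(
    deltas: Sequence[float],
    threshold: float,
    k: int = 3,
    require_same_sign: bool = True,
) -> Optional[tuple[int, ...]]:
    """Earliest run of ``k`` consecutive exposures whose |delta| exceeds
    ``threshold`` (strictly), sharing one sign if ``require_same_sign``.

    ``deltas`` are deltaRDU values ordered by ascending exposure, T0
    excluded. Returns the tuple of positions of the qualifying window,
    or ``None`` (also when fewer than ``k`` values are supplied).
    """
    d = np.asarray(deltas, dtype=float)
    if len(d) < k:
        return None
    for i in range(len(d) - k + 1):
        w = d[i:i + k]
        if np.any(np.isnan(w)) or not np.all(np.abs(w) > threshold):
            continue
        if require_same_sign and not (np.all(w > 0) or np.all(w < 0)):
            continue
        return tuple(range(i, i + k))
    return None


@dataclass
class DifferentialResult:
    """Two-condition comparison outcome for one peptide."""

    protein: str
    start: int
    end: int
    sequence: str
    reference: str
    treatment: str
    exposures: tuple[float, ...]            # non-zero exposures compared
    deltas: tuple[float, ...]               # mean(treat) - mean(ref), fraction RDU
    p_raw: float
    p_corrected: float
    sum_delta: float                        # sum of deltas, T0 excluded
    regulated: str                          # 'up' / 'down' / 'not-regulated' / 'untestable'
    qualifying_run: Optional[tuple[int, ...]] = None
    status: str = "tested"                  # 'tested' / 'untestable' / 'one-condition'

    @property
    def is_regulated(self) -> bool:
        return self.regulated in ("up", "down")


def call_regulated(
    deltas: Sequence[float],
    p_corrected: float,
    thresholds: ThresholdSpec,
    require_same_sign: bool = True,
) -> tuple[str, Optional[tuple[int, ...]]]:
    """Regulation call from the dual criterion: corrected p <= alpha
    (inclusive) AND a qualifying successive-exceedance run."""
    run = successive_exceedance(
        deltas, thresholds.effect_threshold, thresholds.k_successive,
        require_same_sign=require_same_sign)
    if np.isnan(p_corrected) or p_corrected > thresholds.alpha or run is None:
        return "not-regulated", run
    sign = np.sign(np.asarray(deltas, dtype=float)[list(run)]).mean()
    return ("up" if sign > 0 else "down"), run


def differential_analysis(
    records: pd.DataFrame,
    reference: str,
    treatment: str,
    thresholds: ThresholdSpec,
    require_same_sign: bool = True,
) -> pd.DataFrame:
    """Full differential comparison of two conditions.

    ``records`` is a long RDU table covering both conditions. Per shared
    peptide the per-exposure deltaRDU (treatment minus reference on
    replicate means), the raw ANOVA condition p, the BH-corrected p
    (pooled across every testable peptide of the comparison), the summed
    delta (T0 excluded) and the regulation call are computed.

    Peptides observed in only one condition are carried with status
    ``one-condition``; peptides failing the ANOVA design requirements
    with status ``untestable``. Output row order is by peptide key, so
    the result is invariant to input ordering.
    """
    df = records[records["state"].isin([reference, treatment])].copy()
    present = sorted(df["state"].unique())
    if reference not in present or treatment not in present:
        missing = {reference, treatment} - set(present)
        raise ValueError(f"condition(s) {sorted(missing)} absent from the data")

    nz = df[df["exposure"] > 0]
    exposures = np.array(sorted(nz["exposure"].unique()))

    # replicate-complete pivot: (peptide) x (state, exposure, replicate)
    pivot = nz.pivot_table(
        index=PEPTIDE_KEY, columns=["state", "exposure", "replicate"],
        values="rdu", aggfunc="first", sort=True)
    replicates = sorted(nz["replicate"].unique())
    full_cols = pd.MultiIndex.from_product([ [reference, treatment], exposures, replicates])
    pivot = pivot.reindex(columns=full_cols)

    complete = pivot.notna().all(axis=1)
    p_raw = pd.Series(np.nan, index=pivot.index)
    status = pd.Series("untestable", index=pivot.index)

    # fast vectorized path for the complete balanced design
    if complete.any():
        arr = pivot.loc[complete].to_numpy().reshape(
            (-1, 2, len(exposures), len(replicates)))
        p_raw.loc[complete] = _balanced_condition_p_batch(arr)
        status.loc[complete] = "tested"

    # fallback: per-peptide testability assessment on the long data
    if (~complete).any():
        by_pep = dict(tuple(nz.groupby(PEPTIDE_KEY)))
        for key in pivot.index[~complete]:
            obs = by_pep.get(key)
            if obs is None:
                continue
            if set(obs["state"].unique()) != {reference, treatment}:
                status.loc[key] = "one-condition"
                continue
            p = anova_condition_effect(obs)
            if p is not None:
                p_raw.loc[key] = p
                status.loc[key] = "tested"

    p_corr = pd.Series(bh_adjust(p_raw.to_numpy()), index=pivot.index)

    # per-exposure deltas on replicate means
    means = nz.groupby(PEPTIDE_KEY + ["state", "exposure"])["rdu"].mean()
    rows = []
    for key in pivot.index:
        deltas = []
        for t in exposures:
            try:
                mt = means.loc[key + (treatment, t)]
                mr = means.loc[key + (reference, t)]
                deltas.append(mt - mr)
            except KeyError:
                deltas.append(np.nan)
        deltas = np.asarray(deltas)
        pc = float(p_corr.loc[key])
        st = status.loc[key]
        if st == "tested":
            call, run = call_regulated(deltas, pc, thresholds, require_same_sign)
        else:
            call, run = st if st != "one-condition" else "untestable", None
        row = {
            "protein": key[0], "start": key[1], "end": key[2], "sequence": key[3],
            "reference": reference, "treatment": treatment,
            "p_raw": float(p_raw.loc[key]), "p_corrected": pc,
            "sum_delta": float(np.nansum(deltas)) if not np.all(np.isnan(deltas)) else np.nan,
            "regulated": call if st == "tested" else "untestable",
            "status": st,
            "run_start_exposure": exposures[run[0]] if run else np.nan,
        }
        for t, dv in zip(exposures, deltas):
            row[f"delta_{t:g}"] = dv
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(["protein", "start", "end", "sequence"]).reset_index(drop=True)


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot coordinates: summed deltaRDU vs -log10 corrected p."""
    tested = results[results["status"] == "tested"].copy()
    with np.errstate(divide="ignore"):
        tested["neg_log10_p_corrected"] = -np.log10(tested["p_corrected"])
    return tested[["protein", "start", "end", "sequence",
                   "sum_delta", "neg_log10_p_corrected", "regulated"]]
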