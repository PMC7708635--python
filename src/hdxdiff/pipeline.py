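"""End-to-end orchestration: read -> RDU -> statistics -> consolidation
-> exports, from a single run configuration.

Two entry points mirror the two analysis modes:

* :func:`run_single_state` maps the accessibility of one condition —
  per-residue summed RDU over the non-zero exposures, per-exposure
  heatmaps and structure attributes;
* :func:`run_differential` compares two conditions — per-peptide ANOVA
  with BH correction, the dual effect-size/persistence criterion,
  significance-masked consolidations and signed structure attributes
  (convention: deltaRDU = treatment - reference).

Every run writes a machine-readable report with the software version,
all effective parameters (including the computed effect threshold) and
per-stage counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consolidate import (ResidueConsolidation, consolidate,
                          consolidate_differential, export_structure_attributes,
                          heatmap_matrix, plot_heatmap)
from .io import (PEPTIDE_KEY, ParseReport, ProteinSequence, compute_coverage,
                 coverage_table, read_fasta, read_ion_table)
from .stats import ThresholdSpec, differential_analysis, effect_size_threshold, volcano_table
from .uptake import build_kinetics, compute_rdu_table

logger = logging.getLogger("hdxdiff")


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    ``ions`` / ``fasta`` may be paths or already-loaded objects (a
    canonical ion DataFrame / a mapping of protein id to
    :class:`ProteinSequence`).
    """

    ions: object = None
    fasta: object = None
    out_dir: Optional[str] = None
    reference: Optional[str] = None       # condition labels; deltaRDU = treatment - reference
    treatment: Optional[str] = None
    condition: Optional[str] = None       # single-state mode
    alpha: float = 0.01
    effect_multiplier: float = 4.0
    k_successive: int = 3
    dispersion_estimator: str = "sd"
    require_same_sign: bool = True
    d2o_fraction: float = 1.0
    schema: Optional[Mapping[str, str]] = None
    chain_map: Optional[Mapping[str, Sequence[str]]] = None
    attribute: str = "rdu"
    make_figures: bool = False
    seed: int = 0
    verbosity: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def parameters(self) -> dict:
        skip = {"ions", "fasta", "chain_map", "schema"}
        return {f.name: getattr(self, f.name)
                for f in dataclasses.fields(self) if f.name not in skip}


@dataclass
class RunReport:
    """Machine-readable account of one run: effective parameters,
    per-stage counts and accumulated warnings."""

    version: str = __version__
    parameters: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"not JSON serializable: {type(o)}")
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                         default=_default))


@dataclass
class RunResult:
    """In-memory outputs of a pipeline run."""

    rdu: pd.DataFrame
    kinetics: pd.DataFrame
    consolidations: dict[str, ResidueConsolidation]
    report: RunReport
    thresholds: Optional[ThresholdSpec] = None
    results: Optional[pd.DataFrame] = None   # differential mode only
    volcano: Optional[pd.DataFrame] = None
    paths: dict[str, Path] = field(default_factory=dict)


def _load_inputs(config: RunConfig) -> tuple[pd.DataFrame, dict[str, ProteinSequence],
                                             ParseReport]:
    if isinstance(config.ions, pd.DataFrame):
        ions, parse = config.ions, ParseReport(n_read=len(config.ions),
                                               n_kept=len(config.ions))
    elif config.ions is not None:
        ions, parse = read_ion_table(config.ions, schema=config.schema)
    else:
        raise ValueError("config.ions is required")
    if ions.empty:
        raise ValueError("empty ion table: nothing to analyse")
    if isinstance(config.fasta, Mapping):
        proteins = dict(config.fasta)
    elif config.fasta is not None:
        proteins = read_fasta(config.fasta)
    else:
        # fall back to peptide-implied bounds when no FASTA is supplied
        proteins = {}
        for pid, g in ions.groupby("protein"):
            length = int(g["end"].max())
            proteins[pid] = ProteinSequence(pid, "X" * length)
    return ions, proteins, parse


def _check_conditions(ions: pd.DataFrame, wanted: Sequence[str]) -> None:
    present = set(ions["state"].unique())
    missing = [c for c in wanted if c not in present]
    if missing:
        raise ValueError(f"condition(s) {missing} absent from the ion table "
                         f"(present: {sorted(present)})")


def _out(config: RunConfig) -> Optional[Path]:
    if config.out_dir is None:
        return None
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_single_state(config: RunConfig) -> RunResult:
    """Solvent-accessibility map of one condition.

    Consolidates, per protein, the per-residue sum of mean RDU over the
    non-zero exposures (shortest-peptide rule) and the per-exposure
    values feeding the heatmaps, and writes attribute exports plus the
    run report.
    """
    ions, proteins, parse = _load_inputs(config)
    condition = config.condition
    if condition is None:
        states = sorted(ions["state"].unique())
        if len(states) != 1:
            raise ValueError(f"config.condition required (table holds {states})")
        condition = states[0]
    _check_conditions(ions, [condition])
    ions = ions[ions["state"] == condition]

    rdu = compute_rdu_table(ions, d2o_fraction=config.d2o_fraction)
    kin = build_kinetics(rdu)

    report = RunReport(parameters={**config.parameters(), "condition": condition})
    report.warnings.extend(parse.warnings)
    report.counts.update({
        "rows_read": parse.n_read, "rows_dropped": parse.n_dropped,
        "rows_used": len(ions), "peptide_groups": len(rdu),
        "peptides": int(rdu.groupby(PEPTIDE_KEY).ngroups),
    })

    consolidations: dict[str, ResidueConsolidation] = {}
    per_exposure: dict[str, dict[float, ResidueConsolidation]] = {}
    sums = (kin[kin["exposure"] > 0]
            .groupby(PEPTIDE_KEY, as_index=False)["mean_rdu"].sum()
            .rename(columns={"mean_rdu": "sum_rdu"}))
    for pid, prot in proteins.items():
        sub = sums[sums["protein"] == pid]
        consolidations[pid] = consolidate(
            (((r["start"], r["end"]), r["sum_rdu"]) for _, r in sub.iterrows()), prot)
        per_exposure[pid] = {}
        for t, g in kin[kin["protein"] == pid].groupby("exposure"):
            per_exposure[pid][float(t)] = consolidate(
                (((r["start"], r["end"]), r["mean_rdu"]) for _, r in g.iterrows()), prot)
    report.counts["residues_covered"] = int(sum(
        (c.status != "no-data").sum() for c in consolidations.values()))

    result = RunResult(rdu=rdu, kinetics=kin, consolidations=consolidations,
                       report=report)
    out = _out(config)
    if out is not None:
        result.paths["rdu"] = out / "rdu.tsv"
        rdu.to_csv(result.paths["rdu"], sep="\t", index=False)
        result.paths["kinetics"] = out / "kinetics.tsv"
        kin.to_csv(result.paths["kinetics"], sep="\t", index=False)
        cov = coverage_table(
            compute_coverage(
                {(r["start"], r["end"]) for _, r in
                 rdu[rdu["protein"] == pid][["start", "end"]].iterrows()},
                prot)
            for pid, prot in proteins.items())
        result.paths["coverage"] = out / "coverage.tsv"
        cov.to_csv(result.paths["coverage"], sep="\t", index=False)
        cons_frame = pd.concat([c.to_frame() for c in consolidations.values()])
        result.paths["consolidation"] = out / "consolidation.tsv"
        cons_frame.to_csv(result.paths["consolidation"], sep="\t", index=False)
        result.paths["defattr"] = export_structure_attributes(
            list(consolidations.values()), out / "sum_rdu.defattr",
            "chimerax-defattr", config.chain_map, attribute=config.attribute)
        result.paths["viewer_csv"] = export_structure_attributes(
            list(consolidations.values()), out / "sum_rdu_viewer.csv",
            "hdx-viewer-csv", config.chain_map, attribute=config.attribute)
        if config.make_figures:
            for pid, prot in proteins.items():
                m = heatmap_matrix(per_exposure[pid], prot, vmin=0.0, vmax=1.0)
                result.paths[f"heatmap_{pid}"] = plot_heatmap(
                    m, out / f"heatmap_{pid}.png")
        result.paths["report"] = out / "run_report.json"
        report.to_json(result.paths["report"])
    return result


def run_differential(config: RunConfig) -> RunResult:
    """Differential comparison of two conditions (Fig. 1-style pipeline).

    Computes per-peptide deltaRDU kinetics and statistics, masks the
    consolidations by significance and writes signed attribute exports.
    Peptides covered in only one condition are carried as ``no-data``,
    never fatal.
    """
    if config.reference is None or config.treatment is None:
        raise ValueError("differential mode needs config.reference and config.treatment")
    ions, proteins, parse = _load_inputs(config)
    _check_conditions(ions, [config.reference, config.treatment])
    ions = ions[ions["state"].isin([config.reference, config.treatment])]

    rdu = compute_rdu_table(ions, d2o_fraction=config.d2o_fraction)
    kin = build_kinetics(rdu)
    thresholds = effect_size_threshold(
        rdu, multiplier=config.effect_multiplier, alpha=config.alpha,
        k_successive=config.k_successive, estimator=config.dispersion_estimator)
    results = differential_analysis(
        rdu, config.reference, config.treatment, thresholds,
        require_same_sign=config.require_same_sign)
    volcano = volcano_table(results)

    report = RunReport(parameters={**config.parameters(),
                                   "thresholds": thresholds.to_dict()})
    report.warnings.extend(parse.warnings)
    report.counts.update({
        "rows_read": parse.n_read, "rows_dropped": parse.n_dropped,
        "rows_used": len(ions),
        "peptides": len(results),
        "peptides_tested": int((results["status"] == "tested").sum()),
        "peptides_regulated": int(results["regulated"].isin(["up", "down"]).sum()),
    })

    consolidations = {pid: consolidate_differential(results, prot)
                      for pid, prot in proteins.items()}
    report.counts["residues_covered"] = int(sum(
        (c.status != "no-data").sum() for c in consolidations.values()))
    report.counts["residues_regulated"] = int(sum(
        (c.status == "value").sum() for c in consolidations.values()))

    result = RunResult(rdu=rdu, kinetics=kin, consolidations=consolidations,
                       report=report, thresholds=thresholds, results=results,
                       volcano=volcano)
    out = _out(config)
    if out is not None:
        pair = f"{config.treatment}_vs_{config.reference}"
        result.paths["results"] = out / f"differential_{pair}.tsv"
        results.to_csv(result.paths["results"], sep="\t", index=False)
        result.paths["volcano"] = out / f"volcano_{pair}.tsv"
        volcano.to_csv(result.paths["volcano"], sep="\t", index=False)
        cons_frame = pd.concat([c.to_frame() for c in consolidations.values()])
        result.paths["consolidation"] = out / f"consolidation_{pair}.tsv"
        cons_frame.to_csv(result.paths["consolidation"], sep="\t", index=False)
        result.paths["defattr"] = export_structure_attributes(
            list(consolidations.values()), out / f"sum_delta_{pair}.defattr",
            "chimerax-defattr", config.chain_map, attribute="sumDeltaRdu")
        result.paths["viewer_csv"] = export_structure_attributes(
            list(consolidations.values()), out / f"sum_delta_{pair}_viewer.csv",
            "hdx-viewer-csv", config.chain_map, attribute="sumDeltaRdu")
        if config.make_figures:
            lim = max(float(np.nanmax(np.abs(
                [c.values for c in consolidations.values()][0]))) if
                consolidations else 0.3, 1e-6)
            for pid, prot in proteins.items():
                m = heatmap_matrix({0.0: consolidations[pid]}, prot,
                                   vmin=-lim, vmax=lim)
                result.paths[f"heatmap_{pid}"] = plot_heatmap(
                    m, out / f"delta_heatmap_{pid}.png", cmap="coolwarm")
        result.paths["report"] = out / "run_report.json"
        report.to_json(result.paths["report"])
    return result
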