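"""Peptide-to-residue consolidation and structure-attribute export.

Overlapping peptides report redundant values for the residues they
share; to maximize spatial resolution each residue takes the value of
the *shortest* peptide covering it (ties broken by the smaller start,
for determinism). In differential mode only regulated peptides supply
values; residues covered solely by not-regulated peptides are marked
``not-significant`` (rendered grey downstream) and residues without any
testable coverage ``no-data`` (rendered black).

Per-residue values can be exported as ChimeraX ``defattr`` attribute
files or as a simple residue/chain/value/status CSV consumable by
HDX-viewer-style web tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import ProteinSequence

STATUS_VALUE = "value"
STATUS_NOT_SIGNIFICANT = "not-significant"
STATUS_NO_DATA = "no-data"


@dataclass
class ResidueConsolidation:
    """Per-residue consolidated values for one protein.

    Arrays are indexed 0..length-1; residue numbers are recovered via
    ``numbering_offset``. ``values`` is NaN wherever ``status`` is not
    ``value``; ``provenance`` names the peptide that supplied each value.
    """

    protein_id: str
    numbering_offset: int
    values: np.ndarray                    # float, NaN where no value
    status: np.ndarray                    # object array of status strings
    provenance: np.ndarray                # object array of peptide labels or None

    @property
    def length(self) -> int:
        return len(self.values)

    def residue_numbers(self) -> np.ndarray:
        return np.arange(self.length) + self.numbering_offset

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "protein": self.protein_id,
            "residue": self.residue_numbers(),
            "value": self.values,
            "status": self.status,
            "peptide": self.provenance,
        })


def _peptide_label(start: int, end: int) -> str:
    return f"{start}-{end}"


def consolidate(
    peptide_values: Iterable[tuple[tuple[int, int], float]],
    protein: ProteinSequence,
) -> ResidueConsolidation:
    """Map peptide-level values onto residues by the shortest-peptide rule.

    ``peptide_values`` yields ``((start, end), value)`` pairs in protein
    numbering. Each covered residue takes the value of the shortest
    covering peptide; among equal-length peptides the one with the
    smallest start wins. Uncovered residues are ``no-data``.
    """
    items = [((int(s), int(e)), float(v)) for (s, e), v in peptide_values]
    seen: dict[tuple[int, int], float] = {}
    for (s, e), v in items:
        if not protein.contains_interval(s, e):
            raise ValueError(
                f"peptide {s}-{e} outside protein {protein.protein_id!r} bounds")
        if (s, e) in seen and not np.isclose(seen[(s, e)], v, equal_nan=True):
            raise ValueError(
                f"conflicting values for duplicate peptide {s}-{e} of "
                f"{protein.protein_id!r}: {seen[(s, e)]} vs {v}")
        seen[(s, e)] = v

    n = protein.length
    values = np.full(n, np.nan)
    status = np.full(n, STATUS_NO_DATA, dtype=object)
    provenance = np.full(n, None, dtype=object)

    # paint longest-first so the shortest (and, within a length, the
    # smallest-start) peptide is painted last and wins
    order = sorted(seen.items(), key=lambda kv: (-(kv[0][1] - kv[0][0]), -kv[0][0]))
    off = protein.numbering_offset
    for (s, e), v in order:
        sl = slice(s - off, e - off + 1)
        values[sl] = v
        status[sl] = STATUS_VALUE
        provenance[sl] = _peptide_label(s, e)
    return ResidueConsolidation(protein.protein_id, off, values, status, provenance)


def consolidate_differential(
    results: pd.DataFrame,
    protein: ProteinSequence,
    value_col: str = "sum_delta",
) -> ResidueConsolidation:
    """Consolidate a differential-results table for one protein.

    Only regulated peptides contribute values (shortest-peptide rule
    applied among them); residues covered solely by tested-but-not-
    regulated peptides become ``not-significant``; residues without any
    tested coverage (including peptides seen in a single condition)
    remain ``no-data``.
    """
    df = results[results["protein"] == protein.protein_id]
    n = protein.length
    off = protein.numbering_offset
    tested_cov = np.zeros(n, dtype=bool)
    for _, row in df[df["status"] == "tested"].iterrows():
        tested_cov[row["start"] - off: row["end"] - off + 1] = True

    regulated = df[df["regulated"].isin(["up", "down"])]
    cons = consolidate(
        (((row["start"], row["end"]), row[value_col]) for _, row in regulated.iterrows()),
        protein,
    )
    grey = tested_cov & (cons.status == STATUS_NO_DATA)
    cons.status[grey] = STATUS_NOT_SIGNIFICANT
    return cons


def export_structure_attributes(
    cons: ResidueConsolidation | Sequence[ResidueConsolidation],
    path: str | Path,
    fmt: str = "chimerax-defattr",
    chain_map: Optional[Mapping[str, Sequence[str]]] = None,
    attribute: str = "rdu",
) -> Path:
    """Write per-residue values for structure coloring.

    ``chain_map`` maps each protein id to the chain letter(s) carrying it
    on the structure; multi-copy subunits list several chains and receive
    identical attributes on each. ``no-data`` residues are omitted;
    ``not-significant`` residues are written with a sentinel value chosen
    outside the data range and recorded in the file header.

    Formats: ``chimerax-defattr`` (attribute assignment lines
    ``/<chain>:<resnum>\\t<value>``) or ``hdx-viewer-csv``
    (``protein,chain,residue,value,status`` rows).
    """
    if fmt not in ("chimerax-defattr", "hdx-viewer-csv"):
        raise ValueError(f"unknown export format {fmt!r}")
    if isinstance(cons, ResidueConsolidation):
        cons = [cons]
    chain_map = chain_map or {c.protein_id: [chr(ord("A") + i)]
                              for i, c in enumerate(cons)}
    for c in cons:
        if c.protein_id not in chain_map:
            raise ValueError(f"chain_map missing protein {c.protein_id!r}")

    finite = np.concatenate([c.values[np.isfinite(c.values)] for c in cons]) \
        if cons else np.array([])
    if finite.size:
        lo, hi = float(finite.min()), float(finite.max())
        sentinel = lo - max(hi - lo, 1.0)
    else:
        sentinel = -999.0

    path = Path(path)
    lines: list[str] = []
    n_written = 0
    if fmt == "chimerax-defattr":
        lines.append(f"# not-significant sentinel value: {sentinel:g}")
        lines.append(f"attribute: {attribute}")
        lines.append("match mode: 1-to-1")
        lines.append("recipient: residues")
        for c in cons:
            for chain in chain_map[c.protein_id]:
                for i, res in enumerate(c.residue_numbers()):
                    if c.status[i] == STATUS_NO_DATA:
                        continue
                    v = c.values[i] if c.status[i] == STATUS_VALUE else sentinel
                    lines.append(f"\t/{chain}:{int(res)}\t{v:g}")
                    n_written += 1
        path.write_text("\n".join(lines) + "\n")
    else:
        rows = []
        for c in cons:
            for chain in chain_map[c.protein_id]:
                for i, res in enumerate(c.residue_numbers()):
                    if c.status[i] == STATUS_NO_DATA:
                        continue
                    v = c.values[i] if c.status[i] == STATUS_VALUE else sentinel
                    rows.append({"protein": c.protein_id, "chain": chain,
                                 "residue": int(res), "value": v,
                                 "status": c.status[i]})
                    n_written += 1
        pd.DataFrame(rows, columns=["protein", "chain", "residue", "value", "status"]) \
            .to_csv(path, index=False)
    if n_written == 0:
        warnings.warn(f"no residues with data exported to {path}", stacklevel=2)
    return path


def parse_defattr(path: str | Path) -> list[tuple[str, int, float]]:
    """Parse a defattr file back into (chain, residue, value) triples."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.startswith("\t"):
            continue
        spec, value = line.strip().split("\t")
        chain, res = spec.lstrip("/").split(":")
        out.append((chain, int(res), float(value)))
    return out


@dataclass
class HeatmapMatrix:
    """Residue x exposure grid of consolidated values for one protein."""

    protein_id: str
    numbering_offset: int
    exposures: tuple[float, ...]
    grid: np.ndarray          # shape (n_residues, n_exposures); NaN = no data
    vmin: float = 0.0
    vmax: float = 1.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def heatmap_matrix(
    consolidations: Mapping[float, ResidueConsolidation],
    protein: ProteinSequence,
    vmin: float = 0.0,
    vmax: float = 1.0,
) -> HeatmapMatrix:
    """Assemble per-exposure consolidations into a residue x exposure grid.

    ``no-data`` cells are NaN, distinct from a measured zero.
    """
    exposures = tuple(sorted(consolidations))
    grid = np.full((protein.length, len(exposures)), np.nan)
    for j, t in enumerate(exposures):
        c = consolidations[t]
        if c.length != protein.length:
            raise ValueError("consolidation length mismatch")
        grid[:, j] = np.where(c.status == STATUS_VALUE, c.values, np.nan)
    return HeatmapMatrix(protein.protein_id, protein.numbering_offset,
                         exposures, grid, vmin, vmax)


def plot_heatmap(matrix: HeatmapMatrix, path: str | Path, cmap: str = "viridis") -> Path:
    """Render a heatmap figure; no-data cells are shown as gaps."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4.0, matrix.shape[0] / 25), 2.5))
    masked = np.ma.masked_invalid(matrix.grid.T)
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad(color="black")
    im = ax.imshow(masked, aspect="auto", interpolation="nearest",
                   cmap=cm, vmin=matrix.vmin, vmax=matrix.vmax,
                   extent=(matrix.numbering_offset - 0.5,
                           matrix.numbering_offset + matrix.shape[0] - 0.5,
                           len(matrix.exposures) - 0.5, -0.5))
    ax.set_yticks(range(len(matrix.exposures)))
    ax.set_yticklabels([f"{t:g}" for t in matrix.exposures])
    ax.set_xlabel("residue")
    ax.set_ylabel("exposure (min)")
    ax.set_title(matrix.protein_id)
    fig.colorbar(im, ax=ax, label="RDU")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
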