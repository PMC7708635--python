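"""Reading and validation of ion-level HDX-MS tables and protein sequences.

The pipeline consumes curated ion observations — one row per peptide ×
charge state × condition × exposure time × replicate — in a CSV dialect
modelled on the "cluster" exports of vendor curation software (DynamX).
A configurable column mapping absorbs dialect variants; internally every
table uses the canonical schema of :data:`CANONICAL_COLUMNS`.

Coordinates are 1-based and inclusive on both ends throughout the
package, matching the convention used in HDX reports ("peptide 102-114").
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Canonical ion-table columns, in order.
CANONICAL_COLUMNS = [
    "protein",    # protein / subunit identifier
    "start",      # first residue of the peptide (1-based, inclusive)
    "end",        # last residue of the peptide (1-based, inclusive)
    "sequence",   # peptide sequence, 1-letter codes
    "charge",     # ion charge state (positive integer)
    "state",      # condition label (e.g. "alone", "complex")
    "exposure",   # deuteration time in minutes; 0 is the undeuterated reference
    "replicate",  # replicate label
    "intensity",  # MS intensity of the ion (arbitrary units)
    "uptake",     # deuterium uptake in Da relative to the undeuterated centroid
]

#: Columns identifying one peptide.
PEPTIDE_KEY = ["protein", "start", "end", "sequence"]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Negative uptake more extreme than this (Da) rejects the row; milder
#: negatives are treated as centroid noise around the T0 reference and
#: clamped to zero.
NEGATIVE_UPTAKE_TOLERANCE_DA = 0.15


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with its residue numbering.

    ``numbering_offset`` is the residue number of the first character of
    ``sequence`` (1 for full-length constructs).
    """

    protein_id: str
    sequence: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")
        bad = set(self.sequence.upper()) - STANDARD_AA - {"X"}
        if bad:
            raise ValueError(
                f"protein {self.protein_id!r}: non-standard residue codes {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def first_residue(self) -> int:
        return self.numbering_offset

    @property
    def last_residue(self) -> int:
        return self.numbering_offset + len(self.sequence) - 1

    def contains_interval(self, start: int, end: int) -> bool:
        return self.first_residue <= start <= end <= self.last_residue

    @property
    def has_ambiguous(self) -> bool:
        return "X" in self.sequence.upper()


@dataclass(frozen=True)
class IdentificationRecord:
    """Identification-level evidence for one peptide, used by the
    replicate/fragment/intensity filter applied before any uptake maths."""

    protein_id: str
    start: int
    end: int
    sequence: str
    replicate_count: int
    fragments_per_aa: float
    max_intensity: float

    def __post_init__(self) -> None:
        if self.replicate_count < 0:
            raise ValueError("replicate_count must be >= 0")
        if self.fragments_per_aa < 0:
            raise ValueError("fragments_per_aa must be >= 0")


@dataclass
class CoverageSummary:
    """Sequence-coverage statistics for one protein."""

    protein_id: str
    covered_fraction: float          # percent of residues covered by >=1 peptide
    redundancy: float                # mean number of peptides per covered residue
    uncovered_intervals: list[tuple[int, int]]  # maximal gaps, residue numbers


@dataclass
class ParseReport:
    """Outcome of reading an ion table: row counts, dropped rows with
    reasons, and non-fatal warnings."""

    n_read: int = 0
    n_kept: int = 0
    dropped: list[tuple[int, str]] = field(default_factory=list)  # (row index, reason)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped, columns=["row", "reason"])


def inclusive_length(start: int, end: int) -> int:
    """Number of residues in the inclusive interval ``start``..``end``.

    >>> inclusive_length(64, 106)
    43
    """
    if end < start:
        raise ValueError(f"end ({end}) < start ({start})")
    return end - start + 1


def read_fasta(path: str | Path, numbering_offset: int = 1) -> dict[str, ProteinSequence]:
    """Read protein sequences from a FASTA file.

    Returns a mapping of record id to :class:`ProteinSequence`. Sequences
    containing ``X`` are accepted but flagged via ``has_ambiguous``.
    """
    proteins: dict[str, ProteinSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        proteins[rec.id] = ProteinSequence(rec.id, str(rec.seq).upper(), numbering_offset)
    if not proteins:
        raise ValueError(f"no FASTA records in {path}")
    return proteins


def write_fasta(proteins: Mapping[str, ProteinSequence] | Iterable[ProteinSequence],
                path: str | Path) -> None:
    if isinstance(proteins, Mapping):
        proteins = proteins.values()
    with open(path, "w") as fh:
        for prot in proteins:
            fh.write(f">{prot.protein_id}\n")
            seq = prot.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_ion_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    max_bad_fraction: float = 0.01,
) -> tuple[pd.DataFrame, ParseReport]:
    """Read an ion-level CSV into the canonical schema.

    Parameters
    ----------
    path
        CSV file (comma separated, UTF-8, header row).
    schema
        Optional mapping ``{canonical name: column name in the file}`` for
        non-canonical dialects. Unmapped canonical names are looked up
        verbatim.
    max_bad_fraction
        If more than this fraction of rows fail numeric parsing the whole
        read fails (a systematically malformed table should not be
        silently decimated).

    Returns
    -------
    (table, report)
        ``table`` holds one row per retained ion observation, original row
        order preserved; ``report`` lists dropped rows with reasons.

    Notes
    -----
    Row-level curation applied here, mirroring how T0-referenced centroid
    data behave in practice:

    * ``exposure == 0`` rows define the reference and are forced to
      ``uptake = 0`` (warned if they deviate);
    * mildly negative uptake (>= -0.15 Da) is clamped to 0 with a warning,
      more negative values reject the row;
    * coordinate/sequence inconsistencies reject the row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, float_precision="round_trip")
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        source = schema.get(canonical, canonical) if schema else canonical
        if source not in raw.columns:
            raise SchemaError(f"missing mandatory column {source!r} (for {canonical!r})")
        rename[source] = canonical
    df = raw.rename(columns=rename)[CANONICAL_COLUMNS].copy()

    report = ParseReport(n_read=len(df))
    drop_mask = np.zeros(len(df), dtype=bool)

    # numeric coercion; >1% unparseable rows is a schema-level failure
    bad_numeric = np.zeros(len(df), dtype=bool)
    for col in ["exposure", "intensity", "uptake", "start", "end", "charge"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna().to_numpy() & df[col].notna().to_numpy()
        bad |= coerced.isna().to_numpy()
        if col in ("exposure", "intensity"):
            bad_numeric |= bad
        df[col] = coerced
    if len(df) and bad_numeric.sum() / len(df) > max_bad_fraction:
        raise ValueError(
            f"{bad_numeric.sum()} of {len(df)} rows have non-numeric "
            f"exposure/intensity (> {max_bad_fraction:.0%} allowed)"
        )
    for i in np.flatnonzero(bad_numeric):
        report.dropped.append((int(i), "non-numeric exposure/intensity"))
    drop_mask |= bad_numeric

    nan_any = df[["start", "end", "uptake", "charge"]].isna().any(axis=1).to_numpy()
    for i in np.flatnonzero(nan_any & ~drop_mask):
        report.dropped.append((int(i), "unparseable numeric field"))
    drop_mask |= nan_any

    ok = ~drop_mask
    start = df["start"].to_numpy(dtype=float)
    end = df["end"].to_numpy(dtype=float)
    seq_len = df["sequence"].astype(str).str.len().to_numpy()

    bad_coord = ok & (end < start)
    for i in np.flatnonzero(bad_coord):
        report.dropped.append((int(i), "end < start"))
    drop_mask |= bad_coord

    bad_len = ~drop_mask & (seq_len != end - start + 1)
    for i in np.flatnonzero(bad_len):
        report.dropped.append((int(i), "sequence length != end - start + 1"))
    drop_mask |= bad_len

    bad_int = ~drop_mask & (df["intensity"].to_numpy(dtype=float) < 0)
    for i in np.flatnonzero(bad_int):
        report.dropped.append((int(i), "negative intensity"))
    drop_mask |= bad_int

    uptake = df["uptake"].to_numpy(dtype=float)
    too_negative = ~drop_mask & (uptake < -NEGATIVE_UPTAKE_TOLERANCE_DA)
    for i in np.flatnonzero(too_negative):
        report.dropped.append((int(i), f"uptake < -{NEGATIVE_UPTAKE_TOLERANCE_DA} Da"))
    drop_mask |= too_negative

    clamp = ~drop_mask & (uptake < 0)
    if clamp.any():
        report.warnings.append(
            f"{int(clamp.sum())} rows with slightly negative uptake clamped to 0"
        )
        df.loc[clamp, "uptake"] = 0.0

    t0 = ~drop_mask & (df["exposure"].to_numpy(dtype=float) == 0)
    t0_nonzero = t0 & (df["uptake"].to_numpy(dtype=float).round(9) != 0)
    if t0_nonzero.any():
        report.warnings.append(
            f"{int(t0_nonzero.sum())} exposure-0 rows had non-zero uptake; "
            "reset to 0 (T0 defines the reference)"
        )
        df.loc[t0_nonzero, "uptake"] = 0.0

    out = df.loc[~drop_mask].copy()
    for col in ("start", "end", "charge"):
        out[col] = out[col].astype(int)
    out["protein"] = out["protein"].astype(str)
    out["sequence"] = out["sequence"].astype(str)
    out["state"] = out["state"].astype(str)
    out["replicate"] = out["replicate"].astype(str)
    report.n_kept = len(out)
    report.dropped.sort(key=lambda t: t[0])
    return out.reset_index(drop=True), report


def write_ion_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write an ion table in the canonical CSV schema."""
    table[CANONICAL_COLUMNS].to_csv(path, index=False)


def filter_identifications(
    records: Sequence[IdentificationRecord],
    min_replicates: int = 2,
    min_frag_per_aa: float = 0.2,
    min_intensity: float = 1000.0,
) -> tuple[list[IdentificationRecord], list[tuple[IdentificationRecord, str]]]:
    """Apply the peptide identification filter.

    A peptide is retained iff it was identified in at least
    ``min_replicates`` replicates, with at least ``min_frag_per_aa``
    matched fragments per amino acid, and a maximum intensity of at least
    ``min_intensity``. All boundaries are inclusive (>=). The rejection
    log records the first failed criterion per record.
    """
    if min_replicates < 0 or min_frag_per_aa < 0 or min_intensity < 0:
        raise ValueError("filter thresholds must be non-negative")
    retained: list[IdentificationRecord] = []
    rejected: list[tuple[IdentificationRecord, str]] = []
    for rec in records:
        if rec.replicate_count < min_replicates:
            rejected.append((rec, f"replicate_count {rec.replicate_count} < {min_replicates}"))
        elif rec.fragments_per_aa < min_frag_per_aa:
            rejected.append((rec, f"fragments_per_aa {rec.fragments_per_aa} < {min_frag_per_aa}"))
        elif rec.max_intensity < min_intensity:
            rejected.append((rec, f"max_intensity {rec.max_intensity} < {min_intensity}"))
        else:
            retained.append(rec)
    return retained, rejected


def compute_coverage(
    peptides: Iterable[tuple[int, int]],
    protein: ProteinSequence,
) -> CoverageSummary:
    """Sequence coverage of ``protein`` by the peptide intervals.

    ``covered_fraction`` is the percentage of residues covered by at
    least one peptide (overlaps never double-count); ``redundancy`` is
    the mean number of peptides covering each covered residue;
    ``uncovered_intervals`` are the maximal uncovered runs in residue
    numbering.
    """
    counts = np.zeros(protein.length, dtype=int)
    for start, end in peptides:
        if not protein.contains_interval(start, end):
            raise ValueError(
                f"peptide {start}-{end} outside protein {protein.protein_id!r} "
                f"bounds {protein.first_residue}-{protein.last_residue}"
            )
        i0 = start - protein.numbering_offset
        i1 = end - protein.numbering_offset
        counts[i0:i1 + 1] += 1
    covered = counts > 0
    frac = 100.0 * covered.sum() / protein.length
    redundancy = float(counts[covered].mean()) if covered.any() else 0.0

    gaps: list[tuple[int, int]] = []
    in_gap = False
    gap_start = 0
    for i, c in enumerate(covered):
        if not c and not in_gap:
            in_gap, gap_start = True, i
        elif c and in_gap:
            in_gap = False
            gaps.append((gap_start + protein.numbering_offset,
                         i - 1 + protein.numbering_offset))
    if in_gap:
        gaps.append((gap_start + protein.numbering_offset, protein.last_residue))
    return CoverageSummary(protein.protein_id, float(frac), redundancy, gaps)


def coverage_table(summaries: Iterable[CoverageSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({
            "protein": s.protein_id,
            "covered_fraction_pct": s.covered_fraction,
            "redundancy": s.redundancy,
            "uncovered_intervals": ";".join(f"{a}-{b}" for a, b in s.uncovered_intervals),
        })
    return pd.DataFrame(rows)


def ion_table_to_records(table: pd.DataFrame) -> list["IonMeasurement"]:
    """Materialize canonical table rows as :class:`IonMeasurement` objects
    (row-level API; bulk operations stay on the DataFrame)."""
    return [IonMeasurement(**{f.name: row[col] for f, col in zip(
        dataclasses.fields(IonMeasurement), CANONICAL_COLUMNS)})
        for _, row in table.iterrows()]


@dataclass(frozen=True)
class IonMeasurement:
    """One curated ion observation."""

    protein_id: str
    start: int
    end: int
    sequence: str
    charge: int
    condition: str
    exposure_min: float
    replicate: str
    intensity: float
    uptake_da: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end < start")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length inconsistent with coordinates")
        if self.charge < 1:
            raise ValueError("charge must be positive")
        if self.exposure_min < 0:
            raise ValueError("exposure must be non-negative")
        if self.exposure_min == 0 and abs(self.uptake_da) > 1e-9:
            raise ValueError("exposure 0 defines the reference: uptake must be 0")
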