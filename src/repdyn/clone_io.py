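"""Reading, validation and aggregation of processed TCR clone-abundance tables.

The unit of input is one tab-separated file per sample (patient x timepoint x
compartment) in the style of immunoSEQ exports: a header row, one row per
rearrangement, with at minimum a CDR3 amino-acid column and a template-count
column.  Clones are identified by the CDR3 amino-acid sequence alone: rows
sharing a CDR3 are aggregated by summing template counts, and frequencies are
always recomputed from the post-filter total rather than trusted from the
file.  Non-productive rows (empty CDR3, stop codon ``*`` or ambiguity ``X`` in
the CDR3, or an out-of-frame/stop frame flag where a frame column exists) are
dropped before aggregation and tallied per file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "CANONICAL_TIMEPOINTS",
    "COMPARTMENTS",
    "DEFAULT_DIALECT",
    "CloneRecord",
    "CloneTable",
    "SampleSeries",
    "CloneTableError",
    "EmptySampleError",
    "read_clone_table",
    "write_clone_table",
    "productive_count",
    "timepoint_sort_key",
]

#: The 20 proteinogenic amino acids; a productive CDR3 is drawn from these only.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Blood-draw schedule labels: baseline, post-immunotherapy (wk1),
#: post-cryoablation (wk2), post-surgery (wk6).
CANONICAL_TIMEPOINTS = ("Pre", "PI", "PC", "PS")

COMPARTMENTS = ("blood", "tumor_core", "margin_1cm", "margin_3cm", "normal_tissue")

#: Logical field -> header name in the tab-separated dialect.
DEFAULT_DIALECT: Mapping[str, str] = {
    "cdr3aa": "cdr3_amino_acid",
    "count": "templates",
    "frame": "frame_type",
}

# Headers recognised when the configured one is absent (vendor exports vary
# across assay versions).
_FALLBACK_HEADERS = {
    "cdr3aa": ("cdr3_amino_acid", "aminoAcid", "amino_acid", "cdr3aa"),
    "count": ("templates", "count (templates/reads)", "count", "reads"),
    "frame": ("frame_type", "sequenceStatus", "frame"),
}

# frame-flag spellings accepted as productive (case-insensitive)
_PRODUCTIVE_FRAME = {"in", "in-frame", "inframe", "productive"}


class CloneTableError(ValueError):
    """Malformed or invalid clone-abundance table."""


class EmptySampleError(CloneTableError):
    """No productive clone survives filtering; the sample cannot enter statistics."""


@dataclass(frozen=True)
class CloneRecord:
    """One clone: CDR3 amino-acid identity, template count, sample frequency."""

    cdr3aa: str
    count: int
    frequency: float


def _cdr3_is_productive(cdr3aa: object) -> bool:
    if not isinstance(cdr3aa, str) or not cdr3aa:
        return False
    return all(ch in AMINO_ACIDS for ch in cdr3aa)


@dataclass
class CloneTable:
    """A validated, aggregated clone-abundance table for one sample.

    ``records`` maps CDR3 amino-acid sequence to its :class:`CloneRecord`;
    frequencies are ``count / total_count`` and sum to 1.  ``n_discarded``
    is bookkeeping (rows dropped by the productive filter) and does not
    participate in equality.
    """

    sample_id: str
    records: dict[str, CloneRecord]
    total_count: int
    patient_id: str = ""
    timepoint: str = ""
    compartment: str = "blood"
    n_discarded: int = field(default=0, compare=False)

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, int],
        sample_id: str = "sample",
        *,
        patient_id: str = "",
        timepoint: str = "",
        compartment: str = "blood",
        n_discarded: int = 0,
    ) -> "CloneTable":
        """Build a table from a ``cdr3 -> count`` mapping (already aggregated)."""
        clean = {k: int(v) for k, v in counts.items() if int(v) > 0}
        total = sum(clean.values())
        if total <= 0:
            raise EmptySampleError(f"{sample_id}: no clone with a positive count")
        records = {
            k: CloneRecord(k, v, v / total) for k, v in sorted(clean.items())
        }
        table = cls(
            sample_id=sample_id,
            records=records,
            total_count=total,
            patient_id=patient_id,
            timepoint=timepoint,
            compartment=compartment,
            n_discarded=n_discarded,
        )
        table.validate()
        return table

    # -- accessors -------------------------------------------------------
    @property
    def n_clones(self) -> int:
        return len(self.records)

    def frequency(self, cdr3aa: str) -> float:
        """Frequency of a clone, 0.0 where absent."""
        rec = self.records.get(cdr3aa)
        return rec.frequency if rec is not None else 0.0

    def count(self, cdr3aa: str) -> int:
        rec = self.records.get(cdr3aa)
        return rec.count if rec is not None else 0

    def clones(self) -> list[str]:
        return list(self.records)

    def validate(self) -> None:
        if not self.records:
            raise EmptySampleError(f"{self.sample_id}: table has no records")
        total = 0
        fsum = 0.0
        for key, rec in self.records.items():
            if key != rec.cdr3aa:
                raise CloneTableError(
                    f"{self.sample_id}: record key {key!r} != cdr3aa {rec.cdr3aa!r}"
                )
            if not _cdr3_is_productive(rec.cdr3aa):
                raise CloneTableError(
                    f"{self.sample_id}: non-productive CDR3 {rec.cdr3aa!r} in table"
                )
            if rec.count < 1:
                raise CloneTableError(
                    f"{self.sample_id}: clone {key} has count {rec.count} < 1"
                )
            total += rec.count
            fsum += rec.frequency
            if abs(rec.frequency - rec.count / self.total_count) > 1e-12:
                raise CloneTableError(
                    f"{self.sample_id}: clone {key} frequency inconsistent with count"
                )
        if total != self.total_count:
            raise CloneTableError(
                f"{self.sample_id}: counts sum to {total}, total_count={self.total_count}"
            )
        if abs(fsum - 1.0) > 1e-9:
            raise CloneTableError(
                f"{self.sample_id}: frequencies sum to {fsum}, expected 1"
            )


def _resolve_column(columns: Iterable[str], logical: str, dialect: Mapping[str, str]) -> str | None:
    cols = list(columns)
    configured = dialect.get(logical)
    if configured and configured in cols:
        return configured
    for candidate in _FALLBACK_HEADERS.get(logical, ()):
        if candidate in cols:
            return candidate
    return None


def read_clone_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    sample_id: str | None = None,
    patient_id: str = "",
    timepoint: str = "",
    compartment: str = "blood",
) -> CloneTable:
    """Read one sample's clone table, filter non-productive rows, aggregate.

    Rows failing the productive filter are dropped and tallied in the returned
    table's ``n_discarded``.  Rows sharing a CDR3 amino acid are aggregated by
    summing template counts; frequencies are recomputed from the post-filter
    total (a ``productive_frequency`` column in the file is ignored).

    Raises
    ------
    CloneTableError
        Missing mapped column, or a negative / non-integer count (the message
        names the column or 1-based data row).
    EmptySampleError
        No productive row with a positive count survives.
    """
    path = Path(path)
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    cdr3_col = _resolve_column(df.columns, "cdr3aa", dialect)
    count_col = _resolve_column(df.columns, "count", dialect)
    if cdr3_col is None:
        raise CloneTableError(
            f"{path.name}: missing CDR3 amino-acid column "
            f"(expected {dialect['cdr3aa']!r}); found {list(df.columns)}"
        )
    if count_col is None:
        raise CloneTableError(
            f"{path.name}: missing template-count column "
            f"(expected {dialect['count']!r}); found {list(df.columns)}"
        )
    frame_col = _resolve_column(df.columns, "frame", dialect)

    i_cdr3 = df.columns.get_loc(cdr3_col)
    i_count = df.columns.get_loc(count_col)
    i_frame = df.columns.get_loc(frame_col) if frame_col is not None else None

    counts: dict[str, int] = {}
    n_discarded = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        raw_count = row[i_count]
        cdr3 = row[i_cdr3]
        try:
            value = float(raw_count)
        except (TypeError, ValueError):
            raise CloneTableError(
                f"{path.name} row {i}: count {raw_count!r} is not a number"
            ) from None
        if value < 0 or not math.isfinite(value) or value != int(value):
            raise CloneTableError(
                f"{path.name} row {i}: count {raw_count!r} is not a non-negative integer"
            )
        count = int(value)
        if i_frame is not None:
            frame = str(row[i_frame]).strip().lower()
            if frame not in _PRODUCTIVE_FRAME:
                n_discarded += 1
                continue
        if not _cdr3_is_productive(cdr3):
            n_discarded += 1
            continue
        if count == 0:
            continue
        counts[cdr3] = counts.get(cdr3, 0) + count

    if not counts:
        raise EmptySampleError(f"{path.name}: no productive clone survives filtering")
    return CloneTable.from_counts(
        counts,
        sample_id=sample_id if sample_id is not None else path.stem,
        patient_id=patient_id,
        timepoint=timepoint,
        compartment=compartment,
        n_discarded=n_discarded,
    )


def write_clone_table(table: CloneTable, path: str | Path) -> None:
    """Write a table in the default dialect; round-trips through ``read_clone_table``.

    Rows are ordered by descending count then CDR3 so output is deterministic.
    """
    table.validate()
    path = Path(path)
    recs = sorted(table.records.values(), key=lambda r: (-r.count, r.cdr3aa))
    out = pd.DataFrame(
        {
            "cdr3_amino_acid": [r.cdr3aa for r in recs],
            "templates": [r.count for r in recs],
            "frame_type": "In",
            "productive_frequency": [repr(r.frequency) for r in recs],
        }
    )
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def productive_count(table: CloneTable) -> int:
    """Number of distinct productive clones in the sample (post-aggregation)."""
    return table.n_clones


def timepoint_sort_key(label: str) -> tuple[int, str]:
    """Sort key placing canonical timepoints in study order, other labels after."""
    try:
        return (CANONICAL_TIMEPOINTS.index(label), "")
    except ValueError:
        return (len(CANONICAL_TIMEPOINTS), label)


@dataclass
class SampleSeries:
    """Ordered longitudinal series of clone tables for one patient.

    Labels follow the study schema Pre < PI < PC < PS; tissue-site labels are
    permitted in the same namespace and sort after the blood timepoints.
    """

    patient_id: str
    labels: tuple[str, ...]
    tables: dict[str, CloneTable]

    @classmethod
    def from_tables(cls, tables: Iterable[CloneTable]) -> "SampleSeries":
        by_label: dict[str, CloneTable] = {}
        patient = None
        for t in tables:
            if patient is None:
                patient = t.patient_id
            elif t.patient_id != patient:
                raise CloneTableError(
                    f"series mixes patients {patient!r} and {t.patient_id!r}"
                )
            label = t.timepoint or t.sample_id
            if label in by_label:
                raise CloneTableError(f"duplicate series label {label!r}")
            by_label[label] = t
        if not by_label:
            raise CloneTableError("empty sample series")
        labels = tuple(sorted(by_label, key=timepoint_sort_key))
        return cls(patient_id=patient or "", labels=labels, tables=by_label)

    def __getitem__(self, label: str) -> CloneTable:
        return self.tables[label]

    def __contains__(self, label: str) -> bool:
        return label in self.tables
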