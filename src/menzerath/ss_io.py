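"""Protein-record I/O and the continuous-coverage admission filter.

The analysis operates on proteins whose experimentally solved structure
continuously covers at least 95% of the sequence, so that the secondary
structure annotation (α-helices ``H`` and β-strands ``E``, measured in
amino acids) is trustworthy.  "Continuous" means unobserved residues are
allowed only at the termini, so coverage is modelled as a single observed
interval per protein.

Tabular dialects (TSV with a header row, or JSON-lines with the same field
names):

* protein table — columns ``accession``, ``seq_length``, ``locations``
  (semicolon-separated category strings, possibly empty) and ``segments``
  (comma-separated ``KIND:LENGTH`` tokens with KIND in {H, E});
* coverage table — columns ``accession``, ``seq_length``,
  ``observed_start``, ``observed_end`` (1-based inclusive).

Writers emit these dialects deterministically so that write-then-read is
the identity on valid records.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentKind",
    "SSegment",
    "ProteinRecord",
    "CoverageRecord",
    "ParseResult",
    "InvalidRecordError",
    "min_required_observed",
    "passes_coverage",
    "mean_ss_length",
    "filter_by_coverage",
    "read_protein_table",
    "write_protein_table",
    "read_coverage_table",
    "write_coverage_table",
]

#: Minimum fraction of the sequence that must be continuously observed.
COVERAGE_FRACTION_NUM = 19
COVERAGE_FRACTION_DEN = 20  # 19/20 = 0.95


class InvalidRecordError(ValueError):
    """A record violates a structural invariant of the input dialect."""


class SegmentKind(str, Enum):
    """Secondary-structure element types counted by the analysis."""

    HELIX = "H"
    STRAND = "E"


@dataclass(frozen=True)
class SSegment:
    """One secondary-structure segment.

    Parameters
    ----------
    kind
        Helix (``H``) or strand (``E``).
    length
        Segment length in amino acids (≥ 1).
    start, end
        Optional 1-based inclusive residue coordinates; when present they
        must satisfy ``length == end - start + 1``.
    """

    kind: SegmentKind
    length: int
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.length, int) or self.length < 1:
            raise InvalidRecordError(f"segment length must be a positive integer, got {self.length!r}")
        if (self.start is None) != (self.end is None):
            raise InvalidRecordError("start and end must be given together")
        if self.start is not None:
            if self.start > self.end:  # type: ignore[operator]
                raise InvalidRecordError(f"start {self.start} > end {self.end}")
            if self.end - self.start + 1 != self.length:  # type: ignore[operator]
                raise InvalidRecordError(
                    f"coordinates {self.start}..{self.end} inconsistent with length {self.length}"
                )


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier, sequence length, segments and location labels.

    The derived quantities of the analysis are ``x`` (the construct size:
    number of secondary structures) and ``y`` (the constituent size: mean
    segment length in amino acids).
    """

    accession: str
    seq_length: int
    segments: tuple[SSegment, ...]
    locations: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.seq_length < 1:
            raise InvalidRecordError(f"{self.accession}: seq_length must be positive")
        total = sum(s.length for s in self.segments)
        if total > self.seq_length:
            raise InvalidRecordError(
                f"{self.accession}: segment lengths sum to {total} > seq_length {self.seq_length}"
            )

    @property
    def x(self) -> int:
        """Number of secondary-structure segments."""
        return len(self.segments)

    @property
    def y(self) -> float:
        """Mean secondary-structure length (amino acids)."""
        return mean_ss_length(self)


@dataclass(frozen=True)
class CoverageRecord:
    """The single continuously observed interval of one protein's structure."""

    accession: str
    seq_length: int
    observed_start: int
    observed_end: int

    def __post_init__(self) -> None:
        ok = 1 <= self.observed_start <= self.observed_end <= self.seq_length
        if not ok:
            raise InvalidRecordError(
                f"{self.accession}: invalid observed interval "
                f"{self.observed_start}..{self.observed_end} for length {self.seq_length}"
            )

    @property
    def observed_residues(self) -> int:
        return self.observed_end - self.observed_start + 1


def min_required_observed(seq_length: int) -> int:
    """Smallest continuously observed residue count admitting a protein.

    The admission rule requires observation of at least 95% of the sequence,
    i.e. ``ceil(0.95 * L)`` residues.  Computed in exact integer arithmetic
    as ``ceil(19 L / 20)``.

    Examples
    --------
    >>> [min_required_observed(L) for L in (14, 33, 75)]
    [14, 32, 72]
    """
    if not isinstance(seq_length, int) or seq_length < 1:
        raise InvalidRecordError(f"seq_length must be a positive integer, got {seq_length!r}")
    num = COVERAGE_FRACTION_NUM * seq_length
    return -(-num // COVERAGE_FRACTION_DEN)


def passes_coverage(rec: CoverageRecord) -> bool:
    """True iff the observed interval meets the 95% continuous-coverage rule."""
    return rec.observed_residues >= min_required_observed(rec.seq_length)


def mean_ss_length(rec: ProteinRecord) -> float:
    """Arithmetic mean of the record's segment lengths, in amino acids."""
    if not rec.segments:
        raise InvalidRecordError(f"{rec.accession}: no segments; mean length undefined")
    return sum(s.length for s in rec.segments) / len(rec.segments)


def filter_by_coverage(
    proteins: Sequence[ProteinRecord],
    coverage: Sequence[CoverageRecord],
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Partition ``proteins`` into (admitted, rejected) by the coverage rule.

    A protein with no coverage record is rejected (coverage unknown).
    """
    passing = {c.accession for c in coverage if passes_coverage(c)}
    kept = [p for p in proteins if p.accession in passing]
    dropped = [p for p in proteins if p.accession not in passing]
    return kept, dropped


# ---------------------------------------------------------------------------
# Tabular I/O


@dataclass
class ParseResult:
    """Outcome of reading a protein table.

    ``records`` preserves input order.  ``n_zero_segment`` counts rows whose
    segments column yielded no countable structures (excluded from the
    analysis), and ``n_ignored_segments`` counts segment tokens of kinds
    other than H/E (e.g. turns), which are dropped with a log message.
    """

    records: list[ProteinRecord] = field(default_factory=list)
    n_zero_segment: int = 0
    n_ignored_segments: int = 0
    errors: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


_PROTEIN_COLUMNS = ("accession", "seq_length", "locations", "segments")
_COVERAGE_COLUMNS = ("accession", "seq_length", "observed_start", "observed_end")

PathOrIO = Union[str, Path, TextIO]


def _open_maybe(source: PathOrIO, mode: str):
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8", newline=""), True
    return source, False


def _parse_segments(token_field: str, counters: ParseResult) -> tuple[SSegment, ...]:
    segments: list[SSegment] = []
    if not token_field.strip():
        return ()
    for token in token_field.split(","):
        token = token.strip()
        if not token:
            continue
        try:
            kind_s, length_s = token.split(":")
            length = int(length_s)
        except ValueError as exc:
            raise InvalidRecordError(f"malformed segment token {token!r}") from exc
        if kind_s not in ("H", "E"):
            # Turns/3-10 helices etc. are not units of this analysis.
            counters.n_ignored_segments += 1
            continue
        segments.append(SSegment(SegmentKind(kind_s), length))
    return tuple(segments)


def _row_to_record(row: dict, counters: ParseResult) -> ProteinRecord | None:
    segments = _parse_segments(row["segments"], counters)
    if not segments:
        counters.n_zero_segment += 1
        return None
    locations = frozenset(
        tok.strip() for tok in row["locations"].split(";") if tok.strip()
    )
    return ProteinRecord(
        accession=row["accession"],
        seq_length=int(row["seq_length"]),
        segments=segments,
        locations=locations,
    )


def read_protein_table(source: PathOrIO, *, dialect: str = "tsv", on_error: str = "raise") -> ParseResult:
    """Read a protein table in the TSV or JSON-lines dialect.

    Parameters
    ----------
    source
        Path or open text handle.
    dialect
        ``"tsv"`` or ``"jsonl"``.
    on_error
        ``"raise"`` fails fast on the first malformed row; ``"skip"``
        records the error (with its row number) and continues.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    handle, close = _open_maybe(source, "r")
    result = ParseResult()
    try:
        if dialect == "tsv":
            reader = csv.DictReader(handle, delimiter="\t")
            missing = set(_PROTEIN_COLUMNS) - set(reader.fieldnames or ())
            if missing:
                raise InvalidRecordError(f"protein table missing columns: {sorted(missing)}")
            rows: Iterable[dict] = reader
        elif dialect == "jsonl":
            rows = (json.loads(line) for line in handle if line.strip())
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        for i, row in enumerate(rows, start=2 if dialect == "tsv" else 1):
            if dialect == "jsonl":
                row = {
                    "accession": row["accession"],
                    "seq_length": row["seq_length"],
                    "locations": ";".join(row.get("locations", []))
                    if isinstance(row.get("locations"), list)
                    else str(row.get("locations", "")),
                    "segments": ",".join(row["segments"])
                    if isinstance(row.get("segments"), list)
                    else str(row.get("segments", "")),
                }
            try:
                rec = _row_to_record({k: str(row[k]) for k in _PROTEIN_COLUMNS}, result)
            except (InvalidRecordError, KeyError, ValueError) as exc:
                msg = f"row {i}: {exc}"
                if on_error == "raise":
                    raise InvalidRecordError(msg) from exc
                result.errors.append(msg)
                logger.warning("skipping %s", msg)
                continue
            if rec is not None:
                result.records.append(rec)
    finally:
        if close:
            handle.close()
    if result.n_ignored_segments:
        logger.info("ignored %d non-H/E segment tokens", result.n_ignored_segments)
    if result.n_zero_segment:
        logger.info("excluded %d records with zero countable segments", result.n_zero_segment)
    return result


def write_protein_table(records: Iterable[ProteinRecord], dest: PathOrIO, *, dialect: str = "tsv") -> None:
    """Write records in a dialect readable by :func:`read_protein_table`.

    Output is deterministic (locations sorted lexicographically), so a
    write-then-read round trip reproduces the records exactly.
    """
    handle, close = _open_maybe(dest, "w")
    try:
        if dialect == "tsv":
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(_PROTEIN_COLUMNS)
            for rec in records:
                writer.writerow(
                    [
                        rec.accession,
                        rec.seq_length,
                        ";".join(sorted(rec.locations)),
                        ",".join(f"{s.kind.value}:{s.length}" for s in rec.segments),
                    ]
                )
        elif dialect == "jsonl":
            for rec in records:
                json.dump(
                    {
                        "accession": rec.accession,
                        "seq_length": rec.seq_length,
                        "locations": sorted(rec.locations),
                        "segments": [f"{s.kind.value}:{s.length}" for s in rec.segments],
                    },
                    handle,
                )
                handle.write("\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    finally:
        if close:
            handle.close()


def read_coverage_table(source: PathOrIO) -> list[CoverageRecord]:
    """Read a coverage table (TSV)."""
    handle, close = _open_maybe(source, "r")
    try:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(_COVERAGE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise InvalidRecordError(f"coverage table missing columns: {sorted(missing)}")
        return [
            CoverageRecord(
                accession=row["accession"],
                seq_length=int(row["seq_length"]),
                observed_start=int(row["observed_start"]),
                observed_end=int(row["observed_end"]),
            )
            for row in reader
        ]
    finally:
        if close:
            handle.close()


def write_coverage_table(records: Iterable[CoverageRecord], dest: PathOrIO) -> None:
    """Write a coverage table (TSV)."""
    handle, close = _open_maybe(dest, "w")
    try:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_COVERAGE_COLUMNS)
        for rec in records:
            writer.writerow([rec.accession, rec.seq_length, rec.observed_start, rec.observed_end])
    finally:
        if close:
            handle.close()
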