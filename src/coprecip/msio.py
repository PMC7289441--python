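"""Data model and readers/writers for protein-level AP-MS tables.

The unit of input is one pull-down run: a table with one row per protein
ID carrying the search score, the percent sequence coverage and the
per-peptide abundance areas that downstream top-3 quantification (T3PQ)
consumes.  Tables arrive either as delimited text (wide layout, peptide
lists semicolon-joined in single cells; or long layout, peptides in a
companion table) or as the first worksheet of an XLSX workbook with a
user-supplied column-name map.

Missing abundance cells parse to ``None``, never to 0 — a zero would
silently corrupt abundance ranking.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from .errors import ContractError, FormatError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .interactor_calling import InteractorCall

# Uppercase IUPAC amino-acid one-letter codes (20 standard + ambiguity
# codes B/J/X/Z and the rare U/O).
IUPAC_AA = frozenset("ACDEFGHIKLMNPQRSTVWYBJXZUO")

REPORT_COLUMNS = (
    "rank",
    "accession",
    "description",
    "score",
    "coverage",
    "n_peptides",
    "t3pq_mean_area",
    "bait_flag",
)


@dataclass(frozen=True)
class PeptideHit:
    """One identified peptide with its abundance area (arbitrary units).

    ``area`` is ``None`` when the search export carried no area for the
    peptide; such hits count toward the distinct-peptide tally but are
    excluded from abundance quantification.
    """

    sequence: str
    area: float | None = None

    def validate(self) -> None:
        if not self.sequence:
            raise ValidationError("peptide sequence is empty")
        bad = set(self.sequence) - IUPAC_AA
        if bad:
            raise ValidationError(
                f"peptide sequence {self.sequence!r} contains non-IUPAC "
                f"characters {sorted(bad)}"
            )
        if self.area is not None and not self.area >= 0:
            raise ValidationError(
                f"peptide {self.sequence!r} has negative area {self.area!r}"
            )


@dataclass
class ProteinGroupRecord:
    """One protein ID in one pull-down run."""

    accession: str
    description: str
    score: float
    coverage: float
    peptides: list[PeptideHit] = field(default_factory=list)

    @property
    def n_distinct_peptides(self) -> int:
        """Number of unique peptide sequences (not PSM count)."""
        return len({p.sequence for p in self.peptides})

    def present_areas(self) -> list[float]:
        return [p.area for p in self.peptides if p.area is not None]

    def validate(self) -> None:
        if not self.accession:
            raise ValidationError("empty accession")
        if not self.score >= 0:
            raise ValidationError(
                f"{self.accession}: score {self.score!r} is negative"
            )
        if not 0.0 <= self.coverage <= 100.0:
            raise ValidationError(
                f"{self.accession}: coverage {self.coverage!r} outside [0, 100]"
            )
        for pep in self.peptides:
            pep.validate()


@dataclass
class PullDownRun:
    """One pull-down experiment: a bait precipitate or a negative control."""

    run_id: str
    records: list[ProteinGroupRecord] = field(default_factory=list)
    bait_accession: str | None = None
    is_control: bool = False
    #: row-indexed reader diagnostics; excluded from equality so that a
    #: clean round-trip compares equal to the original run.
    diagnostics: list[RowDiagnostic] = field(default_factory=list, compare=False)

    def validate(self) -> None:
        if self.is_control and self.bait_accession is not None:
            raise ValidationError(
                f"run {self.run_id}: control runs have no designated bait"
            )
        seen: set[str] = set()
        for rec in self.records:
            if rec.accession in seen:
                raise ValidationError(
                    f"run {self.run_id}: duplicate accession {rec.accession}"
                )
            seen.add(rec.accession)
            rec.validate()

    def accessions(self) -> set[str]:
        return {rec.accession for rec in self.records}


@dataclass(frozen=True)
class RowDiagnostic:
    """Why a table row was rejected (0-based data-row index)."""

    row_index: int
    message: str


@dataclass(frozen=True)
class TableDialect:
    """How a protein table is laid out on disk.

    ``columns`` maps the canonical field names (``accession``,
    ``description``, ``score``, ``coverage``, ``peptide_sequences``,
    ``peptide_areas``) to the header names actually present.  In the
    ``wide`` layout peptide sequences/areas are ``area_sep``-joined lists
    inside single cells; in the ``long`` layout they live in a companion
    peptide table (``peptide_path``) with columns accession / sequence /
    area.
    """

    sep: str = ","
    layout: str = "wide"  # "wide" | "long"
    columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "accession": "accession",
            "description": "description",
            "score": "score",
            "coverage": "coverage",
            "peptide_sequences": "peptide_sequences",
            "peptide_areas": "peptide_areas",
        }
    )
    area_sep: str = ";"
    peptide_path: str | None = None


DEFAULT_DIALECT = TableDialect()

_MANDATORY = ("accession", "score", "coverage")


def _parse_float(text: str, what: str) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise ValidationError(f"{what}: cannot parse {text!r} as a number") from exc


def _parse_area(text: str) -> float | None:
    text = text.strip()
    if text == "" or text.upper() in {"NA", "NAN", "NONE"}:
        return None
    return _parse_float(text, "peptide area")


def _fallback_sequence(i: int) -> str:
    # Deterministic placeholder sequence for exports without peptide
    # sequences; spelled over amino-acid letters so it stays IUPAC-valid.
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    digits = []
    i += 1
    while i:
        i, r = divmod(i, len(alphabet))
        digits.append(alphabet[r])
    return "PEP" + "".join(reversed(digits))


def _row_to_record(
    row: Mapping[str, str], dialect: TableDialect, peptide_map: Mapping[str, list[PeptideHit]] | None
) -> ProteinGroupRecord:
    cols = dialect.columns
    accession = str(row[cols["accession"]]).strip()
    desc_col = cols.get("description")
    description = str(row.get(desc_col, "") or "") if desc_col else ""
    score = _parse_float(str(row[cols["score"]]), f"{accession}: score")
    coverage = _parse_float(str(row[cols["coverage"]]), f"{accession}: coverage")

    if dialect.layout == "long":
        peptides = list((peptide_map or {}).get(accession, []))
    else:
        areas_cell = str(row.get(cols.get("peptide_areas", ""), "") or "")
        seq_col = cols.get("peptide_sequences")
        seqs_cell = str(row.get(seq_col, "") or "") if seq_col else ""
        areas = (
            [_parse_area(tok) for tok in areas_cell.split(dialect.area_sep)]
            if areas_cell
            else []
        )
        seqs = (
            [tok.strip() for tok in seqs_cell.split(dialect.area_sep)]
            if seqs_cell
            else []
        )
        if seqs and len(seqs) != len(areas):
            raise ValidationError(
                f"{accession}: {len(seqs)} peptide sequences but {len(areas)} areas"
            )
        if not seqs:
            seqs = [_fallback_sequence(i) for i in range(len(areas))]
        peptides = [PeptideHit(s, a) for s, a in zip(seqs, areas)]

    record = ProteinGroupRecord(
        accession=accession,
        description=description,
        score=score,
        coverage=coverage,
        peptides=peptides,
    )
    record.validate()
    return record


def _read_long_peptides(path: Path, dialect: TableDialect) -> dict[str, list[PeptideHit]]:
    peptide_map: dict[str, list[PeptideHit]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.sep)
        for row in reader:
            hit = PeptideHit(row["sequence"].strip(), _parse_area(row.get("area", "")))
            peptide_map.setdefault(row["accession"].strip(), []).append(hit)
    return peptide_map


def _rows_to_run(
    rows: Iterable[Mapping[str, str]],
    header: Sequence[str],
    dialect: TableDialect,
    run_id: str,
    bait_accession: str | None,
    is_control: bool,
    peptide_map: Mapping[str, list[PeptideHit]] | None,
) -> PullDownRun:
    for canonical in _MANDATORY:
        mapped = dialect.columns.get(canonical)
        if mapped is None or mapped not in header:
            raise FormatError(
                f"mandatory column {canonical!r} (mapped to {mapped!r}) "
                f"missing from header {list(header)}"
            )
    run = PullDownRun(
        run_id=run_id, bait_accession=bait_accession, is_control=is_control
    )
    seen: set[str] = set()
    for i, row in enumerate(rows):
        try:
            record = _row_to_record(row, dialect, peptide_map)
        except ValidationError as exc:
            run.diagnostics.append(RowDiagnostic(i, str(exc)))
            continue
        if record.accession in seen:
            raise ValidationError(
                f"run {run_id}: duplicate accession {record.accession}"
            )
        seen.add(record.accession)
        run.records.append(record)
    run.validate()
    return run


def read_protein_table(
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
    *,
    run_id: str | None = None,
    bait_accession: str | None = None,
    is_control: bool = False,
) -> PullDownRun:
    """Read a delimited protein table into a validated :class:`PullDownRun`.

    Rows that violate record invariants are rejected and reported in
    ``run.diagnostics`` (rows in = records out + diagnostics out); a
    duplicate accession or a missing mandatory column aborts the read.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such table: {path}")
    peptide_map = None
    if dialect.layout == "long":
        if dialect.peptide_path is None:
            raise FormatError("long layout requires dialect.peptide_path")
        peptide_map = _read_long_peptides(Path(dialect.peptide_path), dialect)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.sep)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, no header row")
        rows = list(reader)
        header = list(reader.fieldnames)
    return _rows_to_run(
        rows, header, dialect, run_id or path.stem, bait_accession, is_control,
        peptide_map,
    )


def read_protein_xlsx(
    path: str | Path,
    column_map: Mapping[str, str],
    *,
    area_sep: str = ";",
    run_id: str | None = None,
    bait_accession: str | None = None,
    is_control: bool = False,
) -> PullDownRun:
    """Read the first worksheet of an XLSX workbook as a wide protein table.

    The workbook schema is not standardized across search-engine exports,
    so ``column_map`` (canonical name -> worksheet header) is required.
    """
    from openpyxl import load_workbook

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such workbook: {path}")
    wb = load_workbook(path, read_only=True, data_only=True)
    ws = wb.worksheets[0]
    rows_iter = ws.iter_rows(values_only=True)
    try:
        header = [str(c) if c is not None else "" for c in next(rows_iter)]
    except StopIteration:
        raise FormatError(f"{path}: first worksheet is empty") from None
    dialect = TableDialect(columns=dict(column_map), area_sep=area_sep)
    rows = [
        {h: ("" if v is None else str(v)) for h, v in zip(header, values)}
        for values in rows_iter
        if any(v is not None for v in values)
    ]
    wb.close()
    return _rows_to_run(
        rows, header, dialect, run_id or path.stem, bait_accession, is_control,
        None,
    )


def _fmt(value: float | None) -> str:
    # str(float) is the shortest repr that round-trips exactly.
    return "" if value is None else str(value)


def write_protein_table(
    run: PullDownRun, path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> Path:
    """Write a run as a wide delimited table (inverse of the reader)."""
    if dialect.layout != "wide":
        raise ContractError("only the wide layout is written")
    path = Path(path)
    cols = dialect.columns
    fieldnames = [
        cols["accession"],
        cols.get("description", "description"),
        cols["score"],
        cols["coverage"],
        cols.get("peptide_sequences", "peptide_sequences"),
        cols.get("peptide_areas", "peptide_areas"),
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=dialect.sep)
        writer.writerow(fieldnames)
        for rec in run.records:
            writer.writerow(
                [
                    rec.accession,
                    rec.description,
                    _fmt(rec.score),
                    _fmt(rec.coverage),
                    dialect.area_sep.join(p.sequence for p in rec.peptides),
                    dialect.area_sep.join(_fmt(p.area) for p in rec.peptides),
                ]
            )
    return path


def write_run_manifest(
    report_path: str | Path,
    *,
    run_id: str,
    n_records: int,
    provenance: Mapping[str, object] | None = None,
) -> Path:
    manifest = {
        "run_id": run_id,
        "n_records": n_records,
        "provenance": dict(provenance or {}),
    }
    out = Path(str(report_path) + ".manifest.json")
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def write_interactor_report(
    calls: Sequence["InteractorCall"],
    path: str | Path,
    *,
    run_id: str = "",
    provenance: Mapping[str, object] | None = None,
) -> Path:
    """Write ranked interactor calls as a CSV report (stable order by rank).

    A JSON run-manifest is written alongside the report.  Requires ranks
    populated and contiguous from 1.
    """
    ranks = sorted(c.rank for c in calls if c.rank is not None)
    if len(ranks) != len(calls) or ranks != list(range(1, len(calls) + 1)):
        raise ContractError(
            "interactor report requires ranks populated and contiguous from 1"
        )
    path = Path(path)
    ordered = sorted(calls, key=lambda c: c.rank)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REPORT_COLUMNS)
        for c in ordered:
            writer.writerow(
                [
                    c.rank,
                    c.accession,
                    c.description,
                    _fmt(c.score),
                    _fmt(c.coverage),
                    c.n_peptides,
                    _fmt(c.t3pq_mean_area),
                    int(c.is_bait),
                ]
            )
    write_run_manifest(
        path, run_id=run_id, n_records=len(calls), provenance=provenance
    )
    return path


def read_interactor_report(path: str | Path) -> list["InteractorCall"]:
    """Read back a report written by :func:`write_interactor_report`."""
    from .interactor_calling import InteractorCall

    path = Path(path)
    calls: list[InteractorCall] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != list(REPORT_COLUMNS):
            raise FormatError(f"{path}: not an interactor report")
        for row in reader:
            calls.append(
                InteractorCall(
                    accession=row["accession"],
                    description=row["description"],
                    score=float(row["score"]),
                    coverage=float(row["coverage"]),
                    n_peptides=int(row["n_peptides"]),
                    t3pq_mean_area=float(row["t3pq_mean_area"]),
                    rank=int(row["rank"]),
                    is_bait=bool(int(row["bait_flag"])),
                )
            )
    return calls
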