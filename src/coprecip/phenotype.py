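"""Eye-size class model and per-genotype tabulation.

Adult eyes are scored by visual inspection into five categorical
classes relative to the wild-type eye: 0 (eye absent), 25, 50 and 75
(eye smaller than 25%, 50% and 75% of wild type) and 100 (normal size).
When two adjacent classes are both plausible the assignment is
deliberately conservative against the hypothesis being tested: without
a rescue construct the eye goes to the higher (milder-phenotype) class;
with a rescue construct present it goes to the lower class, so rescue
effects are never overstated.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ContractError, ValidationError

SIZE_CLASSES = (0, 25, 50, 75, 100)


@dataclass
class EyeRecord:
    """One scored eye."""

    genotype: str
    size_class: int | None = None
    ambiguous_between: tuple[int, int] | None = None
    rescue_present: bool = False
    note: str = ""  # free-text flag, e.g. "deformed, larger than wild type"

    def __post_init__(self) -> None:
        if self.size_class is not None and self.size_class not in SIZE_CLASSES:
            raise ValidationError(f"unknown size class {self.size_class}")
        if self.ambiguous_between is not None:
            lo, hi = sorted(self.ambiguous_between)
            if not _adjacent(lo, hi):
                raise ValidationError(
                    f"ambiguous pair {self.ambiguous_between} is not adjacent"
                )
            object.__setattr__(self, "ambiguous_between", (lo, hi))
        if self.size_class is None and self.ambiguous_between is None:
            raise ValidationError("eye has neither a class nor an ambiguous pair")


def _adjacent(lo: int, hi: int) -> bool:
    if lo not in SIZE_CLASSES or hi not in SIZE_CLASSES:
        return False
    return SIZE_CLASSES.index(hi) - SIZE_CLASSES.index(lo) == 1


def resolve_ambiguous_class(pair: tuple[int, int], rescue_present: bool) -> int:
    """Assign a dubious eye to one of two adjacent classes.

    Higher class without a rescue construct (a dubious class-50 eye is
    scored 75), lower class with one.
    """
    lo, hi = sorted(pair)
    if not _adjacent(lo, hi):
        raise ContractError(f"pair {pair} is not adjacent in {SIZE_CLASSES}")
    return lo if rescue_present else hi


def resolve_record(record: EyeRecord) -> EyeRecord:
    """Return a record with any ambiguity resolved (unambiguous: unchanged)."""
    if record.ambiguous_between is None:
        return record
    resolved = resolve_ambiguous_class(record.ambiguous_between, record.rescue_present)
    return EyeRecord(
        genotype=record.genotype,
        size_class=resolved,
        ambiguous_between=None,
        rescue_present=record.rescue_present,
        note=record.note,
    )


@dataclass
class EyeClassTally:
    """Per-genotype class counts and percentages."""

    genotype: str
    counts: dict[int, int] = field(
        default_factory=lambda: {c: 0 for c in SIZE_CLASSES}
    )

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    def percentages(self) -> dict[int, float]:
        n = self.n_total
        if n == 0:
            return {c: 0.0 for c in SIZE_CLASSES}
        return {c: 100.0 * k / n for c, k in self.counts.items()}

    def __add__(self, other: "EyeClassTally") -> "EyeClassTally":
        if other.genotype != self.genotype:
            raise ContractError("cannot merge tallies of different genotypes")
        merged = EyeClassTally(self.genotype)
        for c in SIZE_CLASSES:
            merged.counts[c] = self.counts[c] + other.counts[c]
        return merged


def tabulate_classes(records: list[EyeRecord]) -> list[EyeClassTally]:
    """One tally per genotype, in order of first appearance.

    All ambiguities must have been resolved first (see
    :func:`resolve_record`); class counts are conserved.
    """
    tallies: dict[str, EyeClassTally] = {}
    for rec in records:
        if rec.size_class is None:
            raise ContractError(
                f"unresolved ambiguous record for genotype {rec.genotype}"
            )
        tally = tallies.setdefault(rec.genotype, EyeClassTally(rec.genotype))
        tally.counts[rec.size_class] += 1
    return list(tallies.values())


def read_eye_records(path: str | Path) -> list[EyeRecord]:
    """Read a scoring CSV: genotype, eye_id, class, rescue[, note].

    ``class`` is either one label (``75``) or an adjacent ambiguous pair
    (``50/75``); ``rescue`` is 0/1.
    """
    records: list[EyeRecord] = []
    with open(Path(path), newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            cls = row["class"].strip()
            rescue = row.get("rescue", "0").strip() in {"1", "true", "True", "yes"}
            if "/" in cls:
                lo, hi = (int(tok) for tok in cls.split("/"))
                records.append(
                    EyeRecord(
                        genotype=row["genotype"],
                        ambiguous_between=(lo, hi),
                        rescue_present=rescue,
                        note=row.get("note", "") or "",
                    )
                )
            else:
                records.append(
                    EyeRecord(
                        genotype=row["genotype"],
                        size_class=int(cls),
                        rescue_present=rescue,
                        note=row.get("note", "") or "",
                    )
                )
    return records


def write_tally_csv(
    tallies: list[EyeClassTally], path: str | Path, *, long: bool = False
) -> Path:
    """Write tallies wide (one row per genotype) or long (tidy) format.

    Percentages are rendered to one decimal for display; raw counts are
    always present so no information is lost to rounding.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if long:
            writer.writerow(["genotype", "size_class", "count", "percent"])
            for t in tallies:
                pct = t.percentages()
                for c in SIZE_CLASSES:
                    writer.writerow([t.genotype, c, t.counts[c], f"{pct[c]:.1f}"])
        else:
            writer.writerow(
                ["genotype", "n_total"]
                + [f"class_{c}" for c in SIZE_CLASSES]
                + [f"pct_{c}" for c in SIZE_CLASSES]
            )
            for t in tallies:
                pct = t.percentages()
                writer.writerow(
                    [t.genotype, t.n_total]
                    + [t.counts[c] for c in SIZE_CLASSES]
                    + [f"{pct[c]:.1f}" for c in SIZE_CLASSES]
                )
    return path
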