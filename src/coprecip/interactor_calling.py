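"""Stringent interactor calling for GFP-TRAP co-precipitation data.

A protein ID from a bait pull-down is accepted as a bona fide interactor
only if it (1) has at least two distinct peptide sequences, (2) covers at
least 20% of the protein sequence, (3) has an overall search score
strictly above 50, and (4) is absent from an accumulated false-positive
database built as the union of protein IDs recovered in negative-control
pull-downs (non-specific resin/background binders).  Surviving proteins
are quantified by T3PQ — the mean of the three highest peptide abundance
areas — and ranked by that mean; the bait itself is expected to hold
rank 1 and is flagged, not counted among the specific interactors.

Boundary conventions: a score of exactly 50 is removed (the retention
rule is "above 50"), a coverage of exactly 20% is retained (the removal
rule is "<20%").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import AbsentBaitError, ContractError, UndefinedQuantityError, ValidationError
from .msio import ProteinGroupRecord, PullDownRun

RULES = ("min_peptides", "min_coverage", "min_score", "not_blacklisted")


@dataclass(frozen=True)
class FilterThresholds:
    """Cut-offs for the three threshold rules of the stringent filter."""

    min_distinct_peptides: int = 2
    min_coverage: float = 20.0
    min_score_exclusive: float = 50.0

    def __post_init__(self) -> None:
        if self.min_distinct_peptides < 1:
            raise ValidationError("min_distinct_peptides must be >= 1")
        if self.min_coverage < 0 or self.min_score_exclusive < 0:
            raise ValidationError("thresholds must be nonnegative")


@dataclass
class FalsePositiveDB:
    """Accumulated set of accessions seen in negative-control pull-downs."""

    accessions: set[str] = field(default_factory=set)
    source_run_ids: list[str] = field(default_factory=list)

    @property
    def n_control_runs(self) -> int:
        return len(set(self.source_run_ids))

    def __contains__(self, accession: str) -> bool:
        # Exact string match; no isoform collapsing (extension point).
        return accession in self.accessions


@dataclass
class FilterAudit:
    """Per-rule pass/fail flags for one record."""

    min_peptides: bool
    min_coverage: bool
    min_score: bool
    not_blacklisted: bool
    #: T3PQ computed from fewer than 3 present areas (graceful degradation).
    t3pq_degraded: bool = False

    @property
    def passed(self) -> bool:
        return (
            self.min_peptides
            and self.min_coverage
            and self.min_score
            and self.not_blacklisted
        )

    def failed_rules(self) -> list[str]:
        return [r for r in RULES if not getattr(self, r)]


@dataclass
class InteractorCall:
    """A protein that entered the filter, with its audit and quantification."""

    accession: str
    description: str
    score: float
    coverage: float
    n_peptides: int
    t3pq_mean_area: float | None = None
    rank: int | None = None
    is_bait: bool = False
    filter_audit: FilterAudit | None = None


def build_false_positive_db(controls: Iterable[PullDownRun]) -> FalsePositiveDB:
    """Union of all accessions appearing in any negative-control run.

    Deterministic regardless of run order; every supplied run must be a
    control (a bait precipitate in the blacklist would subtract true
    interactors).
    """
    db = FalsePositiveDB()
    for run in controls:
        if not run.is_control:
            raise ContractError(
                f"run {run.run_id} is not a control; refusing to blacklist it"
            )
        db.accessions |= run.accessions()
        db.source_run_ids.append(run.run_id)
    return db


def t3pq(record: ProteinGroupRecord) -> float:
    """Top-3 protein quantification: mean of the three highest peptide areas.

    With fewer than three present areas the mean of the available areas is
    returned (flagged upstream as degraded); with none the quantity is
    undefined and an error is raised rather than silently reporting 0.
    """
    areas = record.present_areas()
    if not areas:
        raise UndefinedQuantityError(
            f"{record.accession}: no peptide areas present, T3PQ undefined"
        )
    top = sorted(areas, reverse=True)[:3]
    return sum(top) / len(top)


def apply_stringent_filter(
    run: PullDownRun,
    db: FalsePositiveDB,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[InteractorCall], list[InteractorCall]]:
    """Evaluate all four rules on every record of a bait pull-down.

    Returns ``(survivors, rejected)``, both unranked; every record in the
    run appears in exactly one of the two lists and carries a full
    per-rule audit.  Survivors get a T3PQ mean area (records whose areas
    are all missing cannot be quantified and are rejected with the audit
    noting the degradation).
    """
    if run.is_control:
        raise ContractError(f"run {run.run_id} is a control, not a bait pull-down")
    survivors: list[InteractorCall] = []
    rejected: list[InteractorCall] = []
    for rec in run.records:
        audit = FilterAudit(
            min_peptides=rec.n_distinct_peptides >= thresholds.min_distinct_peptides,
            min_coverage=rec.coverage >= thresholds.min_coverage,
            min_score=rec.score > thresholds.min_score_exclusive,
            not_blacklisted=rec.accession not in db,
        )
        call = InteractorCall(
            accession=rec.accession,
            description=rec.description,
            score=rec.score,
            coverage=rec.coverage,
            n_peptides=rec.n_distinct_peptides,
            is_bait=(rec.accession == run.bait_accession),
            filter_audit=audit,
        )
        if audit.passed:
            try:
                call.t3pq_mean_area = t3pq(rec)
            except UndefinedQuantityError:
                audit.t3pq_degraded = True
                rejected.append(call)
                continue
            audit.t3pq_degraded = len(rec.present_areas()) < 3
            survivors.append(call)
        else:
            rejected.append(call)
    return survivors, rejected


def rank_interactors(calls: Sequence[InteractorCall]) -> list[InteractorCall]:
    """Rank calls by descending T3PQ mean area, contiguous from 1.

    Ties break by descending score, then lexicographic accession, so the
    ordering is total and byte-reproducible.
    """
    for c in calls:
        if c.t3pq_mean_area is None:
            raise ContractError(f"{c.accession}: t3pq_mean_area not populated")
    ordered = sorted(
        calls, key=lambda c: (-c.t3pq_mean_area, -c.score, c.accession)
    )
    for i, c in enumerate(ordered, start=1):
        c.rank = i
    return ordered


def verify_bait_top(
    ranked: Sequence[InteractorCall], bait: str
) -> tuple[bool, str]:
    """Check that the bait is the most abundant protein in the precipitate.

    Returns ``(ok, diagnostic)``; the diagnostic names the actual rank-1
    accession when the check fails.
    """
    if not ranked:
        raise ContractError("empty ranked list")
    by_acc = {c.accession: c for c in ranked}
    if bait not in by_acc:
        raise AbsentBaitError(f"bait {bait} absent from ranked list")
    top = min(ranked, key=lambda c: c.rank)
    if by_acc[bait].rank == 1:
        return True, f"bait {bait} holds rank 1"
    return (
        False,
        f"bait {bait} holds rank {by_acc[bait].rank}; rank 1 is {top.accession}",
    )


def call_interactors(
    bait_run: PullDownRun,
    controls: Sequence[PullDownRun],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[InteractorCall], list[InteractorCall], FalsePositiveDB]:
    """Full chain: blacklist, four-rule filter, T3PQ, ranking.

    Returns ``(ranked_calls, rejected, db)``.  The ranked list includes
    the bait (flagged ``is_bait``); specific interactors are the non-bait
    entries.
    """
    db = build_false_positive_db(controls)
    survivors, rejected = apply_stringent_filter(bait_run, db, thresholds)
    ranked = rank_interactors(survivors)
    return ranked, rejected, db


def specific_interactors(ranked: Sequence[InteractorCall]) -> list[InteractorCall]:
    """Non-bait survivors, in rank order."""
    return [c for c in sorted(ranked, key=lambda c: c.rank) if not c.is_bait]
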