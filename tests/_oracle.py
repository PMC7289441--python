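"""Independent brute-force re-implementation of the calling chain.

Used as the oracle in equivalence tests: evaluates each filter rule
directly from record fields, recomputes top-3 quantification by a full
sort, and ranks with the same total order.  Deliberately shares no code
with the package implementation.
"""

from __future__ import annotations

import random
import string

from coprecip.msio import PeptideHit, ProteinGroupRecord, PullDownRun


def oracle_ranked_accessions(run, controls, min_pep=2, min_cov=20.0, min_score=50.0):
    """Ranked accession list per the four rules, by exhaustive evaluation."""
    blacklist = set()
    for ctrl in controls:
        for rec in ctrl.records:
            blacklist.add(rec.accession)
    kept = []
    for rec in run.records:
        n_distinct = len({p.sequence for p in rec.peptides})
        passes = (
            n_distinct >= min_pep
            and rec.coverage >= min_cov
            and rec.score > min_score
            and rec.accession not in blacklist
        )
        areas = [p.area for p in rec.peptides if p.area is not None]
        if passes and areas:
            full_sort = sorted(areas, reverse=True)
            top = full_sort[: min(3, len(full_sort))]
            kept.append((rec.accession, sum(top) / len(top), rec.score))
    kept.sort(key=lambda item: (-item[1], -item[2], item[0]))
    return [(acc, t3) for acc, t3, _score in kept]


def random_table(py_rng: random.Random, max_records: int = 50):
    """A random bait run + controls straddling every filter boundary."""
    n = py_rng.randint(0, max_records)
    records = []
    for i in range(n):
        n_pep = py_rng.randint(1, 5)
        seqs = set()
        while len(seqs) < n_pep:
            seqs.add(
                "".join(py_rng.choices("ACDEFGHIKLMNPQRSTVWY", k=py_rng.randint(6, 12)))
            )
        peptides = [
            PeptideHit(s, None if py_rng.random() < 0.1 else py_rng.uniform(0, 1e6))
            for s in sorted(seqs)
        ]
        records.append(
            ProteinGroupRecord(
                accession=f"P{i:04d}",
                description="",
                # values concentrated around the 50 / 20 cut-offs
                score=py_rng.choice([50.0, 49.9, 50.1, py_rng.uniform(0, 200)]),
                coverage=py_rng.choice([20.0, 19.99, py_rng.uniform(0, 100)]),
                peptides=peptides,
            )
        )
    run = PullDownRun(run_id="rand", records=records)
    ctrl_records = [
        ProteinGroupRecord(accession=f"P{i:04d}", description="", score=10.0,
                           coverage=5.0, peptides=[PeptideHit("ACD", 1.0)])
        for i in range(n)
        if py_rng.random() < 0.2
    ]
    controls = [PullDownRun(run_id="ctrl", records=ctrl_records, is_control=True)]
    return run, controls
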