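import numpy as np
import pytest

from coprecip.msio import PeptideHit, ProteinGroupRecord, PullDownRun


def make_record(accession, score=100.0, coverage=50.0, areas=(10.0, 20.0, 30.0),
                n_distinct=None):
    """Record with the given stats; peptide count defaults to len(areas)."""
    seq_pool = ["ACDEFGHIK", "LMNPQRSTV", "WYACDEFGH", "IKLMNPQRS", "TVWYACDEF",
                "GHIKLMNPQ", "RSTVWYACD", "EFGHIKLMN"]
    n = n_distinct if n_distinct is not None else len(areas)
    peptides = [
        PeptideHit(seq_pool[i % len(seq_pool)] + "A" * (i // len(seq_pool)),
                   areas[i] if i < len(areas) else None)
        for i in range(n)
    ]
    return ProteinGroupRecord(accession=accession, description=f"protein {accession}",
                              score=score, coverage=coverage, peptides=peptides)


def make_control(run_id, accessions):
    return PullDownRun(
        run_id=run_id,
        records=[make_record(a, score=30.0, coverage=10.0, areas=(1.0,)) for a in accessions],
        is_control=True,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_run():
    """5-record toy pull-down exercising each filter rule independently."""
    records = [
        make_record("A", score=120.0, coverage=35.0, areas=(5.0, 7.0, 9.0, 11.0)),
        make_record("B", score=60.0, coverage=10.0, areas=(5.0, 7.0, 9.0)),
        make_record("C", score=200.0, coverage=40.0, areas=(5.0,)),
        make_record("D", score=45.0, coverage=50.0, areas=(1.0, 2.0, 3.0, 4.0, 5.0)),
        make_record("E", score=80.0, coverage=25.0, areas=(5.0, 7.0, 9.0)),
    ]
    return PullDownRun(run_id="toy", records=records)
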