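import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from irefkit.identity import Rogid, compute_rogid
from irefkit.mitab_io import Interactor, SourceRecord
from irefkit.synthetic import SimConfig, generate_corpus


def make_protein(seq: str, taxid: int = 9606, **accessions) -> Interactor:
    rogid = compute_rogid(seq, taxid)
    interactor = Interactor(rogid=rogid, taxid=taxid, sequence=seq)
    for acc_type, value in accessions.items():
        values = value if isinstance(value, list) else [value]
        for v in values:
            interactor.add_accession(acc_type, v)
    return interactor


def binary_record(record_id, a: Interactor, b: Interactor, *, source_db="dbA",
                  source_acc=None, pmids=(1,), method_cv="MI:0018",
                  method_name="two hybrid", roles=("neutral", "neutral"),
                  predicted=False) -> SourceRecord:
    return SourceRecord(
        record_id=record_id,
        source_db=source_db,
        source_acc=source_acc or f"acc{record_id}",
        participants=[(a.rogid, roles[0]), (b.rogid, roles[1])],
        pmids=list(pmids),
        method_cv=method_cv,
        method_name=method_name,
        edgetype="X",
        predicted=predicted,
    )


def nary_record(record_id, members, *, source_db="dbA", source_acc=None,
                pmids=(1,), method_cv="MI:0004", bait=None) -> SourceRecord:
    participants = []
    for m in members:
        role = "bait" if bait is not None and m is bait else "neutral"
        participants.append((m.rogid, role))
    return SourceRecord(
        record_id=record_id,
        source_db=source_db,
        source_acc=source_acc or f"acc{record_id}",
        participants=participants,
        pmids=list(pmids),
        method_cv=method_cv,
        method_name="affinity chromatography",
        edgetype="C",
    )


@pytest.fixture
def proteins():
    """Five distinct toy proteins with uniprot accessions."""
    return [
        make_protein("MKVA" + "A" * i, uniprot=f"P0000{i}") for i in range(5)
    ]


@pytest.fixture(scope="session")
def corpus():
    """A mid-sized seeded corpus shared by read-only tests."""
    return generate_corpus(SimConfig(seed=42))


@pytest.fixture(scope="session")
def big_corpus():
    """Corpus at acceptance scale: 1,000 records, duplication 0.5, 3 dbs."""
    return generate_corpus(SimConfig(
        n_proteins=300, n_genes=150, n_records=1000,
        duplication_rate=0.5, n_source_dbs=3, seed=11,
    ))
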