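import pytest

from blasthits.fixtures import SynthSpec, render_report, synth_dataset
from blasthits.model import HSP, Dataset, SeqEntry
from blasthits.taxonomy import load_toy_tree, write_toy_taxdump


def make_hsp(qid=0, sid=0, evalue=1e-10, bit=100.0, **kw):
    base = dict(
        query_id=qid, seq_id=sid, evalue=evalue, bit_score=bit, raw_score=220,
        identity_pct=50.0, positive_pct=60.0, gaps=0, align_len=100,
        q_start=1, q_end=100, s_start=1, s_end=100, q_frame=0, s_frame=0,
    )
    base.update(kw)
    return HSP(**base)


def make_dataset(queries, deflines, hsps):
    """Hand-rolled dataset from (queries, deflines, list of HSP kwargs)."""
    return Dataset(
        queries=list(queries),
        sequences=[SeqEntry(d) if isinstance(d, str) else SeqEntry(*d)
                   for d in deflines],
        hsps=[make_hsp(**kw) for kw in hsps],
    )


@pytest.fixture
def small_dataset():
    return synth_dataset(SynthSpec(n_queries=4, seed=7))


@pytest.fixture
def medium_dataset():
    return synth_dataset(SynthSpec(n_queries=12, hits_per_query=(0, 10), seed=42))


@pytest.fixture
def toy_tree():
    return load_toy_tree()


@pytest.fixture
def taxdump_dir(tmp_path):
    write_toy_taxdump(tmp_path / "taxdump")
    return tmp_path / "taxdump"


@pytest.fixture
def text_report(tmp_path, small_dataset):
    return render_report(small_dataset, "text", tmp_path / "report.txt")


@pytest.fixture
def xml_report(tmp_path, small_dataset):
    return render_report(small_dataset, "xml", tmp_path / "report.xml")
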