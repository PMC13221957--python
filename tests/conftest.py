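import pytest

from narralex.corpus_io import CorpusTable, NarrativeRecord
from narralex.lexicon_engine import default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


def make_record(nid="n1", author=None, text="Hello world.", kind="FPA",
                flag=None, order=0):
    return NarrativeRecord(
        narrative_id=nid,
        author_id=author or nid,
        text=text,
        account_type=kind,
        interpersonal_difficulties=flag,
        publication_order=order,
    )


@pytest.fixture
def small_corpus(tmp_path):
    """Three narratives on disk: metadata CSV plus UTF-8 text files."""
    texts = {
        "a.txt": "I was afraid. My doctor helped me.\n",
        "b.txt": "She visited the hospital.\r\nIt was good.\r\n",
        "c.txt": "I don’t have friends. Not good.\n",
    }
    for name, content in texts.items():
        (tmp_path / name).write_text(content, encoding="utf-8")
    meta = tmp_path / "meta.csv"
    meta.write_text(
        "narrative_id,author_id,file,account_type,"
        "interpersonal_difficulties,publication_order\n"
        "n1,auth1,a.txt,FPA,true,1\n"
        "n2,auth2,b.txt,TPA,,1\n"
        "n3,auth3,c.txt,FPA,false,1\n",
        encoding="utf-8",
    )
    return meta, tmp_path
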