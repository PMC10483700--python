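import pytest

from citedupe.io_formats import Citation, CitationSet


def make_citation(record_id: str, **fields) -> Citation:
    defaults = dict(
        author="Smith, J.; Jones, A.",
        year="2020",
        title="Effects of drug X in rats",
        journal="Journal of Experimental Neuroscience",
        abstract="A study of drug X on outcomes in a rat model.",
        doi="10.1234/abcd1234",
        isbn_issn="1234-5678",
        pages="101-110",
        volume="12",
        issue="3",
        label="",
    )
    defaults.update(fields)
    return Citation(record_id=record_id, **defaults)


@pytest.fixture
def pair_set() -> CitationSet:
    """Two records that are the same publication in different export dialects."""
    a = make_citation("A")
    b = make_citation(
        "B",
        title="Effects of Drug X in Rats.",
        doi="https://doi.org/10.1234/ABCD1234",
        author="Smith J; Jones A",
        abstract="",
    )
    c = make_citation(
        "C",
        title="A completely different study of something else entirely",
        doi="10.9999/zzzz9999",
        author="Brown, B.",
        year="2011",
        journal="Annals of Metabolism",
        pages="55-63",
        volume="4",
        issue="1",
        isbn_issn="8765-4321",
    )
    return CitationSet([a, b, c])
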