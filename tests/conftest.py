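import pytest

from uindex import fixtures


def jats_bytes(
    article_id="PMC900001",
    headings=("Research Article",),
    journal="Journal of Molecular Biology",
    year=2010,
    sections="",
    refs="",
):
    """Assemble a minimal JATS document from section/ref XML snippets."""
    subjects = "".join(f"<subject>{h}</subject>" for h in headings)
    return f"""<?xml version="1.0" encoding="UTF-8"?>
<article article-type="research-article">
  <front>
    <journal-meta><journal-title>{journal}</journal-title></journal-meta>
    <article-meta>
      <article-id pub-id-type="pmc">{article_id}</article-id>
      <article-categories><subj-group>{subjects}</subj-group></article-categories>
      <pub-date><year>{year}</year></pub-date>
    </article-meta>
  </front>
  <body>{sections}</body>
  <back><ref-list>{refs}</ref-list></back>
</article>""".encode()


def ref_xml(label, pmid=None):
    pid = f'<pub-id pub-id-type="pmid">{pmid}</pub-id>' if pmid else ""
    return (
        f'<ref id="B{label}"><label>{label}</label>'
        f"<mixed-citation>Some cited work.{pid}</mixed-citation></ref>"
    )


def xref(label):
    return f'<xref ref-type="bibr" rid="B{label}">{label}</xref>'


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """A default synthetic corpus, generated once per session."""
    out = tmp_path_factory.mktemp("corpus")
    spec = fixtures.FixtureSpec(seed=1)
    jats_paths, medline_paths, truth = fixtures.generate_corpus(spec, out)
    return {
        "spec": spec,
        "jats": jats_paths,
        "medline": medline_paths,
        "truth": truth,
        "dir": out,
    }
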