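"""JATS parsing, methods detection, citation location and universe filtering."""

import itertools

import pytest
from lxml import etree

from uindex import jats
from uindex.jats import (
    METHODS,
    OTHER,
    ReferenceEntry,
    SectionNode,
    build_citing_universe,
    classify_section,
    expand_reference_range,
    has_methods_section,
    is_research_article,
    parse_jats_article,
    resolve_citation_locations,
)

from conftest import jats_bytes, ref_xml, xref


class TestParse:
    def test_sections_refs_and_xrefs_captured(self):
        doc = jats_bytes(
            sections=(
                '<sec sec-type="methods"><title>Methods</title>'
                f"<p>We used a tool {xref(1)}.</p></sec>"
                f"<sec><title>Discussion</title><p>See {xref(2)} and {xref(3)}.</p></sec>"
            ),
            refs=ref_xml(1, 11111) + ref_xml(2, 22222) + ref_xml(3),
        )
        rec = parse_jats_article(doc)
        assert rec.article_id == "PMC900001"
        assert rec.headings == {"Research Article"}
        assert rec.journal_title == "Journal of Molecular Biology"
        assert rec.pub_year == 2010
        assert [s.title for s in rec.sections] == ["Methods", "Discussion"]
        assert [r.ref_id for r in rec.references] == ["B1", "B2", "B3"]
        assert rec.references[0].cited_pmid == "11111"
        assert rec.references[2].cited_pmid is None
        assert ("B1", METHODS) in rec.xref_occurrences
        assert ("B2", OTHER) in rec.xref_occurrences

    def test_empty_article_has_empty_fields(self):
        rec = parse_jats_article(jats_bytes())
        assert rec.sections == [] and rec.references == []
        assert rec.xref_occurrences == []

    def test_truncated_xml_raises_parse_error(self):
        with pytest.raises(etree.XMLSyntaxError):
            parse_jats_article(b"<article><front><body>")

    def test_article_id_falls_back_to_filename(self, tmp_path):
        path = tmp_path / "stem42.xml"
        doc = jats_bytes().replace(
            b'<article-id pub-id-type="pmc">PMC900001</article-id>', b""
        )
        path.write_bytes(doc)
        assert parse_jats_article(path).article_id == "stem42"


class TestResearchArticleFilter:
    @pytest.mark.parametrize(
        "headings,exclusion,expected",
        [
            ({"Research Article"}, {"Review", "Editorial"}, True),
            ({"Review"}, {"Review", "Editorial"}, False),
            ({"REVIEW"}, {"Review"}, False),  # case-insensitive
            (set(), {"Review"}, True),
        ],
    )
    def test_exclusion_by_heading(self, headings, exclusion, expected):
        assert is_research_article(headings, exclusion) is expected
        # oracle: brute-force lowercase intersection
        brute = not {h.lower() for h in headings} & {e.lower() for e in exclusion}
        assert is_research_article(headings, exclusion) == brute


class TestSectionClassification:
    def test_sec_type_attribute_wins(self):
        node = SectionNode("materials|methods", "Cell culture", 0)
        assert classify_section(node) == METHODS

    def test_title_used_when_sec_type_missing(self):
        assert classify_section(SectionNode(None, "Materials and Methods", 0)) == METHODS
        assert classify_section(SectionNode(None, "Discussion", 0)) == OTHER

    def test_non_methods_sec_type_ignores_title(self):
        node = SectionNode("discussion", "Methods", 0)
        assert classify_section(node) == OTHER

    def test_ancestor_propagation_to_depth_four(self):
        root = SectionNode("methods", "Methods", 0)
        root.is_methods = True
        node = root
        for depth, title in enumerate(["Samples", "Assays", "Statistics"], 1):
            node = SectionNode(None, title, depth, parent=node)
            node.is_methods = classify_section(node) == METHODS
            assert node.is_methods, f"depth {depth} lost the methods class"

    def test_has_methods_section(self):
        doc = jats_bytes(sections="<sec><title>Materials and Methods</title></sec>")
        assert has_methods_section(parse_jats_article(doc))
        doc = jats_bytes(sections="<sec><title>Results</title></sec>")
        assert not has_methods_section(parse_jats_article(doc))


class TestRangeExpansion:
    REFS = [ReferenceEntry(f"B{i}", label=str(i)) for i in range(1, 21)]

    def test_matches_brute_force_on_all_ranges(self):
        for lo, hi in itertools.combinations_with_replacement(range(1, 21), 2):
            expanded = expand_reference_range(str(lo), str(hi), self.REFS)
            brute = [f"B{i}" for i in range(lo, hi + 1)]
            assert expanded == brute

    def test_single_element_range(self):
        assert expand_reference_range("2", "2", self.REFS) == ["B2"]

    def test_inverted_range_is_empty(self):
        assert expand_reference_range("5", "2", self.REFS) == []

    def test_non_numeric_labels_skipped(self):
        refs = [ReferenceEntry("Ba", label="a"), ReferenceEntry("B2", label="2")]
        assert expand_reference_range("a", "2", refs) == []
        assert expand_reference_range("1", "3", refs) == ["B2"]


class TestCitationLocations:
    def _article(self):
        sections = (
            '<sec sec-type="methods"><title>Methods</title>'
            f"<p>{xref(1)} and again {xref(1)}.</p></sec>"
            "<sec><title>Discussion</title>"
            f"<p>{xref(1)}, {xref(2)}, and a bad one "
            '<xref ref-type="bibr" rid="B99">99</xref>.</p></sec>'
        )
        refs = ref_xml(1, 11111) + ref_xml(2, 22222) + ref_xml(3, 33333)
        return parse_jats_article(jats_bytes(sections=sections, refs=refs))

    def test_mixed_methods_and_other(self):
        locs = resolve_citation_locations(self._article())
        assert locs["B1"] == {METHODS, OTHER}
        assert locs["B2"] == {OTHER}

    def test_uncited_ref_absent_from_map(self):
        locs = resolve_citation_locations(self._article())
        assert "B3" not in locs

    def test_unknown_rid_skipped(self):
        locs = resolve_citation_locations(self._article())
        assert "B99" not in locs

    def test_range_citation_in_methods(self):
        sections = (
            '<sec sec-type="methods"><title>Methods</title>'
            f"<p>Tools [{xref(2)}-{xref(5)}] were run.</p></sec>"
        )
        refs = "".join(ref_xml(i, 10000 + i) for i in range(1, 7))
        rec = parse_jats_article(jats_bytes(sections=sections, refs=refs))
        locs = resolve_citation_locations(rec)
        assert set(locs) == {"B2", "B3", "B4", "B5"}
        assert all(v == {METHODS} for v in locs.values())


class TestUniverse:
    def test_round_trip_against_ground_truth(self, corpus):
        """Parser output equals the generator's plan for every article."""
        truth = corpus["truth"]
        universe = build_citing_universe(corpus["jats"])
        assert {a.article_id for a in universe} == {
            aid for aid, t in truth.articles.items() if t["retained"]
        }
        for article in universe:
            assert article.citation_locations == truth.articles[
                article.article_id
            ]["locations"]

    def test_location_completeness(self, corpus):
        """Location keys == refs with at least one (possibly ranged) xref."""
        for path in corpus["jats"]:
            rec = parse_jats_article(path)
            locs = resolve_citation_locations(rec)
            known = {r.ref_id for r in rec.references}
            cited = {rid for rid, _ in rec.xref_occurrences if rid in known}
            assert set(locs) == cited

    def test_filtering_monotonicity(self, corpus):
        """Growing the exclusion list never grows the universe."""
        paths = corpus["jats"][:40]
        exclusion = set()
        prev = len(build_citing_universe(paths, exclusion))
        for heading in ["Review", "Editorial", "Letter", "Commentary"]:
            exclusion.add(heading)
            size = len(build_citing_universe(paths, exclusion))
            assert size <= prev
            prev = size

    def test_unreadable_file_is_skipped(self, tmp_path):
        good = tmp_path / "ok.xml"
        good.write_bytes(
            jats_bytes(sections='<sec sec-type="methods"><title>M</title></sec>')
        )
        bad = tmp_path / "bad.xml"
        bad.write_bytes(b"<article><unclosed>")
        universe = build_citing_universe([good, bad, tmp_path / "missing.xml"])
        assert len(universe) == 1

    def test_empty_input_gives_empty_universe(self):
        assert build_citing_universe([]) == []

    def test_citations_table_collapses_per_pmid(self):
        sections = (
            '<sec sec-type="methods"><title>Methods</title>'
            f"<p>{xref(1)} {xref(2)}</p></sec>"
            f"<sec><title>Discussion</title><p>{xref(1)} {xref(3)}</p></sec>"
        )
        # B1 and B3 share a PMID: one row, methods wins
        refs = ref_xml(1, 11111) + ref_xml(2, 22222) + ref_xml(3, 11111)
        rec = parse_jats_article(jats_bytes(sections=sections, refs=refs))
        resolve_citation_locations(rec)
        df = jats.citations_table([rec])
        assert len(df) == 2
        row = df[df.cited_pmid == "11111"].iloc[0]
        assert row.in_methods == 1
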