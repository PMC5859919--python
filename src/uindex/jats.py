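"""Parse JATS/PMC full-text XML into section-aware citation records.

The citing universe is built from full-text research articles.  For each
article we record its section tree, its reference list, and — via ``<xref
ref-type="bibr">`` cross-references in the body — the section class
(``methods`` vs ``other``) of every in-text citation.  A citation occurring
anywhere inside a Materials/Methods section (including nested subsections)
is a *usage* signal; everything else is *awareness*.

Only a small, documented subset of JATS is honoured: ``<article>``,
front-matter subject headings, ``<sec sec-type=...>``, ``<title>``,
``<xref ref-type="bibr" rid=...>``, ``<ref-list>``, ``<ref id=...>``,
``<label>`` and ``<pub-id pub-id-type="pmid">``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

METHODS = "methods"
OTHER = "other"

#: sec-type attribute values recognised as Materials/Methods (lowercased).
DEFAULT_METHODS_SEC_TYPES = frozenset(
    {"materials|methods", "methods", "materials-and-methods"}
)

#: Title patterns consulted only when the sec-type attribute is absent.
#: Each is matched case-insensitively against the full (stripped) title.
DEFAULT_METHODS_TITLE_PATTERNS = (
    r"materials\s+and\s+methods",
    r"methods(\s+and\s+materials)?",
    r"materials\s*/\s*methods",
    r"experimental\s+procedures",
)

#: Subject headings that disqualify an article from the research-article
#: universe.  Fully overridable; matching is case-insensitive.
DEFAULT_EXCLUSION_HEADINGS = frozenset(
    {
        "Review",
        "Editorial",
        "Correction",
        "Retraction",
        "News",
        "Letter",
        "Case Report",
        "Commentary",
    }
)

_DASH_RE = re.compile(r"\s*[-–—]\s*")


@dataclass
class SectionNode:
    """One ``<sec>`` element; ``is_methods`` propagates from ancestors."""

    sec_type: Optional[str]
    title: Optional[str]
    depth: int
    parent: Optional["SectionNode"] = field(default=None, repr=False)
    is_methods: bool = False


@dataclass
class ReferenceEntry:
    """One ``<ref>`` from the reference list."""

    ref_id: str
    label: Optional[str] = None
    cited_pmid: Optional[str] = None
    raw_citation: str = ""


@dataclass
class ArticleRecord:
    """A citing article with its sections, references and citation sites."""

    article_id: str
    headings: set[str] = field(default_factory=set)
    journal_title: str = ""
    pub_year: Optional[int] = None
    sections: list[SectionNode] = field(default_factory=list)
    references: list[ReferenceEntry] = field(default_factory=list)
    #: raw (ref_id, section_class) citation occurrences, ranges expanded
    xref_occurrences: list[tuple[str, str]] = field(default_factory=list)
    #: ref_id -> set of section classes; populated by resolve_citation_locations
    citation_locations: dict[str, set[str]] = field(default_factory=dict)


@dataclass
class SectionConfig:
    """Configurable Materials/Methods detection rules."""

    methods_sec_types: frozenset[str] = DEFAULT_METHODS_SEC_TYPES
    methods_title_patterns: Sequence[str] = DEFAULT_METHODS_TITLE_PATTERNS

    def compiled_patterns(self) -> list[re.Pattern]:
        return [re.compile(p, re.IGNORECASE) for p in self.methods_title_patterns]


def classify_section(
    node: SectionNode,
    methods_sec_types: Iterable[str] = DEFAULT_METHODS_SEC_TYPES,
    methods_title_patterns: Sequence[str | re.Pattern] = DEFAULT_METHODS_TITLE_PATTERNS,
) -> str:
    """Classify a section as ``methods`` or ``other``.

    A section is methods when its ``sec-type`` attribute matches one of
    ``methods_sec_types`` (case-insensitive), or — only when the attribute
    is absent — its title fully matches one of the title patterns, or any
    ancestor section is methods.
    """
    if node.parent is not None and node.parent.is_methods:
        return METHODS
    types = {t.lower() for t in methods_sec_types}
    if node.sec_type is not None:
        return METHODS if node.sec_type.strip().lower() in types else OTHER
    if node.title is not None:
        title = node.title.strip()
        for pat in methods_title_patterns:
            rx = re.compile(pat, re.IGNORECASE) if isinstance(pat, str) else pat
            if rx.fullmatch(title):
                return METHODS
    return OTHER


def is_research_article(
    headings: Iterable[str],
    exclusion_list: Iterable[str] = DEFAULT_EXCLUSION_HEADINGS,
) -> bool:
    """True unless any heading matches the exclusion list (case-insensitive)."""
    excluded = {h.lower() for h in exclusion_list}
    return not any(h.lower() in excluded for h in headings)


def has_methods_section(article: ArticleRecord) -> bool:
    """True iff any section of the article is classified as methods."""
    return any(s.is_methods for s in article.sections)


def expand_reference_range(
    first_label: str,
    last_label: str,
    references: Sequence[ReferenceEntry],
) -> list[str]:
    """Expand a bracketed enumeration like ``[2-5]`` into ref ids.

    Returns the ids of all references whose numeric label lies in
    ``[first, last]`` inclusive, in ascending label order.  Non-numeric or
    inverted bounds cannot be resolved and yield an empty expansion with a
    warning, mirroring the best-effort nature of implicit enumerations.
    """
    try:
        lo, hi = int(first_label), int(last_label)
    except (TypeError, ValueError):
        logger.warning("unresolvable reference range %r-%r", first_label, last_label)
        return []
    if lo > hi:
        logger.warning("inverted reference range %s-%s", lo, hi)
        return []
    matches = []
    for ref in references:
        if ref.label is None:
            continue
        try:
            num = int(ref.label)
        except ValueError:
            continue
        if lo <= num <= hi:
            matches.append((num, ref.ref_id))
    return [ref_id for _, ref_id in sorted(matches)]


def _text(elem: Optional[etree._Element]) -> str:
    return "".join(elem.itertext()).strip() if elem is not None else ""


def parse_jats_article(
    source,
    article_id: Optional[str] = None,
    section_config: Optional[SectionConfig] = None,
) -> ArticleRecord:
    """Parse one JATS article into an :class:`ArticleRecord`.

    ``source`` may be a path, a file-like object or raw bytes.  Missing
    optional structure (no sections, no ``<ref-list>``) produces empty
    fields, not errors; malformed XML raises ``etree.XMLSyntaxError``.
    In-text ``<xref>`` occurrences are captured (with dash-joined xref
    pairs expanded as reference ranges) but the per-reference location map
    is left to :func:`resolve_citation_locations`.
    """
    cfg = section_config or SectionConfig()
    patterns = cfg.compiled_patterns()
    name = None
    if isinstance(source, (str, Path)):
        name = Path(source).stem
        tree = etree.parse(str(source))
    elif isinstance(source, bytes):
        tree = etree.ElementTree(etree.fromstring(source))
    else:
        tree = etree.parse(source)
    root = tree.getroot()

    record = ArticleRecord(article_id=article_id or "")

    # --- front matter -------------------------------------------------
    for aid in root.iter("article-id"):
        if not record.article_id:
            record.article_id = _text(aid)
        if aid.get("pub-id-type") in ("pmc", "pmcid"):
            record.article_id = _text(aid)
    if not record.article_id:
        record.article_id = name or "unknown"
    for subj in root.iter("subject"):
        txt = _text(subj)
        if txt:
            record.headings.add(txt)
    jt = root.find(".//journal-meta//journal-title")
    record.journal_title = _text(jt)
    year_el = root.find(".//article-meta/pub-date/year")
    if year_el is not None:
        try:
            record.pub_year = int(_text(year_el))
        except ValueError:
            record.pub_year = None

    # --- reference list (parsed first: range expansion needs labels) ---
    for ref in root.iter("ref"):
        label = _text(ref.find("label")) or None
        pmid = None
        for pid in ref.iter("pub-id"):
            if pid.get("pub-id-type") == "pmid":
                digits = _text(pid)
                if digits.isdigit():
                    pmid = digits
        record.references.append(
            ReferenceEntry(
                ref_id=ref.get("id") or (label or ""),
                label=label,
                cited_pmid=pmid,
                raw_citation=_text(ref),
            )
        )

    # --- section tree and in-text citation occurrences ----------------
    # One walk carries the enclosing SectionNode, so every xref is
    # attributed to its section (ancestor-propagated methods class).
    body = root.find("body")

    def walk(elem, section: Optional[SectionNode], depth: int) -> None:
        for child in elem:
            if child.tag == "sec":
                node = SectionNode(
                    sec_type=child.get("sec-type"),
                    title=_text(child.find("title")) or None,
                    depth=depth,
                    parent=section,
                )
                node.is_methods = (
                    classify_section(node, cfg.methods_sec_types, patterns)
                    == METHODS
                )
                record.sections.append(node)
                walk(child, node, depth + 1)
                continue
            if child.tag == "xref" and child.get("ref-type", "bibr") == "bibr":
                section_class = (
                    METHODS if section is not None and section.is_methods else OTHER
                )
                for rid in (child.get("rid") or "").split():
                    record.xref_occurrences.append((rid, section_class))
                # dash-joined sibling xrefs denote a range like [2-5]
                if child.tail and _DASH_RE.fullmatch(child.tail):
                    nxt = child.getnext()
                    if (
                        nxt is not None
                        and nxt.tag == "xref"
                        and nxt.get("ref-type", "bibr") == "bibr"
                    ):
                        first = _label_for(child.get("rid"), record.references)
                        last = _label_for(nxt.get("rid"), record.references)
                        for rid in expand_reference_range(
                            first, last, record.references
                        ):
                            record.xref_occurrences.append((rid, section_class))
            walk(child, section, depth)

    if body is not None:
        walk(body, None, 0)
    return record


def _label_for(rid: Optional[str], references: Sequence[ReferenceEntry]):
    if not rid:
        return None
    rid = rid.split()[0]
    for ref in references:
        if ref.ref_id == rid:
            return ref.label
    return None


def resolve_citation_locations(article: ArticleRecord) -> dict[str, set[str]]:
    """Build the ref_id -> {methods, other} map from captured occurrences.

    References never cited in the body are absent from the map; an xref
    pointing at an unknown ref id is logged and skipped.  The map is also
    stored on ``article.citation_locations``.
    """
    known = {ref.ref_id for ref in article.references}
    locations: dict[str, set[str]] = {}
    for rid, section_class in article.xref_occurrences:
        if rid not in known:
            logger.warning(
                "article %s: xref to unknown ref id %r skipped",
                article.article_id,
                rid,
            )
            continue
        locations.setdefault(rid, set()).add(section_class)
    article.citation_locations = locations
    return locations


def build_citing_universe(
    article_paths: Iterable,
    exclusion_list: Iterable[str] = DEFAULT_EXCLUSION_HEADINGS,
    section_config: Optional[SectionConfig] = None,
) -> list[ArticleRecord]:
    """Parse articles and keep the research-article/Methods-bearing universe.

    Retains exactly the articles that pass :func:`is_research_article` and
    :func:`has_methods_section`; each retained record has its citation
    locations resolved.  Unreadable or malformed files are logged and
    skipped.  The parsed/excluded/retained funnel is logged.
    """
    exclusion = set(exclusion_list)
    universe: list[ArticleRecord] = []
    n_parsed = n_not_research = n_no_methods = n_failed = 0
    for path in article_paths:
        try:
            record = parse_jats_article(path, section_config=section_config)
        except (OSError, etree.XMLSyntaxError) as exc:
            logger.error("failed to parse %s: %s", path, exc)
            n_failed += 1
            continue
        n_parsed += 1
        if not is_research_article(record.headings, exclusion):
            n_not_research += 1
            continue
        if not has_methods_section(record):
            n_no_methods += 1
            continue
        resolve_citation_locations(record)
        universe.append(record)
    logger.info(
        "citing universe: %d parsed, %d failed, %d non-research, "
        "%d without methods, %d retained",
        n_parsed,
        n_failed,
        n_not_research,
        n_no_methods,
        len(universe),
    )
    return universe


def citations_table(universe: Sequence[ArticleRecord]):
    """Collapse a universe to one row per (citing article, cited PMID).

    Returns a ``pandas.DataFrame`` with columns ``citing_article_id``,
    ``citing_pub_year``, ``citing_journal``, ``cited_pmid`` and
    ``in_methods`` (0/1).  Only references carrying a PMID participate;
    ``in_methods`` is 1 iff any citation of that PMID in the article falls
    in a methods section.  Rows are sorted for reproducible output.
    """
    import pandas as pd

    rows = []
    for article in universe:
        pmid_of = {
            r.ref_id: r.cited_pmid for r in article.references if r.cited_pmid
        }
        per_pmid: dict[str, int] = {}
        for rid, classes in sorted(article.citation_locations.items()):
            pmid = pmid_of.get(rid)
            if pmid is None:
                continue
            flag = 1 if METHODS in classes else 0
            per_pmid[pmid] = max(per_pmid.get(pmid, 0), flag)
        for pmid, flag in per_pmid.items():
            rows.append(
                (
                    article.article_id,
                    article.pub_year,
                    article.journal_title,
                    pmid,
                    flag,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "citing_article_id",
            "citing_pub_year",
            "citing_journal",
            "cited_pmid",
            "in_methods",
        ],
    )
    return df.sort_values(
        ["citing_article_id", "cited_pmid"], kind="stable"
    ).reset_index(drop=True)
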