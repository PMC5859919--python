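"""MEDLINE record parsing, resource-name extraction and key aggregation.

Candidate informatics-resource publications arrive as MEDLINE/PubMed
citation XML.  Articles describing the same tool or database are pooled
under a single *resource key*: a name is pulled from the title by three
ordered rules (name-before-colon, all-uppercase word, words up to a
version number), then normalised by lowercasing, de-hyphenating and
stripping a trailing version token.  When no rule fires the PMID itself is
the key, so name keys (lowercase text) and fallback keys (all digits)
remain distinguishable namespaces.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from lxml import etree

logger = logging.getLogger(__name__)

#: Generic biomedical acronyms never taken as resource names by the
#: uppercase rule, which otherwise over-fires on ordinary titles.
DEFAULT_UPPERCASE_STOPLIST = frozenset(
    {"DNA", "RNA", "HIV", "PCR", "NMR", "MRI", "USA", "NIH"}
)

#: Maximum number of words before the colon for the colon rule to fire;
#: longer left-hand sides are sentence-style titles, not names.
MAX_COLON_NAME_WORDS = 6

_VERSION_RE = re.compile(r"[vV]?\d+(\.\d+)*")
_YEAR_RE = re.compile(r"(19|20)\d\d")


@dataclass
class ResourceRecord:
    """One candidate informatics-resource publication."""

    pmid: str
    title: str
    abstract: str = ""
    pub_year: Optional[int] = None
    journal_title: str = ""
    mesh_terms: list[str] = field(default_factory=list)
    resource_key: str = ""
    key_source: str = ""  # "name" | "pmid" once assigned


@dataclass
class ResourceGroup:
    """All publications sharing one resource key."""

    resource_key: str
    member_pmids: list[str]
    first_pub_year: Optional[int]


def _text(elem) -> str:
    return "".join(elem.itertext()).strip() if elem is not None else ""


def parse_medline_record(source) -> ResourceRecord:
    """Parse one PubmedArticle/MedlineCitation element into a record.

    ``source`` may be bytes, a path, a file-like object or an lxml
    element.  A record without a PMID or title is rejected with
    ``ValueError`` (logged); a missing abstract is tolerated.
    """
    if isinstance(source, etree._Element):
        root = source
    elif isinstance(source, bytes):
        root = etree.fromstring(source)
    else:
        root = etree.parse(str(source) if isinstance(source, Path) else source).getroot()

    cit = root if root.tag == "MedlineCitation" else root.find(".//MedlineCitation")
    if cit is None:
        cit = root
    pmid = _text(cit.find("PMID"))
    title = _text(cit.find(".//ArticleTitle"))
    if not pmid or not pmid.isdigit():
        logger.warning("MEDLINE record rejected: missing or non-numeric PMID")
        raise ValueError("record has no usable PMID")
    if not title:
        logger.warning("MEDLINE record %s rejected: no title", pmid)
        raise ValueError(f"record {pmid} has no title")

    abstract = " ".join(
        _text(t) for t in cit.findall(".//Abstract/AbstractText")
    ).strip()
    journal = _text(cit.find(".//Journal/Title"))
    year: Optional[int] = None
    y = cit.find(".//JournalIssue/PubDate/Year")
    if y is not None and _text(y).isdigit():
        year = int(_text(y))
    else:
        md = _text(cit.find(".//JournalIssue/PubDate/MedlineDate"))
        m = _YEAR_RE.search(md)
        if m:
            year = int(m.group(0))
    mesh = [
        _text(d)
        for d in cit.findall(".//MeshHeadingList/MeshHeading/DescriptorName")
        if _text(d)
    ]
    return ResourceRecord(
        pmid=pmid,
        title=title,
        abstract=abstract,
        pub_year=year,
        journal_title=journal,
        mesh_terms=mesh,
    )


def iter_medline_records(path) -> Iterator[ResourceRecord]:
    """Yield records from a file holding one or more PubmedArticle entries.

    Rejected records (no PMID/title) are logged and skipped.
    """
    root = etree.parse(str(path)).getroot()
    cits = root.findall(".//MedlineCitation")
    if not cits and root.tag == "MedlineCitation":
        cits = [root]
    for cit in cits:
        try:
            yield parse_medline_record(cit)
        except ValueError:
            continue


def _strip_punct(token: str) -> str:
    return token.strip(".,;()[]{}'\"!?")


def _is_version_token(token: str) -> bool:
    if not _VERSION_RE.fullmatch(token):
        return False
    # a bare 4-digit year is calendar data, not a version
    return not _YEAR_RE.fullmatch(token)


def extract_resource_name(
    title: str,
    abstract: Optional[str] = None,
    stoplist: Iterable[str] = DEFAULT_UPPERCASE_STOPLIST,
) -> Optional[str]:
    """Extract a raw resource name from a title (first matching rule wins).

    Rules, in order: (1) *colon* — a short series of words (at most
    ``MAX_COLON_NAME_WORDS``) followed by a colon names the resource;
    (2) *uppercase* — a word written entirely in capitals (length >= 3,
    not on the acronym stoplist); (3) *version* — a title containing a
    version number yields the words up to and including it.  If nothing
    fires on the title, the colon rule alone is retried on the first
    sentence of the abstract.  Returns ``None`` when no rule applies.
    """
    name = _extract_from_text(title, stoplist)
    if name is None and abstract:
        first_sentence = abstract.split(". ")[0]
        name = _colon_rule(first_sentence)
    return name


def _colon_rule(text: str) -> Optional[str]:
    head, sep, _ = text.partition(":")
    if not sep:
        return None
    head = head.strip()
    if not head or len(head.split()) > MAX_COLON_NAME_WORDS:
        return None
    return head


def _uppercase_rule(text: str, stoplist: Iterable[str]) -> Optional[str]:
    stop = {s.upper() for s in stoplist}
    for token in (_strip_punct(t) for t in text.split()):
        if (
            len(token) >= 3
            and token.isalpha()
            and token.isupper()
            and token not in stop
        ):
            return token
    return None


def _version_rule(text: str) -> Optional[str]:
    tokens = text.split()
    # a version number deep inside a sentence-style title is not a name
    for i, raw in enumerate(tokens[: MAX_COLON_NAME_WORDS]):
        token = _strip_punct(raw)
        if i > 0 and _is_version_token(token):
            return " ".join(_strip_punct(t) for t in tokens[: i + 1])
    return None


def _extract_from_text(text: str, stoplist: Iterable[str]) -> Optional[str]:
    for rule in (
        lambda t: _colon_rule(t),
        lambda t: _uppercase_rule(t, stoplist),
        lambda t: _version_rule(t),
    ):
        name = rule(text)
        if name:
            return name
    return None


def normalize_name(raw_name: str) -> Optional[str]:
    """Normalise a raw name: lowercase, drop hyphens and trailing version.

    ``T-Coffee`` becomes ``tcoffee`` and ``MrBayes 3.2`` becomes
    ``mrbayes``.  Idempotent.  Returns ``None`` when normalisation leaves
    nothing (the caller then falls back to the PMID key).
    """
    text = raw_name.lower().replace("-", "").replace("–", "")
    tokens = [t for t in (_strip_punct(t) for t in text.split()) if t]
    while tokens and _is_version_token(tokens[-1]):
        tokens.pop()
    result = " ".join(tokens)
    return result or None


def assign_resource_key(
    record: ResourceRecord,
    stoplist: Iterable[str] = DEFAULT_UPPERCASE_STOPLIST,
) -> ResourceRecord:
    """Set ``resource_key`` from the extracted name, or the PMID fallback."""
    raw = extract_resource_name(record.title, record.abstract, stoplist)
    key = normalize_name(raw) if raw else None
    if key:
        record.resource_key = key
        record.key_source = "name"
    else:
        record.resource_key = record.pmid
        record.key_source = "pmid"
    return record


def aggregate_resources(records: Iterable[ResourceRecord]) -> list[ResourceGroup]:
    """Partition keyed records into one group per distinct resource key.

    ``first_pub_year`` is the minimum publication year over members; the
    result is sorted by key and independent of input order.
    """
    groups: dict[str, ResourceGroup] = {}
    for rec in records:
        if not rec.resource_key:
            raise ValueError(f"record {rec.pmid} has no resource key")
        grp = groups.get(rec.resource_key)
        if grp is None:
            groups[rec.resource_key] = ResourceGroup(
                rec.resource_key, [rec.pmid], rec.pub_year
            )
        else:
            if rec.pmid not in grp.member_pmids:
                grp.member_pmids.append(rec.pmid)
            years = [y for y in (grp.first_pub_year, rec.pub_year) if y is not None]
            grp.first_pub_year = min(years) if years else None
    for grp in groups.values():
        grp.member_pmids.sort()
    return [groups[k] for k in sorted(groups)]


def resources_table(records: Iterable[ResourceRecord]):
    """Keyed records as a DataFrame (pmid, pub_year, journal, key, source)."""
    import pandas as pd

    rows = [
        (r.pmid, r.pub_year, r.journal_title, r.resource_key, r.key_source)
        for r in records
    ]
    df = pd.DataFrame(
        rows, columns=["pmid", "pub_year", "journal", "resource_key", "key_source"]
    )
    return df.sort_values(["resource_key", "pmid"], kind="stable").reset_index(
        drop=True
    )
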