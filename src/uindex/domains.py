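"""Journal-based assignment of citing articles to biomedical subdomains.

Citing articles are placed into one or more of four subdomains — Biology,
Medicine, Bioinformatics and MedicalInformatics — according to the MeSH
Broad Subject Terms of the journal they appeared in.  A journal counts for
a subdomain when one of its subject terms is, or descends from, the head
terms 'Biology', 'Medicine', 'Computational Biology' (mapped to
Bioinformatics) or 'Medical Informatics'.  Broad-scope journals resolving
to more than two head terms (e.g. megajournals) are assigned to none, as
are unindexed journals; such articles stay in the global tallies but are
excluded from per-domain summaries.  A user override table takes
precedence over the hierarchy.

The packaged term -> head-term table is a best-effort snapshot of the NLM
catalog hierarchy and is fully user-replaceable.
"""

from __future__ import annotations

import re
from importlib import resources
from typing import Iterable, Mapping, Optional

import pandas as pd

CATEGORIES = ("Biology", "Medicine", "Bioinformatics", "MedicalInformatics")

#: head term (as it appears in the NLM catalog) -> subdomain label
HEAD_TERM_CATEGORY = {
    "Biology": "Biology",
    "Medicine": "Medicine",
    "Computational Biology": "Bioinformatics",
    "Medical Informatics": "MedicalInformatics",
}

_PUNCT_RE = re.compile(r"[^\w\s]")


def normalize_journal_title(title: str) -> str:
    """Lowercase, strip punctuation and a leading 'the ', collapse spaces."""
    t = _PUNCT_RE.sub(" ", title.lower())
    t = re.sub(r"\s+", " ", t).strip()
    if t.startswith("the "):
        t = t[4:]
    return t


def load_default_hierarchy() -> dict[str, set[str]]:
    """Packaged term -> head-terms table."""
    with resources.files("uindex.data").joinpath("mesh_broad_terms.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    hierarchy: dict[str, set[str]] = {}
    for term, head in zip(df["term"], df["head_term"]):
        hierarchy.setdefault(term, set()).add(head)
    return hierarchy


def categorize_journal(
    subject_terms: Iterable[str],
    term_hierarchy: Mapping[str, Iterable[str] | str],
    override: Optional[Iterable[str]] = None,
) -> set[str]:
    """Resolve a journal's subject terms to subdomain categories.

    Returns the union of categories reached through the hierarchy, empty
    when the terms resolve to more than two distinct head terms (broad
    scope) or to none at all.  An explicit ``override`` category set, when
    given, wins outright.
    """
    if override is not None:
        return {c for c in override if c in CATEGORIES}
    heads: set[str] = set()
    for term in subject_terms:
        resolved = term_hierarchy.get(term)
        if resolved is None:
            continue
        if isinstance(resolved, str):
            resolved = [resolved]
        heads.update(resolved)
    if len(heads) > 2:
        return set()
    return {HEAD_TERM_CATEGORY[h] for h in heads if h in HEAD_TERM_CATEGORY}


def build_journal_category_map(
    journal_terms: pd.DataFrame,
    term_hierarchy: Optional[Mapping[str, Iterable[str] | str]] = None,
    overrides: Optional[pd.DataFrame] = None,
) -> dict[str, set[str]]:
    """Map normalized journal titles to category sets.

    ``journal_terms`` has columns ``journal_title`` and ``subject_term``
    (one row per term); ``overrides`` has ``journal_title`` and
    ``category``.  Overridden journals bypass the hierarchy entirely.
    """
    hierarchy = term_hierarchy if term_hierarchy is not None else load_default_hierarchy()
    override_map: dict[str, set[str]] = {}
    if overrides is not None:
        for title, cat in zip(overrides["journal_title"], overrides["category"]):
            override_map.setdefault(normalize_journal_title(title), set()).add(cat)
    result: dict[str, set[str]] = {}
    for title, grp in journal_terms.groupby("journal_title"):
        norm = normalize_journal_title(title)
        result[norm] = categorize_journal(
            grp["subject_term"], hierarchy, override_map.get(norm)
        )
    for norm, cats in override_map.items():
        if norm not in result:
            result[norm] = {c for c in cats if c in CATEGORIES}
    return result


def domain_usage_summary(
    collapsed: pd.DataFrame,
    journal_map: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Per-(resource, subdomain) usage counts and proportions.

    ``collapsed`` is the per-article/resource table with ``journal`` and
    ``usage`` columns.  An article contributes to every category its
    journal maps to; articles in uncategorized journals contribute to no
    row.  Returns columns ``resource_key``, ``category``, ``usage_count``,
    ``total_count``, ``usage_proportion``; (resource, category) pairs with
    no citations produce no row.
    """
    counts: dict[tuple[str, str], list[int]] = {}
    for row in collapsed.itertuples(index=False):
        cats = journal_map.get(normalize_journal_title(row.journal or ""), set())
        for cat in cats:
            pair = counts.setdefault((row.resource_key, cat), [0, 0])
            pair[1] += 1
            if row.usage:
                pair[0] += 1
    rows = [
        (key, cat, usage, total, usage / total)
        for (key, cat), (usage, total) in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "resource_key",
            "category",
            "usage_count",
            "total_count",
            "usage_proportion",
        ],
    )
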