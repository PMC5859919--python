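"""Usage/awareness citation tallies and the u-Index.

Each citing article contributes at most 1 to a resource's tallies: the
*total* count increments when the article cites any publication of the
resource at all, and the *usage* count when at least one of those
citations sits in the Materials/Methods section.  The *awareness* count is
their difference.  The usage ratio is usage/awareness, defined as 1 when
awareness is zero but usage is not.  The u-Index for a resource at a given
year is

    u_index = cumulative_total * usage_ratio / years_since_first_pub

with cumulative counts taken over citing-article publication years up to
and including the evaluation year, and the age denominator counting the
first publication year as year 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .jats import METHODS, ArticleRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CitationTally:
    """Per-resource, per-year citation counters."""

    resource_key: str
    year: int
    total_citations: int
    usage_citations: int

    @property
    def awareness_citations(self) -> int:
        return self.total_citations - self.usage_citations


@dataclass(frozen=True)
class UIndexPoint:
    """One point of a cumulative u-Index time series."""

    resource_key: str
    year: int
    cumulative_total: int
    cumulative_usage: int
    usage_ratio: float  # NaN when there are no citations at all
    years_since_first_pub: int
    u_index: float


def usage_ratio(usage: int, awareness: int) -> float:
    """usage/awareness; 1.0 when awareness is 0 and usage is not.

    With no citations at all the ratio is mathematically undefined and a
    ``ValueError`` is raised; callers treat the u-Index as 0 there.
    """
    if usage < 0 or awareness < 0:
        raise ValueError("citation counts must be non-negative")
    if usage + awareness == 0:
        raise ValueError("usage ratio undefined when there are no citations")
    if awareness == 0:
        return 1.0
    return usage / awareness


def u_index(total: int, ratio: float, years_since_first_pub: int) -> float:
    """total * ratio / years, the age-normalised usage-weighted impact."""
    if years_since_first_pub < 1:
        raise ValueError("years_since_first_pub must be >= 1")
    if total == 0:
        return 0.0
    return total * ratio / years_since_first_pub


def collapse_article_citations(
    article: ArticleRecord,
    resource_pmids: Mapping[str, str],
) -> list[tuple[str, bool]]:
    """Collapse one article's citations to at most one entry per resource.

    ``resource_pmids`` maps member PMID -> resource key.  The usage flag
    is true iff any citation of any member publication of the resource
    occurs in a methods section of this article.
    """
    pmid_of = {r.ref_id: r.cited_pmid for r in article.references if r.cited_pmid}
    flags: dict[str, bool] = {}
    for rid, classes in article.citation_locations.items():
        pmid = pmid_of.get(rid)
        if pmid is None:
            continue
        key = resource_pmids.get(pmid)
        if key is None:
            continue
        flags[key] = flags.get(key, False) or (METHODS in classes)
    return sorted(flags.items())


def collapse_citations(
    citations: pd.DataFrame, resource_pmids: Mapping[str, str]
) -> pd.DataFrame:
    """Table form of the per-article collapse.

    ``citations`` is the (citing article, cited PMID) table produced by
    the universe builder.  Returns one row per (citing article, resource)
    with columns ``article_id``, ``year``, ``journal``, ``resource_key``,
    ``usage`` (bool).
    """
    df = citations.copy()
    df["resource_key"] = df["cited_pmid"].map(resource_pmids)
    df = df.dropna(subset=["resource_key"])
    if df.empty:
        return pd.DataFrame(
            columns=["article_id", "year", "journal", "resource_key", "usage"]
        )
    collapsed = (
        df.groupby(["citing_article_id", "resource_key"], as_index=False)
        .agg(
            year=("citing_pub_year", "first"),
            journal=("citing_journal", "first"),
            usage=("in_methods", "max"),
        )
        .rename(columns={"citing_article_id": "article_id"})
    )
    collapsed["usage"] = collapsed["usage"].astype(bool)
    return collapsed[["article_id", "year", "journal", "resource_key", "usage"]]


def tally_by_year(collapsed: pd.DataFrame) -> list[CitationTally]:
    """Count per (resource, citing-article year) tallies.

    Input is the collapsed table (one row per article/resource pair).
    Years with no citations produce no tally row.
    """
    tallies = []
    if collapsed.empty:
        return tallies
    grouped = collapsed.groupby(["resource_key", "year"])
    for (key, year), grp in sorted(grouped, key=lambda kv: kv[0]):
        total = len(grp)
        usage = int(grp["usage"].sum())
        tallies.append(CitationTally(key, int(year), total, usage))
    return tallies


def tallies_table(tallies: Sequence[CitationTally]) -> pd.DataFrame:
    rows = [
        (t.resource_key, t.year, t.total_citations, t.usage_citations,
         t.awareness_citations)
        for t in tallies
    ]
    return pd.DataFrame(
        rows, columns=["resource_key", "year", "total", "usage", "awareness"]
    ).sort_values(["resource_key", "year"], kind="stable").reset_index(drop=True)


def u_index_series(
    tallies: Sequence[CitationTally],
    first_pub_year: int,
    through_year: int,
) -> list[UIndexPoint]:
    """Cumulative u-Index series for one resource.

    One point per year from ``first_pub_year`` through ``through_year``,
    each computed from cumulative usage/awareness counts up to and
    including that year.  Tallies predating the first publication year
    (data glitches in real corpora) are folded into the first year's
    cumulative counts with a warning.
    """
    if first_pub_year > through_year:
        raise ValueError("first_pub_year must not exceed through_year")
    keys = {t.resource_key for t in tallies}
    if len(keys) > 1:
        raise ValueError(f"tallies span multiple resources: {sorted(keys)}")
    key = keys.pop() if keys else ""
    per_year: dict[int, CitationTally] = {}
    for t in tallies:
        year = t.year
        if year < first_pub_year:
            logger.warning(
                "resource %s: tally year %d precedes first publication %d; "
                "folded into the first year",
                t.resource_key, year, first_pub_year,
            )
            year = first_pub_year
        if year in per_year:
            prev = per_year[year]
            per_year[year] = CitationTally(
                t.resource_key,
                year,
                prev.total_citations + t.total_citations,
                prev.usage_citations + t.usage_citations,
            )
        else:
            per_year[year] = CitationTally(
                t.resource_key, year, t.total_citations, t.usage_citations
            )
    points = []
    cum_total = cum_usage = 0
    for year in range(first_pub_year, through_year + 1):
        t = per_year.get(year)
        if t is not None and year <= through_year:
            cum_total += t.total_citations
            cum_usage += t.usage_citations
        years = max(1, year - first_pub_year + 1)
        awareness = cum_total - cum_usage
        if cum_total == 0:
            ratio = math.nan
            ui = 0.0
        else:
            ratio = usage_ratio(cum_usage, awareness)
            ui = u_index(cum_total, ratio, years)
        points.append(
            UIndexPoint(key, year, cum_total, cum_usage, ratio, years, ui)
        )
    return points


def u_index_table(
    tallies: Sequence[CitationTally],
    first_pub_years: Mapping[str, int],
    through_year: Optional[int] = None,
) -> pd.DataFrame:
    """u-Index series for every resource, as one sorted DataFrame.

    ``first_pub_years`` maps resource key -> first publication year; a
    resource with no known first year falls back to its earliest tally
    year.  ``through_year`` defaults to the latest tally year observed.
    """
    by_key: dict[str, list[CitationTally]] = {}
    for t in tallies:
        by_key.setdefault(t.resource_key, []).append(t)
    if through_year is None:
        years = [t.year for t in tallies]
        through_year = max(years) if years else None
    rows = []
    for key in sorted(set(by_key) | set(first_pub_years)):
        ts = by_key.get(key, [])
        first = first_pub_years.get(key)
        if first is None:
            first = min(t.year for t in ts)
        if through_year is None and not ts:
            continue  # never cited and no horizon to report against
        last = through_year if through_year is not None else max(t.year for t in ts)
        for p in u_index_series(ts, first, max(first, last)):
            rows.append(
                (
                    key,
                    p.year,
                    p.cumulative_total,
                    p.cumulative_usage,
                    p.usage_ratio,
                    p.years_since_first_pub,
                    p.u_index,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "resource_key",
            "year",
            "cumulative_total",
            "cumulative_usage",
            "usage_ratio",
            "years_since_first_pub",
            "u_index",
        ],
    )


def rank_resources(
    points: Iterable[UIndexPoint], year: int
) -> list[tuple[str, float]]:
    """Resources at one year, descending by u-Index (ties: key order)."""
    at_year = [p for p in points if p.year == year]
    return [
        (p.resource_key, p.u_index)
        for p in sorted(at_year, key=lambda p: (-p.u_index, p.resource_key))
    ]
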