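"""Synthetic JATS + MEDLINE corpora with machine-readable ground truth.

Every other module is testable offline against corpora produced here.
The generator first lays out an explicit *plan* — which articles exist,
which sections are Materials/Methods, where every in-text citation sits,
which titles trigger which name-extraction rule — and then renders that
plan to XML.  Ground truth (expected citation locations, resource keys,
per-year tallies and u-Index series) is computed directly from the plan
by elementary counting, never by running the parsers or metrics under
test, so it serves as an independent end-to-end oracle.

All randomness flows from one seeded generator; identical (spec, seed)
pairs yield byte-identical corpora.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from lxml import etree

METHODS = "methods"
OTHER = "other"

_FILLER_WORDS = (
    "analysis sequence protein sample gene expression cluster assay data "
    "model result profile tissue variant pathway signal measurement cohort "
    "alignment genome read marker screen network annotation"
).split()

_JOURNALS = (
    "Journal of Molecular Biology",
    "Bioinformatics",
    "PLoS ONE",
    "Nucleic Acids Research",
    "Journal of Clinical Oncology",
    "Journal of Biomedical Informatics",
)

_EXCLUDED_HEADINGS_CYCLE = ("Review", "Editorial", "Letter", "Commentary")

#: (name as written in titles, extraction rule, expected normalized key or
#: None for the PMID fallback, publication years of the papers).
RESOURCE_TEMPLATES = (
    ("T-Coffee", "colon", "tcoffee", (2008,)),
    ("MrBayes 3.2", "colon", "mrbayes", (2008,)),
    ("MUSCLE", "uppercase", "muscle", (2008, 2010)),
    ("SeqSorter 2.1", "version", "seqsorter", (2009,)),
    (None, "none", None, (2009,)),
    ("Gene-Mapper", "colon", "genemapper", (2010,)),
    ("LINNAEUS", "uppercase", "linnaeus", (2010,)),
    ("Pfam", "colon", "pfam", (2008, 2011)),
    ("AlignPro v3", "version", "alignpro", (2011,)),
    (None, "none", None, (2012,)),
    ("ClustalW", "colon", "clustalw", (2008,)),
    ("BLAST", "uppercase", "blast", (2008,)),
)


@dataclass
class FixtureSpec:
    """Shape of a synthetic corpus."""

    n_articles: int = 120
    n_resources: int = 12
    seed: int = 0
    start_year: int = 2009
    end_year: int = 2015


@dataclass
class SectionPlan:
    sec_type: Optional[str]
    title: str
    parent: Optional[int]  # index into the article's section list
    is_methods: bool  # by construction, ancestor-propagated


@dataclass
class RefPlan:
    label: int
    pmid: Optional[str]

    @property
    def ref_id(self) -> str:
        return f"B{self.label}"


@dataclass
class CitationGroup:
    """One bracketed citation group in a given section.

    ``items`` are single labels (int) or inclusive label ranges (lo, hi),
    rendered as dash-joined xref pairs.
    """

    section: int
    items: list


@dataclass
class CitingArticlePlan:
    article_id: str
    headings: tuple
    journal: str
    pub_year: int
    sections: list[SectionPlan]
    refs: list[RefPlan]
    groups: list[CitationGroup]
    expected_research: bool
    expected_methods: bool

    @property
    def expected_retained(self) -> bool:
        return self.expected_research and self.expected_methods

    def expected_locations(self) -> dict[str, set]:
        """ref_id -> section classes, by direct enumeration of the plan."""
        existing = {r.label for r in self.refs}
        locs: dict[str, set] = {}
        for grp in self.groups:
            klass = METHODS if self.sections[grp.section].is_methods else OTHER
            for item in grp.items:
                labels = (
                    [item]
                    if isinstance(item, int)
                    else list(range(item[0], item[1] + 1))
                )
                for lab in labels:
                    if lab in existing:
                        locs.setdefault(f"B{lab}", set()).add(klass)
        return locs


@dataclass
class ResourcePaperPlan:
    pmid: str
    title: str
    abstract: str
    pub_year: int
    journal: str
    expected_key: str
    key_source: str


@dataclass
class GroundTruth:
    """Expected outputs, computed from the plan, never from the system."""

    articles: dict = field(default_factory=dict)  # id -> dict of expectations
    resource_keys: dict = field(default_factory=dict)  # pmid -> (key, source)
    first_pub_year: dict = field(default_factory=dict)  # key -> year
    tallies: dict = field(default_factory=dict)  # (key, year) -> (total, usage)
    uindex: dict = field(default_factory=dict)  # (key, year) -> point dict
    through_year: int = 0


def generate_title(rule: str, name: Optional[str], rng: random.Random) -> str:
    """A title guaranteed to trigger exactly the requested extraction rule."""
    topic = f"{rng.choice(_FILLER_WORDS)} {rng.choice(_FILLER_WORDS)}"
    if rule == "colon":
        return f"{name}: a tool for {topic}"
    if rule == "uppercase":
        return f"Improving {topic} with {name}"
    if rule == "version":
        return f"{name} improves {topic}"
    if rule == "none":
        return f"A generic method for {topic}"
    raise ValueError(f"unknown title rule {rule!r}")


def _filler(rng: random.Random, n: int) -> str:
    return " ".join(rng.choice(_FILLER_WORDS) for _ in range(n))


def plan_resources(spec: FixtureSpec, rng: random.Random) -> list[ResourcePaperPlan]:
    papers: list[ResourcePaperPlan] = []
    next_pmid = 100001
    for i in range(spec.n_resources):
        if i < len(RESOURCE_TEMPLATES):
            name, rule, key, years = RESOURCE_TEMPLATES[i]
        else:  # extra resources beyond the bank fall back to PMID keys
            name, rule, key, years = None, "none", None, (spec.start_year - 1,)
        for j, year in enumerate(years):
            pmid = str(next_pmid)
            next_pmid += 1
            if rule == "uppercase" and j == 1:
                title = f"{name} v3.8 with higher accuracy"  # same key, new paper
            else:
                title = generate_title(rule, name, rng)
            papers.append(
                ResourcePaperPlan(
                    pmid=pmid,
                    title=title,
                    abstract=f"We present an approach to {_filler(rng, 5)}.",
                    pub_year=year,
                    journal=_JOURNALS[(i + j) % len(_JOURNALS)],
                    expected_key=key if key is not None else pmid,
                    key_source="name" if key is not None else "pmid",
                )
            )
    return papers


def _sections_for(style: str) -> tuple[list[SectionPlan], Optional[int], int]:
    """Section list, index of the usage-placement target, index of Discussion."""
    intro = SectionPlan(None, "Introduction", None, False)
    results = SectionPlan(None, "Results", None, False)
    disc = SectionPlan(None, "Discussion", None, False)
    if style == "none":
        return [intro, results, disc], None, 2
    if style == "sec-type":
        methods = SectionPlan("materials|methods", "Cell culture and assays", None, True)
        return [intro, methods, results, disc], 1, 3
    if style == "title":
        methods = SectionPlan(None, "Materials and Methods", None, True)
        return [intro, methods, results, disc], 1, 3
    if style == "nested":
        methods = SectionPlan("methods", "Methods", None, True)
        sub1 = SectionPlan(None, "Samples", 1, True)
        sub2 = SectionPlan(None, "Sequencing", 2, True)
        sub3 = SectionPlan(None, "Statistics", 3, True)
        return [intro, methods, sub1, sub2, sub3, results, disc], 4, 6
    raise ValueError(style)


def plan_citing_articles(
    spec: FixtureSpec,
    papers: list[ResourcePaperPlan],
    rng: random.Random,
) -> list[CitingArticlePlan]:
    years = list(range(spec.start_year, spec.end_year + 1))
    # group papers by resource key for member selection
    by_key: dict[str, list[ResourcePaperPlan]] = {}
    for p in papers:
        by_key.setdefault(p.expected_key, []).append(p)
    keys = sorted(by_key)
    first_year = {k: min(p.pub_year for p in by_key[k]) for k in keys}
    forced_methods = {"linnaeus"}  # degenerate usage-ratio branch
    forced_other = {"blast"}  # zero-usage branch

    plans = []
    next_other_pmid = 900001
    for i in range(spec.n_articles):
        year = years[i % len(years)]
        journal = _JOURNALS[i % len(_JOURNALS)]
        role = i % 10
        if role == 0:
            headings = (_EXCLUDED_HEADINGS_CYCLE[(i // 10) % 4],)
            research = False
            style = "sec-type"
        elif role == 1:
            headings = ("Research Article",)
            research = True
            style = "none"
        else:
            headings = ("Research Article",)
            research = True
            style = ("sec-type", "title", "nested")[i % 3]
        sections, methods_idx, other_idx = _sections_for(style)

        n_refs = 6 + (i % 5)
        eligible = [k for k in keys if first_year[k] <= year]
        n_cited = min(1 + (i % 3), len(eligible))
        cited_keys = rng.sample(eligible, n_cited)
        # map chosen resources onto ref labels 1..k
        refs: list[RefPlan] = []
        resource_labels: list[tuple[int, str]] = []
        label = 1
        for key in cited_keys:
            members = by_key[key]
            paper = members[i % len(members)]
            refs.append(RefPlan(label, paper.pmid))
            resource_labels.append((label, key))
            label += 1
            if len(members) > 1 and i % 4 == 0:
                # cite a second paper of the same resource too
                other_paper = members[(i + 1) % len(members)]
                if other_paper.pmid != paper.pmid:
                    refs.append(RefPlan(label, other_paper.pmid))
                    resource_labels.append((label, key))
                    label += 1
        while label <= n_refs - 1:
            refs.append(RefPlan(label, str(next_other_pmid)))
            next_other_pmid += 1
            label += 1
        refs.append(RefPlan(label, None))  # a reference without a PMID

        groups: list[CitationGroup] = []
        # labels of the always-methods / never-methods resources must not be
        # swept into someone else's range, or their branch would break
        protected = {
            l for l, k in resource_labels if k in forced_methods | forced_other
        }
        for j, (lab, key) in enumerate(resource_labels):
            if key in forced_methods and methods_idx is not None:
                target, alt = methods_idx, methods_idx
            elif key in forced_other or methods_idx is None:
                target, alt = other_idx, other_idx
            elif (i + j) % 3 == 2:
                target, alt = other_idx, other_idx
            else:
                target, alt = methods_idx, other_idx
            pattern = (i + lab) % 4
            sweep_ok = lab + 2 <= len(refs) and not (
                {lab + 1, lab + 2} & protected
            )
            if pattern == 0 or not sweep_ok and pattern >= 2:
                groups.append(CitationGroup(target, [lab]))
            elif pattern == 1:
                # multiplicity: repeated citations collapse to one tally
                groups.append(CitationGroup(target, [lab]))
                groups.append(CitationGroup(target, [lab]))
                groups.append(CitationGroup(alt, [lab]))
            elif pattern == 2:
                # bracketed range [lab-(lab+2)] sweeping neighbouring refs
                groups.append(CitationGroup(target, [(lab, lab + 2)]))
            else:
                # mixed list "[lab, lab+1-lab+2]"
                groups.append(CitationGroup(target, [lab, (lab + 1, lab + 2)]))
        # background citations of non-resource refs in the introduction
        if len(refs) > len(resource_labels) + 1:
            groups.append(CitationGroup(0, [len(resource_labels) + 1]))

        plans.append(
            CitingArticlePlan(
                article_id=f"PMC{i + 1:06d}",
                headings=headings,
                journal=journal,
                pub_year=year,
                sections=sections,
                refs=refs,
                groups=groups,
                expected_research=research,
                expected_methods=style != "none",
            )
        )
    return plans


# ---------------------------------------------------------------- rendering


def _render_jats(plan: CitingArticlePlan, rng: random.Random) -> bytes:
    article = etree.Element("article", {"article-type": "research-article"})
    front = etree.SubElement(article, "front")
    jm = etree.SubElement(front, "journal-meta")
    etree.SubElement(jm, "journal-title").text = plan.journal
    am = etree.SubElement(front, "article-meta")
    aid = etree.SubElement(am, "article-id", {"pub-id-type": "pmc"})
    aid.text = plan.article_id
    cats = etree.SubElement(am, "article-categories")
    sg = etree.SubElement(cats, "subj-group")
    for heading in plan.headings:
        etree.SubElement(sg, "subject").text = heading
    pd_el = etree.SubElement(am, "pub-date")
    etree.SubElement(pd_el, "year").text = str(plan.pub_year)

    body = etree.SubElement(article, "body")
    sec_elems: list[etree._Element] = []
    for sp in plan.sections:
        parent = body if sp.parent is None else sec_elems[sp.parent]
        attrs = {"sec-type": sp.sec_type} if sp.sec_type else {}
        sec = etree.SubElement(parent, "sec", attrs)
        etree.SubElement(sec, "title").text = sp.title
        p = etree.SubElement(sec, "p")
        p.text = _filler(rng, 8) + "."
        sec_elems.append(sec)

    for grp in plan.groups:
        p = etree.SubElement(sec_elems[grp.section], "p")
        p.text = _filler(rng, 4) + " ["
        prev = None
        for k, item in enumerate(grp.items):
            if isinstance(item, int):
                labels = [item]
            else:
                labels = [item[0], item[1]]
            for m, lab in enumerate(labels):
                xref = etree.SubElement(
                    p, "xref", {"ref-type": "bibr", "rid": f"B{lab}"}
                )
                xref.text = str(lab)
                if not isinstance(item, int) and m == 0:
                    xref.tail = "-"
                prev = xref
            if prev is not None and k < len(grp.items) - 1:
                prev.tail = ","
        if prev is not None:
            prev.tail = "]."

    back = etree.SubElement(article, "back")
    ref_list = etree.SubElement(back, "ref-list")
    for ref in plan.refs:
        r = etree.SubElement(ref_list, "ref", {"id": ref.ref_id})
        etree.SubElement(r, "label").text = str(ref.label)
        mc = etree.SubElement(r, "mixed-citation")
        mc.text = f"Author {ref.label}. A cited work on {_filler(rng, 2)}. "
        if ref.pmid:
            pid = etree.SubElement(mc, "pub-id", {"pub-id-type": "pmid"})
            pid.text = ref.pmid
    return etree.tostring(
        article, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _render_medline(paper: ResourcePaperPlan) -> bytes:
    root = etree.Element("PubmedArticleSet")
    pa = etree.SubElement(root, "PubmedArticle")
    cit = etree.SubElement(pa, "MedlineCitation")
    etree.SubElement(cit, "PMID").text = paper.pmid
    art = etree.SubElement(cit, "Article")
    journal = etree.SubElement(art, "Journal")
    issue = etree.SubElement(journal, "JournalIssue")
    pub_date = etree.SubElement(issue, "PubDate")
    etree.SubElement(pub_date, "Year").text = str(paper.pub_year)
    etree.SubElement(journal, "Title").text = paper.journal
    etree.SubElement(art, "ArticleTitle").text = paper.title
    abstract = etree.SubElement(art, "Abstract")
    etree.SubElement(abstract, "AbstractText").text = paper.abstract
    mesh_list = etree.SubElement(cit, "MeshHeadingList")
    mh = etree.SubElement(mesh_list, "MeshHeading")
    etree.SubElement(mh, "DescriptorName").text = "Software"
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


# ------------------------------------------------------------ ground truth


def _truth_from_plans(
    spec: FixtureSpec,
    papers: list[ResourcePaperPlan],
    plans: list[CitingArticlePlan],
) -> GroundTruth:
    truth = GroundTruth(through_year=spec.end_year)
    for p in papers:
        truth.resource_keys[p.pmid] = (p.expected_key, p.key_source)
        prev = truth.first_pub_year.get(p.expected_key)
        truth.first_pub_year[p.expected_key] = (
            p.pub_year if prev is None else min(prev, p.pub_year)
        )

    pmid_to_key = {pmid: key for pmid, (key, _) in truth.resource_keys.items()}
    for plan in plans:
        locs = plan.expected_locations()
        truth.articles[plan.article_id] = {
            "research": plan.expected_research,
            "methods": plan.expected_methods,
            "retained": plan.expected_retained,
            "locations": locs,
        }
        if not plan.expected_retained:
            continue
        pmid_by_ref = {r.ref_id: r.pmid for r in plan.refs if r.pmid}
        usage_by_key: dict[str, bool] = {}
        for rid, classes in locs.items():
            key = pmid_to_key.get(pmid_by_ref.get(rid, ""))
            if key is None:
                continue
            usage_by_key[key] = usage_by_key.get(key, False) or (METHODS in classes)
        for key, usage in usage_by_key.items():
            total, n_usage = truth.tallies.get((key, plan.pub_year), (0, 0))
            truth.tallies[(key, plan.pub_year)] = (
                total + 1,
                n_usage + (1 if usage else 0),
            )

    # cumulative u-Index series by elementary arithmetic
    for key, first in truth.first_pub_year.items():
        cum_total = cum_usage = 0
        for year in range(first, spec.end_year + 1):
            total, usage = truth.tallies.get((key, year), (0, 0))
            cum_total += total
            cum_usage += usage
            years_since = year - first + 1
            awareness = cum_total - cum_usage
            if cum_total == 0:
                ratio, ui = None, 0.0
            elif awareness == 0:
                ratio, ui = 1.0, cum_total * 1.0 / years_since
            else:
                ratio = cum_usage / awareness
                ui = cum_total * ratio / years_since
            truth.uindex[(key, year)] = {
                "cumulative_total": cum_total,
                "cumulative_usage": cum_usage,
                "usage_ratio": ratio,
                "years_since_first_pub": years_since,
                "u_index": ui,
            }
    return truth


def generate_worked_example(
    out_dir,
    n_citing: int = 10,
    n_usage: int = 2,
    seed: int = 0,
    year: int = 2010,
) -> tuple[list[Path], list[Path], GroundTruth]:
    """Corpus with one resource cited by ``n_citing`` articles.

    Exactly ``n_usage`` of the citing articles cite the resource in their
    Materials/Methods section; the rest cite it in the Discussion.  With
    the per-article collapse this realises a tally of
    (total=n_citing, usage=n_usage) in ``year``, which is also the
    resource's first publication year.
    """
    if not 0 <= n_usage <= n_citing:
        raise ValueError("need 0 <= n_usage <= n_citing")
    out = Path(out_dir)
    rng = random.Random(seed)
    paper = ResourcePaperPlan(
        pmid="500001",
        title=generate_title("colon", "T-Coffee", rng),
        abstract=f"We present {_filler(rng, 4)}.",
        pub_year=year,
        journal=_JOURNALS[0],
        expected_key="tcoffee",
        key_source="name",
    )
    plans = []
    for i in range(n_citing):
        sections, methods_idx, other_idx = _sections_for("sec-type")
        target = methods_idx if i < n_usage else other_idx
        plans.append(
            CitingArticlePlan(
                article_id=f"PMC{i + 1:06d}",
                headings=("Research Article",),
                journal=_JOURNALS[i % len(_JOURNALS)],
                pub_year=year,
                sections=sections,
                refs=[RefPlan(1, paper.pmid), RefPlan(2, None)],
                groups=[CitationGroup(target, [1])],
                expected_research=True,
                expected_methods=True,
            )
        )
    spec = FixtureSpec(
        n_articles=n_citing, n_resources=1, seed=seed,
        start_year=year, end_year=year,
    )
    truth = _truth_from_plans(spec, [paper], plans)
    jats_dir = out / "articles"
    medline_dir = out / "medline"
    jats_dir.mkdir(parents=True, exist_ok=True)
    medline_dir.mkdir(parents=True, exist_ok=True)
    jats_paths = []
    for plan in plans:
        path = jats_dir / f"{plan.article_id}.xml"
        path.write_bytes(_render_jats(plan, rng))
        jats_paths.append(path)
    mpath = medline_dir / f"pubmed_{paper.pmid}.xml"
    mpath.write_bytes(_render_medline(paper))
    return jats_paths, [mpath], truth


# ------------------------------------------------------------------ driver


def generate_corpus(
    spec: FixtureSpec, out_dir
) -> tuple[list[Path], list[Path], GroundTruth]:
    """Write a synthetic corpus and return (jats paths, medline paths, truth)."""
    out = Path(out_dir)
    rng = random.Random(spec.seed)
    papers = plan_resources(spec, rng)
    plans = plan_citing_articles(spec, papers, rng)
    truth = _truth_from_plans(spec, papers, plans)

    jats_dir = out / "articles"
    medline_dir = out / "medline"
    jats_dir.mkdir(parents=True, exist_ok=True)
    medline_dir.mkdir(parents=True, exist_ok=True)
    jats_paths = []
    for plan in plans:
        path = jats_dir / f"{plan.article_id}.xml"
        path.write_bytes(_render_jats(plan, rng))
        jats_paths.append(path)
    medline_paths = []
    for paper in papers:
        path = medline_dir / f"pubmed_{paper.pmid}.xml"
        path.write_bytes(_render_medline(paper))
        medline_paths.append(path)
    return jats_paths, medline_paths, truth


def write_ground_truth(truth: GroundTruth, out_dir) -> None:
    """Dump the ground truth as TSV files for external inspection."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "articles.tsv", "w") as fh:
        fh.write("article_id\tresearch\tmethods\tretained\n")
        for aid in sorted(truth.articles):
            a = truth.articles[aid]
            fh.write(
                f"{aid}\t{int(a['research'])}\t{int(a['methods'])}"
                f"\t{int(a['retained'])}\n"
            )
    with open(out / "resource_keys.tsv", "w") as fh:
        fh.write("pmid\tresource_key\tkey_source\n")
        for pmid in sorted(truth.resource_keys):
            key, source = truth.resource_keys[pmid]
            fh.write(f"{pmid}\t{key}\t{source}\n")
    with open(out / "tallies.tsv", "w") as fh:
        fh.write("resource_key\tyear\ttotal\tusage\tawareness\n")
        for (key, year) in sorted(truth.tallies):
            total, usage = truth.tallies[(key, year)]
            fh.write(f"{key}\t{year}\t{total}\t{usage}\t{total - usage}\n")
    with open(out / "uindex.tsv", "w") as fh:
        fh.write(
            "resource_key\tyear\tcumulative_total\tcumulative_usage"
            "\tusage_ratio\tyears_since_first_pub\tu_index\n"
        )
        for (key, year) in sorted(truth.uindex):
            p = truth.uindex[(key, year)]
            ratio = "NA" if p["usage_ratio"] is None else f"{p['usage_ratio']:.6f}"
            fh.write(
                f"{key}\t{year}\t{p['cumulative_total']}\t{p['cumulative_usage']}"
                f"\t{ratio}\t{p['years_since_first_pub']}\t{p['u_index']:.4f}\n"
            )
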