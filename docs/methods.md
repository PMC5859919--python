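# Methods

## The model

`uindex` operationalises a simple behavioural model of citation: authors
who *use* a tool or database cite its publication where they describe
what they did — the Materials/Methods section — while authors who merely
discuss or compare it cite it elsewhere. The package therefore reduces
citation context to a binary section class, `methods` vs `other`, and
builds everything on three counters per resource and year:

- **total** — number of citing articles that cite any publication of the
  resource at least once;
- **usage** — number of citing articles with at least one such citation
  inside a Materials/Methods section;
- **awareness** — total − usage.

Each citing article contributes at most 1 to each counter, whatever the
in-article citation multiplicity. This per-article collapse happens at
the resource level: all member publications of a resource are unioned
before the usage flag is decided, so citing paper A of a tool in the
Introduction and paper B of the same tool in the Methods yields one
usage citation.

The impact metric is

    usage_ratio = usage / awareness          (1 when awareness = 0 and usage > 0)
    u_index     = cumulative_total * usage_ratio / years_since_first_pub

computed per year from cumulative counts up to and including that year.
No sentiment or finer-grained context is modelled; a "Results and
Methods"-style combined section is classified by its sec-type/title like
any other section.

## The citing universe

An article enters the universe iff (a) none of its subject headings is in
the exclusion list and (b) it has a Materials/Methods section. Methods
detection first trusts the `sec-type` attribute (default accepted values
`materials|methods`, `methods`, `materials-and-methods`, case-insensitive)
and consults the title only when the attribute is absent (default
patterns: full-title, case-insensitive matches of "materials and
methods", "methods", "materials/methods", "experimental procedures").
When a `sec-type` is present but not a methods value, the title is
deliberately not consulted — the attribute is taken as authoritative.
Both rule sets and the exclusion heading list (default: Review,
Editorial, Correction, Retraction, News, Letter, Case Report,
Commentary) are configurable; the defaults are this package's own
choices for a mechanism whose exact original lists are not public.

The methods class propagates to all nested subsections: a citation in a
"Statistics" subsection of Methods is a usage citation. Reference ranges
written as dash-joined xref pairs (`[2-5]`, hyphen/en-/em-dash) are
expanded over the numeric labels of the reference list; unresolvable
ranges (non-numeric labels, inverted bounds) are skipped with a warning
rather than guessed. Only references carrying a PMID flow into tallies —
the PMID is the join key to the resource set — but PMID-less references
are retained on the parsed record.

## Resource keys

Name extraction applies three rules to the title in a fixed order, first
match wins: colon (a ≤ 6-word prefix before the first colon), uppercase
(first all-caps alphabetic word of length ≥ 3 not on an acronym stoplist
— DNA, RNA, HIV, PCR, NMR, MRI, USA, NIH by default), version (words up
to and including a version token `v?d[.d]*` found within the first six
words; bare 4-digit years are not versions). The guardrails (prefix
length, minimum length, stoplist, year exclusion) exist because the bare
rules over-fire on ordinary sentence titles; all are configurable. If the
title yields nothing, the colon rule alone is retried on the abstract's
first sentence — a deliberately conservative secondary use. Extracted
names are normalized (lowercase, hyphens removed, trailing version tokens
stripped, whitespace collapsed; idempotent) and records sharing a key are
aggregated; otherwise the PMID is the key. Distinct tools that normalize
to the same name will collide under one key; this is a known limitation
of name-based aggregation, mitigated in practice by manual override
files.

## Metric conventions

- `years_since_first_pub = max(1, year − first_pub_year + 1)`: the first
  publication year counts as year 1, so the metric is defined in the
  publication year itself and never divides by zero.
- total = 0: u-Index is 0 and the ratio is reported as NA (NaN) — no
  citations, no signal.
- usage = 0 with awareness > 0: ratio 0 and u-Index 0, the formula taken
  literally.
- The awareness-zero rule sets the ratio to 1, which makes the u-Index
  equal the total citation count *divided by the age denominator*; a
  degenerate-case reading that skips the age normalisation would
  contradict the formula, so the formula wins here.
- Citations are dated by the citing article's publication year; the
  cumulative series then matches "citations up to and including that
  year" for incoming citations.
- Tallies predating a resource's first publication year (possible with
  messy real-world metadata) are folded into the first year's cumulative
  counts with a warning.
- TSV output rounds reals to 4 decimals; all internal arithmetic is full
  double precision. Rows are ordered (resource_key, year) so repeated
  runs are byte-identical.

## Subdomain assignment

Citing journals are mapped to Biology, Medicine, Bioinformatics
(= Computational Biology) and MedicalInformatics through MeSH Broad
Subject Terms: a journal counts for a category when one of its subject
terms is, or descends from, the corresponding head term. Journals
resolving to more than two distinct head terms (broad-scope megajournals)
and unindexed journals get no category; their articles stay in the global
tallies but are excluded from per-domain summaries. The packaged term →
head-term table is a best-effort snapshot and fully user-replaceable;
an override table (journal → category) takes precedence for journals the
hierarchy cannot reach. Journal titles are joined after normalization
(lowercase, punctuation stripped, leading "the" removed).

## The synthetic corpus generator

`uindex.fixtures` generates JATS and MEDLINE XML from an explicit plan
and derives ground truth (citation locations, resource keys, tallies,
u-Index series) from the plan by elementary counting — never by running
the parsers or metrics — so a pipeline-vs-truth comparison is a genuine
end-to-end oracle. The default corpus has 120 citing articles over
2009–2015 and 12 resources (14 papers) chosen to cover every code path:
excluded headings, missing methods sections, sec-type vs title-only
methods detection, methods subsections nested four deep, explicit,
repeated, ranged and mixed (`[1,3-5]`) citations, references without
PMIDs, all three name-extraction rules plus the PMID fallback,
multi-paper resources, an always-used resource (awareness 0, the
degenerate ratio) and a never-used one. One article in ten is a
review-type heading, one in ten lacks methods, leaving 96 retained — a
funnel large enough to make collapse and cumulative arithmetic
non-trivial while keeping the full suite in seconds. All randomness
(filler text, which resources an article cites) flows from a single
seeded generator; identical (spec, seed) pairs are byte-identical.

What the fixtures do **not** emulate: real PMC markup variance (namespaces,
`xref` idiosyncrasies, OCR noise), citation-practice correlations between
fields, journals or years, and real title morphology beyond the three
rules. Passing the end-to-end oracle therefore demonstrates the
correctness of the counting and metric machinery on well-formed input,
not the empirical precision/recall of name extraction or methods
detection on the live literature.

## Known limitations

- Usage is inferred from section placement only; tools used but cited
  outside Methods (or not cited at all) are undercounted.
- Name collisions and missed resource publications bias keys and pooled
  counts; override files are the escape hatch, not a solution.
- The u-Index inherits every citing-universe bias: it is only comparable
  between resources measured against the same universe.
- Self-citations are not excluded.
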