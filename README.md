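# uindex

Citation counts treat every citation alike, but a citation of a software
tool from the *Materials/Methods* section of a paper is different in kind
from one in the Introduction: the former is evidence the tool was actually
**used**, the latter only that the authors were **aware** of it. `uindex`
builds a section-aware citation network from full-text article XML
(JATS/PMC dialect), aggregates publications describing the same
informatics resource (tool or database) under a normalized *resource key*,
and computes usage/awareness tallies and the **u-Index**, a resource-level
impact metric:

```
usage_ratio = # usage citations / # awareness citations        (1 if awareness = 0)

u-Index     = total # citations x usage_ratio / # years since first publication
```

Counting rules: each citing article contributes **at most 1** to a
resource's total and usage counts (multiple citations within one article
collapse); a citation is *usage* if it occurs anywhere inside a
Materials/Methods section (any nesting depth), *awareness* otherwise;
awareness = total − usage. The citing universe is restricted to research
articles (by subject heading) that have a Materials/Methods section,
identified by the `sec-type` attribute or, failing that, the section
title. Implicit reference enumerations such as `[2-5]` are expanded to
every reference whose numeric label falls in the interval.

Intended users: bibliometricians, tool maintainers tracking adoption, and
anyone mining PMC-style full text for citation context.

## Worked example

The package ships a synthetic-corpus generator with by-construction ground
truth, so the whole pipeline can be exercised without downloading
anything:

```
$ uindex make-fixtures --out-dir corpus --seed 1
wrote 120 JATS articles and 14 MEDLINE records to corpus

$ cat > config.yaml <<EOF
articles_dir: corpus/articles
medline_dir: corpus/medline
out_dir: out
through_year: 2015
EOF

$ uindex run --config config.yaml
INFO uindex.jats: citing universe: 120 parsed, 0 failed, 12 non-research, 12 without methods, 96 retained
pipeline complete; outputs in out
```

The retention funnel (120 → 96) mirrors the universe definition: 12
articles are dropped for excluded headings (reviews, editorials, ...) and
12 for lacking a Materials/Methods section. `out/tallies.tsv` holds the
per-resource, per-year counts, e.g. a resource cited by 5 articles in
2009, 4 of them in Methods:

```
resource_key  year  total  usage  awareness
100006        2009  5      4      1
```

and `out/uindex.tsv` the cumulative series, here for the `muscle` key
(two aggregated publications, first published 2008):

```
resource_key  year  cumulative_total  cumulative_usage  usage_ratio  years_since_first_pub  u_index
muscle        2009  7                 6                 6.0000       2                      21.0000
muscle        2010  11                10                10.0000      3                      36.6667
muscle        2011  14                12                6.0000       4                      21.0000
```

Reading the 2010 row: 11 citing articles so far, 10 of which used the
tool, giving a usage ratio of 10:1 and a u-Index of 11 × 10 / 3 ≈ 36.7 in
the third year since first publication. A sharp drop in the ratio (2011)
means new citations arrived mostly in an awareness context.

Per-stage commands (`build-universe`, `extract-resources`, `compute`,
`domains`) expose the same pipeline piecewise; `uindex domains` joins
citing journals to MeSH Broad Subject Terms to summarise usage by
subdomain (Biology, Medicine, Bioinformatics, MedicalInformatics).

The same functionality is available as a library:

```python
from uindex import build_citing_universe, citations_table, usage_ratio

universe = build_citing_universe(paths)      # parsed + filtered articles
table = citations_table(universe)            # one row per (article, cited PMID)
usage_ratio(2, 8)                            # 0.25
```

## Resource keys

Articles describing the same tool are pooled by a rule-based name
extraction from titles (first match wins): the words before a short
colon-separated prefix (`LINNAEUS: a species name identification system`
→ `LINNAEUS`), an all-uppercase word (`The BLAST toolkit revisited` →
`BLAST`), or the words up to and including a version number. Names are
normalized by lowercasing, removing hyphens and stripping trailing
version tokens (`T-Coffee` → `tcoffee`, `MrBayes 3.2` → `mrbayes`); when
no rule fires the PMID is the key, so name keys and PMID keys stay
distinguishable. The PubMed query strings used to assemble a real
informatics-resource set are shipped as constants in `uindex.queries`.

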