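# blasthits

Headless triage of massive BLAST output: import, taxonomy annotation,
two-way cross-tabulation, text mining and iterative hit selection.

## The problem

A modern similarity search easily produces reports with thousands of
queries and hundreds of thousands of high-scoring pairs (HSPs).  The raw
per-query report format — whether classic pairwise text or XML — is
unusable for whole-dataset questions like *"how many hits per taxon are
actually significant?"* or *"which queries only ever hit hypothetical
proteins?"*.  `blasthits` answers such questions by turning any BLAST
report into a compact, deduplicated dataset and offering a matrix view
over it:

* **Import** — classic pairwise text reports (BLAST 2.2.\* and BLAST+
  banners) and BLAST XML are parsed into a single model: unique query
  names, unique hit deflines (a sequence hit by many queries is stored
  once), and one record per HSP with e-value, bit score, raw score,
  identity/positive percentages (recomputed exactly from the integer
  fraction counts, never from the rounded printed percent), gap and length
  counts and normalised 1-based coordinates.  Datasets persist as
  versioned tab-separated `.bgr` text files.
* **Taxonomy** — NCBI taxdump files are loaded (scientific names only) and
  hits are annotated with TAXIDs either through a `gi → taxid` mapping
  file or by scanning deflines for scientific names (bracketed organism
  field first, then binomials, then genus names; longest match wins, ties
  stay unassigned).
* **Cross-tabulation** — HSPs are binned along any two axes: half-open
  intervals of a numeric attribute (e-values on the log10 scale, with a
  dedicated bin for the printed `0.0`), the queries or hit sequences
  themselves, or an expandable/collapsible taxonomy tree in which every
  hit maps to its deepest visible ancestor.  Cells carry a statistic
  (HSP count, distinct pairs/queries, or mean/min/max of any attribute),
  can be min-max normalised for heat maps, sorted, and *grabbed* — the
  selected HSPs become a new dataset that can be saved, re-opened and
  refined again.  Every HSP lands in exactly one cell, so counts always
  sum to the dataset total.
* **Text mining** — regex search over deflines and query names with
  ready-made templates, and word-frequency tables counted per unique
  header.
* **Alignments** — span layouts per query (all hits on one query) or per
  hit (all queries along one subject, e.g. genes along a chromosome), and
  verbatim extraction of the original alignment stanza bytes from the
  source report.
* **Split/merge** — oversized raw reports can be split into independently
  importable parts at query-block boundaries and the resulting datasets
  merged back losslessly.

A synthetic-data module generates seeded, internally consistent datasets
and renders them as valid BLAST text/XML reports, so the whole pipeline is
testable without any search run or download; a ~50-node slice of the NCBI
taxonomy ships with the package.

## Worked example

```sh
# build demo inputs: a 3-query synthetic XML report, the packaged toy
# taxdump, and a gi->taxid mapping
python - <<'EOF'
from blasthits import fixtures
from blasthits.taxonomy import write_toy_taxdump
d = fixtures.synth_dataset(fixtures.SynthSpec(n_queries=3, seed=42))
fixtures.render_report(d, "xml", "search.xml")
write_toy_taxdump("taxdump")
fixtures.write_gi_mapping(d, "gi.map")
EOF

blasthits import search.xml -o hits.bgr
# imported 3 queries, 9 sequences, 12 HSPs -> hits.bgr
blasthits tax annotate hits.bgr --gi-map gi.map --taxdump taxdump
# gi mapping: 9 assigned, 0 unassigned
blasthits matrix hits.bgr --rows evalue:-100,-50,-20,-5 --cols query --stat count
```

```
        Query_1 transmembrane   Query_2 bent    Query_3 repeat
0
(-inf,1e-100)           1       3
[1e-100,1e-50)  1       3       1
[1e-50,1e-20)           1       1
[1e-20,1e-5)                    1
[1e-5,inf)
```

The 12 HSPs are distributed over e-value decades per query (the `0` row
is reserved for e-values printed as `0.0`; empty cells are genuinely
empty, not zero).  Column sums reproduce each query's HSP count.  The same
dataset cross-tabulated on the collapsed taxonomy axis with a mean-e-value
statistic:

```sh
blasthits matrix hits.bgr --rows tax:taxdump --cols query --stat mean:evalue
```

```
        Query_1 transmembrane   Query_2 bent    Query_3 repeat
root    7.57085e-74     1.29879e-26     5.90928e-07
unassigned
```

With nothing expanded, every annotated hit rolls up to the root row; the
cells show the per-query average e-value.  Finally, grab the significant
subset and persist it for the next analysis round:

```sh
blasthits grab hits.bgr --cutoff evalue lt 1e-50 -o significant.bgr
# grabbed 9 HSPs -> significant.bgr
```

`significant.bgr` is an ordinary `.bgr` dataset: re-open it, re-crosstab
it, merge it with others — the iterative select/save/re-open loop is the
intended mode of use.  See `blasthits --help` for the remaining
subcommands (`grep`, `words`, `split`, `merge`, `layout`, `extract-aln`,
`export`).

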