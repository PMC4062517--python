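# Methods

This note documents the data model, the algorithms, the synthetic-data
generator that stands in for real BLAST runs, and the numerical and design
choices made where the problem left the design open.

## Data model

The atomic unit throughout is the **HSP** (high-scoring pair): one gapped
local alignment between a query and a hit sequence, carrying e-value, bit
score, raw score, identity and positive percentages, gap count, alignment
length, and 1-based inclusive coordinates on both sequences.  "Hit" in
loose usage is ambiguous (a hit sequence may carry several HSPs); the HSP
is the only unit whose counts are conserved under every axis choice, so
all matrix statistics default to HSP counts, with distinct
query–sequence pairs and distinct queries available as alternative
counting units.  Cell averages (e.g. mean identity) likewise average over
HSPs.

A **Dataset** is the deduplicated in-memory form of one report: an ordered
list of unique query names, an ordered list of unique hit deflines (exact
string match on the full defline is the dedup key; for XML the defline is
reconstructed as `Hit_id + " " + Hit_def` unless the id is a generic local
id like `gnl|BL_ORD_ID|…`), and the flat HSP list referencing both by
dense integer ids.  Queries with zero hits are retained so per-query
statistics stay honest.

Two normalisations make the two report dialects canonically comparable:

* identity/positive percentages are always recomputed from the integer
  fraction counts (`Identities = 48/102` → 47.0588…, never the printed
  47) — the printed rounding differs between dialects and versions;
* reverse-strand coordinates are normalised to ascending order with the
  original orientation kept in the sign of the frame field (0 when frames
  do not apply).

Equality of datasets is defined up to order via a canonical form: queries
sorted by name, sequences by defline, HSPs by (query name, defline,
q_start, s_start, bit score descending), ids renumbered.  The canonical
form is idempotent and is the equality basis of every round-trip check.
Canonicalisation drops the source index (byte offsets into the original
report), which is tied to the original HSP order.

## Parsing

XML reports are parsed with a streaming `lxml.etree.iterparse` over
`Iteration` elements, so memory is bounded by the number of unique
deflines plus HSPs rather than the document size.  The inline
qseq/midline/hseq triples are retained for alignment display.

Classic text reports are parsed by a line-oriented state machine over the
raw bytes (`Query=` blocks, `>` defline lines with continuation, `Score
=` stanzas, `Query/Sbjct` coordinate rows).  Coordinates are taken as the
min over printed starts and max over printed ends, which is robust to row
wrapping; `Strand=Plus/Minus` and `Frame = ±n` lines set the frame signs,
with frame semantics resolved by the program banner (BLASTX: query frame;
TBLASTN: subject frame; TBLASTX: both).  Old-style `Expect = e-100`
tokens are read as `1e-100`, and a missing `Positives` field (blastn)
yields a positive percentage of 0.  The byte span of every stanza is
recorded together with a SHA-1 of the file, so alignment text can later be
returned verbatim — extraction refuses to run if the file is missing or
has changed.

Tabular (outfmt 6/7) and archive formats are out of scope, as are
PSI-BLAST rounds beyond the first.

## The .bgr store

The store format (`#BGR1`) is a deliberately frozen dialect: UTF-8,
tab-separated, `#`-prefixed section headers carrying row counts, sections
for queries, sequences (defline + optional TAXID column, filled only after
annotation) and HSPs in a fixed 15-column order.  Floats are written with
`repr`, making write→read lossless and the bytes deterministic for a given
dataset.  Merging unifies queries by name and sequences by defline; a
defline carrying two different TAXIDs across inputs is an error rather
than a silent overwrite.  Duplicate HSP rows across merged files are
retained on purpose: merging the parts of a split report must be lossless,
and dropping "duplicates" would silently alter datasets that legitimately
contain tied HSPs.

Report splitting never divides a query block: text reports are cut at
`Query=` byte boundaries with the original header bytes prepended to each
part; XML reports are re-wrapped with the original non-iteration elements.
Part sizes differ by at most one query, and asking for more parts than
queries degrades to one part per query.

## Taxonomy

The NCBI taxdump (`nodes.dmp`/`names.dmp`, pipe-delimited) is loaded
directly; only `scientific name` rows are kept, one name per node, with
`taxid:<n>` as fallback.  Loading verifies acyclicity and reachability
from the root.  A ~50-node slice of the real taxonomy (metazoan spine
down to a dozen model species, plus fungal/plant/bacterial outgroups) is
generated programmatically by `write_toy_taxdump` for tests and demos.

Annotation never overwrites an existing TAXID unless asked.  The
defline-name route uses a precedence this package defines (the behaviour
is not standardised anywhere): bracketed organism fields first, then
two-word binomial matches over the whole defline, then single-word
(genus) matches; within a tier the longest match wins and a length tie
between distinct taxa leaves the hit unassigned and counted as ambiguous.
This is deliberately conservative — a wrong assignment is worse than none.
The gi route requires the taxid to exist in the loaded tree when a tree is
supplied.  Accession-based mapping (the post-gi era) is a documented
extension point, not implemented; `merged.dmp` handling is likewise out of
scope.

An **expansion state** is the set of expanded nodes.  A node is *visible*
when every strict ancestor is expanded; the visible set always includes
expanded internal nodes themselves, since a hit annotated exactly at such
a node needs a row of its own.  `visible_ancestor` maps any taxon to the
deepest visible node on its root path (root when nothing is expanded, the
taxon itself when everything is), and is idempotent under a fixed state.
Hits without a TAXID occupy a reserved `unassigned` row so conservation
holds on taxonomy axes too.

## The matrix engine

Interval bins are half-open `[low, high)` — the standard convention, and
the one that makes bin refinement exact (splitting a bin preserves the
count sum).  E-value axes take their edges as log10 exponents and bin
`log10(evalue)`; BLAST prints `0.0` for hits beyond float underflow, and
such values get a dedicated `0` bin preceding underflow rather than being
silently floored into the most significant bin, which would distort the
tail.  Underflow/overflow bins are included by default; when explicitly
disabled, out-of-range HSPs are dropped and counted in `Matrix.n_dropped`
(the conservation identity `Σ cells = |hsps|` is stated for the default
configuration).

Heat-map normalisation is min-max over non-empty cells (empty cells are
absent, not zero); a constant matrix maps to 0.5 everywhere.  E-value
statistics are normalised on the log10 scale, with exact zeros clamped to
1e-300 first — at that point the cell is simply "the most significant"
and its exact magnitude is meaningless.  Sorting is stable with ties
broken by label; grabbing unions the HSP index sets of the chosen cells,
or of all cells passing a statistic cut-off.

## Selections

A selection is a set of HSP indices into one parent dataset; set algebra
is only defined between selections of the same parent.  Materialising a
selection renumbers ids densely and carries TAXIDs over.  Zero-hit queries
are dropped at this point — a selection is hit-driven and cannot reference
them — which is the one documented way select-all differs from the parent.
Selections persist only as `.bgr` datasets; there is no separate selection
file format.

## Synthetic data

The generator is the package's model of its study conditions, not a
convenience mock.  Defaults: protein-style (blastp) reports, 10 queries,
0–8 hits per query, 1–2 HSPs per hit, e-values spanning decades 10¹ down
to 10⁻¹⁸⁰ (log10 uniform) with a 1% chance of a printed `0.0`, bit scores
25–1200 decreasing linearly in log10(e-value) with ~3% Gaussian noise,
alignment lengths 40–300 with identities and positives fitted inside the
ungapped columns, and a 30% chance that a hit reuses an already-generated
defline so dedup is always exercised.  Deflines compose a `gi|<n>|` token,
a RefSeq-style accession, vocabulary words (including multiword phrases
like "cell adhesion molecule") and a bracketed species binomial drawn
from the packaged toy taxonomy; a configurable fraction of deflines omits
both gi and species, making them honestly unannotatable — the planted
truth for every defline is recoverable from the defline itself, which is
what the annotation-recovery checks compare against.  Values are
quantised to their printed precision (e-values to 6 significant digits,
bit scores to one decimal) so that render→parse round trips are exact
rather than approximate.

Rendered reports are structurally faithful: wrapped 60-column alignment
rows with running coordinates whose letter content matches the
identity/positive/gap counts exactly (gap columns are placed on the
subject side, so the query span equals the alignment length), `***** No
hits found *****` blocks for hitless queries, and an XML parameter block
that independent parsers (e.g. Biopython's `NCBIXML`, used as a
cross-check oracle in the tests) accept.  What the generator does *not*
emulate: real Karlin–Altschul score statistics (scores are internally
consistent but not physically derived), biological sequence content
(letters are decorative), vendor-specific footer variants, and
multi-round PSI-BLAST structure.  Passing tests therefore demonstrate
correctness of parsing, storage, counting and selection logic on
well-formed reports — not robustness to every formatting quirk observed
in the wild.

## Verification sizes

The round-trip suite runs 100 seeded datasets (shapes from a single
hitless query up to ~10⁴ HSPs) through both report dialects and the
store; conservation and oracle-agreement suites use dozens of smaller
datasets (≤ a few hundred HSPs) where brute-force re-computation is
instant; the workflow analog uses 2 queries × 5,000 HSPs across e-value
decades 10⁰…10⁻²⁰ with a five-interval axis cut at 10⁻¹⁶; split/merge uses
a 1,000-query report in 7 parts.  These sizes keep the whole suite and the
acceptance script in the seconds range on one CPU while still crossing the
10⁴-HSP scale where quadratic mistakes would show.

## Known limitations

* Text-dialect parsing targets the common stanza grammar of BLAST 2.2.\*
  and BLAST+; exotic or vendor-patched layouts may need parser extensions.
* Name-based annotation is exact-match against scientific names; it does
  not handle misspellings, abbreviations ("D. melanogaster") or common
  names.
* The taxonomy axis materialises the full visible frontier; expanding
  thousands of nodes at once will produce matrices with that many rows.
* `.bgr` files store no alignment text; verbatim extraction requires the
  unchanged original report.
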