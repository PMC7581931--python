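# Methods

## The habitat preference model

The toolkit treats "where has this sequence been observed?" as a trait.
A reference database holds 16S rRNA gene sequences, each labeled with
exactly one environmental category (`soil`, `marine`, `human_gut`, ...)
and the research project it was mined from. For a query sequence *q*
with significant similarity hits against the database, let *n_c* be the
number of hit references labeled with category *c*. The habitat
preference score of *q* is the composition

    score_c(q) = n_c / Σ_c' n_c'

Near-identical reference sequences occur under several categories, so a
query is routinely mapped to more than one habitat; the score is a
composition (non-negative, sums to 1), never a hard classification. An
optional variant divides each *n_c* by the category's database size
*S_c* before renormalizing (`normalize_by_category_size=True`). This
damps the head categories — in the packaged census, soil alone is 25%
of all sequences — at the cost of amplifying noise in tiny categories;
the plain hit-count composition is the default.

A community sample is scored as the read-abundance-weighted mean of the
score vectors of its *mapped* features (features with at least one
significant hit), renormalized over mapped features. Unmapped features
are excluded, not spread uniformly, and reported separately as coverage:
the fraction of features mapped and the fraction of reads in mapped
features. Renormalization keeps score rows comparable across samples
with different coverage; the coverage columns carry the information that
renormalization removes. An unweighted mean is available for
presence/absence designs.

`merge_categories` sums scores over user-defined, disjoint category
groups (e.g. a brine-related group `{estuary, hypersaline_lake, marine,
salt_lake, salt_marsh, seawater, marine_sediment}`), preserving the
total; categories covered by no group either pool into `other` (default)
or are dropped with renormalization.

## Database balancing

Public metagenome projects differ enormously in size, so an unbalanced
database would make scores reflect sequencing effort rather than habitat
prevalence. `cap_per_project` retains at most `cap` sequences (default
100) per (category, project) pair, sampled uniformly without replacement
with a fixed seed; groups are processed in sorted order so the result is
independent of input record order, and the operation is idempotent.

The per-category census of the public ProkAtlas habitat database (115
categories, 361,474 sequences) ships as package data; `category_summary`
reproduces its coverage arithmetic — the four largest categories (soil,
marine, freshwater, rhizosphere) cover 55.3% of sequences, the largest
26 cover 90.4%.

## Similarity search

A hit must pass two filters: minimum alignment length (default 150
columns — long enough that partial amplicon fragments still carry
habitat signal, short enough to retain hits for most variable-region
reads; raising it to 200–250 is a standard robustness check) and
minimum percent identity (default 97%, the conventional species-level
cutoff). Identity is matches / alignment columns (gaps included), the
BLAST tabular convention; `N` never counts as a match, not even against
another `N`.

Alignment is exact affine-gap local (Smith-Waterman/Gotoh) dynamic
programming with integer scores +1 match, −2 mismatch, and gap cost
`open + L·extend` with open −5 and extend −2, computed by Biopython's C
`PairwiseAligner`. Exactness per pair is a deliberate design choice:
banded or X-drop extension heuristics produce scores that depend on band
placement, whereas here the per-pair result is provably the optimum and
is verified against an independent full-matrix Python implementation in
the tests. Per (query, reference) pair only the best-scoring HSP is
kept (ties: smaller query start, then reference id, then plus strand),
so one reference can never contribute twice to a score. Reverse-strand
hits are found by aligning the reverse-complemented query; coordinates
are reported 1-based inclusive, ascending on the query, with strand `-`.

Speed at database scale comes from two sound pre-filters in
`search_queries`, not from approximate alignment:

1. **k-mer candidate selection.** An exact k-mer index (default k=12,
   N-containing k-mers excluded) proposes, per query strand, the
   references sharing at least `min_seed_count` (default 2) distinct
   k-mers. A 150 bp fragment at 97% identity shares ~96 intact 12-mers
   with its source in expectation, so the filter is effectively
   lossless for reportable hits while removing most chance candidates
   (two random 1500 bp sequences share a 12-mer ~13% of the time, two
   or more ~1%).
2. **Score floor prescreen.** Any alignment passing the length and
   identity filters must score at least
   `ceil(pid·L_min)·match + (L_min − ceil(pid·L_min))·(min(mismatch,
   extend) + open)` (every non-match column priced at its worst case);
   candidates whose optimal score — computed by the same exact DP in
   score-only mode — falls below this floor cannot yield a hit and are
   skipped before the more expensive traceback.

`align_pair` itself applies no seeding, so single-pair alignment is
always exact regardless of shared k-mers. Hits can be exported to and
imported from 12-column BLAST `-outfmt 6` TSV (strand inferred from
subject coordinate order), so an external search tool can substitute
the built-in one; E-value filtering applies only to imported hits since
the internal aligner computes none.

## Statistics

Two-sided tests throughout, since no direction is assumed.

- **Mann-Whitney U** (`group_score_test`): grouped scores of samples
  with the target source label vs all others. Ties take midranks; the
  p-value is exact (full enumeration) when the smaller group has ≤ 8
  observations and the pooled data is tie-free, otherwise the normal
  approximation with tie and continuity correction (scipy). The U
  reported is the in-group's; U_in + U_out = n_in·n_out holds exactly.
- **Spearman rank correlation** (`gradient_correlation`): Pearson
  correlation of midranks between a grouped score sum and a numeric
  gradient (salinity, age, site order), p from the t approximation.
  Constant input is an error rather than a NaN. Samples missing
  metadata or scores are dropped with a warning; fewer than 3 usable
  samples is an error.
- No multiple-testing correction by default (single planned contrasts);
  Benjamini-Hochberg (`benjamini_hochberg`) is available when screening
  many category groups.

## Co-occurrence network

Each category is described by the composition of representative entries
its references map to. At full scale the mapping comes from an external
reference set supplied as a two-column TSV; at desk scale
`cluster_representatives` provides greedy centroid clustering in input
order (a sequence joins the first centroid it aligns to at ≥ 97%
identity over ≥ 150 columns, else founds a new cluster) — deterministic,
order-dependent, and intended for modest database sizes since it aligns
against existing centroids sequentially.

Pairwise Bray-Curtis dissimilarity `1 − 2·Σmin(u,v)/(Σu+Σv)` between
category composition vectors is thresholded — an edge iff BC is
*strictly* less than the threshold (default 0.9) — into an undirected,
unweighted graph. Betweenness is pair-counting: node *v* scores one for
every connected unordered pair {s, t} (both ≠ v) with at least one
shortest path through *v*, computed from BFS distances via the
condition `d(s,v) + d(v,t) = d(s,t)`. This counts a node once per pair
however many shortest paths cross it, which differs from Freeman
betweenness (fractional credit per path); the Freeman variant is
available with `fractional=True`. Shortest paths ignore the
dissimilarity values (edge presence only).

## Synthetic data generator

The generator provides ground-truth-known inputs in exactly the formats
the pipeline consumes. Per category it draws a pool of ancestor
sequences (i.i.d. uniform nucleotides, default 1500 bp — full-length
16S scale — 50 ancestors per category); a symmetric overlap matrix sets
the probability that an ancestor slot is shared between two categories
(identity ⇒ disjoint pools). Every reference is one substitution-
mutated copy of an ancestor (default rate 1% per base; a mutated base
always changes, so ancestor divergence is Binomial), assigned
round-robin to projects. Communities allocate features to categories in
the requested mixture by largest-remainder rounding (default 40
features), draw each feature as a fresh mutated pool copy, and spread
reads multinomially (default 10,000) with per-category expectation equal
to the mixture. Gradient studies share one feature catalogue (default
15 features per involved category) across samples whose mixtures
interpolate linearly between two endpoints; the interpolation coordinate
is recorded as the `gradient` metadata covariate. An optional
`indel_rate` adds single-base insertions/deletions for exercising gapped
alignment. All outputs are byte-identical for a fixed seed.

What the generator does **not** emulate: 16S secondary structure, GC
and codon biases, conserved/variable region architecture, chimeras,
sequencing-error profiles, primer effects, or realistic phylogenetic
correlation between categories. Consequently, passing recovery tests
demonstrates that the search-score-aggregate machinery is correct and
well-calibrated under controlled divergence, not that real habitat
assignments at these thresholds are accurate — on real data,
cross-category sequence sharing is the dominant effect and scores are
correspondingly more diffuse.

## Numerical and edge-case conventions

- Compositions must sum to 1 within 1e-9; aggregation renormalizes after
  float accumulation so the invariant holds exactly enough.
- Zero hits ⇒ `mapped=False` with empty scores; all-zero samples report
  coverage (0, 0); unmapped samples appear as all-NaN score rows.
- Sequences are uppercased on input; characters outside {A,C,G,T,N} are
  rejected at load with a clear error.
- Subsampling, clustering and generation are deterministic given seeds;
  capping iterates groups in sorted order to decouple the RNG stream
  from input order.
- Integer alignment scores; percent identity printed with 2 decimals in
  tabular output.

## Verification scale

The test suite and the acceptance script verify, at desk scale: the
packaged census arithmetic (exact); aligner score equality with an
independent full-matrix Smith-Waterman on 200 random ≤60 nt pairs;
pair-counting betweenness equality with shortest-path enumeration on
100 random ≤7-node graphs; exact Mann-Whitney p-values against full
enumeration for all group-size combinations up to 6×6 and Spearman
against explicit rank-then-Pearson; and end-to-end recovery on the
default synthetic conditions (3 disjoint 50-ancestor pools, 1500 bp, 1%
mutation) — mixture recovery within 0.05 mean absolute error and
gradient tracking at Spearman ρ ≥ 0.9, each over 10 seeds. These sizes
keep the whole verification run in a few minutes on one CPU while
leaving the generator at its default, realistic settings.

## Known limitations

- The greedy clustering is quadratic in the number of clusters and not
  meant for >10^4 references; supply an external mapping there.
- The internal aligner computes no E-values; statistical significance
  of hits is length+identity thresholding only.
- One category per reference; multi-label references are out of scope.
- Category labels are opaque tokens; no ontology or hierarchy is
  modeled, so grouping related categories is the user's responsibility.
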