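# Methods

## Exact count-ratio test

For one miRNA observed `x` times in library 1 (total clean reads `N1`) and
`y` times in library 2 (total `N2`), the test conditions on `x` and asks
how surprising `y` is under equal underlying abundance:

    p(y | x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

This is the posterior predictive of a Poisson rate under a flat prior —
identically the negative-binomial pmf NB(r = x+1, p = N1/(N1+N2)).  That
identity is what the implementation uses: the point probability is
evaluated in log-gamma space (stable to x+y ≥ 10^6) and the cumulative
tails through the regularized incomplete beta function
(`scipy.stats.nbinom.cdf`/`sf`), so the infinite upper sum needs no
truncation.  Both tails include the observed count (`C + D = 1 + p(y|x)`),
and the default two-sided p-value is `min(1, 2 min(C, D))`; a one-sided
option returns `min(C, D)`.  When `x = y` and `N1 = N2` the lower tail is
exactly 1/2, so the two-sided p is 1.

Because the test needs integer counts while the screening prose works on
normalized expressions, the screen defaults to raw counts with the true
library depths (`count_basis="raw"`, the statistically coherent choice); a
`"rounded-normalized"` mode instead tests `round(rpm)` against depth 10^6
for users who want the literal normalized-data reading.  The two agree
whenever depths are equal, and exactly when depths are 10^6.

### Screening rules

All three must hold, strictly: rpm > `min_expression` (default 50) in at
least one of the three stages; |log2 FC| > `fc_cut` (default 1); p <
`p_cut` (default 0.01).  Zero counts give signed-infinite fold-change
sentinels that pass the fold rule (no pseudocount is added — the remaining
two rules still gate them); 0/0 gives NaN and never passes.  The compared
stage pair defaults to (peak, early) but is a caller decision, as is which
stage is the fold-change numerator — the source workflow is ambiguous on
both, so neither is hard-coded.

## Pattern clustering

Distances are squared Euclidean on the raw three-stage rpm vectors (the
desktop-statistics default for between-group linkage), with plain Euclidean
and a per-miRNA max-rescaling option for shape-only comparisons.
Agglomeration uses unweighted average ("between-group") linkage via the
Lance–Williams update; ties on the minimum inter-cluster distance are
broken on the lexicographically smallest pair of cluster representatives
(each cluster's smallest member id), making the merge history — which is
returned in full — deterministic.  Average linkage is reducible, so
heights never invert.

`cut_tree(history, k)` undoes the last k−1 merges.  Labels A, B, … follow
descending mean earliest-stage expression when the expression profile is
passed in (the profile is not derivable from the merge history alone);
otherwise labels are alphabetical by first member.  Manual reassignments
(`apply_overrides`) are recorded with their from/to labels, never silent —
this supports the common practice of moving a biologically argued outlier
into the cluster it resembles.  k is fixed by the caller (default 5); no
automatic model selection is attempted because the emulated workflow chose
k visually.

## Consensus targets

A gene is a candidate target of a miRNA when at least `min_support`
(default 3) of the configured programs predict the pair.  Programs with no
entry for a miRNA still count in the roster denominator, so miRNAs missing
from most databases naturally end up with empty candidate lists rather
than being special-cased.  Gene symbols are upper-cased before voting;
database variants of the same program (e.g. two miRanda builds, two PicTar
conservation settings) are distinct roster members.  `multiplicity_stats`
reports both "exactly m lists" and "at least 2 lists" conventions, because
published counts of shared targets commonly use the latter.

## Ontology handling and enrichment

The OBO parser covers the is_a subset (`id`, `name`, `namespace`, `is_a`,
`is_obsolete`); other relationship types are out of scope.  Levels are
1-based shortest is_a paths from each namespace root, the convention under
which terms like "binding" sit at level 2.  Annotation follows the
true-path rule, computed once in topological order; a gene reached along
several paths counts once.

The per-term enrichment score is `Σ seq × α^dist` over the term itself
(dist 0) and every descendant with direct annotations, where `seq` is the
count of distinct directly annotated sequences at that descendant and
`dist` its shortest descending edge distance; each descendant contributes
once regardless of path multiplicity.  α is not specified by the emulated
workflow anywhere; the default 0.6 follows the annotation tool that
workflow used, and the parameter is explicit everywhere.  The score is
monotone in α, and on a tree at α = 1 the root score equals the total
number of direct annotations.

Cluster enrichment tests gene-level 2×2 tables (annotated/not ×
test/reference) with scipy's two-sided Fisher's exact test (the standard
"sum of tables with point probability ≤ observed" rule).  The test set is
one cluster's target-gene union; the reference is the union of the other
clusters' targets *minus* the test set, since a gene targeted by miRNAs in
two clusters would otherwise break the disjointness the test requires.
Raw p against 0.05 is the default, matching the emulated workflow's lack
of correction; Benjamini–Hochberg q-values are available behind a flag.
Term-level sampling units (counting GO terms rather than genes) would not
yield a valid 2×2 table and are not implemented.

## Pathway counting

A static 3-column gene→pathway map is intersected with the candidate gene
set; pathways with ≥ `min_genes` (default 3, "more than two") matches are
reported, sorted by count.  No enrichment statistic is computed — with a
couple of hundred candidates the counts themselves are the readout, and
online-service results are database-version-bound and irreproducible.

## Synthetic data: the stated world

* **Counts** — one Poisson library per stage around fixed per-stage means;
  no overdispersion, because the emulated design pools animals into a
  single library per stage, and the count-ratio statistic is exactly the
  Poisson-ratio predictive.  Baselines are log-uniform on [50, 50 000] rpm:
  the screening floor of the emulated study is 50 rpm and its mean
  expression exceeds 2 500 rpm (this range gives mean ≈ 7 200).  Planted
  differential miRNAs have the peak-stage mean scaled *up* by the fold
  factor (default 8), depth 10^6 per library.
* **Patterns** — five fixed three-stage templates encode the five
  published pattern shapes verbally (rising; dip at peak; early-low
  plateau; peak maximum; early-high plateau); no pixel values exist to
  copy.  Gaussian noise, clipped at zero.
* **Predictions** — planted pairs are inserted into ≥ `support_at_least`
  programs, noise pairs into at most `support_at_least − 1`, so the
  consensus at that threshold recovers the planted sets exactly; the noise
  rate applies per (miRNA, non-planted gene).
* **Ontology** — a random rooted DAG (each term gets one parent, 30% a
  second), uniform background annotation at rate 0.05 per (gene, term),
  and planted terms annotating one cluster's genes at multiplied odds.

What a green synthetic test does **not** establish: behaviour under
overdispersed replicates, real prediction-program error structure (which is
correlated, not uniform), or real GO topology (the generated DAGs are far
smaller and shallower).  The generators exist to verify the machinery, not
to imitate biology.

## Numerical and design choices

* The count-ratio formula's depth factor is read as `(N2/N1)^y` — the only
  reading under which the distribution over `y` normalizes to 1 (verified
  to 1e−9 in tests).
* Point probabilities match big-integer rational arithmetic to 1e−12 for
  x+y ≤ 30; Fisher p-values match exhaustive hypergeometric enumeration to
  1e−7 for all tables with margins ≤ 15.
* Report writers sort on primary keys and use fixed column orders; two runs
  on identical inputs produce byte-identical bundles.
* The pipeline halts at the first failing stage with a stage-named error;
  an empty screen is reported explicitly rather than cascading.

## Known limitations

Single-library designs cannot separate biological from sampling variance;
the exact test's p-values are well calibrated only under the Poisson
assumption.  Clustering reproducibility across software depends on the
(unpublished) distance metric of the emulated study; squared Euclidean is a
documented default, not a recovered fact.  The packaged published target
table stores gene symbols verbatim, including one symbol that later
nomenclature revised, and symbol matching is case-insensitive only — no
alias resolution is attempted.
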