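# Methods

## Quantification model

Spectral counting treats the number of MS/MS spectra matched to a protein
in one run ("protein matches") as a semi-quantitative abundance proxy.
The pipeline consumes protein-level report tables; peptide-level evidence
appears only as an optional peptide-set column used for redundancy
resolution.  Raw searching (Mascot, database choice, FDR) is upstream and
out of scope.

## Identification filter

* Score rule: a hit is kept when its protein score is **strictly greater
  than 35** (`strict=True` default).  Because score conventions vary
  between search-engine versions, a non-strict `>=` flag exists.
* Redundancy rule: among hits whose peptide sets are **exactly equal**,
  only the hit with maximal percent coverage survives.  Coverage ties
  break to the lexicographically smallest accession, purely for
  determinism.  Subset relationships (true parsimony inference) are out of
  scope; the rule is applied per run.

## Normalization

Per run *j* with counts `c_ij`:

1. `TM_j` = 4% trimmed mean of the run's column: sort, remove
   `k = floor(n * 0.02)` values from each end, average the rest.  Ties at
   the trim boundary are positional (standard trimmed-mean semantics);
   short columns (`n < 50`) trim nothing.
2. Scale: `v_ij = c_ij / TM_j * 100`.  The trimmed mean of the scaled
   column is exactly 100 (asserted to 1e-9 relative in tests).
3. Zero rule: scaled zeros (non-detections) are set to 1.
4. `x_ij = log2(v_ij)` — the protein expression value.  All
   non-detections therefore share the value log2(1) = 0.

Zeros are **included** in the trimmed-mean computation by default: the
normalized column is the union-with-zeros assembly, and the zero patch is
applied only after scaling, matching the stated order of operations.  The
alternative (trimmed mean over detected proteins only) is available as
`detected_only=True` and recorded in the pipeline manifest, since the two
conventions give different scale factors.  Note that when many proteins in
a column are zero, `TM_j` can be small and scaled values of rare proteins
can fall below 1, producing negative expression values — which is why the
profile bins extend below zero.

## Expression profiles

Unit-width bins from "< -2" to "> 8": bottom bin open `(-inf, -2)`,
interior bins half-open `[k, k+1)` for k = -2..7, top bin `[8, +inf)`.
The half-open convention is a package decision so that every value,
including integer boundaries (8 goes to the top bin), lands in exactly one
bin.  Default grouping pools the runs of a stage (one curve per stage).

## Detection and Venn accounting

A protein is detected at a stage when it appears in at least `min_runs`
runs of that stage (default 1; the aggregation rule is a config key
recorded in the manifest).  The Venn summary computes the seven exclusive
regions of the 3-set diagram directly from membership sets; pairwise and
triple intersections and all unions follow, and inclusion-exclusion
consistency (`|A u B| = |A| + |B| - |A n B|`, the 7 regions partitioning
the union) holds exactly by construction and is property-tested.

## Differential expression

For a stage pair (A, B), proteins detected in neither stage are skipped.
Exclusivity is decided **first**: detected in all runs of one stage and no
run of the other -> `exclusive_A` / `exclusive_B`.  Testing such a protein
would be meaningless — its expression in the empty stage is the constant
zero-fill value.  Everything else gets a two-sample t test on the per-run
expression values: pooled variance, `df = nA + nB - 2` (the classical
Student form; Welch with Satterthwaite df by flag), two-sided p, called
`de` when `p < alpha` (default 0.05, strict).  No multiple-testing
correction by default, mirroring the raw-threshold convention; a BH flag
exists.  Degenerate cases are resolved so pipelines complete: both groups
constant and equal -> t = 0, p = 1; both constant but different -> p = 0
with a `degenerate` flag.  `exclusivity_mode="test"` disables the
presence/absence shortcut and pushes every protein through the t test.

The run-level presence needed by the all-vs-none rule comes from the count
matrix (count >= 1), which is why `classify_de` takes the counts alongside
the expression matrix: absence and a count that normalizes to exactly 1
are indistinguishable after the zero rule.

## Clustering

Distances: euclidean, or correlation (1 - Pearson r; zero-variance
vectors are flagged with a warning and assigned distance 1).  Linkage:
single / complete / average, computed by the explicit O(n^3)
agglomeration with a deterministic tie-break (lowest node-index pair) —
n is 9 runs in the design this package targets, so the cubic scheme is
the transparent choice, and it is cross-checked against
`scipy.cluster.hierarchy` on random instances in the tests.  Defaults are
euclidean + complete linkage (the baseline defaults of the R `hclust`
environment such studies typically use); both are config keys, and since
the upstream metric/linkage of any given published tree is usually
unstated, only the qualitative stage-grouping property (embryonic-like
runs forming one clade) is asserted, not topology reproduction.  Trees
export to Newick with branch lengths equal to merge-height differences.

## Enrichment

One-tailed over-representation p-value per term: `P(X >= k)` for
hypergeometric X with list size n, term background hits K, background
size N.  The EASE score is the same tail with the list-hit count
decremented by one (`P(X >= max(k-1, 0))`), the published EASE
definition — only the 0.1 threshold, not the formula, is usually quoted.
EASE >= Fisher always.  The background defaults to a user-supplied
"whole genome" list; falling back to the detected-protein universe is
possible and changes results (the choice is recorded in the manifest).
Ranking keeps `ease_p < 0.1`, sorts ascending (ties by term id), top 10.
Term databases themselves (GO/KEGG content) are user inputs in GMT
format; no web service is queried.

## Synthetic data generator

Emulates the 3-stage x 3-replicate-run design with protein-level truth:

| parameter | default | meaning |
|---|---|---|
| `n_proteins` | 2000 | proteome size, same order as the ~2500-protein unions such cortex studies report |
| `baseline_log2_mean`, `sd` | 3.0, 1.5 | lognormal abundance across proteins (median ~8 spectra/run, right-skewed like real spectral counts) |
| `dispersion` | 0.2 | negative binomial `var = mu + disp * mu^2`; 0 = Poisson limit |
| `true_lfc` | 3.0 | log2 effect of de classes, applied at the last stage |
| `class_fractions` | conserved 0.15, de_up 0.05, de_down 0.05, exclusive 0.05/stage | remainder is the flat null class |
| `detection_floor` | 1 | count below which a protein is absent from a run's report |
| `score_params` | hits N(80, 15) clipped > 35; 10% decoys U(5, 35) | identification scores; decoys exercise the filter |

Design choices:

* All systematic effects (de shifts, exclusivity at the last stage) load
  on the last, postnatal-like stage, so the two earlier stages are more
  similar to each other — the structure the clustering step must recover.
* Exclusive-class baselines are floored at the abundance median so that
  absence elsewhere is biology, not sampling depth; a stage-exclusive
  protein sitting below the detection floor in its own stage would be an
  unfalsifiable truth label.
* Conserved-class proteins get a +2 log2 abundance offset: "housekeeping"
  proteins detectable in every run.
* A single root seed derives per-run substreams
  (`default_rng([seed, 1, stage, replicate])`), so adding runs or stages
  never perturbs earlier runs' draws.

What the generator does **not** emulate: peptide-level sampling, gel
fractionation, shared-peptide ambiguity (peptide sets are omitted from
synthetic reports), run-order or batch drift, and score-abundance
correlation.  Passing tests therefore demonstrate the pipeline's
arithmetic and its statistical calibration under the stated noise model,
not robustness to those real-data artefacts.

## Problem sizes and tolerances

Tests run the full pipeline at 2000 proteins (one shared fixture) and
calibration checks at 3000 proteins; clustering oracle comparisons use
n <= 8 items against scipy; Fisher/EASE p-values are compared to an exact
rational enumeration oracle at N <= 60 within 1e-12.  The type-I band for
the DE rule on null data is [0.02, 0.09] at alpha 0.05 — deliberately
wide, since a t test on n=3 log-transformed counts is approximate.
Trimmed-mean and round-trip contracts are asserted at 1e-9 relative and
1e-12 absolute respectively.

## Known limitations

* Spectral counting is semi-quantitative; no NSAF/emPAI length
  normalization or variance-stabilizing transform is offered.
* The t test on n=3 log counts is anticonservative for low-count
  proteins; count-model GLMs (edgeR/DESeq-style) are out of scope.
* Protein inference is exact-peptide-set deduplication only, not
  parsimony.
* Published absolute identification counts from any particular study are
  not reproducible from report tables alone (they depend on the raw data
  and search settings); only the overlap arithmetic and summary
  conventions are.
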