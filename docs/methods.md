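# Methods

This note documents the statistical models, numerical conventions and design
choices behind combiscreen, and what the synthetic-data generators do and do
not emulate.

## Signatures

**Disease signature.** Case/control expression is transformed to log2(x+1);
each gene gets a two-sided Welch t-test (unequal variances) with
Benjamini–Hochberg adjustment, and log2FC is the difference of condition
means of the transformed values. A gene is active iff |log2FC| strictly
exceeds the fold-change threshold (default 1) *and* the adjusted p is
strictly below the FDR threshold (default 0.1); both inequalities are strict,
so boundary values are excluded. Genes constant across all samples are
excluded with a warning (a t-test is undefined there); genes with zero
within-arm variance but different means are treated as p = 0. The tumor/
normal pairing of matched cohorts is ignored (unpaired test): the pairing key
is carried in the data model but no paired procedure is defined here.

The Welch-t choice is deliberately dependency-light; RNA-seq count models
(negative-binomial GLMs) would give different gene lists on real data. For
this screen the signature is a sign pattern, not an inference target, and the
test's FDR behaviour is verified directly on simulated null cohorts.

**Consensus signatures (TCS).** Per cell line, a gene's call is the sign of
the median differential score across that line's experiments, zeroed when the
|median| falls below a per-experiment threshold. The TCS direction is the
strict-majority sign across calling cell lines; support counts the agreeing
lines, so it is capped at the number of cell lines used. The per-experiment
threshold defaults to 0 (pure sign of the median) because no canonical
binarization of level-4 robust z-scores exists; it is exposed everywhere.
With continuous scores a zero threshold makes *every* gene call ±1 in every
line, so any realistic screen needs a positive cut — the synthetic panels
carry `call_threshold = 1.0` (half the planted mechanism magnitude, the
usual |z| ≥ 1 rule) as part of their study conditions.

**Reference signatures.** A gene is active iff one sign recurs in at least
`min_fraction` (default 0.5) of the filtered experiments; support is the
number of agreeing experiments. Whether "experiments" means distinct assay
runs or distinct cell-line contexts is left to the caller via the cell-line
filter.

**Tie rule.** Everywhere a sign vote can tie exactly (equal cell-line counts;
both signs reaching `min_fraction` when it is ≤ 0.5), the gene is
conservatively inactive (direction 0) rather than arbitrarily signed.

**Gene universes.** Operations on two signatures use the intersection of
their gene universes; a gene outside a signature's universe counts as
inactive (direction 0) where a third signature is consulted (the reference
in DR).

## Orthogonality

Over genes active in both candidate z and reference r, CR counts sign
products: n_same/(n_same+n_opp) in the default *normalized* mode, or the
literal same:opposite ratio n_same/n_opp in *as_printed* mode. DR does the
same on the disease products z·d restricted to genes with r = 0. The
normalized mode is the default because the OS geometry — OS = √((1−CR)²+DR²)
maximal at CR→0, DR→1 (the upper-left corner of the CR/DR scatter) — only
behaves as intended with both ratios in [0,1]; the literal ratio mode is
retained for fidelity and flags division-by-zero with an infinity sentinel.
Genes with a zero product contribute to neither count. Compounds whose CR or
DR is undefined (empty eligible set) are excluded from rankings and reported,
rather than scored 0, to avoid spuriously extreme OS. Ranking sorts by OS
descending with ties broken by higher DR then lexicographic compound id, so
reruns are bit-identical.

Compound clustering correlates direction×support vectors (not raw scores) so
Pearson r sees the consensus structure; edges require r strictly above the
threshold (default 0.7), and cluster labels come from average-linkage
hierarchical clustering on 1−r cut at the same threshold. The top-k cut for
candidate selection is descriptive, default 3.

## Network pharmacology

Distances are unweighted hop counts restricted to the graph's largest
connected component; protein-set members outside it are dropped with a
warning instead of producing infinite distances. The closest distance
d(X,Y) = (1/|Y|) Σ_y min_x d(x,y) is deliberately asymmetric (it averages
over Y, the disease proteins).

**Null model.** Each of the `n_permutations` (default 100) permutations
replaces *both* X and Y by random node sets matching their sizes and degree
profiles; degrees are binned by floor(log2(degree)) and bins with fewer than
10 candidates are merged with the next lower bin, the standard
network-medicine fallback for sparse tails. z = (d − μ)/σ with μ, σ the mean
and population standard deviation (ddof = 0) of the permuted distances;
σ = 0 flags z as undefined. The proximity computation precomputes the
all-pairs hop-distance matrix once per graph so the permutations reduce to
array indexing; this is exact, not approximate. With a fixed seed the result
is bit-reproducible (sampled index sets are sorted before averaging so
floating-point summation order is stable).

**Separation.** In s_AB = ⟨d_AB⟩ − (⟨d_AA⟩+⟨d_BB⟩)/2, the cross term
averages, over every node of both sets, the distance to the nearest node of
the opposite set (a shared protein contributes 0); the within terms average
the nearest-*distinct*-neighbor distance, with a singleton set's within-term
defined as 0. These conventions make the sign rules hold: identical modules
give s ≤ 0 always, and disjoint well-separated modules give s > 0.

**Exposure categories.** complementary ⟺ z_A < 0 ∧ z_B < 0 ∧ s_AB ≥ 0;
overlapping ⟺ z_A < 0 ∧ z_B < 0 ∧ s_AB < 0; single ⟺ exactly one z < 0;
non otherwise. An undefined z counts as not-negative. A drug with no curated
targets cannot be assessed and raises (the pipeline reports such pairs as
"not assessable" instead of failing the run).

**Tissue filter.** The induced subgraph on proteins with median expression
strictly above the TPM threshold (default 1.0); proteins without expression
data count as not expressed. Proximity can be run against the full or the
filtered interactome; both are supported.

## Synergy scoring

Responses are inhibition fractions (1 − relative viability); a loader
converts viability CSVs. Values outside [−0.2, 1.2] abort with a
scale error; values slightly outside [0, 1] are clipped with a warning.
Replicates are averaged before scoring.

**Bliss.** delta_ij = 100·(observed_ij − (y_A + y_B − y_A·y_B)) from the raw
monotherapy fractions, over combination cells only (the monotherapy axes are
0 by construction and excluded from summaries).

**ZIP.** Monotherapies are fitted with four-parameter logistics bounded to
ymin ∈ [0, 0.3], ymax ∈ [0.7, 1], slope ∈ (0, 20], EC50 > 0 (nonlinear least
squares, tight tolerances; non-convergence falls back to monotonic
interpolation with a warning and a `converged=False` flag). For each
combination cell the response curve along each axis is re-fitted holding the
partner fixed — a potency-shift logistic whose baseline is the partner's
fitted effect — and the delta is the average of the two fitted values minus
the Bliss expectation of the fitted monotherapies. On data exactly
Bliss-independent in two logistic monotherapies the delta surface vanishes
to fitting precision (≲1e-9 on fractions). At least 4 non-zero doses per
axis are required.

**Most synergistic area.** Maximum mean over contiguous 3×3 windows of the
delta surface (the window size is a fixed convention); smaller surfaces use
the largest available window, and ties resolve to the first window in
row-major order. The guarantee most_synergistic_area ≥ synergy_score is
exact whenever the surface tiles into 3×3 blocks (both dimensions divisible
by 3 — true of the default 6×6 combination surface); for other shapes the
max-window mean can in principle drop below the global mean, so the
invariant is asserted on tiling shapes.

## Synthetic data

The generators define the study conditions for every test and are
deterministic given (config, seed).

* **Cohorts** — negative-binomial counts (var = μ + 0.1·μ², log-normal gene
  means with median ≈ 55), 20 case + 20 control samples, 5% of 1000 genes
  planted with a ±2 log2 mean shift (half up, half down). They emulate
  bulk RNA-seq depth and overdispersion but not library-size variation,
  batch effects or gene–gene correlation, so passing tests demonstrate the
  thresholding/FDR machinery, not robustness to real-data artefacts.
* **Perturbation panels** — 100 compounds × 3 cell lines × 3 experiments
  over the cohort's gene universe; profiles are latent mechanism vectors
  (150 genes at magnitude 2) plus per-cell-line offsets (sd 0.3) and
  per-experiment Gaussian noise (sd 0.5), mimicking level-4 robust z-scores.
  Three "reversers" take the opposite sign of the reference mechanism on its
  support and oppose the disease signature elsewhere (CR = 0, DR = 1 by
  construction at zero noise); five "mimics" copy the reference; the rest are
  random. Real perturbation data's dose/time structure is not modelled.
* **PPI graphs** — Barabási–Albert base (400 nodes, m = 3) for degree
  heterogeneity, so degree-matched null sampling is non-trivially exercised;
  a disease module of two 20-node sub-regions densified at p = 0.35 and
  cross-linked at p = 0.02 (configs where the cross probability reaches the
  within probability are rejected as merged). Distant target communities
  hang off the node farthest from the disease module via a 5-node path.
  Scenario placement: complementary = one drug per sub-region; overlapping =
  same sub-region with 50% shared targets; single/non = one/both drugs in
  distant communities.
* **Dose matrices** — 6 doses per drug (geometric, top dose 2×EC50) from
  sub-saturating Hill curves (Emax 0.8 and 0.75), combined under Bliss
  independence plus a planted uniform delta and multiplicative Gaussian
  noise (σ = 0.05), clipped to [0, 1]. Sub-saturation is deliberate: planted
  deltas up to ~0.15 stay below full inhibition, so recovery tests measure
  the scoring, not clipping artefacts.

## Pipeline

One YAML config drives the screen; defaults mirror the screen's standard
operating point (|log2FC| > 1, FDR < 0.1, min_fraction 0.5, correlation 0.7, 100
permutations, top_k 3, TPM 1.0, 3×3 window). Reports contain no timestamps
and all randomness descends from the single config seed through spawned seed
sequences, so identical config + seed reproduces byte-identical reports;
stage outputs (signature TSV, ranking TSV, delta surfaces, report JSON) are
sufficient to resume any downstream stage from disk. Exit codes: 0 success,
2 validation failure, 3 stage failure.

## Problem sizes

Test and acceptance runs use the generator defaults above (1000-gene
cohorts, 100-compound panels, 400-node graphs, 100 null permutations,
6×6 checkerboards), with 10–200 seeded replicates per statistical check —
sizes at which every planted structure is comfortably identifiable while
each check's oracle (closed form, brute-force enumeration, exhaustive
window scan, or Floyd–Warshall) stays exact.

## Known limitations

* The DE test is not a count model; gene lists on real RNA-seq will differ
  from negative-binomial-GLM pipelines.
* The ZIP implementation follows the reference algorithm's structure
  (potency-shift fits against the fitted-monotherapy Bliss expectation) but
  is an independent implementation; numerical agreement with other tools is
  expected only to fitting tolerance.
* Proximity z-scores depend on the null's binning convention; very small
  graphs (< ~20 nodes) collapse into a single degree bin, making the null
  effectively degree-free.
* The exposure taxonomy treats z and s as sharp thresholds at 0; no
  uncertainty is propagated into the category call.
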