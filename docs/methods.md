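# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the choices made where the design was genuinely open.

## Data model

A *section* is one Visium slide: spots on a hexagonally packed array
(array_row/array_col integer coordinates; centre-to-centre pitch 100 µm),
each carrying library-size-normalised, log1p-transformed expression and a
per-cell-type distribution probability from an upstream deconvolution
tool. Sections carry a condition (healthy or RPL) and a gestational age in
weeks. Two spatial domains partition each section: the implantation zone
(IZ) and the glandular-secretory zone (GZ); domain labels are an input
(spatial-domain inference is out of scope). Two spots are directly
adjacent iff their (row, col) offset is one of (0, ±2), (±1, ±1) — the
standard even/odd-offset hex neighbourhood with at most six neighbours;
when array coordinates are unavailable the fallback links spots within
1.2× the modal nearest-neighbour distance. Adjacency never crosses
sections. Expression normalisation scales each spot to the median spot
total before log1p; the target sum is configurable.

## Deconvolution post-processing

Normalised distribution probability: divide each type's probability by its
proportion in the single-cell reference, then renormalise the spot row to
sum to 1. Renormalisation makes rows comparable across conditions; the
operation is idempotent under a uniform reference. Rows that are entirely
zero are emitted as uniform with a warning rather than NaN.

Domain signatures: per gene, log2 FC of expm1 means inside vs outside the
domain (pseudocount 1e-9) and a two-sided Wilcoxon rank-sum P on the log
values (the conventional marker test; the asymptotic tie-corrected form,
since spot counts are in the hundreds). Defaults |log2 FC| ≥ 0.5 and raw
P < 1e-10; BH-adjusted values are reported alongside. A gene is assigned
only to the domain where its mean is highest, which also resolves ties
under permissive thresholds.

Condition contrasts use spot-level ANCOVA: OLS of value on an intercept,
an RPL indicator and gestational age, with the two-sided t-test P of the
indicator. Spots are the units and the covariate is attached per section;
a section-level aggregation can be had by passing per-section summaries to
the same function. A constant covariate falls back to a two-sample t-test
with a warning; a constant response returns P = 1.

## Colocalization

Per section, the Pearson correlation of every pair of cell-type
probability columns across spots, diagonal zeroed; zero-variance types get
zero rows with a warning. Sparsification keeps each type's k = 5 largest
*signed* coefficients (colocalization, not anti-colocalization; the
diagonal is never a candidate), retains all values tied at the k-th rank,
and keeps an entry if either of its two types retains it — the union rule
preserves symmetry, at most 2k survivors per row. Condition matrices are
entrywise means over that condition's sections, aligned by cell-type
label; the disease contrast is mean(RPL) − mean(healthy).

## Ligand–receptor screen

Smoothing averages each spot with its direct hex neighbours (a linear,
row-stochastic operator; isolated spots are fixed points). The screen
correlates smoothed ligand and receptor per section; P is the two-sided
t-approximation of the Pearson test (an exact permutation P is available
for small sections). A pair is spatially coexpressed when ρ ≥ 0 and
P < 0.05. Multi-subunit complexes reduce to the per-spot minimum of their
subunits (limiting-subunit semantics) before all steps. Condition-level
sets are unions over that condition's sections, a pair counted once.
Per-spot interaction score = smoothed ligand × smoothed receptor; a
coexpressed pair is assigned to the domain with the higher mean score.
Differential interaction between spot groups uses the rank-sum test on
scores with log2 FC of group means; defaults log2 FC ≥ 0.1 and P < 1e-5
(where two printed thresholds disagreed for this step, the Methods value
1e-5 is the default and both are exposed), BH adjustment across pairs.
Attribution: among ordered type pairs (a, b) with colocalization ≥ 0.1
(self-pairs count as colocalized), the argmax of reference mean ligand
expression in a × mean receptor expression in b, ties broken
lexicographically and logged; "unassigned" when nothing qualifies.

A calibration caveat: neighbour smoothing induces spatial autocorrelation,
so when two *independent* genes are smoothed and then screened, the
nominal P is anticonservative (measured flagged fraction ≈ 0.15 at
α = 0.05 on a 500-spot hex grid). The screen itself is calibrated for its
stated input: on independent pairs it flags ≈ 2.5–4% (the one-sided region
of the two-sided test). Interpreting screen hits therefore requires the
planted-power view (sensitivity ≈ 1.0 at realized ρ = 0.5, n = 1000) more
than the raw null rate of the composed smoothing+screen path.

## MIC

The maximal information coefficient is implemented from scratch following
the MINE characteristic-matrix construction: over all grids of i columns ×
j rows with i·j ≤ B(n) = n^α, maximise the mutual information of the
induced histogram over grid-line placements and normalise by
log min(i, j); MIC is the maximum entry over both axis orientations.
One axis is equipartitioned (ties never split); the other is optimised
exactly by a dynamic program over clumps — runs of points that provably
never benefit from an internal boundary — with at most c·i superclumps as
candidate boundaries. Defaults are the original α = 0.6, c = 15; B is
floored at 4 so the 2×2 grid is always admissible. The estimator depends
only on rank/tie structure, hence is exactly invariant under strictly
increasing transforms, and symmetric because both orientations are
searched. A brute-force reference (`mic_exhaustive`) enumerates *all*
column placements for tiny n; at n = 12 with no superclump truncation the
dynamic program agrees with it to machine precision.

Tracking-gene selection computes MIC(gene, subset probability) per
candidate, keeps MIC ≥ 0.9, clusters survivors by average-linkage
hierarchical clustering on 1 − Pearson correlation of spot profiles (2–6
clusters, chosen by silhouette), and retains clusters whose mean profile
correlates positively with the subset probability. The clustering method
and cluster-selection rule were unspecified upstream; this choice matches
the stated outcome (a positively correlated gene set) and is configurable.
At desk scale (hundreds of spots, negative-binomial counts) MIC of a
composition-driven gene rarely exceeds ~0.4, so the 0.9 threshold mainly
serves near-deterministic relationships; the MIC *ranking* is informative
regardless (dNK1 signature genes fill the top ranks on synthetic data).

## Spot projection and enriched spots

Projection is the probability-weighted sum Σ_t p[s,t]·a_t over a subset
list, no renormalisation — linear in the attribute, zero where the subsets
are absent. Raw (not reference-normalised) probabilities are the default,
with a flag to use normalised ones. A spot is enriched for a type when its
probability is ≥ the mean probability of that type and ≥ 0.1; the mean is
per section (sections are separate slides), falling back to the pooled
mean without a grid. Mapped cells are retained iff their spot is enriched
for their own subset.

## Trajectory permutation test

The upstream velocity tool's cell×cell transition matrix is summarised as
the mean outgoing transition mass from one subset onto another — a
transparent surrogate for graph-abstraction transition confidence that
preserves the quantity's meaning (directed group-to-group flow) and is the
statistic the permutation nulls. The test shuffles subset labels uniformly
(group sizes preserved), recomputes the statistic per shuffle, and reports
the add-one-smoothed one-sided empirical P, (1 + #{null ≥ obs})/(1 + n);
the hypothesis is directional (dNK2 → dNK1). A stack of posterior
transition matrices is supported by reporting median confidence and P.

## Synthetic generator

Defaults (the study conditions): 40×40 hex grid (1600 spots) per section,
three sections per condition, 12 subsets, 1200 genes, IZ as the upper 40%
row band. Per-spot compositions are Dirichlet draws with concentrations
base × domain enrichment × RPL effect; the disease effect (IZ only)
reduces dNK1 and dM2 concentrations to 40% and doubles CD8 T. Counts are
negative binomial (dispersion 10, ~5000 counts/spot) over
proportion-weighted subset profiles; signature genes are elevated e² in
their own subset with each subset's signature budget equalised so
background genes have identical relative expression everywhere — non-planted
catalog pairs are therefore null by construction. Planted LR pairs
multiply a shared smooth latent field (squared-exponential kernel, length
scale 3 spot pitches) into both genes in the host domain, with amplitude
calibrated from empirical smoothed variances so the realized smoothed
correlation targets the configured ρ (realized 0.6 ± 0.1 over seeds at
ρ* = 0.6). The RPL interaction effect scales both genes' log expression by
√0.5 in the disease host domain, halving the product score. Observed
probabilities add Dirichlet resampling noise (concentration 50) to the
true proportions to mimic deconvolution error. Transition matrices mix
(1−δ) uniform mass with δ concentrated on the target group for source-group
cells, with multiplicative gamma jitter (shape 5) and row renormalisation
so the δ = 0 null is exchangeable rather than degenerate; default δ = 0.3,
100 cells per dNK subset.

What the generator does *not* emulate: tissue morphology and image-derived
covariates, per-spot cell-count variation, spatially correlated
deconvolution error, batch effects between sections, multi-subunit
complexes in the planted catalog, and gene–gene correlation beyond
composition and the planted fields. Passing tests therefore demonstrate
correctness of the statistics under a controlled, somewhat idealised null
and signal structure — not performance on real tissue.

## Problem sizes and numerics

Benchmarks run at: MIC oracle n = 12 (50 instances; no superclump
truncation, so the dynamic program is exact); screen calibration 1000
pairs × 500 spots; screen power 100 seeds × 1000-spot sections with a
150-gene panel; permutation calibration 500 datasets × 200 shuffles (180
cells); ANCOVA n = 2000 with 500 null replicates; end-to-end 20 seeds at
full default scale. Pseudocounts: 1e-9 in fold changes; probability rows
compared to 1 at 1e-9; smoothing linearity and projection linearity hold
to 1e-12. Degenerate inputs (constant vectors, all-zero rows, empty gene
sets) warn and return the neutral value rather than raising, except where
a precondition is violated (empty groups, unknown ids), which raises.

The `analysis/` drivers are the command-line surface: each stage is a
numbered script over the library; `pipeline.run_all` executes all six
stages from one config and writes a JSON report whose contents are
bit-reproducible given (inputs, config, seed).
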