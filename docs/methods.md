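# Methods

## Splicing kinetics and the steady-state velocity model

Per gene, unspliced and spliced abundances follow du/dt = α − βu,
ds/dt = βu − γs with transcription rate α (molecules/unit time), splicing
rate β and degradation rate γ (both 1/unit time). The closed-form solution

    u(τ) = α/β + (u0 − α/β)e^(−βτ)
    s(τ) = s0·e^(−γτ) + (α/γ)(1 − e^(−γτ)) + ((α − β·u0)/(γ − β))(e^(−γτ) − e^(−βτ))

is used everywhere (clipped at 0 against floating-point underflow). The
case γ = β makes the last term singular; rather than switching to the
τ·e^(−βτ) limit formula, constructing such a gene program raises an
explicit error — the steady-state fit only identifies γ/β, so nothing is
lost by excluding the measure-zero degenerate case.

Only the ratio γ/β is identifiable from the steady-state relation
u* = (γ/β)s*, so the simulator normalises β = 1 and the fitted `gamma_hat`
is directly that ratio. The fit is least squares through the origin,
Σ(u·s)/Σ(s²), over the cells in the bottom or top `fit_quantile` of pooled
spliced expression (both tails: near-zero and saturated cells are the ones
plausibly near steady state). Ties at a quantile boundary are all included,
so membership does not depend on cell ordering. A gene whose extreme set
carries no spliced signal has an undefined slope and is dropped with a
record, as are genes with non-positive fitted slopes.

Defaults: `k_cells = 20` (pooling), `fit_quantile = 0.02`,
`spliced_average_min = 0.5` (gene filter on mean *pooled* spliced
expression; filtering runs after pooling), `delta_t = 1`, Malat1 excluded
(its dominant read pileup distorts fits in mouse brain data). Pooling
neighbours are found by Euclidean distance in the top-30 PCs of log1p
library-size-normalised spliced counts, and pooled profiles are means of
raw counts over the k nearest cells including self.

## Transition probabilities

Neighbour sets are built on the 2-D embedding (Euclidean, self excluded)
with n = max(`min_neighborhood` = 300, source-population size), capped at
n_cells − 1. cc[i,j] is the Pearson correlation across kept genes between
transform(current[:,j] − current[:,i]) and transform(deltaE[:,i]); the
transform is the elementwise signed square root (variance stabilisation;
`scale = "none"` disables it). Zero-variance correlations are set to 0.
tp rows are softmax(cc/σ) with σ = 0.05, computed with a per-row max shift;
each row sums to 1 to machine precision.

Per-cell fate mass m_i(P) sums tp[i,j] over neighbours j in population P;
the masses partition each row. Mass to the cell's own population is its
population-level self-renewal. An alternative reading — the mean
per-neighbour probability instead of the sum — is available via
`per_neighbor_mean`. Velocity and transition models are fitted per
condition; terminal populations outside the lineage of interest can be
excluded up front via `exclude_populations`.

Condition comparisons use a two-sided Wilcoxon rank-sum test on the
per-cell masses of each (source, target) pair. Ranks use midranks; exact
mode computes the full null distribution of the rank sum by a subset-count
dynamic programme over doubled ranks (exact under ties too; two-sided p =
P(|T − E[T]| ≥ |t_obs − E[T]|)), used automatically when n_x + n_y ≤ 20;
above that a normal approximation with tie correction and a 0.5 continuity
correction is used. Raw p-values are the primary readout; a
Benjamini–Hochberg column is emitted for transparency. Pairs with fewer
than `min_cells = 2` source cells in either condition are flagged
not-comparable rather than raised.

## Composition enrichment

Under the null that a cluster's abundance is condition-independent, its
TBI cell count is Binomial(n, p0) with p0 the TBI share of all analysed
cells (computed over the full cell set entering the clustering being
tested). The two-sided p is the minimum-likelihood exact value (sum of
P(X = k′) over k′ with P(X = k′) ≤ P(X = k)), delegated to
`scipy.stats.binomtest`, which implements the same convention as R's
`binom.test`; an exhaustive-enumeration oracle verifies it in the tests.
No multiple-testing correction is applied to these panels. Gene-set
utilities report percentage overlap (100·|A∩B|/|A|), pairwise common-gene
counts (input to standard agglomerative clustering, typically cut at
k = 3), and case-insensitive substring keyword filtering of GO/KEGG term
tables. Substring matching is deliberately coarse: the keyword "Genesis"
catches every *genesis* compound, including non-neural terms such as
"ribosome biogenesis" — acceptable for a screening sort, not a precise
ontology query.

## Spatial zones

Geometry is abstracted to a signed 1-D offset d in nucleus-width units from
the granule-cell-layer/hilus boundary (positive toward the molecular
layer), with local GCL thickness T ∈ [4, 8] (validated T ≥ 4). Bands are
left-closed/right-open: Hilus d < −2; SGZ −2 ≤ d < 0; GL1 0 ≤ d < T−3;
GL2 T−3 ≤ d < T; ML d ≥ T. The half-open convention fixes boundary
ownership (d = 0 belongs to GL1) and makes assignment a total function.
Zone percentages are computed per (animal, population) and partition to
100 over the five zones; a pooled GL1+2 row is reported alongside.
Conditions are compared per (population, zone) with a two-tailed unpaired
pooled-variance t-test on per-animal percentages (Welch behind a flag;
animals, not cells, are the experimental unit here). Zero-variance
degenerate inputs return p = 1 (equal means) or a logged p = 0.

## What the generator emulates — and what it does not

The simulator draws, per condition, cells along a trunk
(NSC-stage1 → NSC-stage2 → RG-like) that splits into neuronal
(N-stage1 → N-stage2) and astrocytic (A-stage1 → A-stage2) arms. Each cell
takes the neuronal arm with the condition's fate bias (Bernoulli draw,
defaults 0.5 Control / 0.75 TBI), lands uniformly in one segment of its
path and uniformly in latent time within it (`segment_duration` = 3 time
units at β = 1). Gene programs switch α at segment boundaries with (u, s)
carried continuously across, producing the induction/repression transients
the quantile fit needs; 70% of genes peak in one random segment (8× over a
0.4× baseline), the rest are constitutive, γ log-uniform on [0.1, 2]. An
optional high-expression constitutive "Malat1" gene exercises the
conventional exclusion. Counts are Poisson on kinetic means scaled by a
per-cell LogNormal(0, 0.3²) capture efficiency and globally rescaled to
~3000 spliced counts/cell (negative-binomial optional); the embedding is
the first two PCs of log1p spliced counts (PCA, not UMAP, for bit-exact
reproducibility). Default sizes follow a targeted recovery of 6000 cells
per condition with 5/6 animals (round-robin); tests and the acceptance
script run scaled-down instances (150–1000 cells, 40–100 genes) chosen so
the full suite completes in minutes while every population still exceeds
its neighbourhood floor.

For γ-recovery studies, `simulate_cycle` drives genes through one full
induction–repression cycle with a per-phase duration of 40 time units —
at least 4/γ for the slowest gene (γ = 0.1) — so late-induction cells
genuinely approach the steady state the extreme-quantile estimator assumes.

The spatial generator places populations by Normal(mean, sd) offsets per
condition (defaults: N-stage3 displaced from SGZ into the granule layer
and A-stage1 from SGZ toward the hilus under TBI, 4 Control / 5 TBI
animals, one GCL thickness per animal drawn uniformly from [4, 8]).

Not emulated: ambient RNA, doublets, batch effects, cell-cycle structure,
QC-discarded cells, animal-level biological variability in expression, and
2-D tissue geometry (an adapter computing signed offsets from coordinates
and boundary polylines can feed the same zone machinery). Passing tests on
this generator therefore demonstrate the pipeline's internal correctness
and its sensitivity to fate-bias and location shifts of realistic size —
not robustness to every artefact of real droplet data.

## Known limitations

- **The per-cell condition comparison is anticonservative.** All cells of
  a condition share one realised dataset and one fitted model (embedding
  geometry, pooling, γ estimates, realised branch abundances), so their
  fate masses are not independent draws: realisation-level noise shifts
  every cell of a condition coherently. Measured on identical-parameter
  conditions across 100 simulations, roughly half of all (source, target)
  pairs reach p < 0.05 — far above nominal — and the inflation does not
  shrink with dataset size, because the condition-level offset and the
  test's standard error both scale as 1/√N. This mirrors how such per-cell
  tests are conventionally reported in the field; treat the Wilcoxon
  p-values as descriptive rankings, not calibrated error rates. A
  calibrated alternative needs condition-level replication (e.g. animals
  as units), at the cost of power at small animal numbers.
- The γ fit assumes extreme-expression cells are at steady state; genes
  observed only mid-transient are biased.
- The max(300, population size) neighbourhood rule makes neighbourhoods
  near-global on datasets not much larger than 300 cells per condition,
  blurring locality.
- Exact Wilcoxon cost grows with the squared total rank sum; above ~60
  observations the normal approximation is the practical mode.
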