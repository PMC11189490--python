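# dgfate

Steady-state RNA velocity, fate-transition statistics and spatial zone
analysis for branching neural-stem-cell (NSC) lineages — with a seeded
synthetic-data generator so the whole pipeline is testable end to end
without any downloads.

## The scientific problem

Adult hippocampal neurogenesis arises from NSCs in the subgranular zone
(SGZ) of the dentate gyrus (DG). These stem cells pass through a radial
glia-like (RG-like) bipotent state that feeds both a neuronal (N-stage) and
an astrocytic (A-stage) lineage. An insult such as traumatic brain injury
(TBI) can tilt this fate decision. Quantifying such a shift from single-cell
RNA-seq requires three kinds of machinery, all implemented here:

1. **Steady-state RNA velocity.** Per gene, unspliced (u) and spliced (s)
   transcript abundances follow

       du/dt = α − βu,        ds/dt = βu − γs,

   so cells at steady state satisfy u = (γ/β)·s. With β normalised to 1,
   γ is fitted per gene as the origin-constrained least-squares slope of u
   on s over the cells at extreme (bottom/top quantile, `fit.quantile =
   0.02`) pooled spliced expression (`kCells = 20` nearest-neighbour
   pooling, genes kept at mean pooled spliced ≥ 0.5, Malat1 excluded).
   The residual v = u − γs is the velocity; `current` (pooled s) and
   `deltaE` (Δt·v) matrices feed the next step.

2. **Embedding transition probabilities.** For each cell i and each of its
   n nearest embedding neighbours j (n = max(300, |source population|)),
   cc[i,j] is the Pearson correlation across genes between the expression
   displacement toward j and the cell's own predicted change (after a
   signed-sqrt variance-stabilising transform), and
   tp[i,j] = softmax_j(cc[i,j]/σ) with σ = 0.05 is a row-stochastic
   transition matrix. Summing tp row mass over neighbours of each target
   population gives per-cell fate masses; Control vs TBI distributions are
   compared with a two-sided Wilcoxon rank-sum test (exact below a
   configurable sample size, tie- and continuity-corrected normal
   approximation above it). Velocity and transition models are fitted per
   condition.

3. **Composition and location statistics.** Cluster abundance shifts are
   scored with an exact two-sided binomial test of the TBI cell count
   against the TBI share p0 of the whole cell set (minimum-likelihood
   two-sidedness, the `binom.test` convention). Spatial shifts use a 1-D
   DG coordinate in nucleus widths: Hilus (d < −2), SGZ (−2 ≤ d < 0, the
   two-nucleus band below the granule cell layer), GL1, GL2 (the
   three-nucleus band below the molecular layer) and ML, with per-animal
   zone percentages compared by a two-tailed unpaired t-test.

The synthetic generator simulates the branching lineage with per-gene
(α per segment, β, γ) kinetics solved analytically, a condition-dependent
neuronal fate bias, Poisson counts with per-cell capture efficiency, a
deterministic PCA embedding, and a layered DG spatial layout.

## Worked example

```python
import pandas as pd
from dgfate import *

lineage = LineageSpec(
    cells_per_condition={"Control": 500, "TBI": 500},
    fate_bias_by_condition={"Control": 0.5, "TBI": 0.75},
)
programs = default_gene_programs(lineage, n_genes=100, seed=1)
dataset = simulate_dataset(lineage, programs, seed=1)

summaries = []
for cond in ("Control", "TBI"):
    sub = dataset.subset_condition(cond)
    vel = estimate_velocity(sub, VelocityConfig())   # kCells=20, fit.quantile=0.02
    summaries.append(population_transition_summary(
        sub.embedding, sub.cell_meta["population"].to_numpy(),
        vel.current, vel.delta_e, condition=cond,
        config=TransitionConfig(sigma=0.05, min_neighborhood=300),
    ))
result = compare_conditions(pd.concat(summaries, ignore_index=True))
rg = result[(result.source == "RG-like")
            & result.target.isin(["N-stage1", "A-stage1", "RG-like"])]
print(rg[["source", "target", "median_Control", "median_TBI", "p_value"]]
      .round(4).to_string(index=False))
```

prints

```
 source   target  median_Control  median_TBI  p_value
RG-like A-stage1          0.1761      0.0818   0.0000
RG-like N-stage1          0.1223      0.2864   0.0000
RG-like  RG-like          0.6882      0.6150   0.1705
```

Read: raising the simulated neuronal fate bias from 0.5 (Control) to 0.75
(TBI) roughly doubles the median transition mass of RG-like cells toward
the first neuronal population and halves the mass toward the first
astrocytic population (both Wilcoxon p < 1e-6), while population-level
self-renewal (RG-like → RG-like mass) is not significantly changed — the
in-silico analogue of an injury-induced pro-neurogenic fate shift.

The same analysis is available as a CLI over an on-disk layout
(MatrixMarket counts + TSV metadata):

```sh
dgfate run-all --outdir runs/demo --seed 1
dgfate validate runs/demo/data
```

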