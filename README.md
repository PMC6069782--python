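# mdnorm

Joint normalization and differential analysis of paired Hi-C contact
matrices.

## The problem

A Hi-C experiment yields, per chromosome, a symmetric matrix of interaction
frequencies (IFs) between genomic bins of size *X* (the resolution).
Comparing two Hi-C datasets — tumor vs. normal, two cell types, two
replicates from different labs — is confounded by *between-dataset* biases:
differences in sequencing depth, restriction enzyme, library preparation and
processing that shift and warp one matrix relative to the other. Methods
that normalize each matrix *individually* (ICE, KR, SCN, ...) do not remove
these joint biases, so bias gets mistaken for biology.

`mdnorm` is for anyone comparing two processed Hi-C matrices who needs the
differences they call to survive that confounding.

## The method

Every interacting bin pair in both datasets becomes a point on the **MD
plot**:

- *M* = log2(IF2 / IF1), the log difference between the datasets,
- *D* = distance between the two bins in units of the resolution
  (the off-diagonal index of the contact matrix),
- *A* = (IF1 + IF2) / 2, the pair's average expression.

Because the vast majority of chromatin interactions are stable between
conditions, any systematic trend of M as a function of D is bias, not
biology. A locally weighted polynomial regression (loess, tricube weights,
local degree-1 fit by default) of M on D estimates that trend *f(D)*, and
both datasets are rescaled symmetrically:

```
log2(IF1') = log2(IF1) + f(D)/2
log2(IF2') = log2(IF2) - f(D)/2
```

This centers M at zero at every distance while conserving each pair's
geometric mean (log2 IF1' + log2 IF2' = log2 IF1 + log2 IF2). Normalized
IFs below one are dropped.

Differences are then detected per chromosome by standardizing M:
Z_i = (M_i − M̄)/σ_M, where M̄ and σ_M are computed after discarding
low-support pairs (A below a user threshold, default 15; those pairs get
Z = 0 and are not tested). Two-sided normal p-values are corrected for
multiple testing within each distance stratum (Benjamini–Hochberg by
default; per-chromosome, Holm, Bonferroni and no correction available), and
pairs with adjusted p below α are called differential.

The package also ships:

- a **synthetic-data generator** (power-law distance decay, negative
  binomial counts, injectable distance-dependent bias, optional A/B
  checkerboard structure) so everything is testable without downloads;
- a **controlled-difference benchmark**: sample bin pairs, set both IFs to
  their replicate average, multiply one side by a known fold change, and
  score detection with the Matthews correlation coefficient (MCC);
- **A/B compartment** detection (observed/expected → correlation matrix →
  first principal component) and three similarity metrics showing that
  joint normalization preserves compartments.

## Worked example

```python
import numpy as np
from mdnorm import (SimulationParams, simulate_replicate_pair, join_pair,
                    fit_trend, LoessJointNormalizer,
                    DifferentialInteractionTest, default_bias_library)

# two synthetic replicates with a smooth distance-dependent bias between them
bias = default_bias_library()["linear_in_logD"]()
t1, t2, truth = simulate_replicate_pair(
    SimulationParams(n_bins=250, seed=1, bias_fn=bias))

joint = join_pair(t1, t2)                       # MD-plane records
norm = LoessJointNormalizer(span=0.2).fit_transform(joint)
test = DifferentialInteractionTest(a_min=15, alpha=0.05).fit(norm)

print(f"joined pairs:        {len(joint)}")
print(f"after normalization: {len(norm)}")
print(f"sigma_M:             {test.stats_.sigma_M:.3f}")
print(f"called differences:  {len(test.predict())}")
print(f"max |f| before:      {np.abs(fit_trend(joint, span=0.2).fitted).max():.3f}")
print(f"max |f| after:       {np.abs(fit_trend(norm, span=0.2).fitted).max():.3f}")
```

prints

```
joined pairs:        28282
after normalization: 28282
sigma_M:             0.267
called differences:  16
max |f| before:      0.741
max |f| after:       0.011
```

The injected bias trend (up to 0.74 on the log2 scale) is removed to ~0.01
by the joint normalization; the 16 calls among 28k tested pairs on
replicate data with no true differences reflect the 5% FDR operating on a
slightly heavy-tailed count ratio.

`LoessJointNormalizer` and `DifferentialInteractionTest` are
scikit-learn-style estimators (`get_params`/`set_params`, fitted attributes
`trend_`, `stats_`, `results_`); the module-level functions (`fit_trend`,
`apply_joint_normalization`, `compute_zscores`, `adjust_pvalues`, ...) are
the underlying building blocks.

## Command line

```sh
mdnorm simulate  --n-bins 250 --bias linear_in_logD --seed 1 --out-dir sim
mdnorm normalize sim/sim1.triplet3.tsv sim/sim2.triplet3.tsv \
    --resolution 1000000 --chrom chrS --span auto --out-dir norm
mdnorm compare   sim/sim1.triplet3.tsv sim/sim2.triplet3.tsv \
    --resolution 1000000 --chrom chrS --a-min 15 --alpha 0.05 --out-dir cmp
mdnorm benchmark sim/sim1.triplet3.tsv sim/sim2.triplet3.tsv \
    --resolution 1000000 --chrom chrS --n-changes 200 --fold-changes 2,3,4 \
    --out-dir bench
mdnorm compartments sim/sim1.triplet3.tsv sim/sim2.triplet3.tsv \
    --resolution 1000000 --chrom chrS --out-dir comp
```

Inputs are sparse upper-triangular text matrices (3-column
`start1 start2 IF` triplets, or 7-column BEDPE-like with chromosome names);
an optional BED file of CNV/blacklist regions can be excluded with
`--exclude`. Multi-chromosome BEDPE inputs are processed independently per
chromosome, optionally in parallel (`--n-workers`); results are identical
regardless of worker count. All outputs are TSV with headers.

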