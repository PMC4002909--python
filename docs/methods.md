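# Methods

## Model and training procedure

`pathsom` trains a rectangular self-organizing map by online competitive
learning. Patterns are presented one at a time in a seeded random order
that is reshuffled every epoch; the best-matching unit (BMU) is the unit
minimizing the combined distance

    d_lm = (1 - alpha) * eps_lm + alpha * b_lm,

with `eps_lm` the Euclidean distance to the prototype and `b_lm` the
biological term defined below. The BMU and every unit within a square
(Chebyshev) neighborhood of the current radius are moved toward the
pattern by the current learning rate (a rectangular kernel: all units in
the ball receive the full rate). BMU ties are broken toward the lowest
unit index (row-major).

Schedules:

- **Neighborhood radius** starts at `round(max(rows, cols) / 4)`
  (round half up — "a quarter of the map size" does not define a
  rounding, so one was fixed) and shrinks linearly to 0 at the final
  epoch.
- **Learning rate** decays linearly from 0.5 to 0.01 over the epochs.
  Only monotone decay matters for convergence of this family of
  algorithms; the linear form is the simplest that satisfies it.
- **Epochs** default to 200, enough for the toy problems here to reach a
  stable quantization error an order of magnitude below the data spread.

After the last epoch, every pattern is assigned by minimum combined
distance to the trained prototypes (ties to the lowest unit index),
using the final membership snapshot for the biological term. A flag on
`SOMResults.project` switches the final projection to Euclidean-only.

## The biological term

Pathway knowledge enters through a symmetric connectivity matrix `rho`,
`rho_ij` = number of metabolic pathways (KEGG-style annotations) in
which patterns `i` and `j` both participate, computed by counting
pathway-set intersections from a long-format annotation table. The
diagonal stores each pattern's own pathway count but is never consumed:
every formula iterates over `i != j`. Unannotated patterns keep all-zero
rows rather than being excluded — in real integrated datasets only a
small fraction of genes (roughly a tenth) map to metabolic pathways, and
they must still be clustered.

For a candidate pattern `l` and a cluster with member set `Omega`:

    pi_out = mean of rho_ij over unordered pairs within Omega \ {l}
    pi_in  = mean of rho_ij over unordered pairs within Omega U {l}
    b_lm   = (pi_out - pi_in) / max(pi_out, pi_in)

Means over fewer than two members are 0, and `b = 0` when both averages
vanish (the 0/0 convention; in particular, empty clusters and clusters
of only unannotated patterns are neutral, so unannotated patterns are
effectively placed by the Euclidean term alone). `b` is bounded in
[-1, 1] by construction; `b = -1` is maximal attraction (e.g. a
singleton cluster fully connected to the candidate). The "average
number of connections" is taken as the unordered-pair mean; a
per-member-sum convention would change the values but not the sign
structure on block-structured connectivity.

**Membership bookkeeping.** The member sets used by `b` are refreshed
once per epoch by default: all `b` values within an epoch use the
previous epoch's assignments, which makes results independent of
presentation order within the epoch, and the first epoch is
Euclidean-only because no memberships exist yet. An
`membership_refresh="online"` option instead moves each pattern's
membership to its BMU immediately at presentation time (still
deterministic given the seed, since the presentation order is seeded).
At `alpha = 0` the biological machinery is skipped entirely and training
is bit-identical to a standard Euclidean SOM — this reduction is tested
exactly, not approximately.

Training keeps per-epoch work vectorized: with the snapshot fixed, the
whole `patterns x units` matrix of `b` values is computed in one pass
from cluster aggregates (`O(n^2 k)` dense algebra), and the sequential
presentation loop is a compiled (numba) kernel. The compiled path is
tested for exact agreement with the pure-Python reference functions.

## Validation measures

For a partition with `k` non-empty clusters (centroids are always the
SOM prototypes `w_m`, never recomputed member means):

- **Compactness** `C` = mean over clusters of the mean member-to-
  prototype distance (0 is best).
- **Separation** `S` = `2/(k^2-k) * sum_{i<j} ||w_i - w_j||` (higher is
  better).
- **Davies-Bouldin** `DB` = `(1/k) sum_i max_{j!=i} (C_i + C_j) /
  ||w_i - w_j||`; undefined (error) for coincident centroids.
- **Dunn** `D` = minimum single-linkage inter-cluster distance divided
  by the maximum cluster diameter — the textbook form. Descriptions of
  Dunn via "distance to the global centroid" exist in the applied
  literature but do not match the standard index; the standard form is
  implemented.
- **Biological internal connectivity**
  `P = -log10((1/k') sum_m p_m / p_m*)`, where
  `p_m = 1 + sum over ordered in-cluster pairs of rho_ij` and
  `p_m* = 1 + sum over members i of rho_ij to every other pattern j in
  the dataset`. Both sums count ordered pairs, so their ratio matches
  the unordered convention. Only non-empty clusters containing at least
  one connected pattern enter the average (`k'`); if there are none
  (i.e. `rho` is entirely zero) every ratio is trivially 1 and `P = 0`.
  Each ratio is at most 1 term-by-term, so `P >= 0`, with 0 meaning
  every cluster already contains all the connections its members have.
  The log base (default 10) is configurable.
- **GMLC** `G` = `H_flat + (-Gamma) + P`: `H_flat = 1 - H/H_max` is the
  normalized Shannon entropy shortfall of the cluster-occupancy
  distribution (0 = perfectly flat; defined as 0 for a single cluster),
  and `Gamma` is the mean Pearson correlation between member profiles
  and their cluster prototype (sign-inverted in the sum; correlations
  against constant vectors contribute 0). Each component sits behind its
  own function so any one can be corrected or re-based independently,
  and `G` is exactly their sum.

## Resampling significance

To compare training configurations, the package repeatedly (default
100x) draws a seeded subsample (default 90% of patterns, without
replacement), trains every configuration on the same subsample with a
fresh seed per (resample, configuration), records each partition's `P`,
and runs a one-way ANOVA across configurations. Seeds for duplicated
configurations are independent, so under the null the samples are iid
draws from the same distribution; the all-constant edge case (possible
on tiny symmetric problems) is reported as `p = 1`. The procedure's
null calibration is verified empirically: over 100 repetitions of a
duplicated-configuration comparison the rejection rate at the 5% level
is approximately nominal.

## Synthetic data

`make_toy` emulates a two-structure benchmark: four Gaussian clouds of
100 points in 2-D (means on a square of side 4, sd 0.5 — separated by
~8 sd, so Euclidean clustering at 4 units recovers them essentially
perfectly), with pathway links placed to *disagree* with geometry. From
each cloud the 20 points most extreme along the outward direction (the
largest projection of `point - global centroid` onto the unit vector
from the global centroid to the cloud mean) are split, in extremity
order, among four cross-cloud connectivity sets; each set therefore has
5 members in every cloud, 20 in all. Within a set every pair shares
`link_strength = 3` pathways (realized as an explicit annotation table,
three pathways per set, so the generator exercises the same loader path
as user data); everything else shares none. The counts 5 and 3 are the
package's chosen instance of this design — small enough that linked
points are genuine outliers of their cloud, with a shared-pathway count
deep enough to register as strong connections.

`make_annotated_mixture` produces a Gaussian-mixture expression matrix
in which an exact fraction of patterns carries 1-3 random pathway
memberships, emulating the sparse-annotation situation of real
integrated datasets and exercising the unannotated-pattern paths.

What the toy does *not* emulate: real transcript/metabolite profiles
are high-dimensional, noisy, and have dense, graded pathway overlap
(most pattern pairs share at least one pathway), whereas the toy's
connectivity is sparse (99% of pairs share nothing) and binary at the
set level. Passing toy tests therefore demonstrates the mechanics —
reduction at `alpha = 0`, attraction of linked patterns, the direction
of the compactness/connectivity trade-off — not performance on real
data.

## Behavior across the alpha range, and a known regime

Raising `alpha` trades Euclidean quality for biological connectivity:
compactness and Davies-Bouldin worsen monotonically while `P` improves
— this is the intended behavior and holds cleanly in the densely
annotated regime (e.g. a fully annotated 70-pattern metabolite-scale
dataset on a 6x6 map, where mean `P` over 20 seeds decreases strictly
from `alpha = 0` through `0.75`).

On the *sparse* toy connectivity, however, the improvement in `P` is
not monotone all the way: it holds through `alpha = 0.5` but can invert
slightly at `alpha = 0.75` on maps much larger than the number of
connectivity sets. The mechanism is documented rather than hidden: the
average-based `b` gives 0 for staying in an already-pure cluster — the
same score as an empty cluster — and scores a foreign cluster of
identical composition slightly better than the pattern's own (the pair
counts differ by one member), so once the Euclidean anchor is weak,
linked patterns keep migrating between equivalent hosts (~17% of
assignments still change per epoch at the end of training) and the
final partition samples a churning state. At `alpha = 1.0` on a map
with as many units as connectivity sets the sets are never split, which
is the property the toy was designed to show. Users applying large
`alpha` to sparsely annotated data should expect this regime; the
`membership_refresh="online"` option changes the micro-dynamics but not
the phenomenon.

## Numerical conventions and degenerate inputs

- Exact reproducibility: identical (data, connectivity, config, seed)
  gives bit-identical weights and partitions; all randomness flows from
  a single `numpy` generator per fit.
- Weight initialization: seeded uniform within each dimension's data
  range (default) or a deterministic grid spanning the first two
  principal components (`init_scheme="pca-grid"`).
- The two distance terms are combined on their native scales, exactly as
  the weighted sum is written (`eps` is unbounded, `b` in [-1, 1]); a
  `rescale_epsilon` flag divides `eps` by the dataset's maximum pairwise
  distance for users who want both terms on a comparable scale. It is
  off by default and is a documented deviation aid, not part of the
  model.
- NaNs in expression data are rejected at load time (a `dropna` loader
  option removes incomplete rows); duplicate pattern IDs are rejected;
  pattern IDs are matched exactly and case-sensitively between
  expression, annotation and connectivity inputs to avoid silent
  mis-joins.
- Degenerate metric inputs raise errors rather than returning sentinel
  values: separation/DB/Dunn require at least two non-empty clusters,
  DB requires distinct centroids, Dunn a nonzero maximum diameter.
- Single-pattern connectivity matrices are flagged degenerate in
  `rho_summary` (no off-diagonal entries exist).

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated
data: the 400-point toy set (20 training seeds per condition), a
120-point scaled-down toy for the repeated null-calibration of the
resampling ANOVA (100 repetitions of 50 resamples at 4x4/60 epochs),
and a 70-pattern fully annotated mixture for the dense-annotation
comparison. These sizes were chosen so the complete battery re-runs
from scratch in a few minutes on one CPU while keeping every
qualitative conclusion stable across seeds.

## Known limitations

- Rectangular grids with square neighborhoods only; no toroidal or
  hexagonal topology, no batch-SOM variant, no growing maps.
- Map size is user-set configuration (6x6 and 10x10 are the documented
  reference scales); no automatic cluster-number selection.
- Pathway annotations are consumed as a pre-extracted two-column table;
  no live KEGG retrieval or KGML parsing. All pathway kinds (ortholog
  `ko...` and global `map...` identifiers) count equally in `rho`.
- The flatness and coherence components of `G` are one reasonable
  realization of "occupancy flatness" and "profile coherence"; they are
  deliberately isolated behind single functions so alternative
  definitions can be swapped in.
- GO-based homogeneity scoring and gene-set enrichment are out of
  scope.
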