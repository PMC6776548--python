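# Methods

## Problem and model

Given a panel of cancer cell lines screened against two drugs A and B,
each cell line *i* carries a length-4 dose-response profile (DRP)
`X_i = (logIC50_A, AUC_A, logIC50_B, AUC_B)`.  The goal is to partition
the cohort into subpopulations with homogeneous joint response, nominate
binary genomic biomarkers enriched in each subpopulation, and classify
the drug pair by how its subpopulations distribute over sensitivity
quadrants — in particular to flag *divergent* pairs (disjoint
subpopulations sensitive to one drug or the other but not both), the
pattern of interest for combination therapy.

log(IC50) inputs are treated as already log-transformed (µM scale) and
are never exponentiated, so the log base is effectively a labelling
choice.  AUC is the area under the fitted dose-response curve in [0, 1].

### Similarity network

All DRP columns are z-scored once over the full cohort (sample sd,
ddof = 1) before any distance is computed.  AUC lives in [0, 1] while
log(IC50) spans several units; without a declared scaling, Euclidean-type
comparisons (and the silhouette gate below) would be dominated by IC50.
Constant columns are mapped to 0 with their sd recorded as 0; recorded
means/sds let every subpopulation summary be reported on the original
measurement scale.

The cohort is modelled as a complete weighted graph.  For an ordered
pair (i, j):

    delta_ij(a)   = X_i(a) - X_j(a)                       (signed)
    g_i(a)        = mean over k != i of delta_ik(a)       (complete-graph
                                                           neighbourhood mean)
    t(a)          = delta_ij(a) + g_i(a) + g_j(a)
    Sigma_ij      = t t' / 9                              (rank <= 1, PSD)
    d(i, j)       = (delta_ij' pinv(Sigma_ij) delta_ij)^beta,   beta = 0.5
    w(i, j)       = exp(-d)                               in (0, 1]

Because `Sigma` has rank at most one, its Moore-Penrose pseudo-inverse is
`9 t t' / ||t||^4`, giving the closed form
`d = (9 (t . delta)^2 / ||t||^4)^beta` (and `d = 0` when `t = 0`: the
pseudo-inverse of the zero matrix is zero).  A generic SVD pseudo-inverse
code path is retained purely as a numerical cross-check; the two routes
agree to < 1e-13 on random cohorts.

Two structural facts about this measure shape everything downstream.
First, `t` is orientation-dependent (swapping i and j does not flip its
sign), so W is computed once per unordered pair with the
`(min(i, j), max(i, j))` orientation and mirrored; W is therefore exactly
symmetric by construction.  Second, with standardized columns
`g_i = N/(N-1) (X_i - mean X)`, so `t ≈ 2 (X_i - mean X)` regardless of
j: the quadratic form compares the projection of `X_j` onto the direction
of `X_i`'s deviation from the cohort centroid with `||X_i||`.  The
measure is thus largely *radial*: profiles at the same depth along
nearby directions look similar even when they differ strongly on an
orthogonal axis.  This is a property of the model, not of the
implementation; the synthetic presets (below) are designed with it in
mind.

Numerical guards: `||t|| < 1e-12` is treated as `t = 0`; `d` is capped at
700 before exponentiation so `w` never underflows out of (0, 1].  An
`absolute` option averages |delta| in the neighbourhood means instead of
signed delta; it is exposed but not the default — signed means make
`g_i` the centrality statistic above, while absolute values would break
the covariance analogy.

### Recursive spectral segmentation

Nodes are bisected along the Fiedler vector — the eigenvector of the
second-smallest eigenvalue of the graph Laplacian `L = D - W` on the
node's induced submatrix of the *global* W (the network and its
neighbourhood statistics are computed once; a per-node recomputation mode
exists behind `recompute_network`).  The unnormalized Laplacian is the
default; `L_sym` is available via `laplacian_variant="normalized"`.  The
vector is oriented so its first entry above 1e-12 in absolute value is
positive, entries within 1e-12 of zero go to the positive side, and a
one-signed vector (degenerate near-disconnected case) falls back to a
median split — together these make the recursion fully deterministic.

A proposed split is accepted only if (1) the parent has >= 40 members,
(2) both children have >= 20, and (3) the mean two-cluster silhouette of
the children is >= 0.25.  Violations terminate the node as a leaf with
the reason recorded.  The silhouette is computed in the globally
standardized 4-D DRP space with Euclidean distances (singletons
contribute 0); a `1 - w` network-distance variant is available but
non-default, because the silhouette must be comparable across nodes of
different sizes while w embeds pair-specific Sigma weighting.  The
defaults 40 / 20 / 0.25 are the configuration under which all shipped
results are computed.

Consequences worth knowing: a rejected split terminates the node even
when a better split exists (in particular, a split that would isolate a
tiny outlier group freezes the node), and symmetric cluster layouts can
produce degenerate Fiedler vectors whose zero crossing bisects a middle
cluster.  Both behaviours are inherent to the stated recursion.

### Biomarker enrichment

For every subpopulation (leaves by default, all nodes optionally) and
every binary feature, a 2x2 table counts cell lines inside/outside the
subpopulation with/without the feature; cell lines absent from the BEM
are excluded from all cells.  Significance is the one-sided (greater)
Fisher exact test, computed as the hypergeometric upper tail
`P[X >= in_mut]` — the two descriptions are the same test.  P-values are
BH-adjusted per subpopulation across features (each subpopulation is its
own biomarker-nomination question; a pooled family is available).
Features with fewer than 3 positive cell lines cohort-wide are skipped
as untestable.  Tissue and pathway-activity flags ride through the same
machinery as extra BEM columns.

### Drug-pair classification

The 20th percentile (linear interpolation between closest ranks) of each
drug's log(IC50) over all cell lines defines the cutoffs P20_A and
P20_B.  A subpopulation with mean log(IC50) pair (y_A, y_B) is
`both_sensitive` if y_A < P20_A and y_B < P20_B, `a_only` if only the
first holds, `b_only` if only the second, else `resistant` (ties land on
the resistant side, matching the >= rule).  For each quadrant, the count
of leaves is compared against the expected proportion — the empirical
fraction of *individual* cell lines in that quadrant under the same
cutoffs, i.e. the distribution had no segmentation been performed — with
a one-sided (greater) exact binomial test at alpha = 0.05.  The pair's
response type follows the precedence both_sensitive > divergent
(A-only and B-only both significant) > single-preferential > none;
conflicts are flagged ambiguous and logged.

Two summaries accompany the classification: the size-weighted mean
within-leaf Pearson correlation of the two log(IC50)s (leaves with < 3
members or a constant column are skipped and weights renormalized), and,
across a grid of pairs, a hypergeometric upper-tail test of whether a
drug's pairs are over-represented in a response type.

## Synthetic cohorts

The generator emulates a GDSC-like screen: several hundred to ~1500 cell
lines, Gaussian per-cluster response profiles with AUC clipped to [0, 1]
(clipping, not truncated sampling, for simplicity; clips are logged), and
a sparse binary event matrix whose planted markers are Bernoulli(0.8)
inside their cluster and Bernoulli(0.05) — the sparse somatic background
rate — elsewhere.  Everything is reproducible from a single integer seed.

Five preset scenarios produce the five response archetypes by
construction.  Their geometry is deliberate, informed by the radial
character of the similarity and by the termination gates:

- cluster positions are staggered and asymmetric (regular grids create
  degenerate Fiedler spectra), and clusters sharing a quadrant direction
  differ in depth;
- the total sensitive mass per drug is exactly 20% of the cohort, so the
  percentile cutoff falls in the empty gap between the sensitive and
  resistant blocks and every planted cluster lands cleanly in its
  designed quadrant;
- large single-cluster "absorbers" (a deep opposite-drug cluster in the
  preferential presets, a broad shallow both-sensitive monolith in the
  divergent preset) soak up most of that 20% quota, pushing the expected
  single-drug quadrant fractions down to ~0.07–0.16 so that 3–4 leaves
  in a quadrant is decisively over-represented at alpha = 0.05, while
  themselves contributing a single insignificant leaf; the monolith's
  breadth also catches borderline resistant stragglers in an
  already-terminal leaf instead of letting them freeze a splittable node.

The homogeneous preset is a single 4-D Gaussian cloud: a spatially
coherent planar cut of such a cloud has silhouette well below 0.25 in
four dimensions, so it stays one leaf.

What passing on these cohorts does *not* show: real screens have heavier
tails, tissue-correlated covariance, missing-value structure and
markers entangled across lineages — none of which the generator
emulates.  Recovery rates here validate the machinery, not performance
on portal data.

## Problem sizes and defaults

Shipped analyses use cohorts of 300–1500 lines (presets), 120 lines per
pair for the 18 x 18 cross-panel grid (324 pairs), 100 generator seeds
for recovery-rate estimates, and the exhaustive grid of 2x2 tables with
total <= 60 (635,376 tables) for the exact-test oracle in the test
suite (total <= 40 in the acceptance script).  Defaults throughout:
beta = 0.5, gates 40/20/0.25, percentile 20, alpha 0.05, BH per node,
minimum 3 positive lines per testable feature.

## Known limitations

- The rank-one Sigma makes the distance insensitive to profile
  differences orthogonal to the pair's radial direction; clusters that
  differ only on such axes may not be separated even when Euclidean
  geometry would trivially separate them.
- The termination rules can freeze a large node when the proposed split
  isolates an outlier group smaller than the child-size threshold.
- Analysis commands are deterministic and seed-free; all randomness is
  confined to the synthetic generator.
- Tables are read whole into memory; cohorts are dense N x N, so memory
  grows quadratically (N = 2000 is ~100 MB per tensor — fine; N = 20000
  is not the intended regime).
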