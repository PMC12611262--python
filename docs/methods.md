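# Methods

## Compartment calling

The caller takes a symmetric, non-negative per-chromosome contact matrix at
a fixed bin size (default 250 kb) and produces a signed compartment track.

**Balancing.** ICE is implemented as a symmetric Sinkhorn-type iteration:
the matrix is divided by the outer product of its marginals normalized to
mean one until the coefficient of variation (CV) of unmasked row sums falls
below `tol = 1e-6` (cap 200 iterations; hitting the cap flags the result
unconverged and warns). Before iterating, bins whose raw marginal is below
10% of the median marginal are masked (sparsity filter), alongside all-zero
bins. The total count over unmasked bins is restored by a final global
rescale, and the accumulated per-bin bias is returned. For strictly
positive matrices this fixed point is the unique doubly-balanced scaling,
which is how the tests can compare it against an independently coded
balancing oracle.

**Scaling.** Each chromosome is scaled so its unmasked upper-triangle total
(including the diagonal) is 10⁶ — the conventional "scale to 1M" step that
makes eigenvector magnitudes comparable across chromosomes.

**Observed/expected.** Every entry is divided by the mean contact at its
genomic distance (mean over unmasked pairs on the |i−j| diagonal).
Distances at which no contact was observed anywhere are set to the neutral
value 1.0 rather than NA — this touches only empty far-diagonal bands at
low depth and keeps the downstream correlation defined.

**Eigenvector.** The compartment signal is the leading eigenvector of the
column-centered Pearson correlation matrix of the O/E map (PCA on the
correlation matrix), unit-normalized, NA on masked bins. PC1 is used;
constant O/E columns raise an error naming the offending bins. The global
sign is fixed by correlating with a covariate that is higher in A regions —
gene density per bin for real annotations, the planted state vector in
synthetic runs. |r| < 0.1 flags the orientation as ambiguous. Discrete
calls are then sign(track): positive A, negative B, exact zero NA (the
sign convention leaves zero undefined, so it is not forced into either
class).

Permutation equivariance holds for balancing and scaling; it cannot hold
for the O/E step, whose expectation is a function of genomic distance and
therefore of bin order.

## Profiling

Per-cell-type tracks over one bin grid are stacked into a cell-types × bins
matrix; any bin undefined in at least one cell type is dropped (count
recorded). Distances are d = 1 − Pearson r between rows; clustering is
Ward linkage on those precomputed distances (SciPy); PCA is feature-wise
mean-centered without variance scaling — compartment values share a common
scale, and scaling would inflate noisy bins. Component signs are fixed by
making each loading vector's largest-magnitude element positive. Expression
profiles are log2(count+1)-transformed and zero-variance genes dropped
before PCA. Top-k loading selection takes the k most-positive and k
most-negative loadings (ties by feature ordinal; fewer than k available on
a side returns all with a warning). Bin-to-gene mapping uses half-open
interval overlap, strand-agnostic, deduplicated.

## The organotropism statistic

Pair states concatenate the normal and cancer compartment letters per bin
(AA, AB, BA, BB; NA propagates). Group consensus keeps a label only where
every line of the group shows the identical non-NA label — the strictest
reading of "consistent between members of the group". Crossing the primary
organ's pair state with the secondary organ's yields the 16 categories;
`AB_BB` and `BA_AA` are organ-permissive. The permissive fraction divides
by bins whose *primary* pair state is AB or BA; the
per-all-informative-bins variant is also reported. Per-category
percentages (×100 of informative bins) feed the cross-organ adjustment:

    adjusted(BA_AA) = (1 − p(TA|NA)) · percent(BA_AA)
    adjusted(AB_BB) = (1 − p(TB|NB)) · percent(AB_BB)

with p(TA|NA) = #(secondary normal A ∧ secondary cancer A) / #(secondary
normal A), per line, minimized over the secondary organ's cancer lines
(p(TB|NB) analogous). The formula is applied exactly in this orientation —
(1 − p of the stable compartment) times the category whose secondary side
sits in that compartment — even though a p-weighting could also be argued;
a `weight_by_p` flag exposes the alternative for sensitivity analysis and
is off by default. Cross-organ comparisons restrict all tracks to the
common defined bin set first, so every organ's percentages share one
denominator basis.

## EMT scoring

The single-sample enrichment score ranks a sample's genes by expression
(descending; ties broken by gene identifier so results are platform
independent) and walks down the ranking: +1/n at signature genes, −1/(N−n)
elsewhere; the score is the signed maximum-magnitude deviation, in [−1, 1].
It is a rank statistic, hence invariant under monotone transforms of
expression. This is a deliberately simple, fully specified statistic; it
is not a numerical clone of kernel-density ECDF enrichment methods, but
preserves sample orderings, which is the reproducible surface here.

nnPCA restricts the (log2(count+1), gene-centered) matrix to a signature
set and finds axes with non-negative unit-norm gene loadings maximizing
projection variance, by projected power iteration on the covariance
(multiply, clip negatives, renormalize; tolerance 1e-8, cap 500
iterations). Because clipping a mixed-sign principal axis leaves two
candidate cones, the iteration is started from both the clipped leading
principal axis and its clipped negation, keeping the higher-variance
solution — deterministic, no random restarts needed in practice. Further
axes use Hotelling deflation of the data matrix; per-axis scores are the
projections of the residual the axis was fit to; cross-axis cosines are
recorded but not constrained. E and M scores are the first-axis
projections of the E- and M-set submatrices; the combined axis is M − E.

## The synthetic study system

The generator defines the conditions every end-to-end check runs under.

**Contact maps.** E[i,j] = C·(|i−j|+1)^(−α)·(1+δ) for same-compartment
pairs and (1−δ) otherwise, with C set so the expected total over unordered
pairs equals the depth; counts are Poisson, symmetric, zero diagonal.
Poisson (not negative-binomial) keeps the oracle analytic and is adequate
for planted-structure recovery. Defaults: 400 bins of 250 kb per
chromosome, α = 1, δ = 0.3, depth 10⁶ — a deep-coverage regime in which
the caller recovers planted states essentially perfectly; the recovery
tests also scan lower depths where accuracy degrades gracefully.

**Panel.** The primary-organ normal epithelium is an alternating A/B block
vector with geometric block lengths (mean 8 bins). Secondary (and
optionally decoy) organ normals differ at a configured fraction of bins
(`organ_divergence`, default 0.25, drawn outside the EMT bins; decoy bins
drawn disjointly from the target organ's). Cancer lines derive from their
organ's normal by four exhaustively bookkept mechanisms per bin:

- *EMT tilt*: a designated bin subset (`emt_bin_fraction`, default 0.15)
  flips once the line's EMT parameter crosses a per-bin uniform threshold —
  a monotone gradient. Primary cancer lines span EMT parameters linspace
  (0, 1), localized lines at the epithelial end, metastatic at the
  mesenchymal end; secondary-organ cancers sit at 0.5.
- *Permissive switches*: at organ-divergent bins, primary cancer lines
  flip toward the secondary organ's state with probability 0.5
  (metastatic) or 0.1 (localized) — the planted organotropism signal.
- *Clonal switches*: half of the background cancer switch rate (0.05
  total) is shared by every cancer line of an organ, mirroring
  subtype-shared compartment changes; without a shared component,
  group-consensus denominators would be nearly empty, which real panels do
  not show.
- *Private switches*: the remaining rate, independent per line.

**Expression.** Gene baselines are log-normal (log2 mean 6, sd 1.5);
epithelial-set genes decrease and mesenchymal-set genes increase linearly
in the EMT parameter (effect 2.0 log2 units across the gradient), with
gamma-Poisson (negative-binomial-style) noise at dispersion 0.1. The
default annotation holds 1200 genes: 232 epithelial and 193 mesenchymal
signature genes placed only in bins that are A in every cell type, and
flat genes everywhere — so differential expression and compartment
switching are decoupled by construction, and the expected overlap between
the two PC1 signatures is near zero.

All randomness flows from a single integer seed through named sub-streams
(seeded by CRC32 of (chromosome, purpose, cell-type) tags), so any piece
of a panel can be regenerated independently and whole experiments are
reproducible.

**What the generator does not emulate.** TADs, loops, translocations and
copy-number effects; single-cell sparsity; inter-chromosomal contacts;
trans-acting expression programs beyond the single EMT axis; batch
effects. Passing the end-to-end tests therefore demonstrates that the
statistics recover the signals they define under idealized noise, not that
real Hi-C biases are fully handled.

## Problem sizes in the standard experiments

Recovery uses 20 single-chromosome replicates (400 bins). The
metastatic-vs-localized experiment uses 10 chromosomes (4000 bins, 1000
organ-divergent "eligible" bins) per replicate; the cross-organ experiment
4 chromosomes with a decoy organ; the EMT gradient 8 cancer lines on one
chromosome; the signature-overlap design 3 chromosomes. These sizes give
stable statistics while keeping a full suite run inside a coffee break.

## Known limitations

- The ICE fixed point is unique only for matrices whose support is
  connected; pathological block-diagonal inputs converge to one of several
  scalings (not an issue for simulated or real chromosome-wide data).
- PC1 is assumed to be the compartment axis; an option to choose among the
  first three components by covariate correlation exists but defaults off,
  and per-chromosome PC selection heuristics are deliberately out of scope.
- The enrichment statistic's absolute values are not comparable with
  kernel-based enrichment scores; only orderings are.
- With very small panels (< 3 cancer lines per group) the consensus rule
  leaves few informative bins and the permissive fraction becomes noisy;
  the summary records all denominators so this is visible.
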