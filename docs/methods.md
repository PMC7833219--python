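# Methods

This note documents the model implemented by `geostress`, the numerical
choices behind it, what the synthetic-data generators emulate, and the
limitations a user should keep in mind.

## The model

A wearable recording is three (or more) channels sampled on a shared
clock: heart-rate variability X, step frequency Y and blood oxygenation Z,
used as surrogate markers of stress. The analysis assumes the channels are
approximately normally distributed and approximately self-similar over the
recording span; under those assumptions the per-segment Hurst exponent is
a meaningful, unit-free summary of each segment's dynamics, and the three
channels become comparable after projection.

1. **Segmentation.** The span [t₁, t_{k+1}] is cut into k > 1 equal
   segments (half-open [t_m, t_{m+1}), last segment closed, so samples are
   partitioned without double counting and the union of segments covers
   the span exactly).
2. **Complexity projection.** Each segment of each channel is mapped to
   its Hurst exponent H ∈ (0, 1]. The triple of per-segment tracks
   (H(X), H(Y), H(Z)) is the *stress indicatrix*. The projection is lossy
   by construction: within-segment microstructure is discarded.
3. **Perceptron.** γ_m = sign(H(Z)_m − E[H(Z)]) with sign(0) → +1.
   The threshold is the subject's own mean SpO2 complexity, so
   "hypoxemia" (γ = −1) is strictly relative — no clinical threshold.
4. **Domain partition.** The labelled points (H(X)_m, H(Y)_m) live in the
   effective rectangle Ω spanned by their ranges. Per label class, the
   points are clustered; each cluster is convexified; overlapping
   opposite-class hulls are separated by a thin layer; a Delaunay
   triangulation of a regular mesh over Ω is classified by nearest hull.
5. **Indices.** pGSI τ = (positive triangulated area)/meas(Ω); pSRI
   θ = mean distance of positive points inside ∪Ω⁺ to the union of
   negative-subdomain boundaries; behavioural entropy bE accumulates the
   signed jumps of any single track.
6. **Power law.** Across subjects or replicates, (τ_j, bE_j) pairs are
   summarised by bE ≈ α·τ^β via nonlinear least squares over (α, β) ∈ ℝ².

## Estimators and numerical choices

**Hurst estimation (default: corrected R/S).** The rescaled-range
statistic is averaged over non-overlapping windows at geometrically spaced
sizes (ratio √2, minimum window 8, maximum n/2); the estimate is
0.5 + slope of log(R/S) − log E₀[R/S] against log window, where E₀ is the
Anis-Lloyd-Peters expectation under iid Gaussian noise. Subtracting the
null expectation removes most of the small-sample bias that otherwise
drags estimates toward 1/2; the √2-spaced grid doubles the number of
regression points over a dyadic grid and measurably reduces the slope
variance. Estimates are clipped to (0, 1] (a zero estimate is clipped to
machine epsilon to respect the open lower bound). Order-1 detrended
fluctuation analysis is available as `hurst_method="dfa"`; it has smaller
bias for strongly persistent signals at the cost of higher variance on
short segments. Residual bias of the corrected R/S on exact fractional
Gaussian noise at n = 4096 is about −0.05 at H = 0.7 and +0.03 at
H = 0.3; both estimators keep the mean absolute recovery error under 0.1
for H ∈ {0.3, 0.5, 0.7} (verified in the test suite).

**Minimum segment size.** Segments with fewer than 32 samples (or fewer
than `min_segment_samples`, if raised) are flagged as undefined-complexity
gaps rather than estimated; R/S slopes regress over too few windows below
that size to be trustworthy. Flagged segments carry no perceptron label;
behavioural entropy excises them and reconnects the track across the gap,
reporting the excision count.

**Cluster-count selection.** Per label class, agglomerative clustering
with complete linkage is run three times — under Bray-Curtis, Chebyshev
and normalized squared Euclidean dissimilarities — because complete
linkage accepts arbitrary precomputed dissimilarity matrices. Within each
run the Calinski-Harabasz (variance-ratio) criterion picks the cluster
count over k = 2 … 6, and the run yielding the fewest clusters wins. The
variance-ratio score is undefined at k = 1, so a decision rule is needed
for unsplittable classes: a split is accepted only when its score exceeds
3·n (n = class size). Empirically the best split of a single Gaussian
cloud scores ≈ 0.6–1.1·n while genuinely separated blobs score above
10·n, so the factor-3 rule separates the regimes without an absolute
threshold. The normalized squared Euclidean dissimilarity is squared
Euclidean distance after per-coordinate standardization; the alternative
reading (normalizing each 2-vector by its own component mean) collapses
all points with equal coordinate differences and is degenerate in a 2-D
plane, so it is not used.

**Separation layers.** When a positive and a negative hull overlap with
positive area, both are shrunk inward by ε/2 (negative mitre buffer),
repeated up to 25 times. ε defaults to 1% of the diagonal of Ω. A polygon
is never shrunk to emptiness, and heavily intermixed classes may retain
residual overlap — tolerated, since triangle classification (not the
polygons themselves) defines the final areas. Slightly overlapping hulls
become disjoint after a few iterations.

**Triangulation and areas.** The mesh is a regular 60 × 60 point grid over
Ω (configurable, ≥ 10 per axis), Delaunay-triangulated; each triangle
takes the class of the hull union nearest to its centroid (ties → +1,
the same completion as the perceptron's sign(0) rule). Every triangle is
classified, so the class areas sum to meas(Ω) exactly and the covering
property of the partition holds by construction; triangulated areas agree
with a 10⁵-point rejection-sampling oracle to well within 1% of meas(Ω).
With no negative (or no positive) hull at all, τ is returned as exactly
1.0 (or 0.0) rather than triangulated. A 2-D logistic-regression class
map (`classifier="logistic"`) can replace nearest-hull labelling as a
cross-check; the geometric path is canonical and both can be reported
when they disagree.

**pSRI.** Distances are Euclidean in the complexity plane, measured from
each positive-labelled point lying inside ∪Ω⁺ to the union of negative
polygon exteriors. With m⁺ = 0 the index is undefined (NaN, flagged).
With no negative subdomain the distance is taken to ∂Ω and flagged
`no-negative-boundary` — the case is genuinely open; measuring against
the domain boundary keeps the index finite and monotone in the points'
distance from the domain edge.

**Behavioural entropy.** Both variants sum over the m−1 consecutive
jumps. The local variant applies each jump's own sign, which telescopes
to H_m − H₁; the global variant signs the total variation by the net
drift. The two definitions in circulation differ in whether the m-th term
references a jump beyond the track's end; the implementation sums over
the m−1 existing jumps, the only reading in which the stated jump set
exists. sign(0) contributes 0, so constant tracks give bE = 0 exactly.

**Power-law fit.** Deterministic multistart Levenberg-Marquardt over a
fixed grid: amplitudes ±{10⁻³, 10⁻², 0.1, 1, 10} × exponents
{−2, −1, −0.5, −0.1, 0, 0.1, 0.5, 1, 2, 5}, plus a flat-law start at
(mean bE, 0) and, when all bE share one nonzero sign, the log-log linear
solution. Ties between local optima break by smallest residual, then
smallest |β|. Adding starts can only keep or lower the residual. Pooled
fitting (one law per channel over all subjects) is the default, matching
the usual cross-subject presentation; per-subject fitting is a loop over
rows.

## Defaults and units

| parameter | default | meaning |
|---|---|---|
| `dt` | 30 s | resampling step (effective coarse-grained resolution) |
| `samples_per_segment` | 225 | target segment size when `k` unset; with dt = 30 s a ~15 h recording yields k = 8 |
| `hurst_method` | `rs` | corrected rescaled-range |
| `min_segment_samples` | 32 | below: flagged, not estimated |
| `epsilon` | 1% of diag(Ω) | separation-layer width |
| `mesh` | 60 | mesh points per axis |
| bins (density diagnostic) | 60 | histogram resolution |

Timestamps are seconds as float with t = 0 at the first sample (ISO-8601
converted on read). HRV is carried in ms, SF in steps/s (floored at 0),
SpO2 in %. The sampling rate of the raw sensor stream before
coarse-graining is configuration (`dt`), not a model constant. Missing
values are dropped per channel before linear-interpolation resampling;
gaps longer than 10·dt are interpolated but flagged. The normality
diagnostic (60-bin histogram + D'Agostino-Pearson test) is reporting-only
and never gates the pipeline, since approximate normality is an
assumption of the complexity space, not a testable gate.

## What the synthetic data emulate — and what they do not

The generators reproduce the statistical structure the model assumes:
Gaussian marginals, exact self-similarity within segments (circulant
embedding of the fractional-Gaussian-noise autocovariance is exact for
every H ∈ (0, 1)), piecewise-constant Hurst profiles, and negative
SpO2-vs-HRV/SF cross-correlation imposed on the innovations before
H-shaping (realized correlations are therefore approximate — jointly
exact correlation and self-similarity across different H is
over-constrained; realization within ±0.1 at n = 5000 is verified by
test). Channel scales (HRV 50 ± 15 ms, SF 1.0 ± 0.5 steps/s, SpO2
97 ± 1%) are physiologically plausible placeholders.

Real recordings violate these idealisations: non-stationarity within
segments, motion artefacts, sensor drop-outs, non-Gaussian tails (SF in
particular is zero-inflated during rest), and Hurst profiles that change
continuously rather than blockwise. Passing tests on synthetic data
therefore demonstrate the *machinery* — estimator calibration, geometric
correctness, index semantics — not clinical validity of the indices on
real subjects.

The scenario presets encode the three qualitative regimes of the
complexity plane: `rest` (balanced labels, normoxemic segments ranging
widely over the plane), `physical` (high SF complexity = low H(SF), low
HRV complexity = high H(HRV), hypoxemia-dominant) and `mental` (the
mirror image). They are constructions for exercising the pipeline, not
fitted to any subject.

## Problem sizes

The shipped tests and examples run at the scale the method is designed
for: 8 segments of ~225 samples at 30 s resolution (~15 h of recording),
Hurst calibration at n = 4096 over 20 seeds, neutrality and
entropy-sign checks over 50 seeded replicates, and a 10⁵-point
Monte-Carlo area oracle. These sizes keep every result stable across
seeds while remaining quick to re-run.

## Known limitations

- R/S and DFA estimates on ~225-sample segments have a standard
  deviation of roughly 0.06–0.12; per-segment tracks at that scale are
  noisy, and indices built on them inherit that noise. Longer segments
  trade temporal resolution for estimator precision.
- The cluster-count rule (factor-3 variance-ratio acceptance) is
  calibrated for blob-like classes of ~10–200 points; very large or very
  elongated classes may split differently.
- Convex subdomains cannot represent non-convex class regions; the
  partition tolerates intermixed points by design, so τ is a smoothed
  area fraction, not a classification accuracy.
- With heavily intermixed classes the separation layers may not fully
  disconnect hulls (residual overlap is tolerated and reported via
  `separation_iterations`).
- The power-law fit treats τ values near 0 with negative exponents as
  ill-conditioned; the multistart grid covers β ∈ [−2, 5], and exponents
  far outside that range rely on the data-driven log-log start.
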