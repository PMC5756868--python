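# Methods

## Problem setting

A central-place forager (the motivating case is a plunge-diving seabird)
leaves its colony, commutes, searches, rests on the water, and returns. GPS
fixes every 2 minutes describe the path; a time–depth recorder time-stamps
every dive deeper than 1 m, giving an independent record of prey-capture
attempts. The package asks, method by method: when a fix is labeled
*search*, how often does a dive actually happen there, and how often does a
run of search fixes contain no dive at all?

## Preprocessing

Lon/lat fixes are projected to planar meters with a WGS84 transverse-
Mercator (UTM) projection implemented from the standard series expansions
(round-trip accurate to < 1e-6 degrees; verified against the ellipsoidal
meridian arc). Tracks are linearly interpolated to a constant fix interval
(default 120 s); gaps longer than 30 min are never interpolated across —
the track splits into segments, and all sequence-aware computations (HMM
runs, chains) respect segment boundaries. Per-fix metrics:

- step length `‖p_{i+1} − p_i‖` (m); backward speed `‖p_i − p_{i−1}‖/Δt`;
  acceleration = change in backward speed over Δt;
- signed turning angle at i between segments (i−1,i) and (i,i+1), in
  (−π, π], counterclockwise positive (classifiers use |turn|, so the
  convention is inert);
- tortuosity over the 9-fix window: chord `‖p_{i+4} − p_{i−4}‖` divided by
  the along-track distance, hence always in [0, 1] and exactly 1 on a
  straight monotone window.

Metrics whose window leaves the track are NaN, never zero-filled. Fixes
within 5 km of the colony or with solar elevation below −6° (civil
twilight; NOAA solar-position approximation, ~0.2° accurate) are marked
invalid: they stay in the frame (and still break chains) but are excluded
from classification and from every rate denominator. Tracks split into
trips wherever ≥ 3 consecutive fixes sit inside the colony radius; chains
never span trips.

Dive onsets are the first sample of each maximal run of depth samples
> 1 m. Each dive is matched to the temporally nearest fix (ties to the
earlier fix); dives beyond half an interval outside the track span, or
matched to invalid fixes, are flagged unmatched and dropped from
denominators with a logged count.

## Annotation methods

**First passage time.** Computed on the spatially rediscretized path (equal
500-m along-track spacing) so it measures geometry, not fix rate. FPT at a
point is the time from the last backward to the first forward crossing of
the circle of radius r, crossings solved exactly on the linear segments.
Radius ladder: 50 m plus 500-m rungs to 12 km. Per bird, r* maximizes the
variance of ln FPT; the ceil(n/6) highest-FPT points (ties to the earlier
index) seed the search area — the union of circles of radius r* — and every
valid 2-min fix inside the union is search, the rest travel. The sextile is
a count quantile, not an FPT-value cut. Only the single dominant scale is
used; nested multi-scale analysis is out of scope.

**MacQueen k-means.** Features (step length, |turn|), z-scored. MacQueen's
online update (centroid moves after every assignment) from k distinct
random seed points, best of 10 seeded restarts per k. Explained variance
EV(k) = between-cluster SS / total SS; the elbow picks the smallest k whose
next cluster adds < 0.1 × (EV(2) − EV(1)). Behaviors: largest mean step and
smallest mean |turn| → travel, smallest step → rest, remainder → search;
if one cluster wins twice, fall back to pure step ordering with a warning.
On cleanly separated 3-state feature data the elbow returns k = 3; on the
continuous reference simulation the heavy-tailed travel cluster often
splits and k = 4 is selected — both extra clusters map to behaviors by the
ordering rule, so the annotation remains 3-state. The threshold is a
constructor parameter for users who want a stricter elbow.

**Speed–tortuosity thresholds.** The three expert rules applied verbatim
with strict/inclusive comparisons as written; a rule cannot fire if one of
its metrics is undefined. The rule set has no rest state; non-search valid
fixes are travel.

**Hidden Markov model.** Observations (step, turn) per fix; per-state gamma
(parameterized by mean and sd) and von Mises (mean, concentration)
emissions; undefined observations contribute probability 1. The likelihood
is the scaled forward recursion, restarting the initial distribution at
every segment of consecutive valid fixes; zero steps are perturbed to half
the smallest positive step (a gamma has no mass at 0). Fitting maximizes
the forward log-likelihood directly with L-BFGS over unconstrained
transforms (log for positive parameters, multinomial logit for transition
rows and the initial distribution), from several random starts with gamma
means seeded at step quantiles; fitted states are reported sorted by mean
step, mapped rest < search < travel. Decoding is Viterbi with ties toward
the lower state index. The inner forward/Viterbi loops are numba-compiled;
both are verified against exhaustive path enumeration at small T. The model
is fitted pooled per colony (per-bird fitting is a one-line change: pass a
single bird's frame).

**EMbC.** Features (speed, |turn|). Each feature carries a delimiter
(initialized at the median) splitting it low/high; the four bins LL, LH,
HL, HH each hold a bivariate Gaussian. Iteration: hard-assign points by
their side of each delimiter, refit bin Gaussians and weights, move each
delimiter to the weight-weighted midpoint of the pooled low and high bin
means, until the mixture log-likelihood stabilizes. Labels: LL → rest,
HL → travel, LH → search, and HH → search by default (the high-speed,
high-turn bin is ambiguous between extensive search and maneuvering
transit; a constructor switch relabels it travel). Emptied bins get a
floored weight (1e-6) and a regularized covariance. Note one structural
consequence of median-anchored delimiters: a single tight cloud of points
is split into four quarter-bins rather than collapsing to one bin, exactly
as k-means would split a single Gaussian.

## Density surfaces and the modified t-test

Quartic (biweight) kernel, K(d) = 3/(πh²)(1 − (d/h)²)² for d < h, evaluated
at cell centers; bandwidth and cell size both default to 10 km; the grid
origin snaps to multiples of the cell size so identical inputs give
byte-identical grids. Mass is conserved for interior points (unit integral
verified by quadrature); boundary truncation is not compensated. Track and
dive surfaces share the track grid's support (cells within one bandwidth of
a track point).

The correlation between the two surfaces uses the Clifford–Richardson–Hémon
estimator with Dutilleul's correction: Moran-type correlograms ρ̂_A(k),
ρ̂_B(k) over equal-width distance classes (width = cell size), effective
sample size M̂ = n / (1 + 2 Σ_k m_k ρ̂_A(k) ρ̂_B(k) / n) clipped to [3, n],
and F = r²(M̂ − 2)/(1 − r²) on F(1, M̂ − 2). Distance classes span **all**
pairs: truncating the correlogram at half the grid diameter (a common
shortcut) measurably inflates the type-I error (~7.5% vs ~5.5% at nominal
5% on 1,000-replicate null calibrations), because the omitted long-range
classes carry negative autocorrelation products. Calibration is checked
against smoothed-white-noise null fields on which the naive Pearson test
rejects ~70% of the time.

## Dive prediction

Gradient-boosted shallow trees (logistic loss) on step length, speed,
|turn|, local solar hour (UTC + lon/15, integer 0–23) and tortuosity; rows
with undefined metrics are dropped with a count. Stratified 75/25 split.
Hyperparameters are chosen from a small grid by mean out-of-bag AUROC over
bootstrap resamples; the number of resamples defaults to 500 (the
conventional repeated-resampling setting) but the reference comparison and
the acceptance script use 30, which we found ample to separate a two-point
grid. The decision threshold maximizes Youden's J on pooled out-of-bag
predictions — the only concession to class imbalance, deliberately
mirroring the low-recall regime such models show on real dive data. Cross-
colony transfer is evaluated by fitting on one colony's table and scoring
another's.

## Synthetic data

The simulator is the package's ground-truth source and mirrors the HMM's
generative assumptions: a latent 3-state Markov chain (travel/search/rest)
with state-specific gamma steps and von Mises turns. Defaults, chosen to
mimic a plunge-diving seabird at 2-min fixes and fixed once:

| state  | step mean (m) | step sd | turn κ | meaning at 120 s        |
|--------|---------------|---------|--------|-------------------------|
| travel | 1,800         | 500     | 10     | ~15 m/s, straight       |
| search | 300           | 150     | 1      | ~2.5 m/s, tortuous      |
| rest   | 30            | 20      | 0.5    | drift                   |

Transition matrix rows (travel, search, rest): (0.92, 0.07, 0.01),
(0.06, 0.90, 0.04), (0.04, 0.10, 0.86); start in travel. During travel the
von Mises turn mean is shifted by 0.4 × the wrapped bearing error toward
"away from colony" in the trip's first half and "toward colony" in the
second, so trips leave and return while emissions stay in the von Mises
family. Dives are per-fix Bernoulli draws: p = 0.2 in search, 0.002
elsewhere, with onset jittered uniformly within half a fix interval. Each
bird uses an independent seed substream, so bird k's trip is invariant to
the number of birds. Trips start at 07:00 UTC in mid-June at 52–56° N, so
a 10-h trip is fully daylight and the night filter is exercised by
construction rather than emptying the data.

A second generator, `simulate_patchy_track`, plants area-restricted search
explicitly: straight commute legs alternating with tortuous movement
confined to circles of known radius — the ground truth for
first-passage-time scale recovery (a 2-km planted radius is recovered
within a factor of 2 in 10/10 seeded replicates).

What the simulator does **not** emulate: GPS dropout during dive bouts,
location error, tidal drift during rest, wind-dependent commute speeds,
inter-individual heterogeneity, or dives clustered within search bouts
(dives are conditionally independent given the state). Passing tests
therefore demonstrate correctness of the algorithms under the models'
own assumptions, not field performance; on real tracks the methods' rates
will differ, and the cross-method *ordering* is the robust output.

## Problem sizes and determinism

The reference comparison uses 6 birds × 10 h per colony × 2 colonies
(~3,600 fixes); HMM parameter recovery uses a single 20,000-fix simulation
(recovering gamma step means within ~1% and transition entries within
~0.01, Viterbi accuracy ~90%); the calibration study uses 1,000 null grids
of 15 × 15 cells. These sizes were chosen so the whole suite replays in a
few minutes; all randomness flows from explicit integer seeds and repeated
runs are byte-identical (the comparison report is written with a fixed
float format for that reason).

## Known limitations

- The UTM implementation targets mid-latitude use a few degrees around the
  central meridian; it is not a general-purpose geodesy library.
- The solar-position approximation ignores leap seconds and refraction
  (irrelevant at a −6° threshold).
- FPT is O(n²) per radius in path points; fine for multi-day trips at
  500-m spacing, not for months-long tracks.
- The HMM assumes state-independent fix intervals and no covariates on
  transitions.
- EMbC is specified structurally (quadrant semantics); it is not intended
  to be numerically bit-compatible with other implementations.
- Kendall's τ z-score is recovered from the two-sided p-value of the
  tie-corrected statistic; for very small chain counts the normal
  approximation is rough.
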