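# Methods

This note documents the models, numerical choices and known
limitations of `synlab`. It describes what the code computes and why
the defaults are what they are; every number quoted here is produced
by the test suite or by `scripts/acceptance.py`, not asserted from
elsewhere.

## Preprocessing

Raw EMG (13 lower-limb muscles, 2 kHz) is high-pass filtered at
50 Hz, full-wave rectified and low-pass filtered at 20 Hz to form the
linear envelope. "4th-order zero-phase Butterworth" is ambiguous
between design order and effective order after forward-backward
filtering; we design 2nd-order sections and apply `sosfiltfilt`,
giving a 4th-order effective magnitude response — the conventional
reading in movement science. The design order is a parameter. Tiny
negative values left by low-passing the rectified signal are clipped
at zero so envelopes stay non-negative.

Amplitude normalization is per muscle and per trial: subtract the
channel minimum, divide by the resulting maximum. A zero-range
channel maps to all zeros with a warning rather than an error, since
a dead electrode should not abort a batch run.

Time normalization resamples each gait cycle to 200 points, 100 for
stance (touchdown to lift-off) and 100 for swing (lift-off to next
touchdown), by linear interpolation — shape-preserving and
non-negative. Phase windows are half-open ([touchdown, lift-off) and
[lift-off, next touchdown)) so the boundary sample is owned by
exactly one phase. Only the first 30 complete cycles are used;
shorter trials are accepted as-is. A complete cycle needs the next
touchdown, so a trial with k touchdowns yields k − 1 cycles; the
synthetic generator therefore emits n_cycles + 1 touchdowns.

## NMF and rank selection

Multiplicative Frobenius updates with a 1e-12 epsilon guard in the
denominators (configurable). Initialization is i.i.d. uniform on
(0, 1]. R² (1 − SS_res/SS_tot about the grand mean of V) is computed
every iteration from the Gram matrices already needed by the updates
(||V−MP||² = ||V||² − 2⟨M, VPᵀ⟩ + tr((MᵀM)(PPᵀ))), so convergence
tracking adds almost no cost. The loop stops when the relative R²
change over the last 20 iterations falls below 1e-4 (0.01%); an
absolute-change mode is exposed via `relative_tol=False`. A max_iter
cap of 2000 guards pathological inputs.

Each candidate rank 1…10 is fitted from 10 random restarts with
seeds derived deterministically from a master seed
(`master + rank*100 + restart`), keeping the best-R² solution, which
makes the whole extraction reproducible bit-for-bit. Rank selection
fits an OLS line to the R²-vs-rank curve, dropping the lowest rank
until the fit MSE (computed on raw R² units in [0, 1]) falls below
1e-4, returning the first rank of the first sufficiently linear
tail, or the 9th rank when only two points remain.

NMF solutions carry a scale ambiguity; all cross-trial comparisons
use `SynergyModel.normalized()`, which scales module columns to unit
maximum and primitives inversely.

## Functional classification

Per locomotion condition, the mean-cycle curves (200 points) of all
extracted primitives are stacked and factorized with the same NMF
engine at k = (maximum rank among trials) + 1, yielding "principal
shapes". A primitive is provisionally assigned to its largest-weight
shape when that weight is at least the mean of the full weight
matrix, and confirmed fundamental when its R² against the
(weight-scaled) shape reaches 25% of the mean R² of the other
provisionally assigned primitives against their own shapes (4× that
mean when it is negative, the candidate itself excluded). Shapes are
named by peak location: weight acceptance [0, 50), propulsion
[50, 100), early swing [100, 150), late swing [150, 200); the
windows are configurable since only functional descriptions, not
boundaries, are standard. Clustering mean cycles rather than full
6000-point primitives reflects that shape similarity, not
cycle-to-cycle noise, defines a functional cluster.

A caveat found while validating with hand-stepped fixtures: an exact
50/50 sum of two disjoint activation bells scores R² ≈ 0.3–0.45
against either constituent shape and therefore *passes* the
25%-of-average gate — the stated thresholds label clean two-bell
blends fundamental. Real combined primitives are messier and score
far lower; the test suite asserts agreement with the hand-stepped
decision rule rather than a hard-coded "combined" outcome.

## Primitive geometrics

CoA treats the cycle as a circle with θ_t = 2πt/p, t = 0…p−1
(origin at the first stance point), and is the quadrant-correct
`atan2` of the sine/cosine-weighted sums — the single-argument
arctan form is ambiguous for negative cosine sums. A uniform cycle
has no CoA and raises `UndefinedCoAError`. Trial-level aggregation
is the circular (resultant-vector) mean, not the arithmetic mean, so
activity near the cycle boundary does not average to mid-cycle.

FWHM counts points *strictly* above half the min-subtracted maximum
(strictness configurable); a constant cycle gives 0. The
half-maximum heat map is the per-time-point fraction of cycles above
their own half maximum; its sum over the 200 points equals the
trial-mean FWHM, an identity the tests assert numerically.

## Fractal analysis

Rescaled range R/S of a segment: range of the mean-centered
cumulative sum divided by the population (divisor n) standard
deviation (the sample-SD variant is a parameter; the slope is
insensitive at these lengths). Window sizes are n, n/2, n/4, …
stopping before any size falls under 200 points (the normalized
cycle period), with the full-length single-segment window included
as the first point; trailing remainders at non-dividing window sizes
are discarded, the classical practice. H is the OLS slope of
log(R/S) on log(N) (natural logs; the base cancels in the slope).
The fit R² is reported and a warning is emitted below 0.9 — strongly
periodic series fit a power law poorly, which is informative in
itself. Estimates are flagged, never clipped, outside [0, 1].
Constant segments are excluded rather than propagating NaN.

Trial-level H averages over *all* primitives, combined synergies
included; a `fundamental_mask` argument restricts the average when
wanted.

Calibration on exact fractional Gaussian noise (circulant-embedding
generator, Davies–Harte, exact by construction) at n = 6000 gives
mean estimates ≈ 0.34 / 0.52 / 0.71 for true H = 0.3 / 0.5 / 0.7 —
within the known small-sample bias of R/S and strictly ordered,
which is what the downstream between-condition comparisons rely on.

## Gait parameters

Per cycle: duration from consecutive touchdowns, swing = duration −
stance, cadence = 120/duration (two steps per one-limb gait cycle,
assuming symmetric stepping — only one limb's events are recorded).
The last touchdown has no following cycle and is dropped.
Variability is the percent CV with sample (n−1) standard deviation.

## Statistics

Scalar outcomes use the 2×2 within-participant design environment ×
locomotion type. For a balanced within 2×2 design, the type II
repeated-measures F of each effect equals the squared paired t on
the participant-level factor contrast; the implementation computes
these directly and the tests verify exact agreement (1e-8 on F) with
an independent repeated-measures ANOVA implementation. Residuals of
the Gaussian cell-means model gate the path: Shapiro–Wilk p ≥ 0.05
keeps the parametric engine, otherwise all values are rank-
transformed and re-fed to the same engine — a documented
approximation to fully rank-based ANOVA. Levene's test
(median-centered) reports variance homogeneity. Post hoc LSD is the
six pairwise paired t-tests with Benjamini–Hochberg adjustment.
Under a Gaussian null at n = 30 the empirical type-I error per
effect is ≈ 0.05 (asserted within [0.04, 0.06] over 10,000
replicates).

1-D comparisons of motor primitives use permutation SPM rather than
random-field theory: RFT smoothness estimation is out of scope and
permutation inference is assumption-light and directly testable.
The pointwise environment F comes from each participant's
cycle-averaged curves (paired design); because averaging removes any
dependence on cycle order, the prescribed cycle-order re-
randomization leaves the observed statistic unchanged and the
resampling acts through the null distribution: per resample,
environment labels are flipped within participants, the maximum F
over the 200 points builds the critical threshold (1 − α quantile),
and the maximum suprathreshold run length yields cluster p-values
(max-statistic cluster-extent inference). Because the threshold and
cluster inference are permutation-based, cluster locations from
parametric SPM implementations are comparable by overlap, not
point-for-point. The default 10,000 resamples is configurable; the
validity tests use 500 with 200 replicates and observe a
false-positive cluster rate at or below the nominal 5% (≤ 7% bound
with Monte-Carlo slack).

## Synthetic data

The generator is the ground truth for every recovery test. Four
fundamental synergies are emulated: module weightings concentrated
on knee/hip extensors (weight acceptance), plantarflexors
(propulsion), dorsiflexors (early swing) and knee flexors (late
swing), with ±20% uniform seed-dependent variation; primitives are
wrapped-Gaussian bells (circular, so late-swing activity wraps into
the next cycle) peaking at points 25/75/125/175 with SD 10–12
points, per-cycle peak jitter (default SD 2 points) and lognormal
per-cycle amplitude variability (default 10%). Envelope noise is
zero-clipped Gaussian with SD expressed as a fraction of the
envelope maximum — clipping rather than rectifying keeps envelopes
non-negative without doubling noise power. The raw-like signal is a
10–500 Hz band-limited Gaussian carrier (emulating the acquisition
band-pass, which the software chain therefore never re-applies)
amplitude-modulated by the envelopes at 2 kHz. Gait events default
to comfortable walking: cycle 1.05 s, stance 0.65 s, stance CV 4%,
cycle CV 2%.

What the generator does **not** emulate: electrode artifacts and
crosstalk, non-Gaussian EMG noise statistics (the truncated-Gaussian
envelope noise is a stand-in; real EMG noise is uncharacterized
here), treadmill-belt speed fluctuation, and any systematic
environment effect — so passing recovery tests demonstrates
correctness of the algorithms, not that real overground/treadmill
differences will reproduce.

## Problem sizes

Validation uses the full trial geometry (13 × 6000 matrices,
30 cycles) throughout. Monte-Carlo sizes were chosen once per
analysis: 10 noiseless and 50 noisy trials for recovery, 100 seeds
per level for fGn calibration, 200 replicates × 500 resamples for
SPM validity, 10,000 replicates for scalar-ANOVA calibration, and
12 trials for the end-to-end summary in `scripts/acceptance.py`.

## Known limitations

- Deposit (RData) ingestion requires the optional `pyreadr`
  dependency and real deposit files; it is exercised only for the
  trial-key grammar in the offline suite.
- The rank-transform fallback approximates, not reproduces,
  dedicated robust rank-based ANOVA estimators.
- The 30-level gait-cycle factor enters the SPM design only through
  cycle averaging (fixed within-participant factor); a model with
  explicit cycle effects would need the cycle-paired structure that
  single-limb deposits do not constrain.
- R/S estimation of H is biased upward for small H at these series
  lengths; between-condition *comparisons* are unaffected since the
  bias is shared.
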