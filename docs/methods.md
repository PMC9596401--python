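# Methods

This note documents the models, estimators, numerical choices, and
limitations of `shoal`. Units are meters, seconds, and m/s throughout.

## Study design being analyzed

The analysis chain targets pond telemetry experiments: a small school
(~10 fish) in a ~40 m x 25 m earthen pond, positioned in 2-D roughly every
1.3 s by an acoustic array, with a floating platform casting shade over one
of five candidate 5 m x 5 m squares ('a'–'e'); the platform moves to the
next square each trial. Every position belongs to one of three categories:
`shade_day` (daylight, under the active square, boundary inclusive),
`open_day` (daylight, elsewhere), and `night` (never split by location —
platform interaction at night is minimal). Day intervals come from the
trial schedule; nothing is hard-coded.

## Preprocessing

**Expelled transmitters.** For each fish, the magnitudes of consecutive
position increments are scanned with a sliding 1-h window (60-s hop,
prefix-sum implementation; windows need ≥ 2 increments). A window whose
standard deviation falls below 20% of the fish's overall increment sd flags
the trajectory, which is then dropped in its entirety. Two deterministic
rules replace the original study's visual inspection step: (1) a trajectory
whose total spatial extent is at most ten times its median increment
magnitude is dropped as stationary — this catches a tag that was already
on the bottom at the first detection, for which the purely relative 20%
rule is blind because its variability is uniformly low; (2) a trajectory
with numerically constant increments (overall sd below 1e-9 of the mean
increment) is kept with zero flagged windows — exactly uniform motion
carries no expelled-tag signature. The window length (3600 s), ratio
(0.2), and hop (60 s) are parameters.

**Detection gaps.** Inter-detection gaps strictly longer than 1 h split
the trajectory; the gap is excised and both flanking segments kept. A gap
of exactly 1 h is retained.

**Synchronization.** All fish are resampled onto a common grid (default
4 s, anchored at the floor of the earliest detection) by nearest-neighbor
interpolation. Ties between two equidistant detections resolve to the
earlier detection; a detection exactly halfway between two grid points
belongs to the earlier grid point. A grid point with no detection within
dt/2 is marked invalid rather than carrying a stale fix — this prevents
phantom stationary fish at the cost of a ~0.1% invalid rate at the 1.3-s
mean interval.

## Shade selection

Hourly occupancy is the fraction of detections inside the shade square per
clock-aligned 1-h window (empty windows omitted); the weighted mean of the
hourly fractions equals the global fraction by construction. The
random-movement baseline is area(shade ∩ pond)/area(pond) = 0.025 for the
default geometry. Preference is quantified by a maximum-likelihood
logistic regression of the binary under-shade outcome on a daylight
indicator, pooling all fish of a trial; with a single binary predictor the
MLE equals the empirical class-conditional proportions, so the probability
increment Δp = p̂(shade|day) − p̂(shade|night) is exact, with a Wald p-value
on the daylight coefficient. Complete separation (e.g. shade never entered
at night) is flagged; the increment then comes from the proportions and the
p-value is NaN. Observations are individual detections with no
autocorrelation correction — a deliberate statistical simplification that
overstates significance on strongly autocorrelated tracks; increments are
unaffected. The shifted-shade control reclassifies all positions against
the previous/next trial's square (from the rotation order) and refits; a
genuine platform preference produces a near-zero control increment.

## Speed and persistence

Speeds are ||Δposition||/Δt between *consecutive raw detections* (the
methods operate before any resampling), within runs that are homogeneous in
category and have all gaps ≤ 10 s (the telemetry's stated tail bound); only
runs of more than 50 observations are kept. Per category the package
reports mean ± SEM, Fisher moment skewness with a seeded 1000-replicate
bootstrap SE (the bootstrap is the package's choice; an exact SE for the
moment skewness of an unknown distribution is not available), and the
empirical complementary CDF (anchored at p(0) = 1). Group comparisons use
a seeded two-sided permutation test on pooled individual speed values with
the add-one estimate p = (1 + #{|T_perm| ≥ |T_obs|})/(n_perm + 1); the
pool is sorted and the larger group ordered first internally so the
p-value is exactly symmetric under label swap. Serial correlation within
segments is ignored by the permutation unit — a documented caveat, not a
bug.

**DFA.** The Hurst exponent of a speed segment: integrate the
mean-centered series into the profile Y(t); for each scale n, cut Y into
floor(m/n) forward non-overlapping blocks (trailing remainder dropped),
subtract an OLS line per block, and set F(n) = sqrt(mean squared
residual); fit log F(n) against log n by OLS over ~20 log-spaced integer
scales in [10, m/4] (deduplicated; scales with F = 0 excluded; at least 4
scales required). The square root is deliberate: the study's printed
formula omits the radical while naming F "root-mean-square"; without the
radical the fitted exponent would double, contradicting the quoted
h ≈ 0.5 behavior of uncorrelated series. Segments shorter than 128 samples
are skipped (too few scales for a stable fit). Calibration measured at
design time (length 4096, 100 replicates): mean ĥ within ~0.015 of the
truth for H ∈ {0.3, 0.5, 0.7, 0.9}, and ĥ ≈ 1.49 for integrated white
noise (theory 1.5). The shuffle control re-estimates h on seeded
permutations; persistent series collapse to ≈ 0.5.

## Order parameters

Directions u_i are unit forward displacements between consecutive 4-s
frames (computed on the synchronized grid, since synchronization is what
makes frame-level school quantities well defined). A fish is excluded from
a frame if invalid at either endpoint, if its displacement is zero, or if
it sits within 1e-12 (relative) of the school center of mass (r_i
undefined). Frames with fewer than five usable fish are skipped, extending
the study-level ≥ 5 fish rule to frames. O_p = |Σu_i|/N;
O_r = |Σ(u_i × r_i)_z|/N with r_i unit vectors from the center of mass of
the included fish. Both are hard-asserted into [0, 1]. A frame is
`shade_day` when at least half of the included fish are under shade (the
10% rule is specific to network windows). Distributions use a 50x50 joint
histogram on [0,1]² and Gaussian KDE (Scott bandwidth) marginals. Note the
finite-size floor: N random directions have E|Σu|/N ≈ sqrt(pi)/(2 sqrt N)
(≈ 0.28 at N = 10), so a disordered swarm never shows O_p ≈ 0.

## Interaction networks

Per frame, fish are linked when their Voronoi cells share a boundary,
computed as Delaunay adjacency (the exact dual for points in general
position). Unbounded cells still neighbor through their infinite ridge —
no clipping to the pond boundary (the package's convention; clipping could
only remove adjacencies between hull fish). Collinear, cocircular, or
duplicate configurations are resolved by a deterministic 1e-9 m jitter
(fixed internal seed) — far below telemetry accuracy. Frames with < 5
valid fish produce no graph but still count in the window denominator.

Windows are non-overlapping (default 600 s), anchored at the grid start.
w_ij = (#frames adjacent / #frames in window)/(N − 1) with N the number of
fish tracked in the trial (a trial constant, so κ keeps its [0, 1] meaning
when fish drop out of frames). A window is `night` when the majority of
its positions fall at night; a day window is `shade_day` iff strictly more
than 10% of its positions are under shade. Weighted degree κ_i = Σ_j w_ij
(∈[0,1]); k is the mean over all N fish, isolated vertices included.
Weighted transitivity follows the triangle-intensity form: normalize
ŵ = w/max(w) over the network, c_i = Σ_{j≠h}(ŵ_ij ŵ_ih ŵ_jh)^{1/3} /
(k_i^b(k_i^b − 1)) with k_i^b the binary degree (c_i = 0 for degree < 2),
C = mean over all N fish. This matches the NetworkX weighted clustering
coefficient, which serves as an independent cross-check in the tests. A
sensitivity routine re-runs the aggregation over Δt ∈ {5, 10, 20} min and
thresholds ∈ {5, 10, 20}%.

Two structural facts are worth knowing when interpreting k and C. With
full detection coverage, Σ_j (time fraction neighboring j) equals the mean
Voronoi degree of a fish, so k ≈ 2(3N − 3 − h̄)/(N(N−1)) where h̄ is the
mean number of hull vertices: k measures configuration *shape* (compact
blob → small hull → high k; perimeter-strung fish → large hull → low k),
and data dropouts lower it further. And because weights are max-normalized,
C is driven by the homogeneity of pair neighbor-fractions: a school whose
members mix smoothly shares neighbor time evenly (C high), while a frozen
configuration is just a triangulation (binary clustering ≈ 0.4) and
strongly uneven weights depress C.

## Synthetic school simulator

The generative model is invented plumbing — the study describes no
movement model — and is tuned only to realize the qualitative regimes the
analysis should recover; no resemblance to real Silver Carp beyond those
regimes is claimed.

**Kinematics.** Point agents with heading θ_i integrate at dt = 0.5 s with
speed from a per-fish series: mode-dependent mean (0.13 under shade, 0.23
roaming, 0.21 at night — the regime means seen in this kind of telemetry)
times a lognormal factor exp(σz − σ²/2), σ = 0.5, where z is exact
unit-variance fractional Gaussian noise at the configured target Hurst
exponent (default 0.65). Davies–Harte circulant embedding makes the fGn
exact, and the lognormal transform rescales the autocovariance by a
lag-independent factor, so the DFA exponent is preserved while speeds stay
strictly positive.

**Steering by mode** (gains are module constants, calibrated by simulation
scans at design time):

* *polarized/roam* — all fish relax toward a shared heading carrying small
  OU noise, steered off the walls near a 5-m margin; tight cohesion
  (radius 0.8 m) keeps a compact, internally mixing blob. Measured mean
  O_p ≈ 0.99 on truth tracks.
* *swarm* — strongly diffusing independent headings (2.6 rad/√s) with weak
  cohesion beyond 3 m; measured mean O_p ≈ 0.28–0.29, the finite-N floor.
* *milling* — headings track the counterclockwise tangent about a fixed
  center with a radial correction toward per-fish orbit radii 1.5–3.5 m;
  measured mean O_r ≈ 0.93.
* *night* — persistent headings (0.10 rad/√s), no cohesion; within 2 m of
  a wall fish follow it (thigmotaxis), leaving on average every 120 s to
  strike back across the pond. Perimeter-heavy, weakly coordinated
  exploration.
* *shelter* — outside fish transit straight to the shade square at roaming
  speed; settled fish cruise the square with moderate persistence
  (0.5 rad/√s), avoid its central 1.5 m (holding the light gradient near
  the platform edge), and reflect off the square's walls.

Walls are reflective (single bounce plus clip for the rectangular fast
path; nearest-boundary projection for general polygons), so no absorbing
states exist.

**Shade preference.** In the `mixed-schedule` state, nights use the night
mode and daylight alternates school-level sheltering and roaming bouts
with exponential dwells splitting a 40-min cycle p : (1 − p), so the
expected sheltered fraction of daytime equals `shade_preference_day`. The
alternation is school-level rather than per-fish: real schools select the
platform largely together, and group bouts are what produces both
`shade_day` and `open_day` windows downstream (a per-fish drift would park
>10% of positions under shade in every daytime window at any moderate
preference, extinguishing the open-day category). In short trials the
realized fraction is bout-noisy — by design, mirroring trial-to-trial
variability in real ponds.

**Measurement.** Detection times are gamma(shape 4, mean 1.3 s) renewal
intervals per fish (<0.2% of intervals exceed 10 s). Positioning error is
an Ornstein–Uhlenbeck process per coordinate with stationary sd 0.38 m and
60-s correlation time, sampled exactly at the irregular detection times.
The OU choice is deliberate: 0.38 m is the *marginal* accuracy, but white
noise of that size at 1.3-s spacing would generate ~0.3 m/s of apparent
speed from noise alone — more than the regime means — so consecutive-fix
error in the real system must be small and slowly drifting (stable
multipath geometry), which the OU model captures while preserving the
marginal sd. Noisy fixes outside the pond are projected back to the
boundary. `inject_transmitter_loss` freezes a fish at its loss location
plus 1-cm white noise (a motionless tag on the bottom positions very
repeatably), which is what makes the 20% variability rule able to fire.
All randomness derives from the config seed; runs are bit-reproducible.

**What the simulator does not emulate.** Detection dropouts correlated
with behavior or position, tag-code collisions in dense huddles, 3-D
depth, hydrodynamics, individual personalities, predators, or any
temperature/light response. Passing tests therefore demonstrate that the
estimators recover known ground truth under idealized sampling — not that
real fish behave like the model.

## Problem sizes used in tests

The test suite and acceptance checks run the simulator at desk scale —
trials of 0.5–8 h rather than 48 h, chosen so that every stage still has
hundreds of frames and tens of windows per category (e.g. an 8-h trial
yields ~220k detections, 7,200 frames, and 48 ten-minute networks). DFA
calibration uses series of length 4096 with 100 replicates per condition;
the Voronoi oracle comparison uses 1,000 random frames of 5–12 fish.

## Known limitations

* The logistic preference model treats autocorrelated detections as
  independent; p-values are anti-conservative (increments are unbiased).
* DFA on detection-derived speeds is attenuated toward 0.5 by measurement
  noise and irregular sampling (target 0.8 recovers ≈ 0.67 end to end);
  comparisons between categories remain well ordered.
* The permutation test permutes individual speed values, ignoring serial
  correlation within segments.
* Network k separates behavioral categories only through configuration
  shape (hull count) when detection coverage is complete; with patchier
  real data, dropouts would add further separation.
* Frame category uses a ≥ 50% under-shade rule and window category a
  majority-night rule; both are conventions where the source analysis is
  silent.
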