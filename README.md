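# shoal

Analysis of how shaded environments alter the collective behavior of small
fish schools tracked by acoustic telemetry in experimental ponds.

Floating platforms anchored in earthen ponds cast shade that many fish
species select during daylight. Beyond *whether* fish choose shade, the
interesting question is how the school's behavior differs under the
platform, out in the open during the day, and at night: how fast fish move,
how persistent their speeds are, how aligned the school is, and how stable
each fish's local neighborhood remains. `shoal` implements that full
analysis chain for telemetry of ~10-fish schools positioned every ~1.3 s,
and bundles a synthetic school simulator with known ground truth so every
stage can be validated end to end without field data.

Intended users: movement ecologists and collective-behavior researchers
working with high-resolution positional telemetry of animal groups.

## What it computes

**Preprocessing** (`shoal.preprocess`). Expelled transmitters are detected
by the variability rule: the standard deviation of consecutive
position-increment magnitudes in a sliding 1-h window is compared to the
fish's overall variability, and any window below 20% flags the whole
trajectory. Tracks are split at detection gaps > 1 h, every position is
classified as `shade_day` / `open_day` / `night` (night is not split by
location), and all fish are synchronized onto a common 4-s grid by
nearest-neighbor resampling.

**Shade selection** (`shoal.occupancy`). Hourly under-shade occupancy
fractions against the random-movement baseline (shade area / pond area),
and a logistic regression of under-shade status on a daylight indicator.
The headline quantity is the probability increment

&nbsp;&nbsp;&nbsp;&nbsp;Δp = p(shade | day) − p(shade | night),

with a shifted-shade control that refits against the platform positions of
the neighboring trials, where a genuine platform preference must vanish.

**Speed and persistence** (`shoal.speed`, `shoal.dfa`). Speeds are computed
between consecutive raw detections within category-homogeneous runs of more
than 50 consecutive observations (gaps ≤ 10 s). Per category: mean ± SEM,
skewness ± bootstrap SE, complementary CDF p(v), and seeded permutation
tests for group differences. The Hurst exponent h of each speed segment is
estimated by detrended fluctuation analysis: integrate the mean-centered
series into the profile Y(t), linearly detrend non-overlapping blocks of
size n, compute F(n) = sqrt(⟨Y_n²⟩), and fit F(n) ∼ n^h by OLS in log-log
over ~20 log-spaced scales in [10, m/4]. h = 0.5 is an uncorrelated series;
h > 0.5 long-range persistence. A shuffle control confirms the persistence
lives in the temporal ordering.

**School order** (`shoal.order`). Per 4-s frame, with u_i the unit forward
direction of fish i and r_i the unit vector from the school center of mass,

&nbsp;&nbsp;&nbsp;&nbsp;O_p = |Σ u_i| / N &nbsp;&nbsp; (polarization),
&nbsp;&nbsp;&nbsp;&nbsp;O_r = |Σ (u_i × r_i)_z| / N &nbsp;&nbsp; (rotation/milling),

computed only for frames with ≥ 5 usable fish, plus joint histograms and
Gaussian-KDE marginals per category.

**Interaction networks** (`shoal.networks`). At each frame, fish whose
Voronoi cells share a boundary (Delaunay neighbors) are linked; graphs are
aggregated over non-overlapping 10-min windows into weighted networks with
w_ij = (fraction of frames adjacent) / (N − 1), so the weighted degree
κ_i = Σ_j w_ij lies in [0, 1]. Windows are `shade_day` when > 10% of their
positions are under shade. Reported per window: average weighted degree k
and the Onnela average weighted transitivity C (triangle intensities via
geometric means of max-normalized weights), with sensitivity re-runs over
window length and threshold.

**Simulator** (`shoal.simulate`). A zonal (repulsion/alignment/attraction
style) school model with presets for polarized, swarm, and milling states,
school-level shelter/roam alternation controlled by `shade_preference_day`,
per-fish speeds driven by exact fractional Gaussian noise with a target
Hurst exponent (Davies–Harte synthesis in `shoal.fgn`), gamma-distributed
detection intervals (mean 1.3 s), slowly-drifting positioning error
(marginal sd 0.38 m), and transmitter-loss injection.

## Worked example

Each script in `examples/` exercises one capability. For instance:

```
$ python examples/collective_order.py
polarized: <O_p> = 0.987  <O_r> = 0.091  P(O_p>0.9) = 0.99  P(O_r>0.9) = 0.00  (449 frames)
swarm    : <O_p> = 0.292  <O_r> = 0.180  P(O_p>0.9) = 0.00  P(O_r>0.9) = 0.00  (449 frames)
milling  : <O_p> = 0.270  <O_r> = 0.933  P(O_p>0.9) = 0.00  P(O_r>0.9) = 0.81  (449 frames)

finite-size floor for 10 random directions: sqrt(pi)/(2 sqrt(10)) = 0.280 (a disordered swarm cannot reach O_p = 0)
```

The three behavioral presets are cleanly separated by the two order
parameters: aligned schools reach O_p ≈ 1, milling schools O_r ≈ 1, and a
disordered swarm sits at the finite-size floor of O_p (≈ 0.28 for N = 10 —
random directions never sum exactly to zero).

```
$ python examples/shade_preference.py
...
logistic fit: p(shade|day)=0.477 p(shade|night)=0.001
probability increment = +0.476 (Wald p = 0)
control (previous trial's square): increment = +0.030
control (next trial's square): increment = +0.009
```

The school configured to shelter ~70% of daylight shows a large,
significant daytime shade preference, while the same fit against the
neighboring trials' (unshaded) platform positions collapses to zero — the
preference tracks the platform itself, not a corner of the pond.

See also `examples/simulate_and_preprocess.py` (quality filters catching a
shed transmitter), `examples/speed_persistence.py` (speed summaries, DFA
and shuffle control), and `examples/interaction_networks.py` (weighted
network metrics by category).

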