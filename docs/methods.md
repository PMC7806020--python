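# Methods

This note records the models, numerical choices, and limitations behind
the package, in the order a user meets them: the behavior policy, the
virtual arena, the metrics, and the transfer-entropy analysis.

## Behavior policy: a six-state Markov chain on a 1 Hz clock

The replica's controller is a discrete-time Markov chain over the joint
space (behavior × proximity) = {St, Sw, A} × {C, F}, indexed in the fixed
order (St-C, St-F, Sw-C, Sw-F, A-C, A-F). One chain tick is one second:
that is the rate at which live-predator videos are scored for calibration
and the only rate consistent with a 20-min open-loop schedule containing
1,200 events. No dwell-time constraint is imposed on the chain (the live
predator's ethogram requires 4 s of immobility to score "stationary", but
there is no basis for carrying that constraint onto the replica's policy).

**Calibration.** `build_transition_matrix` counts observed i→j transitions
and divides by departures from i. States never departed from get an
identity (absorbing) row — a conservative choice that keeps the matrix
row-stochastic — and are flagged in the matrix metadata so downstream code
can tell estimated rows from placeholder rows. Calibration segments are
chosen by `select_max_attack_window`, which scans every contiguous 1-min
window of the per-second attack-fraction series and returns the earliest
maximizer (deterministic tie-break).

**Stationary analysis.** `stationary_distribution` solves the linear
system π(P − I) = 0 with Σπ = 1 appended, rather than using raw
eigendecomposition, because the linear-system route directly yields a
real, nonnegative, normalized solution; the unit tests cross-check it
against the left-eigenvector route. Chains without a unique stationary
distribution (rank(Pᵀ − I) < n − 1, i.e. multiple closed communicating
classes) are rejected with an explicit error. Note that an irreducible
*periodic* chain still has a unique stationary vector and is accepted.

**Marginalization.** The open-loop three-state policy is obtained by
aggregating, for each behavior pair (b, b′), the joint transition mass
from both proximity variants of b into any variant of b′, weighted by the
stationary probability of each source state:

    M_OL(b, b′) = Σ_p [Σ_p′ M_CL((b,p), (b′,p′))] · π_CL(b,p) / π_OL(b).

This preserves stationarity: the stationary vector of M_OL equals the
behavior-marginal of π_CL (tested to 1e-6). A caveat worth recording: the
stationary vector of the *printed, 3-decimal-rounded* open-loop matrix
differs from the marginal of π_CL by up to ~0.002 purely from rounding;
tests compare through the exact marginalization route.

**Proximity classifier.** The central tank's 42 cm length is divided into
three half-open thirds [0, 14), [14, 28), [28, 42] with the origin on the
replica-side wall; the water column into halves with the midline assigned
to the lower half. The fish is close iff it is in the third adjacent to
the replica's tank *and* in the replica's vertical half. The half-open
conventions make every boundary decision unambiguous.

## Virtual arena

Coordinates: origin at the bottom corner of the central tank on the
replica side; x along the 42 cm length (0 at the replica-side wall), y
along the 30 cm width, z up from the base; units cm and seconds. The
lateral tank occupies x ∈ [−16, 0]. Water depth defaults to 15 cm — the
value that reconciles "five 3-cm depth bins" with a bottom section of
5 cm — and is configurable.

**Replica kinematics** (30 Hz, driven by the 1 Hz state stream):

- *Stationary*: descend at 3 cm/s to the bottom, then freeze.
- *Swimming*: track an elliptical horizontal orbit about the lateral-tank
  center, semi-axes 1.175 cm (x) and 5 cm (y) (axis lengths 2.35 and
  10 cm). The two printed nominal axis speeds (1.01 and 1.33 cm/s) cannot
  both be realized by a single elliptical phase rate, so the phase rate
  blends them: ω = (v_x/a_x + v_y/a_y)/2 ≈ 0.56 rad/s. Each swim second,
  the y-speed jitters by ±0.1 cm/s with probability 0.1, and the replica
  steps ±1 cm vertically with probability 0.2 (reflected at the surface
  and the base so the step magnitude is preserved). On entering the swim
  state away from the orbit, the replica approaches the current orbit
  point at a capped 6 cm/s, which keeps the trajectory continuous.
- *Attacking*: a constant-speed (default 3 cm/s, configurable — the
  attack's path is described but its speed is not specified anywhere)
  back-and-forth sweep along the wall adjacent to the central tank, 1 cm
  off the wall, at the current depth.

Behavior changes take effect instantly at each 1 Hz tick; an in-progress
attack sweep is truncated. Replica headings are not simulated (none of the
analyzed quantities depend on them).

**Fish model.** A bounded correlated random walk, chosen because the
analysis pipeline only needs realistic occupancy and kinematic statistics
plus a switchable robot→fish coupling — not a mechanistic swimming model.
Per 30 Hz frame: heading diffuses with sd 0.3 rad, speed ~ N(7, 2) cm/s
truncated at zero (matching typical zebrafish cruising speeds of
6–7 cm/s). The vertical velocity is bout-like: drawn once per second as
N(drift, 2) cm/s and held within the second, giving cm-scale vertical
excursions rather than sub-millimeter jitter (iid per-frame vertical noise
averages out over a second and would pin the fish to the floor). The
baseline vertical drift is −0.3 cm/s (mild bottom preference, the geotaxis
baseline), plus an extra −0.5 cm/s during habituation (novel-tank bottom
preference that relaxes once the observation starts). Walls reflect via
billiard folding of the within-second displacement.

**Escape coupling.** When the coupling gain g > 0 and the replica is
attacking in the current second, the fish receives an escape drift of
magnitude g × mean speed: vertically away from the replica's current
vertical half (weight `vertical_coupling`) and longitudinally away from
the replica-side third (weight `horizontal_coupling`). With g = 0 the
trajectory law is exactly independent of the robot's states (same rng
draws, bitwise-identical paths). Coupling is active only during the
observation window — during habituation a curtain hides the replica. The
default gain is 0.5 (escape drift 3.5 cm/s, i.e. a deliberate but not
panicked response); the study default couples vertically only, mirroring
the finding that the replica influences the fish's vertical and not its
horizontal position. In this generator the escape response applies in any
condition with a visible replica (control forces g = 0), so open-loop
trials also carry a detectable vertical information flow — unlike the live
animals; the closed-loop-specific acceptance scenario therefore uses
closed-loop trials only.

**Trial structure.** 16 min = 600 s habituation + 360 s observation;
robot states at exactly 1 Hz, trajectories at exactly 30 Hz; one seeded
`numpy` generator per trial, recorded in the trial metadata, making trials
byte-reproducible. In closed loop, the proximity fed to the chain at tick
t is classified from both agents' positions at the end of second t − 1.
Because the proximity component of the next joint state is overridden by
this live measurement, the realized joint sequence recovers only the
behavior-transition block sums of the joint matrix, not its full rows;
the tests check exactly that.

## Metrics

All positional series are smoothed before differentiation with a centered
moving average of 18 frames (0.6 s at 30 Hz). An even-order centered
window is realized the standard way, with half-weight end taps over 19
taps, which keeps the kernel symmetric and passes affine trends through
unchanged; at the series edges the window shrinks symmetrically. Speed is
‖Δx‖/Δt on smoothed positions; acceleration re-smooths the velocity
before differencing; turn rate is arccos of the normalized inner product
of consecutive velocities divided by Δt, with the cosine clamped to
[−1, 1] and frames below 1e-6 cm/s emitting no sample (NaN, excluded from
bin means). Bottom entries are counted on the smoothed depth series with
no hysteresis. The bottom section is the bottom third of the water column
(5 cm at default depth; both the fraction and the absolute height move
together when the depth is reconfigured). Metrics are computed on the
observation window only and averaged within three equal time bins (2 min
each at the default window; the bins rescale for shorter windows). In the
control condition the avoidance distance is measured to the geometric
center of the lateral tank's water volume, and replica occupancy values
are reported as missing.

## Transfer entropy

History length 1 for both processes and no embedding delay: the coarse
symbolization (1 body length, 1 Hz) is what makes that defensible. Fish
positions are down-sampled by decimation (every 30th sample, starting at
the first observation sample) and binned into half-open 3 cm bins, the
upper boundary belonging to the last bin; the robot series is the 1 Hz
behavior stream itself (no re-derivation from the trajectory). The
plug-in estimator counts (F_{t+1}, F_t, R_t) triples; 0·log(0) terms are
0 and no pseudo-counts are added. The estimate is a conditional mutual
information of the empirical joint, hence always ≥ 0, and is biased
upward at finite N — the surrogate test is what makes values
interpretable, since the null shares the bias.

The analysis window defaults to the 360-s observation window (360 samples
at 1 Hz). It is configurable: a 16-min trial analyzed over its full
duration gives ~960 samples, and "about 600 points" sits between the two,
so the window length is exposed rather than hard-coded.

**Surrogate test.** The observed statistic is the mean TE over the true
(fish_i, robot_i) pairs. Surrogates re-pair the fish series with a
uniformly random permutation of the robot series (identity permitted),
1,000 times by default; unequal series lengths are truncated to the
shorter of each pair. Since only pairings change, all N² pairwise TE
values are precomputed once and each permutation is a mean of table
lookups. Significance: observed mean ≥ 95% quantile of the null means,
with the additional requirement that the observed mean exceed the 5%
quantile so that a fully degenerate null (every re-pairing giving the
same mean, e.g. identical series) is never declared significant.

## What the simulations do and do not show

The generator reproduces the *statistical structure the analysis assumes*:
tank geometry, trial timing, 1 Hz policy ticks, 30 Hz tracking, bounded
stochastic swimming with bottom preference, and a causal, vertical-only
robot→fish coupling switchable by one parameter. It does not model
perception, memory, learned avoidance, thrashing/erratic bouts, or any
neuro-behavioral mechanism — so passing tests demonstrate that the
*pipeline* detects coupling when present at the configured strength and
stays at the nominal ~5% false-positive rate when absent, not that live
zebrafish behave like the model. Quantities measured on live animals
(χ² statistics, the activity table, figure values) are out of reach of
any simulation and are not targeted.

## Problem sizes used by the test suite

Chain-sampling checks use 10⁵ steps (occupancy estimator sd ≈ 0.007 given
the chain's second eigenvalue of 0.966). Estimator/oracle agreement is
checked on 200 random instances of length ≤ 50 with alphabets ≤ 4. The
type-I-rate check uses 200 replicates of 16 independent trial pairs of
360 samples. Coupling detection uses 16 full-length (16-min) closed-loop
trials per scenario with 1,000 surrogate permutations.
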