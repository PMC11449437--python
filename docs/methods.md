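# Methods

This note documents the model, the estimation procedures, the synthetic-data
generator and the numerical choices behind `hydrataxis`. It is the package's
account of its own science; every number quoted here is computed by the test
suite or by `scripts/acceptance.py`.

## The behavioral decomposition

*Hydra vulgaris* locomotes by somersaulting: the animal anchors its foot
(basal disk), sways its body column, then tumbles in the direction its head
(hypostome) was pointing and reattaches the foot at a new site. Phototaxis in
a lane chamber with a light panel at one end is decomposed into three
per-animal quantities:

* **Head orientation** `theta`: the unsigned angle between the foot-to-head
  vector and the foot-to-light vector, in [0°, 180°]. Internally a signed
  version in (−180°, 180°] is used, measured from the toward-light direction
  (the −x axis; the light source is modelled as the plane x = 0), positive
  toward +y. 0° means pointing straight at the light, 180° directly away.
* **Jump distance** `d`: the Euclidean displacement of the foot across a
  somersault, in mm.
* **Jump rate** `lambda`: the Poisson intensity of somersaults, estimated per
  animal as `N_h / T_h` (jumps per hour over the observation window) and
  pooled across a cohort as `sum(N_h) / sum(T_h)`, the maximum-likelihood
  estimate for merged Poisson observations.

An animal has performed phototaxis when its foot first comes closer to the
light plane than the phototaxis threshold (10 mm by default, configurable)
within the analysis horizon (8 h).

## The generative model

Time advances in steps of `dt` (default 20 s, matching the extraction
cadence of one retained frame per 20 s of 1 frame/s video, so simulation and
extraction share a time base). Each iteration performs three updates:

1. **Heading: biased correlated random walk (BCRW).** With bias weight
   `w` in [0, 1] and target direction `Omega_T = 0` (toward the light, by
   construction of the heading frame):

       theta[t+1] = wrap( w*(Omega_T + phi) + (1-w)*(theta[t] + delta) )

   `phi` and `delta` are independent noise draws, each from a Student-t
   location-scale distribution truncated to [−180°, 180°] and renormalised
   (angular noise has no meaning outside the circle). `wrap` maps to
   (−180°, 180°]. The convex combination is wrapped linear angle arithmetic,
   not a weighted circular mean; the two agree in the small-angle regime the
   walk spends nearly all its time in, and the linear form makes the pure
   limits exact: `w = 1` with zero noise snaps the heading to the light in
   one step, `w = 0` with zero noise preserves the initial heading forever.
   Heading updates happen at every iteration, whether or not a jump occurs.

2. **Jump decision: Poisson process.** A jump occurs with probability
   `p = 1 − exp(−lambda · dt)` per step, independently across steps. This
   per-step Bernoulli discretisation gives exactly Poisson(`lambda·T`)
   jump counts over a horizon `T` (verified by a chi-square goodness-of-fit
   on 1000 simulated animals), and is preferred over exponential waiting
   times because the heading state must advance every step anyway.

3. **Position update.** On a jump, the distance is drawn from the pooled
   jump-distance KDE (below) and the foot moves that distance along the
   absolute direction obtained by rotating the toward-light direction by the
   current heading; without a jump the displacement is zero. Lane walls
   reflect the endpoint in y and clamp x to [0, lane_length], so distance to
   the light never increases through a wall.

A simulated animal starts with its foot uniform in the start zone (23–35 mm
from the light) and across the lane width, and an initial heading uniform on
the circle. Starved and fed animals share every parameter except the jump
rate: fed animals are a two-component mixture, assigned "active" with
probability `fed_active_fraction` before simulation and given
`lambda_fed_active` or `lambda_fed_inactive`. Simulation stops at the first
threshold crossing or at the 8 h horizon, whichever comes first.

### Default parameters (the synthetic study conditions)

| parameter | default | why |
|---|---|---|
| `w` | 0.8 | strong but imperfect light attraction; heading changes concentrate near 0°, matching the qualitative description of the observed walk |
| `phi` noise | t(mu=0, sigma=30°, nu=5), truncated ±180° | heavy-tailed scatter of the bias term |
| `delta` noise | t(0, 10°, 5), truncated ±180° | small persistence noise: the head does not jump around between frames |
| `lambda_starved` | 2.0 h⁻¹ | with a ~4.4 mm mean jump this reproduces the ~0.8 cm/h crawl speed reported for the animal and brings starved animals to the light comfortably within 8 h |
| `lambda_fed_active` | 0.8 h⁻¹ | active-but-slower fed subpopulation |
| `lambda_fed_inactive` | 0.1 h⁻¹ | animals that barely translocate (≤3 jumps per 8 h with high probability) |
| `fed_active_fraction` | 0.5 | roughly half of fed animals are inactive |
| jump distances | 22 values, 2.0–8.1 mm, mean 4.43 mm | a somersault displaces the foot by at least about one body length; sub-millimetre displacements are attachment jitter, not jumps |
| `dt` | 20 s | the extraction cadence |
| horizon | 8 h | the analysis window |

Geometry defaults: lane 50 × 5 mm, light plane at x = 0, phototaxis
threshold 10 mm, start zone 23–35 mm, 1 frame/s. None of the lane
dimensions or the threshold are dictated by data; all are configuration.

## Estimation

* **Rates.** `lambda_starved` pools the whole starved cohort. Fed animals
  are first classified by the extracted jump count: "inactive" iff
  `N_h ≤ 3` per 8 h (configurable cutoff), then pooled per subclass;
  `fed_active_fraction` is the observed share of active animals. Note the
  classification truncates the inactive subclass at 3 events, so with ~25
  inactive animals at 0.1 h⁻¹ the estimate rests on roughly 20 events and
  carries a ~20% sampling error — recovering this rate is intrinsically the
  noisiest part of the fit.
* **Jump distances.** Starved and fed distances are statistically
  indistinguishable, so they are pooled and fitted with a Gaussian-kernel
  KDE with boundary reflection at zero (distances are positive):
  `pdf(x) = mean_i[ N(x; x_i, h) + N(x; −x_i, h) ]` for x ≥ 0. The
  bandwidth defaults to Silverman's rule `0.9·min(sd, IQR/1.34)·n^(−1/5)`.
  Sampling draws a datum uniformly, adds N(0, h) and reflects at zero.
* **Heading noise.** A single truncated-t location-scale law is fitted by
  maximum likelihood (Nelder-Mead on (mu, log sigma, log nu), three start
  values of nu, renormalised truncated likelihood) to the pooled observed
  per-step heading changes and used for both `phi` and `delta`.
* **Bias weight.** `w` is not directly identified by any of the above;
  `calibrate_w` scans a grid, simulating heading chains at each candidate
  and minimising a discrepancy against the observations (common random
  numbers across the grid; ties resolve to the smaller `w`). Given only
  heading changes the discrepancy is their Kolmogorov-Smirnov distance —
  but when the noise law was itself fitted to those observed changes this
  is degenerate: a pure random walk (`w = 0`) driven by that noise
  reproduces the change distribution exactly. Supplying the observed
  heading *levels* switches the discrepancy to the difference in the
  variance ratio `Var(changes) / Var(levels)`. For this heading process
  the noise terms are independent of the current heading, so the lag-one
  autocovariance of the heading is `(1−w)·Var(theta)` and the ratio equals
  `2w` whatever the noise laws are — the calibration is thereby robust to
  the single fitted noise law standing in for the two distinct generating
  noise terms, and recovers the generating `w` exactly on a 0.05 grid in
  the end-to-end tests. (The ratio uses linear variances of wrapped
  angles; for walks concentrated well inside ±180° the wrapping is
  immaterial, and the simulation-based comparison applies the same
  distortion to both sides in any case.)

## Statistics

* **Head orientations** are compared with the common-median test, the
  circular analogue of the Kruskal-Wallis test: with the pooled circular
  median `m_hat`, `m_i` counts the group-i angles on the negative side
  (signed circular distance < 0; angles exactly at the median count as
  non-negative), and

      P = N²/(M(N−M)) · sum_i m_i²/n_i − N·M/(N−M),   M = sum m_i,

  referred to chi-square with k−1 degrees of freedom. The circular median
  minimises the mean absolute circular distance; the objective is piecewise
  linear with breakpoints at the data and their antipodes, so the minimiser
  is found exactly on that candidate set (O(n log n) with prefix sums), with
  exact ties broken by the circular mean of the tied candidates.
* **Jump distances and jump counts** are compared with the two-sided
  Mann-Whitney U test, reported as `U = min(U_x, U_y)`: exact null
  distribution when the combined sample is ≤ 16 and tie-free, otherwise the
  normal approximation with tie and continuity corrections (delegated to
  scipy; an independent full-enumeration oracle in the test suite verifies
  the exact branch for every sample-size pair up to combined size 10).

## Extraction from pose tracks

Pose CSVs carry (x, y, likelihood) per frame for foot, body and head.
Rows where any likelihood falls below the confidence cutoff (default 0.6)
are dropped — an automated stand-in for manually relabelling mislabelled
frames — then tracks are downsampled to every 20th retained frame.

Jumps are detected as runs of consecutive inter-sample foot displacements
exceeding `epsilon` (default 1.0 mm): each maximal run (runs separated by
fewer than `min_dwell` = 2 quiet samples are merged, since the foot has not
settled) becomes one event from the last pre-run sample to the first
post-run sample, and events whose net displacement is ≤ `epsilon` are
discarded. The threshold sits well below a somersault (several mm) and well
above attachment jitter (sub-mm). `T_h` is the elapsed time of the analysed
window, `min(observation span, 8 h)`.

The per-sample theta series pools all retained frames by default; a
`pre_jump_only` option restricts it to the sample immediately preceding
each jump.

## The synthetic-data generator

`generate_cohort` runs the model for starved and fed cohorts and renders
each trajectory as a full-resolution pose track (1 frame/s, 28 800 frames
for 8 h): the foot at the simulated location, the head one body length
(3 mm) away along the current heading, the body column at the midpoint,
each with isotropic Gaussian tracking jitter (sigma 0.05 mm) per point per
frame, and a configurable fraction (2%) of corrupted frames whose body
point is teleported and flagged with low confidence. Where a full body
length does not fit in the lane along the heading, the rendered body is
contracted against the wall rather than clipped: contraction preserves the
head *direction*, so the extracted orientation equals the simulated
heading everywhere (clipping the head into the lane would distort the
orientations of exactly the animals sitting at the light-end wall and
fabricate a spurious group difference). The heading advances
every model step even while the foot is stationary, so theta extraction is
exercised independently of jumps. A ground-truth record (per-animal group,
subclass, true rate, injected jump times/distances, heading series, seeds)
is serialised next to the pose file.

Two deliberate departures from the bare model in the generator:

* **No threshold termination.** Real recordings continue after an animal
  reaches the light; the generator renders the full horizon so that
  extracted jump counts reflect the full-window rates the fit expects.
* **Mirrored walls during rendering.** Post-arrival animals live at the
  light-end wall, where endpoint clamping would convert sampled jumps into
  near-zero phantom displacements and depress every recovered rate by
  about a third. In the generator a jump that would exit the lane is
  therefore mirrored back inside at full length — the animal cannot attach
  beyond the wall and tumbles back. The model proper keeps clamping (which
  guarantees monotone descent in the deterministic limit); it never enters
  the post-arrival regime because it terminates at the crossing.

What the generator does *not* emulate: body posture dynamics between
somersaults (sway, contraction, nodding), multi-frame somersault kinematics
(a jump is instantaneous between adjacent frames), tracking failures that
persist over many frames, optical-gradient strength, and any post-arrival
behavior change (simulated animals keep the same walk near the light).
Passing tests therefore demonstrate internal consistency of the pipeline
and correctness of the estimators under the model's assumptions, not
performance on real video-derived tracks.

At the 20 s observation cadence, two jumps in adjacent (or near-adjacent)
steps are indistinguishable from one longer somersault; the ground truth
exposes `observable_events()`, which merges such runs exactly as the
detector must see them, and recovery tests compare against that record.

## Numerical choices and degenerate inputs

* Angles are held in degrees and wrapped to (−180°, 180°] with the boundary
  mapping to +180.
* Noise sampling is rejection from the untruncated t location-scale law;
  all samplers are deterministic given a `numpy` Generator or integer seed,
  and cohort simulations derive per-animal seeds from the cohort seed via
  `SeedSequence`.
* The truncated-t fit refuses samples with zero spread, fewer than 10
  points, or values outside the truncation bounds; optimizer failure from
  all start points raises a fit error naming the starts.
* The common-median test refuses data entirely on one side of the pooled
  median, and warns when any group has fewer than 5 angles.
* `fit_model` raises if a fed activity subclass is empty unless explicitly
  allowed (`allow_empty_subclass`), in which case the missing rate is 0 and
  the fraction reflects the observed split.
* Problem sizes in the test suite (cohorts of 50+50 animals for end-to-end
  recovery, 1000 animals for the Poisson law, 200 replicates for test
  calibration, 100 replicate seeds for the satiety contrast) are chosen so
  each check has clear statistical resolution while the whole suite runs in
  a few minutes on one CPU.

## Known limitations

* Eqs. of the heading update are a reconstruction from a verbal
  description; adding noise inside each weighted term (rather than after
  mixing) is a modelling choice, as is linear-wrapped rather than circular
  averaging.
* The inactive-fed rate estimate is information-limited (see Estimation).
* Boundary behavior (reflection, clamping, mirroring) is a construction;
  nothing in the source data constrains wall interactions.
* The 48 h scale of the original recordings is out of scope; everything
  here concerns the first 8 h.
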