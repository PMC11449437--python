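# hydrataxis

Analysis and generative modelling of satiety-dependent phototaxis in the
freshwater cnidarian *Hydra vulgaris*.

Starved hydras placed in a lane chamber reliably somersault their way to a
light source within 8 hours; recently fed animals mostly do not. This
package is for quantitative behavior researchers who want to dissect that
kind of goal-directed locomotion into its elements. It decomposes each
pose-tracked animal into three parameters —

* **head orientation** θ ∈ [0°, 180°], the angle between the foot→hypostome
  vector and the foot→light vector,
* **jump distance** *d*, the Euclidean foot displacement across a
  somersault, and
* **jump rate** λ = N_h / T_h, the Poisson intensity of somersaults
  (pooled over a cohort as Σ N_h / Σ T_h),

— fits a generative model, and simulates phototaxis as a **biased correlated
random walk** (BCRW) with Poisson-timed jumps:

    θ_{t+1} = wrap( w·(Ω_T + φ) + (1 − w)·(θ_t + δ) )        heading, Ω_T = 0 toward the light
    P(jump in dt) = 1 − exp(−λ·dt)                            jump decision
    d ~ KDE(D)  on a jump, else 0                             jump distance
    foot moves d along the heading; stop at threshold or 8 h

with bias weight *w*, persistence weight 1 − *w*, truncated Student-t noise
terms φ and δ, and *d* drawn from a boundary-reflected Gaussian KDE of the
pooled empirical jump distances *D*. Starved and fed groups share every
parameter except λ (fed animals are an active/inactive mixture) — and that
single difference is enough to reproduce the starved/fed contrast in
simulation. Group comparisons use the common-median test (the circular
analogue of the Kruskal-Wallis test) for θ and the Mann-Whitney U test for
*d* and jump counts. A first-class synthetic-data module renders simulated
cohorts as pose-estimation CSV files with known ground truth, so the entire
pipeline is testable without any recordings. See `docs/methods.md` for the
full model description and design rationale.

## Worked example

Generate a small synthetic experiment (10 starved + 10 fed animals,
rendered as 8 h of 1 frame/s pose tracking), extract the behavioral
parameters, fit the model, re-simulate and test the group contrasts — all
in one command:

```sh
cat > demo.yaml <<'YAML'
extraction:
  px_to_mm: 1.0
simulation:
  n_starved: 10
  n_fed: 10
YAML
hydrataxis pipeline --config demo.yaml --seed 7 --out demo_run
```

This prints (abbreviated):

```json
{
  "fed_active_fraction": 0.4,
  "lambda_hat": {
    "fed_active": 1.0001389081816918,
    "fed_inactive": 0.16669078281001304,
    "starved": 2.050284761772469
  },
  "observed_crossing_fraction": {"fed": 0.5, "starved": 1.0},
  "simulated": {
    "fed":     {"crossing_fraction": 0.2, "n": 10},
    "starved": {"crossing_fraction": 1.0, "n": 10}
  },
  "tests": {
    "distance_mwu": {"pvalue": 0.38388317199197264, "...": "..."},
    "njumps_mwu":   {"pvalue": 0.0001746242085521927, "...": "..."},
    "theta_cmtest": {"pvalue": 0.08228082788061691, "...": "..."}
  }
}
```

Reading the numbers: the recovered jump rates (`lambda_hat`, jumps per
hour) separate starved animals (~2.1/h) from the active (~1.0/h) and
inactive (~0.17/h) fed subpopulations; every starved animal crossed the
phototaxis threshold within 8 h while half the fed animals did. The jump
count comparison is highly significant (Mann-Whitney p ≈ 2·10⁻⁴), while
head orientation (common-median test) and jump distance are not
(p ≈ 0.08 and 0.38) — only the jump rate distinguishes the groups. The run
directory holds the generated pose file, ground truth, per-animal
summaries, fitted parameters, the report and a manifest; rerunning with the
same seed reproduces `report.json` byte for byte.

The same stages are available individually (`hydrataxis synth | extract |
fit | simulate | stats`, see `--help`) and as library functions:

```python
import hydrataxis as hx
geo = hx.ChamberGeometry()                      # 50 x 5 mm lane, light at x=0
trajs = hx.simulate_cohort(hx.default_params(), "starved", 30, geo, seed=1)
sum(t.crossed for t in trajs)                   # -> 29
```

## Pose CSV dialect

Three header rows (`scorer` / `bodyparts` / `coords`), then one row per
frame. The first column is the frame index; an `individual` and a `group`
column identify the animal (multi-animal files are consecutive row
blocks); each tracked body part (`foot`, `body`, `head` — aliases such as
`basal_disk`/`hypostome` are accepted) contributes `x,y,likelihood`
columns. Coordinates are converted to mm with the mandatory
`extraction.px_to_mm` config scale. `examples/config.yaml` documents every
configuration key and its default.

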