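# Methods

This document specifies the quantities `curiomap` computes, the statistical
models it fits, how the synthetic generators were designed, and the main
numerical choices.

## 1. Roaming entropy

For one trial, let `c_1 … c_k` be occupancy counts over `k` discrete bins and
`p_i = c_i / n` with `n` the number of retained samples. Roaming entropy is

```
RE = −Σ_{p_i > 0} p_i log2 p_i / log2 k     ∈ [0, 1]
```

0 means all time in one bin, 1 means uniform coverage of all `k` bins. A
degenerate bin space (`k = 1`) returns 0 by convention. Results may also be
reported on a 0–100 scale (`percent=True`).

**Path RE.** Rooms are square arenas (default 16 m × 16 m) discretised at
0.5 m, i.e. a 32×32 grid with `k = 1024` when unoccluded. Furniture-occluded
cells are inaccessible and excluded from `k`; samples landing in them (e.g.
tracker glitches) are dropped and the count reported. The cell of a sample is
`(floor(y/0.5), floor(x/0.5))`, with coordinates exactly on the far wall
clamped into the last cell.

**Head-direction RE.** Yaw ∈ [−180, 180) (relative to the room's entry
direction) and pitch ∈ [−90, 90] are binned at 10°×10°, giving a fixed
`k = 18 × 36 = 648` regardless of which bins are visited. Pitch exactly +90
is clamped into the top row.

## 2. Sketch-map scoring

Each sketch map (participant × room) is scored by two raters on four
dimensions — object presence (OP), spatial distortion (SD), relative
positioning (RP), spatial proportion (SP) — on a 1–5 scale in 0.5 steps. The
composite is the mean over dimensions of the per-dimension rater means, and is
invariant to rater and dimension order.

Inter-rater reliability per dimension is the two-way consistency intraclass
coefficient for a single rater (ICC(C,1), computed with `pingouin`), reported
alongside the Pearson correlation. Internal consistency of the four
dimensions (on rater-mean scores) is Cronbach's alpha,
`α = k/(k−1) · (1 − Σ item variances / variance of totals)` with sample
variances, plus a 93% nonparametric bootstrap percentile interval over units.

## 3. Design variables

Trial-level predictors (curiosity, interest, path RE, head RE) are separated
into a **within-person** deviation `x_w = x − person mean` and a
**between-person** component `x_m = person mean − grand mean of person means`.
Duration is grand-mean centred; trait subscales (Joyous Exploration,
Deprivation Sensitivity, Stress Tolerance, Thrill Seeking; 1–7) are centred
across participants. Incomplete trials are dropped listwise with a warning
and a recorded count; participants contributing a single trial are flagged
because their within-person deviations are degenerate zeros.

## 4. Multilevel models

All models are Gaussian (multivariate) linear mixed models,

```
y_i = B' x_i + U_{g(i)}' z_i + e_i,    e_i ~ N_d(0, Σ)
```

with participant random effects `vec(U_g) ~ N(0, T)`.

* **Exploration model** (bivariate, outcomes path RE and head RE): fixed
  effects curiosity_w, interest_w, curiosity_m, interest_m, duration_c per
  outcome; random intercepts and (by default) random within-person slopes;
  residuals correlated across the two outcomes (the residual correlation is a
  reported parameter). Evidence for a *double dissociation* is assessed by
  cross-outcome contrasts of the same coefficient (e.g. curiosity_w on
  path RE minus curiosity_w on head RE), computed draw-wise.
* **Moderation model** (outcome path RE): the exploration fixed effects plus
  the four centred traits and their interactions with curiosity_w; the
  Stress-Tolerance × curiosity_w interaction is the focal parameter.
* **Cognitive-map model** (outcome composite sketch score): curiosity,
  interest, path RE and head RE, each split within/between, plus duration.
* **Mediation**: two submodels with matched sampler settings —
  `path_re ~ curiosity_w + curiosity_m + duration_c` (path *a*) and
  `composite ~ curiosity_w + path_re_w + means + duration_c` (path *b*) —
  and the indirect effect as the draw-wise product `a·b` (never the product
  of posterior means, which is biased for skewed product distributions).

### Priors and sampler

No probabilistic-programming backend is assumed; the models are conjugate
throughout and sampled with a custom blocked Gibbs sampler (`curiomap.gibbs`):

* `vec(B) ~ N(0, diag(prior_sd²))`, prior SD 5 on intercepts, 1 elsewhere
  (weak next to coefficients of order 10⁻³–10⁻¹);
* `T ~ InvWishart(qd+2, 10⁻⁴ I)`, `Σ ~ InvWishart(d+2, 10⁻⁴ I)`.

The fixed effects are drawn with the random effects integrated out (a
partially collapsed update via the Woodbury identity), followed by the exact
conditional of the random effects — one joint `(B, U)` draw per iteration.
This removes the slow mixing between global and person intercepts that a
naive Gibbs scheme exhibits. Inverse-Wishart draws use the Bartlett
decomposition; multivariate normal draws use Cholesky solves of the canonical
(precision) form.

Default settings are 4 chains × 4800 iterations with the first half as
warm-up; a `reduced` preset (2 × 1200) serves tests and demos. Chains are
seeded via `numpy.random.SeedSequence.spawn`, so fits are reproducible given
a seed. Posterior summaries report the mean and the **93% highest posterior
density interval** (shortest window containing ⌈0.93·n⌉ sorted draws).
Convergence is gated on split-R-hat ≤ 1.01 and bulk ESS ≥ 400 (computed with
`arviz`) for every structural (fixed-effect) parameter; fits that fail carry
a visible warning and `converged=False`. Small random-effect SDs can mix
slowly without affecting the structural estimates; they are reported but not
gated.

## 5. Synthetic generators

Two generators cover complementary validation needs.

**Agent-based cohort** (`generate_cohort`). Rooms are generated by rejection
sampling of furniture rectangles keeping the accessible region 4-connected
(~30% occlusion). Each trial draws correlated latent *drive* and *interest*
states (person intercept SD 0.5, trial correlation 0.4) and walks a correlated
random walk at 3.4 m/s, 60 Hz: candidate headings (±100°, 9 options, scored
at a 1 m lookahead) are weighted by persistence, revisit avoidance rising with
drive, and a home pull and pausing probability falling with drive; gaze yaw
and pitch follow mean-reverting random walks whose innovation SD grows with
interest. Trait Stress Tolerance multiplies the drive→coverage coupling.
Ratings discretise the latents onto 1–10; durations are log-normal (mean 33 s,
SD 23 s). Sketch scores come from the drive latent plus the realised path RE,
with a person effect, per-dimension noise, and independent per-rater noise.
The rater noise SD (0.32) was set analytically so that single-rater ICC lands
near the 0.70–0.78 range typical of trained raters, before any test was run
against that band. This generator has the right *signs and orderings* but no
closed-form regression coefficients.

**Linear cohort** (`generate_linear_cohort`). Outcomes are drawn *exactly*
from the regression structure the models fit, using the realised within-person
deviations of the integer ratings, so every coefficient is known ground truth.
Default effect sizes are plausible published-scale values for this paradigm
(curiosity→path-RE 0.0039, interest→head-RE 0.0058, residual correlation
0.34, Stress-Tolerance moderation 0.0041, path-RE→composite 0.80, implying an
indirect effect of 0.0031). Residual SDs (0.05 path, 0.04 head, 0.30
composite) were chosen by an a-priori power calculation: at n = 60×16 with
rating SD ≈ 1.9, the posterior SD of a within-person slope is roughly
`sd_e / (sd_rating · √n) ≈ 0.0009`, so the focal contrasts sit ≈ 4 posterior
SDs from zero — estimable but not trivially so. `LinearEffects.null()` zeroes
every structural effect for interval-calibration checks.

## 6. Problem sizes and runtime

Typical sizes: 60 participants × 16 rooms = 960 trials; trajectories of
~2000 samples per trial (60 Hz × ~33 s). The walker costs ~40 µs per sample;
a reduced-preset bivariate fit on 960 trials takes ~15–25 s; the full preset
takes a few minutes. `scripts/acceptance.py` completes in ~3 minutes.

## 7. Limitations

* The printed human-study coefficients cannot be recomputed here because the
  study dataset is download-gated; the corresponding acceptance test fails
  with an explanatory message rather than skipping (see
  `tests/test_acceptance.py::test_criterion_8_...`).
* The sampler assumes Gaussian outcomes; RE is bounded in [0, 1], which is
  harmless at the observed effect scales but matters for RE near the bounds.
* The agent model is a calibration device, not a cognitive model; its
  parameter values were fixed a priori and never tuned against test outcomes.
* Random-effect covariances use weakly-informative inverse-Wishart priors;
  with very few participants (< ~10) these priors become influential.
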