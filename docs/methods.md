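# Methods

This note documents the models, parameter choices and numerical
decisions behind `eventarena`, in the spirit of a statistical software
methods appendix. Nothing here reports an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Arena geometry and goal placement

Rooms are square, 40 × 40 arbitrary units (a.u.), with a 10 a.u. wall
height kept as metadata. The goal cube is 3 a.u.; a hidden goal becomes
visible when the navigator enters a circle of 7 a.u. diameter around it
and a trial ends inside a circle of 2 a.u. diameter (we read "within a
circle of 2 a.u." as a diameter, giving a 1 a.u. contact radius; this is
the reading consistent with requiring the visibility radius to exceed
the contact radius). Coordinates are continuous with the origin at a
fixed corner; all distances are Euclidean.

Old-goal (OPA) locations are rejection-sampled under three rules: at
least `wall_margin` = 3 a.u. from every wall (the box can be circled);
at least a 3-second walk from every starting corner; and approximate
even tiling of the floor, operationalized as a 6 × 6 occupancy grid
over the admissible floor with at most 2 locations per cell. Walking
speed is nowhere fixed by the paradigm description, so it is an
explicit `speed` parameter (default 4 a.u./s, making the 3-second rule
a 12 a.u. clearance — a mid-range walking speed for a 40 a.u. room
where typical start-to-goal distances are 15–30 a.u.). New-goal (NPA)
locations obey the same wall margin, a 3-second clearance from the NPA
start (the midpoint of the wall opposite the full-wallpaper wall), at
least 7 a.u. from the same room's OPA and at least 2 a.u. from every
other room's OPA. Rejection sampling is capped (default 10,000 draws)
and raises an explicit infeasibility error; with the default geometry,
36 + 36 locations are placeable in effectively every seed (verified
over 100 seeds in the test suite).

## The synthetic navigator

Motion is integrated at constant speed with a 0.1 s timestep, a bounded
turn rate (2π rad/s — the navigator turns in place quickly, as with
key-press steering), Gaussian heading noise per step (SD 0.08 rad), and
no backing up. Navigation is waypoint-directed:

- **Guided trials.** The agent aims at the goal plus an isotropic 2-D
  Gaussian error whose SD is its current *memory spread*; on reaching
  an aim point without the goal appearing, it draws a fresh estimate,
  falling back to an exhaustive sweep after 8 failed re-aims. Once the
  goal is visible it is approached directly.
- **Naive trials** (NPA block 1). By default the agent sweeps an
  Archimedean spiral around the room center whose pitch (85% of the
  visibility radius) guarantees the goal cannot slip between loops,
  followed by a serpentine sweep as a coverage backstop. With
  probability `luck_prob` the naive search instead takes a near-direct
  heading (small angular error toward the goal) — luck is a property
  of the heading, not of goal proximity.

Memory spread on hidden-goal training block *b* is
`base_precision · learning_rate^(b−2) · f_room · f_participant`, with
lognormal room and participant factors. Defaults: `base_precision` = 8
a.u., `learning_rate` = 0.85, `room_precision_sd` = 0.5,
`participant_precision_sd` = 0.25. These produce mean-PE learning
curves that fall from ≈ 2.3 in block 2 toward ≈ 1.05 by block 12 while
retaining room-to-room variability at the end of training — the
variability that the prior-knowledge analysis feeds on.

One-shot NPA memory spread (block 2) is multiplicative on the log
scale:

    log σ_NPA2 = log(npa_base) + β·z_room + u_participant
                 + luck_penalty·lucky1 + ε

where `z_room` is the room's standardized latent OPA precision, `β`
(`coupling_beta`) is the ground-truth schema coupling, `lucky1` flags a
lucky block-1 search (lucky finds are penalized: a near-miss encounter
teaches less than a deliberate search), and ε is Gaussian
(`npa_noise_sd` = 0.35). The participant-level term `u_participant` is
drawn *independently* of the OPA participant factor, so that at β = 0
the two phases are exactly unrelated and the null of the inference
stage is a true null; a shared participant skill factor would otherwise
induce a small between-participant confound that random intercepts do
not fully absorb. Block 3 spread is block-2 spread × 0.5.

`coupling_beta` defaults to 0.8, the moderate effect size calibrated by
the repository's power study (examples/tests sweep 0–0.8): at the study
scale of 16 participants × 36 rooms it yields ≈ 95% power for the
schema-benefit test at α = 0.05, comfortably above the 80% target,
while β ≈ 0.6 sits near the 80% boundary.

`luck_prob` defaults to 0.12; the lucky-shot fraction of naive searches
is then ≈ 12% of block-1 trials in simulated cohorts (reported by the
pipeline, not asserted, since it is cohort-specific).

### Two generation modes

`simulate_participant` integrates full trajectories and is the primary
generator: its logs flow through the same scoring code a real
experiment's logs would. `simulate_cohort` draws per-trial *path
lengths* from the identical aiming geometry (legs between memory
estimates until one passes within the visibility radius) without
timestep integration, plus a closed-form spiral arc cost for naive
searches. It exists because replicate-cohort Monte-Carlo — 200
cohorts of 16 × 36 for the type-I and power calibrations — is two
orders of magnitude too slow with stepwise integration. Fast-mode
trials carry the generator's lucky flag directly instead of a
Fréchet classification.

What the generator does *not* emulate: visual realism, wallpaper/face
stimuli, head-direction or velocity profiles of human steering,
fatigue and attention drift, and any dependence of search strategy on
room identity. Consequently, passing tests demonstrate that the
*pipeline* recovers the statistical structure it assumes — not that
human cohorts satisfy that structure.

## Trajectory scoring

PE uses the full start-to-goal-center distance as denominator even
though trials end at the contact radius, so a perfectly direct trial
scores slightly below 1; this matches the paradigm's ED definition and
is consistent across trials. Time-to-goal is measured from navigation
onset (after the fixed 8 s planning period on NPA trials). Under the
constant-speed agent, PE and time-to-goal correlate at r > 0.9.

Lucky-shot classification compares the trajectory with the straight
start-to-goal segment by **discrete Fréchet distance** (dynamic program
over the coupling lattice), after resampling both polylines at 0.5 a.u.
arc-length steps. Resampling removes vertex-density artifacts — the
classification is invariant to how densely a path was logged; the
resampler retains original vertices where the path turns so corners
and fold-backs survive. The cutoff is 3.5 a.u. — the radius at which
the hidden goal becomes visible, i.e. a path this close to optimal
cannot miss — and empirically corresponds to ≈ 15% excess path length,
while correctly catching zigzag paths that accrue ~30% PE on top of the
optimal line. Raw-vertex (unresampled) comparison is available via a
flag. For the regression stage, block-1 PE is decomposed per
participant into the lucky indicator and a residual PE, which is the
raw PE for non-lucky trials and the participant's mean non-lucky PE
for lucky trials (mean imputation keeps the two predictors orthogonal;
the exact coding is exposed in config).

## Prior-knowledge metrics

- **Day-1 criterion**: weighted mean PE over blocks 6–8 with weights
  0.15/0.25/0.6; pass iff strictly below 2.
- **OPA_recent**: block-12 PE per room, untransformed.
- **OPA_average**: weighted mean of blocks 9–12 with linear weights
  (1,2,3,4)/10 — "linear weighting toward the end of practice" — after
  Dixon's Q screening at the 95% level; weights are renormalized over
  surviving trials. At most one of four trials can ever be removed.
  The exact weighting scheme matters little (weighted and unweighted
  versions correlate ≈ 0.96 in simulated cohorts) and is config-exposed.
- **Dixon's Q** uses the classic two-sided r10 statistic — the gap
  between the most extreme value and its neighbor over the range,
  evaluated at the more suspect end. The critical value is *simulated*
  (10⁶ Gaussian null draws, cached per (n, α)) rather than read from a
  table, making the calibration auditable; at n = 4, α = 0.05 the
  simulated value reproduces the published two-tailed 0.829 and the
  empirical false-positive rate is 5% ± 1%.

## Inference

**Repeated-measures ANOVA.** One-way within-subject F with
Greenhouse–Geisser epsilon from the double-centered condition
covariance; corrected df are the uncorrected pair scaled by ε, with ε
clipped to its analytic bounds [1/(k−1), 1]. The implementation is
plain matrix algebra and is tested to 1e-8 against an independent
oracle (pingouin). The two-level condition × block comparison (old
vs. new goal learning rates) reduces algebraically to one-way tests on
condition means and per-block differences.

**Mixed models.** The engine fits variance-components models
y = Xβ + Σ_k Z_k u_k + e by REML on the profiled deviance, optimizing
the variance ratios γ_k = σ_k²/σ_e² with L-BFGS-B on log γ using an
analytic gradient; the Woodbury identity keeps each likelihood
evaluation O(q³) in the number of random-effect columns (q ≈ 100 at
study scale) rather than O(n³). Random slopes are independent of
intercepts (zero-correlation parameterization, lme4's `(0+x||g)`); the
paradigm description does not specify correlation structure and the
maximal slope set is config-exposed. Fixed-effect t-tests use
**Satterthwaite** df: df_j = 2·Var(β̂_j)²/(∇f' A ∇f), with the gradient
of the coefficient variance taken numerically over the variance
parameters and A the inverse negative Hessian of the REML
log-likelihood (finite differences with steps floored at 1e-5·σ_e² —
smaller steps lose the curvature of near-zero components to roundoff;
components estimated at the zero boundary are held fixed). df fall
back to the residual df n − p if the curvature matrix is singular.
Estimates, standard errors, variance components and df are verified
against R `lmerTest` (rel. 5% on df, much tighter on estimates) and
statsmodels `MixedLM` in the test suite; with all variances at zero
the fit reduces to OLS to 1e-4.

**Pruning.** The maximal model is fit first. It counts as unfittable
when the optimizer fails *or* a random-slope variance collapses to the
zero boundary (a singular fit — the analogue of lme4's singular-fit
warning; with a robust bounded optimizer outright failure is rare, so
the boundary is the operative trigger). One slope is removed per
round — interaction slopes first, then main-effect slopes in reverse
order of entry — and every removal is recorded on the result. Random
intercepts are never removed; an intercepts-only model that still
fails raises. A line-search abort at an already-converged optimum
(gradient below 1e-3, boundary components pushing inward) is not
treated as failure.

**Schema-benefit model.** `NPA2_PE ~ prior + lucky + residual_PE` with
crossed participant/room intercepts and maximal participant slopes on
all three predictors, pruned as above; `prior` is OPA_recent or
OPA_average by a switch. PE enters untransformed by default; a log-PE
option exists for heavy-tailed simulations. Activity models replace
the prior with a per-trial activity covariate (or add it, in omnibus
form), and a reversed form regresses activity on the prior, the
residual search efficiency and their interaction. No multiple-testing
correction is applied across ROI models; reports should (and the CLI
does) annotate this.

**Calibration at study scale** (16 × 36, fast generator, 200
replicates each, run in the acceptance suite): type-I error of the
prior coefficient at α = 0.05 under β = 0 lands in [0.03, 0.08]
(slightly conservative, as Satterthwaite tests often are); power at
β = 0.8 exceeds 0.9; null-coupling effect estimates center on zero.

## Degenerate inputs and numerical edges

Zero-range samples yield no Dixon outlier; identical PEs average to
themselves under any weights; polylines with repeated vertices are
deduplicated before resampling; trajectory CSVs are parsed with
round-trip float precision so logs survive a write/read cycle bitwise
to 1e-6; rank-deficient fixed-effect designs and single-level grouping
factors are rejected with explicit errors rather than fit.

## Known limitations

- The navigator's search strategies are the simplest ones that produce
  realistic polylines; no claim of cognitive realism is made.
- The REML engine supports independent variance components only — no
  intercept–slope correlations and no multivariate random effects.
- Absolute trial durations are simulator-defined (self-paced trials
  have no canonical speed), so only relative and ratio quantities are
  comparable across implementations.
- The activity covariate is a statistical stand-in coupled to the
  performance signal; it models no hemodynamics.
- Cohort-level human statistics (the original study's F and t values)
  depend on subject data that are not distributable and are outside
  what the simulation can or should reproduce.
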