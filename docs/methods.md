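# Methods

This note documents the models, algorithms and design choices behind
`nodcycles`, in the package's own terms.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Terminology and segmentation

A **nod** is one or more continuous vertical head movements, beginning and
ending at rest, regardless of whether it starts upward or downward.  A
**half-cycle** is a single monotone movement between inflection points; a
**cycle** is a pair of consecutive opposite-direction half-cycles, and an
odd trailing half-cycle also counts as a cycle, so N half-cycles yield
⌈N/2⌉ cycles.  A cycle's **magnitude** is the highest minus lowest pitch
(degrees) within it — twice the amplitude of an idealized cosine.  A nod's
**length** is its number of cycles; a cycle's **position** its 1-based
index.

Segmentation operates on head pitch from the OpenFace convention
(`pose_Rx`, radians, downward-positive), sign-inverted and converted to
degrees so that upward motion is positive.  The pipeline is:

1. **Smoothing.** Centered moving average with an odd window (frames);
   window 0 (or 1) disables smoothing.  At segment edges the window shrinks
   to the available frames, so the segment keeps its length.  The default
   window is 5 frames; `select_window_size` re-derives a window by
   minimising the mean absolute error (MAE) between estimated and manually
   annotated half-cycle counts over an annotated subset, breaking ties
   toward the smaller window (less waveform distortion).
2. **Inflection detection.** Points where the sign of the first difference
   flips.  Zero differences inherit the most recent nonzero sign (a leading
   zero-run takes the first nonzero sign), so plateaus never generate
   spurious inflections.  Half-cycle count = inflections + 1.  Single-frame
   segments cannot be differenced and are flagged `too_short`.
3. **Cycle assembly and magnitude.** Half-cycles are paired in order;
   boundary frames are shared between adjacent cycles, and magnitude is
   computed on the *smoothed* series so extremes stay consistent with the
   detected boundaries.  (Whether to measure on raw or smoothed pitch is a
   genuinely open choice; smoothed keeps the magnitude and the boundaries
   mutually consistent and is what the round-trip tests exercise.)
4. **Exclusions**, applied per nod with precedence
   `too_short > magnitude_gt_90 > zero_magnitude > length_gt_5`:
   a nod is dropped entirely if any cycle exceeds 90° (head-pose
   misestimation) or has magnitude exactly 0 (motion too small to detect,
   or segmentation slack), and nods longer than 5 cycles are excluded from
   the modelling table (they are rare and leave the power-law terms poorly
   constrained).  Exclusion is nod-level, not cycle-level, because a bad
   cycle casts doubt on the whole nod's segmentation.

Frames are 0-based; segments half-open `[start_s, end_s)`; the starting
direction (up- vs down-nod) is recorded but unused by the models, which
pool both kinds.

## 2. The magnitude model

For cycle `i` with magnitude `y_i` (degrees, > 0):

    y_i ~ Gamma(k, mu_i / k)          mean mu_i, variance mu_i^2 / k
    log mu_i = fixed(position_i, length_i) + alpha_n[nod(i)] + alpha_p[part(i)]
    alpha_n ~ Normal(0, sigma_n),  alpha_p ~ Normal(0, sigma_p)

Cycles from the same nod share an intensity baseline, and participants
differ in how vigorously they nod; the two random intercepts absorb that
non-independence.  The fixed part is

    fixed(q, l) = a-term + b-term * g(q) + c-term * final

with `g(q) = q - 1` (linear declination) or `q^2 - 1` (quadratic variants),
`final = 1` iff `q = l`, and for `l = 1` only the a-term.  Each of a, b, c
is either constant or a power law of length:

    a_l = alpha_a + beta_a (l - 1)^gamma_a     (base length 1)
    b_l = alpha_b + beta_b (l - 2)^gamma_b     (base length 2)
    c_l = alpha_c + beta_c (l - 2)^gamma_c     (base length 2)

`alpha` is exactly the value at the base length; to preserve that for every
admissible exponent we define `0^gamma := 0` including `gamma = 0` (the
resulting discontinuity in `gamma` at the base is measure-zero under the
continuous prior).  `gamma >= 0` keeps the direction of `beta` meaningful;
`0 < gamma < 1` with `beta > 0` gives a monotonically increasing, concave
length profile.  The catalog holds models 1–8 (all constant/varying
combinations, linear g) and models 9–10 (quadratic g with varying `a`,
constant or varying `b`); the count of fixed-effect scalars (3–9) is the
parameter count used for parsimony comparisons.

Priors: Normal(0, 10) on a, b, c, alpha, beta; the exponents get the same
normal truncated to `[0, inf)` — i.e. half-Normal(0, 10) — which is the
natural reading of "Normal prior + non-negativity constraint";
half-Cauchy(0, 5) on `k`, `sigma_n`, `sigma_p`.  A parameter is reported as
*significant* when its central 95% credible interval excludes zero.

## 3. MCMC engine

No probabilistic-programming backend is used; the sampler is written
in-package as a Gibbs sweep of slice-sampling updates (step-out/shrinkage,
Neal 2003), which is derivative-free and tuning-robust:

* **Fixed-effect scalars** and `k` from their full conditionals (`k` and
  the random-effect scales on the log scale with the Jacobian term; the
  exponents bounded below at 0).  Slice width 0.5 (0.3 on log scales).
* **Random intercepts** are conditionally independent given the globals, so
  all nod intercepts are updated in one vectorized slice-sampling pass
  (per-group likelihoods via `bincount`), likewise participants.
* **Translation move.** Coordinate-wise Gibbs mixes the global intercept
  against the mean of thousands of random intercepts very slowly.  The
  likelihood is invariant under `intercept += delta, alpha_group -= delta`,
  and along that line the priors are jointly Gaussian, so `delta` is
  sampled exactly and applied — one conjugate step per grouping per sweep.
* **Power-law ridge moves.** Within a varying triple, `(beta, gamma)` is
  strongly correlated: the likelihood constrains `beta * d^gamma` over the
  few observed length offsets `d`.  Two extra moves per sweep address this:
  slice updates along random directions in the triple's 3-D subspace, and a
  reparameterized update of `gamma` holding `r = beta * d_ref^gamma` fixed
  (with the `d_ref^-gamma` Jacobian), where `d_ref` is the geometric mean
  of the positive offsets in the data — the curve pivots about the
  best-constrained point instead of crawling along the ridge.

Draw bookkeeping follows thinning-era conventions: `iterations` total
sweeps, `warmup` discarded, every `thin`-th retained.  The **paper profile**
is 8 chains, warmup 1000, 4000 iterations / thin 3 (5000 / 4 for models 3,
8, 9, 10), i.e. 1000 draws per chain, 8000 total.  The **fast profile**
(4 chains, 1000 warmup + 1000 retained, thin 1) is the default for tests
and the recovery study; with the moves above it passes the convergence
criterion on the recovery problem while keeping a full fit to a few minutes
on one CPU.  Chains are seeded from a `SeedSequence` spawned per chain, so
runs are bit-for-bit reproducible; initial states are overdispersed across
chains.  Convergence requires all split-Rhat (arviz) below 1.05, strictly;
`check_convergence` lists offenders and can abort downstream use.  Per-draw
random intercepts and the (draws × observations) log-likelihood matrix are
retained (float32) for LOO.

The log-scale linear predictor is clipped at ±30 before exponentiation —
far outside any plausible posterior region, it only guards against
overflow during early warmup.

## 4. Model comparison

Expected log pointwise predictive density (elpd) is estimated by
Pareto-smoothed importance-sampling leave-one-out cross-validation
(arviz `loo`, standard tail rule; observations with Pareto k > 0.7 are
flagged).  For each model the difference from the highest-elpd model and
its standard error are computed from the *pointwise* elpd differences
(`se_diff = sd * sqrt(n)`; the exact convention of the reference tooling is
not documented, this is the standard one).  A model is significantly worse
when `|elpd_diff| > 1.96 * se_diff`.  Selection: among the best model and
all models not significantly worse, take the fewest fixed-effect scalars,
ties to the lower model id.  Random-effect scales and `k` are common to all
models and excluded from the parsimony count, which reproduces the
published preference orderings (varying-`a`-only over richer variants).

## 5. Synthetic corpus

`simulate_cycle_table` draws from exactly the generative model above.
Defaults are the published best-model medians (`alpha_a` 1.087, `beta_a`
0.093, `gamma_a` 0.865, `b` −0.098, `c` −0.509, `sigma_n` 0.492, `sigma_p`
0.297, `k` 1.976), 36 participants with nods assigned uniformly, and a
length distribution with P(length = 1) = 0.42 and the remaining mass
geometric (ratio 0.5) over lengths 2–5 — the single-nod share is reported
for the source corpus; the tail shape is not printed anywhere, so the
geometric tail is a modelling choice kept behind a config knob, and no
acceptance check depends on it.

`render_pitch_trace` / `render_corpus` invert the kinematics: each cycle
becomes a half-cosine excursion pair (a single half-cycle for trailing
singles, injected with probability 0.1 to exercise the odd-half-cycle
rule), half-cycle durations uniform on [0.15, 0.45] s at 30 fps (at least
3 frames), starting direction down with probability 0.5, flat rest gaps
between a participant's nods, optional i.i.d. Gaussian jitter, and exact
ground-truth inflection frames.  What this does *not* emulate: irregular
real waveforms, drift, multi-axis rotation, co-occurring gestures, or
correlated head-pose estimation noise.  Passing round-trip tests therefore
demonstrate the correctness of the segmentation logic, not its robustness
to everything real recordings can contain.

## 6. Recovery study and problem sizes

The acceptance script and heavy tests use 3,000 nods / 36 participants —
about a third of the source corpus's retained nod count, chosen so a full
recovery fit stays within minutes while leaving all eight parameters
identified.  At this size the posterior for the weakly identified exponent
`gamma_a` is wide (only four positive length offsets constrain it); its
median can sit a few tenths from the truth while its interval covers
comfortably.  The recovery criterion is therefore coverage-based: medians
must be within one interval-width of the truth and at least 7 of 8
intervals must cover.  Model-selection recovery compares the generating
structure against the all-constant model and the quadratic-decay variant
on the same simulated data.

## 7. Known limitations

* The sampler is serial per chain; chains run sequentially (the target
  environment is single-CPU).
* PSIS-LOO relies on arviz's implementation; only its inputs and the
  comparison rule are in-package.
* The segmentation assumes annotated nod segments; detecting nods in
  continuous recordings (vs. shakes, tilts) is out of scope.
* Magnitudes are measured on the smoothed trace, so very short half-cycles
  (a few frames) are attenuated by the moving average; the window-selection
  MAE criterion balances this against noise-induced spurious inflections.
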