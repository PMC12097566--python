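# nodcycles

Head nods in conversation are not a uniform up-and-down wiggle: the vertical
(pitch) excursions of a repetitive nod follow a structured envelope.  The
first cycle of a longer nod is bigger (*anticipatory rising*), magnitude
decays steadily with each successive cycle (*declination*), and the last
cycle of a repetitive nod is smaller still (*final lowering*) — patterns
strikingly parallel to the phonology of pitch in speech.

`nodcycles` is a Python package for quantifying that structure.  It covers
the full chain from motion capture to model selection:

* **kinematics** — turn frame-level head-pitch series (OpenFace
  `FeatureExtraction` CSV dialect, `pose_Rx` in radians) plus nod-segment
  annotations into a table of nod *cycles*: moving-average smoothing,
  inflection-point detection, half-cycle pairing, per-cycle magnitude
  (highest minus lowest pitch, in degrees), and outlier exclusion.
* **model_family / inference** — hierarchical Gamma regressions for cycle
  magnitude, fitted by MCMC.
* **comparison** — PSIS-LOO model comparison with a significance + Occam
  selection rule.
* **synthetic** — a generative simulator (cycle tables and rendered pitch
  traces with exact ground truth) so the whole pipeline is testable without
  any recordings.
* **cli / pipeline** — `nodcycles simulate | segment | fit | compare | run`.

## The model

Cycle magnitude \(y_i > 0\) (degrees) for cycle \(i\) at 1-based position
\(q_i\) of a nod with \(\ell_i\) cycles is modelled as

```
y_i ~ Gamma(k, mu_i / k)                      E[y_i] = mu_i
log mu_i = fixed(q_i, l_i) + alpha_n[nod(i)] + alpha_p[participant(i)]
alpha_n ~ Normal(0, sigma_n),   alpha_p ~ Normal(0, sigma_p)
```

with the fixed part combining a first-cycle level `a`, a per-position
declination slope `b` and a final-cycle lowering `c`
(`final = 1` iff `q = l`; for single nods only `a` applies):

```
fixed(q, l) = a + b (q - 1) + c final
```

Each of `a`, `b`, `c` may be constant across nod lengths or re-parameterized
as a power law of length, e.g.

```
a_l = alpha_a + beta_a (l - 1)^gamma_a ,   gamma_a >= 0
```

so `alpha_a` is the single-nod level and `0 < gamma_a < 1` means the
first-cycle magnitude grows concavely with length.  The ten members of the
family (`model_catalog()`) are all constant/varying combinations of
`a`, `b`, `c` with the linear position term, plus two variants with a
quadratic decay `b (q^2 - 1)`.  Priors are Normal(0, 10) on location
parameters (half-Normal for the exponents) and half-Cauchy(0, 5) on `k`,
`sigma_n`, `sigma_p`.

Fitting uses an in-package Gibbs/slice-sampling MCMC engine (vectorized over
the thousands of conditionally independent nod intercepts, with dedicated
moves for the correlated power-law parameter pairs).  Models are compared by
PSIS-LOO elpd; a model is rejected only when its elpd deficit exceeds
1.96 × its standard error, and among the statistically indistinguishable set
the model with the fewest fixed-effect parameters is selected.

## Worked example

Simulate a corpus from the default generative settings (3,000 nods, 36
participants, 42% single nods, the varying-`a` model as truth), refit that
model, and compare it against the all-constant and quadratic-decay variants:

```python
import nodcycles as nc
from nodcycles.synthetic import SimConfig, simulate_cycle_table

table, truth = simulate_cycle_table(SimConfig(n_nods=3000, seed=1))
fit5 = nc.fit_mcmc(nc.model_catalog()[4], table, nc.MCMCConfig.fast(seed=1))
print(nc.summarize_posterior(fit5))
```

```
  parameter    median    ci_low   ci_high  significant      rhat     ess_bulk
0   alpha_a  1.067006  0.949178  1.179076         True  1.003166  1666.153636
1    beta_a  0.060159  0.018721  0.127309         True  1.021533   258.214743
2   gamma_a  1.110838  0.454607  1.978151         True  1.030120   271.074242
3         b -0.102174 -0.140073 -0.065128         True  1.019662   230.611727
4         c -0.515744 -0.585824 -0.444618         True  1.020809   328.562631
5   sigma_n  0.464997  0.434504  0.496358         True  1.015514   271.376393
6   sigma_p  0.306006  0.239885  0.400245         True  1.001170  2573.564745
7         k  1.944314  1.858123  2.030009         True  1.006363   722.879982
```

Every 95% credible interval covers the simulation truth (`alpha_a` 1.087,
`beta_a` 0.093, `gamma_a` 0.865, `b` −0.098, `c` −0.509, `sigma_n` 0.492,
`sigma_p` 0.297, `k` 1.976): the negative `b` is the declination slope per
position on the log scale, the negative `c` the extra final-cycle reduction,
and `k ≈ 1.9` the Gamma shape (variance `mu²/k`).  Comparing against
Model 1 (constant `a`) and Model 9 (quadratic decay):

```
model_id      elpd_loo  elpd_diff  se_diff  significant  n_params  selected
       1 -11710.691153 -12.039023 5.058026         True         3     False
       5 -11698.652131   0.000000 0.000000        False         5      True
       9 -11707.140197  -8.488066 3.889165         True         5     False
```

Both alternatives are significantly worse (|elpd_diff| > 1.96 × se_diff),
so the generating structure — length-dependent first-cycle level with linear
declination — is correctly re-selected.

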