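# tsdfit

Statistical toolkit for estimating the **thermal reaction norm of sex ratio**
in species with temperature-dependent sex determination (TSD) — turtles,
crocodilians and some lizards whose embryonic sex is set by the incubation
temperature during the thermosensitive period.

Given constant-temperature incubation records (a temperature, a count of
male and of female hatchlings per incubation group), `tsdfit` estimates the
two quantities that summarize a TSD pattern:

* the **pivotal temperature** `P`, the constant temperature producing a 1:1
  sex ratio, and
* the **transitional range of temperatures** `TRT`, the width of the
  temperature window yielding mixed sex ratios (bounded by default at
  5%–95% male frequency).

Sex ratio is the relative male frequency throughout.

## Models

Two sigmoid families map temperature `t` to expected male frequency:

* **logistic** — `sr(t) = (1 + exp((P − t)/S))⁻¹`, with `S` one fourth of
  the inverse of the slope at `P` (negative `S`: males at cool temperatures,
  the common TSD Ia orientation). Its TRT has the closed form
  `TRT = |S·K_l|` with `K_l = |2 ln(l/(1−l))|`.
* **flexit** — a flexible logistic with independent shape parameters `K1`
  and `K2` for the transitions toward the lower and upper asymptotes,
  allowing the asymmetric patterns real incubation data often show. It
  reduces exactly to the logistic at `K1 = K2 = 1`, and its TRT also has a
  closed form.

Counts are modeled binomially, so every sexed embryo carries information:

```
L_i = C(M_i + F_i, M_i) · sr(t_i)^M_i · (1 − sr(t_i))^F_i
```

On top of the maximum-likelihood machinery (multi-start bounded
quasi-Newton, finite-difference Hessian standard errors, sign-coherent
Cholesky resampling for intervals on `P`, `TRT` and the curve), the package
provides a parametric-bootstrap deviance test, AICc/Akaike-weight model
comparison, BIC *w*-value tests of whether several datasets share one
reaction norm, and an adaptive Metropolis–Hastings sampler for Bayesian
credibility intervals — the method of choice when few (or no) mixed-sex
incubations are available.

The worldwide *Lepidochelys olivacea* (olive ridley sea turtle)
constant-incubation compilation (40 incubation groups, three Regional
Management Units) ships as a built-in fixture.

## Worked example

```python
import tsdfit as tf

ds = tf.filter_dataset(tf.table1_fixture())      # amplitude > 2 °C excluded,
ep = ds.subset(rmu="East Pacific")               # intersexes excluded

fit = tf.fit_mle(ep, "logistic")
print(f"P = {fit.params.P:.2f} SE {fit.se[0]:.2f}   "
      f"S = {fit.params.S:.2f} SE {fit.se[1]:.2f}   -lnL = {fit.neg_ln_L:.2f}")

draws = tf.resample_parameters(fit, n=10_000, seed=1)
print(tf.ci_derived(fit, draws).round(2))
```

prints

```
P = 30.48 SE 0.10   S = -0.39 SE 0.05   -lnL = 15.92
          q0.025   q0.5  q0.975
quantity
P          30.27  30.47   30.68
TRT         1.65   2.27    2.89
```

i.e. the pooled East Pacific data put the pivotal temperature near 30.5 °C
with a 95% interval of about ±0.2 °C, and the 5%–95% transitional range
near 2.3 °C. The same analysis is available from the shell:

```
tsdfit fit --fixture table1 --rmu "East Pacific"
tsdfit mcmc --fixture table1 --rmu "East Pacific" --iterations 100000 --seed 1
tsdfit compare --fixture table1 --split rmu
```

The `compare --split rmu` command reports a BIC *w*-value of ≈ 0.98 in
favor of separate reaction norms for the three regional units, driven by
the distinctly lower pivotal temperature of the Northeast Indian rookery.

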