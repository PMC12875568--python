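# driftswitch

Simultaneous detection of **gradual** and **abrupt** structural change in
intensive-longitudinal (person-period) panels — the kind of data produced by
ecological momentary assessment and mHealth intervention studies, where each
of N people contributes an equally spaced outcome series across several study
periods (pre-intervention, intervention, post-intervention).

`driftswitch` is aimed at quantitative psychologists, biostatisticians and
methodologists who want to ask, for a given dynamic parameter: *did it drift
slowly, jump between regimes, both, or neither — and for whom?*

## The model

The core is a multilevel AR(1) process for person *i* at time *t*:

```
Y_it = mu_it + phi_i (Y_i,t-1 - mu_i,t-1) + eps_it,   eps_it ~ N(0, IIV_it)
phi_i ~ N[-1,1](phi_0, sigma_phi^2)
```

`mu_it` is the time-varying baseline and `IIV_it` the time-varying process
noise (intra-individual variability). Each of these two parameters may follow:

* a **growth curve** (GCM): `mu_it = beta_0i + beta_1i * Period_ip`, with
  period coded 0–3 (intercept = pre-intervention level, slope = per-period
  increment); for IIV the growth curve acts on `ln(IIV_it)`;
* a **random walk** (RW): `mu_it = mu_i,t-1 + e_it`, `e_it ~ N(0, sigma_e^2)`
  — a semiparametric drift whose process-noise SD, evaluated against a
  region of practical equivalence (ROPE (0, .05)), diagnoses whether *any*
  time variation is present;
* a **regime-switching** (RS) deviation: `mu_it = beta_0i + Delta_mu,S_it +
  zeta_i,Dmu`, where the latent regime S_it in {1..S} follows a Markov chain
  with multinomial-logit transition probabilities

  ```
  P(S_t = r | S_t-1 = s) ∝ exp(alpha_rs,0 + alpha_rs,1 * Period2_it x Treatment_i)
  ```

  (staying log-odds fixed at 0; regime-1 deviations fixed at 0).

Fitting is Bayesian MCMC: an adaptive Metropolis-within-Gibbs sampler on the
regime-**marginalized** likelihood (a forward algorithm whose emission at
time *t* conditions on the pair (S_t, S_t-1), since the AR term references the
regime-dependent `mu_i,t-1`), with regime paths recovered per retained draw by
backward sampling. Model comparison uses AIC / BIC / sample-size-adjusted BIC
(`sBIC = -2 lnL + k ln(n(n+2)/24)`), the normalized posterior-classification
entropy

```
E = 1 + (1 / (n ln K)) * sum_itk p_itk ln p_itk,
```

AUC / recall / precision against simulated truth, HDI/ROPE sensitivity, and
the combined decision rules (IC; entropy/AUC + IC; entropy/AUC + sensitivity)
with classifier threshold .6 and sensitivity threshold .2.

## Worked example

Simulate a frequent-transition panel (two-regime abrupt baseline shift of 2
on top of a period growth curve) and refit the generating model:

```python
import driftswitch as ds

scn = ds.preset_scenario("sim1_large_N50T100").with_size(20, 60)
panel, truth = ds.simulate_dataset(scn, 3)

model = ds.RegimeSwitchingAR(panel, "GCM-RS2")
res = model.fit(settings=ds.MCMCSettings(n_chains=2, n_iter=1500,
                                         n_burnin=500, seed=7))
print(res.summary().round(3).to_string())
m = ds.fit_metrics(res, truth, name="GCM-RS2")
print(f"AIC {m.aic:.0f}  BIC {m.bic:.0f}  sBIC {m.sbic:.0f}  "
      f"entropy {m.entropy:.2f}  AUC {m.auc:.2f}")
```

Output:

```
                    mean     sd  hdi_95_lower  hdi_95_upper   rhat      ess
parameter
phi0               0.353  0.032         0.294         0.417  1.015  278.440
beta00            -0.038  0.057        -0.147         0.069  1.056   45.264
sigma_beta0        0.139  0.053         0.039         0.235  1.038   40.903
beta10             0.472  0.021         0.429         0.508  1.040   54.885
iiv0               0.495  0.012         0.474         0.521  1.003  324.593
delta_mu[2]        2.006  0.064         1.882         2.133  1.000  402.478
sigma_delta_mu[2]  0.235  0.054         0.140         0.343  1.012  126.321
alpha0[2,1]       -0.488  0.103        -0.682        -0.284  1.010  380.448
alpha0[1,2]       -0.645  0.103        -0.855        -0.460  1.008  364.640
alpha1[2,1]        1.078  0.330         0.469         1.762  1.008  365.383
alpha1[1,2]       -1.221  0.237        -1.733        -0.815  1.002  269.427

AIC 2990  BIC 3046  sBIC 3089  entropy 0.92  AUC 1.00
```

The abrupt-shift posterior mean `delta_mu[2] = 2.006` recovers the generating
value 2.0; `phi0`, `iiv0` (the process-noise SD psi) and the transition
log-odds recover .3, .5 and (-.5, -.5, 1, -1); entropy .92 says the two
regimes are cleanly separated, and AUC 1.00 confirms it against the simulated
regime paths. `alpha1[2,1] > 0` recovers the design effect: treated persons
switch into the high-baseline regime more readily during the intervention
period.

A thin CLI mirrors the library: `driftswitch simulate | fit | select |
replicate` (see `driftswitch --help`).

## Data contract

Long CSV with columns `id, time, y, treatment, period, period2`; `time` is
unit-spaced within person, missing outcomes are empty cells or `NA` (treated
as missing at random), `treatment` is 0/1 per person, `period` in {0,1,2,3}
non-decreasing, `period2` is 1 during the intervention period. Covariate
columns are optional and default to 0. An empirical panel that follows this
contract can be fitted with the `"empirical"` prior profile.

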