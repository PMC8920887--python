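# swbair

Air-equivalent concentrations from silicone wristband passive samplers.

Silicone wristbands (SWBs) absorb volatile and semi-volatile organic
compounds from the air around the wearer, but most studies stop at extract
concentrations (ng per sampler), which cannot be compared across chemicals,
studies, or regulatory levels. `swbair` closes that gap: it converts the
amount *N* (ng) found in a worn sampler into the **air-equivalent
concentration** *C<sub>a</sub>* (ng/L) under standard indoor conditions
(25 °C, 50 % RH, low wind), using the rate-constant equations of passive
sampling theory:

```
C_a = N / (V_s · K_sa · (1 − e^(−k_e·t)))                      (dissipation form)
C_a = N / (V_s · K_sa · (1 − e^(−R_s·t / (V_s·K_sa))))         (sampling-rate form)
```

where *V<sub>s</sub>* is the silicone volume (mass/density), *K<sub>sa</sub>*
the silicone–air partition coefficient, *t* the days worn, and
*k<sub>e</sub>* (day⁻¹) or *R<sub>s</sub>* (L/day) the exchange-rate
parameter (*R<sub>s</sub>* = *k<sub>e</sub>·V<sub>s</sub>·K<sub>sa</sub>*).

The package covers the full calibration-to-application pipeline:

- **Uptake kinetics** — robust nonlinear fits (Michaelis–Menten-shaped or
  first-order curves, IRLS/Tukey-bisquare loss) of chamber time-series to
  estimate the equilibrium amount *N<sub>s-eq</sub>*, hence
  *K<sub>sa</sub>* = *N<sub>s-eq</sub>*/*V<sub>s</sub>*/*C<sub>a</sub>*, the
  sampling rate from the linear uptake phase, and *k<sub>e</sub>*, all with
  first-order propagation of uncertainty.
- **Predictive models** — weighted (1/Y²) linear regression of
  log *K<sub>sa</sub>* on boiling point or log *K<sub>oa</sub>*, 95 %
  prediction intervals, the high-confidence-data filter (SD < 1 log unit),
  and repeated k-fold cross-validation.
- **Air equivalency** — a registry of published cross-validated
  log *K<sub>sa</sub>* models,

  | id | equation |
  |---|---|
  | `bp_test_cv`  | log K_sa = 0.020·BP(TEST °C) + 0.527 |
  | `bp_opera_cv` | log K_sa = 0.019·BP(OPERA °C) + 0.829 |
  | `log_koa_cv`  | log K_sa = 0.867·log K_oa + 0.190 |

  with the recommended BP-TEST → BP-OPERA fallback, plus model-agreement
  comparisons (fold differences, Spearman rank correlation).
- **Synthetic chamber data** — a seeded simulator of exposure experiments
  (first-order uptake, lognormal multiplicative noise, LOD censoring) so
  every stage is testable against known ground truth.
- A 22-chemical built-in property table (14 VOCs, 8 SVOCs) with CAS numbers,
  QSAR boiling points, log *K<sub>oa</sub>*, vapor pressures, and chamber
  exposure concentrations.

## Worked example

Given a deployment file `deployments.csv`:

```csv
chemical,amount_ng,sampler_mass_g,days_worn
Benzene,50,4.76,7
Toluene,120,4.76,7
Phenanthrene,35,4.76,7
```

```bash
swbair air-equiv --deployments deployments.csv --out ca.csv
```

produces (abridged):

| chemical | ca_ng_per_l | model_used | ke_source | warnings |
|---|---|---|---|---|
| Benzene | 40.90 | bp_test_cv | equilibrium-assumption | lower bound |
| Toluene | 47.42 | bp_test_cv | equilibrium-assumption | lower bound |
| Phenanthrene | 0.000364 | bp_test_cv | equilibrium-assumption | lower bound; log K_sa = 7.35 > 6 … relevancy reduced |

Benzene: log K_sa = 0.020·96.2 + 0.527 = 2.451, so
C_a = 50 / (0.004327 L · 10^2.451) ≈ 40.9 ng/L — the 7-day wear filtered
air containing roughly 41 ng benzene per liter, assuming equilibrium was
reached (true for VOCs within hours).  For phenanthrene the predicted
log K_sa of 7.35 exceeds the relevancy threshold: equilibrium is never
approached during a week's wear and the air route may not dominate uptake,
so the estimate is flagged.  The same computation is available from Python
via `predict_log_ksa`, `DeploymentRecord` and `air_equivalent_conc`.

Other subcommands: `simulate` (chamber scenarios from YAML),
`fit-kinetics` (uptake curves → K_sa, R_s, k_e table), `build-model`,
`crossval`, and `compare-models`.  Every run writes a JSON manifest with
input digests and the settings in force.

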