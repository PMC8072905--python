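# ehrpk

Compartmental pharmacokinetic analysis of mycophenolic acid (MPA) with
enterohepatic recycling (EHR), for intravenous bolus, oral gavage, and
supralingual mucoadhesive-patch dosing in rats.

MPA is glucuronidated in the liver, excreted into bile, deconjugated by
gut bacteria and re-absorbed, so its plasma profile shows secondary
peaks that plain mammillary models cannot describe. `ehrpk` implements
the route-specific EHR model family — central (± peripheral) disposition
plus bile and gut amount compartments, a dual fast/slow absorption depot
with a 5-compartment transit chain for the extravascular routes, and a
lagged zero-order patch release — together with everything needed to
analyse such data end to end:

* exact forward simulation of noise-free profiles (matrix-exponential
  propagation of the linear system; stiff ODE path as cross-check),
* a synthetic-cohort generator reproducing the study design (group
  sizes 5/3/3, 0.5 mg/kg, route-specific sampling schedules, lognormal
  between-animal variability, proportional residual error, 0.5 ng/mL
  LLOQ censoring),
* per-subject maximum-likelihood fitting under the proportional error
  model (profiled sigma, log-scale multi-start optimization), AIC model
  selection with the ΔAIC ≥ 2 rule, and a transit-compartment-number
  scan,
* non-compartmental analysis (linear trapezoidal AUC₀₋₄₈, terminal
  half-life from the last three quantifiable points, Cmax/Tmax),
  absolute bioavailability F_abs, per-animal EHR%, and patch/tongue
  dose accounting,
* goodness-of-fit diagnostics (IWRES, observed-vs-predicted tables).

Key formulas, in the field's notation:

* bile emptying: `GBr = 1/Tau`, transfer `A_bile/Tau` (continuous mode)
* error model: `C_obs,ij = C_pred,ij (1 + eps_ij)`, `eps ~ N(0, sigma²)`
* `F_abs (%) = 100 · (AUC_test · Dose_iv) / (AUC_iv · Dose_test)`
* `EHR% = 100 · K_cb / (K_cb + CL/V + CL2/V2)` (IV, oral);
  `100 · K_cb / (K_cb + CL/V)` (supralingual)
* `AIC = −2LL + 2p` with p = structural parameters + sigma

See `docs/methods.md` for the model assumptions, numerical choices and
limitations.

## Worked example

Simulate the IV and oral arms of the study design, run NCA, estimate
bioavailability, and fit each IV subject's EHR model:

```python
from ehrpk import (CohortSpec, FitConfig, f_abs, fit_subject,
                   nca_route_table, summarize_cohort)
from ehrpk.cohort import generate_cohort

iv = generate_cohort(CohortSpec(route="IV", seed=1))
po = generate_cohort(CohortSpec(route="ORAL", seed=2))
auc_iv = nca_route_table(iv)["auc_0_48"].mean()
auc_po = nca_route_table(po)["auc_0_48"].mean()
print(f"mean AUC0-48  IV   {auc_iv:8.0f} ng*h/mL")
print(f"mean AUC0-48  oral {auc_po:8.0f} ng*h/mL")
print(f"oral F_abs          {f_abs(auc_po, auc_iv, 0.5, 0.5):6.1f} %")

fits = [fit_subject(s, cfg=FitConfig(n_starts=3, seed=1)) for s in iv]
print(summarize_cohort(fits).loc[["cl", "v", "k_cb", "tau", "ehr_pct"]]
      .round(3))
```

prints

```
mean AUC0-48  IV       5784 ng*h/mL
mean AUC0-48  oral     3454 ng*h/mL
oral F_abs            59.7 %

              mean      sd  n
parameter
cl          82.438  49.956  5
v          114.112  26.350  5
k_cb         1.614   0.717  5
tau          2.549   1.538  5
ehr_pct     65.506  11.710  5
```

The AUCs are the trapezoidal areas of this particular synthetic cohort
(seed 1/2); `F_abs` is the dose-normalized AUC ratio of the oral arm to
IV; the fit summary is the mean ± SD across the five IV animals of the
estimated apparent clearance (mL/(kg·h)), central volume (mL/kg),
central→bile rate constant (1/h), bile-emptying interval (h) and the
per-animal recycling percentage. With only five noisy animals the
cohort means sit within sampling error of the generating values.

The same pipeline is scriptable from the shell:

```sh
ehrpk simulate --config cfg.yaml --seed 1 --out out/
ehrpk fit  --data out/dataset.csv --out out/
ehrpk nca  --data out/dataset.csv --out out/
ehrpk report --fits out/fits.csv --nca out/nca.csv --out out/
```

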