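# hepwx

Water-exchange-modified dual-input tracer kinetic analysis of liver
DCE-MRI, with the resampling survival statistics used to screen the fitted
parameters as prognostic biomarkers in small oncology cohorts.

## Who this is for

Quantitative-imaging researchers analyzing dynamic contrast-enhanced MRI of
the liver — in particular hepatocellular carcinoma under antiangiogenic
therapy — who want kinetic parameter estimates that account for the liver's
dual (arterial + portal-venous) blood supply **and** for finite
intercompartmental water exchange, instead of the usual fast-exchange-limit
(FXL) shortcut.

## The model

Tissue tracer kinetics follow one of five dual-input models — Tofts-Kety
(TK), extended Tofts-Kety (ETK), two-compartment exchange (2CX), adiabatic
approximation to tissue homogeneity (AATH) and distributed parameter (DP) —
with a unified parameterization: total plasma flow per tissue volume
F/V_T, arterial flow fraction γ, fractional plasma and interstitial volumes
v_P and v_I, and a permeability term (extraction fraction E, or PS/V_T with
E = 1 − e^(−PS/F) for AATH/DP and E = PS/(PS+F) for 2CX), so that
K^Trans = E·F/V_T for every model.  The vascular input is

    c_in(t) = γ·c_A(t − t_Lag,T) + (1−γ)·c_PV(t − t_Lag,T)

with both input functions in a causal sums-of-exponentials family, which
keeps the tissue concentration C_T(t) fully analytic (the DP Bessel tail is
integrated semi-analytically).

Concentrations map to measured SPGR signal through shutter-speed water
exchange: longitudinal magnetization in the blood / interstitium / cell
sites obeys Bloch-McConnell exchange (2SX for TK, 3S2X for the vascular
models) with mean intracellular and intravascular water lifetimes τ_C and
τ_B; the pre-pulse steady state under a TR-spaced pulse train gives the
relative enhancement E_T(t) that is fitted, by bounded multi-start
least squares, at each voxel or ROI.

Derived reporting quantities follow liver-perfusion conventions: BF =
(F/V_T)·100/(ρ_T·(1−H_LV)) in mL/min/100 g, BV = v_B·100/ρ_T in mL/100 g
with v_B = v_P/(1−H_SV), MTT = (v_P+v_I)/(F/V_T), and the cell fraction
v_C = 1 − v_B − v_I.

For survival screening, each parameter is assessed two ways: (i) one-year
survival discrimination via an ROC cutoff (point closest to the top-left
corner) chosen inside leave-one-out cross-validation, with Kaplan-Meier
curves and a 1000-permutation log-rank P; (ii) association with overall
survival via univariate Cox regression on log2(parameter), so
HR = exp(b) is the hazard ratio per two-fold change, again with a
permutation P.

## Worked example

No imaging data ship with the package; the synthetic-data module generates
cohorts with realistic advanced-HCC parameter scales, the breath-hold
sampling grid (two 7-s acquisitions per 35-s cycle, starting 5 s after
injection), additive enhancement noise, and survival times tied to a chosen
parameter through a proportional-hazards law.

```python
import numpy as np
from hepwx import (CohortSpec, cox_univariate_log2, generate_cohort_study,
                   hazard_percent_change)

spec = CohortSpec(n_patients=20, log_hr=np.log(8.418), seed=1)
cohort = generate_cohort_study(spec, "ETK")
res = cox_univariate_log2(cohort["v_C"], cohort["os_months"],
                          cohort["event"], n_perm=1000, seed=1)
print(f"HR per two-fold v_C change: {res.hr:.2f} "
      f"(permutation P = {res.permutation_p:.3f})")
print(f"risk change per +0.1 v_C: "
      f"{hazard_percent_change(res.hr, 0.1, 'log_scale'):.1f}%")
```

prints

```
HR per two-fold v_C change: 12.76 (permutation P = 0.018)
risk change per +0.1 v_C: 29.0%
```

i.e. this simulated cohort carries a strong adverse effect of the cell
fraction v_C on overall survival: each doubling of v_C multiplies the
hazard of death by ~13 (a noisy small-sample estimate of the generating
hazard ratio 8.418), equivalently a +0.1 absolute increase in v_C raises
the hazard by ~29%.  At n = 20 such estimates scatter widely from cohort
to cohort, which is exactly why the pipeline reports permutation rather
than asymptotic P values.

The full pipeline (simulate → fit → survival statistics, with
cohort-summary, cutoff/log-rank and Cox/HR tables plus Kaplan-Meier plots)
runs from the command line:

```bash
hepwx all --config config.yaml --seed 7 --out results/
```

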