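# oxydose

Longitudinal hyperoxemia-exposure analysis for ICU cohorts.

Supraphysiologic arterial oxygen (hyperoxemia, PaO2 above 13.3 kPa / 100 mm Hg)
is a suspected, contested source of harm in critically ill patients. Most
database studies reduce oxygen exposure to a single blood-gas value;
`oxydose` instead treats it as a longitudinal exposure and implements the
full analysis pipeline for epidemiologists and intensive-care researchers:

1. **Hyperoxemia dose** from irregular arterial blood-gas series: with
   PaO2(t) linearly interpolated between samples (only across gaps
   ≤ 12 h; unobserved time counts as unexposed),

   dose = AUC{ max(0, PaO2(t) − 13.3) } / W  (kPa),

   over a potential-exposure window of W = 24, 72, 120 or 168 h. A dose of
   1 kPa means the patient averaged 1 kPa above the boundary all window.
2. **Censoring-free nested cohorts**: adult index admissions staying > 24 h
   (minus treatment-limitation, pre-admission CPR, QC failures and
   incomplete cases), nested into subsets with stay ≥ W so the exposure
   window is untouched by discharge or death (no informative censoring).
3. **Spike-at-zero mortality models**: ICU death ~ dose (linear) +
   any-exposure indicator + respiratory diagnosis, sex, prior dependency,
   admission type, continuous mechanical ventilation, and restricted cubic
   splines for age, weight and APACHE II; logit, probit or cloglog link;
   optional exposure x diagnosis / ventilation interactions fitted by
   ridge-penalized maximum likelihood with the penalty chosen by AIC over
   effective degrees of freedom.
4. **Bootstrap optimism correction**: c-index, Brier score and calibration
   slope/intercept corrected by refitting the entire procedure on
   resamples (default B = 500), plus precision-recall and calibration
   curves.
5. **Counterfactual average treatment effect**: plug-in g-computation
   contrasting each episode's fitted risk with its risk at zero exposure,
   reported in percentage points of ICU mortality.

A fully specified synthetic ICU cohort generator (log-normal stays,
irregular blood-gas sampling with occasional > 12 h gaps, a spike-at-zero
subgroup, logistic mortality with known coefficients) makes every stage
testable without patient data.

## Worked example

```python
import numpy as np
from oxydose import BloodGasSeries, compute_exposure

series = BloodGasSeries("demo", np.array([0.0, 10.0]), np.array([10.0, 20.0]))
out = compute_exposure(series, window_h=24)
print(out.auc_kpa_h, out.dose_kpa)
```

PaO2 rises from 10 to 20 kPa over 10 h, crossing the 13.3 kPa boundary at
t = 3.3 h; the triangle above the boundary holds `22.445` kPa·h, giving a
24-h dose of `0.9352` kPa.

End to end on synthetic data (`examples/fit_mortality_model.py`, 12,000
patients generated with a true any-exposure odds ratio of 1.5 and no dose
effect):

```
n=10350, log-likelihood=-1932.8, AIC=3899.6
any_exposure    OR 1.73 (1.35-2.21)  chi2=19.073  p=0.000
dose_kpa        OR 1.03 (0.96-1.10)  chi2=0.625  p=0.429
```

The fitted indicator OR brackets the true 1.5 while the dose OR sits at the
null, i.e. the spike-at-zero pair separates "ever exposed" from "how much".
Each `examples/*.py` script exercises one capability the same way; the
`oxydose` CLI (`simulate`, `compute-exposure`, `run-all`) wraps the library
for shell use.

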