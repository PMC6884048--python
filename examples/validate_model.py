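"""Optimism-corrected performance of the day-1 model via the bootstrap."""

from oxydose import (
    GeneratorConfig,
    ModelDefinition,
    apply_exclusions,
    bootstrap_validate,
    build_nested_subsets,
    generate_cohort,
)

admissions, blood_gas = generate_cohort(GeneratorConfig(n_patients=8000, seed=2))
cohort, _ = apply_exclusions(admissions)
(day1,) = build_nested_subsets(cohort, blood_gas, windows=[24])

report = bootstrap_validate(day1.table, ModelDefinition(), B=200, seed=2)
for metric in ("c_index", "brier", "calibration_slope", "calibration_intercept"):
    print(
        f"{metric:22s} apparent {report.apparent[metric]:7.4f}  "
        f"optimism {report.optimism[metric]:+7.4f}  "
        f"corrected {report.corrected[metric]:7.4f}"
    )
print(f"average precision {report.average_precision:.4f}  "
      f"AIC {report.aic:.1f}  resamples {report.n_resamples} "
      f"(skipped {report.n_skipped})")

# The corrected column estimates how the modelling procedure would perform
# on new patients: the whole procedure (knot placement included) is refitted
# on each resample and the train-test performance gap is subtracted from the
# apparent metrics.  A corrected calibration slope below 1 quantifies the
# genuine overfitting of a ~18-column model at this number of deaths.
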