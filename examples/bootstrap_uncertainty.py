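"""Bootstrap confidence intervals for kinetic constants under realistic noise.

Simulates a nitrate influx assay with 5 % multiplicative measurement noise
(a typical IRMS-derived error level), fits the two-stage model, and
attaches 95 % percentile intervals from a case-resampling bootstrap
stratified within concentration levels — the resampling respects the
4-replicates-per-concentration design.
"""

from ninflux import (
    AssayDesign,
    NoiseModel,
    bootstrap_ci,
    fit_two_stage,
    reference,
    simulate_influx,
)

truth = reference.NITRATE_PARAMS
dataset = simulate_influx(truth, AssayDesign(n_source="nitrate"),
                          NoiseModel(kind="multiplicative-normal",
                                     cv_or_sigma=0.05, seed=7))
fit = fit_two_stage(dataset)
fit = bootstrap_ci(dataset, fit, n_boot=500, seed=11, level=0.95)

print("95% bootstrap percentile intervals (500 resamples):\n")
print(f"{'param':>6} {'truth':>8} {'estimate':>9} {'lo':>8} {'hi':>8}")
for name in ("V1", "Km1", "V2", "Km2", "T"):
    lo, hi = fit.ci[name]
    print(f"{name:>6} {getattr(truth, name):>8.3g} "
          f"{getattr(fit.params, name):>9.4g} {lo:>8.4g} {hi:>8.4g}")

print("\nV1 and Km1 (the high-affinity phase) are tightly determined by the "
      "eight sub-threshold concentrations;\nV2 and Km2 trade off along a "
      "ridge because the assay stops at 10 mM, well below nitrate's Km2 "
      "saturation,\nso their individual intervals are wider while the fitted "
      "curve itself is stable.")
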