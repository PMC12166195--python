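# ninflux

Biphasic Michaelis–Menten kinetics for short-term ¹⁵N influx assays, plus the
tidy metabolite analytics that usually accompany N-nutrition experiments.

Plant roots take up ammonium and nitrate through two transport systems: a
high-affinity system (HATS) that saturates at sub-millimolar concentrations,
and a low-affinity system (LATS) that only contributes above an activation
threshold. A short-term tracer assay measures influx *v* (μmol/g DW/h) at a
series of external concentrations *S* (mM); `ninflux` models it as

```
v(S) = V1·S/(Km1+S)                              S <  T
v(S) = V1·T/(Km1+T) + V2·(S−T)/(Km2+S−T)         S ≥  T
```

with HATS constants (V1, Km1), LATS constants (V2, Km2) and threshold T.
The curve is continuous at T by construction. The package is aimed at
plant-nutrition researchers who need to:

- **simulate** influx assays (concentration grid × replicates × noise model)
  and treatment × organ × replicate × analyte metabolite tables, with full
  provenance and seed control;
- **fit** the model by nonlinear least squares with the threshold profiled
  over a candidate set (the objective is non-smooth in T), compare biphasic
  vs single-phase fits by AICc, and quantify uncertainty with a
  design-stratified case bootstrap;
- **summarise** metabolite tables the way N-treatment studies report them:
  per-replicate amino-acid ratios (Gln:Glu, Gln:Thea), per-sample total free
  amino acids, and log₂ fold-change matrices where each analyte is divided
  by its across-treatment mean.

## Worked example

```python
from ninflux import (AssayDesign, NoiseModel, simulate_influx,
                     fit_two_stage, reference)

truth = reference.NITRATE_PARAMS           # V1=2.02, Km1=0.31, V2=16.0,
                                           # Km2=2.29, T=2.0
data = simulate_influx(truth, AssayDesign(n_source="nitrate"),
                       NoiseModel(kind="none", seed=1))
fit = fit_two_stage(data)
print({k: round(v, 4) for k, v in fit.params.to_dict().items()})
print(f"SSE = {fit.sse:.2e}")
```

prints

```
{'V1': 2.02, 'Km1': 0.31, 'V2': 16.0, 'Km2': 2.29, 'T': 2.0}
SSE = 6.44e-29
```

i.e. from a noise-free 13-concentration × 4-replicate assay the profiled
fit returns the generating constants to machine precision, with an SSE of
numerical zero: the nitrate HATS half-saturates at 0.31 mM and tops out at
2.02 μmol/g DW/h, and above the 2 mM threshold the LATS adds up to
16 μmol/g DW/h with a 2.29 mM half-saturation. Under 5 % measurement noise
the same call recovers the constants to a few per cent and
`bootstrap_ci(data, fit, n_boot=500, seed=11)` attaches 95 % percentile
intervals (see `examples/bootstrap_uncertainty.py`).

The `examples/` directory holds one short narrative script per capability:
`fit_influx_kinetics.py`, `bootstrap_uncertainty.py`,
`metabolite_analytics.py` and `ape_conversion.py` (IRMS atom-%-excess →
influx-rate conversion). The same functionality is scriptable from the
shell via the thin `ninflux` CLI (`simulate-influx`, `fit-influx`,
`simulate-metabolites`, `analyze-metabolites`); every run echoes its
effective configuration and seed into the output directory.

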