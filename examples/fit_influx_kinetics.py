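"""Recover biphasic uptake constants from a simulated ¹⁵N influx assay.

Simulates a noise-free nitrate influx assay on the standard 13-point
concentration grid (0.01–10 mM, 4 replicate plants each) from known
two-stage Michaelis–Menten parameters, then re-estimates all five
parameters by profiled nonlinear least squares and compares the biphasic
model against a single-phase fit by AICc.
"""

from ninflux import (
    AssayDesign,
    NoiseModel,
    compare_models,
    fit_single_mm,
    fit_two_stage,
    reference,
    simulate_influx,
)

truth = reference.NITRATE_PARAMS
dataset = simulate_influx(truth, AssayDesign(n_source="nitrate"),
                          NoiseModel(kind="none", seed=1))
print(f"simulated {len(dataset)} replicate-level records "
      f"({len(dataset.data['S_mM'].unique())} concentrations x 4 replicates)")

two = fit_two_stage(dataset)
mono = fit_single_mm(dataset)
comparison = compare_models(mono, two)

print("\ngenerating truth :", truth.to_dict())
print("recovered        :", {k: round(v, 4) for k, v in two.params.to_dict().items()})
print(f"\ntwo-stage SSE = {two.sse:.2e}  (zero up to float precision: the "
      "profiled fit recovers the generating curve exactly)")
print(f"mono SSE      = {mono.sse:.2f}   (a single Michaelis-Menten phase "
      "cannot bend through the LATS rise above 2 mM)")
print(f"AICc selects  : {comparison.selected}")

# The threshold profile shows why T = 2 mM wins: SSE is minimal there.
print("\nthreshold profile (T in mM -> SSE), 5 best candidates:")
for entry in sorted(two.t_profile, key=lambda e: e["sse"])[:5]:
    print(f"  T = {entry['T']:<5g} SSE = {entry['sse']:.3g}")
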