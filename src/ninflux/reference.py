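"""Published reference constants for tea-root N influx assays.

These are the field's printed values for *Camellia sinensis* 'Yabukita':
the 13-concentration assay grid, the fitted two-stage kinetic constants for
ammonium and nitrate influx into new roots, the five ammonium:nitrate
hydroponic treatments, and the tracer enrichment of the feeding solutions.
They serve as generating truth for simulations and as presets for the CLI.
"""

from __future__ import annotations

from .kinetics import KineticParams

#: External concentration grid of the influx assay, mM.
CONCENTRATION_GRID_MM: tuple[float, ...] = (
    0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.75, 1.0, 2.0, 5.0, 10.0
)

#: Replicate plants per concentration in the influx assay.
ASSAY_REPLICATES: int = 4

#: Tracer incubation time, minutes (informational; rates are per hour).
ASSAY_DURATION_MIN: float = 10.0

#: 15N abundance of the (15NH4)2SO4 / K15NO3 feeding solutions, atom %.
TRACER_ATOM_PERCENT: float = 99.9

#: Fitted two-stage constants for 15NH4+ influx into new roots.
#: HATS: Km 0.02 mM, Vmax 1.81 μmol/g DW/h; LATS: Km 81.3 mM, Vmax 213.7
#: (the near-linear high-concentration rise), activated at 0.5 mM.
AMMONIUM_PARAMS = KineticParams(V1=1.81, Km1=0.02, V2=213.7, Km2=81.3, T=0.5)

#: Fitted two-stage constants for 15NO3- influx into new roots.
#: HATS: Km 0.31 mM, Vmax 2.02; LATS: Km 2.29 mM, Vmax 16.0, activated at 2 mM.
NITRATE_PARAMS = KineticParams(V1=2.02, Km1=0.31, V2=16.0, Km2=2.29, T=2.0)

N_SOURCE_PRESETS: dict[str, KineticParams] = {
    "ammonium": AMMONIUM_PARAMS,
    "nitrate": NITRATE_PARAMS,
}

#: The five hydroponic treatments, label -> (ammonium mM, nitrate mM).
#: Labels are ammonium:nitrate percentage ratios at a fixed 2.86 mM total N.
TREATMENTS: dict[str, tuple[float, float]] = {
    "100:0": (2.86, 0.0),
    "75:25": (2.14, 0.71),
    "50:50": (1.43, 1.43),
    "25:75": (0.71, 2.14),
    "0:100": (0.0, 2.86),
}

#: Replicate plants per treatment in the growth/metabolite experiment.
TREATMENT_REPLICATES: int = 6
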