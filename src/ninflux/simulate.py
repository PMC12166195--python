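"""Simulators for ¹⁵N influx assays and N-metabolite concentration tables.

The influx simulator draws replicate uptake measurements on a concentration
grid from the two-stage kinetic model plus measurement noise, emulating a
short-term ¹⁵N labelling assay read out by isotope-ratio mass spectrometry.
The metabolite simulator draws a tidy treatment × organ × replicate ×
analyte concentration table around user-declared cell means, emulating the
free-amino-acid profiling of a multi-treatment hydroponic experiment.

Both simulators embed full provenance (generating parameters, design, noise
model, seed) in their outputs so round trips are self-describing, and both
are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .errors import ConfigurationError, DomainError, MeasurementError
from .kinetics import KineticParams, rate_curve

__all__ = [
    "AssayDesign",
    "NoiseModel",
    "InfluxDataset",
    "MetaboliteDesign",
    "MetaboliteTable",
    "simulate_influx",
    "simulate_metabolites",
    "ape_to_influx",
    "default_metabolite_design",
]

INFLUX_COLUMNS = ["n_source", "S_mM", "replicate", "v_umol_per_gDW_h"]
METABOLITE_COLUMNS = ["treatment", "organ", "replicate", "analyte", "concentration"]

_NOISE_KINDS = ("none", "multiplicative-normal", "additive-normal")


@dataclass(frozen=True)
class AssayDesign:
    """Design of one influx assay: grid, replication and incubation time.

    Defaults are the published tea-root assay: 13 concentrations from
    0.01 to 10 mM, 4 replicate plants each, 10-minute incubation (the
    duration is informational — rates are handled per hour throughout).
    """

    n_source: str = "ammonium"
    grid: tuple[float, ...] = reference.CONCENTRATION_GRID_MM
    replicates: int = reference.ASSAY_REPLICATES
    duration_min: float = reference.ASSAY_DURATION_MIN

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.size == 0 or np.min(g) <= 0:
            raise ConfigurationError("grid must be non-empty and strictly positive")
        if not np.all(np.diff(g) > 0):
            raise ConfigurationError("grid must be strictly increasing")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        object.__setattr__(self, "grid", tuple(float(x) for x in g))

    def to_dict(self) -> dict:
        return {"n_source": self.n_source, "grid": list(self.grid),
                "replicates": self.replicates, "duration_min": self.duration_min}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model for simulated influx rates.

    kind
        ``"none"``, ``"multiplicative-normal"`` (v = max(0, rate·(1+ε)),
        ε ~ N(0, cv)) or ``"additive-normal"`` (v = max(0, rate+ε),
        ε ~ N(0, σ) in rate units).
    cv_or_sigma
        Coefficient of variation (dimensionless) for the multiplicative
        kind, standard deviation (rate units) for the additive kind.
    seed
        Seed for the generator; identical seeds give bit-identical data.
    """

    kind: str = "multiplicative-normal"
    cv_or_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ConfigurationError(
                f"unknown noise kind {self.kind!r}; expected one of {_NOISE_KINDS}")
        if self.cv_or_sigma < 0:
            raise ConfigurationError("cv_or_sigma must be >= 0")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "cv_or_sigma": self.cv_or_sigma, "seed": self.seed}


@dataclass(frozen=True)
class InfluxDataset:
    """Replicate-level influx observations for one N source.

    ``data`` is a tidy frame with columns ``n_source, S_mM, replicate,
    v_umol_per_gDW_h``; ``provenance`` records how it was produced (for
    synthetic data: generating parameters, design, noise model and seed).
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in INFLUX_COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"influx table missing columns: {missing}")
        if len(self.data):
            if (self.data["S_mM"] <= 0).any():
                raise ConfigurationError("all S_mM must be > 0")
            if (self.data["v_umol_per_gDW_h"] < 0).any():
                raise ConfigurationError("all rates must be >= 0")
            dup = self.data.duplicated(subset=["n_source", "S_mM", "replicate"])
            if dup.any():
                raise ConfigurationError(
                    "duplicate (n_source, S, replicate) records at rows "
                    f"{list(self.data.index[dup])}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def S(self) -> np.ndarray:
        return self.data["S_mM"].to_numpy(dtype=float)

    @property
    def v(self) -> np.ndarray:
        return self.data["v_umol_per_gDW_h"].to_numpy(dtype=float)


def simulate_influx(params: KineticParams, design: AssayDesign,
                    noise: NoiseModel) -> InfluxDataset:
    """Simulate one influx assay from the two-stage model.

    Returns one record per (grid concentration × replicate).  With
    ``noise.kind == "none"`` every rate equals the model value exactly;
    noisy draws are truncated at zero.
    """
    grid = np.asarray(design.grid, dtype=float)
    rates = rate_curve(params, grid)
    n_rep = design.replicates
    rng = np.random.default_rng(noise.seed)

    base = np.repeat(rates, n_rep)
    if noise.kind == "none":
        v = base
    elif noise.kind == "multiplicative-normal":
        eps = rng.normal(0.0, noise.cv_or_sigma, size=base.size)
        v = np.maximum(0.0, base * (1.0 + eps))
    else:  # additive-normal
        eps = rng.normal(0.0, noise.cv_or_sigma, size=base.size)
        v = np.maximum(0.0, base + eps)

    df = pd.DataFrame({
        "n_source": design.n_source,
        "S_mM": np.repeat(grid, n_rep),
        "replicate": np.tile(np.arange(1, n_rep + 1), grid.size),
        "v_umol_per_gDW_h": v,
    })
    prov = {
        "generator": "ninflux.simulate.simulate_influx",
        "params": params.to_dict(),
        "design": design.to_dict(),
        "noise": noise.to_dict(),
    }
    return InfluxDataset(data=df, provenance=prov)


@dataclass(frozen=True)
class MetaboliteDesign:
    """Design of a simulated metabolite profiling experiment.

    ``means`` maps every (treatment, organ, analyte) cell to its expected
    concentration (amount per g DW); a missing cell is a configuration
    error.  Replicates are drawn from a normal around the cell mean with
    standard deviation ``cv * mean``, truncated at zero.
    """

    treatments: tuple[str, ...]
    organs: tuple[str, ...]
    analytes: tuple[str, ...]
    means: Mapping[tuple[str, str, str], float]
    cv: float = 0.10
    replicates: int = reference.TREATMENT_REPLICATES
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatments", tuple(self.treatments))
        object.__setattr__(self, "organs", tuple(self.organs))
        object.__setattr__(self, "analytes", tuple(self.analytes))
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.cv < 0:
            raise ConfigurationError("cv must be >= 0")
        missing = [(t, o, a) for t in self.treatments for o in self.organs
                   for a in self.analytes if (t, o, a) not in self.means]
        if missing:
            raise ConfigurationError(
                f"means missing for {len(missing)} design cells, e.g. {missing[:3]}")
        bad = [k for k, m in self.means.items() if m < 0]
        if bad:
            raise ConfigurationError(f"negative means for cells: {bad[:3]}")

    def to_dict(self) -> dict:
        return {
            "treatments": list(self.treatments),
            "organs": list(self.organs),
            "analytes": list(self.analytes),
            "means": {"|".join(k): v for k, v in self.means.items()},
            "cv": self.cv,
            "replicates": self.replicates,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetaboliteDesign":
        means = {tuple(k.split("|")): float(v) for k, v in d["means"].items()}
        return cls(treatments=tuple(d["treatments"]), organs=tuple(d["organs"]),
                   analytes=tuple(d["analytes"]), means=means,
                   cv=float(d.get("cv", 0.10)),
                   replicates=int(d.get("replicates", 6)),
                   seed=int(d.get("seed", 0)))


@dataclass(frozen=True)
class MetaboliteTable:
    """Tidy treatment × organ × replicate × analyte concentration records."""

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in METABOLITE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"metabolite table missing columns: {missing}")
        if len(self.data):
            if (self.data["concentration"] < 0).any():
                raise ConfigurationError("concentrations must be >= 0")
            dup = self.data.duplicated(
                subset=["treatment", "organ", "replicate", "analyte"])
            if dup.any():
                raise ConfigurationError(
                    "duplicate (treatment, organ, replicate, analyte) records")

    def __len__(self) -> int:
        return len(self.data)


def simulate_metabolites(design: MetaboliteDesign) -> MetaboliteTable:
    """Draw a tidy metabolite table from a design.

    One record per (treatment × organ × replicate × analyte); truncated-
    normal concentrations around the design means at the design CV;
    deterministic under the design seed.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for t in design.treatments:
        for o in design.organs:
            for a in design.analytes:
                mu = float(design.means[(t, o, a)])
                draws = np.maximum(
                    0.0, rng.normal(mu, design.cv * mu, size=design.replicates))
                for r, val in enumerate(draws, start=1):
                    rows.append((t, o, r, a, val))
    df = pd.DataFrame(rows, columns=METABOLITE_COLUMNS)
    prov = {
        "generator": "ninflux.simulate.simulate_metabolites",
        "design": design.to_dict(),
        "noise": "truncated-normal",
    }
    return MetaboliteTable(data=df, provenance=prov)


def ape_to_influx(ape_sample: float, ape_source: float, n_total: float,
                  duration_h: float) -> float:
    """Convert an IRMS-measured ¹⁵N enrichment to an influx rate.

    Minimal isotope-dilution formula: the fraction of tissue N that is
    newly taken-up label is ``ape_sample / ape_source``, so

        rate = (ape_sample / ape_source) * n_total / duration_h

    with ``ape_sample`` the atom % ¹⁵N excess of the tissue, ``ape_source``
    the atom % ¹⁵N of the feeding solution (99.9 for the usual tracer
    salts), ``n_total`` total N per g DW and ``duration_h`` the incubation
    time in hours.  Natural-abundance background subtraction is the
    caller's responsibility (a documented non-goal here).
    """
    if not (0 <= ape_sample <= 100) or not (0 < ape_source <= 100):
        raise DomainError("atom % values must lie in [0, 100] with ape_source > 0")
    if ape_sample > ape_source:
        raise MeasurementError(
            f"sample enrichment ({ape_sample}) exceeds source enrichment "
            f"({ape_source}): physically inconsistent measurement")
    if n_total <= 0:
        raise DomainError("n_total must be > 0")
    if duration_h <= 0:
        raise DomainError("duration_h must be > 0")
    return (ape_sample / ape_source) * n_total / duration_h


def default_metabolite_design(cv: float = 0.10, replicates: int | None = None,
                              seed: int = 0) -> MetaboliteDesign:
    """A realistic default design emulating the tea FAA experiment.

    Five ammonium:nitrate treatments (total N fixed at 2.86 mM), two organs
    (new leaves, new roots), six replicates and a small panel of free amino
    acids dominated by theanine.  Cell means (μmol / g DW) encode the
    field's qualitative patterns: theanine and arginine rise with the
    ammonium proportion, glutamine peaks at the 25:75 treatment, glutamate
    stays comparatively flat.
    """
    treatments = tuple(reference.TREATMENTS)
    organs = ("new_leaves", "new_roots")
    analytes = ("Thea", "Gln", "Glu", "Arg", "Asp")
    # mean concentration per analyte, ordered 100:0, 75:25, 50:50, 25:75, 0:100
    profiles: dict[str, dict[str, Sequence[float]]] = {
        "new_leaves": {
            "Thea": (120.0, 115.0, 95.0, 80.0, 55.0),
            "Gln": (18.0, 16.0, 20.0, 30.0, 14.0),
            "Glu": (12.0, 12.5, 12.0, 13.0, 11.0),
            "Arg": (40.0, 25.0, 12.0, 6.0, 2.0),
            "Asp": (8.0, 8.5, 9.0, 9.5, 8.0),
        },
        "new_roots": {
            "Thea": (90.0, 85.0, 70.0, 55.0, 35.0),
            "Gln": (10.0, 9.0, 12.0, 16.0, 17.0),
            "Glu": (9.0, 9.5, 9.0, 10.0, 9.0),
            "Arg": (30.0, 18.0, 9.0, 4.0, 1.5),
            "Asp": (6.0, 6.5, 7.0, 7.5, 6.5),
        },
    }
    means = {
        (t, o, a): float(profiles[o][a][i])
        for i, t in enumerate(treatments) for o in organs for a in analytes
    }
    return MetaboliteDesign(
        treatments=treatments, organs=organs, analytes=analytes, means=means,
        cv=cv, replicates=replicates or reference.TREATMENT_REPLICATES, seed=seed)
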