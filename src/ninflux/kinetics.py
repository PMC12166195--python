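"""Single-phase and two-stage Michaelis–Menten rate laws for root N influx.

The two-stage model describes short-term nitrogen uptake by roots as the sum
of a high-affinity transport system (HATS), active at all concentrations, and
a low-affinity transport system (LATS) that switches on above an activation
threshold ``T``::

    v(S) = V1*S/(Km1+S)                                   for S <  T
    v(S) = V1*T/(Km1+T) + V2*(S-T)/(Km2+S-T)              for S >= T

with external substrate concentration ``S`` (mM) and influx ``v``
(μmol / g DW / h).  The HATS branch is frozen at its value at ``T`` once the
LATS is active, which makes the curve continuous at ``S = T`` by construction.
Continuity is therefore structural and never enforced numerically.

Units are the field's conventional ones (mM, μmol/g dry weight/h) but the
model layer is unit-agnostic beyond internal consistency: normalising a
10-minute tracer incubation to an hourly rate is the data producer's job.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, PhaseOrderWarning

__all__ = ["MonoParams", "KineticParams", "mm_rate", "two_stage_rate", "rate_curve"]


@dataclass(frozen=True)
class MonoParams:
    """Parameters of a single Michaelis–Menten phase.

    Attributes
    ----------
    V : float
        Maximal rate, μmol / g DW / h.  Must be positive.
    Km : float
        Michaelis constant, mM (substrate concentration at half-maximal
        rate).  Must be positive.
    """

    V: float
    Km: float

    def __post_init__(self) -> None:
        if not (self.V > 0):
            raise DomainError(f"V must be > 0, got {self.V}")
        if not (self.Km > 0):
            raise DomainError(f"Km must be > 0, got {self.Km}")

    def to_dict(self) -> dict:
        return {"V": float(self.V), "Km": float(self.Km)}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "MonoParams":
        return cls(V=float(d["V"]), Km=float(d["Km"]))

    @classmethod
    def from_json(cls, s: str) -> "MonoParams":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the two-stage (HATS + LATS) influx model.

    Attributes
    ----------
    V1, Km1 : float
        Maximal rate and Michaelis constant of the high-affinity phase
        (μmol/g DW/h and mM).  ``V1 > 0``, ``Km1 > 0``.
    V2, Km2 : float
        Maximal rate and Michaelis constant of the low-affinity phase.
        ``V2 >= 0`` (zero disables the phase), ``Km2 > 0``.
    T : float
        Activation threshold of the low-affinity phase, mM.  ``T > 0``.

    The phase-labelling convention is ``Km1 <= Km2`` (phase 1 is the
    high-affinity one).  Inputs violating it are normalised by swapping the
    two (V, Km) pairs, with a :class:`PhaseOrderWarning`.
    """

    V1: float
    Km1: float
    V2: float
    Km2: float
    T: float

    def __post_init__(self) -> None:
        if not (self.V1 > 0):
            raise DomainError(f"V1 must be > 0, got {self.V1}")
        if not (self.Km1 > 0):
            raise DomainError(f"Km1 must be > 0, got {self.Km1}")
        if self.V2 < 0:
            raise DomainError(f"V2 must be >= 0, got {self.V2}")
        if not (self.Km2 > 0):
            raise DomainError(f"Km2 must be > 0, got {self.Km2}")
        if not (self.T > 0):
            raise DomainError(f"T must be > 0, got {self.T}")
        if self.Km1 > self.Km2:
            warnings.warn(
                "Km1 > Km2: swapping phases to restore the high-affinity-first "
                "labelling convention (Km1 <= Km2)",
                PhaseOrderWarning,
                stacklevel=2,
            )
            v1, km1 = self.V1, self.Km1
            object.__setattr__(self, "V1", self.V2)
            object.__setattr__(self, "Km1", self.Km2)
            object.__setattr__(self, "V2", v1)
            object.__setattr__(self, "Km2", km1)
            if not (self.V1 > 0):
                raise DomainError("after phase normalisation V1 must be > 0")

    def to_dict(self) -> dict:
        return {"V1": float(self.V1), "Km1": float(self.Km1), "V2": float(self.V2),
                "Km2": float(self.Km2), "T": float(self.T)}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        return cls(V1=float(d["V1"]), Km1=float(d["Km1"]), V2=float(d["V2"]),
                   Km2=float(d["Km2"]), T=float(d["T"]))

    @classmethod
    def from_json(cls, s: str) -> "KineticParams":
        return cls.from_dict(json.loads(s))


def _check_nonneg(S: np.ndarray) -> None:
    if S.size and np.min(S) < 0:
        raise DomainError("substrate concentration S must be >= 0")


def mm_rate(params: MonoParams, S):
    """Single-phase Michaelis–Menten rate V*S/(Km+S).

    ``S`` may be a scalar or array-like of concentrations (mM, >= 0); the
    return has the same shape.  The rate satisfies 0 <= v < V.
    """
    arr = np.asarray(S, dtype=float)
    _check_nonneg(arr)
    out = params.V * arr / (params.Km + arr)
    return float(out) if np.isscalar(S) or arr.ndim == 0 else out


def _two_stage(V1, Km1, V2, Km2, T, S: np.ndarray) -> np.ndarray:
    below = S < T
    plateau = V1 * T / (Km1 + T)
    x = np.where(below, 0.0, S - T)
    return np.where(below, V1 * S / (Km1 + S), plateau + V2 * x / (Km2 + x))


def two_stage_rate(params: KineticParams, S):
    """Two-stage (HATS + LATS) influx rate at concentration ``S`` (mM).

    Piecewise evaluation exactly as printed above; continuous at ``S = T``
    and bounded above by ``V1 + V2``.  Scalar in, scalar out; arrays pass
    through elementwise.
    """
    arr = np.asarray(S, dtype=float)
    _check_nonneg(arr)
    out = _two_stage(params.V1, params.Km1, params.V2, params.Km2, params.T, arr)
    return float(out) if np.isscalar(S) or arr.ndim == 0 else out


def rate_curve(params: KineticParams, grid) -> np.ndarray:
    """Evaluate the two-stage model on a concentration grid.

    Preserves grid order and length; an empty grid yields an empty array.
    """
    arr = np.asarray(grid, dtype=float)
    if arr.size == 0:
        return np.empty(0, dtype=float)
    _check_nonneg(arr)
    return _two_stage(params.V1, params.Km1, params.V2, params.Km2, params.T, arr)
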