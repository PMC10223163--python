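"""Parameter, regimen and profile containers.

All quantities follow the package-wide unit convention: time in hours,
volumes in litres, clearances in L/h, doses in mg and concentrations in
ng/mL.  Oral parameters are *apparent* (CL/F, Vc/F, ...): bioavailability
F never appears on its own because it cancels throughout.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

__all__ = ["ModelParameters", "DoseRegimen", "ConcentrationProfile"]


@dataclass(frozen=True)
class ModelParameters:
    """Fixed-effect parameters of the two-compartment oral model.

    Parameters
    ----------
    cl_f : float
        Apparent clearance from the central compartment (L/h, or L/h/kg
        for a per-kg rat parameterisation).
    vc_f : float
        Apparent central volume of distribution (L or L/kg).
    q_f : float
        Apparent inter-compartmental clearance (L/h or L/h/kg).
    vp_f : float
        Apparent peripheral volume of distribution (L or L/kg).
    ka : float
        First-order absorption rate constant (1/h).
    d2 : float
        Duration of the zero-order absorption process (h).
    f1 : float
        Fraction of the dose absorbed by the first-order pathway; the
        remaining ``1 - f1`` enters through the zero-order pathway.
    alag2 : float
        Lag time before the zero-order input starts (h).  The
        first-order pathway has no lag.
    """

    cl_f: float
    vc_f: float
    q_f: float
    vp_f: float
    ka: float
    d2: float
    f1: float
    alag2: float

    def __post_init__(self) -> None:
        for name in ("cl_f", "vc_f", "q_f", "vp_f", "ka", "d2"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0.0:
                raise InvalidParameterError(
                    f"{name} must be finite and strictly positive, got {value!r}"
                )
        if not math.isfinite(self.f1) or not 0.0 <= self.f1 <= 1.0:
            raise InvalidParameterError(f"f1 must lie in [0, 1], got {self.f1!r}")
        if not math.isfinite(self.alag2) or self.alag2 < 0.0:
            raise InvalidParameterError(f"alag2 must be >= 0, got {self.alag2!r}")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def scaled_by_weight(self, bw: float) -> "ModelParameters":
        """Convert a per-kg parameter set to absolute values for body weight ``bw`` (kg).

        Volumes and clearances scale linearly with weight; rate constants,
        durations and fractions are weight-independent.
        """
        if bw <= 0:
            raise InvalidInputError(f"body weight must be positive, got {bw!r}")
        return self.replace(
            cl_f=self.cl_f * bw,
            vc_f=self.vc_f * bw,
            q_f=self.q_f * bw,
            vp_f=self.vp_f * bw,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**{f.name: float(d[f.name]) for f in dataclasses.fields(cls)})


@dataclass(frozen=True)
class DoseRegimen:
    """An oral dosing schedule: ``n_doses`` doses of ``dose`` mg every ``tau`` h."""

    dose: float
    tau: float = 24.0
    n_doses: int = 1
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise InvalidInputError(f"dose must be >= 0, got {self.dose!r}")
        if self.tau <= 0:
            raise InvalidInputError(f"tau must be > 0, got {self.tau!r}")
        if self.n_doses < 1:
            raise InvalidInputError(f"n_doses must be >= 1, got {self.n_doses!r}")

    @property
    def dose_times(self) -> np.ndarray:
        return self.start_time + self.tau * np.arange(self.n_doses)


@dataclass
class ConcentrationProfile:
    """A concentration-time course for one subject.

    ``times`` (h) must be strictly increasing; ``conc`` is in ng/mL and must
    be non-negative unless ``is_noisy`` marks the profile as carrying
    residual error.
    """

    times: np.ndarray
    conc: np.ndarray
    subject_id: str = "typical"
    arm: str = "control"
    is_noisy: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.conc.shape:
            raise InvalidInputError("times and conc must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise InvalidInputError("profile must contain at least one sample")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if not self.is_noisy and np.any(self.conc < -1e-9):
            raise InvalidInputError("noise-free concentrations must be non-negative")

    def __len__(self) -> int:
        return self.times.size
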