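"""Covariate application and rat-to-human extrapolation.

Carbamazepine pretreatment enters the model as a binary covariate with two
fractional effects: it raises apparent clearance (enzyme/transporter
induction speeds elimination) and prolongs the zero-order absorption
duration (intestinal efflux slows uptake).

Interspecies extrapolation uses simple allometry with exponent 1 for
volumes and liver-blood-flow (LBF) proportionality for clearances:
rivaroxaban is cleared predominantly by the liver, so absolute clearance
is assumed proportional to absolute liver blood flow.  The human
first-order absorption rate constant is not scaled but taken from
clinical data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidCovariateError, InvalidInputError
from .params import ModelParameters

__all__ = [
    "CovariateEffects",
    "SpeciesProfile",
    "apply_cbz",
    "scale_volume",
    "scale_clearance_lbf",
    "convert_dose_bsa",
    "extrapolate_to_human",
]


@dataclass(frozen=True)
class CovariateEffects:
    """Fractional covariate changes: ``param_test = param_control * (1 + effect)``."""

    cl_cbz: float = 0.0
    d2_cbz: float = 0.0

    def __post_init__(self) -> None:
        for name in ("cl_cbz", "d2_cbz"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= -1.0:
                raise InvalidCovariateError(
                    f"{name} must be finite and > -1 (parameters stay positive), got {v!r}"
                )


@dataclass(frozen=True)
class SpeciesProfile:
    """Species constants: body weight (kg) and liver blood flow (mL/min/kg)."""

    bw: float
    lbf: float

    def __post_init__(self) -> None:
        if self.bw <= 0 or self.lbf <= 0:
            raise InvalidInputError("body weight and liver blood flow must be positive")


def apply_cbz(params: ModelParameters, eff: CovariateEffects) -> ModelParameters:
    """Apply the carbamazepine covariate to a control-arm (typical value) set.

    Clearance becomes ``cl_f * (1 + cl_cbz)`` and the zero-order duration
    ``d2 * (1 + d2_cbz)``; all other parameters are untouched.
    """
    return params.replace(
        cl_f=params.cl_f * (1.0 + eff.cl_cbz),
        d2=params.d2 * (1.0 + eff.d2_cbz),
    )


def scale_volume(
    v_per_kg: float,
    rat: SpeciesProfile,
    target: SpeciesProfile,
    *,
    exponent: float = 1.00,
) -> float:
    """Allometric volume scaling: absolute rat volume times ``(BW ratio)**exponent``."""
    if v_per_kg <= 0:
        raise InvalidInputError("volume must be positive")
    v_rat_abs = v_per_kg * rat.bw
    return v_rat_abs * (target.bw / rat.bw) ** exponent


def scale_clearance_lbf(
    cl_per_kg: float, rat: SpeciesProfile, target: SpeciesProfile
) -> float:
    """Liver-blood-flow clearance scaling.

    Absolute rat clearance is multiplied by the ratio of *absolute* liver
    blood flows (mL/min/kg times body weight), i.e. clearance is taken as
    proportional to total hepatic perfusion.
    """
    if cl_per_kg <= 0:
        raise InvalidInputError("clearance must be positive")
    cl_rat_abs = cl_per_kg * rat.bw
    return cl_rat_abs * (target.lbf * target.bw) / (rat.lbf * rat.bw)


def convert_dose_bsa(human_dose_per_kg: float, factor: float) -> float:
    """Convert a human mg/kg dose to the rat-equivalent mg/kg dose.

    ``factor`` is the body-surface-area conversion factor between the two
    species (human-to-rat, < 1); the rat-equivalent dose is the human
    per-kg dose divided by it.
    """
    if factor <= 0:
        raise InvalidInputError("conversion factor must be positive")
    if human_dose_per_kg < 0:
        raise InvalidInputError("dose must be non-negative")
    return human_dose_per_kg / factor


def extrapolate_to_human(
    rat_params: ModelParameters,
    rat: SpeciesProfile,
    target: SpeciesProfile,
    human_ka: float,
) -> ModelParameters:
    """Extrapolate a per-kg rat parameter set to absolute target-species values.

    Volumes scale allometrically, clearances by liver blood flow, the
    first-order absorption rate constant is replaced by the clinically
    derived ``human_ka``, and the absorption-shape parameters (d2, f1,
    alag2) carry over unchanged.
    """
    if human_ka <= 0:
        raise InvalidInputError("human_ka must be positive")
    return ModelParameters(
        cl_f=scale_clearance_lbf(rat_params.cl_f, rat, target),
        vc_f=scale_volume(rat_params.vc_f, rat, target),
        q_f=scale_clearance_lbf(rat_params.q_f, rat, target),
        vp_f=scale_volume(rat_params.vp_f, rat, target),
        ka=human_ka,
        d2=rat_params.d2,
        f1=rat_params.f1,
        alag2=rat_params.alag2,
    )
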