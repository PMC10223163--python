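"""Synthetic rat PK study generation.

Emulates the design of the source rat experiment: two groups of six rats
(control = rivaroxaban alone, test = rivaroxaban after carbamazepine
pretreatment), a single 3 mg/kg oral dose, and nine blood samples over
24 h including a pre-dose sample.  Body weights are drawn log-normally,
individual parameters get the usual log-normal variability on CL/F and
Vc/F, observations carry combined additive + proportional error, and
values below the LLOQ are flagged (and excluded from fitting downstream).

Every generated dataset keeps its per-subject true parameters so that
estimation code can be scored against the generating truth.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .model import simulate_analytic
from .params import DoseRegimen, ModelParameters
from .population import VariabilityModel, add_residual
from .scaling import CovariateEffects, apply_cbz

__all__ = ["StudyDesign", "SyntheticDataset", "default_design", "generate_study"]


@dataclass(frozen=True)
class StudyDesign:
    """Design constants of a two-group single-dose rat PK study."""

    n_per_group: int = 6
    dose_per_kg: float = 3.0           # mg/kg
    sampling_times: tuple = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 10.0, 24.0)  # h
    bw_mean: float = 0.25              # kg
    bw_cv: float = 10.0                # %
    lloq: float = 1.0                  # ng/mL
    groups: tuple = ("control", "test")

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise InvalidInputError("n_per_group must be >= 1")
        times = np.asarray(self.sampling_times, dtype=float)
        if np.any(times < 0) or (times.size > 1 and not np.all(np.diff(times) > 0)):
            raise InvalidInputError("sampling times must be non-negative and increasing")
        if self.dose_per_kg < 0 or self.bw_mean <= 0 or self.lloq < 0:
            raise InvalidInputError("invalid design constants")


@dataclass
class SyntheticDataset:
    """A generated study: long-format observations plus hidden truth."""

    records: pd.DataFrame              # subject, group, bw_kg, time_h, conc_ng_ml, blq
    true_parameters: dict              # subject -> parameter dict (incl. bw, etas)
    design: StudyDesign
    seed: int
    meta: dict = field(default_factory=dict)

    def observations(self, include_blq: bool = False) -> pd.DataFrame:
        """Post-dose observation records, optionally without BLQ rows (M1 handling)."""
        df = self.records[self.records.time_h > 0.0]
        if not include_blq:
            df = df[~df.blq]
        return df.reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    def write_truth(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "design": asdict(self.design),
            "true_parameters": self.true_parameters,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def default_design() -> StudyDesign:
    """The emulated rat study: 2 x 6 rats, 3 mg/kg, 9 samples over 24 h."""
    return StudyDesign()


def generate_study(
    design: StudyDesign,
    typical: ModelParameters,
    eff: CovariateEffects,
    var: VariabilityModel,
    seed: int,
) -> SyntheticDataset:
    """Generate one synthetic rat study.

    ``typical`` is the per-kg control-arm parameter set; test-group animals
    get the covariate effects applied before individual variability.
    """
    rng_bw, rng_eta, rng_res = (
        np.random.Generator(np.random.PCG64(s))
        for s in np.random.SeedSequence(seed).spawn(3)
    )
    times = np.asarray(design.sampling_times, dtype=float)

    rows = []
    truth: dict = {}
    for group in design.groups:
        group_typ = apply_cbz(typical, eff) if group == "test" else typical
        for j in range(design.n_per_group):
            sid = f"{group[:1]}{j + 1:02d}"
            omega_bw = design.bw_cv / 100.0
            bw = float(design.bw_mean * np.exp(rng_bw.normal(0.0, omega_bw)))
            eta_cl = rng_eta.normal(0.0, var.omega(var.iiv_cv_cl)) if var.iiv_cv_cl > 0 else 0.0
            eta_vc = rng_eta.normal(0.0, var.omega(var.iiv_cv_vc)) if var.iiv_cv_vc > 0 else 0.0
            indiv_per_kg = group_typ.replace(
                cl_f=group_typ.cl_f * float(np.exp(eta_cl)),
                vc_f=group_typ.vc_f * float(np.exp(eta_vc)),
            )
            indiv_abs = indiv_per_kg.scaled_by_weight(bw)
            dose = design.dose_per_kg * bw
            regimen = DoseRegimen(dose=dose, tau=24.0, n_doses=1)
            profile = simulate_analytic(indiv_abs, regimen, times,
                                        subject_id=sid, arm=group)
            noisy = add_residual(profile, var, rng_res)
            truth[sid] = {
                "group": group, "bw_kg": bw, "dose_mg": dose,
                "eta_cl": float(eta_cl), "eta_vc": float(eta_vc),
                **{f"{k}_per_kg": v for k, v in indiv_per_kg.to_dict().items()},
            }
            for t, c in zip(noisy.times, noisy.conc):
                rows.append({"subject": sid, "group": group, "bw_kg": bw,
                             "time_h": float(t), "conc_ng_ml": float(c),
                             "blq": bool(c < design.lloq)})

    records = pd.DataFrame(rows)
    return SyntheticDataset(records=records, true_parameters=truth,
                            design=design, seed=seed)
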