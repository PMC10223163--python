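"""Canonical published inputs: rat PK estimates, species constants, variability,
covariate coefficients, clinical and PBPK reference values.

The rat fixed effects are per-kg apparent parameters from the source rat
study; everything downstream (covariate application, interspecies scaling,
human simulation) starts from these numbers.  Values are stored at full
printed precision; report layers round for display.
"""
from __future__ import annotations

from .params import ModelParameters
from .scaling import CovariateEffects, SpeciesProfile

__all__ = [
    "RAT_TYPICAL_PER_KG",
    "CBZ_EFFECTS",
    "RAT",
    "HUMAN",
    "HUMAN_KA",
    "D2_TEST_TABLE",
    "BSA_CONVERSION_FACTOR",
    "VARIABILITY_DEFAULTS",
    "HUMAN_DOSE_MG",
    "HUMAN_TAU_H",
    "RAT_DOSE_PER_KG",
    "RAT_SAMPLING_TIMES_H",
    "CLINICAL_REFERENCES",
    "PBPK_REFERENCE",
]

#: typical-value rat parameters (control arm), per kg of body weight
RAT_TYPICAL_PER_KG = ModelParameters(
    cl_f=0.609,   # L/h/kg
    vc_f=0.701,   # L/kg
    q_f=0.665,    # L/h/kg
    vp_f=5.60,    # L/kg
    ka=2.31,      # 1/h
    d2=6.62,      # h
    f1=0.260,
    alag2=0.501,  # h
)

#: carbamazepine covariate coefficients: fractional increases in CL/F and D2
CBZ_EFFECTS = CovariateEffects(cl_cbz=2.11, d2_cbz=0.339)

#: zero-order absorption duration of the CBZ arm as printed in the parameter
#: table (the covariate arithmetic gives 8.864 h; the table rounds to 8.84 h,
#: which the human simulation uses by default)
D2_TEST_TABLE = 8.84

RAT = SpeciesProfile(bw=0.25, lbf=85.0)
HUMAN = SpeciesProfile(bw=60.0, lbf=21.0)

#: human first-order absorption rate constant, taken from clinical profiles
HUMAN_KA = 0.97  # 1/h

#: body-surface-area factor converting human mg/kg doses to rat-equivalent mg/kg
BSA_CONVERSION_FACTOR = 0.164

#: inter-individual variability (%CV) and residual-error magnitudes shared by
#: rat and human simulations
VARIABILITY_DEFAULTS = {
    "iiv_cv_cl": 49.0,    # %
    "iiv_cv_vc": 47.0,    # %
    "sigma_add": 13.6,    # ng/mL
    "sigma_prop": 23.2,   # %
}

HUMAN_DOSE_MG = 20.0
HUMAN_TAU_H = 24.0

RAT_DOSE_PER_KG = 3.0  # mg/kg, single oral dose
RAT_SAMPLING_TIMES_H = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 10.0, 24.0)

#: clinically observed exposure of 20 mg oral rivaroxaban (mean, low, high)
#: used by the two-fold model-qualification check
CLINICAL_REFERENCES = {
    "auc_first": (1847.5, 1559.6, 2244.9),   # ng*h/mL
    "cmax_first": (219.7, 189.9, 291.6),     # ng/mL
    "auc_ss": (2619.2, 2329.9, 2908.4),      # ng*h/mL
    "cmax_ss": (341.5, 273.5, 409.5),        # ng/mL
}

#: literature PBPK-model predictions of the same interaction, kept only for
#: side-by-side display in reports: metric -> (control mean, test mean,
#: relative change %)
PBPK_REFERENCE = {
    "auc_first": (2221.3, 1438.7, 35.2),
    "auc_ss": (2467.3, 1838.4, 25.5),
    "cmax_first": (266.3, 166.1, 37.7),
    "cmax_ss": (282.3, 179.5, 36.4),
}
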