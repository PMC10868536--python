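"""Growth-trait adjustment to a 100 kg endpoint and fixed-effect pre-correction.

Pig growth and carcass traits (days to 100 kg AGE, average daily gain ADG,
backfat BF, loin muscle depth LMD, lean meat percentage LMP) are recorded at
an off-test weight near but not exactly 100 kg.  Industry adjustment formulas
standardise each record to the 100 kg endpoint with constants that differ
between sire-line and dam-line animals.  After adjustment, phenotypes are
pre-corrected for fixed effects (sex, batch, population) by ordinary
least-squares residualisation; the grand mean is re-added so corrected
phenotypes keep the trait's scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AdjustmentConstants",
    "DEFAULT_CONSTANTS",
    "adjust_age",
    "adjust_adg",
    "adjust_ratio_trait",
    "adjust_lmp",
    "adjust_table",
    "precorrect_fixed_effects",
]


@dataclass(frozen=True)
class AdjustmentConstants:
    """Sex-specific constants of the 100 kg adjustment formulas.

    ``age_cf_multiplier`` scales growth rate (weight/age) into the AGE
    correction factor; ``bf``/``lmd`` hold the (A, B) pairs of the ratio
    adjustment A / (A + B * (weight - 100)); the ``lmp_*`` coefficients define
    the linear lean-meat-percentage predictor from adjusted BF and LMD.
    """

    age_cf_multiplier: dict = field(
        default_factory=lambda: {"sire": 1.826, "dam": 1.715}
    )
    bf: dict = field(
        default_factory=lambda: {"sire": (13.47, 0.1115), "dam": (15.65, 0.1566)}
    )
    lmd: dict = field(
        default_factory=lambda: {"sire": (50.52, 0.228), "dam": (52.01, 0.228)}
    )
    lmp_intercept: float = 61.21920
    lmp_bf_coef: float = -0.77665
    lmp_lmd_coef: float = 0.15239


DEFAULT_CONSTANTS = AdjustmentConstants()

#: sex labels accepted as sire-line / dam-line
_SEX_MAP = {"sire": "sire", "male": "sire", "dam": "dam", "female": "dam"}


def _sex_group(sex: str) -> str:
    try:
        return _SEX_MAP[str(sex).lower()]
    except KeyError:
        raise ValueError(f"unrecognised sex label {sex!r}; expected male/female")


def adjust_age(
    measured_age: float,
    measured_weight: float,
    sex: str,
    constants: AdjustmentConstants = DEFAULT_CONSTANTS,
) -> float:
    """Days to 100 kg from age and weight at measurement.

    AGE_adj = age - (weight - 100) / CF with CF = (weight/age) * multiplier.
    The multiplier is 1.826 for sire-line and 1.715 for dam-line animals.
    """
    if measured_weight <= 0:
        raise ValueError(f"measured_weight must be positive, got {measured_weight}")
    if measured_age <= 0:
        raise ValueError(f"measured_age must be positive, got {measured_age}")
    cf = (measured_weight / measured_age) * constants.age_cf_multiplier[_sex_group(sex)]
    return measured_age - (measured_weight - 100.0) / cf


def adjust_adg(adjusted_age: float) -> float:
    """Average daily gain to 100 kg: 100 kg over the adjusted days."""
    if adjusted_age <= 0:
        raise ValueError(f"adjusted_age must be positive, got {adjusted_age}")
    return 100.0 / adjusted_age


def adjust_ratio_trait(
    trait: str,
    measured_value: float,
    measured_weight: float,
    sex: str,
    constants: AdjustmentConstants = DEFAULT_CONSTANTS,
) -> float:
    """Adjust BF or LMD (mm) to 100 kg: value * A / (A + B*(weight - 100))."""
    trait = trait.lower()
    if trait not in ("bf", "lmd"):
        raise ValueError(f"trait must be 'BF' or 'LMD', got {trait!r}")
    a, b = getattr(constants, trait)[_sex_group(sex)]
    denom = a + b * (measured_weight - 100.0)
    if denom <= 0:
        raise ValueError(
            f"adjustment denominator nonpositive at measured_weight={measured_weight}"
        )
    return measured_value * a / denom


def adjust_lmp(
    adjusted_bf: float,
    adjusted_lmd: float,
    constants: AdjustmentConstants = DEFAULT_CONSTANTS,
) -> float:
    """Lean meat percentage at 100 kg from the adjusted BF and LMD (mm).

    Affine predictor: intercept 61.21920, -0.77665 per mm backfat,
    +0.15239 per mm loin depth.
    """
    if not (np.isfinite(adjusted_bf) and np.isfinite(adjusted_lmd)):
        raise ValueError("adjusted BF and LMD must be finite")
    return (
        constants.lmp_intercept
        + constants.lmp_bf_coef * adjusted_bf
        + constants.lmp_lmd_coef * adjusted_lmd
    )


def adjust_table(
    records: pd.DataFrame, constants: AdjustmentConstants = DEFAULT_CONSTANTS
) -> pd.DataFrame:
    """Vectorised adjustment of a measured-record table.

    Expects columns ``sex, measured_weight_kg, measured_age_d, measured_bf_mm,
    measured_lmd_mm``; returns the input with ``AGE_adj, ADG_adj, BF_adj,
    LMD_adj, LMP_adj`` appended.
    """
    out = records.copy()
    age = [
        adjust_age(a, w, s, constants)
        for a, w, s in zip(
            records["measured_age_d"], records["measured_weight_kg"], records["sex"]
        )
    ]
    out["AGE_adj"] = age
    out["ADG_adj"] = [adjust_adg(a) for a in age]
    out["BF_adj"] = [
        adjust_ratio_trait("bf", v, w, s, constants)
        for v, w, s in zip(
            records["measured_bf_mm"], records["measured_weight_kg"], records["sex"]
        )
    ]
    out["LMD_adj"] = [
        adjust_ratio_trait("lmd", v, w, s, constants)
        for v, w, s in zip(
            records["measured_lmd_mm"], records["measured_weight_kg"], records["sex"]
        )
    ]
    out["LMP_adj"] = [
        adjust_lmp(b, d, constants) for b, d in zip(out["BF_adj"], out["LMD_adj"])
    ]
    return out


def precorrect_fixed_effects(
    phenotypes: pd.DataFrame,
    traits: list[str],
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Pre-correct phenotypes for fixed effects by OLS residualisation.

    Each trait is regressed on the categorical covariates (dummy-coded with an
    intercept); the corrected phenotype is the residual plus the grand mean,
    stored in a ``<trait>_c`` column.  Collinear design columns are dropped
    by the least-squares solve itself (minimum-norm solution), so redundant
    factor levels are harmless.  With no covariates the trait is returned
    unchanged.  The corrected phenotype preserves the trait mean exactly.
    """
    out = phenotypes.copy()
    covariates = covariates or []
    if covariates:
        design = pd.get_dummies(
            phenotypes[covariates].astype(str), drop_first=True, dtype=float
        )
        X = np.column_stack([np.ones(len(phenotypes)), design.to_numpy()])
    else:
        X = np.ones((len(phenotypes), 1))
    for trait in traits:
        y = phenotypes[trait].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        out[f"{trait}_c"] = resid + y.mean()
    return out
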