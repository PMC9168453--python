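"""TSP-referenced concentrations, production/consumption rates, enrichments.

The internal standard TSP (trimethylsilyl propionate, 9 equivalent methyl
protons, 0.2 mM) anchors absolute ¹H quantification: a metabolite's
concentration follows from its per-proton integral relative to the TSP
per-proton integral.  Concentrations accumulated over the incubation are
converted to rates per 10⁶ cells, and ¹³C fractional enrichments are simple
satellite/(satellite + unlabeled) integral fractions.
"""

from __future__ import annotations

import warnings

from pydantic import BaseModel, Field, model_validator

from ..errors import ConfigurationError

__all__ = [
    "QuantConfig",
    "quantify_vs_tsp",
    "production_rate",
    "enrichment_from_satellites",
    "acetyl_enrichment",
    "glucose_consumption_rate",
    "oxidative_triose_rate",
    "pc_anaplerotic_rate",
]

#: Number of protons behind the citrate ¹H quartet (two CH2 groups).
CITRATE_PROTONS = 4
#: Methyl protons of lactate and alanine.
METHYL_PROTONS = 3


class QuantConfig(BaseModel):
    """Experiment bookkeeping needed to turn integrals into rates.

    ``medium_volume_mL`` has no default: the incubation volume must be
    supplied explicitly to avoid silent unit errors.
    """

    model_config = {"extra": "forbid"}

    tsp_conc_mM: float = Field(default=0.2, gt=0)
    tsp_protons: int = Field(default=9, ge=1)
    incubation_h: float = Field(default=48.0, gt=0)
    medium_volume_mL: float = Field(gt=0)
    n_cells: float = Field(gt=0)

    @model_validator(mode="after")
    def _check(self) -> "QuantConfig":
        return self


def quantify_vs_tsp(
    metabolite_integral: float,
    n_protons: int,
    tsp_integral: float,
    cfg: QuantConfig,
) -> float:
    """Absolute concentration (mM) from a ¹H integral vs the TSP reference.

    conc = (I_met / n_protons) / (I_TSP / tsp_protons) × tsp_conc_mM
    """
    if n_protons < 1:
        raise ConfigurationError("n_protons must be >= 1")
    if tsp_integral <= 0:
        raise ConfigurationError("TSP integral must be positive")
    per_proton_met = metabolite_integral / n_protons
    per_proton_tsp = tsp_integral / cfg.tsp_protons
    return per_proton_met / per_proton_tsp * cfg.tsp_conc_mM


def production_rate(conc_mM: float, cfg: QuantConfig) -> float:
    """Average production rate in nmol/h per 10⁶ cells over the incubation.

    rate = conc_mM × volume_mL × 1000 / (incubation_h × n_cells / 10⁶)
    (mM × mL = µmol; ×1000 → nmol).
    """
    if cfg.medium_volume_mL is None or cfg.n_cells is None:
        raise ConfigurationError("medium_volume_mL and n_cells are required")
    nmol = conc_mM * cfg.medium_volume_mL * 1000.0
    return nmol / (cfg.incubation_h * cfg.n_cells / 1e6)


def enrichment_from_satellites(
    unlabeled_multiplet_integral: float, satellite_multiplet_integral: float
) -> float:
    """Fractional ¹³C enrichment from ¹H satellite integrals.

    The ¹³C-bound protons appear as satellite multiplets split by ¹J(C,H);
    the labeled fraction is satellite / (satellite + unlabeled).
    """
    if unlabeled_multiplet_integral < 0 or satellite_multiplet_integral < 0:
        raise ValueError("integrals must be nonnegative")
    total = unlabeled_multiplet_integral + satellite_multiplet_integral
    if total == 0:
        raise ValueError("both integrals are zero; enrichment undefined")
    return satellite_multiplet_integral / total


def acetyl_enrichment(labeled_integral: float, unlabeled_integral: float) -> float:
    """Acetyl-CoA pool enrichment from glutamate C4 multiplet components.

    The caller supplies the labeled and unlabeled glutamate C4 integrals
    (e.g. from the ¹³C₃ labeling pattern of secreted glutamate); the
    arithmetic is the same integral fraction as for the satellites.
    """
    return enrichment_from_satellites(unlabeled_integral, labeled_integral)


def glucose_consumption_rate(
    glc13C_integral: float,
    lac13C_integral: float,
    lac_conc_mM: float,
    glucose_initial_mM: float,
    cfg: QuantConfig,
    f_p: float = 1.0,
    labeled_carbons_per_glucose: int = 2,
    tracer_purity: float = 0.99,
) -> float:
    """Glucose consumption rate from ¹³C glucose-vs-lactate integrals.

    The remaining [1,6-¹³C₂]glucose concentration is obtained by scaling the
    ¹³C lactate concentration (``lac_conc_mM × f_p``, one labeled carbon per
    lactate) by the glucose/lactate ¹³C integral ratio and dividing by the
    number of labeled carbons per glucose molecule and the tracer's isotopic
    purity.  The consumed amount (initial − remaining) is then converted to
    a rate.

    Parameters
    ----------
    f_p
        Fractional ¹³C enrichment of the lactate (pyruvate) pool, used to
        convert total lactate concentration to ¹³C-lactate concentration.
    labeled_carbons_per_glucose
        2 for [1,6-¹³C₂]glucose (each glucose yields two trioses carrying
        one label apiece).
    """
    if lac13C_integral <= 0:
        raise ConfigurationError("13C lactate integral must be positive")
    if glc13C_integral < 0:
        raise ValueError("glucose integral must be nonnegative")
    lac13C_conc = lac_conc_mM * f_p
    remaining = (
        lac13C_conc
        * (glc13C_integral / lac13C_integral)
        / labeled_carbons_per_glucose
        / tracer_purity
    )
    consumed = glucose_initial_mM - remaining
    if consumed < 0:
        warnings.warn(
            f"apparent negative glucose consumption ({consumed:.3g} mM); clipping to 0",
            stacklevel=2,
        )
        consumed = 0.0
    return production_rate(consumed, cfg)


def oxidative_triose_rate(
    glucose_rate: float,
    lactate_rate: float,
    alanine_rate: float,
    other_efflux: float = 0.0,
) -> float:
    """Triose flux left for oxidative metabolism, nmol/h per 10⁶ cells.

    Each consumed glucose yields two trioses; trioses secreted as lactate or
    alanine (or other effluxes) are subtracted.  Negative balances are
    floored at zero with a warning.
    """
    for name, v in [("glucose_rate", glucose_rate), ("lactate_rate", lactate_rate),
                    ("alanine_rate", alanine_rate), ("other_efflux", other_efflux)]:
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    rate = 2.0 * glucose_rate - lactate_rate - alanine_rate - other_efflux
    if rate < 0:
        warnings.warn(
            f"oxidative triose rate {rate:.3g} < 0 (effluxes exceed 2x glucose); "
            "flooring at 0",
            stacklevel=2,
        )
        return 0.0
    return rate


def pc_anaplerotic_rate(triose_rate: float, p: float) -> float:
    """Anaplerotic carbon flux through PC: oxidative triose rate × PC fraction."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"PC fraction p must lie in [0, 1), got {p}")
    if triose_rate < 0:
        raise ValueError("triose_rate must be nonnegative")
    return triose_rate * p
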