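"""Compound constants and pharmacodynamic parameter sets.

The PD defaults are the optimized population values of the published
THC / 11-OH-THC model: a sigmoid Emax "feeling high" response driven by
summed effect-site concentrations (k_e0 = 2 /h, Emax = 80 mm,
EC50 = 0.21 uM, Hill = 1.8) and an indirect-response "alertness" model
(k_out = 1 /h, 90% maximal inhibition of the zero-order input,
EC50 = 0.23 uM, Hill = 1.9).  Interindividual variability is carried as a
coefficient of variation (%) on Emax and EC50 for each endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


class InvalidParameterError(ValueError):
    """A parameter violates its physical or structural constraints."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class CompoundParams:
    """Physicochemical and absorption constants for one compound.

    ``f_a``/``k_a`` govern first-order oral absorption, ``lung_f_a``/
    ``lung_k_a`` first-order pulmonary absorption of inhaled doses.
    """

    name: str
    molar_mass: float  # g/mol
    f_a: float = 0.0  # oral fraction absorbed
    k_a: float = 1.0  # 1/h
    lung_f_a: float = 0.0
    lung_k_a: float = 1.0  # 1/h

    def __post_init__(self) -> None:
        _require(self.molar_mass > 0, "molar_mass must be > 0")
        _require(0.0 <= self.f_a <= 1.0, "f_a must lie in [0, 1]")
        _require(0.0 <= self.lung_f_a <= 1.0, "lung_f_a must lie in [0, 1]")
        _require(self.k_a > 0, "k_a must be > 0")
        _require(self.lung_k_a > 0, "lung_k_a must be > 0")


@dataclass(frozen=True)
class FeelingHighParams:
    """Direct effect-compartment Emax model for VAS "feeling high".

    The two compounds share Emax and EC50; the response depends on the
    *sum* of their effect-site concentrations.  ``k_e0`` values are kept
    as separate fields but default equal (the published model uses one
    value for both compounds).
    """

    k_e0_thc: float = 2.0  # 1/h
    k_e0_11oh: float = 2.0  # 1/h
    e_max: float = 80.0  # mm, maximum VAS increase
    ec50: float = 0.21  # uM (summed effect-site concentration)
    hill: float = 1.8
    cv_emax: float = 34.0  # %
    cv_ec50: float = 70.0  # %, reduced from a 126% literature value

    def __post_init__(self) -> None:
        _require(self.k_e0_thc > 0 and self.k_e0_11oh > 0, "k_e0 must be > 0")
        _require(self.e_max > 0, "e_max must be > 0")
        _require(self.ec50 > 0, "ec50 must be > 0")
        _require(self.hill > 0, "hill must be > 0")
        _require(self.cv_emax >= 0 and self.cv_ec50 >= 0, "CVs must be >= 0")

    def with_values(self, **kw) -> "FeelingHighParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class AlertnessParams:
    """Indirect-response (turnover) model for VAS "alertness".

    Zero-order production ``k_in = baseline * k_out`` is inhibited by a
    sigmoid Emax function of the summed THC + 11-OH-THC brain
    concentrations; first-order loss at ``k_out``.  ``e_max_pct`` is the
    maximal inhibition stored as a percent (converted to a fraction in
    exactly one place, :func:`AlertnessParams.e_max_fraction`).
    """

    k_out: float = 1.0  # 1/h
    baseline: float = 60.0  # mm
    e_max_pct: float = 90.0  # % maximal inhibition of k_in
    ec50: float = 0.23  # uM (summed brain concentration)
    hill: float = 1.9
    cv_emax: float = 30.0  # %
    cv_ec50: float = 30.0  # %

    def __post_init__(self) -> None:
        _require(self.k_out > 0, "k_out must be > 0")
        _require(0.0 < self.baseline <= 100.0, "baseline must lie in (0, 100]")
        # individual draws from a 30% CV log-normal around the 90% default
        # legitimately exceed 100%, so only positivity is structural here
        _require(self.e_max_pct > 0.0, "e_max_pct must be > 0")
        _require(self.ec50 > 0, "ec50 must be > 0")
        _require(self.hill > 0, "hill must be > 0")
        _require(self.cv_emax >= 0 and self.cv_ec50 >= 0, "CVs must be >= 0")

    @property
    def k_in(self) -> float:
        """Zero-order production rate (mm/h) implied by the steady state."""
        return self.baseline * self.k_out

    @property
    def e_max_fraction(self) -> float:
        return self.e_max_pct / 100.0

    def with_values(self, **kw) -> "AlertnessParams":
        return replace(self, **kw)


def dose_to_amount(amount_mg: float, molar_mass: float) -> float:
    """Convert a dose in mg to umol given the molar mass in g/mol.

    mg / (g/mol) = mmol, times 1000 -> umol; the bridge between mg dose
    regimens and uM concentration scales.
    """
    if molar_mass <= 0:
        raise InvalidParameterError("molar_mass must be > 0")
    if amount_mg < 0:
        raise InvalidParameterError("amount_mg must be >= 0")
    return amount_mg / molar_mass * 1000.0


THC_MG_PER_CIGARETTE = 2.55
"""mg THC per legal cannabis cigarette (850 mg at 0.3% THC)."""


def cigarettes_to_mg(n_cigarettes: float) -> float:
    """THC dose (mg) delivered by ``n_cigarettes`` standard cigarettes."""
    if n_cigarettes < 0:
        raise InvalidParameterError("n_cigarettes must be >= 0")
    return n_cigarettes * THC_MG_PER_CIGARETTE


# Standard chemistry constants; not model-fitted quantities.
THC = CompoundParams(
    name="THC",
    molar_mass=314.46,
    f_a=0.45,
    k_a=0.7,
    lung_f_a=0.6,
    lung_k_a=200.0,
)

OH_THC = CompoundParams(name="11-OH-THC", molar_mass=330.46)

#: Lung f_a values used across the source inhalation studies; the pairing
#: of value to trial is study-specific configuration, not a model constant.
LUNG_FA_VALUES = (0.22, 0.025, 0.05, 0.4, 0.6, 0.9)
LUNG_KA_VALUES = (12.0, 200.0)

DEFAULT_FEELING_HIGH = FeelingHighParams()
DEFAULT_ALERTNESS = AlertnessParams()
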