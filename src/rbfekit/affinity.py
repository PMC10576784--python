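"""Affinity measurements and their conversion to binding free energies.

Measured affinities (dissociation constants Kd, inhibition constants Ki, or
IC50 values) are converted to absolute binding free energies via

    dG = kT ln X,

with X the concentration in molar units, and to relative binding free
energies between two ligands a, b of the same series via

    ddG_ab = -kT ln(X_b / X_a) = dG_a - dG_b.

Under common assay conditions the ratio of two IC50s equals the ratio of the
corresponding Kis (and Kds), so relative free energies are comparable across
measure types even though IC50-derived absolute free energies carry an
unknown additive constant.  All energies are in kcal/mol; the temperature is
300 K unless overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .exceptions import InvalidMeasurementError, MixedMeasureTypeError

#: Boltzmann constant in kcal/mol/K (molar gas constant over calories).
BOLTZMANN_KCAL = 1.9872e-3

#: Temperature (K) assumed for all conversions unless overridden.
DEFAULT_TEMPERATURE = 300.0


class MeasureType(str, Enum):
    """How an affinity was measured."""

    KD = "Kd"
    KI = "Ki"
    IC50 = "IC50"

    @property
    def absolute_scale_known(self) -> bool:
        """IC50-derived free energies carry an unknown additive constant."""
        return self is not MeasureType.IC50


class Qualifier(str, Enum):
    """Censoring qualifier: ``lt``/``gt`` mark detection-limit values."""

    EQ = "eq"
    LT = "lt"
    GT = "gt"


@dataclass(frozen=True)
class ThermoConstants:
    """Thermodynamic constants used in every free-energy conversion.

    Parameters
    ----------
    boltzmann_kcal
        Boltzmann constant in kcal/mol/K. Fixed at 1.9872e-3.
    temperature
        Absolute temperature in kelvin; must be positive. Default 300 K.
    """

    boltzmann_kcal: float = BOLTZMANN_KCAL
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise InvalidMeasurementError(
                f"temperature must be positive, got {self.temperature}"
            )

    @property
    def kt(self) -> float:
        """kT in kcal/mol."""
        return self.boltzmann_kcal * self.temperature


DEFAULT_THERMO = ThermoConstants()


@dataclass(frozen=True)
class AffinityMeasurement:
    """One compound's measured affinity in one assay.

    ``value`` is the concentration in molar units and must be strictly
    positive.  ``qualifier`` records detection-limit censoring: ``lt`` means
    the true affinity is below the reported limit, ``gt`` above it.
    ``std_err`` is an optional reported standard error in kcal/mol.
    """

    compound_id: str
    measure_type: MeasureType
    value: float
    qualifier: Qualifier = Qualifier.EQ
    std_err: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise InvalidMeasurementError(
                f"{self.compound_id}: affinity value must be > 0 M, got {self.value}"
            )
        # allow plain strings at construction for convenience
        object.__setattr__(self, "measure_type", MeasureType(self.measure_type))
        object.__setattr__(self, "qualifier", Qualifier(self.qualifier))


def abs_dg(m: AffinityMeasurement, c: ThermoConstants = DEFAULT_THERMO) -> float:
    """Absolute binding free energy kT ln(X) in kcal/mol.

    For IC50 measurements the result is defined only up to an additive
    constant shared by the assay; rank and relative metrics are unaffected.
    """
    if not m.value > 0:
        raise InvalidMeasurementError(f"{m.compound_id}: non-positive value")
    return c.kt * math.log(m.value)


def rel_ddg(
    m_a: AffinityMeasurement,
    m_b: AffinityMeasurement,
    c: ThermoConstants = DEFAULT_THERMO,
    *,
    allow_mixed_types: bool = False,
) -> float:
    """Relative binding free energy ddG_ab = -kT ln(X_b / X_a) in kcal/mol.

    Antisymmetric in its arguments and equal to ``abs_dg(m_a) - abs_dg(m_b)``.
    Mixing measure types (e.g. Kd vs IC50) relies on the ratio-equivalence
    assumption and must be opted into with ``allow_mixed_types``.
    """
    if m_a.measure_type is not m_b.measure_type and not allow_mixed_types:
        raise MixedMeasureTypeError(
            f"{m_a.compound_id} ({m_a.measure_type.value}) vs "
            f"{m_b.compound_id} ({m_b.measure_type.value}): pass "
            "allow_mixed_types=True to accept cross-type ratios"
        )
    return -c.kt * math.log(m_b.value / m_a.value)


def pki_to_kcal(p: float, c: ThermoConstants = DEFAULT_THERMO) -> float:
    """Convert a pKi-unit magnitude (decades of Ki) to kcal/mol.

    One pKi unit is a ten-fold affinity change, i.e. ln(10) kT kcal/mol
    (about 1.37 kcal/mol at 300 K).
    """
    if p < 0:
        raise InvalidMeasurementError(f"pKi magnitude must be >= 0, got {p}")
    return math.log(10.0) * c.kt * p


def abs_rmse_to_pairwise_rmse(sigma: float) -> float:
    """Propagate an absolute-dG RMSE to the implied pairwise ddG RMSE.

    Assuming unbiased, Gaussian errors, the error of a difference of two
    independent absolute free energies has sqrt(2) times the standard
    deviation of the absolute errors.
    """
    if sigma < 0:
        raise InvalidMeasurementError(f"RMSE must be >= 0, got {sigma}")
    return math.sqrt(2.0) * sigma
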