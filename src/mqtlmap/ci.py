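"""Confidence-interval imputation for QTLs reported without a CI.

Many literature QTLs report only the variance explained (R²) and the size of
the mapping population.  An expected 95% CI width can then be imputed from
empirically calibrated population-type constants:

    CI = 530 / (N * R²)   for backcross / F2-derived populations
    CI = 163 / (N * R²)   for recombinant-inbred-line populations

where N is the population size.  RILs accumulate more recombination events,
hence the smaller constant.  A missing LOD score defaults to 2.5.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Iterable

from .core import PopulationType, QTLRecord

logger = logging.getLogger(__name__)

DEFAULT_LOD = 2.5

#: 95% normal interval spans +/- 1.96 sigma.
CI_TO_SIGMA_DIVISOR = 3.92

# F2-derived families use the 530 constant; fully inbred families the 163 one.
# TC and advanced F generations are treated as F2-derived, DH as inbred.
_F2_FAMILY = {
    PopulationType.BC,
    PopulationType.F2,
    PopulationType.F2_3,
    PopulationType.F3_4,
    PopulationType.TC,
}
_RIL_FAMILY = {PopulationType.RIL, PopulationType.DH}

_FORMULA_CONSTANT = {
    **{p: 530.0 for p in _F2_FAMILY},
    **{p: 163.0 for p in _RIL_FAMILY},
}


class NoFormulaError(ValueError):
    """No CI-imputation formula applies to this population type."""


def normalize_r_squared(r_squared: float) -> float:
    """Rescale an R² given as a percent (value > 1) to a fraction."""
    if r_squared > 1:
        logger.warning("R² %.3g > 1; interpreting as percent", r_squared)
        return r_squared / 100.0
    return r_squared


def impute_ci(
    n: int, r_squared: float, population_type: PopulationType | str
) -> float:
    """Impute a 95% CI width (cM) from population size, R² and type."""
    population_type = PopulationType(population_type)
    if n <= 0 or r_squared <= 0:
        raise ValueError(
            f"population size and R² must be positive (N={n}, R²={r_squared})"
        )
    r_squared = normalize_r_squared(r_squared)
    try:
        constant = _FORMULA_CONSTANT[population_type]
    except KeyError:
        raise NoFormulaError(
            f"no CI-imputation formula for population type "
            f"{population_type.value!r}; record must carry an explicit CI or "
            "flanking markers"
        ) from None
    if population_type in {PopulationType.TC, PopulationType.F3_4, PopulationType.DH}:
        logger.debug(
            "population type %s assigned to the %s-constant formula",
            population_type.value,
            int(constant),
        )
    return constant / (n * r_squared)


def apply_lod_default(record: QTLRecord, default: float = DEFAULT_LOD) -> QTLRecord:
    """Return the record with a missing LOD filled in by the default."""
    if record.lod is None:
        return replace(record, lod=default)
    return record


def apply_lod_defaults(
    records: Iterable[QTLRecord], default: float = DEFAULT_LOD
) -> list[QTLRecord]:
    return [apply_lod_default(r, default) for r in records]


def ci_to_sigma(ci_width: float) -> float:
    """Convert a 95% CI width (cM) to the standard deviation of the QTL position."""
    if ci_width <= 0:
        raise ValueError(f"CI width must be positive, got {ci_width}")
    return ci_width / CI_TO_SIGMA_DIVISOR


def sigma_to_ci(sigma: float) -> float:
    """Inverse of :func:`ci_to_sigma`."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return sigma * CI_TO_SIGMA_DIVISOR
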