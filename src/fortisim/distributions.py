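"""Parametric habitual-intake distributions and the fortification mean shift.

Usual (long-run average) daily intakes of a micronutrient within a population
stratum are right-skewed and are modelled here by a two-parameter log-normal
or gamma distribution.  Both families are re-parameterised internally by
their analytic mean and coefficient of variation (CV = sd/mean) because the
two operations this module exists for are mean/CV-natural:

* construction from a (mean, CV) pair, and
* modelling fortification as a rightward shift of the whole distribution —
  the fortified distribution keeps the family and, under the default
  convention, the CV of the unfortified one, while its mean increases by
  exactly the daily intake contribution of the fortificant.

A constant-SD shift convention is available as a sensitivity switch.

Closed-form conversions used throughout:

* log-normal: ``sigma^2 = ln(1 + cv^2)``, ``mu = ln(mean) - sigma^2 / 2``
* gamma: ``shape = 1 / cv^2``, ``scale = mean * cv^2``
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy import stats

from .errors import InvalidParameterError

LOGNORMAL = "lognormal"
GAMMA = "gamma"
FAMILIES = (LOGNORMAL, GAMMA)

#: CVs at or below this are treated as a point mass for cdf/quantile purposes.
POINT_MASS_CV = 1e-6

SHIFT_CV = "cv"
SHIFT_SD = "sd"


@dataclass(frozen=True)
class IntakeDistribution:
    """Usual-intake distribution for one country x age-sex group x nutrient.

    Parameters
    ----------
    family:
        ``"lognormal"`` or ``"gamma"``.
    mean, cv:
        Analytic mean (intake units/day) and coefficient of variation.
    country, age_sex_group, nutrient:
        Optional stratum identifiers carried for error messages and reports.
    """

    family: str
    mean: float
    cv: float
    country: str = ""
    age_sex_group: str = ""
    nutrient: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidParameterError(f"unknown family {self.family!r}")
        if not (self.mean > 0):
            raise InvalidParameterError(f"mean must be positive, got {self.mean}")
        if not (self.cv > 0):
            raise InvalidParameterError(f"cv must be positive, got {self.cv}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_mean_cv(
        cls,
        family: str,
        mean: float,
        cv: float,
        **identifiers: str,
    ) -> "IntakeDistribution":
        """Build a distribution with the given analytic mean and CV."""
        return cls(family=family, mean=float(mean), cv=float(cv), **identifiers)

    @classmethod
    def from_params(
        cls,
        family: str,
        param1: float,
        param2: float,
        **identifiers: str,
    ) -> "IntakeDistribution":
        """Build from family-native parameters.

        ``(param1, param2)`` are (mu, sigma) on the log scale for the
        log-normal family and (shape, scale) for the gamma family.
        """
        if not (param2 > 0):
            raise InvalidParameterError(f"param2 must be positive, got {param2}")
        if family == LOGNORMAL:
            mu, sigma = float(param1), float(param2)
            mean = math.exp(mu + sigma**2 / 2.0)
            cv = math.sqrt(math.expm1(sigma**2))
        elif family == GAMMA:
            shape, scale = float(param1), float(param2)
            if not (shape > 0):
                raise InvalidParameterError(f"gamma shape must be positive, got {shape}")
            mean = shape * scale
            cv = 1.0 / math.sqrt(shape)
        else:
            raise InvalidParameterError(f"unknown family {family!r}")
        return cls(family=family, mean=mean, cv=cv, **identifiers)

    # -- native parameters -------------------------------------------------

    @property
    def param1(self) -> float:
        """Log-normal mu, or gamma shape."""
        if self.family == LOGNORMAL:
            sigma2 = math.log1p(self.cv**2)
            return math.log(self.mean) - sigma2 / 2.0
        return 1.0 / self.cv**2

    @property
    def param2(self) -> float:
        """Log-normal sigma, or gamma scale."""
        if self.family == LOGNORMAL:
            return math.sqrt(math.log1p(self.cv**2))
        return self.mean * self.cv**2

    @property
    def sd(self) -> float:
        return self.mean * self.cv

    @property
    def is_point_mass(self) -> bool:
        return self.cv <= POINT_MASS_CV

    def moments(self) -> tuple[float, float, float]:
        """Return ``(mean, sd, cv)`` in intake units/day."""
        return self.mean, self.sd, self.cv

    # -- density / cdf / quantile ------------------------------------------

    def _frozen(self):
        if self.family == LOGNORMAL:
            return stats.lognorm(s=self.param2, scale=math.exp(self.param1))
        return stats.gamma(a=self.param1, scale=self.param2)

    def pdf(self, x):
        return self._frozen().pdf(x)

    def cdf(self, x):
        """P(intake <= x); a point mass steps from 0 to 1 at the mean."""
        if self.is_point_mass:
            import numpy as np

            return (np.asarray(x, dtype=float) >= self.mean).astype(float)
        return self._frozen().cdf(x)

    def quantile(self, p):
        if self.is_point_mass:
            return self.mean
        return self._frozen().ppf(p)

    def sample(self, n: int, rng) -> "object":
        """Draw ``n`` usual intakes (used only by sampling oracles)."""
        return self._frozen().rvs(size=n, random_state=rng)

    # -- the fortification shift -------------------------------------------

    def shift(self, delta: float, convention: str = SHIFT_CV) -> "IntakeDistribution":
        """Shift the distribution right by a fortificant contribution.

        The shifted distribution keeps the family; its mean is
        ``mean + delta`` exactly.  Under the default ``"cv"`` convention the
        CV is preserved (the SD scales with the mean); under ``"sd"`` the SD
        is preserved instead.
        """
        if delta < 0:
            raise InvalidParameterError(
                f"fortification contribution must be non-negative, got {delta}"
            )
        if delta == 0:
            return self
        new_mean = self.mean + float(delta)
        if convention == SHIFT_CV:
            new_cv = self.cv
        elif convention == SHIFT_SD:
            new_cv = self.sd / new_mean
        else:
            raise InvalidParameterError(f"unknown shift convention {convention!r}")
        return replace(self, mean=new_mean, cv=new_cv)


def shift_distribution(
    dist: IntakeDistribution, delta: float, convention: str = SHIFT_CV
) -> IntakeDistribution:
    """Functional alias for :meth:`IntakeDistribution.shift`."""
    return dist.shift(delta, convention=convention)
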