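"""Uncertainty descriptors and Latin hypercube sampling.

Nominal biokinetic parameters become statistical quantities: a normal
parameter with mean ``mu`` and coefficient of variation ``c_v`` has
``sigma = c_v * mu`` and 95% bounds ``mu -/+ 1.96 sigma`` (the 2.5th and
97.5th percentiles); a lognormal parameter with geometric mean ``mu*`` and
geometric SD ``sigma*`` has bounds ``mu* / (sigma*)^1.96`` and
``mu* * (sigma*)^1.96``.

Latin hypercube sampling (LHS) operates on the [min, max]-truncated
distribution of each parameter: the truncated probability mass is split into
``n`` equal-probability strata, one value is drawn per stratum by inverse
CDF, and columns are paired by independent random permutations.  A fixed
seed reproduces the design bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .nuclear_data import LN2, ValidationError

__all__ = [
    "ParameterSpec",
    "SampleMatrix",
    "transfer_coefficient",
    "propagate_k_cv",
    "normal_bounds",
    "lognormal_bounds",
    "latin_hypercube",
    "Z95",
    "DEFAULT_CV",
]

#: Two-sided 95% coverage multiplier used throughout (2.5th/97.5th percentiles).
Z95 = 1.96

#: Default coefficient of variation assumed for biokinetic transfer
#: coefficients when no parameter-specific information is available.
DEFAULT_CV = 0.20


def transfer_coefficient(t_half: float, deposition_fraction: float) -> float:
    """Transfer coefficient k = ln2 / T * F (d^-1).

    ``t_half`` is the removal half-time from the donor compartment (days) and
    ``deposition_fraction`` the fraction of the outflow deposited in the
    receiving compartment.
    """
    if not t_half > 0:
        raise ValidationError(f"half-time must be positive, got {t_half}")
    if not 0.0 <= deposition_fraction <= 1.0:
        raise ValidationError(
            f"deposition fraction out of [0,1]: {deposition_fraction}"
        )
    return LN2 / t_half * deposition_fraction


def propagate_k_cv(cv_components) -> float:
    """First-order product-rule propagation: cv_k = sqrt(sum cv_i^2).

    Components are the coefficients of variation of the multiplicative
    factors entering a transfer coefficient (half-time, deposition fraction,
    and any further multiplicative factor supplied).
    """
    cvs = [float(c) for c in cv_components]
    if any(c < 0 for c in cvs):
        raise ValidationError(f"coefficients of variation must be >= 0: {cvs}")
    return math.sqrt(sum(c * c for c in cvs))


def normal_bounds(mu: float, cv: float) -> tuple[float, float]:
    """95% bounds (2.5th, 97.5th percentiles) of a normal parameter.

    Raises if the lower bound is non-positive: rate parameters must stay
    positive, and the caller should switch to a lognormal description.
    """
    if not mu > 0:
        raise ValidationError(f"mean must be positive, got {mu}")
    if cv < 0:
        raise ValidationError(f"cv must be >= 0, got {cv}")
    sigma = cv * mu
    lo, hi = mu - Z95 * sigma, mu + Z95 * sigma
    if lo <= 0 and cv > 0:
        raise ValidationError(
            f"normal 2.5th percentile non-positive ({lo:.4g}); "
            "use a lognormal description for this parameter"
        )
    return lo, hi


def lognormal_bounds(gm: float, gsd: float) -> tuple[float, float]:
    """95% bounds of a lognormal parameter: gm / gsd^1.96, gm * gsd^1.96."""
    if not gm > 0:
        raise ValidationError(f"geometric mean must be positive, got {gm}")
    if gsd < 1.0:
        raise ValidationError(f"geometric SD must be >= 1, got {gsd}")
    factor = gsd ** Z95
    return gm / factor, gm * factor


@dataclass(frozen=True)
class ParameterSpec:
    """One sampled parameter: distribution family, location, spread, bounds.

    For ``distribution="normal"``, ``mean``/``cv`` are the arithmetic mean
    and coefficient of variation; for ``"lognormal"`` they are the geometric
    mean and geometric SD.  ``min``/``max`` default to the distribution's
    2.5th/97.5th percentiles but may be overridden (several published
    parameter tables are asymmetric about their means; explicit bounds are
    honoured as printed rather than forced symmetric).
    """

    name: str
    distribution: str  # "normal" | "lognormal"
    mean: float
    cv: float
    min: float | None = None
    max: float | None = None

    def __post_init__(self) -> None:
        if self.distribution not in ("normal", "lognormal"):
            raise ValidationError(f"unknown distribution {self.distribution!r}")
        if not self.mean > 0:
            raise ValidationError(f"{self.name}: location must be positive")
        lo, hi = self.min, self.max
        if lo is None or hi is None:
            if self.distribution == "normal":
                if self.cv > 0 and self.mean - Z95 * self.cv * self.mean <= 0:
                    raise ValidationError(
                        f"{self.name}: normal bounds cross zero; use lognormal"
                    )
                lo, hi = (
                    (self.mean, self.mean)
                    if self.cv == 0
                    else normal_bounds(self.mean, self.cv)
                )
            else:
                lo, hi = lognormal_bounds(self.mean, self.cv)
            object.__setattr__(self, "min", lo)
            object.__setattr__(self, "max", hi)
        if not (self.min <= self.max):
            raise ValidationError(f"{self.name}: min > max")
        if self.min < 0:
            raise ValidationError(f"{self.name}: negative minimum for rate parameter")

    @property
    def sigma(self) -> float:
        """Scale on the natural axis: sigma for normal, sd of logs for lognormal."""
        if self.distribution == "normal":
            return self.cv * self.mean
        return math.log(self.cv)

    def is_degenerate(self) -> bool:
        return self.sigma == 0.0 or self.min == self.max

    def _frozen(self):
        """The underlying (untruncated) scipy distribution."""
        if self.distribution == "normal":
            return stats.norm(loc=self.mean, scale=self.sigma)
        return stats.lognorm(s=self.sigma, scale=self.mean)


@dataclass(frozen=True)
class SampleMatrix:
    """An n x m Latin hypercube design with its column names and seed."""

    names: tuple[str, ...]
    values: np.ndarray  # shape (n, m)
    seed: int

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.names))


def _lhs_column(
    spec: ParameterSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    if spec.is_degenerate():
        return np.full(n, spec.mean)
    dist = spec._frozen()
    p_lo = float(dist.cdf(spec.min))
    p_hi = float(dist.cdf(spec.max))
    if not p_hi > p_lo:
        return np.full(n, 0.5 * (spec.min + spec.max))
    # one uniform draw inside each of the n equal-probability strata
    strata = p_lo + (p_hi - p_lo) * (np.arange(n) + rng.uniform(size=n)) / n
    values = np.asarray(dist.ppf(strata), dtype=float)
    values = np.clip(values, spec.min, spec.max)  # guard ppf round-off
    return rng.permutation(values)


def latin_hypercube(
    specs: list[ParameterSpec], n: int, seed: int
) -> SampleMatrix:
    """Draw an n-run LHS design over the given parameter specs.

    Each column is stratified on its own truncated distribution and then
    independently permuted (random pairing across parameters).  The same
    (specs, n, seed) triple yields a bit-identical matrix.
    """
    if n < 2:
        raise ValidationError(f"need at least 2 samples, got {n}")
    rng = np.random.default_rng(seed)
    cols = [_lhs_column(spec, n, rng) for spec in specs]
    values = np.column_stack(cols) if cols else np.empty((n, 0))
    return SampleMatrix(
        names=tuple(s.name for s in specs), values=values, seed=seed
    )
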