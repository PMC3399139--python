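"""Node-age calibration priors built from volcanic-island ages.

Two families are supported, mirroring the two ways island ages are used to
calibrate divergence times:

* a *probabilistic* (soft) calibration — a normal density centred on the
  island age, wide enough that the lower 99% one-sided limit reaches the
  present (age 0), so the data may pull the node age away from the island
  age in either direction;
* a *punctual* calibration — a hard-bounded uniform interval of total width
  0.02 Ma around the island age, emulating a fixed calibration point: any
  age outside the bounds has zero prior probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np

#: One-sided 99% standard-normal quantile: Phi(Z99) = 0.99.
Z99 = 2.3263478740408408

#: Half-width (Ma) of a punctual hard-bounded calibration interval.
PUNCTUAL_HALF_WIDTH = 0.01

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class CalibrationPrior:
    """A per-node calibration density: ``normal(mean, sd)`` or ``hard_uniform``."""

    kind: Literal["normal", "hard_uniform"]
    mean: Optional[float] = None
    sd: Optional[float] = None
    lower: Optional[float] = None
    upper: Optional[float] = None

    def __post_init__(self):
        if self.kind == "normal":
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise ValueError("normal prior requires mean and sd > 0")
        elif self.kind == "hard_uniform":
            if (
                self.lower is None
                or self.upper is None
                or not (0 <= self.lower < self.upper)
            ):
                raise ValueError("hard_uniform prior requires 0 <= lower < upper")
        else:
            raise ValueError(f"unknown prior kind {self.kind!r}")

    @property
    def reference_age(self) -> float:
        """The island age the prior encodes (mean, or interval midpoint)."""
        if self.kind == "normal":
            return float(self.mean)
        return 0.5 * (self.lower + self.upper)

    def log_density(self, age: float) -> float:
        return prior_log_density(self, age)

    def density(self, age) -> np.ndarray:
        """Vectorized density, for plotting grids and KL references."""
        age = np.asarray(age, dtype=float)
        if self.kind == "normal":
            z = (age - self.mean) / self.sd
            return np.exp(-0.5 * z * z) / (self.sd * math.sqrt(2 * math.pi))
        inside = (age >= self.lower) & (age <= self.upper)
        return np.where(inside, 1.0 / (self.upper - self.lower), 0.0)


def compute_prior_sd(mean: float) -> float:
    """Standard deviation (Ma) for a soft normal calibration of a given mean.

    The sd is chosen so the one-sided 99% lower limit of ``N(mean, sd)``
    reaches age zero (the present): ``sd = mean / Z99``, then rounded to the
    nearest 0.1 Ma as calibration tables conventionally print them.
    """
    if mean <= 0:
        raise ValueError(f"calibration mean must be positive, got {mean}")
    return math.floor(mean / Z99 * 10.0 + 0.5) / 10.0


def punctual_interval(mean: float) -> tuple[float, float]:
    """Hard bounds (Ma) emulating a punctual calibration at ``mean``.

    The interval is ``mean ± 0.01`` Ma — narrow enough that the node age is
    effectively fixed, while remaining a proper density.
    """
    if mean <= PUNCTUAL_HALF_WIDTH:
        raise ValueError(
            f"punctual calibration mean must exceed {PUNCTUAL_HALF_WIDTH}, got {mean}"
        )
    # round to the printed precision to avoid float dust in serialized tables
    return (round(mean - PUNCTUAL_HALF_WIDTH, 6), round(mean + PUNCTUAL_HALF_WIDTH, 6))


def prior_log_density(prior: CalibrationPrior, age: float) -> float:
    """Log-density of a calibration prior at ``age`` (Ma).

    The normal family is deliberately not truncated at zero: the dating
    model's own support (node ages above their children's, hence >= 0)
    imposes nonnegativity and implicitly renormalizes.
    """
    if prior.kind == "normal":
        z = (age - prior.mean) / prior.sd
        return -0.5 * z * z - math.log(prior.sd) - _LOG_SQRT_2PI
    if prior.lower <= age <= prior.upper:
        return -math.log(prior.upper - prior.lower)
    return -math.inf


@dataclass(frozen=True)
class CalibrationEntry:
    """One calibrated node: the MRCA of ``(taxon_a, taxon_b)`` tied to an island."""

    taxon_a: str
    taxon_b: str
    island_name: str
    island_age: float
    prior: Optional[CalibrationPrior] = None

    def __post_init__(self):
        if self.island_age <= 0:
            raise ValueError("island_age must be positive")


@dataclass(frozen=True)
class CalibrationTable:
    entries: tuple[CalibrationEntry, ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(self.entries))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def build_schemes(table: CalibrationTable) -> tuple[CalibrationTable, CalibrationTable]:
    """Expand island ages into the two parallel calibration schemes.

    Returns ``(normal_scheme, punctual_scheme)`` over the same nodes: the
    first assigns each node ``normal(island_age, compute_prior_sd(island_age))``,
    the second the hard-bounded ``punctual_interval(island_age)``.
    """
    if len(table) == 0:
        raise ValueError(
            "calibration table is empty; at least one calibrated node is "
            "required to anchor the timescale"
        )
    normal_entries = []
    punctual_entries = []
    for e in table:
        m = e.island_age
        normal_entries.append(
            replace(e, prior=CalibrationPrior("normal", mean=m, sd=compute_prior_sd(m)))
        )
        lo, hi = punctual_interval(m)
        punctual_entries.append(
            replace(e, prior=CalibrationPrior("hard_uniform", lower=lo, upper=hi))
        )
    return CalibrationTable(tuple(normal_entries)), CalibrationTable(tuple(punctual_entries))
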