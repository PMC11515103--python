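"""Marginal distributions of the simulated clinical variables.

Each of the five cohort columns (heart rate, systolic blood pressure,
Glasgow Coma Scale, base deficit, transfusion volume) is described by a
:class:`MarginalSpec`: either a normal distribution truncated to
physiologic limits, or -- for the GCS only -- a trimodal discrete
distribution on the integers 3..15 built from discretized normal
components centred at the modes 3, 7 and 15.

Values are produced by pushing copula uniforms through the inverse CDF
(:func:`inverse_marginal`).  ``quantile`` truncation inverts the CDF of
the bounded law and preserves the copula's rank structure exactly; the
``clip`` mode (the pipeline default) inverts the unrestricted normal and
clips, which creates point masses at the limits and attenuates rank
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigError, DomainError

#: Canonical column order of a cohort table.
VARIABLES = ("hr", "sbp", "gcs", "bd", "transfusion")

#: Integer support of the Glasgow Coma Scale.
GCS_SUPPORT = np.arange(3, 16)

#: Required modes of the trimodal GCS mixture.
GCS_MODES = (3, 7, 15)

TRUNCATION_MODES = ("quantile", "clip")


@dataclass(frozen=True)
class MixtureComponent:
    """One discretized-normal component of the trimodal GCS mixture."""

    weight: float
    mode: int
    spread: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ConfigError(f"mixture weight {self.weight} not in [0, 1]")
        if self.spread <= 0:
            raise ConfigError(f"mixture spread {self.spread} must be positive")


@dataclass(frozen=True)
class MarginalSpec:
    """Parametric description of one variable's marginal distribution.

    Parameters
    ----------
    name
        One of ``hr``, ``sbp``, ``gcs``, ``bd``, ``transfusion``.
    family
        ``"truncated-normal"`` or ``"discrete-trimodal"`` (GCS only).
    location, scale
        Mean and SD of the underlying normal, in the variable's units.
        Ignored for the discrete-trimodal family (the mixture rules).
    lower_bound, upper_bound
        Physiologic truncation limits.
    round_to_integer
        Round sampled values half-away-from-zero, then re-clip.
    mixture
        Three :class:`MixtureComponent` entries; required iff the family
        is ``discrete-trimodal``.
    placeholder
        Marks parameter values as documented placeholders rather than
        registry-derived estimates; propagated into run warnings.
    """

    name: str
    family: str
    location: float = 0.0
    scale: float = 1.0
    lower_bound: float = -np.inf
    upper_bound: float = np.inf
    round_to_integer: bool = False
    mixture: tuple[MixtureComponent, ...] | None = None
    placeholder: bool = False

    def __post_init__(self) -> None:
        if self.name not in VARIABLES:
            raise ConfigError(f"unknown variable name {self.name!r}")
        if self.family not in ("truncated-normal", "discrete-trimodal"):
            raise ConfigError(f"unknown marginal family {self.family!r}")
        if self.family == "discrete-trimodal" and self.name != "gcs":
            raise ConfigError(
                f"discrete-trimodal family is reserved for gcs, got {self.name!r}"
            )
        if not self.lower_bound < self.upper_bound:
            raise ConfigError(
                f"{self.name}: lower_bound {self.lower_bound} must be < "
                f"upper_bound {self.upper_bound}"
            )
        if self.scale <= 0:
            raise ConfigError(f"{self.name}: scale must be positive")
        if self.family == "discrete-trimodal":
            if self.mixture is None or len(self.mixture) != 3:
                raise ConfigError("discrete-trimodal requires a 3-component mixture")
            total = sum(c.weight for c in self.mixture)
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"mixture weights sum to {total}, expected 1")
            modes = tuple(sorted(c.mode for c in self.mixture))
            if modes != GCS_MODES:
                raise ConfigError(f"gcs mixture modes must be {GCS_MODES}, got {modes}")
        elif self.mixture is not None:
            raise ConfigError("mixture is only valid for the discrete-trimodal family")
        # Hard physiologic invariants.
        if self.name == "gcs":
            if self.family != "discrete-trimodal":
                raise ConfigError("gcs must use the discrete-trimodal family")
            if (self.lower_bound, self.upper_bound) != (3, 15):
                raise ConfigError("gcs bounds must be exactly [3, 15]")
            if not self.round_to_integer:
                raise ConfigError("gcs requires round_to_integer=True")
        if self.name == "transfusion" and self.lower_bound != 0:
            raise ConfigError("transfusion lower_bound must be 0")
        if self.name == "hr" and self.upper_bound != 220:
            raise ConfigError("hr upper_bound must be 220")


def trimodal_pmf(spec: MarginalSpec) -> np.ndarray:
    """Probability mass function of the trimodal GCS on the support 3..15.

    Each component is a normal discretized to integer bins; the end bins
    absorb the tails beyond the bounds (equivalent to rounding then
    clipping), so the mixture is exactly normalized by construction.
    """
    if spec.family != "discrete-trimodal":
        raise ConfigError("trimodal_pmf requires a discrete-trimodal spec")
    assert spec.mixture is not None
    hi = GCS_SUPPORT + 0.5
    lo = GCS_SUPPORT - 0.5
    hi = np.where(GCS_SUPPORT == spec.upper_bound, np.inf, hi)
    lo = np.where(GCS_SUPPORT == spec.lower_bound, -np.inf, lo)
    pmf = np.zeros(GCS_SUPPORT.size)
    for comp in spec.mixture:
        pmf += comp.weight * (
            stats.norm.cdf(hi, comp.mode, comp.spread)
            - stats.norm.cdf(lo, comp.mode, comp.spread)
        )
    return pmf / pmf.sum()


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def inverse_marginal(
    spec: MarginalSpec,
    u: float | np.ndarray,
    truncation: str = "quantile",
) -> np.ndarray:
    """Map uniforms in (0, 1) to variable values via the inverse CDF.

    ``truncation="quantile"`` inverts the CDF of the normal restricted to
    the bounds (no point mass at the limits); ``"clip"`` inverts the
    unrestricted normal and clips.  The discrete-trimodal family is
    inverted through its cumulative mass function and is unaffected by
    the truncation mode.
    """
    if truncation not in TRUNCATION_MODES:
        raise ConfigError(f"truncation must be one of {TRUNCATION_MODES}")
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise DomainError("uniform inputs must lie strictly inside (0, 1)")

    if spec.family == "discrete-trimodal":
        cum = np.cumsum(trimodal_pmf(spec))
        idx = np.searchsorted(cum, u, side="left")
        return GCS_SUPPORT[np.minimum(idx, GCS_SUPPORT.size - 1)].astype(float)

    if truncation == "quantile":
        a = (spec.lower_bound - spec.location) / spec.scale
        b = (spec.upper_bound - spec.location) / spec.scale
        x = stats.truncnorm.ppf(u, a, b, loc=spec.location, scale=spec.scale)
    else:
        x = stats.norm.ppf(u, loc=spec.location, scale=spec.scale)
    x = np.clip(x, spec.lower_bound, spec.upper_bound)
    if spec.round_to_integer:
        x = np.clip(_round_half_away(x), spec.lower_bound, spec.upper_bound)
    return x
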