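"""Target rank-correlation structure and its Gaussian-copula translation.

Correlation targets are specified on the Spearman scale as a magnitude
matrix plus a sign matrix, so physiologic direction conventions (SBP and
GCS vary inversely with the other variables) are kept separate from the
strength of association.  The exact Gaussian-copula relation

    r = 2 * sin(pi * rho_s / 6)

converts each Spearman target into the latent normal correlation that
reproduces it, and the resulting matrix is validated for positive
definiteness (with a nearest-correlation-matrix repair as a logged
fallback).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.correlation_tools import corr_nearest

from .errors import ConfigError, CorrelationError, StructuralError
from .marginals import VARIABLES

SCENARIOS = ("equal", "unequal", "swap-equal", "swap-unequal")

#: Minimum eigenvalue below which a copula matrix is treated as non-PD.
PD_EPS = 1e-10


def spearman_to_copula_param(rho_s: float | np.ndarray) -> float | np.ndarray:
    """Latent Gaussian correlation reproducing a Spearman target.

    Exact for the bivariate Gaussian copula: ``r = 2 sin(pi rho_s / 6)``.
    Odd in ``rho_s``, fixes 0 and +/-1, and satisfies ``|r| >= |rho_s|``.
    """
    arr = np.asarray(rho_s, dtype=float)
    if np.any(np.abs(arr) > 1.0):
        raise CorrelationError("Spearman correlation must lie in [-1, 1]")
    out = 2.0 * np.sin(np.pi * arr / 6.0)
    return float(out) if np.isscalar(rho_s) else out


def _check_sign_consistent(signs: np.ndarray) -> None:
    # signs is consistent iff s_ij == d_i * d_j for per-variable flips d;
    # d can be read off the first row when it is itself consistent.
    d = signs[0]
    if not np.array_equal(signs, np.outer(d, d)):
        raise CorrelationError(
            "sign matrix is not flippable to all-positive by per-variable "
            "sign changes"
        )


@dataclass(frozen=True)
class CorrelationSpec:
    """Labelled 5x5 Spearman target: magnitudes, signs, and scenario id."""

    magnitudes: np.ndarray
    signs: np.ndarray
    scenario_id: str
    labels: tuple[str, ...] = VARIABLES

    def __post_init__(self) -> None:
        mags = np.asarray(self.magnitudes, dtype=float)
        signs = np.asarray(self.signs, dtype=float)
        object.__setattr__(self, "magnitudes", mags)
        object.__setattr__(self, "signs", signs)
        if self.scenario_id not in SCENARIOS:
            raise ConfigError(f"unknown scenario_id {self.scenario_id!r}")
        if tuple(self.labels) != VARIABLES:
            raise ConfigError(f"labels must be {VARIABLES}")
        k = len(VARIABLES)
        if mags.shape != (k, k) or signs.shape != (k, k):
            raise StructuralError("correlation matrices must be 5x5")
        if not np.array_equal(mags, mags.T) or not np.array_equal(signs, signs.T):
            raise StructuralError("correlation matrices must be symmetric")
        if np.any(mags < 0) or np.any(mags > 1):
            raise CorrelationError("magnitudes must lie in [0, 1]")
        if not np.allclose(np.diag(mags), 1.0):
            raise StructuralError("magnitude diagonal must be 1")
        if not np.all(np.isin(signs, (-1.0, 1.0))):
            raise CorrelationError("signs must be -1 or +1")
        if not np.allclose(np.diag(signs), 1.0):
            raise StructuralError("sign diagonal must be +1")
        _check_sign_consistent(signs)

    @property
    def target(self) -> np.ndarray:
        """Signed Spearman target matrix (signs * magnitudes)."""
        return self.signs * self.magnitudes


@dataclass(frozen=True)
class ValidatedCopulaMatrix:
    """Copula correlation matrix after PD validation / repair."""

    matrix: np.ndarray
    repaired: bool
    repair_distance: float

    @property
    def cholesky(self) -> np.ndarray:
        return np.linalg.cholesky(self.matrix)


def validate_correlation_matrix(spec: CorrelationSpec) -> ValidatedCopulaMatrix:
    """Translate a Spearman target into a validated copula matrix.

    Applies :func:`spearman_to_copula_param` off-diagonal, then checks
    positive definiteness.  A matrix that fails the check is projected to
    the nearest positive-definite correlation matrix; the Frobenius
    distance of the repair is recorded (structural defects -- asymmetry,
    non-unit diagonal -- are errors, never silently repaired, and are
    already rejected by :class:`CorrelationSpec`).
    """
    target = spec.target
    copula = np.asarray(spearman_to_copula_param(target), dtype=float)
    np.fill_diagonal(copula, 1.0)
    eigvals = np.linalg.eigvalsh(copula)
    if eigvals.min() > PD_EPS:
        return ValidatedCopulaMatrix(copula, repaired=False, repair_distance=0.0)
    repaired = np.asarray(corr_nearest(copula, threshold=1e-8))
    np.fill_diagonal(repaired, 1.0)
    repaired = (repaired + repaired.T) / 2.0
    if np.linalg.eigvalsh(repaired).min() <= 0:
        raise CorrelationError("positive-definite repair failed")
    distance = float(np.linalg.norm(repaired - copula, ord="fro"))
    return ValidatedCopulaMatrix(repaired, repaired=True, repair_distance=distance)


def _filled(k: int, value: float) -> np.ndarray:
    m = np.full((k, k), value)
    np.fill_diagonal(m, 1.0)
    return m


def default_signs() -> np.ndarray:
    """Physiologic direction convention: sbp and gcs flip sign."""
    flips = np.array([1.0 if v not in ("sbp", "gcs") else -1.0 for v in VARIABLES])
    return np.outer(flips, flips)


def scenario_correlation(scenario_id: str, *, base: float = 0.55,
                         strong: float = 0.8, weak: float = 0.3) -> CorrelationSpec:
    """Build the target Spearman structure for one of the four scenarios.

    ``equal``/``swap-equal``: all off-diagonal magnitudes at ``base``.
    ``unequal``/``swap-unequal``: the strongly-associated block
    {hr, sbp, gcs, transfusion} is mutually at ``strong``; bd keeps
    ``base`` with the predictors and drops to ``weak`` with transfusion.
    Raising the within-block magnitudes alongside the transfusion ones is
    what keeps the matrix positive definite while preserving the bd
    target exactly -- holding them at ``base`` makes the matrix non-PD
    and the nearest-PD repair would silently inflate bd-transfusion.
    """
    if scenario_id not in SCENARIOS:
        raise ConfigError(f"unknown scenario_id {scenario_id!r}")
    mags = _filled(len(VARIABLES), base)
    if scenario_id in ("unequal", "swap-unequal"):
        block = [VARIABLES.index(v) for v in ("hr", "sbp", "gcs", "transfusion")]
        for a in block:
            for b in block:
                if a != b:
                    mags[a, b] = strong
        i, t = VARIABLES.index("bd"), VARIABLES.index("transfusion")
        mags[i, t] = mags[t, i] = weak
    return CorrelationSpec(magnitudes=mags, signs=default_signs(),
                           scenario_id=scenario_id)
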