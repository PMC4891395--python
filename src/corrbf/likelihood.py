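"""Reduced likelihood of the sample Pearson correlation.

Under a bivariate normal model the data enter every hypothesis test only
through the sufficient pair ``(n, r)``: the location and scale parameters of
the two margins are nuisance parameters that can be removed analytically,
leaving the sampling density of the sample correlation ``r`` given the
population correlation ``rho``.  That density is the likelihood used by all
Bayes factors in this package.

The exact density involves the Gaussian hypergeometric function:

    p(r | rho, n) = (n-2) * Gamma(n-1) / (sqrt(2*pi) * Gamma(n-1/2))
                    * (1-rho^2)^((n-1)/2) * (1-r^2)^((n-4)/2)
                    * (1-rho*r)^(-(n-3/2))
                    * 2F1(1/2, 1/2; n-1/2; (1+rho*r)/2)

Evaluation is carried out in log space; the 2F1 argument (1+rho*r)/2 lies in
(0, 1) where the series converges (c - a - b = n - 3/2 > 0 guarantees
convergence at the endpoint).  A large-n approximation that drops the slowly
varying hypergeometric factor is provided for cross-checking only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "BivariateSample",
    "StudySummary",
    "DegenerateDataError",
    "InsufficientDataError",
    "pearson_r",
    "log_r_density",
    "r_density",
    "log_r_density_jeffreys_approx",
    "classical_p_two_sided",
]

SMALL_N_WARNING = (
    "n < 10: with so few pairs the Bayes factor is dominated by the prior "
    "on rho rather than by the data"
)


class InsufficientDataError(ValueError):
    """Fewer complete pairs than the minimum (4) required downstream."""


class DegenerateDataError(ValueError):
    """Zero variance in a coordinate or |r| = 1: the reduced likelihood
    degenerates and every Bayes factor integral diverges."""


@dataclass(frozen=True)
class StudySummary:
    """Sufficient summary of one correlational study.

    Parameters
    ----------
    n : int
        Number of complete observation pairs, at least 4.
    r : float
        Sample Pearson correlation, strictly inside (-1, 1).
    label : str
        Free-text identifier carried through reports.
    """

    n: int
    r: float
    label: str = ""

    def __post_init__(self) -> None:
        n = int(self.n)
        if n != self.n:
            raise TypeError(f"n must be an integer, got {self.n!r}")
        object.__setattr__(self, "n", n)
        if n < 4:
            raise InsufficientDataError(f"need n >= 4 complete pairs, got {n}")
        r = float(self.r)
        if not math.isfinite(r):
            raise ValueError(f"r must be finite, got {r!r}")
        if abs(r) >= 1.0:
            raise DegenerateDataError(f"|r| must be < 1, got r = {r}")
        object.__setattr__(self, "r", r)
        if n < 10:
            warnings.warn(SMALL_N_WARNING, UserWarning, stacklevel=3)


@dataclass(frozen=True)
class BivariateSample:
    """Raw paired observations, reduced to a :class:`StudySummary`.

    ``pairs`` is a sequence of (x, y) measurements.  Pairs with a missing
    (NaN) coordinate are dropped by :func:`pearson_r`; non-finite values that
    are not NaN are rejected.
    """

    pairs: Sequence[tuple[float, float]]
    label: str = ""
    n_dropped: int = field(default=0, compare=False)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(self.pairs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("pairs must be a sequence of (x, y) tuples")
        return arr[:, 0], arr[:, 1]


def pearson_r(sample: BivariateSample) -> StudySummary:
    """Product-moment correlation of a raw sample.

    Missing (NaN) pairs are dropped and counted; infinite values raise.
    Degenerate data — fewer than 4 complete pairs, zero variance in either
    coordinate, or a perfect linear relation (|r| = 1) — raise, because all
    downstream integrals are undefined there.
    """
    x, y = sample.as_arrays()
    keep = ~(np.isnan(x) | np.isnan(y))
    n_dropped = int((~keep).sum())
    x, y = x[keep], y[keep]
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite (infinite) measurement in sample")
    n = x.size
    if n < 4:
        raise InsufficientDataError(
            f"need at least 4 complete pairs, got {n} "
            f"({n_dropped} dropped for missing values)"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in a coordinate; r undefined")
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} pair(s) with missing values", UserWarning,
            stacklevel=2,
        )
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-14:
        raise DegenerateDataError(
            f"perfect linear relation (r = {r:+.0f}); downstream tests "
            "require |r| < 1"
        )
    return StudySummary(n=n, r=r, label=sample.label)


def _validate_args(r: np.ndarray, rho: np.ndarray, n: float) -> None:
    if n < 4:
        raise ValueError(f"n must be >= 4, got {n}")
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| must be < 1")
    if np.any(np.abs(rho) >= 1.0):
        raise ValueError("|rho| must be < 1")


def log_r_density(r, rho, n: int):
    """Log of the exact sampling density of r given (rho, n).

    Vectorized over ``r`` and ``rho`` (broadcast).  The density is per unit
    r on (-1, 1).
    """
    r = np.asarray(r, dtype=float)
    rho = np.asarray(rho, dtype=float)
    _validate_args(r, rho, n)
    z = 0.5 * (1.0 + rho * r)
    hyp = special.hyp2f1(0.5, 0.5, n - 0.5, z)
    if np.any(~np.isfinite(hyp)) or np.any(hyp <= 0):
        raise ArithmeticError(
            f"hypergeometric evaluation failed for n={n}, "
            f"z range [{np.min(z)}, {np.max(z)}]"
        )
    out = (
        math.log(n - 2)
        + special.gammaln(n - 1)
        - 0.5 * math.log(2.0 * math.pi)
        - special.gammaln(n - 0.5)
        + 0.5 * (n - 1) * np.log1p(-rho * rho)
        + 0.5 * (n - 4) * np.log1p(-r * r)
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(hyp)
    )
    return out if out.ndim else float(out)


def r_density(r, rho, n: int):
    """Exact sampling density of the sample correlation; see module docs."""
    return np.exp(log_r_density(r, rho, n))


def log_r_density_jeffreys_approx(r, rho, n: int):
    """Large-n approximate reduced likelihood (cross-check only).

    Drops the hypergeometric factor and normalizes over (-1, 1) in r by the
    exact beta-function constant for the rho = 0 case; for rho != 0 the
    result is unnormalized up to a slowly varying factor.  Use only to
    sanity-check Bayes factors, never as the primary likelihood.
    """
    r = np.asarray(r, dtype=float)
    rho = np.asarray(rho, dtype=float)
    _validate_args(r, rho, n)
    log_c = -special.betaln(0.5, 0.5 * (n - 2)) - math.log(2.0)
    out = (
        log_c
        + 0.5 * (n - 1) * np.log1p(-rho * rho)
        + 0.5 * (n - 4) * np.log1p(-r * r)
        - (n - 1.5) * np.log1p(-rho * r)
    )
    return out if out.ndim else float(out)


def classical_p_two_sided(summary: StudySummary) -> float:
    """Two-sided p value for the null rho = 0.

    Uses the exact t transform: t = r * sqrt((n-2)/(1-r^2)) follows a
    Student t distribution with n-2 degrees of freedom under the null.
    """
    n, r = summary.n, summary.r
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))
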