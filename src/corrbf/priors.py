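"""Prior distributions on the population correlation rho.

Each alternative hypothesis in the test suite is defined by a prior on
rho over (-1, 1):

* ``UniformPrior`` — Jeffreys' default two-sided alternative, U(-1, 1);
  also covers one-sided (U(0, 1)) and interval-null (U(-c, c)) restrictions.
* ``StretchedBetaPrior`` — a beta(alpha, alpha) distribution on (rho+1)/2
  rescaled to (-1, 1).  Its spread is indexed by gamma = 1/alpha: gamma = 1
  is the uniform prior, gamma -> 0 collapses onto the point null.
* ``TruncatedPrior`` — any prior restricted to (lo, hi) and renormalized.
* ``PosteriorPrior`` — the posterior of rho from an original study, used as
  the alternative's prior in the replication test.

Priors expose ``logpdf``/``pdf`` on the open interval and their support;
normalization is exact by construction (uniform, stretched beta) or by
adaptive quadrature (truncation mass, posterior-based normalizing constant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import integrate, special

if TYPE_CHECKING:
    from .likelihood import StudySummary

__all__ = [
    "RhoPrior",
    "UniformPrior",
    "StretchedBetaPrior",
    "TruncatedPrior",
    "PosteriorPrior",
    "truncate",
    "parse_prior",
    "EmptySupportError",
]


class EmptySupportError(ValueError):
    """Truncation interval carries no prior mass."""


def _check_rho(rho: np.ndarray) -> None:
    if np.any(np.abs(rho) >= 1.0):
        raise ValueError("rho must lie strictly inside (-1, 1)")


class RhoPrior:
    """Base class: a probability density for rho on a sub-interval of (-1, 1)."""

    lo: float = -1.0
    hi: float = 1.0

    def logpdf(self, rho):  # pragma: no cover - abstract
        raise NotImplementedError

    def pdf(self, rho):
        rho = np.asarray(rho, dtype=float)
        _check_rho(rho)
        out = np.where(
            (rho > self.lo) & (rho < self.hi),
            np.exp(self.logpdf(np.clip(rho, self.lo + 1e-15, self.hi - 1e-15))),
            0.0,
        )
        return out if out.ndim else float(out)

    def spec_string(self) -> str:  # pragma: no cover - abstract
        raise NotImplementedError

    def __repr__(self) -> str:
        return f"{type(self).__name__}({self.spec_string()!r})"


@dataclass(repr=False)
class UniformPrior(RhoPrior):
    """Uniform prior on (lo, hi); the default alternative is U(-1, 1)."""

    lo: float = -1.0
    hi: float = 1.0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.lo < self.hi <= 1.0):
            raise ValueError(f"need -1 <= lo < hi <= 1, got ({self.lo}, {self.hi})")

    def logpdf(self, rho):
        rho = np.asarray(rho, dtype=float)
        _check_rho(rho)
        out = np.where(
            (rho > self.lo) & (rho < self.hi),
            -math.log(self.hi - self.lo),
            -np.inf,
        )
        return out if out.ndim else float(out)

    def spec_string(self) -> str:
        if (self.lo, self.hi) == (-1.0, 1.0):
            return "uniform"
        if (self.lo, self.hi) == (0.0, 1.0):
            return "onesided"
        if self.lo == -self.hi:
            return f"interval:c={self.hi:g}"
        return f"uniform:lo={self.lo:g},hi={self.hi:g}"


@dataclass(repr=False)
class StretchedBetaPrior(RhoPrior):
    """beta(alpha, alpha) on (rho+1)/2, stretched to (-1, 1).

    ``gamma = 1/alpha`` is the width on the sensitivity-analysis axis;
    alpha = 1 (gamma = 1) is the uniform prior.  Construct with either
    parameter: ``StretchedBetaPrior(alpha=2)`` or
    ``StretchedBetaPrior.from_gamma(0.5)``.
    """

    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and math.isfinite(self.alpha)):
            raise ValueError(f"alpha must be positive and finite, got {self.alpha}")

    @classmethod
    def from_gamma(cls, gamma: float) -> "StretchedBetaPrior":
        if not (0.0 < gamma <= 1.0):
            raise ValueError(f"gamma must lie in (0, 1], got {gamma}")
        return cls(alpha=1.0 / gamma)

    @property
    def gamma(self) -> float:
        return 1.0 / self.alpha

    def logpdf(self, rho):
        rho = np.asarray(rho, dtype=float)
        _check_rho(rho)
        a = self.alpha
        # beta density of (rho+1)/2 times the Jacobian 1/2
        out = (
            (a - 1.0) * (np.log1p(rho) + np.log1p(-rho))
            - (2.0 * a - 1.0) * math.log(2.0)
            - special.betaln(a, a)
        )
        return out if out.ndim else float(out)

    def spec_string(self) -> str:
        return f"beta:gamma={self.gamma:g}"


@dataclass(repr=False)
class TruncatedPrior(RhoPrior):
    """A base prior restricted to (lo, hi) and renormalized."""

    base: RhoPrior
    lo: float = -1.0
    hi: float = 1.0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.lo < self.hi <= 1.0):
            raise ValueError(f"need -1 <= lo < hi <= 1, got ({self.lo}, {self.hi})")
        if not (self.base.lo < self.hi and self.base.hi > self.lo):
            raise EmptySupportError("truncation interval outside base support")
        lo = max(self.lo, self.base.lo)
        hi = min(self.hi, self.base.hi)
        self.lo, self.hi = lo, hi
        self._log_mass = math.log(_prior_mass(self.base, lo, hi))

    def logpdf(self, rho):
        rho = np.asarray(rho, dtype=float)
        _check_rho(rho)
        out = np.where(
            (rho > self.lo) & (rho < self.hi),
            self.base.logpdf(np.clip(rho, self.lo + 1e-15, self.hi - 1e-15))
            - self._log_mass,
            -np.inf,
        )
        return out if out.ndim else float(out)

    def spec_string(self) -> str:
        return f"truncate({self.base.spec_string()},{self.lo:g},{self.hi:g})"


def _prior_mass(prior: RhoPrior, lo: float, hi: float) -> float:
    """Mass of ``prior`` on (lo, hi); sin(theta) substitution tames the
    endpoint behaviour of stretched-beta priors with alpha < 1."""
    t_lo, t_hi = math.asin(lo), math.asin(hi)
    val, _ = integrate.quad(
        lambda t: prior.pdf(math.sin(t)) * math.cos(t), t_lo, t_hi, limit=200
    )
    if val <= 1e-300:
        raise EmptySupportError(
            f"prior has no mass on ({lo}, {hi}); cannot truncate"
        )
    return val


class PosteriorPrior(RhoPrior):
    """Posterior of rho from an original study, used as a prior.

    The density is the normalized product of a base prior (default: the
    uniform default alternative) and the reduced likelihood of the original
    study's (n, r).  Evaluated analytically; the normalizing constant is the
    base-prior marginal likelihood of the original study, computed once by
    adaptive quadrature.
    """

    def __init__(self, origin: "StudySummary", base: RhoPrior | None = None):
        from .bayes import marginal_likelihood  # deferred: avoids cycle

        self.origin = origin
        self.base = base if base is not None else UniformPrior()
        self.lo, self.hi = self.base.lo, self.base.hi
        z, z_err = marginal_likelihood(origin, self.base)
        self._log_z = math.log(z)
        self.normalization_error = z_err

    def logpdf(self, rho):
        from .likelihood import log_r_density

        rho = np.asarray(rho, dtype=float)
        _check_rho(rho)
        inside = (rho > self.lo) & (rho < self.hi)
        rho_in = np.clip(rho, self.lo + 1e-15, self.hi - 1e-15)
        out = np.where(
            inside,
            log_r_density(self.origin.r, rho_in, self.origin.n)
            + self.base.logpdf(rho_in)
            - self._log_z,
            -np.inf,
        )
        return out if out.ndim else float(out)

    def spec_string(self) -> str:
        return f"replication:n={self.origin.n},r={self.origin.r:g}"


def truncate(prior: RhoPrior, lo: float, hi: float) -> RhoPrior:
    """Restrict ``prior`` to (lo, hi) and renormalize.

    Uniform priors truncate to uniform priors exactly; anything else is
    wrapped in :class:`TruncatedPrior`.
    """
    if isinstance(prior, UniformPrior):
        new_lo, new_hi = max(lo, prior.lo), min(hi, prior.hi)
        if new_lo >= new_hi:
            raise EmptySupportError("truncation interval outside base support")
        return UniformPrior(new_lo, new_hi)
    return TruncatedPrior(prior, lo, hi)


def parse_prior(spec: str) -> RhoPrior:
    """Parse a compact prior specification string.

    Accepted forms: ``uniform``, ``onesided``, ``beta:gamma=0.5``,
    ``interval:c=0.01``, ``replication:n=51,r=0.57``.
    """
    from .likelihood import StudySummary

    spec = spec.strip().lower()
    if spec == "uniform":
        return UniformPrior()
    if spec == "onesided":
        return UniformPrior(0.0, 1.0)
    head, _, tail = spec.partition(":")
    kv = {}
    if tail:
        for item in tail.split(","):
            k, _, v = item.partition("=")
            if not v:
                raise ValueError(f"malformed prior option {item!r} in {spec!r}")
            kv[k.strip()] = float(v)
    if head == "beta":
        if "gamma" in kv:
            return StretchedBetaPrior.from_gamma(kv["gamma"])
        if "alpha" in kv:
            return StretchedBetaPrior(alpha=kv["alpha"])
        raise ValueError(f"beta prior needs gamma= or alpha= in {spec!r}")
    if head == "interval":
        c = kv.get("c")
        if c is None or not (0.0 < c < 1.0):
            raise ValueError(f"interval prior needs c= in (0, 1) in {spec!r}")
        return UniformPrior(-c, c)
    if head == "replication":
        if "n" not in kv or "r" not in kv:
            raise ValueError(f"replication prior needs n= and r= in {spec!r}")
        return PosteriorPrior(StudySummary(n=int(kv["n"]), r=kv["r"]))
    raise ValueError(f"unknown prior specification {spec!r}")
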