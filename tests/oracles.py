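"""Independent numerical oracles for the test suite.

Everything here is deliberately written against mpmath (arbitrary
precision) or plain brute-force trapezoid sums, sharing no code with the
package's scipy-based fast path, so agreement between the two routes is a
genuine cross-check.
"""

from __future__ import annotations

import mpmath as mp

mp.mp.dps = 30


def mp_r_density(r: float, rho: float, n: int) -> mp.mpf:
    """Sampling density of the sample correlation, in arbitrary precision."""
    r, rho, n = mp.mpf(r), mp.mpf(rho), mp.mpf(n)
    const = (n - 2) * mp.gamma(n - 1) / (mp.sqrt(2 * mp.pi) * mp.gamma(n - mp.mpf("0.5")))
    return (
        const
        * (1 - rho**2) ** ((n - 1) / 2)
        * (1 - r**2) ** ((n - 4) / 2)
        * (1 - rho * r) ** (mp.mpf("1.5") - n)
        * mp.hyp2f1(mp.mpf("0.5"), mp.mpf("0.5"), n - mp.mpf("0.5"), (1 + rho * r) / 2)
    )


def mp_marginal_uniform(r: float, n: int, lo: float = -1.0, hi: float = 1.0) -> mp.mpf:
    """Marginal likelihood under a uniform prior on (lo, hi), mpmath quad."""
    width = mp.mpf(hi) - mp.mpf(lo)
    return (
        mp.quad(lambda rho: mp_r_density(r, rho, n), [lo, 0, float(r), hi] if lo < 0 < hi else [lo, float(max(min(r, hi), lo)), hi])
        / width
    )


def mp_bf01(r: float, n: int) -> float:
    """Two-sided default Bayes factor, fully independent route."""
    return float(mp_r_density(r, 0.0, n) / mp_marginal_uniform(r, n))


def mp_bf0_plus(r: float, n: int) -> float:
    """One-sided Bayes factor against rho ~ U(0, 1)."""
    return float(mp_r_density(r, 0.0, n) / mp_marginal_uniform(r, n, 0.0, 1.0))


def trapezoid_marginal(r: float, n: int, prior_pdf, lo: float, hi: float,
                       points: int = 1_000_001) -> float:
    """Brute-force trapezoid marginal likelihood on a huge uniform grid."""
    import numpy as np

    from corrbf.likelihood import r_density  # density only; not the quadrature

    eps = 1e-9
    rho = np.linspace(lo + eps, hi - eps, points)
    f = r_density(r, rho, n) * prior_pdf(rho)
    return float(np.trapezoid(f, rho))
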