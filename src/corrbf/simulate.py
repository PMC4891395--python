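"""Synthetic bivariate-normal data and Bayes factor calibration experiments.

The generative model matches the one assumed by every test in the package:
pairs (x, y) drawn from a bivariate normal with correlation rho.  Location
and scale are nuisance parameters — every Bayes factor depends on the data
only through (n, r), which is invariant under affine rescaling of either
coordinate — so the defaults are means 0 and scales 1.

Random streams: one :class:`numpy.random.Generator` per replicate, seeded
as ``default_rng([seed, rep])`` so replicates are order-independent and the
whole module is reproducible from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bayes import bf01_default
from .likelihood import BivariateSample, StudySummary, pearson_r

__all__ = [
    "SimulationSpec",
    "simulate_bivariate",
    "bf_consistency_experiment",
    "min_trials_for_detection",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a bivariate-normal simulation."""

    n: int
    rho: float
    mean_x: float = 0.0
    mean_y: float = 0.0
    sd_x: float = 1.0
    sd_y: float = 1.0
    reps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1.0:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")
        if self.sd_x <= 0 or self.sd_y <= 0:
            raise ValueError("scales must be positive")
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")
        if self.n < 4:
            raise ValueError(f"n must be >= 4, got {self.n}")


def _draw(spec: SimulationSpec, rep: int) -> BivariateSample:
    rng = np.random.default_rng([int(spec.seed), int(rep)])
    # Cholesky of the 2x2 correlation matrix
    z = rng.standard_normal((spec.n, 2))
    x = z[:, 0]
    y = spec.rho * z[:, 0] + math.sqrt(1.0 - spec.rho**2) * z[:, 1]
    pairs = np.column_stack(
        [spec.mean_x + spec.sd_x * x, spec.mean_y + spec.sd_y * y]
    )
    return BivariateSample(
        pairs=[tuple(row) for row in pairs],
        label=f"sim(n={spec.n},rho={spec.rho:g},seed={spec.seed},rep={rep})",
    )


def simulate_bivariate(spec: SimulationSpec) -> list[BivariateSample]:
    """Draw ``spec.reps`` independent datasets; bit-reproducible per seed."""
    return [_draw(spec, rep) for rep in range(spec.reps)]


def bf_consistency_experiment(
    spec: SimulationSpec, ns: Sequence[int] | None = None
) -> pd.DataFrame:
    """Quantiles of BF01 across replicates, per sample size.

    Under data generated from the null (rho = 0) the evidence for the null
    accumulates: the median BF01 grows with n.  Under rho != 0 the median
    BF01 falls below 1.  Returns a table indexed by n with the quartiles of
    the default two-sided BF01 over ``spec.reps`` replicates.
    """
    ns = list(ns) if ns is not None else [spec.n]
    rows = []
    for n in ns:
        sub = replace(spec, n=int(n))
        bfs = [
            bf01_default(pearson_r(sample)).bf01
            for sample in simulate_bivariate(sub)
        ]
        q25, q50, q75 = np.quantile(bfs, [0.25, 0.5, 0.75])
        rows.append(
            {"n": int(n), "reps": spec.reps, "bf01_q25": q25,
             "bf01_median": q50, "bf01_q75": q75}
        )
    return pd.DataFrame(rows).set_index("n")


def min_trials_for_detection(p_success: float, power: float) -> int:
    """Smallest k with 1 - (1 - p)^k >= power.

    The detection-power arithmetic for repeated independent draws, each
    succeeding with probability ``p_success``: e.g. a diagnostic draw with
    10% hit rate needs 22 draws for 90% power.
    """
    if not (0.0 < p_success < 1.0):
        raise ValueError(f"p_success must lie in (0, 1), got {p_success}")
    if not (0.0 < power < 1.0):
        raise ValueError(f"power must lie in (0, 1), got {power}")
    k = math.ceil(math.log1p(-power) / math.log1p(-p_success))
    k = max(k, 1)
    # guard against float edge cases right at the boundary
    while 1.0 - (1.0 - p_success) ** k < power:
        k += 1
    while k > 1 and 1.0 - (1.0 - p_success) ** (k - 1) >= power:
        k -= 1
    return k
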