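"""Model/Results front end for the correlation Bayes factor suite.

:class:`CorrelationBayesModel` bundles one study's data — raw pairs or the
sufficient (n, r) summary — with an alternative-hypothesis prior; ``fit()``
runs the quadrature and returns :class:`CorrelationBayesResults` carrying
the Bayes factors, the posterior of rho, a credible interval, the classical
p value, and a ``summary()`` table.  Everything the results object reports
is recomputable from the underlying functions in :mod:`corrbf.bayes` and
:mod:`corrbf.posterior`; this class only organizes them.

Example
-------
>>> from corrbf import CorrelationBayesModel
>>> res = CorrelationBayesModel.from_summary(480, -0.01).fit()
>>> round(res.bf01, 2)
17.08
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bayes import (
    BayesFactorResult,
    SensitivityCurve,
    bf0_plus,
    bf0_replication,
    bf01_default,
    bf01_sensitivity,
    bf_interval_null,
    marginal_likelihood,
)
from .likelihood import (
    BivariateSample,
    StudySummary,
    classical_p_two_sided,
    pearson_r,
)
from .posterior import PosteriorGrid, credible_interval, posterior_grid, savage_dickey
from .priors import RhoPrior, UniformPrior, parse_prior

__all__ = ["CorrelationBayesModel", "CorrelationBayesResults"]


class CorrelationBayesModel:
    """Bayesian hypothesis tests for one correlational study.

    Construct from a summary (``from_summary``), raw arrays (``from_data``)
    or a DataFrame (``from_dataframe``); then ``fit()``.
    """

    def __init__(self, summary: StudySummary, prior: RhoPrior | str = "uniform"):
        self.summary = summary
        self.prior = parse_prior(prior) if isinstance(prior, str) else prior

    @classmethod
    def from_summary(
        cls, n: int, r: float, label: str = "", prior: RhoPrior | str = "uniform"
    ) -> "CorrelationBayesModel":
        return cls(StudySummary(n=n, r=r, label=label), prior=prior)

    @classmethod
    def from_data(
        cls,
        x: Sequence[float],
        y: Sequence[float],
        label: str = "",
        prior: RhoPrior | str = "uniform",
    ) -> "CorrelationBayesModel":
        sample = BivariateSample(
            pairs=list(zip(np.asarray(x, float), np.asarray(y, float))),
            label=label,
        )
        return cls(pearson_r(sample), prior=prior)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        x: str,
        y: str,
        prior: RhoPrior | str = "uniform",
    ) -> "CorrelationBayesModel":
        return cls.from_data(df[x], df[y], label=f"{x}~{y}", prior=prior)

    def fit(
        self, ci_mass: float = 0.95, grid_points: int = 4001
    ) -> "CorrelationBayesResults":
        """Run the quadrature and posterior tabulation."""
        res_default = bf01_default(self.summary)
        res_onesided = bf0_plus(self.summary)
        grid = posterior_grid(self.summary, self.prior, points=grid_points)
        ci = credible_interval(grid, ci_mass)
        return CorrelationBayesResults(
            model=self,
            bf01_result=res_default,
            bf0_plus_result=res_onesided,
            posterior=grid,
            ci=ci,
            ci_mass=ci_mass,
        )


@dataclass
class CorrelationBayesResults:
    """Fitted results: Bayes factors, posterior of rho, diagnostics."""

    model: CorrelationBayesModel
    bf01_result: BayesFactorResult
    bf0_plus_result: BayesFactorResult
    posterior: PosteriorGrid
    ci: tuple[float, float]
    ci_mass: float

    @property
    def summary_data(self) -> StudySummary:
        return self.model.summary

    @property
    def bf01(self) -> float:
        """Two-sided default Bayes factor for the null (uniform alternative)."""
        return self.bf01_result.bf01

    @property
    def bf10(self) -> float:
        return self.bf01_result.bf10

    @property
    def bf0_plus(self) -> float:
        """One-sided Bayes factor for the null against rho ~ U(0, 1)."""
        return self.bf0_plus_result.bf01

    @property
    def p_value(self) -> float:
        return classical_p_two_sided(self.summary_data)

    @property
    def posterior_mean(self) -> float:
        return self.posterior.mean()

    def savage_dickey_check(self) -> float:
        """BF01 via the posterior/prior height ratio at rho = 0.

        Independent numerical route; should agree with ``bf01`` to ~1%%.
        """
        return savage_dickey(self.summary_data, UniformPrior()).bf01

    def sensitivity(self, gammas: Sequence[float] | None = None) -> SensitivityCurve:
        if gammas is None:
            gammas = np.linspace(0.005, 1.0, 200)
        return bf01_sensitivity(self.summary_data, gammas)

    def interval_null(self, c: float = 0.01) -> BayesFactorResult:
        return bf_interval_null(self.summary_data, c)

    def replication_test(self, original: StudySummary) -> BayesFactorResult:
        return bf0_replication(original, self.summary_data)

    def marginal_likelihood(self) -> float:
        return marginal_likelihood(self.summary_data, self.model.prior)[0]

    def summary(self) -> str:
        """Human-readable results table."""
        s = self.summary_data
        lo, hi = self.ci
        lines = [
            "Correlation Bayes factor test",
            "=" * 46,
            f"study            {s.label or '<unnamed>'}",
            f"n                {s.n}",
            f"r                {s.r:+.4f}",
            f"p (two-sided)    {self.p_value:.4f}",
            "-" * 46,
            f"BF01 (uniform)   {self.bf01:.4f}",
            f"BF10             {self.bf10:.4f}",
            f"BF0+ (one-sided) {self.bf0_plus:.4f}",
            f"posterior mean   {self.posterior_mean:+.4f}",
            f"{self.ci_mass*100:.0f}% CI          [{lo:+.4f}, {hi:+.4f}]",
            f"numeric error    {self.bf01_result.numeric_error:.2e}",
            "=" * 46,
        ]
        return "\n".join(lines)
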