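"""Model selection: DIC and the logistic-regression shape screen.

DIC follows the classic Spiegelhalter decomposition
``DIC = D_bar + pD`` with ``pD = D_bar - D(theta_bar)``, where the
deviance ``D = -2 log L`` includes the full binomial normalising
constant and ``theta_bar`` is the vector of marginal posterior means.
Lower DIC is better.

The shape screen is the standard preliminary test for functional-
response type: a binomial GLM of the proportion of prey eaten on a
cubic polynomial in initial prey density.  A significantly negative
linear coefficient indicates a type II (decelerating) response, a
significantly positive one a type III (sigmoid) response.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .inference import Dataset, PosteriorChain, log_likelihood
from .models import ModelKind, Params

__all__ = [
    "DICResult",
    "ResponseShape",
    "ShapeTestResult",
    "deviance",
    "dic",
    "rank_models",
    "shape_test",
]


@dataclass(frozen=True)
class DICResult:
    mean_deviance: float
    deviance_at_mean: float

    @property
    def pd(self) -> float:
        """Effective number of parameters."""
        return self.mean_deviance - self.deviance_at_mean

    @property
    def dic(self) -> float:
        return self.mean_deviance + self.pd


def deviance(kind: ModelKind, params: Params, data: Dataset) -> float:
    """D = -2 log-likelihood (binomial, full normalising constant)."""
    ll = log_likelihood(kind, params, data)
    return math.inf if ll == -math.inf else -2.0 * ll


def dic(chain: PosteriorChain, kind: ModelKind, data: Dataset) -> DICResult:
    """Deviance information criterion from a post-burn-in chain."""
    if len(chain) == 0:
        raise ValueError("empty chain")
    devs = np.array(
        [deviance(kind, Params.from_vector(kind, row), data) for row in chain.draws]
    )
    d_at_mean = deviance(kind, chain.mean_params(), data)
    return DICResult(mean_deviance=float(np.mean(devs)), deviance_at_mean=d_at_mean)


def rank_models(results: Mapping[str, DICResult]) -> list[tuple[str, DICResult]]:
    """Order models by ascending DIC, ties broken alphabetically."""
    if len(results) < 2:
        raise ValueError("need at least 2 models to rank")
    return sorted(results.items(), key=lambda kv: (kv[1].dic, kv[0]))


class ResponseShape(str, enum.Enum):
    TYPE_II = "type II"
    TYPE_III = "type III"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ShapeTestResult:
    coefficients: np.ndarray  # intercept upward, for the retained degree
    p_values: np.ndarray
    classification: ResponseShape
    degree: int = 0


def shape_test(data: Dataset, alpha: float = 0.05, max_degree: int = 3) -> ShapeTestResult:
    """Functional-response shape screen via polynomial logistic regression.

    Starting from ``Ne/N0 ~ logistic(b0 + b1 N0 + ... + bk N0^k)``
    (cubic by default), the highest-order term is dropped while it is
    not significant at level ``alpha`` (backward elimination, the usual
    simplification of the polynomial screen — the cubic Wald test on b1
    alone is badly collinear over five density levels).  Classification
    is by the sign of the linear coefficient of the retained model: a
    significantly negative b1 is a type II (decelerating) response, a
    significantly positive one type III.  Non-convergence or an
    insignificant linear term yields ``INDETERMINATE``, never an
    exception.
    """
    import statsmodels.api as sm

    n0 = data.n0.astype(float)
    distinct = np.unique(n0)
    if distinct.size < 2:
        raise ValueError("shape test needs at least 2 distinct initial densities")
    degree = min(max_degree, distinct.size - 1)
    endog = np.column_stack([data.ne, data.n0 - data.ne]).astype(float)
    try:
        while True:
            exog = np.column_stack([n0**k for k in range(degree + 1)])
            with np.errstate(all="ignore"):
                fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
            coefs = np.asarray(fit.params, float)
            pvals = np.asarray(fit.pvalues, float)
            if degree == 1 or (np.isfinite(pvals[degree]) and pvals[degree] < alpha):
                break
            degree -= 1
    except Exception:
        nan = np.full(2, np.nan)
        return ShapeTestResult(nan, nan, ResponseShape.INDETERMINATE, degree=0)
    b1, p1 = coefs[1], pvals[1]
    if not np.isfinite(b1) or not np.isfinite(p1) or p1 >= alpha:
        shape = ResponseShape.INDETERMINATE
    elif b1 < 0:
        shape = ResponseShape.TYPE_II
    else:
        shape = ResponseShape.TYPE_III
    return ShapeTestResult(coefs, pvals, shape, degree=degree)
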