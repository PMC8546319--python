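"""Approximate moments of an elementwise product of two phenotypes.

Given only means, variances, and pairwise covariances of two phenotypes and
a set of conditioning variables (plus an assumed marginal law for each
conditioner), this module approximates the product's mean, variance, and its
covariance with each conditioner:

* the conditional mean of each factor given a conditioner ``x`` comes from
  the implied simple linear regression;
* the conditional variance is the regression residual variance (constant in
  ``x``) for continuous factors, or ``g (1 - g)`` for binary factors;
* the conditional correlation of the factors given ``x`` is estimated by
  their partial correlation;
* expectations over ``x`` use the assumed marginal law (exact sums for
  discrete laws, Gauss--Hermite quadrature for Gaussian ones).

The product's mean is an exact sample identity; the covariance and variance
are approximations that lean on joint-linearity/homoscedasticity
assumptions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .pcss_model import Degenerate, PcssError, PredictorDistribution

__all__ = [
    "ConditionalMoments",
    "ProductMoments",
    "FactorStats",
    "ConditionerStats",
    "conditional_mean",
    "conditional_variance",
    "conditional_moments",
    "partial_correlation",
    "conditional_covariance",
    "conditional_product_mean",
    "conditional_product_variance",
    "cov_predictor_product",
    "product_mean",
    "product_variance",
    "unconditional_product_variance",
    "pair_product_moments",
]

DEFAULT_EPS = 1e-6


@dataclass
class ConditionalMoments:
    """Conditional mean line ``a + b x`` and conditional variance of one factor.

    For continuous factors ``hvar`` is the (constant) residual variance; for
    binary factors the conditional variance is ``g (1 - g)`` with the mean
    clamped into ``(eps, 1 - eps)``.
    """

    a: float
    b: float
    hvar: float = float("nan")
    is_binary: bool = False
    eps: float = DEFAULT_EPS

    def mean_at(self, x):
        g = self.a + self.b * np.asarray(x, dtype=float)
        if self.is_binary:
            g = np.clip(g, self.eps, 1.0 - self.eps)
        if g.ndim == 0:
            return float(g)
        return g

    def var_at(self, x):
        if self.is_binary:
            g = self.mean_at(x)
            return g * (1.0 - np.asarray(g))
        out = np.full_like(np.asarray(x, dtype=float), self.hvar)
        if out.ndim == 0:
            return float(out)
        return out


@dataclass
class ProductMoments:
    """Approximated summary statistics of a phenotype product.

    ``cov_with`` maps non-intercept design-column names to the approximated
    sample covariance of that column with the product.  ``order_trace``
    records the multiplication order(s) that produced the estimate.
    """

    mean: float
    variance: float
    cov_with: dict[str, float]
    order_trace: tuple = ()

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise PcssError(f"product variance must be >= 0; got {self.variance}")


@dataclass(frozen=True)
class FactorStats:
    """Marginal summary of one factor entering a product."""

    mean: float
    var: float
    is_binary: bool = False


@dataclass(frozen=True)
class ConditionerStats:
    """One conditioning variable: its moments, assumed law, and covariances
    with the two factors."""

    name: str
    mean: float
    var: float
    dist: PredictorDistribution | None
    cov1: float
    cov2: float


# ---------------------------------------------------------------------------
# elementary pieces
# ---------------------------------------------------------------------------


def conditional_mean(
    y_mean: float,
    x_mean: float,
    x_var: float,
    s_xy: float,
    binary: bool = False,
    eps: float = DEFAULT_EPS,
) -> ConditionalMoments:
    """Conditional-mean line of a phenotype given a predictor.

    ``b = s_xy / s_x²``, ``a = ȳ - b x̄``.  A zero-variance predictor is
    degenerate: the conditional mean is constant at ``ȳ``.
    """
    if x_var > 0:
        b = s_xy / x_var
    else:
        b = 0.0
    a = y_mean - b * x_mean
    return ConditionalMoments(a=a, b=b, is_binary=binary, eps=eps)


def conditional_variance(y_var: float, s_xy: float, x_var: float, n: int) -> float:
    """Residual variance of the implied simple regression, floored at 0.

    ``(n - 1)(s_y² - b s_xy) / (n - 2)`` with ``b = s_xy / s_x²``.
    """
    if n <= 2:
        raise PcssError(f"need n > 2 for a residual variance; got n={n}")
    b = s_xy / x_var if x_var > 0 else 0.0
    return max((n - 1) * (y_var - b * s_xy) / (n - 2), 0.0)


def conditional_moments(
    y: FactorStats,
    x_mean: float,
    x_var: float,
    s_xy: float,
    n: int,
    eps: float = DEFAULT_EPS,
) -> ConditionalMoments:
    """Full conditional-moment bundle of factor ``y`` given one conditioner."""
    cm = conditional_mean(y.mean, x_mean, x_var, s_xy, binary=y.is_binary, eps=eps)
    if not y.is_binary:
        cm.hvar = conditional_variance(y.var, s_xy, x_var, n)
    return cm


def partial_correlation(r12: float, r_x1: float, r_x2: float) -> float:
    """Sample partial correlation of two phenotypes controlling for x.

    Returns 0 when either phenotype is perfectly correlated with x, and the
    result is clamped to [-1, 1].
    """
    for r in (r12, r_x1, r_x2):
        if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
            raise PcssError(f"correlations must lie in [-1, 1]; got {r}")
    if abs(abs(r_x1) - 1.0) < 1e-12 or abs(abs(r_x2) - 1.0) < 1e-12:
        return 0.0
    denom = math.sqrt((1.0 - r_x1**2) * (1.0 - r_x2**2))
    return float(np.clip((r12 - r_x1 * r_x2) / denom, -1.0, 1.0))


def conditional_covariance(
    cm1: ConditionalMoments, cm2: ConditionalMoments, r_partial: float, x
):
    """Conditional covariance of the factors at ``x``: ``r √(h1 h2)``."""
    return r_partial * np.sqrt(cm1.var_at(x) * cm2.var_at(x))


def conditional_product_mean(cm1: ConditionalMoments, cm2: ConditionalMoments, ccov, x):
    """Conditional mean of the product at ``x``: ``g1 g2 + h12``."""
    return cm1.mean_at(x) * cm2.mean_at(x) + ccov


def conditional_product_variance(g1, g2, h1, h2, h12, mode: str = "normal"):
    """Conditional variance of the product of two factors.

    ``mode="normal"`` uses the bivariate-normal product-variance form

        g1² h2 + g2² h1 + h1 h2 + 2 g1 g2 h12 + h12²

    ``mode="printed"`` evaluates the literal published expression
    ``h1 h2 + g1 h2 + g2 h1 + (g1 g2 + h12) h12`` (its conditional means
    enter linearly; kept only for comparison).  Results are floored at 0.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if mode == "normal":
        out = g1**2 * h2 + g2**2 * h1 + h1 * h2 + 2.0 * g1 * g2 * h12 + h12**2
    elif mode == "printed":
        out = h1 * h2 + g1 * h2 + g2 * h1 + (g1 * g2 + h12) * h12
    else:
        raise PcssError(f"unknown mode {mode!r}; expected 'normal' or 'printed'")
    out = np.maximum(out, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def cov_predictor_product(
    g_w2: Callable | np.ndarray,
    dist: PredictorDistribution,
    x_mean: float,
) -> float:
    """Approximate ``s_{x, w}`` as ``E_f[(X - x̄) g(w|X)]`` under the assumed
    law of the conditioner.

    ``g_w2`` may be a callable evaluated at the quadrature points, or an
    array already aligned with ``dist.expectation_nodes()``.
    """
    if dist is None:
        raise PcssError("conditioner has no assumed distribution")
    xs, ws = dist.expectation_nodes()
    g = g_w2(xs) if callable(g_w2) else np.asarray(g_w2, dtype=float)
    return float(np.sum(ws * (xs - x_mean) * g))


def product_mean(mean1: float, mean2: float, s12: float, n: int) -> float:
    """Exact sample mean of the elementwise product:
    ``ȳ1 ȳ2 + s12 (n - 1) / n``."""
    return mean1 * mean2 + s12 * (n - 1) / n


def unconditional_product_variance(
    mean1: float, var1: float, mean2: float, var2: float, s12: float
) -> float:
    """Normal-theory product variance with no conditioning (fallback when no
    usable conditioner exists)."""
    return max(
        mean1**2 * var2 + mean2**2 * var1 + var1 * var2 + 2 * mean1 * mean2 * s12 + s12**2,
        0.0,
    )


# ---------------------------------------------------------------------------
# assembled pair moments
# ---------------------------------------------------------------------------


def _corr(cov: float, var_a: float, var_b: float) -> float:
    if var_a <= 0.0 or var_b <= 0.0:
        return 0.0
    return float(np.clip(cov / math.sqrt(var_a * var_b), -1.0, 1.0))


def _variance_estimate(
    xs: np.ndarray,
    ws: np.ndarray,
    g: np.ndarray,
    hw: np.ndarray,
    n: int,
    w_mean: float,
    discrete: bool,
) -> float:
    """One conditioner's product-variance estimate.

    Discrete law: ``[Σ_x ((n f(x) - 1) h(w|x) + n f(x) (g(w|x) - w̄)²)] / (n-1)``
    — the between/within decomposition that is exact when ``f`` matches the
    empirical frequencies.  The Gaussian analogue replaces the unweighted
    ``Σ_x h`` with ``E_f[h]``.
    """
    e_h = float(np.sum(ws * hw))
    e_dev = float(np.sum(ws * (g - w_mean) ** 2))
    correction = float(np.sum(hw)) if discrete else e_h
    return max((n * e_h - correction + n * e_dev) / (n - 1), 0.0)


def pair_product_moments(
    n: int,
    f1: FactorStats,
    f2: FactorStats,
    s12: float,
    conditioners: Sequence[ConditionerStats],
    var_names: Iterable[str] | None = None,
    binary_product: bool | None = None,
    eps: float = DEFAULT_EPS,
    eq12_mode: str = "normal",
) -> tuple[float, float, dict[str, float]]:
    """Approximate mean, variance, and per-conditioner covariances of the
    product of two factors.

    Parameters
    ----------
    n : sample size.
    f1, f2 : marginal summaries of the factors.
    s12 : sample covariance of the factors.
    conditioners : variables to approximate covariances against; each needs
        positive variance and an assumed law to contribute (others get
        covariance 0 with a warning).
    var_names : names of the conditioners whose variance estimates enter the
        median; defaults to all usable conditioners.
    binary_product : both factors binary (enables the clamped-mean /
        Bernoulli-variance estimator variants); inferred when None.
    eq12_mode : conditional product variance form ("normal" or "printed").

    Returns
    -------
    (mean, variance, cov_with) where cov_with maps conditioner names to
    approximated covariances.
    """
    if binary_product is None:
        binary_product = f1.is_binary and f2.is_binary

    w_mean = product_mean(f1.mean, f2.mean, s12, n)
    if binary_product:
        w_mean = float(np.clip(w_mean, eps, 1.0 - eps))

    var_names = set(var_names) if var_names is not None else None
    r12 = _corr(s12, f1.var, f2.var)

    covs: dict[str, float] = {}
    var_estimates: list[float] = []
    for c in conditioners:
        usable = c.var > 0.0 and c.dist is not None and not isinstance(c.dist, Degenerate)
        if not usable:
            if c.dist is None and c.var > 0.0:
                raise PcssError(
                    f"conditioner {c.name!r} has no assumed distribution; "
                    "cannot take expectations over its support"
                )
            warnings.warn(
                f"conditioner {c.name!r} is degenerate; setting its covariance "
                "with the product to 0 and excluding it from the variance median",
                RuntimeWarning,
                stacklevel=2,
            )
            covs[c.name] = 0.0
            continue

        cm1 = conditional_moments(f1, c.mean, c.var, c.cov1, n, eps=eps)
        cm2 = conditional_moments(f2, c.mean, c.var, c.cov2, n, eps=eps)
        rp = partial_correlation(
            r12, _corr(c.cov1, c.var, f1.var), _corr(c.cov2, c.var, f2.var)
        )

        xs, ws = c.dist.expectation_nodes()
        g1 = np.asarray(cm1.mean_at(xs), dtype=float)
        g2 = np.asarray(cm2.mean_at(xs), dtype=float)
        h1 = np.asarray(cm1.var_at(xs), dtype=float)
        h2 = np.asarray(cm2.var_at(xs), dtype=float)
        h12 = rp * np.sqrt(h1 * h2)
        g = g1 * g2 + h12
        if binary_product:
            g = np.clip(g, eps, 1.0 - eps)

        covs[c.name] = float(np.sum(ws * (xs - c.mean) * g))

        if not binary_product and (var_names is None or c.name in var_names):
            hw = conditional_product_variance(g1, g2, h1, h2, h12, mode=eq12_mode)
            var_estimates.append(
                _variance_estimate(xs, ws, g, np.asarray(hw, dtype=float), n, w_mean, c.dist.is_discrete)
            )

    if binary_product:
        w_var = w_mean * (1.0 - w_mean) * n / (n - 1)
    elif var_estimates:
        w_var = float(np.median(var_estimates))
    else:
        w_var = unconditional_product_variance(f1.mean, f1.var, f2.mean, f2.var, s12)

    return w_mean, w_var, covs


def product_variance(
    n: int,
    f1: FactorStats,
    f2: FactorStats,
    s12: float,
    conditioners: Sequence[ConditionerStats],
    var_names: Iterable[str] | None = None,
    binary_product: bool | None = None,
    eps: float = DEFAULT_EPS,
    eq12_mode: str = "normal",
) -> float:
    """Approximated sample variance of the product (median across the usable
    conditioners; Bernoulli form for binary products; unconditional fallback
    with no usable conditioner)."""
    _, w_var, _ = pair_product_moments(
        n,
        f1,
        f2,
        s12,
        conditioners,
        var_names=var_names,
        binary_product=binary_product,
        eps=eps,
        eq12_mode=eq12_mode,
    )
    return w_var
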