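"""Full regression models for products and logical combinations of phenotypes.

For two phenotypes the product moments come straight from
:mod:`~pcssreg.product_moments`.  For ``m > 2`` the pair machinery is applied
recursively — ``w_l = w_{l-1} · y_l`` — carrying along the approximated
covariances of the running product with every design predictor and every
not-yet-consumed phenotype.  Because the recursion depends on the
multiplication order, all ``m!/2`` orderings unique up to the first two terms
are evaluated and the median of each scalar summary (mean, variance, each
covariance) across orderings is used.

Logical AND of binary phenotypes is the plain product; logical OR is handled
through complements: ``y1 ∨ y2 = 1 - (1 - y1)(1 - y2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Sequence

import numpy as np

from .pcss_model import (
    Bernoulli,
    Degenerate,
    Gaussian,
    PcssError,
    PcssSet,
    PredictorDistribution,
    RegressionResult,
    VariableInfo,
    ols_from_pcss,
)
from .product_moments import (
    DEFAULT_EPS,
    ConditionerStats,
    FactorStats,
    ProductMoments,
    pair_product_moments,
)

__all__ = [
    "CombinationSpec",
    "DEFAULT_M_CAP",
    "complement_stats",
    "product_moments_from_pcss",
    "product_model",
    "and_model",
    "or_model",
]

#: refuse recursion above this many phenotypes unless explicitly overridden
DEFAULT_M_CAP = 6


@dataclass(frozen=True)
class CombinationSpec:
    """A requested combined phenotype and the design to regress it on."""

    phenotypes: tuple[str, ...]
    op: str = "product"  # product | and | or
    design: tuple[str, ...] = ("intercept", "snp")

    def __post_init__(self) -> None:
        if self.op not in ("product", "and", "or"):
            raise PcssError(f"op must be product/and/or; got {self.op!r}")
        if len(self.phenotypes) < 2:
            raise PcssError("a combination needs at least two phenotypes")


def _derived_distribution(v: VariableInfo, mean: float, var: float, eps: float) -> PredictorDistribution:
    """Law assumed for a phenotype when it acts as a conditioning variable."""
    if v.distribution is not None:
        return v.distribution
    if v.vtype == "binary":
        return Bernoulli(float(np.clip(mean, eps, 1.0 - eps)))
    return Gaussian(mean, float(np.sqrt(max(var, 0.0))))


def _design_predictors(pcss: PcssSet, design: Sequence[str]) -> list[VariableInfo]:
    preds = []
    for nm in design:
        v = pcss.variable(nm)
        if v.role == "intercept":
            continue
        if v.distribution is None and pcss.var(nm) > 0.0:
            raise PcssError(
                f"design predictor {nm!r} carries no marginal distribution; one is "
                "required to approximate its covariance with the product"
            )
        preds.append(v)
    return preds


def _recurse_ordering(
    pcss: PcssSet,
    order: Sequence[str],
    design_preds: Sequence[VariableInfo],
    binary_all: bool,
    eps: float,
    eq12_mode: str,
) -> tuple[float, float, dict[str, float]]:
    """Run the recursion for one multiplication order.

    Returns the approximated (mean, variance, covariances-with-design-predictors)
    of the full product.
    """
    n = pcss.n
    m = len(order)
    eligible = {
        v.name
        for v in design_preds
        if pcss.var(v.name) > 0.0 and not isinstance(v.distribution, Degenerate)
    }

    def pheno_cond(name: str, cov1: float, cov2: float) -> ConditionerStats:
        v = pcss.variable(name)
        mean, var = pcss.mean(name), pcss.var(name)
        return ConditionerStats(
            name, mean, var, _derived_distribution(v, mean, var, eps), cov1, cov2
        )

    def pred_cond(v: VariableInfo, cov1: float, cov2: float) -> ConditionerStats:
        return ConditionerStats(
            v.name, pcss.mean(v.name), pcss.var(v.name), v.distribution, cov1, cov2
        )

    # ---- base pair -------------------------------------------------------
    a, b = order[0], order[1]
    remaining = list(order[2:])
    is_final = m == 2
    binary_step = binary_all and is_final
    fa = FactorStats(pcss.mean(a), pcss.var(a), is_binary=binary_step)
    fb = FactorStats(pcss.mean(b), pcss.var(b), is_binary=binary_step)
    conds = [pred_cond(v, pcss.cov(v.name, a), pcss.cov(v.name, b)) for v in design_preds]
    conds += [pheno_cond(r, pcss.cov(r, a), pcss.cov(r, b)) for r in remaining]
    var_names = eligible if eligible else set(remaining)
    w_mean, w_var, covs = pair_product_moments(
        n,
        fa,
        fb,
        pcss.cov(a, b),
        conds,
        var_names=var_names,
        binary_product=binary_step,
        eps=eps,
        eq12_mode=eq12_mode,
    )

    # ---- extension steps: w_l = w_{l-1} * y_l -----------------------------
    for l in range(2, m):
        yl = order[l]
        remaining = list(order[l + 1 :])
        is_final = l == m - 1
        binary_step = binary_all and is_final
        fw = FactorStats(w_mean, w_var, is_binary=binary_step)
        fy = FactorStats(pcss.mean(yl), pcss.var(yl), is_binary=binary_step)
        s12 = covs[yl]
        conds = [pred_cond(v, covs[v.name], pcss.cov(v.name, yl)) for v in design_preds]
        conds += [pheno_cond(r, covs[r], pcss.cov(r, yl)) for r in remaining]
        var_names = eligible if eligible else set(remaining)
        w_mean, w_var, covs = pair_product_moments(
            n,
            fw,
            fy,
            s12,
            conds,
            var_names=var_names,
            binary_product=binary_step,
            eps=eps,
            eq12_mode=eq12_mode,
        )

    return w_mean, w_var, {v.name: covs[v.name] for v in design_preds}


def _orderings(phenotypes: Sequence[str]) -> list[tuple[str, ...]]:
    if len(phenotypes) == 2:
        return [tuple(phenotypes)]
    # unique up to the order of the first two terms
    seen = []
    for perm in permutations(sorted(phenotypes)):
        if perm[0] < perm[1]:
            seen.append(perm)
    return seen


def product_moments_from_pcss(
    pcss: PcssSet,
    phenotypes: Sequence[str],
    design: Sequence[str],
    eps: float = DEFAULT_EPS,
    eq12_mode: str = "normal",
    m_cap: int = DEFAULT_M_CAP,
    allow_large: bool = False,
) -> ProductMoments:
    """Approximate the summary statistics of ``y1 · y2 ··· ym`` from PCSS.

    Covariances are produced for every non-intercept design column.  Implied
    product/predictor correlations outside [-1, 1] are clamped with a warning.
    """
    phenotypes = tuple(phenotypes)
    m = len(phenotypes)
    if m < 2:
        raise PcssError("need at least two phenotypes")
    if m > m_cap and not allow_large:
        raise PcssError(
            f"product of {m} phenotypes exceeds the cap of {m_cap}; the recursion "
            "compounds approximation error for large products — pass allow_large=True "
            "to override"
        )
    if m > m_cap:
        warnings.warn(
            f"estimating a product of {m} phenotypes; accuracy degrades as m grows "
            "and results should be treated with caution",
            RuntimeWarning,
            stacklevel=2,
        )
    for nm in phenotypes:
        if pcss.variable(nm).role == "intercept":
            raise PcssError(f"{nm!r} is an intercept column, not a phenotype")

    design_preds = _design_predictors(pcss, design)
    binary_all = all(pcss.variable(nm).vtype == "binary" for nm in phenotypes)

    results = [
        _recurse_ordering(pcss, order, design_preds, binary_all, eps, eq12_mode)
        for order in _orderings(phenotypes)
    ]
    w_mean = float(np.median([r[0] for r in results]))
    w_var = float(np.median([r[1] for r in results]))
    cov_with = {
        v.name: float(np.median([r[2][v.name] for r in results])) for v in design_preds
    }

    # clamp implied correlations into [-1, 1]
    for nm, cv in cov_with.items():
        bound = np.sqrt(max(w_var, 0.0) * max(pcss.var(nm), 0.0))
        if abs(cv) > bound:
            warnings.warn(
                f"implied correlation of the product with {nm!r} exceeds 1 in "
                "magnitude; clamping the covariance",
                RuntimeWarning,
                stacklevel=2,
            )
            cov_with[nm] = float(np.sign(cv) * bound)

    return ProductMoments(
        mean=w_mean,
        variance=w_var,
        cov_with=cov_with,
        order_trace=tuple(_orderings(phenotypes)),
    )


def product_model(
    pcss: PcssSet,
    spec: CombinationSpec,
    eps: float = DEFAULT_EPS,
    eq12_mode: str = "normal",
    m_cap: int = DEFAULT_M_CAP,
    allow_large: bool = False,
    median_over: str = "terms",
) -> RegressionResult:
    """Fit the regression of a phenotype product on the requested design.

    ``median_over="terms"`` (default) medians the moment summaries across
    multiplication orderings before a single fit; ``"coefficients"`` fits per
    ordering and medians the coefficient and SE vectors instead (kept for
    comparison).
    """
    if median_over not in ("terms", "coefficients"):
        raise PcssError(f"median_over must be 'terms' or 'coefficients'; got {median_over!r}")

    if median_over == "coefficients" and len(spec.phenotypes) > 2:
        design_preds = _design_predictors(pcss, spec.design)
        binary_all = all(pcss.variable(nm).vtype == "binary" for nm in spec.phenotypes)
        fits = []
        for order in _orderings(spec.phenotypes):
            w_mean, w_var, covs = _recurse_ordering(
                pcss, order, design_preds, binary_all, eps, eq12_mode
            )
            pm = ProductMoments(w_mean, max(w_var, 0.0), covs, order_trace=(order,))
            fits.append(ols_from_pcss(pcss, pm, spec.design))
        beta = np.median([f.beta for f in fits], axis=0)
        se = np.median([f.se for f in fits], axis=0)
        tstat = np.where(se > 0, beta / se, np.nan)
        from scipy.special import stdtr

        df = fits[0].df
        pvalue = np.where(se > 0, 2.0 * stdtr(df, -np.abs(tstat)), 1.0)
        return RegressionResult(
            names=fits[0].names,
            beta=beta,
            se=se,
            tstat=tstat,
            pvalue=pvalue,
            sigma2=float(np.median([f.sigma2 for f in fits])),
            df=df,
            n=fits[0].n,
            p=fits[0].p,
        )

    pm = product_moments_from_pcss(
        pcss,
        spec.phenotypes,
        spec.design,
        eps=eps,
        eq12_mode=eq12_mode,
        m_cap=m_cap,
        allow_large=allow_large,
    )
    return ols_from_pcss(pcss, pm, spec.design)


def complement_stats(pcss: PcssSet, phenotypes: Sequence[str]) -> PcssSet:
    """Summary statistics after replacing each named binary phenotype ``y``
    with ``1 - y``.

    Means map to ``1 - mean``; covariances with variables outside the
    complemented set flip sign; variances and covariances within the set are
    preserved.  Applying the transform twice is the identity.
    """
    out = pcss.copy()
    idx = [out.index(nm) for nm in phenotypes]
    inside = np.zeros(len(out.variables), dtype=bool)
    inside[idx] = True
    for i in idx:
        out.means[i] = 1.0 - out.means[i]
        out.covariance[i, ~inside] *= -1.0
        out.covariance[~inside, i] *= -1.0
    new_vars = list(out.variables)
    for i in idx:
        v = new_vars[i]
        dist = v.distribution
        if isinstance(dist, Bernoulli):
            dist = Bernoulli(1.0 - dist.p)
        new_vars[i] = VariableInfo(v.name, v.role, v.vtype, dist)
    return PcssSet(out.n, new_vars, out.means, out.covariance, validate=False)


def _require_binary(pcss: PcssSet, spec: CombinationSpec) -> None:
    bad = [nm for nm in spec.phenotypes if pcss.variable(nm).vtype != "binary"]
    if bad:
        raise PcssError(
            f"logical combinations require binary phenotypes; non-binary: {bad}"
        )


def and_model(
    pcss: PcssSet,
    spec: CombinationSpec,
    eps: float = DEFAULT_EPS,
    **kwargs,
) -> RegressionResult:
    """Regression model for the conjunction of binary phenotypes (their product)."""
    _require_binary(pcss, spec)
    return product_model(pcss, spec, eps=eps, **kwargs)


def or_moments_from_pcss(
    pcss: PcssSet,
    phenotypes: Sequence[str],
    design: Sequence[str],
    eps: float = DEFAULT_EPS,
    **kwargs,
) -> ProductMoments:
    """Moments of the disjunction ``y1 ∨ ... ∨ ym = 1 - Π (1 - yk)``."""
    comp = complement_stats(pcss, phenotypes)
    pm = product_moments_from_pcss(comp, phenotypes, design, eps=eps, **kwargs)
    return ProductMoments(
        mean=float(np.clip(1.0 - pm.mean, eps, 1.0 - eps)),
        variance=pm.variance,
        cov_with={nm: -cv for nm, cv in pm.cov_with.items()},
        order_trace=pm.order_trace,
    )


def or_model(
    pcss: PcssSet,
    spec: CombinationSpec,
    eps: float = DEFAULT_EPS,
    **kwargs,
) -> RegressionResult:
    """Regression model for the disjunction of binary phenotypes."""
    _require_binary(pcss, spec)
    pm = or_moments_from_pcss(pcss, spec.phenotypes, spec.design, eps=eps, **kwargs)
    return ols_from_pcss(pcss, pm, spec.design)
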