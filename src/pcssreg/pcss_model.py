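"""Data model for pre-computed summary statistics (PCSS) and exact
reconstruction of ordinary-least-squares fits from them.

A :class:`PcssSet` holds the sample size, per-variable means, and the joint
sample variance--covariance matrix (``n - 1`` denominator) over all
predictors and phenotypes.  Given those quantities, the cross-product
matrices that OLS needs are algebraic identities::

    X'X = (n - 1) S(X) + n x̄ x̄'
    X'w = (n - 1) s_{w,x} + n w̄ x̄
    w'w = (n - 1) s_w²   + n w̄²

so a linear model for any response whose mean, variance, and covariances
with the design columns are known can be fit without individual-level data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import stdtr

__all__ = [
    "PcssError",
    "CollinearDesignError",
    "PredictorDistribution",
    "GenotypeHwe",
    "Bernoulli",
    "Gaussian",
    "Degenerate",
    "distribution_from_spec",
    "VariableInfo",
    "PcssSet",
    "RegressionResult",
    "reconstruct_xtx",
    "reconstruct_xtw",
    "ols_from_pcss",
]

ROLES = ("predictor", "phenotype", "intercept")
VTYPES = ("continuous", "binary", "genotype")

#: default cap on cond(X'X); above it the solve is refused
DEFAULT_CONDITION_CAP = 1e10

#: residual-variance floor used when the approximated moments make sigma2 < 0
SIGMA2_FLOOR = 1e-12

_GH_ORDER = 64
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(_GH_ORDER)
_GH_WEIGHTS = _GH_WEIGHTS / math.sqrt(math.pi)


class PcssError(ValueError):
    """Invalid summary-statistic input."""


class CollinearDesignError(np.linalg.LinAlgError):
    """X'X is singular or too ill-conditioned to solve safely."""


# ---------------------------------------------------------------------------
# marginal predictor distributions
# ---------------------------------------------------------------------------


class PredictorDistribution:
    """Marginal law of one variable, used to take expectations over its
    support when approximating product moments.

    Subclasses expose :meth:`expectation_nodes`, a quadrature view that is
    exact for discrete laws (support points with their masses) and a 64-node
    Gauss--Hermite rule for Gaussian laws.
    """

    kind: str = "base"
    is_discrete: bool = True

    def moments(self) -> tuple[float, float]:
        raise NotImplementedError

    def expectation_nodes(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(points, weights)`` with ``sum(weights) == 1``."""
        raise NotImplementedError

    def param_values(self) -> tuple[float, ...]:
        raise NotImplementedError


@dataclass(frozen=True)
class GenotypeHwe(PredictorDistribution):
    """Minor-allele count at Hardy-Weinberg equilibrium: binomial(2, maf)."""

    maf: float

    kind = "genotype_hwe"
    is_discrete = True

    def __post_init__(self) -> None:
        if not 0.0 < self.maf < 1.0:
            raise PcssError(f"MAF must be in (0, 1); got {self.maf}")

    def support(self) -> np.ndarray:
        return np.array([0.0, 1.0, 2.0])

    def pmf(self, x) -> np.ndarray:
        p = self.maf
        table = {0.0: (1 - p) ** 2, 1.0: 2 * p * (1 - p), 2.0: p**2}
        return np.vectorize(lambda v: table.get(float(v), 0.0))(x)

    def moments(self) -> tuple[float, float]:
        p = self.maf
        return 2 * p, 2 * p * (1 - p)

    def expectation_nodes(self) -> tuple[np.ndarray, np.ndarray]:
        p = self.maf
        return (
            np.array([0.0, 1.0, 2.0]),
            np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]),
        )

    def param_values(self) -> tuple[float, ...]:
        return (self.maf,)


@dataclass(frozen=True)
class Bernoulli(PredictorDistribution):
    p: float

    kind = "bernoulli"
    is_discrete = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise PcssError(f"Bernoulli p must be in [0, 1]; got {self.p}")

    def support(self) -> np.ndarray:
        return np.array([0.0, 1.0])

    def pmf(self, x) -> np.ndarray:
        return np.where(np.asarray(x) == 1.0, self.p, np.where(np.asarray(x) == 0.0, 1 - self.p, 0.0))

    def moments(self) -> tuple[float, float]:
        return self.p, self.p * (1 - self.p)

    def expectation_nodes(self) -> tuple[np.ndarray, np.ndarray]:
        return np.array([0.0, 1.0]), np.array([1 - self.p, self.p])

    def param_values(self) -> tuple[float, ...]:
        return (self.p,)


@dataclass(frozen=True)
class Gaussian(PredictorDistribution):
    mu: float
    sigma: float

    kind = "gaussian"
    is_discrete = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise PcssError(f"Gaussian sigma must be >= 0; got {self.sigma}")

    def moments(self) -> tuple[float, float]:
        return self.mu, self.sigma**2

    def expectation_nodes(self) -> tuple[np.ndarray, np.ndarray]:
        # physicists' Gauss-Hermite: E[g(X)] = sum w_i g(mu + sqrt(2) sigma t_i)
        return self.mu + math.sqrt(2.0) * self.sigma * _GH_NODES, _GH_WEIGHTS

    def param_values(self) -> tuple[float, ...]:
        return (self.mu, self.sigma)


@dataclass(frozen=True)
class Degenerate(PredictorDistribution):
    value: float = 1.0

    kind = "degenerate"
    is_discrete = True

    def support(self) -> np.ndarray:
        return np.array([self.value])

    def pmf(self, x) -> np.ndarray:
        return np.where(np.asarray(x) == self.value, 1.0, 0.0)

    def moments(self) -> tuple[float, float]:
        return self.value, 0.0

    def expectation_nodes(self) -> tuple[np.ndarray, np.ndarray]:
        return np.array([self.value]), np.array([1.0])

    def param_values(self) -> tuple[float, ...]:
        return (self.value,)


_DIST_KINDS = {
    "genotype_hwe": GenotypeHwe,
    "bernoulli": Bernoulli,
    "gaussian": Gaussian,
    "degenerate": Degenerate,
}


def distribution_from_spec(kind: str, params: Sequence[float]) -> PredictorDistribution:
    """Build a distribution from its text descriptor, e.g. ``("gaussian", (0, 1))``."""
    try:
        cls = _DIST_KINDS[kind]
    except KeyError:
        raise PcssError(f"unknown distribution kind {kind!r}; expected one of {sorted(_DIST_KINDS)}") from None
    return cls(*[float(v) for v in params])


# ---------------------------------------------------------------------------
# variables and the summary-statistic set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariableInfo:
    """Metadata for one column of the (virtual) data matrix."""

    name: str
    role: str  # predictor | phenotype | intercept
    vtype: str = "continuous"  # continuous | binary | genotype
    distribution: PredictorDistribution | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PcssError(f"role must be one of {ROLES}; got {self.role!r}")
        if self.vtype not in VTYPES:
            raise PcssError(f"vtype must be one of {VTYPES}; got {self.vtype!r}")


class PcssSet:
    """Sample size, means, and joint covariance of all predictors and phenotypes.

    Parameters
    ----------
    n : int
        Sample size the statistics were computed on.
    variables : sequence of VariableInfo
        Ordered variable metadata; order matches ``means`` and ``covariance``.
    means : array-like, shape (k,)
    covariance : array-like, shape (k, k)
        Sample covariances (``n - 1`` denominator).
    validate : bool
        Run invariant checks at construction (disable in tight loops where
        the inputs come from trusted exact computation).
    """

    __slots__ = ("n", "variables", "means", "covariance", "_index")

    def __init__(
        self,
        n: int,
        variables: Sequence[VariableInfo],
        means,
        covariance,
        validate: bool = True,
    ) -> None:
        self.n = int(n)
        self.variables = tuple(variables)
        self.means = np.asarray(means, dtype=float)
        self.covariance = np.asarray(covariance, dtype=float)
        self._index = {v.name: i for i, v in enumerate(self.variables)}
        if validate:
            self.validate()

    # -- accessors ---------------------------------------------------------

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise PcssError(f"unknown variable {name!r}") from None

    def variable(self, name: str) -> VariableInfo:
        return self.variables[self.index(name)]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def mean(self, name: str) -> float:
        return float(self.means[self.index(name)])

    def var(self, name: str) -> float:
        i = self.index(name)
        return float(self.covariance[i, i])

    def cov(self, a: str, b: str) -> float:
        return float(self.covariance[self.index(a), self.index(b)])

    def copy(self) -> "PcssSet":
        return PcssSet(
            self.n, self.variables, self.means.copy(), self.covariance.copy(), validate=False
        )

    # -- invariants --------------------------------------------------------

    def validate(self, corr_tol: float = 1e-8) -> None:
        k = len(self.variables)
        if self.n <= 0:
            raise PcssError(f"sample size must be positive; got {self.n}")
        if len(self._index) != k:
            raise PcssError("variable names must be unique")
        if self.means.shape != (k,):
            raise PcssError(f"means must have shape ({k},); got {self.means.shape}")
        if self.covariance.shape != (k, k):
            raise PcssError(f"covariance must have shape ({k}, {k}); got {self.covariance.shape}")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8, rtol=1e-8):
            raise PcssError("covariance matrix is not symmetric")
        d = np.diag(self.covariance)
        if np.any(d < 0):
            raise PcssError("covariance diagonal has negative entries")
        sd = np.sqrt(np.maximum(d, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = self.covariance / np.outer(sd, sd)
        off = corr[~np.eye(k, dtype=bool)]
        off = off[np.isfinite(off)]
        if off.size and np.max(np.abs(off)) > 1 + corr_tol:
            raise PcssError(
                f"implied correlation outside [-1, 1]: max |r| = {np.max(np.abs(off)):.6g}"
            )
        intercepts = [v for v in self.variables if v.role == "intercept"]
        if len(intercepts) > 1:
            raise PcssError("at most one intercept variable is allowed")
        for v in intercepts:
            i = self.index(v.name)
            if abs(self.means[i] - 1.0) > 1e-8:
                raise PcssError("intercept mean must be 1")
            if np.max(np.abs(self.covariance[i])) > 1e-8:
                raise PcssError("intercept covariances must be 0")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PcssSet(n={self.n}, variables={[v.name for v in self.variables]})"


# ---------------------------------------------------------------------------
# regression results
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    """Coefficients and inference for one reconstructed linear model."""

    names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    pvalue: np.ndarray
    sigma2: float
    df: int
    n: int
    p: int

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def pval(self, name: str) -> float:
        return float(self.pvalue[self.names.index(name)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "term": list(self.names),
                "beta": self.beta,
                "se": self.se,
                "t": self.tstat,
                "p": self.pvalue,
            }
        )


# ---------------------------------------------------------------------------
# exact cross-product reconstruction and the OLS fit
# ---------------------------------------------------------------------------


def reconstruct_xtx(pcss: PcssSet, design: Sequence[str]) -> np.ndarray:
    """Exact X'X over the named design columns: ``(n-1) S(X) + n x̄ x̄'``."""
    idx = [pcss.index(name) for name in design]
    s = pcss.covariance[np.ix_(idx, idx)]
    xbar = pcss.means[idx]
    return (pcss.n - 1) * s + pcss.n * np.outer(xbar, xbar)


def reconstruct_xtw(pcss_cov_xw, w_mean: float, x_means, n: int) -> np.ndarray:
    """Exact X'w: ``(n-1) s_{w,x} + n w̄ x̄``."""
    cov = np.asarray(pcss_cov_xw, dtype=float)
    xm = np.asarray(x_means, dtype=float)
    if cov.shape != xm.shape:
        raise PcssError(f"dimension mismatch: cov {cov.shape} vs means {xm.shape}")
    return (n - 1) * cov + n * float(w_mean) * xm


def _collinear_columns(xtx: np.ndarray, names: Sequence[str]) -> list[str]:
    # columns loading on the near-null eigenvector
    vals, vecs = np.linalg.eigh(xtx)
    v = np.abs(vecs[:, 0])
    cutoff = 0.3 * v.max() if v.max() > 0 else 0.0
    return [nm for nm, load in zip(names, v) if load >= cutoff]


def ols_from_pcss(
    pcss: PcssSet,
    response,
    design: Sequence[str],
    condition_cap: float = DEFAULT_CONDITION_CAP,
) -> RegressionResult:
    """Fit ``w ~ design`` from summary statistics alone.

    ``response`` is either the name of a phenotype in ``pcss`` or any object
    with ``mean``, ``variance``, and ``cov_with`` (a mapping from design
    names to covariances; intercept entries may be omitted), such as
    :class:`~pcssreg.product_moments.ProductMoments`.

    When the response moments are the exact sample moments of some dataset,
    the fit equals a direct OLS fit on that dataset to machine precision;
    with approximated product moments it inherits their approximation error.
    """
    names = tuple(design)
    n, p = pcss.n, len(names)
    if p == 0:
        raise PcssError("design must name at least one column")
    if n <= p:
        raise PcssError(f"need n > p; got n={n}, p={p}")

    xtx = reconstruct_xtx(pcss, names)
    cond = np.linalg.cond(xtx)
    if not np.isfinite(cond) or cond > condition_cap:
        culprits = _collinear_columns(xtx, names)
        raise CollinearDesignError(
            f"X'X is singular or ill-conditioned (cond={cond:.3g} > cap {condition_cap:.3g}); "
            f"near-collinear columns: {culprits}"
        )

    if isinstance(response, str):
        w_mean = pcss.mean(response)
        w_var = pcss.var(response)
        cov = np.array([pcss.cov(response, nm) for nm in names])
    else:
        w_mean = float(response.mean)
        w_var = float(response.variance)
        cov_map: Mapping[str, float] = response.cov_with
        cov = np.empty(p)
        for j, nm in enumerate(names):
            if pcss.variable(nm).role == "intercept":
                cov[j] = 0.0
            else:
                try:
                    cov[j] = cov_map[nm]
                except KeyError:
                    raise PcssError(
                        f"response moments carry no covariance with design column {nm!r}"
                    ) from None

    xtw = reconstruct_xtw(cov, w_mean, pcss.means[[pcss.index(nm) for nm in names]], n)
    beta = np.linalg.solve(xtx, xtw)
    wtw = (n - 1) * w_var + n * w_mean**2
    df = n - p
    sigma2 = (wtw - float(beta @ xtw)) / df

    floored = False
    if sigma2 < 0.0:
        warnings.warn(
            f"residual variance estimate negative ({sigma2:.3g}); flooring at {SIGMA2_FLOOR}"
            " and reporting p = 1",
            RuntimeWarning,
            stacklevel=2,
        )
        sigma2 = SIGMA2_FLOOR
        floored = True
    elif sigma2 == 0.0:
        warnings.warn(
            "residual variance is exactly 0; t statistics undefined, reporting p = 1",
            RuntimeWarning,
            stacklevel=2,
        )

    xtx_inv = np.linalg.inv(xtx)
    var_beta = sigma2 * np.diag(xtx_inv)
    se = np.sqrt(np.maximum(var_beta, 0.0))
    tstat = np.full(p, np.nan)
    pvalue = np.ones(p)
    ok = se > 0
    if np.any(ok):
        tstat[ok] = beta[ok] / se[ok]
        # stdtr is the CDF of Student's t; two-sided p from |t|
        pvalue[ok] = 2.0 * stdtr(df, -np.abs(tstat[ok]))
    if floored:
        pvalue = np.ones(p)

    return RegressionResult(
        names=names,
        beta=beta,
        se=se,
        tstat=tstat,
        pvalue=pvalue,
        sigma2=float(sigma2),
        df=df,
        n=n,
        p=p,
    )
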