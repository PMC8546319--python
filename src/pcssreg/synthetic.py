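"""Synthetic individual-level data generators, IPD fitting oracles, and the
two simulation studies used to validate the summary-statistic approximation.

The *null* study draws datasets where the variant is independent of every
phenotype, fits the summary-statistic product model per replicate, and
reports empirical rejection rates across significance thresholds.  The
*factorial* study crosses generation parameters at two levels each, fits the
same model both from exact summary statistics and directly on the
individual-level data, and summarises the discrepancies (bias, MSE, and
test-decision disagreement).

Correlated Bernoulli phenotypes are produced with a Gaussian copula whose
latent correlation is calibrated by bisection so the realised phenotype
correlation matches its target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations, product as iter_product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri, owens_t, stdtr

from .combine import CombinationSpec, product_model
from .pcss_model import (
    Bernoulli,
    Degenerate,
    Gaussian,
    GenotypeHwe,
    PcssError,
    PcssSet,
    RegressionResult,
    VariableInfo,
)

__all__ = [
    "SimulationConfig",
    "IpdDataset",
    "bvn_cdf",
    "max_binary_corr",
    "latent_binary_corr",
    "simulate_null_dataset",
    "simulate_factorial_dataset",
    "exact_pcss_from_ipd",
    "ipd_oracle_fit",
    "ipd_logistic_fit",
    "run_type1_experiment",
    "run_comparison_experiment",
    "Type1Result",
    "ComparisonResult",
]


# ---------------------------------------------------------------------------
# bivariate normal CDF and the Gaussian copula for correlated Bernoullis
# ---------------------------------------------------------------------------


def bvn_cdf(h, k, rho):
    """Standard bivariate normal CDF ``P(X <= h, Y <= k)`` via Owen's T.

    Vectorised over all three arguments.
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, float), np.asarray(k, float), np.asarray(rho, float)
    )
    shape = h.shape
    h = h.ravel().copy()
    k = k.ravel().copy()
    rho = rho.ravel()
    # nudge exact zeros; the Owen's T decomposition divides by h and k
    h[np.abs(h) < 1e-12] = 1e-12
    k[np.abs(k) < 1e-12] = 1e-12

    out = np.empty_like(h)
    hi = rho > 1.0 - 1e-12
    lo = rho < -1.0 + 1e-12
    mid = ~(hi | lo)
    if np.any(hi):
        out[hi] = ndtr(np.minimum(h[hi], k[hi]))
    if np.any(lo):
        out[lo] = np.maximum(ndtr(h[lo]) + ndtr(k[lo]) - 1.0, 0.0)
    if np.any(mid):
        hm, km, rm = h[mid], k[mid], rho[mid]
        s = np.sqrt(1.0 - rm**2)
        ah = (km - rm * hm) / (hm * s)
        ak = (hm - rm * km) / (km * s)
        delta = np.where(hm * km < 0, 0.5, 0.0)
        val = 0.5 * (ndtr(hm) + ndtr(km)) - owens_t(hm, ah) - owens_t(km, ak) - delta
        out[mid] = np.clip(val, 0.0, 1.0)
    return out.reshape(shape) if shape else float(out[0])


def max_binary_corr(p1, p2):
    """Fréchet upper bound on the correlation of Bernoulli(p1), Bernoulli(p2)."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    return (np.minimum(p1, p2) - p1 * p2) / denom


def latent_binary_corr(p1, p2, rho, tol: float = 1e-10, maxiter: int = 80):
    """Latent Gaussian correlation that yields Bernoulli margins (p1, p2) with
    correlation ``rho`` under thresholding (``Y_k = 1{Z_k <= Φ⁻¹(p_k)}``).

    Bisection on the latent correlation; vectorised.  Raises when the target
    exceeds the Fréchet bound.
    """
    p1, p2, rho = np.broadcast_arrays(
        np.asarray(p1, float), np.asarray(p2, float), np.asarray(rho, float)
    )
    shape = p1.shape
    p1, p2, rho = p1.ravel(), p2.ravel(), rho.ravel()
    if np.any(rho > max_binary_corr(p1, p2) + 1e-12):
        raise PcssError("target Bernoulli correlation exceeds its Fréchet bound")
    z1, z2 = ndtri(p1), ndtri(p2)
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    target_p11 = rho * denom + p1 * p2
    lo = np.full_like(rho, -1.0 + 1e-9)
    hi = np.full_like(rho, 1.0 - 1e-9)
    for _ in range(maxiter):
        mid = 0.5 * (lo + hi)
        val = bvn_cdf(z1, z2, mid)
        high = val > target_p11
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
        if np.max(hi - lo) < tol:
            break
    out = 0.5 * (lo + hi)
    return out.reshape(shape) if shape else float(out[0])


# ---------------------------------------------------------------------------
# configuration and datasets
# ---------------------------------------------------------------------------


def _default_comparison_factors(m: int) -> dict:
    # levels chosen so the strongest cell has roughly 90% power at 1e-8
    # (the published design's stated calibration) and the weakest is near-null
    return {
        "n": (600, 1500),
        "maf": (0.15, 0.4),
        "beta_snp": (0.05, 0.2),
        "rho": (0.2, 0.5),
    }


def _default_comparison_fixed(m: int, phenotype_type: str) -> dict:
    fixed = {
        "alpha2": 0.25,
        "alpha3": 0.3,
        "beta_x2": 0.2,
        "beta_x3": 0.15,
        "sigma": 0.8,
    }
    fixed["beta0"] = -0.5 if phenotype_type == "binary" else 1.5
    return fixed


@dataclass
class SimulationConfig:
    """Settings for the null Type-I-error study or the factorial comparison
    study.

    Ranges mirror moderate, positive-mean regimes; the exact parameter
    distributions used in the original experiments are not published, so
    these are declared defaults rather than reconstructions.
    """

    study: str = "null_type1"  # null_type1 | factorial
    m: int = 2
    phenotype_type: str = "continuous"  # continuous | binary
    replicates: int = 50_000
    seed: int | None = None
    n_range: tuple[int, int] = (500, 2000)
    maf_range: tuple[float, float] = (0.1, 0.5)
    mean_range: tuple[float, float] | None = None
    sd_range: tuple[float, float] = (0.5, 2.0)
    rho_range: tuple[float, float] | None = None
    alphas: tuple[float, ...] = (5e-2, 1e-3, 1e-5, 1e-6)
    # factorial-study settings
    reps_per_cell: int = 1000
    factors: dict | None = None
    fixed: dict | None = None
    comparison_alphas: tuple[float, ...] = tuple(10.0 ** -a for a in range(1, 9))
    infeasible: str = "resample"  # resample | error

    def __post_init__(self) -> None:
        if self.study not in ("null_type1", "factorial"):
            raise PcssError(f"unknown study {self.study!r}")
        if self.phenotype_type not in ("continuous", "binary"):
            raise PcssError(f"unknown phenotype type {self.phenotype_type!r}")
        if self.m < 2:
            raise PcssError("need at least two phenotypes")
        if self.mean_range is None:
            self.mean_range = (0.2, 0.8) if self.phenotype_type == "binary" else (0.5, 3.0)
        if self.rho_range is None:
            self.rho_range = (0.0, 0.5) if self.phenotype_type == "binary" else (0.1, 0.7)
        if self.study == "factorial":
            if self.factors is None:
                self.factors = _default_comparison_factors(self.m)
            base_fixed = _default_comparison_fixed(self.m, self.phenotype_type)
            base_fixed.update(self.fixed or {})
            self.fixed = base_fixed

    @property
    def phenotype_names(self) -> tuple[str, ...]:
        return tuple(f"y{k + 1}" for k in range(self.m))

    @property
    def design(self) -> tuple[str, ...]:
        if self.study == "null_type1":
            return ("intercept", "snp")
        if self.m == 2:
            return ("intercept", "snp", "x2", "x3")
        return ("intercept", "snp", "x2")


@dataclass
class IpdDataset:
    """One simulated individual-level dataset."""

    genotype: np.ndarray
    covariates: dict[str, np.ndarray]
    phenotypes: np.ndarray  # (n, m)
    binary_phenotypes: bool
    maf: float
    covariate_info: dict[str, VariableInfo] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.genotype.shape[0]

    @property
    def m(self) -> int:
        return self.phenotypes.shape[1]

    @property
    def phenotype_names(self) -> tuple[str, ...]:
        return tuple(f"y{k + 1}" for k in range(self.m))

    def column(self, name: str) -> np.ndarray:
        if name == "intercept":
            return np.ones(self.n)
        if name == "snp":
            return self.genotype
        if name in self.covariates:
            return self.covariates[name]
        if name.startswith("y"):
            k = int(name[1:]) - 1
            if 0 <= k < self.m:
                return self.phenotypes[:, k]
        raise PcssError(f"unknown column {name!r}")

    def design_matrix(self, names: Sequence[str]) -> np.ndarray:
        return np.column_stack([self.column(nm) for nm in names])


# ---------------------------------------------------------------------------
# parameter draws (vectorised, with feasibility rejection)
# ---------------------------------------------------------------------------


def _draw_corr_matrices(rng, size: int, m: int, rho_range, max_tries: int = 1000):
    """Pairwise-uniform correlation matrices, resampled until PSD."""
    npair = m * (m - 1) // 2
    iu = np.triu_indices(m, k=1)
    rho = rng.uniform(rho_range[0], rho_range[1], (size, npair))
    mats = np.broadcast_to(np.eye(m), (size, m, m)).copy()
    mats[:, iu[0], iu[1]] = rho
    mats[:, iu[1], iu[0]] = rho
    if m > 2:
        for _ in range(max_tries):
            bad = np.linalg.eigvalsh(mats)[:, 0] < 1e-10
            if not bad.any():
                break
            nb = int(bad.sum())
            r = rng.uniform(rho_range[0], rho_range[1], (nb, npair))
            sub = np.broadcast_to(np.eye(m), (nb, m, m)).copy()
            sub[:, iu[0], iu[1]] = r
            sub[:, iu[1], iu[0]] = r
            mats[bad] = sub
        else:  # pragma: no cover - would need a pathological range
            raise PcssError("could not draw a positive semi-definite correlation matrix")
    return mats


def _draw_null_params(cfg: SimulationConfig, rng, size: int) -> dict:
    out = {
        "n": rng.integers(cfg.n_range[0], cfg.n_range[1] + 1, size),
        "maf": rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size),
        "mu": rng.uniform(cfg.mean_range[0], cfg.mean_range[1], (size, cfg.m)),
    }
    if cfg.phenotype_type == "continuous":
        out["sd"] = rng.uniform(cfg.sd_range[0], cfg.sd_range[1], (size, cfg.m))
        out["corr"] = _draw_corr_matrices(rng, size, cfg.m, cfg.rho_range)
    else:
        iu = np.triu_indices(cfg.m, k=1)
        mu = out["mu"]
        rho = rng.uniform(cfg.rho_range[0], cfg.rho_range[1], (size, len(iu[0])))
        for _ in range(1000):
            bound = np.column_stack(
                [max_binary_corr(mu[:, i], mu[:, j]) for i, j in zip(*iu)]
            )
            bad = (rho > bound - 1e-9).any(axis=1)
            if not bad.any():
                break
            if cfg.infeasible == "error":
                raise PcssError("infeasible Bernoulli correlation target")
            nb = int(bad.sum())
            mu[bad] = rng.uniform(cfg.mean_range[0], cfg.mean_range[1], (nb, cfg.m))
            rho[bad] = rng.uniform(cfg.rho_range[0], cfg.rho_range[1], (nb, len(iu[0])))
        latent = np.column_stack(
            [
                latent_binary_corr(mu[:, i], mu[:, j], rho[:, c])
                for c, (i, j) in enumerate(zip(*iu))
            ]
        )
        mats = np.broadcast_to(np.eye(cfg.m), (size, cfg.m, cfg.m)).copy()
        mats[:, iu[0], iu[1]] = latent
        mats[:, iu[1], iu[0]] = latent
        if cfg.m > 2:
            for _ in range(1000):
                bad = np.linalg.eigvalsh(mats)[:, 0] < 1e-10
                if not bad.any():
                    break
                mats[bad] += np.eye(cfg.m) * 1e-8  # nudge borderline matrices
        out["rho"] = rho
        out["latent"] = mats
    return out


def _params_row(cfg: SimulationConfig, params: dict, i: int) -> dict:
    row = {"n": int(params["n"][i]), "maf": float(params["maf"][i]), "mu": params["mu"][i]}
    if cfg.phenotype_type == "continuous":
        row["sd"] = params["sd"][i]
        row["corr"] = params["corr"][i]
    else:
        row["rho"] = params["rho"][i]
        row["latent"] = params["latent"][i]
    return row


def simulate_null_dataset(config: SimulationConfig, rng, params: dict | None = None) -> IpdDataset:
    """Draw one dataset where the variant is independent of all phenotypes.

    ``params`` (a single parameter draw) may be supplied to separate the
    parameter stream from the data stream; otherwise one is drawn from
    ``rng`` first.
    """
    if params is None:
        drawn = _draw_null_params(config, rng, 1)
        params = _params_row(config, drawn, 0)
    n, maf = params["n"], params["maf"]
    genotype = rng.binomial(2, maf, n).astype(float)
    mu = np.asarray(params["mu"], float)
    if config.phenotype_type == "continuous":
        sd = np.asarray(params["sd"], float)
        cov = np.outer(sd, sd) * params["corr"]
        chol = np.linalg.cholesky(cov)
        phenos = mu + rng.standard_normal((n, config.m)) @ chol.T
        binary = False
    else:
        chol = np.linalg.cholesky(params["latent"])
        z = rng.standard_normal((n, config.m)) @ chol.T
        phenos = (z <= ndtri(mu)).astype(float)
        binary = True
    return IpdDataset(
        genotype=genotype,
        covariates={},
        phenotypes=phenos,
        binary_phenotypes=binary,
        maf=maf,
        covariate_info={},
        params=dict(params),
    )


def simulate_factorial_dataset(
    params: Mapping[str, float],
    rng,
    m: int = 2,
    phenotype_type: str = "continuous",
) -> IpdDataset:
    """Draw one dataset from the factorial design.

    The variant is at HWE with the given MAF; a binary covariate follows a
    logistic model of the variant (``x2 ~ Bernoulli(expit(alpha2 x1))``); a
    continuous covariate (two-phenotype designs only) is linear in the
    variant with mean 0, variance 1, and correlation ``alpha3``; phenotypes
    follow ``u(y_k) = beta0 + x' beta_k + eps`` with multivariate-normal
    errors, through the identity link for continuous phenotypes and the
    logit link for binary ones.
    """
    n = int(params["n"])
    maf = float(params["maf"])
    alpha2 = float(params.get("alpha2", 0.0))
    x1 = rng.binomial(2, maf, n).astype(float)
    x2 = rng.binomial(1, expit(alpha2 * x1)).astype(float)
    covariates = {"x2": x2}
    # marginal law of x2 under HWE mixing of the logistic model
    g_probs = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    p_x2 = float(np.sum(g_probs * expit(alpha2 * np.arange(3.0))))
    covariate_info = {"x2": VariableInfo("x2", "predictor", "binary", Bernoulli(p_x2))}

    use_x3 = m == 2
    if use_x3:
        alpha3 = float(params.get("alpha3", 0.0))
        g_std = (x1 - 2 * maf) / math.sqrt(2 * maf * (1 - maf))
        x3 = alpha3 * g_std + math.sqrt(max(1 - alpha3**2, 0.0)) * rng.standard_normal(n)
        covariates["x3"] = x3
        covariate_info["x3"] = VariableInfo("x3", "predictor", "continuous", Gaussian(0.0, 1.0))

    sigma = float(params.get("sigma", 1.0))
    rho = float(params.get("rho", 0.0))
    corr = np.full((m, m), rho)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr) * sigma
    eps = rng.standard_normal((n, m)) @ chol.T

    beta0 = float(params.get("beta0", 0.0))
    beta_snp = float(params.get("beta_snp", 0.0))
    beta_x2 = float(params.get("beta_x2", 0.0))
    beta_x3 = float(params.get("beta_x3", 0.0))
    u = beta0 + beta_snp * x1[:, None] + beta_x2 * x2[:, None] + eps
    if use_x3:
        u = u + beta_x3 * covariates["x3"][:, None]

    if phenotype_type == "binary":
        phenos = (rng.random((n, m)) < expit(u)).astype(float)
        binary = True
    else:
        phenos = u
        binary = False
    return IpdDataset(
        genotype=x1,
        covariates=covariates,
        phenotypes=phenos,
        binary_phenotypes=binary,
        maf=maf,
        covariate_info=covariate_info,
        params=dict(params),
    )


# ---------------------------------------------------------------------------
# exact summary statistics and IPD oracles
# ---------------------------------------------------------------------------


def exact_pcss_from_ipd(
    ipd: IpdDataset, validate: bool = False, descriptors: str = "sample"
) -> PcssSet:
    """Exact sample means and (n-1)-denominator covariances of every column,
    with marginal-law descriptors attached to the predictors.

    ``descriptors="sample"`` (default) parameterises each predictor's assumed
    law from the sample moments — the MAF a repository would publish — which
    keeps the law's mean consistent with the stored mean.  A mismatch there
    (``descriptors="true"``, which uses the generating parameters) leaks the
    mean-product term into the covariance approximation and makes the null
    test anticonservative.
    """
    names = ["snp"] + list(ipd.covariates) + list(ipd.phenotype_names)
    data = np.column_stack([ipd.genotype] + list(ipd.covariates.values()) + [ipd.phenotypes])
    k = data.shape[1]
    means = np.concatenate([[1.0], data.mean(axis=0)])
    cov = np.zeros((k + 1, k + 1))
    cov[1:, 1:] = np.cov(data, rowvar=False, ddof=1)
    variables = [VariableInfo("intercept", "intercept", "continuous", Degenerate(1.0))]
    if descriptors == "sample":
        maf_hat = float(np.clip(means[1] / 2.0, 1e-9, 1.0 - 1e-9))
        variables.append(VariableInfo("snp", "predictor", "genotype", GenotypeHwe(maf_hat)))
    else:
        variables.append(VariableInfo("snp", "predictor", "genotype", GenotypeHwe(ipd.maf)))
    for j, nm in enumerate(ipd.covariates, start=1):
        info = ipd.covariate_info.get(nm, VariableInfo(nm, "predictor", "continuous", None))
        if descriptors == "sample":
            col_mean = float(means[j + 1])
            col_sd = float(np.sqrt(max(cov[j + 1, j + 1], 0.0)))
            if info.vtype == "binary":
                dist = Bernoulli(float(np.clip(col_mean, 0.0, 1.0)))
            else:
                dist = Gaussian(col_mean, col_sd)
            info = VariableInfo(nm, "predictor", info.vtype, dist)
        variables.append(info)
    vtype = "binary" if ipd.binary_phenotypes else "continuous"
    for nm in ipd.phenotype_names:
        variables.append(VariableInfo(nm, "phenotype", vtype, None))
    return PcssSet(ipd.n, variables, means, cov, validate=validate)


def _combined_response(ipd: IpdDataset, spec: CombinationSpec) -> np.ndarray:
    cols = [ipd.column(nm) for nm in spec.phenotypes]
    if spec.op in ("product", "and"):
        w = cols[0].copy()
        for c in cols[1:]:
            w = w * c
        return w
    w = 1.0 - cols[0]
    for c in cols[1:]:
        w = w * (1.0 - c)
    return 1.0 - w


def _ols_ipd(X: np.ndarray, w: np.ndarray, names: Sequence[str]) -> RegressionResult:
    n, p = X.shape
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ w)
    resid = w - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(xtx)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    tstat = np.full(p, np.nan)
    pvalue = np.ones(p)
    ok = se > 0
    tstat[ok] = beta[ok] / se[ok]
    pvalue[ok] = 2.0 * stdtr(df, -np.abs(tstat[ok]))
    return RegressionResult(
        names=tuple(names),
        beta=beta,
        se=se,
        tstat=tstat,
        pvalue=pvalue,
        sigma2=sigma2,
        df=df,
        n=n,
        p=p,
    )


def ipd_oracle_fit(ipd: IpdDataset, spec: CombinationSpec) -> RegressionResult:
    """Direct OLS fit on the literal combined phenotype (the oracle the
    summary-statistic path is judged against)."""
    w = _combined_response(ipd, spec)
    X = ipd.design_matrix(spec.design)
    return _ols_ipd(X, w, spec.design)


def ipd_logistic_fit(ipd: IpdDataset, spec: CombinationSpec) -> RegressionResult | None:
    """Covariate-adjusted logistic regression on a binary combined phenotype.

    Returns None when the fit fails to converge (e.g., perfect separation).
    """
    import statsmodels.api as sm

    w = _combined_response(ipd, spec)
    X = ipd.design_matrix(spec.design)
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(w, X).fit(disp=0, maxiter=200)
    except Exception:
        return None
    if not np.all(np.isfinite(res.bse)):
        return None
    return RegressionResult(
        names=tuple(spec.design),
        beta=np.asarray(res.params, float),
        se=np.asarray(res.bse, float),
        tstat=np.asarray(res.tvalues, float),
        pvalue=np.asarray(res.pvalues, float),
        sigma2=float("nan"),
        df=ipd.n - X.shape[1],
        n=ipd.n,
        p=X.shape[1],
    )


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------


@dataclass
class Type1Result:
    table: pd.DataFrame
    pvalues: np.ndarray
    config: SimulationConfig

    def rate_at(self, alpha: float) -> float:
        row = self.table[np.isclose(self.table["alpha"], alpha)]
        if row.empty:
            return float(np.mean(self.pvalues < alpha))
        return float(row["rate"].iloc[0])


def run_type1_experiment(config: SimulationConfig, progress: bool = False) -> Type1Result:
    """Empirical Type I error of the summary-statistic product test under the
    null, at each configured significance threshold."""
    rng = np.random.default_rng(config.seed)
    reps = config.replicates
    params = _draw_null_params(config, rng, reps)
    streams = rng.spawn(reps)
    spec = CombinationSpec(config.phenotype_names, "product", ("intercept", "snp"))

    pvalues = np.empty(reps)
    iterator = range(reps)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="null replicates")
    for i in iterator:
        row = _params_row(config, params, i)
        ipd = simulate_null_dataset(config, streams[i], params=row)
        pcss = exact_pcss_from_ipd(ipd)
        res = product_model(pcss, spec)
        pvalues[i] = res.pval("snp")

    rows = []
    for alpha in config.alphas:
        rate = float(np.mean(pvalues < alpha))
        mc_se = math.sqrt(max(rate * (1 - rate), 1e-300) / reps)
        rows.append(
            {
                "alpha": alpha,
                "replicates": reps,
                "rejections": int(np.sum(pvalues < alpha)),
                "rate": rate,
                "mc_se": mc_se,
                "ci_lo": max(rate - 1.96 * mc_se, 0.0),
                "ci_hi": min(rate + 1.96 * mc_se, 1.0),
            }
        )
    return Type1Result(table=pd.DataFrame(rows), pvalues=pvalues, config=config)


@dataclass
class ComparisonResult:
    cells: pd.DataFrame
    disagreement: pd.DataFrame
    overall: dict
    config: SimulationConfig


def _disagreement_rows(alphas, p_a: np.ndarray, p_b: np.ndarray, label: str) -> list[dict]:
    """Test-decision disagreement of method a vs reference b at each alpha."""
    rows = []
    for alpha in alphas:
        ra = p_a < alpha
        rb = p_b < alpha
        overall = float(np.mean(ra != rb))
        n_fail_b = int(np.sum(~rb))
        n_rej_b = int(np.sum(rb))
        rows.append(
            {
                "comparison": label,
                "alpha": alpha,
                "overall": overall,
                "reject_given_ref_fail": float(np.sum(ra & ~rb) / n_fail_b) if n_fail_b else np.nan,
                "fail_given_ref_reject": float(np.sum(~ra & rb) / n_rej_b) if n_rej_b else np.nan,
            }
        )
    return rows


def run_comparison_experiment(
    config: SimulationConfig, logistic: bool | None = None, progress: bool = False
) -> ComparisonResult:
    """Factorial comparison of the summary-statistic fit against the
    individual-level oracle: bias/MSE of the variant's slope, SE, and |t|,
    plus test-decision disagreement rates across significance thresholds."""
    if config.study != "factorial":
        raise PcssError("run_comparison_experiment needs a factorial-study config")
    if logistic is None:
        logistic = config.phenotype_type == "binary"
    rng = np.random.default_rng(config.seed)
    spec = CombinationSpec(config.phenotype_names, "product", config.design)

    factor_names = list(config.factors)
    cells = list(iter_product(*(config.factors[f] for f in factor_names)))
    cell_rows = []
    all_p_pcss, all_p_ipd, all_p_logit = [], [], []
    all_err = {"beta": [], "se": [], "abst": []}
    all_beta_ipd = []

    iterator = cells
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm

        iterator = tqdm(cells, desc="factorial cells")
    for cell in iterator:
        params = dict(config.fixed)
        params.update(dict(zip(factor_names, cell)))
        reps = config.reps_per_cell
        streams = rng.spawn(reps)
        b_p = np.empty(reps)
        b_i = np.empty(reps)
        se_p = np.empty(reps)
        se_i = np.empty(reps)
        t_p = np.empty(reps)
        t_i = np.empty(reps)
        p_p = np.empty(reps)
        p_i = np.empty(reps)
        p_l = np.full(reps, np.nan)
        for r in range(reps):
            ipd = simulate_factorial_dataset(
                params, streams[r], m=config.m, phenotype_type=config.phenotype_type
            )
            pcss = exact_pcss_from_ipd(ipd)
            fit_p = product_model(pcss, spec)
            fit_i = ipd_oracle_fit(ipd, spec)
            j = spec.design.index("snp")
            b_p[r], b_i[r] = fit_p.beta[j], fit_i.beta[j]
            se_p[r], se_i[r] = fit_p.se[j], fit_i.se[j]
            t_p[r] = abs(fit_p.tstat[j]) if np.isfinite(fit_p.tstat[j]) else 0.0
            t_i[r] = abs(fit_i.tstat[j])
            p_p[r], p_i[r] = fit_p.pvalue[j], fit_i.pvalue[j]
            if logistic:
                lres = ipd_logistic_fit(ipd, spec)
                if lres is not None:
                    p_l[r] = lres.pvalue[j]
        err_beta = b_p - b_i
        err_se = se_p - se_i
        err_t = t_p - t_i
        row = dict(zip(factor_names, cell))
        row.update(
            {
                "reps": reps,
                "ipd_beta_mean": float(np.mean(b_i)),
                "beta_bias": float(np.mean(err_beta)),
                "beta_mse": float(np.mean(err_beta**2)),
                "se_bias": float(np.mean(err_se)),
                "se_mse": float(np.mean(err_se**2)),
                "abst_bias": float(np.mean(err_t)),
                "abst_mse": float(np.mean(err_t**2)),
            }
        )
        cell_rows.append(row)
        all_p_pcss.append(p_p)
        all_p_ipd.append(p_i)
        all_p_logit.append(p_l)
        all_err["beta"].append(err_beta)
        all_err["se"].append(err_se)
        all_err["abst"].append(err_t)
        all_beta_ipd.append(b_i)

    p_pcss = np.concatenate(all_p_pcss)
    p_ipd = np.concatenate(all_p_ipd)
    dis_rows = _disagreement_rows(config.comparison_alphas, p_pcss, p_ipd, "pcss_vs_ipd_linear")
    if logistic:
        p_logit = np.concatenate(all_p_logit)
        ok = np.isfinite(p_logit)
        dis_rows += _disagreement_rows(
            config.comparison_alphas, p_pcss[ok], p_logit[ok], "pcss_vs_ipd_logistic"
        )
    overall = {
        "ipd_beta_mean": float(np.mean(np.concatenate(all_beta_ipd))),
        "ipd_beta_mean_abs": float(np.mean(np.abs(np.concatenate(all_beta_ipd)))),
    }
    for key, chunks in all_err.items():
        err = np.concatenate(chunks)
        overall[f"{key}_bias"] = float(np.mean(err))
        overall[f"{key}_mse"] = float(np.mean(err**2))
    return ComparisonResult(
        cells=pd.DataFrame(cell_rows),
        disagreement=pd.DataFrame(dis_rows),
        overall=overall,
        config=config,
    )
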