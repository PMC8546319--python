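import numpy as np
import pytest

from pcssreg import (
    Degenerate,
    GenotypeHwe,
    PcssSet,
    VariableInfo,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def pcss_from_columns(columns: dict, roles: dict | None = None, vtypes: dict | None = None,
                      dists: dict | None = None, include_intercept: bool = True) -> PcssSet:
    """Exact summary statistics of literal data columns (test helper)."""
    roles = roles or {}
    vtypes = vtypes or {}
    dists = dists or {}
    names = list(columns)
    data = np.column_stack([np.asarray(columns[nm], dtype=float) for nm in names])
    n = data.shape[0]
    means = data.mean(axis=0)
    cov = np.cov(data, rowvar=False, ddof=1)
    if cov.ndim == 0:
        cov = cov.reshape(1, 1)
    variables = [
        VariableInfo(nm, roles.get(nm, "phenotype"), vtypes.get(nm, "continuous"), dists.get(nm))
        for nm in names
    ]
    if include_intercept:
        variables = [VariableInfo("intercept", "intercept", "continuous", Degenerate(1.0))] + variables
        means = np.concatenate([[1.0], means])
        full = np.zeros((len(names) + 1, len(names) + 1))
        full[1:, 1:] = cov
        cov = full
    return PcssSet(n, variables, means, cov, validate=True)


@pytest.fixture
def toy_pcss():
    """x = (0,1,2,1) genotype-like predictor, y = (1,2,3,2) phenotype."""
    return pcss_from_columns(
        {"x": [0, 1, 2, 1], "y": [1, 2, 3, 2]},
        roles={"x": "predictor"},
        vtypes={"x": "genotype"},
        dists={"x": GenotypeHwe(0.5)},
    )


def random_binary_pcss(rng, n=400, rho_latent=0.3, p1=0.4, p2=0.6, maf=0.3):
    """Exact PCSS of a small binary-phenotype dataset with a null SNP."""
    from scipy.special import ndtri

    g = rng.binomial(2, maf, n).astype(float)
    L = np.linalg.cholesky(np.array([[1.0, rho_latent], [rho_latent, 1.0]]))
    z = rng.standard_normal((n, 2)) @ L.T
    y1 = (z[:, 0] <= ndtri(p1)).astype(float)
    y2 = (z[:, 1] <= ndtri(p2)).astype(float)
    pcss = pcss_from_columns(
        {"snp": g, "y1": y1, "y2": y2},
        roles={"snp": "predictor"},
        vtypes={"snp": "genotype", "y1": "binary", "y2": "binary"},
        dists={"snp": GenotypeHwe(max(g.mean() / 2, 1e-6))},
    )
    return pcss, g, y1, y2
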