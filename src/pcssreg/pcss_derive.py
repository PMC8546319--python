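"""Derive missing summary statistics from common GWAS-repository quantities.

Repositories rarely publish a full joint covariance matrix.  What they do
publish — minor allele frequencies, single-marker slopes and standard
errors, and per-marker test statistics — determines the missing pieces:

* a variant in Hardy-Weinberg equilibrium has genotype mean ``2 maf`` and
  variance ``2 maf (1 - maf)`` (binomial with 2 trials);
* the genotype/phenotype covariance is the single-marker slope times the
  genotype variance (inverting ``b = cov / var``);
* the phenotype/phenotype correlation is approximated by the correlation of
  the two traits' Z statistics over markers associated with neither trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .pcss_model import GenotypeHwe, PcssError, PcssSet, VariableInfo

__all__ = [
    "MarkerSummary",
    "hwe_moments",
    "cov_from_marginal_slope",
    "pheno_corr_from_z",
    "read_marker_table",
    "marker_pcss",
]

logger = logging.getLogger(__name__)

DEFAULT_ASSOC_THRESHOLD = 2.0
MIN_NULL_MARKERS = 30


@dataclass(frozen=True)
class MarkerSummary:
    """Single-marker GWAS summary row: MAF plus per-variable slope/SE/Z."""

    snp: str
    maf: float
    n: int
    beta: Mapping[str, float] = field(default_factory=dict)
    se: Mapping[str, float] = field(default_factory=dict)
    z: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise PcssError(f"MAF must be in (0, 0.5]; got {self.maf} for {self.snp}")
        if self.n <= 0:
            raise PcssError(f"n must be positive; got {self.n} for {self.snp}")


def hwe_moments(maf: float) -> tuple[float, float]:
    """Mean and variance of a minor-allele count under HWE: ``(2p, 2p(1-p))``."""
    if not 0.0 < maf <= 0.5:
        raise PcssError(f"MAF must be in (0, 0.5]; got {maf}")
    return 2.0 * maf, 2.0 * maf * (1.0 - maf)


def cov_from_marginal_slope(slope: float, genotype_variance: float) -> float:
    """Genotype/phenotype covariance implied by a single-marker slope.

    Inverts the simple-regression identity ``b = cov / var`` to
    ``cov = b · var``.
    """
    if genotype_variance <= 0.0:
        raise PcssError(f"genotype variance must be > 0; got {genotype_variance}")
    return slope * genotype_variance


def pheno_corr_from_z(
    z1,
    z2,
    assoc_threshold: float = DEFAULT_ASSOC_THRESHOLD,
    min_markers: int = MIN_NULL_MARKERS,
) -> float:
    """Phenotype correlation approximated by the correlation of Z statistics
    over markers associated with neither trait (both ``|z|`` below the
    threshold)."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise PcssError("Z vectors must be aligned on the same markers")
    keep = (np.abs(z1) < assoc_threshold) & (np.abs(z2) < assoc_threshold)
    if keep.sum() < min_markers:
        raise PcssError(
            f"only {int(keep.sum())} markers survive the |z| < {assoc_threshold} filter; "
            f"need at least {min_markers}"
        )
    r = float(np.corrcoef(z1[keep], z2[keep])[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def read_marker_table(
    path,
    phenotypes: Sequence[str] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[MarkerSummary]:
    """Read a per-SNP summary TSV.

    Expected columns: ``snp``, ``maf``, ``n``, and per-phenotype triplets
    ``<pheno>_beta`` / ``<pheno>_se`` / ``<pheno>_z`` (the SE and Z columns
    are optional).  ``column_map`` renames file columns to those conventions
    first.  Rows that fail validation are skipped with a logged reason.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in ("snp", "maf", "n"):
        if col not in df.columns:
            raise PcssError(f"marker table is missing required column {col!r}")
    if phenotypes is None:
        phenotypes = sorted(
            {c[: -len("_beta")] for c in df.columns if c.endswith("_beta")}
        )

    out: list[MarkerSummary] = []
    for _, row in df.iterrows():
        try:
            beta, se, z = {}, {}, {}
            for ph in phenotypes:
                if f"{ph}_beta" in df.columns and np.isfinite(row[f"{ph}_beta"]):
                    beta[ph] = float(row[f"{ph}_beta"])
                if f"{ph}_se" in df.columns and np.isfinite(row[f"{ph}_se"]):
                    se[ph] = float(row[f"{ph}_se"])
                if f"{ph}_z" in df.columns and np.isfinite(row[f"{ph}_z"]):
                    z[ph] = float(row[f"{ph}_z"])
            out.append(
                MarkerSummary(
                    snp=str(row["snp"]),
                    maf=float(row["maf"]),
                    n=int(row["n"]),
                    beta=beta,
                    se=se,
                    z=z,
                )
            )
        except (PcssError, ValueError) as exc:
            logger.warning("skipping marker row %r: %s", row.get("snp", "?"), exc)
    return out


def marker_pcss(
    marker: MarkerSummary,
    base: PcssSet,
    snp_name: str = "snp",
    required: Sequence[str] | None = None,
) -> PcssSet:
    """Assemble a per-SNP summary set by adding a derived genotype column to a
    base set of phenotype/covariate statistics.

    Resolution order per cell: a user-supplied value in ``base`` wins; else
    the value is derived (HWE moments for the genotype, slope x variance for
    its covariances); else assembly fails.  Derivations are logged.

    ``required`` names the base variables whose covariance with the SNP must
    resolve (default: all variables that have a slope entry; others error
    only if later requested by a design).
    """
    if snp_name in base.names:
        raise PcssError(f"base set already contains a variable named {snp_name!r}")

    g_mean, g_var = hwe_moments(marker.maf)
    logger.debug(
        "marker %s: derived genotype mean=%.6g var=%.6g from MAF=%.4g",
        marker.snp,
        g_mean,
        g_var,
        marker.maf,
    )

    k = len(base.variables)
    names = list(base.names)
    need = list(required) if required is not None else list(marker.beta)
    missing = [nm for nm in need if nm not in marker.beta and base.variable(nm).role != "intercept"]
    if missing:
        raise PcssError(
            f"marker {marker.snp}: no single-marker slope available to derive the "
            f"SNP covariance with {missing}"
        )

    cov_row = np.zeros(k)
    for nm in need:
        if base.variable(nm).role == "intercept":
            continue
        cov_row[base.index(nm)] = cov_from_marginal_slope(marker.beta[nm], g_var)
        logger.debug(
            "marker %s: derived cov(snp, %s) = %.6g", marker.snp, nm, cov_row[base.index(nm)]
        )

    means = np.concatenate([[g_mean], base.means])
    covariance = np.zeros((k + 1, k + 1))
    covariance[0, 0] = g_var
    covariance[0, 1:] = cov_row
    covariance[1:, 0] = cov_row
    covariance[1:, 1:] = base.covariance
    variables = [
        VariableInfo(snp_name, "predictor", "genotype", GenotypeHwe(marker.maf))
    ] + list(base.variables)
    n = marker.n if marker.n else base.n
    return PcssSet(n, variables, means, covariance, validate=True)
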