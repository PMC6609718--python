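"""Single-locus genome scan with a univariate linear mixed model.

The response is a pseudo-phenotype (fitted direct or social genetic effect
plus residual from the social animal model); the model per SNP is

    y = mu + x m + a + e,   a ~ N(0, sigma_g^2 K),  e ~ N(0, sigma_e^2 I)

with K a relationship matrix controlling polygenic background.  The null
variance ratio delta = sigma_e^2/sigma_g^2 is estimated once by REML via
the eigendecomposition of K and reused for every SNP (the standard
approximate strategy); each SNP is then a generalised least squares fit in
the rotated coordinates with a 1-df Wald chi-square test of m = 0.

The pseudo-phenotype is already corrected for sex, year-month, litter and
group, so the fixed part of the scan model carries only the intercept and
the SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .genoqc import GenotypeMatrix
from .relatedness import RelationshipMatrix

__all__ = [
    "NullModelFit",
    "AssociationResult",
    "fit_null_lmm",
    "scan",
    "classify",
    "genomic_inflation",
    "GENOME_WIDE_P",
    "SUGGESTIVE_P",
]

GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 5e-7


@dataclass
class NullModelFit:
    """REML null model: variance ratio and the spectral cache for GLS."""

    delta: float  # sigma_e^2 / sigma_g^2
    sigma_g2: float
    sigma_e2: float
    loglik: float
    eigvals: np.ndarray
    rot: np.ndarray  # U.T, rotates data into the eigenbasis of K
    y_rot: np.ndarray
    sample_ids: list

    @property
    def weights(self) -> np.ndarray:
        return self.eigvals + self.delta

    @property
    def variance_ratio(self) -> float:
        """Polygenic share sigma_g^2 / (sigma_g^2 + sigma_e^2)."""
        return 1.0 / (1.0 + self.delta)


def _reml_loglik_delta(delta, lam, y_r, X_r):
    w = lam + delta
    Xw = X_r / w[:, None]
    XtWX = X_r.T @ Xw
    try:
        XtWXi = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        return -np.inf
    beta = XtWXi @ (Xw.T @ y_r)
    r = y_r - X_r @ beta
    n, p = X_r.shape
    rss = float(r @ (r / w))
    if rss <= 0:
        return -np.inf
    sig = rss / (n - p)
    _, logdet_xx = np.linalg.slogdet(XtWX)
    return -0.5 * ((n - p) * (np.log(2 * np.pi * sig) + 1.0) + np.log(w).sum() + logdet_xx)


def fit_null_lmm(y, K: RelationshipMatrix | np.ndarray, sample_ids=None) -> NullModelFit:
    """REML estimate of the polygenic/residual variance ratio.

    Eigendecomposes K once; the restricted likelihood is maximised over
    log10(delta) on [-6, 6] (grid bracketing + bounded refinement).  With
    K = I the likelihood is flat in delta and the scan reduces to ordinary
    least squares.
    """
    if isinstance(K, RelationshipMatrix):
        sample_ids = list(K.ids)
        Kmat = K.values
    else:
        Kmat = np.asarray(K, float)
    y = np.asarray(y, float)
    n = len(y)
    if Kmat.shape != (n, n):
        raise ValueError("K must be square and match len(y)")
    if np.var(y) == 0:
        raise ValueError("degenerate response: zero variance")
    lam, U = np.linalg.eigh(Kmat)
    lam = np.maximum(lam, 0.0)
    rot = U.T
    y_r = rot @ y
    X_r = rot @ np.ones((n, 1))

    grid = np.linspace(-6, 6, 25)
    vals = [_reml_loglik_delta(10.0**g, lam, y_r, X_r) for g in grid]
    g0 = grid[int(np.argmax(vals))]
    res = minimize_scalar(
        lambda g: -_reml_loglik_delta(10.0**g, lam, y_r, X_r),
        bounds=(g0 - 1.0, g0 + 1.0), method="bounded",
        options={"xatol": 1e-6},
    )
    delta = float(10.0**res.x)
    ll = float(-res.fun)

    w = lam + delta
    Xw = X_r / w[:, None]
    beta = np.linalg.solve(X_r.T @ Xw, Xw.T @ y_r)
    r = y_r - X_r @ beta
    sigma_g2 = float(r @ (r / w)) / (n - X_r.shape[1])
    return NullModelFit(
        delta=delta, sigma_g2=sigma_g2, sigma_e2=sigma_g2 * delta, loglik=ll,
        eigvals=lam, rot=rot, y_rot=y_r,
        sample_ids=list(sample_ids) if sample_ids is not None else list(range(n)),
    )


@dataclass
class AssociationResult:
    contig: str
    pos: int
    ref: str
    alt: str
    maf: float
    n_miss: int
    beta: float
    se: float
    wald_stat: float
    p_value: float
    tier: str = "none"
    note: str = ""


def scan(
    y,
    genotypes: GenotypeMatrix,
    null: NullModelFit,
    sample_ids=None,
    reestimate_delta: bool = False,
) -> pd.DataFrame:
    """Per-SNP Wald tests of the SNP effect under the rotated LMM.

    ``sample_ids`` (or the genotype matrix's samples) must equal the null
    model's sample order exactly — misalignment is a hard error, never a
    silent reordering.  Missing dosages are mean-imputed per locus;
    monomorphic loci are reported with a skip note and p = NaN.  Results
    are ordered by contig then position.
    """
    ids = list(sample_ids) if sample_ids is not None else list(genotypes.samples)
    if ids != list(null.sample_ids):
        raise ValueError("sample order of genotypes does not match the null model fit")
    y = np.asarray(y, float)
    X = genotypes.dosages
    n, m = X.shape
    if n != len(y):
        raise ValueError("genotype and phenotype sample counts differ")

    mu = np.nanmean(X, axis=0)
    n_miss = np.isnan(X).sum(axis=0)
    Xi = np.where(np.isnan(X), mu[None, :], X)
    p_alt = mu / 2.0
    maf = np.minimum(p_alt, 1.0 - p_alt)
    mono = np.nanstd(Xi, axis=0) == 0

    w = null.weights
    y_r = null.y_rot
    ones_r = null.rot @ np.ones(n)
    G_r = null.rot @ Xi

    if reestimate_delta:
        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        for j in range(m):
            if mono[j]:
                continue
            X_r2 = np.column_stack([ones_r, G_r[:, j]])
            grid = np.linspace(-6, 6, 25)
            vals = [_reml_loglik_delta(10.0**g, null.eigvals, y_r, X_r2) for g in grid]
            dj = 10.0 ** grid[int(np.argmax(vals))]
            bj, sj = _gls_snp(y_r, ones_r, G_r[:, j], null.eigvals + dj)
            beta[j], se[j] = bj, sj
    else:
        beta, se = _gls_snp_vec(y_r, ones_r, G_r, w)
        beta[mono] = np.nan
        se[mono] = np.nan

    wald = (beta / se) ** 2
    pval = stats.chi2.sf(wald, df=1)
    out = genotypes.loci[["contig", "pos", "ref", "alt"]].copy()
    out["maf"] = maf
    out["n_miss"] = n_miss
    out["beta"] = beta
    out["se"] = se
    out["wald_stat"] = wald
    out["p_value"] = pval
    out["note"] = np.where(mono, "monomorphic: skipped", "")
    out = out.sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)
    return out


def _gls_snp_vec(y_r, ones_r, G_r, w):
    """Closed-form intercept+SNP GLS across all SNPs at once."""
    iw = 1.0 / w
    s00 = float(ones_r @ (iw * ones_r))
    s0y = float(ones_r @ (iw * y_r))
    syy = float(y_r @ (iw * y_r))
    s0g = G_r.T @ (iw * ones_r)
    sgg = np.einsum("ij,ij->j", G_r, iw[:, None] * G_r)
    sgy = G_r.T @ (iw * y_r)
    det = s00 * sgg - s0g**2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (s00 * sgy - s0g * s0y) / det
        alpha = (s0y - s0g * beta) / s00
        rss = syy - alpha * s0y - beta * sgy
        n = len(y_r)
        sigma2 = rss / (n - 2)
        var_beta = sigma2 * s00 / det
        se = np.sqrt(var_beta)
    return beta, se


def _gls_snp(y_r, ones_r, g_r, w):
    b, s = _gls_snp_vec(y_r, ones_r, g_r[:, None], w)
    return float(b[0]), float(s[0])


def classify(
    results: pd.DataFrame,
    genome_wide: float = GENOME_WIDE_P,
    suggestive: float = SUGGESTIVE_P,
) -> pd.DataFrame:
    """Label each SNP's significance tier (strict-< boundary convention)."""
    out = results.copy()
    p = out["p_value"].to_numpy()
    tier = np.where(p < genome_wide, "genome_wide",
                    np.where(p < suggestive, "suggestive", "none"))
    tier = np.where(np.isnan(p), "none", tier)
    out["tier"] = tier
    return out


def genomic_inflation(p_values) -> float:
    """Lambda_GC: median observed chi-square over its null median."""
    p = np.asarray(p_values, float)
    p = p[np.isfinite(p)]
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.isf(0.5, df=1))
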