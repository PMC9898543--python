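"""Phenotype preparation: normalization, covariates, hidden factors.

Raw PDUI lives on [0,1] with missingness; association testing wants an
approximately Gaussian phenotype free of technical structure.  The fixed
pipeline order is

1. rank-based inverse-normal transform per gene,
2. residualize on known covariates + genotype PCs,
3. estimate hidden factors from the residual matrix (truncated SVD, a
   light-weight stand-in for a probabilistic factor model of expression
   residuals),
4. residualize on the hidden factors.

Missing cells are mean-imputed for factor estimation only; they stay
missing in the phenotype handed to association testing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "inverse_normal_transform",
    "genotype_pcs",
    "hidden_factors",
    "residualize",
    "encode_covariates",
    "default_n_factors",
    "prepare_phenotypes",
]


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform, missing-aware.

    Non-missing values are replaced by ``Phi^-1(rank / (n + 1))`` with
    average ranks on ties; NaN stays NaN.  Requires >= 3 non-missing values
    and at least two distinct values (ranks of an all-constant vector are
    undefined up to ties covering everything).
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = ~np.isnan(x)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"need >= 3 non-missing values, got {n}")
    obs = x[mask]
    if np.all(obs == obs[0]):
        raise ValueError("all-constant input: ranks undefined")
    ranks = stats.rankdata(obs, method="average")
    out[mask] = stats.norm.ppf(ranks / (n + 1))
    return out


def genotype_pcs(G: GenotypeMatrix, k: int = 5) -> pd.DataFrame:
    """Top-k principal components of the standardized dosage matrix.

    Dosages are mean-imputed, centered, and scaled by ``sqrt(2 f (1-f))``
    (the binomial SD under Hardy-Weinberg); the sign of each PC is fixed so
    its largest-magnitude loading is positive.  If the matrix has rank < k
    the available PCs are returned with a warning.
    """
    if k >= min(G.n_samples, G.n_variants):
        raise ValueError(f"k={k} must be < min(n={G.n_samples}, m={G.n_variants})")
    X = G.dosages.copy()
    mu = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = mu[idx[1]]
    f = mu / 2.0
    scale = np.sqrt(2.0 * f * (1.0 - f))
    scale[scale == 0] = 1.0
    X = (X - mu) / scale

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if rank < k:
        logger.warning("genotype matrix rank %d < requested k=%d; returning %d PCs", rank, k, rank)
        k = rank
    scores = U[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(
        scores, index=list(G.sample_ids), columns=[f"PC{j + 1}" for j in range(k)]
    )


def default_n_factors(n_samples: int) -> int:
    """Hidden-factor count keyed on cohort size (15/30/35/60 ladder)."""
    if n_samples < 150:
        return 15
    if n_samples < 250:
        return 30
    if n_samples < 350:
        return 35
    return 60


def hidden_factors(residuals: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k principal factors of the genes x samples residual matrix.

    Genes are standardized (missing cells mean-imputed per gene) and the
    left-out structure is summarized by truncated SVD over samples.  The
    returned sample x factor table is ready to be used as covariates.
    """
    n_samples = residuals.shape[1]
    if k >= n_samples:
        raise ValueError(f"k={k} must be < n_samples={n_samples}")
    if k == 0:
        return pd.DataFrame(index=list(residuals.columns))
    M = residuals.to_numpy(dtype=float)
    mu = np.nanmean(M, axis=1, keepdims=True)
    M = np.where(np.isnan(M), mu, M)
    M = M - M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    M = M / sd
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    k = min(k, int((s > s.max() * 1e-12).sum()))
    scores = Vt[:k].T * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(scores[:, j]))
        if scores[lead, j] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(
        scores, index=list(residuals.columns), columns=[f"factor{j + 1}" for j in range(k)]
    )


def encode_covariates(covariates: pd.DataFrame, categorical: list[str] | None = None) -> pd.DataFrame:
    """Dummy-encode categorical columns, drop the reference level."""
    if covariates.shape[1] == 0:
        return covariates.copy()
    categorical = categorical or [
        c for c in covariates.columns if covariates[c].dtype == object
    ]
    enc = pd.get_dummies(covariates, columns=categorical, drop_first=True, dtype=float)
    const = [c for c in enc.columns if enc[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate columns after encoding: {const}")
    return enc


def residualize(phenotypes: pd.DataFrame, covariates: pd.DataFrame | None) -> pd.DataFrame:
    """Per-gene OLS residuals of phenotype on [intercept + covariates].

    ``phenotypes`` is genes x samples; ``covariates`` is samples x p (may be
    None/empty for intercept-only, i.e. mean-centering).  Missing phenotype
    cells stay missing; each gene is fitted on its non-missing samples.
    Raises on rank-deficient design, listing the collinear columns.
    """
    samples = list(phenotypes.columns)
    if covariates is None or covariates.shape[1] == 0:
        C = np.ones((len(samples), 1))
        names = ["intercept"]
    else:
        cov = covariates.loc[samples]
        C = np.column_stack([np.ones(len(samples)), cov.to_numpy(dtype=float)])
        names = ["intercept"] + list(cov.columns)
        rank = np.linalg.matrix_rank(C)
        if rank < C.shape[1]:
            # identify offending columns by greedy QR-style elimination
            bad = []
            keep = [0]
            for j in range(1, C.shape[1]):
                trial = keep + [j]
                if np.linalg.matrix_rank(C[:, trial]) == len(keep):
                    bad.append(names[j])
                else:
                    keep.append(j)
            raise ValueError(f"covariate design is rank deficient; collinear columns: {bad}")

    Y = phenotypes.to_numpy(dtype=float)
    out = np.full_like(Y, np.nan)
    complete = ~np.isnan(Y).any(axis=1)
    if complete.any():
        # fast path: one shared solve for fully observed genes
        beta, *_ = np.linalg.lstsq(C, Y[complete].T, rcond=None)
        out[complete] = (Y[complete].T - C @ beta).T
    for i in np.flatnonzero(~complete):
        mask = ~np.isnan(Y[i])
        if mask.sum() <= C.shape[1]:
            continue
        beta, *_ = np.linalg.lstsq(C[mask], Y[i, mask], rcond=None)
        out[i, mask] = Y[i, mask] - C[mask] @ beta
    return pd.DataFrame(out, index=phenotypes.index, columns=phenotypes.columns)


def prepare_phenotypes(
    pdui: pd.DataFrame,
    known_covariates: pd.DataFrame | None = None,
    genotypes: GenotypeMatrix | None = None,
    n_pcs: int = 5,
    n_factors: int | None = None,
    categorical: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full preparation pipeline; returns (residual phenotypes, covariates).

    Order: inverse-normal transform -> residualize(known + genotype PCs) ->
    hidden factors on residuals -> residualize(hidden factors).
    """
    samples = list(pdui.columns)
    transformed = pdui.apply(lambda row: inverse_normal_transform(row.to_numpy()), axis=1, result_type="expand")
    transformed.columns = samples

    pieces = []
    if known_covariates is not None and known_covariates.shape[1] > 0:
        pieces.append(encode_covariates(known_covariates.loc[samples], categorical))
    if genotypes is not None and n_pcs > 0:
        pcs = genotype_pcs(genotypes, k=n_pcs)
        pieces.append(pcs.loc[samples])
    known = pd.concat(pieces, axis=1) if pieces else None
    resid = residualize(transformed, known)

    if n_factors is None:
        n_factors = default_n_factors(len(samples))
    n_factors = min(n_factors, len(samples) - 2)
    if n_factors > 0:
        factors = hidden_factors(resid, n_factors)
        resid = residualize(resid, factors)
    else:
        factors = pd.DataFrame(index=samples)
    all_cov = pd.concat([known, factors], axis=1) if known is not None else factors
    logger.info(
        "phenotype pipeline: INT -> residualize(%d known cols) -> %d hidden factors -> residualize",
        0 if known is None else known.shape[1],
        n_factors,
    )
    return resid, all_cov
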