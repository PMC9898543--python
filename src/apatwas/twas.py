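"""APA-TWAS: cis-heritability, PDUI prediction models, summary-stat scan.

Training side (reference panel with genotypes + residualized PDUI):

- ``estimate_cis_h2`` fits the single-component mixed model
  ``y ~ N(0, sg2 * K + se2 * I)`` with ``K = X X' / m`` from standardized
  cis genotypes, profiling the likelihood over ``h2 = sg2/(sg2+se2)`` via a
  spectral decomposition; the test against h2=0 uses the boundary mixture
  ``0.5 chi2_0 + 0.5 chi2_1``.
- ``train_weight_model`` gates on heritability significance, then fits
  BLUP/ridge (penalty set by h2), LASSO, and Elastic Net; the method with
  the best cross-validated R^2 is selected (tie precedence
  BLUP > Elastic Net > LASSO).

Scan side (GWAS summary statistics + an LD reference):

- ``harmonize`` aligns sumstats to model alleles, dropping strand-ambiguous
  variants, indels, and low-MAF variants, and flipping z on allele swaps;
- ``twas_z`` computes ``Z = w'z / sqrt(w' S w)`` with the shrunk LD matrix
  ``S = (1-theta) Sigma + theta I``;
- ``conditional_z`` removes the predicted-phenotype component from each
  SNP's z for regional plots;
- ``weight_permutation_p`` shuffles the weight-to-variant assignment to
  test whether the association is driven by the weights rather than locus
  LD structure.

Weights are always on the standardized-genotype scale, making the Z
statistic invariant to positive rescaling of w.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.linear_model import ElasticNetCV, LassoCV
from sklearn.model_selection import KFold

from .aqtlmap import qvalues
from .simdata import GenotypeMatrix, Variant

logger = logging.getLogger(__name__)

__all__ = [
    "HeritabilityEstimate",
    "WeightModel",
    "estimate_cis_h2",
    "train_weight_model",
    "harmonize",
    "twas_z",
    "twas_scan",
    "conditional_z",
    "weight_permutation_p",
]

AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}
DEFAULT_SHRINKAGE = 0.1
METHOD_PRECEDENCE = ["blup", "enet", "lasso"]  # tie-break order on CV R^2


@dataclass(frozen=True)
class HeritabilityEstimate:
    h2: float
    p_lrt: float
    loglik: float
    loglik_null: float


@dataclass
class WeightModel:
    transcript_id: str
    variants: list[Variant]
    weights: dict[str, np.ndarray]  # method -> standardized-scale weights
    cv_r2: dict[str, float]
    selected: str
    h2: float
    h2_p: float
    n_train: int
    seed: int
    panel_id: str = "panel"

    @property
    def selected_weights(self) -> np.ndarray:
        return self.weights[self.selected]

    @property
    def normalized_accuracy(self) -> float | None:
        """CV R^2 of the selected method divided by cis-h2 (None if h2<=0)."""
        if self.h2 <= 0:
            return None
        return self.cv_r2[self.selected] / self.h2


def _profile_loglik(h2: float, lam: np.ndarray, y2_top: np.ndarray, rss0: float, n: int) -> float:
    """Profile log-likelihood of the variance ratio, spectral form.

    ``lam`` are the nonzero eigenvalues of K with rotated squared phenotype
    ``y2_top``; ``rss0`` is the squared norm in the null space of K (n-m
    dims, eigenvalue 0).
    """
    d = h2 * lam + (1.0 - h2)
    d0 = 1.0 - h2
    n_zero = n - len(lam)
    sigma2 = (np.sum(y2_top / d) + rss0 / d0) / n
    logdet = np.sum(np.log(d)) + n_zero * np.log(d0)
    return -0.5 * (n * np.log(sigma2) + logdet + n * (1.0 + np.log(2.0 * np.pi)))


def estimate_cis_h2(y: np.ndarray, X_std: np.ndarray) -> HeritabilityEstimate:
    """REML-style profile estimate of cis heritability from standardized X.

    The phenotype is centered; the likelihood is profiled over the total
    variance and maximized over h2 on [0, 1-1e-6] by bounded 1-D search.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X_std, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("need a non-empty standardized cis genotype matrix")
    mask = ~np.isnan(y)
    y, X = y[mask], X[mask]
    n, m = X.shape
    if n < 50:
        logger.warning("estimating cis-h2 with only n=%d samples", n)
    y = y - y.mean()
    yty = float(y @ y)
    if yty == 0:
        raise ValueError("phenotype has zero variance")

    # spectral pieces of K = XX'/m without forming the n x n kernel
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    lam = s**2 / m
    keep = lam > lam.max() * 1e-12 if lam.size else np.zeros(0, bool)
    lam = lam[keep]
    yt = U[:, keep].T @ y
    y2_top = yt**2
    rss0 = max(yty - float(y2_top.sum()), 0.0)

    upper = 1.0 - 1e-6
    res = optimize.minimize_scalar(
        lambda h: -_profile_loglik(h, lam, y2_top, rss0, n),
        bounds=(0.0, upper),
        method="bounded",
        options={"xatol": 1e-6},
    )
    h2 = float(res.x)
    ll = -float(res.fun)
    ll0 = _profile_loglik(0.0, lam, y2_top, rss0, n)
    if ll0 > ll:  # boundary optimum
        h2, ll = 0.0, ll0
    lrt = 2.0 * (ll - ll0)
    p = 0.5 * stats.chi2.sf(lrt, 1) if lrt > 0 else 1.0
    return HeritabilityEstimate(h2=h2, p_lrt=float(max(p, np.nextafter(0, 1))), loglik=ll, loglik_null=ll0)


def _blup_weights(X: np.ndarray, y: np.ndarray, h2: float) -> np.ndarray:
    """Ridge/BLUP weights with penalty lambda = m (1 - h2) / h2."""
    n, m = X.shape
    h2 = min(max(h2, 1e-4), 1.0 - 1e-6)
    lam = m * (1.0 - h2) / h2
    A = X.T @ X + lam * np.eye(m)
    return np.linalg.solve(A, X.T @ y)


def train_weight_model(
    y: np.ndarray,
    G_cis: GenotypeMatrix,
    folds: int = 5,
    seed: int = 0,
    h2_gate: float = 0.05,
    bonferroni_n: int | None = None,
    transcript_id: str = "",
    panel_id: str = "panel",
) -> WeightModel | None:
    """Train heritability-gated cis prediction models of residualized PDUI.

    Returns None when the gene is gated out: heritability LRT p at or above
    the gate (``h2_gate``, divided by ``bonferroni_n`` when given), or no
    method achieving positive cross-validated R^2.  Cross-validated R^2 is
    the squared correlation between out-of-fold predictions and phenotype.
    """
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y)
    Xs = G_cis.standardized()[mask]
    y = y[mask]
    n, m = Xs.shape
    if n < folds:
        raise ValueError(f"fewer samples ({n}) than folds ({folds})")
    yc = y - y.mean()

    her = estimate_cis_h2(yc, Xs)
    gate = h2_gate / bonferroni_n if bonferroni_n else h2_gate
    if her.p_lrt >= gate:
        logger.info("%s gated out: h2 p=%.3g >= %.3g", transcript_id, her.p_lrt, gate)
        return None

    rng_alphas = np.logspace(-3, 0.5, 20)

    def fit_all(Xtr, ytr):
        w = {}
        w["blup"] = _blup_weights(Xtr, ytr, her.h2)
        lasso = LassoCV(alphas=rng_alphas, cv=3, max_iter=5000, random_state=seed).fit(Xtr, ytr)
        w["lasso"] = lasso.coef_
        enet = ElasticNetCV(
            alphas=rng_alphas, l1_ratio=0.5, cv=3, max_iter=5000, random_state=seed
        ).fit(Xtr, ytr)
        w["enet"] = enet.coef_
        return w

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = {meth: np.zeros(n) for meth in METHOD_PRECEDENCE}
    for tr, te in kf.split(Xs):
        w_fold = fit_all(Xs[tr], yc[tr] - yc[tr].mean())
        for meth in METHOD_PRECEDENCE:
            oof[meth][te] = Xs[te] @ w_fold[meth]
    cv_r2 = {}
    for meth in METHOD_PRECEDENCE:
        pred = oof[meth]
        if np.std(pred) == 0:
            cv_r2[meth] = 0.0
        else:
            r = np.corrcoef(pred, yc)[0, 1]
            cv_r2[meth] = float(r**2) if r > 0 else 0.0  # anti-predictive is not skill
    best = max(METHOD_PRECEDENCE, key=lambda meth: cv_r2[meth])  # stable on ties
    if cv_r2[best] <= 0:
        logger.info("%s gated out: best CV R^2 %.3g <= 0", transcript_id, cv_r2[best])
        return None

    weights = fit_all(Xs, yc)
    return WeightModel(
        transcript_id=transcript_id,
        variants=list(G_cis.variants),
        weights={meth: np.asarray(w, float) for meth, w in weights.items()},
        cv_r2=cv_r2,
        selected=best,
        h2=her.h2,
        h2_p=her.p_lrt,
        n_train=n,
        seed=seed,
        panel_id=panel_id,
    )


def harmonize(
    sumstats: pd.DataFrame,
    model: WeightModel,
    ld_ref: GenotypeMatrix,
    maf_min: float = 0.01,
    shrinkage: float = DEFAULT_SHRINKAGE,
):
    """Align sumstats and LD reference to the model's variants.

    Drops strand-ambiguous (A/T, C/G) pairs, indels, variants with
    reference-panel MAF <= ``maf_min``, and variants missing from either
    the sumstats or the LD reference.  When sumstats alleles are swapped
    relative to the model, z is negated.  Returns
    ``(w, z, Sigma_shrunk, kept_variant_ids)`` or None (with a logged
    reason) when fewer than one variant survives.
    """
    ss = sumstats.set_index("snp")
    ld_ids = {v.id: i for i, v in enumerate(ld_ref.variants)}
    ld_af = ld_ref.alt_freq()

    w_sel = model.selected_weights
    keep_idx: list[int] = []
    z_out: list[float] = []
    ld_idx: list[int] = []
    counts = {"ambiguous": 0, "indel": 0, "maf": 0, "missing": 0, "allele_mismatch": 0}
    for j, v in enumerate(model.variants):
        if len(v.ref) != 1 or len(v.alt) != 1:
            counts["indel"] += 1
            continue
        if frozenset((v.ref, v.alt)) in AMBIGUOUS:
            counts["ambiguous"] += 1
            continue
        if v.id not in ss.index or v.id not in ld_ids:
            counts["missing"] += 1
            continue
        i_ld = ld_ids[v.id]
        f = ld_af[i_ld]
        if min(f, 1 - f) <= maf_min:
            counts["maf"] += 1
            continue
        row = ss.loc[v.id]
        a1, a2 = str(row["a1"]), str(row["a2"])
        if len(a1) != 1 or len(a2) != 1:
            counts["indel"] += 1
            continue
        if (a1, a2) == (v.alt, v.ref):
            z_out.append(float(row["z"]))
        elif (a1, a2) == (v.ref, v.alt):
            z_out.append(-float(row["z"]))
        else:
            counts["allele_mismatch"] += 1
            continue
        keep_idx.append(j)
        ld_idx.append(i_ld)
    if len(keep_idx) < 1:
        logger.info("%s: no variant survives harmonization (%s)", model.transcript_id, counts)
        return None
    logger.info(
        "%s: %d/%d variants after harmonization (dropped %s)",
        model.transcript_id, len(keep_idx), len(model.variants), counts,
    )
    w = w_sel[keep_idx]
    z = np.array(z_out)
    sigma = ld_ref.subset(np.array(ld_idx)).ld_matrix()
    q = len(keep_idx)
    sigma = (1.0 - shrinkage) * sigma + shrinkage * np.eye(q)
    kept_ids = [model.variants[j].id for j in keep_idx]
    return w, z, sigma, kept_ids


def twas_z(w: np.ndarray, z: np.ndarray, sigma: np.ndarray, tol: float = 1e-8):
    """Summary-statistic association: Z = w'z / sqrt(w' Sigma w).

    Returns ``(Z, p)``; raises when the denominator is below tolerance
    (association non-computable).
    """
    w = np.asarray(w, float)
    z = np.asarray(z, float)
    denom2 = float(w @ sigma @ w)
    if denom2 <= tol:
        raise ValueError(f"w' Sigma w = {denom2:.3g} below tolerance {tol}")
    Z = float(w @ z) / np.sqrt(denom2)
    p = 2.0 * stats.norm.sf(abs(Z))
    return Z, float(max(p, np.nextafter(0, 1)))


def twas_scan(
    models: list[WeightModel],
    sumstats: pd.DataFrame,
    ld_ref: GenotypeMatrix,
    maf_min: float = 0.01,
    shrinkage: float = DEFAULT_SHRINKAGE,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Scan all models against one GWAS; FDR across the scan.

    Rows for skipped models carry a reason code and NaN statistics; q-values
    are computed over the computable rows (BH default, Storey by flag).
    Output order follows sorted transcript ids, so the scan is invariant to
    the input ordering of models.
    """
    rows = []
    for model in sorted(models, key=lambda m: m.transcript_id):
        triple = harmonize(sumstats, model, ld_ref, maf_min=maf_min, shrinkage=shrinkage)
        if triple is None:
            rows.append(
                {"transcript_id": model.transcript_id, "z_twas": np.nan, "p": np.nan,
                 "n_snps": 0, "reason": "no_variants_after_harmonization"}
            )
            continue
        w, z, sigma, kept = triple
        try:
            Z, p = twas_z(w, z, sigma)
        except ValueError:
            rows.append(
                {"transcript_id": model.transcript_id, "z_twas": np.nan, "p": np.nan,
                 "n_snps": len(kept), "reason": "degenerate_denominator"}
            )
            continue
        rows.append(
            {"transcript_id": model.transcript_id, "z_twas": Z, "p": p,
             "n_snps": len(kept), "reason": ""}
        )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = qvalues(out.loc[ok, "p"].to_numpy(), method=fdr_method)
    return out


def conditional_z(
    z: np.ndarray, w: np.ndarray, sigma: np.ndarray, z_twas: float, eps: float = 1e-6
) -> np.ndarray:
    """Per-SNP GWAS z after removing the predicted-phenotype component.

    With ``c = Sigma w / sqrt(w' Sigma w)`` (the correlation of each SNP's
    statistic with the TWAS statistic), the conditioned score is
    ``(z_j - c_j Z) / sqrt(max(1 - c_j^2, eps))``.
    """
    w = np.asarray(w, float)
    z = np.asarray(z, float)
    denom = np.sqrt(float(w @ sigma @ w))
    c = (sigma @ w) / denom
    return (z - c * z_twas) / np.sqrt(np.maximum(1.0 - c**2, eps))


def weight_permutation_p(
    w: np.ndarray,
    z: np.ndarray,
    sigma: np.ndarray,
    n_perm: int = 100_000,
    seed: int = 0,
) -> float:
    """Empirical p from shuffling the weight-to-variant assignment.

    Recomputes |Z| for each permutation of w over the variants;
    ``p = (1 + #{|Z_perm| >= |Z_obs|}) / (n_perm + 1)``.  With all weights
    equal every permutation reproduces Z, so p = 1 (flagged in the log).
    """
    w = np.asarray(w, float)
    z = np.asarray(z, float)
    q = len(w)
    if q < 2:
        raise ValueError("need >= 2 variants to permute weights")
    if np.all(w == w[0]):
        logger.warning("all weights equal: permutation p is 1 by construction")
    z_obs = abs(twas_z(w, z, sigma)[0])
    rng = np.random.default_rng(seed)
    count = 0
    chunk = 2000
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        W = np.empty((k, q))
        for i in range(k):
            W[i] = w[rng.permutation(q)]
        num = W @ z
        den = np.sqrt(np.einsum("pi,ij,pj->p", W, sigma, W))
        count += int((np.abs(num / den) >= z_obs - 1e-12).sum())
        done += k
    return (1.0 + count) / (n_perm + 1.0)
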