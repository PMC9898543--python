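"""cis-3'aQTL mapping: per-SNP regression, permutations, FDR, diagnostics.

For each gene, every variant within 1 Mbp of its 3'UTR is tested by simple
linear regression of the residualized phenotype on alt-allele dosage
(covariates were removed upstream, so permutations can shuffle the
phenotype directly).  The gene-level statistic is the minimum nominal p
across cis variants; its null distribution comes from 1000 phenotype
permutations and the empirical p uses the plus-one rule, so it can never be
0 and never exceeds 1.  Gene-level p-values are converted to q-values
(Storey with pi0 at lambda=0.5, or Benjamini-Hochberg).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .apaquant import UtrRegion
from .simdata import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AqtlRecord",
    "GeneAqtlSummary",
    "cis_pairs",
    "marginal_assoc",
    "gene_empirical_p",
    "qvalues",
    "annotate_qq",
    "enrichment_or",
    "map_aqtl",
]

DEFAULT_WINDOW = 1_000_000
DEFAULT_N_PERM = 1000


@dataclass(frozen=True)
class AqtlRecord:
    gene_id: str
    variant_id: str
    beta: float
    se: float
    t: float
    p_nominal: float
    n: int


@dataclass(frozen=True)
class GeneAqtlSummary:
    gene_id: str
    lead_variant: str
    min_p_nominal: float
    empirical_p: float
    q_value: float | None = None


def cis_pairs(
    regions: list[UtrRegion], G: GenotypeMatrix, window: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """All (transcript, variant) pairs with the variant inside the cis window.

    A variant is cis iff its (1-based) position lies within
    ``[utr_start - window, utr_end + window]`` (closed) on the same
    chromosome, with the UTR interval in 0-based half-open coordinates.
    """
    pos = G.positions
    chroms = G.chroms
    rows = []
    for region in regions:
        lo = region.start - window  # utr_start 0-based; pos is 1-based so >= lo+1... see note
        hi = region.end + window
        # convert: genomic base at 0-based coordinate c has 1-based position c+1;
        # closed window in 1-based positions is [start - window + 1, end + window]
        mask = (chroms == region.chrom) & (pos >= lo + 1) & (pos <= hi)
        for j in np.flatnonzero(mask):
            rows.append((region.gene_id, region.transcript_id, int(j), G.variants[j].id))
    return pd.DataFrame(rows, columns=["gene_id", "transcript_id", "variant_idx", "variant_id"])


def marginal_assoc(y: np.ndarray, g: np.ndarray, gene_id: str = "", variant_id: str = "") -> AqtlRecord | None:
    """Simple linear regression of phenotype on dosage with t-test p.

    Missing (y, g) pairs are dropped listwise.  Returns None (logged) for a
    monomorphic dosage after missingness.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    mask = ~(np.isnan(y) | np.isnan(g))
    y, g = y[mask], g[mask]
    n = len(y)
    if n < 3 or np.all(g == g[0]):
        logger.info("skipping %s/%s: monomorphic or too few observations", gene_id, variant_id)
        return None
    gc = g - g.mean()
    yc = y - y.mean()
    sxx = gc @ gc
    beta = (gc @ yc) / sxx
    resid = yc - beta * gc
    df = n - 2
    sigma2 = (resid @ resid) / df
    se = np.sqrt(sigma2 / sxx)
    if se == 0:
        t = np.inf if beta != 0 else 0.0
        p = 0.0 if beta != 0 else 1.0
    else:
        t = beta / se
        p = 2.0 * stats.t.sf(abs(t), df)
    return AqtlRecord(gene_id=gene_id, variant_id=variant_id, beta=float(beta), se=float(se), t=float(t), p_nominal=float(max(p, np.nextafter(0, 1))), n=n)


def _min_p_from_r2(r2_max: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p of the strongest correlation, via the t transform."""
    r2_max = np.clip(r2_max, 0.0, 1.0 - 1e-15)
    t = np.sqrt(df * r2_max / (1.0 - r2_max))
    return 2.0 * stats.t.sf(t, df)


def gene_empirical_p(
    y: np.ndarray,
    X: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    variant_ids: list[str] | None = None,
    gene_id: str = "",
) -> GeneAqtlSummary:
    """Gene-level permutation empirical p for the best cis association.

    Observed statistic: minimum nominal p across cis variants.  Permutations
    shuffle the residualized phenotype; empirical
    ``p = (1 + #{perm min-p <= observed}) / (n_perm + 1)``.  Since the
    nominal p is a monotone function of squared correlation at fixed n, the
    comparison is done on max r^2 (complete-data fast path).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    mask = ~np.isnan(y)
    if np.isnan(X).any():
        col_mu = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X = X.copy()
        X[idx] = col_mu[idx[1]]
    y, X = y[mask], X[mask]
    n = len(y)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError(f"{gene_id}: no testable cis variant")
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    ys = (y - y.mean()) / y.std()
    df = n - 2

    r_obs = ys @ Xs / n
    r2_obs = r_obs**2
    j_best = int(np.argmax(r2_obs))
    obs_min_p = float(_min_p_from_r2(np.array([r2_obs[j_best]]), df)[0])

    rng = np.random.default_rng(seed)
    count = 0
    chunk = 200
    for lo in range(0, n_perm, chunk):
        k = min(chunk, n_perm - lo)
        P = np.empty((k, n))
        for i in range(k):
            P[i] = ys[rng.permutation(n)]
        R = (P @ Xs) / n
        perm_max_r2 = (R**2).max(axis=1)
        count += int((perm_max_r2 >= r2_obs[j_best]).sum())
    emp = (1.0 + count) / (n_perm + 1.0)

    kept_ids = (
        [vid for vid, k in zip(variant_ids, keep) if k]
        if variant_ids is not None
        else [f"v{j}" for j in np.flatnonzero(keep)]
    )
    return GeneAqtlSummary(
        gene_id=gene_id,
        lead_variant=kept_ids[j_best],
        min_p_nominal=obs_min_p,
        empirical_p=float(emp),
    )


def qvalues(p: np.ndarray, method: str = "storey", lambda_: float = 0.5) -> np.ndarray:
    """q-values: Storey (pi0 estimated at a single lambda) or BH.

    Storey: ``pi0 = min(1, #{p > lambda} / ((1 - lambda) m))``; q is pi0
    times the BH step-up value, so Storey with pi0 forced to 1 is exactly BH.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    bh = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return bh
    if method != "storey":
        raise ValueError(f"unknown method {method!r}")
    m = p.size
    pi0 = min(1.0, (p > lambda_).sum() / ((1.0 - lambda_) * m)) if m else 1.0
    if pi0 == 0:
        pi0 = 1.0 / m
    return np.minimum(pi0 * bh, 1.0)


def annotate_qq(
    gwas_p: pd.Series,
    annotation_sets: dict[str, set],
    qtl_p_threshold: float = 1e-5,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """QQ-plot tables of GWAS p-values stratified by annotation membership.

    ``gwas_p`` is indexed by SNP id.  For each named SNP set, returns sorted
    observed -log10 p with uniform expected quantiles, plus the genomic
    inflation factor ``lambda = median(chi2) / 0.4549`` of the subset.  The
    ``qtl_p_threshold`` documents the cutoff used to build the sets and is
    recorded in the output.
    """
    tables = []
    lambdas = {}
    for name, snps in annotation_sets.items():
        sub = gwas_p.loc[gwas_p.index.intersection(list(snps))]
        if sub.empty:
            logger.warning("annotation %s has empty intersection with GWAS SNPs", name)
            lambdas[name] = np.nan
            continue
        obs = np.sort(sub.to_numpy())
        k = len(obs)
        expected = (np.arange(1, k + 1) - 0.5) / k
        chi2 = stats.chi2.isf(obs, 1)
        lambdas[name] = float(np.median(chi2) / 0.4549)
        tables.append(
            pd.DataFrame(
                {
                    "set": name,
                    "expected_neglog10p": -np.log10(expected),
                    "observed_neglog10p": -np.log10(obs),
                    "qtl_p_threshold": qtl_p_threshold,
                }
            )
        )
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=["set", "expected_neglog10p", "observed_neglog10p", "qtl_p_threshold"]
    )
    return table, lambdas


def _ld_prune(G: GenotypeMatrix, snp_ids: list[str], r2_max: float) -> list[str]:
    """Greedy LD pruning by position order."""
    idx = [i for i, v in enumerate(G.variants) if v.id in set(snp_ids)]
    X = G.standardized()[:, idx]
    n = X.shape[0]
    kept: list[int] = []
    for j in range(X.shape[1]):
        ok = True
        for k in kept:
            r = (X[:, j] @ X[:, k]) / n
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return [G.variants[idx[j]].id for j in kept]


def enrichment_or(
    significant: set,
    annotation: set,
    background: set,
    mafs: dict | None = None,
    maf_bins: int = 5,
    ld_genotypes: GenotypeMatrix | None = None,
    ld_prune_r2: float = 0.8,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Enrichment odds ratio of an annotation among GWAS-significant SNPs.

    A simplified alternative to full LD/distance-matched enrichment: the
    background is optionally LD-pruned (greedy, r^2 cutoff) and stratified
    into MAF bins; the 2x2 odds ratio (Haldane-Anscombe 0.5 correction on
    zero cells) is computed per bin and combined by total counts, with a
    percentile bootstrap CI over background SNPs.  Output metadata marks the
    method as "simplified".
    """
    if not (significant <= background and annotation <= background):
        raise ValueError("background must contain both the significant and annotation sets")
    snps = sorted(background)
    if ld_genotypes is not None:
        snps = _ld_prune(ld_genotypes, snps, ld_prune_r2)
    snps = np.array(snps)
    sig = np.array([s in significant for s in snps])
    ann = np.array([s in annotation for s in snps])

    if mafs is not None:
        maf = np.array([mafs[s] for s in snps])
        edges = np.quantile(maf, np.linspace(0, 1, maf_bins + 1))
        bins = np.clip(np.searchsorted(edges, maf, side="right") - 1, 0, maf_bins - 1)
    else:
        bins = np.zeros(len(snps), dtype=int)

    def table_or(sig_v, ann_v, bins_v):
        a = b = c = d = 0.0
        for bin_id in np.unique(bins_v):
            m = bins_v == bin_id
            if m.sum() == 0:
                continue
            a += np.sum(sig_v[m] & ann_v[m])
            b += np.sum(sig_v[m] & ~ann_v[m])
            c += np.sum(~sig_v[m] & ann_v[m])
            d += np.sum(~sig_v[m] & ~ann_v[m])
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c)

    or_hat = table_or(sig, ann, bins)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    m = len(snps)
    for i in range(n_boot):
        idx = rng.integers(0, m, size=m)
        boots[i] = table_or(sig[idx], ann[idx], bins[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "odds_ratio": float(or_hat),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_background": int(m),
        "method": "simplified (MAF-bin matching + LD pruning; no distance matching)",
    }


def map_aqtl(
    phenotypes: pd.DataFrame,
    G: GenotypeMatrix,
    regions: list[UtrRegion],
    window: int = DEFAULT_WINDOW,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    fdr_method: str = "storey",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full cis scan: per-pair nominal stats + per-gene empirical p and q.

    ``phenotypes`` is (gene_id, transcript_id)- or transcript-indexed rows x
    sample columns, already residualized; samples must match ``G``.
    Per-gene permutation seeds derive deterministically from ``seed``.
    """
    pairs = cis_pairs(regions, G, window=window)
    sample_order = [G.sample_ids.index(s) for s in phenotypes.columns]
    dosages = G.dosages[sample_order]

    pair_rows = []
    gene_rows = []
    tindex = (
        phenotypes.index.get_level_values("transcript_id")
        if isinstance(phenotypes.index, pd.MultiIndex)
        else phenotypes.index
    )
    for ti, (transcript_id, sub) in enumerate(pairs.groupby("transcript_id", sort=True)):
        where = np.flatnonzero(tindex == transcript_id)
        if where.size == 0:
            continue
        y = phenotypes.iloc[where[0]].to_numpy(dtype=float)
        vidx = sub["variant_idx"].to_numpy()
        for j, vid in zip(vidx, sub["variant_id"]):
            rec = marginal_assoc(y, dosages[:, j], gene_id=transcript_id, variant_id=vid)
            if rec is not None:
                pair_rows.append(rec)
        summary = gene_empirical_p(
            y,
            dosages[:, vidx],
            n_perm=n_perm,
            seed=(seed + 1009 * ti) % (2**31),
            variant_ids=list(sub["variant_id"]),
            gene_id=transcript_id,
        )
        gene_rows.append(summary)

    pair_df = pd.DataFrame([r.__dict__ for r in pair_rows])
    gene_df = pd.DataFrame([r.__dict__ for r in gene_rows]).drop(columns=["q_value"], errors="ignore")
    if not gene_df.empty:
        gene_df["q_value"] = qvalues(gene_df["empirical_p"].to_numpy(), method=fdr_method)
    return pair_df, gene_df
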