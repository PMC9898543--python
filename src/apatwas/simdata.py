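"""Synthetic data with the statistical structure the pipeline assumes.

Every downstream stage (PDUI quantification, cis-aQTL mapping, TWAS,
colocalization) is testable against ground truth produced here, without any
controlled-access cohort.  All generators are seed-deterministic.

The genotype model is haplotype-based with first-order Markov local LD:
each haplotype walks along the chromosome carrying a latent uniform that is
copied from the previous site with probability ``ld_rho`` and redrawn
otherwise; thresholding the uniform at the site's allele frequency yields
the allele.  With equal frequencies at adjacent sites the haplotype allele
correlation equals ``ld_rho`` exactly; with unequal frequencies it is the
comonotone (maximal) correlation scaled by ``ld_rho``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Variant",
    "GenotypeMatrix",
    "SimTruth",
    "sim_genotypes",
    "sim_pdui",
    "sim_coverage",
    "sim_gwas",
]

# non-ambiguous ref/alt pairs: strand flips cannot be mistaken for allele swaps
_SAFE_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
_AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based
    id: str
    ref: str
    alt: str
    maf: float  # generating minor-allele frequency


@dataclass
class GenotypeMatrix:
    """Individuals x variants alt-allele dosages in {0,1,2}; NaN = missing."""

    dosages: np.ndarray
    variants: list[Variant]
    sample_ids: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be in {0,1,2} or NaN")
        pos_by_chrom: dict[str, int] = {}
        for v in self.variants:
            prev = pos_by_chrom.get(v.chrom)
            if prev is not None and v.pos <= prev:
                raise ValueError(f"positions not strictly increasing on {v.chrom}")
            pos_by_chrom[v.chrom] = v.pos

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants])

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def alt_freq(self) -> np.ndarray:
        """Empirical alt-allele frequency per variant (ignoring missing)."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def standardized(self) -> np.ndarray:
        """Mean-imputed dosages, centered and scaled to unit variance.

        Monomorphic-in-sample columns get all-zero scores.
        """
        X = self.dosages.copy()
        mu = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = mu[idx[1]]
        X -= mu
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        return X / sd

    def ld_matrix(self) -> np.ndarray:
        """Pearson correlation of dosages (mean-imputed)."""
        X = self.standardized()
        return (X.T @ X) / X.shape[0]

    def subset(self, variant_idx: np.ndarray) -> "GenotypeMatrix":
        variant_idx = np.asarray(variant_idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, variant_idx],
            variants=[self.variants[i] for i in variant_idx],
            sample_ids=list(self.sample_ids),
            seed=self.seed,
        )


@dataclass
class SimTruth:
    """Ground truth for one simulated gene panel.

    Per-gene arrays are aligned with the gene order of :func:`sim_pdui`.
    """

    causal_idx: list[np.ndarray]  # variant indices into the genotype matrix
    beta: list[np.ndarray]  # PDUI units per alt allele
    baseline: np.ndarray  # baseline PDUI per gene, in [0,1]
    breakpoint: np.ndarray  # proximal poly(A) site, nt from UTR 5' end
    utr_length: np.ndarray
    noise_sd: np.ndarray
    alpha: float = 0.0  # trait SD per PDUI SD, for the mediated GWAS mode
    seed: int = 0

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.breakpoint = np.asarray(self.breakpoint, dtype=int)
        self.utr_length = np.asarray(self.utr_length, dtype=int)
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        if np.any((self.baseline < 0) | (self.baseline > 1)):
            raise ValueError("baseline PDUI must lie in [0,1]")
        if np.any((self.breakpoint <= 0) | (self.breakpoint >= self.utr_length)):
            raise ValueError("breakpoint must lie strictly inside the UTR")
        if np.any(self.noise_sd < 0):
            raise ValueError("noise SD must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.causal_idx)


def _haplotypes(
    rng: np.random.Generator, n_hap: int, freqs: np.ndarray, ld_rho: float
) -> np.ndarray:
    m = len(freqs)
    u = np.empty((n_hap, m))
    u[:, 0] = rng.random(n_hap)
    for j in range(1, m):
        fresh = rng.random(n_hap)
        copy = rng.random(n_hap) < ld_rho
        u[:, j] = np.where(copy, u[:, j - 1], fresh)
    return (u < freqs[None, :]).astype(np.int8)


def sim_genotypes(
    n_individuals: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.0,
    seed: int = 0,
    chrom: str = "1",
    start_pos: int = 10_000,
    spacing: int = 2_000,
    ambiguous_fraction: float = 0.0,
) -> GenotypeMatrix:
    """Simulate diploid genotypes with tunable local LD.

    Parameters
    ----------
    maf_range
        Closed interval for the per-variant minor-allele frequency, drawn
        uniformly; must satisfy ``0 < low <= high < 0.5``.
    ld_rho
        First-order Markov copying probability between adjacent sites on a
        haplotype, in ``[0, 1)``.
    ambiguous_fraction
        Fraction of variants assigned strand-ambiguous (A/T or C/G) allele
        pairs, for harmonization-filter tests.
    """
    low, high = maf_range
    if not (0 < low <= high <= 0.5):
        raise ValueError(f"require 0 < maf_low <= maf_high <= 0.5, got {maf_range}")
    if not (0 <= ld_rho < 1):
        raise ValueError(f"require 0 <= ld_rho < 1, got {ld_rho}")
    if n_individuals < 1 or n_variants < 1:
        raise ValueError("n_individuals and n_variants must be positive")

    rng = np.random.default_rng(seed)
    mafs = rng.uniform(low, high, size=n_variants)
    hap = _haplotypes(rng, 2 * n_individuals, mafs, ld_rho)
    dos = (hap[0::2] + hap[1::2]).astype(float)

    # guarantee polymorphism in-sample: flip one haplotype at monomorphic sites
    for j in np.flatnonzero((dos.sum(axis=0) == 0) | (dos.sum(axis=0) == 2 * n_individuals)):
        i = rng.integers(n_individuals)
        dos[i, j] = 1.0 if dos[i, j] != 1.0 else 2.0 if dos[i, j] == 0.0 else 0.0

    n_amb = int(round(ambiguous_fraction * n_variants))
    amb_sites = set(rng.choice(n_variants, size=n_amb, replace=False)) if n_amb else set()
    variants = []
    for j in range(n_variants):
        pairs = _AMBIGUOUS_PAIRS if j in amb_sites else _SAFE_PAIRS
        ref, alt = pairs[rng.integers(len(pairs))]
        variants.append(
            Variant(
                chrom=chrom,
                pos=start_pos + j * spacing,
                id=f"rs{chrom}_{j}",
                ref=ref,
                alt=alt,
                maf=float(mafs[j]),
            )
        )
    sample_ids = [f"IND{i:05d}" for i in range(n_individuals)]
    return GenotypeMatrix(dosages=dos, variants=variants, sample_ids=sample_ids, seed=seed)


def sim_pdui(
    G: GenotypeMatrix,
    truth: SimTruth,
    covariate_effects: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Simulate genes x samples PDUI values.

    Model per gene g and sample i::

        y_gi = baseline_g + sum_k beta_gk * (dosage_ik - 2 f_k) + c_i + eps,
        eps ~ N(0, noise_sd_g^2),   y clipped to [0, 1] after noise.

    Dosages are centered at their expectation so the marginal mean stays at
    the baseline; the regression slope on raw dosage is still ``beta``.
    """
    rng = np.random.default_rng(seed)
    n = G.n_samples
    out = np.empty((truth.n_genes, n))
    cov = np.zeros(n) if covariate_effects is None else np.asarray(covariate_effects, float)
    freqs = G.alt_freq()
    for g in range(truth.n_genes):
        idx = np.asarray(truth.causal_idx[g], dtype=int)
        beta = np.asarray(truth.beta[g], dtype=float)
        if idx.size and (idx.min() < 0 or idx.max() >= G.n_variants):
            raise ValueError(f"gene {g}: causal index out of range")
        genetic = np.zeros(n)
        if idx.size:
            centered = G.dosages[:, idx] - 2.0 * freqs[idx]
            genetic = centered @ beta
        y = truth.baseline[g] + genetic + cov
        if truth.noise_sd[g] > 0:
            y = y + rng.normal(0.0, truth.noise_sd[g], size=n)
        out[g] = np.clip(y, 0.0, 1.0)
    return out


def sim_coverage(
    pdui_value: float,
    utr_length: int,
    breakpoint: int,
    mean_depth: float,
    dispersion: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Two-segment per-base coverage over one 3'UTR, 5'->3' oriented.

    Expected depth is ``mean_depth`` on ``[0, breakpoint)`` (both isoforms)
    and ``mean_depth * pdui_value`` on ``[breakpoint, utr_length)`` (distal
    isoform only).  Counts are negative binomial with
    ``Var = mu + dispersion * mu^2``; ``dispersion=0`` returns the exact
    expectation (deterministic, not Poisson) for noiseless fixtures.
    """
    if not (0 < breakpoint < utr_length):
        raise ValueError(f"breakpoint {breakpoint} outside UTR of length {utr_length}")
    if not (0.0 <= pdui_value <= 1.0):
        raise ValueError(f"pdui_value must be in [0,1], got {pdui_value}")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")

    mu = np.full(utr_length, float(mean_depth))
    mu[breakpoint:] = mean_depth * pdui_value
    if dispersion == 0.0:
        return mu
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.zeros(utr_length)
    pos = mu > 0
    r = 1.0 / dispersion
    p = r / (r + mu[pos])
    out[pos] = rng.negative_binomial(r, p).astype(float)
    return out


def sim_gwas(
    ld,
    gamma: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    alpha: float | None = None,
    n_gwas: int = 10_000,
    seed: int = 0,
    variants: list[Variant] | None = None,
    jitter: float = 1e-8,
):
    """Simulate GWAS summary-statistic z-scores for one locus.

    Under the standard summary-statistic model the marginal z-vector is
    ``z ~ MVN(sqrt(n) * Sigma @ gamma, Sigma)`` where ``gamma`` holds joint
    per-SNP effects on the standardized scale.  In the *mediated* mode the
    trait acts on SNPs only through the molecular phenotype:
    ``gamma = alpha * w`` with ``w`` the standardized-genotype PDUI weights,
    making the end-to-end positive control internally consistent with the
    TWAS estimand.

    Parameters
    ----------
    ld
        Either a :class:`GenotypeMatrix` (LD computed from dosages, alleles
        copied into the output) or an LD correlation matrix.
    gamma, (weights, alpha)
        Exactly one of direct SNP effects or the mediated pair.

    Returns
    -------
    pandas.DataFrame
        Columns ``snp, a1, a2, z, n`` (a1 = effect/alt allele).
    """
    import pandas as pd

    if n_gwas <= 0:
        raise ValueError("n_gwas must be positive")
    if isinstance(ld, GenotypeMatrix):
        sigma = ld.ld_matrix()
        variants = ld.variants
    else:
        sigma = np.asarray(ld, dtype=float)
    q = sigma.shape[0]
    if gamma is None:
        if weights is not None and alpha is not None:
            gamma = float(alpha) * np.asarray(weights, dtype=float)
        else:
            gamma = np.zeros(q)
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape != (q,):
        raise ValueError(f"effect vector of length {gamma.shape} does not conform to LD {q}")

    mean = np.sqrt(n_gwas) * sigma @ gamma
    rng = np.random.default_rng(seed)
    try:
        L = np.linalg.cholesky(sigma + jitter * np.eye(q))
    except np.linalg.LinAlgError:
        # shrink toward identity until PSD
        L = None
        for theta in (0.01, 0.05, 0.1, 0.5):
            try:
                L = np.linalg.cholesky((1 - theta) * sigma + theta * np.eye(q))
                break
            except np.linalg.LinAlgError:
                continue
        if L is None:
            raise np.linalg.LinAlgError("LD matrix not positive semidefinite after shrinkage")
    z = mean + L @ rng.standard_normal(q)

    if variants is not None:
        snp = [v.id for v in variants]
        a1 = [v.alt for v in variants]
        a2 = [v.ref for v in variants]
    else:
        snp = [f"snp{j}" for j in range(q)]
        a1 = ["G"] * q
        a2 = ["A"] * q
    return pd.DataFrame({"snp": snp, "a1": a1, "a2": a2, "z": z, "n": int(n_gwas)})


# ------------------------------------------------------------ study builder

def concat_genotypes(parts: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Column-concatenate genotype matrices over the same samples."""
    if not parts:
        raise ValueError("nothing to concatenate")
    sample_ids = parts[0].sample_ids
    for p in parts[1:]:
        if p.sample_ids != sample_ids:
            raise ValueError("sample ids differ between genotype blocks")
    return GenotypeMatrix(
        dosages=np.hstack([p.dosages for p in parts]),
        variants=[v for p in parts for v in p.variants],
        sample_ids=list(sample_ids),
        seed=parts[0].seed,
    )


class StudyData:
    """A coherent simulated study: genotypes, truth, PDUI, coverage, GWAS.

    Attributes
    ----------
    G : GenotypeMatrix
        Reference-panel genotypes, one LD block per gene (one chromosome
        per gene).
    gene_blocks : list of ndarray
        Per-gene variant indices into ``G``.
    regions : list of UtrRegion
        One single-exon 3'UTR per gene.
    truth : SimTruth
    pdui : ndarray, genes x samples
    profiles : dict transcript_id -> list of CoverageProfile (optional)
    sumstats : pandas.DataFrame (optional)
        GWAS z-scores over all variants; null genes carry no signal, the
        causal gene's signal is mediated through its PDUI weights.
    """

    def __init__(self, G, gene_blocks, regions, truth, pdui, profiles, sumstats):
        self.G = G
        self.gene_blocks = gene_blocks
        self.regions = regions
        self.truth = truth
        self.pdui = pdui
        self.profiles = profiles
        self.sumstats = sumstats


def simulate_study(
    n_genes: int = 10,
    n_samples: int = 100,
    m_per_gene: int = 20,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.6,
    h2: float = 0.3,
    noise_sd: float = 0.08,
    baseline_range: tuple[float, float] = (0.35, 0.75),
    utr_length: int = 400,
    depth: float = 50.0,
    dispersion: float = 0.05,
    causal_gene: int | None = None,
    alpha: float = 0.0,
    n_gwas: int = 50_000,
    make_coverage: bool = False,
    make_sumstats: bool = False,
    seed: int = 0,
) -> StudyData:
    """Simulate a full reference panel plus (optionally) coverage and GWAS.

    Each gene gets its own chromosome with ``m_per_gene`` cis variants and
    one causal variant (the middle one) whose effect size is set so the
    causal SNP explains ``h2`` of the PDUI variance.  If ``make_sumstats``,
    GWAS z-scores are drawn for every variant: zero effects everywhere
    except the ``causal_gene`` locus, where the per-SNP effects are
    ``alpha`` times the standardized PDUI weights (trait acts through PDUI).
    """
    rng = np.random.default_rng(seed)
    from .apaquant import CoverageProfile, UtrRegion

    blocks = []
    regions = []
    offset = 0
    gene_blocks = []
    for g in range(n_genes):
        Gg = sim_genotypes(
            n_samples, m_per_gene, maf_range=maf_range, ld_rho=ld_rho,
            seed=int(rng.integers(2**31)), chrom=str(g + 1),
            start_pos=400_000, spacing=2_000,
        )
        blocks.append(Gg)
        gene_blocks.append(np.arange(offset, offset + m_per_gene))
        offset += m_per_gene
        regions.append(
            UtrRegion(chrom=str(g + 1), start=500_000, end=500_000 + utr_length,
                      strand="+", gene_id=f"GENE{g}", transcript_id=f"TX{g}")
        )
    G = concat_genotypes(blocks)
    freqs = G.alt_freq()

    causal_idx = []
    beta = []
    for g in range(n_genes):
        j = int(gene_blocks[g][m_per_gene // 2])
        f = freqs[j]
        b = 0.0
        if h2 > 0:
            b = np.sqrt(h2 / (1.0 - h2)) * noise_sd / np.sqrt(2.0 * f * (1.0 - f))
        causal_idx.append(np.array([j]))
        beta.append(np.array([b]))
    truth = SimTruth(
        causal_idx=causal_idx,
        beta=beta,
        baseline=rng.uniform(*baseline_range, size=n_genes),
        breakpoint=np.full(n_genes, utr_length // 2),
        utr_length=np.full(n_genes, utr_length),
        noise_sd=np.full(n_genes, noise_sd),
        alpha=alpha,
        seed=seed,
    )
    pdui = sim_pdui(G, truth, seed=int(rng.integers(2**31)))

    profiles = {}
    if make_coverage:
        cov_rng = np.random.default_rng(int(rng.integers(2**31)))
        for g, region in enumerate(regions):
            profs = []
            for i, sid in enumerate(G.sample_ids):
                vals = sim_coverage(
                    float(pdui[g, i]), utr_length, int(truth.breakpoint[g]),
                    depth, dispersion, seed=cov_rng,
                )
                profs.append(CoverageProfile(sample_id=sid, values=vals))
            profiles[region.transcript_id] = profs

    sumstats = None
    if make_sumstats:
        sd_y = noise_sd / np.sqrt(1.0 - h2) if h2 < 1 else noise_sd
        frames = []
        for g in range(n_genes):
            block = blocks[g]
            gamma = np.zeros(m_per_gene)
            if causal_gene is not None and g == causal_gene and alpha != 0.0:
                local = m_per_gene // 2
                j = int(gene_blocks[g][local])
                u = truth.beta[g][0] * np.sqrt(2.0 * freqs[j] * (1.0 - freqs[j])) / sd_y
                w = np.zeros(m_per_gene)
                w[local] = u
                gamma = alpha * w
            frames.append(
                sim_gwas(block, gamma=gamma, n_gwas=n_gwas, seed=int(rng.integers(2**31)))
            )
        import pandas as pd

        sumstats = pd.concat(frames, ignore_index=True)

    return StudyData(G, gene_blocks, regions, truth, pdui, profiles, sumstats)
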