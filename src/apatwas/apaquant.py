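"""PDUI quantification from per-base coverage (two-segment breakpoint model).

Each gene's 3'UTR carries a proximal and a distal poly(A) site.  Reads from
both isoforms cover the region upstream of the proximal site; only the
long-isoform reads cover the downstream segment.  A single proximal
breakpoint P is therefore fitted *jointly* across all samples, and each
sample's distal usage index is the ratio of its downstream to upstream mean
depth:

    PDUI = clip(mu_dist / mu_prox, 0, 1)

The joint objective is the profile log-likelihood of two normals with free
mean and variance per segment per sample, summed over samples:

    sum_s [ -(n1/2) ln(RSS1_s/n1) - (n2/2) ln(RSS2_s/n2) ]

maximized over candidate P on a grid; ties break to the smallest P.  A pure
least-squares objective is available as a config alternative.

Coordinates: BED/bedGraph inputs are 0-based half-open; coverage profiles
are always transcript-oriented (position 0 = 5' end of the 3'UTR, i.e. the
highest genomic coordinate for minus-strand genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "UtrRegion",
    "CoverageProfile",
    "BreakpointFit",
    "PduiMatrix",
    "extract_utr_regions",
    "load_coverage",
    "fit_two_segment",
    "pdui_matrix",
]

DEFAULT_MIN_SEG = 100
DEFAULT_STEP = 1
DEFAULT_MIN_MEAN_COV = 20.0
DEFAULT_MIN_SAMPLE_FRACTION = 0.5


@dataclass(frozen=True)
class UtrRegion:
    """One 3'UTR: 0-based half-open genomic interval plus identity."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.transcript_id}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageProfile:
    """Per-base depth over one 3'UTR for one sample, 5'->3' oriented."""

    sample_id: str
    values: np.ndarray
    total_depth_factor: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be a 1-D array")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")


@dataclass
class BreakpointFit:
    """Jointly fitted breakpoint and per-sample segment summaries."""

    P: int
    sample_ids: list[str]
    mu_prox: np.ndarray
    mu_dist: np.ndarray
    var_prox: np.ndarray
    var_dist: np.ndarray
    pdui: np.ndarray  # NaN where the sample failed coverage or mu_prox == 0
    objective: float
    n_samples_used: int


@dataclass
class PduiMatrix:
    """Rows = (gene, transcript), columns = samples, values in [0,1]/NaN."""

    values: pd.DataFrame  # MultiIndex (gene_id, transcript_id) x sample columns
    breakpoints: pd.Series  # per-row fitted P (nt from UTR 5' end)
    regions: dict  # transcript_id -> UtrRegion


def extract_utr_regions(bed12: pd.DataFrame, min_seg: int = DEFAULT_MIN_SEG) -> list[UtrRegion]:
    """Extract 3'UTR regions from BED12 transcript models.

    The 3'UTR is the portion of the transcript downstream of the CDS
    (thickStart/thickEnd) on the transcript strand, restricted to the last
    exon.  Non-coding records (thickStart == thickEnd) are skipped and
    counted; regions shorter than ``2 * min_seg`` are dropped with a logged
    reason.
    """
    regions: list[UtrRegion] = []
    n_noncoding = 0
    n_short = 0
    for rec in bed12.itertuples(index=False):
        if rec.thickStart == rec.thickEnd:
            n_noncoding += 1
            continue
        sizes = [int(s) for s in str(rec.blockSizes).rstrip(",").split(",")]
        starts = [int(s) for s in str(rec.blockStarts).rstrip(",").split(",")]
        if rec.strand == "+":
            last_start = rec.chromStart + starts[-1]
            utr_start = max(int(rec.thickEnd), last_start)
            utr_end = int(rec.chromEnd)
        else:
            first_end = rec.chromStart + starts[0] + sizes[0]
            utr_start = int(rec.chromStart)
            utr_end = min(int(rec.thickStart), first_end)
        if utr_end - utr_start < 2 * min_seg:
            n_short += 1
            logger.info(
                "dropping %s: 3'UTR length %d < 2*min_seg=%d",
                rec.name, max(utr_end - utr_start, 0), 2 * min_seg,
            )
            continue
        gene_id = getattr(rec, "gene_id", None) or str(rec.name).split("|")[0]
        regions.append(
            UtrRegion(
                chrom=str(rec.chrom),
                start=utr_start,
                end=utr_end,
                strand=str(rec.strand),
                gene_id=gene_id,
                transcript_id=str(rec.name),
            )
        )
    if n_noncoding:
        logger.info("skipped %d non-coding records", n_noncoding)
    if n_short:
        logger.info("dropped %d regions shorter than 2*min_seg", n_short)
    return regions


def _chrom_dialect(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("chr") else "chr" + chrom


def load_coverage(
    bedgraph: pd.DataFrame | str,
    region: UtrRegion,
    sample_id: str = "sample",
    total_depth_factor: float = 1.0,
) -> CoverageProfile:
    """Per-base coverage over ``region`` from a bedGraph, 5'->3' oriented.

    Bases absent from the bedGraph are 0.  A chromosome-dialect mismatch
    ("chr1" vs "1") raises an explicit error naming both dialects.
    """
    if isinstance(bedgraph, str):
        from .iocli import read_bedgraph

        bedgraph = read_bedgraph(bedgraph)
    arr = np.zeros(region.length)
    chroms = set(bedgraph["chrom"].astype(str).unique())
    sub = bedgraph[bedgraph["chrom"] == region.chrom]
    if sub.empty and chroms and _chrom_dialect(region.chrom) in chroms:
        raise ValueError(
            f"chromosome naming mismatch: region uses {region.chrom!r} but the "
            f"bedGraph uses {_chrom_dialect(region.chrom)!r}"
        )
    for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
        lo = max(int(start), region.start) - region.start
        hi = min(int(end), region.end) - region.start
        if lo < hi:
            arr[lo:hi] = value
    if region.strand == "-":
        arr = arr[::-1]
    return CoverageProfile(sample_id=sample_id, values=arr, total_depth_factor=total_depth_factor)


def _segment_rss(values: np.ndarray, candidates: np.ndarray):
    """RSS and means of both segments for every candidate split, via prefix sums."""
    c1 = np.concatenate(([0.0], np.cumsum(values)))
    c2 = np.concatenate(([0.0], np.cumsum(values**2)))
    L = len(values)
    n1 = candidates.astype(float)
    n2 = L - n1
    s1 = c1[candidates]
    s2 = c1[-1] - s1
    q1 = c2[candidates]
    q2 = c2[-1] - q1
    mu1 = s1 / n1
    mu2 = s2 / n2
    rss1 = np.maximum(q1 - s1**2 / n1, 0.0)
    rss2 = np.maximum(q2 - s2**2 / n2, 0.0)
    return mu1, mu2, rss1, rss2, n1, n2


def fit_two_segment(
    profiles: list[CoverageProfile],
    min_seg: int = DEFAULT_MIN_SEG,
    step: int = DEFAULT_STEP,
    min_mean_cov: float = DEFAULT_MIN_MEAN_COV,
    objective: str = "profile_likelihood",
) -> BreakpointFit | None:
    """Fit the shared breakpoint P across samples and per-sample PDUI.

    Samples whose whole-region mean depth (after depth normalization) is
    below ``min_mean_cov`` do not contribute to the fit and get NaN PDUI.
    Returns None when no sample passes the coverage filter.  Ties in the
    objective break to the smallest P.
    """
    if objective not in ("profile_likelihood", "least_squares"):
        raise ValueError(f"unknown objective {objective!r}")
    if not profiles:
        raise ValueError("need at least one coverage profile")
    L = len(profiles[0].values)
    if any(len(p.values) != L for p in profiles):
        raise ValueError("all profiles must have equal length")
    if L < 2 * min_seg:
        raise ValueError(f"region length {L} < 2*min_seg={2 * min_seg}")

    norm = [p.values / p.total_depth_factor for p in profiles]
    passing = np.array([v.mean() >= min_mean_cov for v in norm])
    if not passing.any():
        return None

    candidates = np.arange(min_seg, L - min_seg + 1, step)
    total = np.zeros(len(candidates))
    per_sample = []
    eps = 1e-12  # floor for exactly piecewise-constant (noiseless) segments
    for v, ok in zip(norm, passing):
        mu1, mu2, rss1, rss2, n1, n2 = _segment_rss(v, candidates)
        per_sample.append((mu1, mu2, rss1, rss2, n1, n2))
        if not ok:
            continue
        if objective == "profile_likelihood":
            total += -(n1 / 2) * np.log(np.maximum(rss1 / n1, eps)) - (n2 / 2) * np.log(
                np.maximum(rss2 / n2, eps)
            )
        else:
            total += -(rss1 + rss2)
    best = int(np.argmax(total))  # argmax takes the first (smallest P) on ties
    P = int(candidates[best])

    k = len(profiles)
    mu_prox = np.empty(k)
    mu_dist = np.empty(k)
    var_prox = np.empty(k)
    var_dist = np.empty(k)
    pdui = np.full(k, np.nan)
    for i, (mu1, mu2, rss1, rss2, n1, n2) in enumerate(per_sample):
        mu_prox[i] = mu1[best]
        mu_dist[i] = mu2[best]
        var_prox[i] = rss1[best] / n1[best]
        var_dist[i] = rss2[best] / n2[best]
        if passing[i] and mu1[best] > 0:
            pdui[i] = min(max(mu2[best] / mu1[best], 0.0), 1.0)
    return BreakpointFit(
        P=P,
        sample_ids=[p.sample_id for p in profiles],
        mu_prox=mu_prox,
        mu_dist=mu_dist,
        var_prox=var_prox,
        var_dist=var_dist,
        pdui=pdui,
        objective=float(total[best]),
        n_samples_used=int(passing.sum()),
    )


def pdui_matrix(
    profiles_by_region: dict[str, list[CoverageProfile]],
    regions: list[UtrRegion],
    min_seg: int = DEFAULT_MIN_SEG,
    step: int = DEFAULT_STEP,
    min_mean_cov: float = DEFAULT_MIN_MEAN_COV,
    min_sample_fraction: float = DEFAULT_MIN_SAMPLE_FRACTION,
    objective: str = "profile_likelihood",
) -> PduiMatrix:
    """Fit every region and assemble the genes x samples PDUI matrix.

    Rows with non-missing fraction below ``min_sample_fraction`` are
    dropped.  Sample columns are sorted for order invariance; duplicate
    sample ids raise.
    """
    rows = {}
    bps = {}
    region_map = {}
    all_samples: set[str] = set()
    for region in regions:
        profs = profiles_by_region.get(region.transcript_id)
        if not profs:
            continue
        ids = [p.sample_id for p in profs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sample ids for {region.transcript_id}")
        all_samples.update(ids)
        fit = fit_two_segment(
            profs, min_seg=min_seg, step=step, min_mean_cov=min_mean_cov, objective=objective
        )
        if fit is None:
            continue
        frac = np.mean(~np.isnan(fit.pdui))
        if frac < min_sample_fraction:
            logger.info(
                "dropping %s: non-missing fraction %.2f < %.2f",
                region.transcript_id, frac, min_sample_fraction,
            )
            continue
        rows[(region.gene_id, region.transcript_id)] = dict(zip(fit.sample_ids, fit.pdui))
        bps[(region.gene_id, region.transcript_id)] = fit.P
        region_map[region.transcript_id] = region

    columns = sorted(all_samples)
    index = pd.MultiIndex.from_tuples(rows.keys(), names=["gene_id", "transcript_id"]) if rows else (
        pd.MultiIndex.from_arrays([[], []], names=["gene_id", "transcript_id"])
    )
    values = pd.DataFrame(
        [[rows[key].get(s, np.nan) for s in columns] for key in rows],
        index=index,
        columns=columns,
    )
    breakpoints = pd.Series({k: bps[k] for k in rows}, dtype=int) if rows else pd.Series(dtype=int)
    return PduiMatrix(values=values, breakpoints=breakpoints, regions=region_map)
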