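"""Colocalization of two association signals at one locus (ABF framework).

Assumes at most one causal variant per trait.  Each variant's evidence is a
Wakefield approximate Bayes factor computed from its z-score, sampling
variance V, and prior effect SD W:

    lABF = 0.5 * [ ln(1 - r) + r z^2 ],   r = W^2 / (W^2 + V).

Five hypotheses partition the causal configurations of the locus: H0 no
association, H1/H2 one trait only, H3 two distinct causal variants, H4 a
shared causal variant.  Posterior probabilities PP0-PP4 come from the
prior-weighted sums of per-configuration Bayes factors, accumulated in log
space (log-sum-exp) so loci with thousands of variants and large z do not
overflow.  PP4 >= 0.5 is the conventional colocalization call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "ColocResult",
    "log_abf",
    "var_from_zn",
    "coloc_posteriors",
    "classify_coloc",
    "DEFAULT_W_QUANT",
    "DEFAULT_W_CC",
]

DEFAULT_W_QUANT = 0.15  # prior effect SD, quantitative trait (phenotype-SD scale)
DEFAULT_W_CC = 0.2  # prior effect SD, case-control (log-odds scale)


@dataclass(frozen=True)
class ColocResult:
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_variants: int
    p1: float
    p2: float
    p12: float

    @property
    def pp(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


def var_from_zn(maf: np.ndarray, n: int) -> np.ndarray:
    """Approximate sampling variance of a standardized quantitative-trait
    effect: ``V ~= 1 / (2 n f (1-f))``."""
    maf = np.asarray(maf, float)
    return 1.0 / (2.0 * n * maf * (1.0 - maf))


def log_abf(z: np.ndarray, V: np.ndarray, W: float = DEFAULT_W_QUANT) -> np.ndarray:
    """Per-variant log approximate Bayes factor (alternative vs null)."""
    z = np.asarray(z, float)
    V = np.asarray(V, float)
    if np.any(V <= 0):
        raise ValueError("sampling variance V must be positive")
    r = W**2 / (W**2 + V)
    return 0.5 * (np.log1p(-r) + r * z**2)


def coloc_posteriors(
    labf1: np.ndarray,
    labf2: np.ndarray,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    Unnormalized log hypothesis weights (lse = log-sum-exp over variants)::

        S0 = 0
        S1 = ln p1 + lse(labf1)
        S2 = ln p2 + lse(labf2)
        S3 = ln p1 + ln p2 + ln( exp(lse1 + lse2) - sum_j exp(labf1_j + labf2_j) )
        S4 = ln p12 + lse(labf1 + labf2)

    The S3 cross-term (all ordered pairs of *distinct* variants) is computed
    stably as ``lse1 + lse2 + log(-expm1(lse12 - lse1 - lse2))``.  With a
    single variant H3 is impossible; PP3 = 0 by convention (logged).
    """
    labf1 = np.asarray(labf1, float)
    labf2 = np.asarray(labf2, float)
    if labf1.shape != labf2.shape or labf1.ndim != 1 or labf1.size == 0:
        raise ValueError("lABF vectors must be equal-length, 1-D, non-empty")
    if not (0 < p1 < 1 and 0 < p2 < 1 and 0 < p12 < 1 and p1 + p2 + p12 < 1):
        raise ValueError("require p1, p2, p12 in (0,1) with p1+p2+p12 < 1")
    q = labf1.size
    lse1 = logsumexp(labf1)
    lse2 = logsumexp(labf2)
    lse12 = logsumexp(labf1 + labf2)

    s0 = 0.0
    s1 = np.log(p1) + lse1
    s2 = np.log(p2) + lse2
    s4 = np.log(p12) + lse12
    diff = lse12 - (lse1 + lse2)  # <= 0, equality iff a single variant
    if q == 1 or diff >= -1e-15:
        if q == 1:
            logger.info("single-variant locus: PP3 = 0 by convention")
        s3 = -np.inf
    else:
        s3 = np.log(p1) + np.log(p2) + lse1 + lse2 + np.log(-np.expm1(diff))

    s = np.array([s0, s1, s2, s3, s4])
    pp = np.exp(s - logsumexp(s))
    pp /= pp.sum()
    return ColocResult(
        pp0=float(pp[0]), pp1=float(pp[1]), pp2=float(pp[2]),
        pp3=float(pp[3]), pp4=float(pp[4]),
        n_variants=q, p1=p1, p2=p2, p12=p12,
    )


def classify_coloc(result: ColocResult, threshold: float = 0.5) -> bool:
    """Colocalization call: PP4 at or above the threshold."""
    return result.pp4 >= threshold
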