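"""Clonality statistics: subclonal classification, enrichment of balanced
rearrangements among subclonal SVs, and a binomial goodness-of-fit test for
SV allele frequencies.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import BALANCED_CLASSES, SampleMeta, SVClass

CCF_CUTOFF = 0.7  # variants with CCF below this are called subclonal


def classify_clonality(ccf: float, cutoff: float = CCF_CUTOFF) -> str:
    """``subclonal`` iff ccf < cutoff; the boundary itself is clonal."""
    if not (0 <= ccf <= 2):
        raise ValueError(f"CCF must be in [0, 2], got {ccf}")
    return "subclonal" if ccf < cutoff else "clonal"


def subclonal_fraction(ccfs, cutoff: float = CCF_CUTOFF) -> float:
    ccfs = np.asarray(list(ccfs), dtype=float)
    if len(ccfs) == 0:
        raise ValueError("no variants")
    return float(np.mean(ccfs < cutoff))


def scnr_test(svs, cutoff: float = CCF_CUTOFF) -> float:
    """Enrichment of balanced rearrangements (inversions and
    inter-chromosomal translocations) among subclonal SVs.

    ``svs`` is an iterable of (svclass, ccf).  One-sided hypergeometric test
    of P(X >= x) with population N = all SVs, K = balanced SVs, draws
    n = subclonal SVs, observed x = subclonal balanced SVs.
    """
    svs = [(SVClass(c) if not isinstance(c, SVClass) else c, float(ccf))
           for c, ccf in svs]
    if not svs:
        raise ValueError("no SVs")
    N = len(svs)
    K = sum(1 for c, _ in svs if c in BALANCED_CLASSES)
    n = sum(1 for _, ccf in svs if ccf < cutoff)
    x = sum(1 for c, ccf in svs if c in BALANCED_CLASSES and ccf < cutoff)
    return float(stats.hypergeom.sf(x - 1, N, K, n))


# ---------------------------------------------------------------------------
# binomial vs beta-binomial dispersion test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DispersionResult:
    p_values: np.ndarray
    statistics: np.ndarray
    rejection_fraction: float
    alpha_level: float
    beta: float


def betabinom_params(mu: float, n: float, sigma: float) -> tuple[float, float]:
    """Method-of-moments beta-binomial parameters for n trials with mean
    ``mu`` and standard deviation ``sigma`` of the success counts:

        beta  = (mu - n)(mu^2 - mu n + sigma^2) / (mu^2 - mu n + n sigma^2)
        alpha = -mu beta / (mu - n)
    """
    denom = mu * mu - mu * n + n * sigma * sigma
    if denom == 0:
        raise ValueError("degenerate moments for beta-binomial")
    beta = (mu - n) * (mu * mu - mu * n + sigma * sigma) / denom
    alpha = -mu * beta / (mu - n)
    return alpha, beta


def dispersion_test(b_list, d_list, meta: SampleMeta,
                    alpha_level: float = 0.05,
                    per_variant_depth: bool = False) -> DispersionResult:
    """Per-variant likelihood-ratio test of binomial vs beta-binomial fit.

    Intended for copy-number-neutral variants, whose expected heterozygous
    VAF is half the purity: the null model is Binomial(d_j, t/2).  The
    alternative's beta parameter is estimated sample-wide from the moments
    of the observed supporting counts (mean mu = mu_d * t/2, sigma = s.d. of
    the counts), with a per-variant alpha from the variant's depth; the LRT
    statistic is referred to chi-square with one degree of freedom.  When
    the counts are under-dispersed relative to binomial, the beta-binomial
    moment fit is infeasible and the statistic is zero (no evidence of
    overdispersion).

    ``per_variant_depth`` estimates beta from each variant's own depth
    rather than the sample mean depth.
    """
    b = np.asarray(list(b_list), dtype=float)
    d = np.asarray(list(d_list), dtype=float)
    if len(b) < 2:
        raise ValueError("need at least 2 variants to estimate dispersion")
    p0 = meta.purity / 2.0
    mu_d = float(np.mean(d))
    sigma = float(np.std(b, ddof=1))

    ll0 = stats.binom.logpmf(b, np.round(d).astype(int), p0)

    stats_ = np.zeros(len(b))
    beta_report = np.nan
    for j in range(len(b)):
        n_j = d[j] if per_variant_depth else mu_d
        mu = n_j * p0
        try:
            alpha_j, beta_j = betabinom_params(mu, d[j], sigma)
        except ValueError:
            continue
        if alpha_j <= 0 or beta_j <= 0:
            continue  # moment fit infeasible: no overdispersion evidence
        beta_report = beta_j
        ll1 = stats.betabinom.logpmf(int(round(b[j])), int(round(d[j])),
                                     alpha_j, beta_j)
        stats_[j] = max(0.0, 2.0 * (ll1 - ll0[j]))

    p_values = stats.chi2.sf(stats_, df=1)
    return DispersionResult(
        p_values=p_values, statistics=stats_,
        rejection_fraction=float(np.mean(p_values < alpha_level)),
        alpha_level=alpha_level, beta=beta_report)
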