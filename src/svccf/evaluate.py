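"""Benchmarking metrics against a known truth set.

Truth sets come from the synthetic-data generator (or any in-silico mixture
with known mixing proportions): per-variant true CCFs and cluster labels,
with shared variants clonal and sample-private variants subclonal.  Inferred
and true clusters are matched by alternating extremes (highest-to-highest,
lowest-to-lowest, second-highest, ...) and errors are reported signed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clonality import CCF_CUTOFF
from .io_formats import CNAnnotation, SampleMeta
from .model import CCF_CAP, compute_weight, multiplicity_candidates, variant_ccf


@dataclass(frozen=True)
class TruthTable:
    """Ground truth for benchmarking: per-variant true CCF, cluster id and
    clonality label, plus per-cluster true means."""

    variants: pd.DataFrame       # id, true_ccf, true_cluster, clonal (bool)
    cluster_means: np.ndarray    # true mean CCF per cluster id

    def __post_init__(self):
        required = {"id", "true_ccf", "true_cluster", "clonal"}
        missing = required - set(self.variants.columns)
        if missing:
            raise ValueError(f"truth table missing columns {sorted(missing)}")
        if np.any((self.variants["true_ccf"] < 0)
                  | (self.variants["true_ccf"] > CCF_CAP)):
            raise ValueError("true CCFs must lie in [0, 2]")


def match_clusters(true_means, inferred_means):
    """Match cluster means by alternating extremes.

    Pairs are formed highest-with-highest, then lowest-with-lowest, then
    second-highest, second-lowest and so on, until either list is exhausted.
    Returns (pairs, unmatched_true, unmatched_inferred) where pairs is a
    list of (true_mean, inferred_mean).
    """
    t = sorted(map(float, true_means), reverse=True)
    f = sorted(map(float, inferred_means), reverse=True)
    if not t or not f:
        raise ValueError("both cluster lists must be non-empty")
    n = min(len(t), len(f))
    order = []  # index offsets from the top (0) and bottom (-1) alternating
    hi, lo = 0, -1
    for step in range(n):
        if step % 2 == 0:
            order.append(hi)
            hi += 1
        else:
            order.append(lo)
            lo -= 1
    pairs = [(t[i], f[i]) for i in order]
    used_t = {i % len(t) for i in order}
    used_f = {i % len(f) for i in order}
    unmatched_t = [t[i] for i in range(len(t)) if i not in used_t]
    unmatched_f = [f[i] for i in range(len(f)) if i not in used_f]
    return pairs, unmatched_t, unmatched_f


def optimal_multiplicity_and_ccf(b: float, d: float, cn: CNAnnotation,
                                 meta: SampleMeta, true_cluster_ccf: float,
                                 eps: float | None = None):
    """Best multiplicity given the true cluster CCF, and the resulting CCF.

    Brute-force maximisation of the binomial log-likelihood with
    ``f = w(m) * phi_true + eps`` over the admissible multiplicity set; the
    CCF then follows from the linear VAF transform with ``w(m*)``.
    """
    eps = meta.error_rate if eps is None else eps
    cands = multiplicity_candidates(cn)
    best_m, best_ll = None, -np.inf
    for m in cands:
        w = compute_weight(float(m), cn, meta)
        f = np.clip(w * true_cluster_ccf + eps, 1e-12, 1 - 1e-12)
        ll = (b * np.log(f) + (d - b) * np.log1p(-f))
        if ll > best_ll + 1e-12:
            best_m, best_ll = float(m), ll
    w_star = compute_weight(best_m, cn, meta)
    ccf_star = variant_ccf(b / d, w_star, eps) if d > 0 and w_star > 0 else np.nan
    return best_m, ccf_star


def metrics(truth: TruthTable, results, meta: SampleMeta | None = None,
            cn_lo=None, cn_hi=None, cutoff: float = CCF_CUTOFF) -> dict:
    """Benchmark a fit against truth.

    Returns cluster_number_error (true K - inferred K), signed
    mean_cluster_ccf_error and mean_variant_ccf_error (inferred - true),
    mean_multiplicity_error (inferred m - m implied by the true cluster
    mean), and subclonal sensitivity/specificity at the CCF cutoff.
    """
    inferred = results.variant_ccfs().set_index("id")
    tv = truth.variants.set_index("id")
    missing = sorted(set(tv.index) ^ set(inferred.index))
    if missing:
        raise ValueError(f"variant id mismatch between truth and results: "
                         f"{missing[:5]}...")
    inferred = inferred.loc[tv.index]

    true_k = len(truth.cluster_means)
    inferred_means = results.cluster_means
    pairs, _, _ = match_clusters(truth.cluster_means, inferred_means)
    cluster_err = float(np.mean([f - t for t, f in pairs]))

    variant_err = float(np.mean(inferred["ccf"].to_numpy()
                                - tv["true_ccf"].to_numpy()))

    # multiplicity error vs the multiplicity implied by the true cluster mean
    mult_err = np.nan
    if meta is not None and cn_lo is not None:
        model_data = results.model._data
        errs = []
        for j, vid in enumerate(tv.index):
            phi_true = float(tv.loc[vid, "true_ccf"])
            for i, anns in enumerate((cn_lo, cn_hi)):
                if anns is None:
                    continue
                m_star, _ = optimal_multiplicity_and_ccf(
                    model_data.b[j, i], model_data.d[j, i], anns[j], meta,
                    phi_true, eps=model_data.eps)
                errs.append(results.multiplicities[j, i] - m_star)
        mult_err = float(np.mean(errs)) if errs else np.nan

    truly_sub = ~tv["clonal"].to_numpy(dtype=bool)
    called_sub = inferred["ccf"].to_numpy() < cutoff
    tp = int(np.sum(truly_sub & called_sub))
    fn = int(np.sum(truly_sub & ~called_sub))
    tn = int(np.sum(~truly_sub & ~called_sub))
    fp = int(np.sum(~truly_sub & called_sub))
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan

    return {
        "cluster_number_error": true_k - results.K_effective,
        "mean_cluster_ccf_error": cluster_err,
        "mean_variant_ccf_error": variant_err,
        "mean_multiplicity_error": mult_err,
        "subclonal_sensitivity": sens,
        "subclonal_specificity": spec,
    }
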