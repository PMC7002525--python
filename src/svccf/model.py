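"""Dual-breakend Bayesian binomial mixture model for CCF inference.

Each SV ``j`` contributes supporting read counts ``b_{i,j}`` out of depth
``d_{i,j}`` at its two breakends ``i in {1,2}``.  Conditional on the cancer
cell fraction (CCF) ``phi_k`` of the cluster the SV belongs to, the two ends
are independently binomial with success probability

    f_{i,j,k} = w_{i,j} * phi_k + eps,
    w_{i,j}   = t * (m_{i,j} (1 - eps) - n_tot_t eps)
                / ((1 - t) n_tot_n + t n_tot_t),

where ``t`` is tumour purity, ``eps`` the sequencing error constant,
``m_{i,j}`` the variant multiplicity (number of mutated chromosomal copies,
a point estimate over a finite candidate set determined by the background
copy number) and ``n_tot_n``, ``n_tot_t`` the total normal and tumour copy
number at the breakend (fraction-weighted for subclonal segments).  Both
ends of an SV share one cluster assignment ``z_j`` and one ``phi``.

Inference is coordinate-ascent variational Bayes on the factorised posterior
``q(Z) q(phi) q(pi)`` with a Gaussian prior on each ``phi_k`` and a
symmetric Dirichlet prior on the mixing weights.  Because the binomial
likelihood is not conjugate to the Gaussian, expectations over ``q(phi_k)``
are evaluated with Gauss-Hermite quadrature; the quadrature rule defines the
surrogate evidence lower bound (ELBO) that every update maximises, so the
ELBO trace is non-decreasing by construction.  The cluster number is chosen
by running the fit over a range of K and several restarts and keeping the
best-ELBO solution, followed by quality control (drop empty clusters, drop
clusters holding under 1% of the data, merge clusters whose means are less
than 0.10 apart, refitting after each step).
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import digamma, gammaln

from .io_formats import CNAnnotation, SampleMeta

log = logging.getLogger(__name__)

_F_MIN = 1e-12  # success-probability floor inside logs
CCF_CAP = 2.0


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def compute_weight(m: float, cn: CNAnnotation, meta: SampleMeta) -> float:
    """CCF-to-VAF conversion weight for one breakend.

    ``w = t (m (1 - eps) - n_tot_t eps) / ((1 - t) n_tot_n + t n_tot_t)``.
    """
    t, eps = meta.purity, meta.error_rate
    n_t, n_n = cn.total_tumour, cn.total_normal
    denom = (1.0 - t) * n_n + t * n_t
    if denom <= 0:
        raise ValueError("zero population copy number; check purity/CN input")
    return t * (m * (1.0 - eps) - n_t * eps) / denom


def multiplicity_candidates(cn: CNAnnotation) -> np.ndarray:
    """Finite set of admissible multiplicities at a breakend.

    Clonal background: integers ``1..n_maj``.  Subclonal background: all
    fraction-weighted sums ``sum_r rho_r x_r`` with ``x_r in 0..n_maj_r``
    per copy-number clone (non-integer values arise because the mutation may
    sit on copies present in only part of the tumour).
    """
    if not cn.subclonal:
        n_maj = int(np.floor(cn.states[0].major + 1e-9))
        if n_maj < 1:
            raise ValueError("no mutable copies: clonal major copy number < 1")
        return np.arange(1, n_maj + 1, dtype=float)
    ranges = [range(int(np.floor(s.major + 1e-9)) + 1) for s in cn.states]
    fracs = [s.frac for s in cn.states]
    vals = sorted({round(sum(f * x for f, x in zip(fracs, combo)), 10)
                   for combo in itertools.product(*ranges)})
    vals = np.asarray(vals, dtype=float)
    if vals.max() <= 0:
        raise ValueError("no mutable copies: all subclonal major copy numbers 0")
    return vals


def variant_ccf(vaf: float, w: float, eps: float) -> float:
    """Per-end variant-level CCF: ``min(2, (VAF - eps) / w)``, floored at 0."""
    if w <= 0:
        raise ValueError("non-positive weight; cannot transform VAF to CCF")
    return float(min(CCF_CAP, max(0.0, (vaf - eps) / w)))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Tuning parameters of the mixture fit.

    The fit explores ``k_range`` cluster numbers with ``repeats`` restarts
    each (defaults 1..6 and 5).  ``phi_prior_mean``/``phi_prior_var`` set the
    Gaussian prior on cluster CCFs; ``dirichlet_conc`` the symmetric
    Dirichlet concentration (small values are sparsity-inducing so surplus
    clusters empty out and quality control can prune them).
    ``qc_small_frac`` and ``qc_merge_gap`` are the quality-control
    thresholds: clusters holding less than 1% of variants are removed and
    clusters whose means are less than 0.10 apart are merged.
    """

    k_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    repeats: int = 5
    max_iter: int = 1000
    elbo_tol: float = 1e-6
    seed: int = 0
    error_rate: float | None = None  # defaults to SampleMeta.error_rate
    phi_prior_mean: float = 1.0
    phi_prior_var: float = 1.0
    dirichlet_conc: float = 1e-2
    qc_small_frac: float = 0.01
    qc_merge_gap: float = 0.10
    n_quad: int = 12

    def __post_init__(self):
        if len(self.k_range) == 0:
            raise ValueError("k_range must be non-empty")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not (0 < self.qc_small_frac < 1 and 0 < self.qc_merge_gap < 1):
            raise ValueError("QC thresholds must be in (0,1)")


# ---------------------------------------------------------------------------
# internal variational state
# ---------------------------------------------------------------------------

class _Quadrature:
    def __init__(self, n: int):
        nodes, weights = hermegauss(n)  # probabilists': integrates vs N(0,1)
        self.nodes = nodes
        self.weights = weights / weights.sum()


def _binom_logpmf(b, d, f):
    """Generalised binomial log-pmf (real-valued trials allowed)."""
    f = np.clip(f, _F_MIN, 1.0 - _F_MIN)
    return (gammaln(d + 1.0) - gammaln(b + 1.0) - gammaln(d - b + 1.0)
            + b * np.log(f) + (d - b) * np.log1p(-f))


class _VIState:
    """Variational parameters for a single (K, restart) fit."""

    def __init__(self, data: "_ModelData", K: int, mu0, s0, alpha0: float,
                 cfg: ModelConfig, quad: _Quadrature):
        self.data = data
        self.K = K
        self.cfg = cfg
        self.quad = quad
        self.mu = np.asarray(mu0, dtype=float).copy()        # (K,)
        self.s = np.asarray(s0, dtype=float).copy()          # (K,) std devs
        self.alpha0 = alpha0
        self.alpha = np.full(K, alpha0 + data.J / K)         # Dirichlet params
        self.m = data.init_multiplicities()                  # (J,2)
        self.w = data.weights(self.m)                        # (J,2)
        self.r = np.full((data.J, K), 1.0 / K)               # responsibilities
        self.elbo_trace: list[float] = []
        self.converged = False

    # -- expected log-likelihood under q(phi_k) ---------------------------

    def _phi_nodes(self):
        # (K, Q) quadrature nodes for each cluster's Gaussian posterior
        return self.mu[:, None] + self.s[:, None] * self.quad.nodes[None, :]

    def _ell_under_q(self, w=None):
        """E_{q(phi_k)}[log p(b_j | d_j, phi)] summed over ends -> (J, K)."""
        w = self.w if w is None else w
        phi = self._phi_nodes()                               # (K, Q)
        f = w[:, :, None, None] * phi[None, None, :, :] + self.data.eps
        ll = _binom_logpmf(self.data.b[:, :, None, None],
                           self.data.d[:, :, None, None], f)  # (J,2,K,Q)
        return np.einsum("jikq,q->jk", ll, self.quad.weights)

    def _ell_at_phi(self, phi_k: float, w_col, k: int):
        """log-lik of all variants at a fixed phi value (J,)."""
        f = w_col * phi_k + self.data.eps
        return _binom_logpmf(self.data.b, self.data.d, f).sum(axis=1)

    # -- coordinate updates ----------------------------------------------

    def _eln_pi(self):
        return digamma(self.alpha) - digamma(self.alpha.sum())

    def update_z(self, ell=None):
        ell = self._ell_under_q() if ell is None else ell
        logr = ell + self._eln_pi()[None, :]
        logr -= logr.max(axis=1, keepdims=True)
        r = np.exp(logr)
        self.r = r / r.sum(axis=1, keepdims=True)

    def update_pi(self):
        self.alpha = self.alpha0 + self.r.sum(axis=0)

    def _phi_objective(self, k: int, mu_k: float, s_k: float) -> float:
        phi = mu_k + s_k * self.quad.nodes                    # (Q,)
        f = self.w[:, :, None] * phi[None, None, :] + self.data.eps
        ll = _binom_logpmf(self.data.b[:, :, None], self.data.d[:, :, None], f)
        ell = ll.sum(axis=1) @ self.quad.weights              # (J,)
        cfg = self.cfg
        prior = -((mu_k - cfg.phi_prior_mean) ** 2 + s_k ** 2) / (
            2.0 * cfg.phi_prior_var)
        entropy = np.log(s_k)
        return float(self.r[:, k] @ ell + prior + entropy)

    def update_phi(self, n_newton: int = 4):
        """Numerically maximise the surrogate ELBO over (mu_k, log s_k).

        Damped Newton steps with backtracking; a candidate is accepted only
        if it improves the objective, which keeps the ELBO monotone.
        """
        for k in range(self.K):
            mu_k, ls_k = self.mu[k], np.log(self.s[k])
            fbest = self._phi_objective(k, mu_k, np.exp(ls_k))
            h = 1e-4
            for _ in range(n_newton):
                improved = False
                for dim in (0, 1):
                    def obj(x):
                        if dim == 0:
                            return self._phi_objective(k, x, np.exp(ls_k))
                        return self._phi_objective(k, mu_k, np.exp(x))
                    x0 = mu_k if dim == 0 else ls_k
                    fp = obj(x0 + h)
                    fm = obj(x0 - h)
                    grad = (fp - fm) / (2 * h)
                    curv = (fp - 2 * fbest + fm) / (h * h)
                    step = -grad / curv if curv < -1e-12 else np.sign(grad) * 0.1
                    step = np.clip(step, -1.0, 1.0)
                    for _bt in range(8):
                        cand = obj(x0 + step)
                        if cand > fbest:
                            if dim == 0:
                                mu_k = x0 + step
                            else:
                                ls_k = x0 + step
                            fbest = cand
                            improved = True
                            break
                        step *= 0.5
                if not improved:
                    break
            self.mu[k], self.s[k] = mu_k, float(np.exp(ls_k))

    def update_m(self):
        """Multiplicity point estimates: per-end argmax over the candidate
        set of the responsibility-weighted expected binomial log-likelihood;
        ties break toward the smallest candidate (conservative CCF)."""
        phi = self._phi_nodes()                               # (K, Q)
        data = self.data
        for j in range(data.J):
            for i in range(2):
                cands = data.xi[j][i]
                if len(cands) == 1:
                    continue
                wc = data.weight_of(j, i, cands)              # (C,)
                f = wc[:, None, None] * phi[None, :, :] + data.eps
                ll = _binom_logpmf(data.b[j, i], data.d[j, i], f)
                ell = ll @ self.quad.weights                  # (C, K)
                score = ell @ self.r[j]                       # (C,)
                best = np.flatnonzero(score >= score.max() - 1e-12)[0]
                self.m[j, i] = cands[best]
        self.w = data.weights(self.m)

    # -- ELBO --------------------------------------------------------------

    def elbo(self) -> float:
        cfg = self.cfg
        ell = self._ell_under_q()
        eln_pi = self._eln_pi()
        val = float((self.r * ell).sum())
        val += float((self.r * eln_pi[None, :]).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            rlogr = np.where(self.r > 0, self.r * np.log(self.r), 0.0)
        val -= float(rlogr.sum())
        # Dirichlet prior and entropy
        a0 = np.full(self.K, self.alpha0)
        val += float(gammaln(a0.sum()) - gammaln(a0).sum()
                     + ((a0 - 1) * eln_pi).sum())
        val -= float(gammaln(self.alpha.sum()) - gammaln(self.alpha).sum()
                     + ((self.alpha - 1) * eln_pi).sum())
        # Gaussian prior and entropy for each phi_k
        val += float(np.sum(
            -0.5 * np.log(2 * np.pi * cfg.phi_prior_var)
            - ((self.mu - cfg.phi_prior_mean) ** 2 + self.s ** 2)
            / (2 * cfg.phi_prior_var)))
        val += float(np.sum(0.5 * np.log(2 * np.pi * np.e * self.s ** 2)))
        return val

    def run(self, max_iter: int | None = None):
        max_iter = max_iter or self.cfg.max_iter
        prev = -np.inf
        for _ in range(max_iter):
            self.update_z()
            self.update_pi()
            self.update_phi()
            self.update_m()
            cur = self.elbo()
            self.elbo_trace.append(cur)
            if np.isfinite(prev) and abs(cur - prev) <= self.cfg.elbo_tol * max(
                    1.0, abs(prev)):
                self.converged = True
                break
            prev = cur
        return self


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

class _ModelData:
    """Vectorised per-variant arrays with multiplicity candidate sets."""

    def __init__(self, ids, b, d, cn_lo, cn_hi, meta: SampleMeta, eps: float):
        self.ids = list(ids)
        self.b = np.asarray(b, dtype=float)
        self.d = np.asarray(d, dtype=float)
        if self.b.shape != self.d.shape or self.b.ndim != 2 or self.b.shape[1] != 2:
            raise ValueError("b and d must be (J, 2) arrays")
        if np.any(self.b > self.d) or np.any(self.b < 0):
            raise ValueError("need 0 <= b <= d")
        self.J = self.b.shape[0]
        self.meta = meta
        self.eps = eps
        self.cn = list(zip(cn_lo, cn_hi))
        self.xi = [(multiplicity_candidates(lo), multiplicity_candidates(hi))
                   for lo, hi in self.cn]
        # w(m) is linear in m: w = a*m + c per (j, i)
        t = meta.purity
        self._a = np.empty((self.J, 2))
        self._c = np.empty((self.J, 2))
        for j, (lo, hi) in enumerate(self.cn):
            for i, ann in enumerate((lo, hi)):
                denom = (1 - t) * ann.total_normal + t * ann.total_tumour
                self._a[j, i] = t * (1 - eps) / denom
                self._c[j, i] = -t * ann.total_tumour * eps / denom

    def weights(self, m: np.ndarray) -> np.ndarray:
        return self._a * m + self._c

    def weight_of(self, j: int, i: int, m) -> np.ndarray:
        return self._a[j, i] * np.asarray(m, dtype=float) + self._c[j, i]

    def init_multiplicities(self) -> np.ndarray:
        m = np.empty((self.J, 2))
        for j in range(self.J):
            for i in range(2):
                cands = self.xi[j][i]
                positive = cands[cands > 0]
                pool = positive if len(positive) else cands
                m[j, i] = pool[np.argmin(np.abs(pool - 1.0))]
        return m

    def empirical_ccf(self) -> np.ndarray:
        """Per-variant CCF with unit multiplicity, mean over informative ends."""
        w = self.weights(np.ones_like(self.b))
        with np.errstate(divide="ignore", invalid="ignore"):
            vaf = np.where(self.d > 0, self.b / np.maximum(self.d, 1e-12), np.nan)
        ccf = np.clip((vaf - self.eps) / w, 0.0, CCF_CAP)
        return np.nanmean(np.where(self.d > 0, ccf, np.nan), axis=1)


# ---------------------------------------------------------------------------
# public model / results
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = ("id", "b1", "d1", "b2", "d2")


class BreakpointMixture:
    """Mixture model over SV breakpoints, built from filtered variants.

    Parameters
    ----------
    variants : DataFrame
        One row per SV with columns ``id, b1, d1, b2, d2`` (supporting reads
        and depth per end, post normal-read adjustment).
    cn_lo, cn_hi : sequences of CNAnnotation
        Background copy-number annotation per end; default diploid clonal.
    meta : SampleMeta
        Purity, ploidy, error rate and read-level parameters.
    config : ModelConfig
    """

    def __init__(self, variants: pd.DataFrame, meta: SampleMeta,
                 cn_lo=None, cn_hi=None, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
        if missing:
            raise ValueError(f"variants table missing columns {missing}")
        if len(variants) == 0:
            raise ValueError("no variants to cluster")
        self.variants = variants.reset_index(drop=True)
        J = len(self.variants)
        default = CNAnnotation.default()
        cn_lo = list(cn_lo) if cn_lo is not None else [default] * J
        cn_hi = list(cn_hi) if cn_hi is not None else [default] * J
        eps = (self.config.error_rate if self.config.error_rate is not None
               else meta.error_rate)
        self.meta = meta
        self._data = _ModelData(
            self.variants["id"], self.variants[["b1", "b2"]].to_numpy(),
            self.variants[["d1", "d2"]].to_numpy(), cn_lo, cn_hi, meta, eps)

    @classmethod
    def from_filtered(cls, kept, meta: SampleMeta,
                      config: ModelConfig | None = None) -> "BreakpointMixture":
        """Build from the filter step's kept list of
        (Breakpoint, ReadCounts, CNAnnotation_lo, CNAnnotation_hi)."""
        from .count import compute_vaf

        rows, cn_lo, cn_hi = [], [], []
        for bp, counts, ann_lo, ann_hi in kept:
            ev_lo, ev_hi = compute_vaf(counts)
            rows.append({"id": bp.id, "b1": ev_lo.b, "d1": ev_lo.d,
                         "b2": ev_hi.b, "d2": ev_hi.d,
                         "svclass": bp.svclass.value})
            cn_lo.append(ann_lo)
            cn_hi.append(ann_hi)
        return cls(pd.DataFrame(rows), meta, cn_lo=cn_lo, cn_hi=cn_hi,
                   config=config)

    # -- fitting ----------------------------------------------------------

    def _init_state(self, K: int, rng: np.random.Generator,
                    jitter: bool) -> _VIState:
        cfg = self.config
        quad = _Quadrature(cfg.n_quad)
        emp = self._data.empirical_ccf()
        emp = emp[np.isfinite(emp)]
        if len(emp) == 0:
            emp = np.array([1.0])
        qs = np.quantile(emp, (np.arange(K) + 0.5) / K)
        if jitter:
            qs = qs + rng.normal(0.0, 0.05, size=K)
        mu0 = np.clip(qs, 0.02, CCF_CAP)
        s0 = np.full(K, 0.1)
        return _VIState(self._data, K, mu0, s0, cfg.dirichlet_conc, cfg, quad)

    def fit(self, seed: int | None = None) -> "BreakpointMixtureResults":
        """Run the VI fit over the configured K range and restarts, pick the
        best-ELBO solution and apply quality control."""
        cfg = self.config
        base_seed = cfg.seed if seed is None else seed
        best: _VIState | None = None
        n_fits = 0
        for K in cfg.k_range:
            K = min(K, self._data.J)  # no more clusters than variants
            for rep in range(cfg.repeats):
                rng = np.random.default_rng(
                    np.random.SeedSequence(base_seed, spawn_key=(K, rep)))
                state = self._init_state(K, rng, jitter=rep > 0)
                state.run()
                n_fits += 1
                if best is None or state.elbo_trace[-1] > best.elbo_trace[-1]:
                    best = state
        results = BreakpointMixtureResults(self, best, seed=base_seed,
                                           n_fits=n_fits)
        return results._apply_qc()


# ---------------------------------------------------------------------------

class BreakpointMixtureResults:
    """Fitted mixture: posterior cluster CCFs, assignments, multiplicities.

    ``cluster_means``/``cluster_vars`` are the Gaussian posterior moments of
    each cluster CCF, ``weights`` the posterior mean mixing proportions,
    ``responsibilities`` the (J, K) soft assignments, ``multiplicities`` the
    (J, 2) per-end point estimates, ``elbo``/``elbo_trace`` the surrogate
    evidence lower bound.
    """

    def __init__(self, model: BreakpointMixture, state: _VIState,
                 seed: int, n_fits: int, qc_log=None):
        self.model = model
        self._state = state
        self.seed = seed
        self.n_fits = n_fits
        self.qc_log = qc_log or []
        self.converged = state.converged

    # -- basic accessors --------------------------------------------------

    @property
    def K(self) -> int:
        return self._state.K

    @property
    def K_effective(self) -> int:
        """Clusters holding at least one variant (by hard assignment)."""
        return len(np.unique(self.assignments))

    @property
    def cluster_means(self) -> np.ndarray:
        return self._state.mu.copy()

    @property
    def cluster_vars(self) -> np.ndarray:
        return self._state.s.copy() ** 2

    @property
    def weights(self) -> np.ndarray:
        return self._state.alpha / self._state.alpha.sum()

    @property
    def responsibilities(self) -> np.ndarray:
        return self._state.r.copy()

    @property
    def assignments(self) -> np.ndarray:
        return self._state.r.argmax(axis=1)

    @property
    def multiplicities(self) -> np.ndarray:
        return self._state.m.copy()

    @property
    def elbo(self) -> float:
        return self._state.elbo_trace[-1]

    @property
    def elbo_trace(self) -> np.ndarray:
        return np.asarray(self._state.elbo_trace)

    # -- per-variant CCFs --------------------------------------------------

    def variant_ccfs(self) -> pd.DataFrame:
        """Per-end and representative CCFs via the linear VAF transform.

        ``ccf = mean(ccf_lo, ccf_hi)`` over informative ends, capped at 2.
        """
        data = self.model._data
        w = self._state.w
        rows = []
        for j in range(data.J):
            per_end = []
            for i in range(2):
                if data.d[j, i] > 0 and w[j, i] > 0:
                    vaf = data.b[j, i] / data.d[j, i]
                    per_end.append(variant_ccf(vaf, w[j, i], data.eps))
                else:
                    per_end.append(np.nan)
            rep = float(np.nanmean(per_end)) if not all(
                np.isnan(x) for x in per_end) else np.nan
            rows.append({"id": data.ids[j], "ccf_lo": per_end[0],
                         "ccf_hi": per_end[1], "ccf": min(CCF_CAP, rep),
                         "cluster": int(self.assignments[j]),
                         "cluster_ccf": float(self._state.mu[self.assignments[j]]),
                         "m_lo": float(self._state.m[j, 0]),
                         "m_hi": float(self._state.m[j, 1])})
        return pd.DataFrame(rows)

    # -- quality control ---------------------------------------------------

    def _drop_clusters(self, keep_idx: np.ndarray):
        st = self._state
        st.mu = st.mu[keep_idx]
        st.s = st.s[keep_idx]
        st.alpha = st.alpha[keep_idx]
        st.r = st.r[:, keep_idx]
        st.r /= st.r.sum(axis=1, keepdims=True)
        st.K = len(keep_idx)

    def _refine(self):
        st = self._state
        st.elbo_trace = []
        st.run()

    def _apply_qc(self) -> "BreakpointMixtureResults":
        """Remove empty clusters, remove clusters holding < 1% of the data,
        merge clusters with means under the merge gap; refit after each."""
        cfg = self.model.config
        st = self._state

        # (1) empty clusters
        occupied = np.unique(st.r.argmax(axis=1))
        if len(occupied) < st.K:
            self.qc_log.append(f"removed {st.K - len(occupied)} empty clusters")
            self._drop_clusters(occupied)
            self._refine()

        # (2) small clusters (< qc_small_frac of the data)
        while st.K > 1:
            sizes = np.bincount(st.r.argmax(axis=1), minlength=st.K)
            small = np.flatnonzero(sizes < cfg.qc_small_frac * self.model._data.J)
            if len(small) == 0:
                break
            drop = small[np.argmin(sizes[small])]
            self.qc_log.append(f"removed small cluster {drop} "
                               f"({sizes[drop]} variants)")
            self._drop_clusters(np.array([k for k in range(st.K) if k != drop]))
            self._refine()

        # (3) merge clusters with means < qc_merge_gap apart
        while st.K > 1:
            order = np.argsort(st.mu)
            gaps = np.diff(st.mu[order])
            idx = int(np.argmin(gaps))
            if gaps[idx] >= cfg.qc_merge_gap:
                break
            a, b = order[idx], order[idx + 1]
            wa = st.r[:, a].sum() + 1e-12
            wb = st.r[:, b].sum() + 1e-12
            merged_mu = (wa * st.mu[a] + wb * st.mu[b]) / (wa + wb)
            self.qc_log.append(
                f"merged clusters at {st.mu[a]:.3f} and {st.mu[b]:.3f}")
            st.mu[a] = merged_mu
            st.s[a] = max(st.s[a], st.s[b])
            st.r[:, a] += st.r[:, b]
            st.alpha[a] += st.alpha[b] - st.alpha0
            self._drop_clusters(np.array([k for k in range(st.K) if k != b]))
            self._refine()
        return self

    # -- reporting ---------------------------------------------------------

    def cluster_table(self) -> pd.DataFrame:
        sizes = np.bincount(self.assignments, minlength=self.K)
        return pd.DataFrame({
            "cluster": np.arange(self.K),
            "mean_ccf": self.cluster_means,
            "sd_ccf": np.sqrt(self.cluster_vars),
            "weight": self.weights,
            "n_variants": sizes,
        })

    def assignment_table(self) -> pd.DataFrame:
        ccfs = self.variant_ccfs()
        resp = self.responsibilities
        for k in range(self.K):
            ccfs[f"resp_{k}"] = resp[:, k]
        return ccfs

    def run_metadata(self) -> dict:
        cfg = self.model.config
        return {
            "seed": self.seed,
            "k_range": ",".join(map(str, cfg.k_range)),
            "repeats": cfg.repeats,
            "n_fits": self.n_fits,
            "k_selected": self.K,
            "k_effective": self.K_effective,
            "elbo": self.elbo,
            "converged": self.converged,
            "error_rate": self.model._data.eps,
            "purity": self.model.meta.purity,
            "ploidy": self.model.meta.ploidy,
            "qc": "; ".join(self.qc_log) if self.qc_log else "none",
        }

    def summary(self) -> str:
        lines = ["Dual-breakend binomial mixture fit",
                 "=" * 42,
                 f"variants: {self.model._data.J}    purity: "
                 f"{self.model.meta.purity:.2f}",
                 f"clusters (post-QC): {self.K}    ELBO: {self.elbo:.3f}",
                 "",
                 f"{'cluster':>8} {'mean CCF':>10} {'sd':>8} "
                 f"{'weight':>8} {'n':>6}"]
        tab = self.cluster_table()
        for _, row in tab.iterrows():
            lines.append(f"{int(row.cluster):>8} {row.mean_ccf:>10.4f} "
                         f"{row.sd_ccf:>8.4f} {row.weight:>8.4f} "
                         f"{int(row.n_variants):>6}")
        if self.qc_log:
            lines += ["", "QC: " + "; ".join(self.qc_log)]
        return "\n".join(lines)

    def plot_ccf(self, ax=None, bins=40):
        """Histogram of representative variant CCFs with cluster means."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ccfs = self.variant_ccfs()["ccf"].dropna()
        ax.hist(ccfs, bins=bins, color="0.7")
        for mu in self.cluster_means:
            ax.axvline(mu, color="crimson", ls="--")
        ax.set_xlabel("cancer cell fraction")
        ax.set_ylabel("SV count")
        return ax

    def write(self, out_dir) -> dict:
        from .io_formats import write_results

        return write_results(self, self.model.variants, out_dir)

    # -- post-assignment ---------------------------------------------------

    def post_assign(self, variants: pd.DataFrame, cn_lo=None, cn_hi=None,
                    meta: SampleMeta | None = None) -> "BreakpointMixtureResults":
        from .postassign import post_assign

        return post_assign(variants, self, meta or self.model.meta,
                           cn_lo=cn_lo, cn_hi=cn_hi)
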