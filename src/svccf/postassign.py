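"""Assign variants to the clusters of an existing (reference) fit.

When a sample yields too few filtered SVs to cluster reliably (fewer than
about 10), or when variants were filtered out of the main fit, they can be
assigned to clusters inferred from another variant set — typically SVs onto
SNV-derived clusters or vice versa.  The reference posterior over cluster
CCFs ``q(phi)`` is frozen; only the assignments ``q(Z_post)`` and mixing
weights ``q(pi_post)`` are iterated to convergence, so the post-assignment
reflects the new variants' own proportions rather than mimicking the
reference mixing weights.  Multiplicities are re-estimated over the new
variants' own candidate sets.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import SampleMeta
from .model import (BreakpointMixture, BreakpointMixtureResults, ModelConfig,
                    _Quadrature, _VIState)

#: below this many filtered SVs, post-assignment onto a reference fit is
#: preferred over an independent fit
MIN_SVS_FOR_CLUSTERING = 10


@dataclass(frozen=True)
class ReferenceFit:
    """Minimal frozen reference: cluster CCF posterior means and variances.

    Stands in for a full results object when the reference clustering was
    produced by an earlier run (e.g. read back from a run directory, or an
    SNV clustering from another tool exporting Gaussian cluster CCFs).
    """

    cluster_means: np.ndarray
    cluster_vars: np.ndarray

    @property
    def K(self) -> int:
        return len(self.cluster_means)

    @classmethod
    def from_run_dir(cls, run_dir) -> "ReferenceFit":
        from pathlib import Path

        tab = pd.read_csv(Path(run_dir) / "cluster_summary.tsv", sep="\t")
        return cls(tab["mean_ccf"].to_numpy(float),
                   tab["sd_ccf"].to_numpy(float) ** 2)


class _FrozenPhiState(_VIState):
    """VI state whose q(phi) is pinned to the reference posterior."""

    def update_phi(self, n_newton: int = 4):  # noqa: ARG002 - frozen
        return


class PostAssignResults(BreakpointMixtureResults):
    """Results of a post-assignment run.

    Quality control differs from the main fit: clusters whose reference
    means are closer than the merge gap have their assignment labels merged,
    but the frozen reference means are never re-estimated; merged clusters
    report the responsibility-weighted mean of their reference means,
    flagged in ``qc_log``.
    """

    def _apply_qc(self) -> "PostAssignResults":
        cfg = self.model.config
        st = self._state

        occupied = np.unique(st.r.argmax(axis=1))
        if len(occupied) < st.K:
            self.qc_log.append(f"removed {st.K - len(occupied)} empty clusters")
            self._drop_clusters(occupied)
            self._refine()

        while st.K > 1:
            sizes = np.bincount(st.r.argmax(axis=1), minlength=st.K)
            small = np.flatnonzero(sizes < cfg.qc_small_frac * self.model._data.J)
            if len(small) == 0:
                break
            drop = small[np.argmin(sizes[small])]
            self.qc_log.append(f"removed small cluster {drop}")
            self._drop_clusters(np.array([k for k in range(st.K) if k != drop]))
            self._refine()

        # label-merge only: reference phi is frozen, report weighted means
        while st.K > 1:
            order = np.argsort(st.mu)
            gaps = np.diff(st.mu[order])
            idx = int(np.argmin(gaps))
            if gaps[idx] >= cfg.qc_merge_gap:
                break
            a, b = order[idx], order[idx + 1]
            wa = st.r[:, a].sum() + 1e-12
            wb = st.r[:, b].sum() + 1e-12
            self.qc_log.append(
                f"label-merged reference clusters at {st.mu[a]:.3f} and "
                f"{st.mu[b]:.3f} (reported mean is weight-averaged)")
            st.mu[a] = (wa * st.mu[a] + wb * st.mu[b]) / (wa + wb)
            st.s[a] = max(st.s[a], st.s[b])
            st.r[:, a] += st.r[:, b]
            st.alpha[a] += st.alpha[b] - st.alpha0
            self._drop_clusters(np.array([k for k in range(st.K) if k != b]))
            self._refine()
        return self


def post_assign(variants: pd.DataFrame,
                reference: BreakpointMixtureResults,
                meta: SampleMeta,
                cn_lo=None, cn_hi=None,
                config: ModelConfig | None = None) -> PostAssignResults:
    """Assign ``variants`` to the clusters of ``reference``.

    ``variants`` follows the model's input table (``id, b1, d1, b2, d2``)
    with optional per-end copy-number annotations.  Returns results for the
    new variants only; the reference fit is not modified.
    """
    if reference.K < 1:
        raise ValueError("reference fit has no clusters")
    cfg = config or (reference.model.config if hasattr(reference, "model")
                     else ModelConfig())
    model = BreakpointMixture(variants, meta, cn_lo=cn_lo, cn_hi=cn_hi,
                              config=cfg)
    quad = _Quadrature(cfg.n_quad)
    state = _FrozenPhiState(model._data, reference.K,
                            reference.cluster_means,
                            np.sqrt(reference.cluster_vars),
                            cfg.dirichlet_conc, cfg, quad)
    state.run()
    results = PostAssignResults(model, state, seed=cfg.seed, n_fits=1)
    results.qc_log.append("post-assignment against frozen reference CCFs")
    return results._apply_qc()
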