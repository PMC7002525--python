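"""The variational mixture: weights, multiplicities, fitting, QC, CCFs."""
import numpy as np
import pandas as pd
import pytest

from svccf import (BreakpointMixture, CNAnnotation, CNState, ModelConfig,
                   SampleMeta, annotations_from_dataset, compute_weight,
                   multiplicity_candidates, simulate_counts, variant_ccf,
                   SimConfig)
from tests.conftest import make_variant_table

FAST = ModelConfig(k_range=(1, 2, 3), repeats=2, seed=0)


class TestComputeWeight:
    def test_pure_diploid_limit(self, diploid):
        meta = SampleMeta(purity=1.0, error_rate=0.0)
        assert compute_weight(1, diploid, meta) == pytest.approx(0.5)

    def test_impure_diploid(self, diploid):
        # w = 0.8 * 1 / (0.2*2 + 0.8*2) = 0.4
        meta = SampleMeta(purity=0.8, error_rate=0.0)
        assert compute_weight(1, diploid, meta) == pytest.approx(0.4)

    def test_error_rate_contribution(self, diploid):
        # w = (0.999 - 2*0.001) / 2 = 0.4985 at t=1, m=1, n_tot=2
        meta = SampleMeta(purity=1.0, error_rate=1e-3)
        assert compute_weight(1, diploid, meta) == pytest.approx(0.4985)

    def test_subclonal_uses_weighted_total(self, subclonal_cn):
        meta = SampleMeta(purity=1.0, error_rate=0.0)
        n_tot = subclonal_cn.total_tumour
        assert compute_weight(1, subclonal_cn, meta) == pytest.approx(1 / n_tot)


class TestMultiplicityCandidates:
    def test_clonal_major_two(self):
        cn = CNAnnotation((CNState(2, 1, 1.0),))
        assert list(multiplicity_candidates(cn)) == [1.0, 2.0]

    def test_clonal_major_one(self, diploid):
        assert list(multiplicity_candidates(diploid)) == [1.0]

    def test_subclonal_enumeration(self):
        # rho = (0.7, 0.3), majors (2, 1): all weighted sums of per-clone
        # integer states
        cn = CNAnnotation((CNState(2, 0, 0.7), CNState(1, 1, 0.3)))
        cands = multiplicity_candidates(cn)
        assert list(cands) == pytest.approx([0.0, 0.3, 0.7, 1.0, 1.4, 1.7])

    def test_no_mutable_copies_raises(self):
        with pytest.raises(ValueError, match="no mutable"):
            multiplicity_candidates(CNAnnotation((CNState(0, 1, 1.0),)))


class TestVariantCCF:
    def test_identity_at_vaf_equal_weight(self):
        assert variant_ccf(0.4, 0.4, 0.0) == pytest.approx(1.0)

    def test_cap_at_two(self):
        assert variant_ccf(0.9, 0.1, 0.0) == 2.0

    def test_linear_transform(self):
        assert variant_ccf(0.24, 0.4, 0.0) == pytest.approx(0.6)

    def test_floor_at_zero(self):
        assert variant_ccf(0.0005, 0.4, 1e-3) == 0.0

    def test_nonpositive_weight_raises(self):
        with pytest.raises(ValueError):
            variant_ccf(0.3, 0.0, 0.0)

    def test_noiseless_limit_recovers_phi(self, diploid):
        # exact vaf = w * phi gives back phi for any phi below the cap
        meta = SampleMeta(purity=0.75, error_rate=1e-3)
        w = compute_weight(1, diploid, meta)
        for phi in (0.2, 0.5, 1.0, 1.5):
            vaf = w * phi + meta.error_rate
            assert variant_ccf(vaf, w, meta.error_rate) == pytest.approx(phi)


class TestFit:
    def test_single_clone_recovery(self, meta):
        rng = np.random.default_rng(1)
        w = compute_weight(1, CNAnnotation.default(), meta)
        df = make_variant_table(rng, 100, 1.0, w)
        res = BreakpointMixture(df, meta, config=FAST).fit()
        assert res.K_effective == 1
        assert abs(res.cluster_means[0] - 1.0) < 0.05

    def test_two_clone_recovery(self, meta):
        cfg = SimConfig(n_sv=(50, 50), clone_ccfs=(1.0, 0.4), purity=0.75,
                        depth=100, seed=11)
        ds, _ = simulate_counts(cfg)
        cn_lo, cn_hi = annotations_from_dataset(ds)
        res = BreakpointMixture(ds, cfg.meta(), cn_lo=cn_lo, cn_hi=cn_hi,
                                config=FAST).fit()
        assert res.K_effective == 2
        mus = np.sort(res.cluster_means)
        assert np.abs(mus - [0.4, 1.0]).max() < 0.05

    def test_duplicated_data_same_means(self, meta):
        rng = np.random.default_rng(2)
        df = make_variant_table(rng, 60, 1.0, 0.375)
        dup = pd.concat([df, df.assign(id=df["id"] + "_dup")],
                        ignore_index=True)
        res1 = BreakpointMixture(df, meta, config=FAST).fit()
        res2 = BreakpointMixture(dup, meta, config=FAST).fit()
        assert np.abs(np.sort(res1.cluster_means)
                      - np.sort(res2.cluster_means)).max() < 0.02

    def test_elbo_monotone_every_fit(self, meta):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            df = make_variant_table(rng, 40, 0.7, 0.375)
            res = BreakpointMixture(df, meta, config=ModelConfig(
                k_range=(1, 2), repeats=1, seed=seed)).fit()
            diffs = np.diff(res.elbo_trace)
            assert np.all(diffs >= -1e-8)

    def test_responsibilities_rows_sum_to_one(self, meta):
        rng = np.random.default_rng(3)
        df = make_variant_table(rng, 50, 0.8, 0.375)
        res = BreakpointMixture(df, meta, config=FAST).fit()
        np.testing.assert_allclose(res.responsibilities.sum(axis=1), 1.0,
                                   atol=1e-9)
        assert np.all(res._state.alpha >= res.model.config.dirichlet_conc)

    def test_run_metadata_records_search(self, meta):
        rng = np.random.default_rng(4)
        df = make_variant_table(rng, 30, 1.0, 0.375)
        res = BreakpointMixture(df, meta).fit()  # default config
        md = res.run_metadata()
        assert md["k_range"] == "1,2,3,4,5,6"
        assert md["repeats"] == 5
        assert md["n_fits"] == 30

    def test_single_end_degeneracy(self, meta):
        # masking one end (d=0) reproduces the single-end likelihood exactly
        from svccf.model import _ModelData, _binom_logpmf

        rng = np.random.default_rng(5)
        df = make_variant_table(rng, 20, 1.0, 0.375)
        df2 = df.copy()
        df2["b2"], df2["d2"] = 0, 0
        default = CNAnnotation.default()
        data = _ModelData(df2["id"], df2[["b1", "b2"]].to_numpy(),
                          df2[["d1", "d2"]].to_numpy(),
                          [default] * 20, [default] * 20, meta,
                          meta.error_rate)
        w = data.weights(np.ones((20, 2)))
        phi = 0.9
        f = w * phi + meta.error_rate
        ll_dual = _binom_logpmf(data.b, data.d, f).sum(axis=1)
        ll_single = _binom_logpmf(df["b1"].to_numpy(float),
                                  df["d1"].to_numpy(float), f[:, 0])
        np.testing.assert_allclose(ll_dual, ll_single, rtol=1e-12)


class TestMultiplicityEstimation:
    def brute_force(self, b, d, cands, w_of, phi_nodes, qweights, r_j, eps):
        from svccf.model import _binom_logpmf

        best, best_score = None, -np.inf
        for m in cands:
            w = w_of(m)
            f = w * phi_nodes + eps
            ell = _binom_logpmf(b, d, f) @ qweights      # (K,)
            score = float(ell @ r_j)
            if score > best_score + 1e-12:
                best, best_score = m, score
        return best

    def test_update_matches_brute_force(self):
        # exhaustive maximisation over the candidate set on random variants
        # with amplified and subclonal backgrounds
        rng = np.random.default_rng(7)
        meta = SampleMeta(purity=0.7)
        n = 60
        anns = []
        for _ in range(n):
            if rng.random() < 0.5:
                anns.append(CNAnnotation((CNState(int(rng.integers(1, 5)),
                                                  1, 1.0),)))
            else:
                rho = rng.uniform(0.2, 0.8)
                anns.append(CNAnnotation((
                    CNState(int(rng.integers(1, 4)), 1, round(rho, 2)),
                    CNState(int(rng.integers(1, 3)), 1, round(1 - rho, 2)))))
        d = rng.poisson(80, (n, 2)).clip(min=10)
        b = rng.binomial(d, rng.uniform(0.05, 0.6, (n, 2)))
        df = pd.DataFrame({"id": [f"v{i}" for i in range(n)],
                           "b1": b[:, 0], "d1": d[:, 0],
                           "b2": b[:, 1], "d2": d[:, 1]})
        model = BreakpointMixture(df, meta, cn_lo=anns, cn_hi=anns,
                                  config=ModelConfig(k_range=(2,), repeats=1))
        state = model._init_state(2, np.random.default_rng(0), jitter=False)
        state.update_z()
        state.update_m()
        phi = state._phi_nodes()
        for j in range(n):
            for i in range(2):
                cands = state.data.xi[j][i]
                expect = self.brute_force(
                    state.data.b[j, i], state.data.d[j, i], cands,
                    lambda m: state.data.weight_of(j, i, m), phi,
                    state.quad.weights, state.r[j], state.data.eps)
                assert state.m[j, i] == pytest.approx(expect)


class TestQC:
    def _fit_two_groups(self, meta, mu1, mu2, n1=60, n2=60, seed=0):
        rng = np.random.default_rng(seed)
        w = 0.375
        a = make_variant_table(rng, n1, mu1, w, depth=300)
        b = make_variant_table(rng, n2, mu2, w, depth=300)
        b["id"] = b["id"] + "_b"
        df = pd.concat([a, b], ignore_index=True)
        cfg = ModelConfig(k_range=(2,), repeats=2, seed=seed)
        return BreakpointMixture(df, meta, config=cfg).fit()

    def test_close_clusters_merge(self, meta):
        # means 0.92 and 0.88 are 4% apart: under the 10% merge rule
        res = self._fit_two_groups(meta, 0.92, 0.88)
        assert res.K == 1

    def test_separated_clusters_survive(self, meta):
        # 15% apart: no merge
        res = self._fit_two_groups(meta, 1.0, 0.85)
        assert res.K == 2

    def test_small_cluster_removed(self, meta):
        # 1 variant of 200 (0.5%) below the 1% rule
        res = self._fit_two_groups(meta, 1.0, 0.4, n1=199, n2=1)
        assert res.K == 1

    def test_two_percent_cluster_survives(self, meta):
        res = self._fit_two_groups(meta, 1.0, 0.4, n1=196, n2=4)
        assert res.K == 2
        assert np.sort(res.cluster_table()["n_variants"])[0] == 4
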