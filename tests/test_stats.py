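"""Vertex-wise GLM, RFT cluster correction, permutation oracle,
partial correlation."""

import numpy as np
import pytest
from scipy import stats as ss

from amygshape import meshes, stats as vstats


@pytest.fixture(scope="module")
def sphere3(ico3):
    return ico3


class TestGLM:
    def test_hand_data_matches_bruteforce(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([1.0, 3, 2, 5, 4])
        sm = vstats.fit_vertexwise_glm(y[:, None], x)
        r = np.corrcoef(x, y)[0, 1]
        t_expect = r * np.sqrt(3 / (1 - r ** 2))
        assert sm.t[0] == pytest.approx(t_expect, abs=1e-12)
        assert sm.p[0] == pytest.approx(2 * ss.t.sf(abs(t_expect), 3), abs=1e-12)

    def test_direction_equivalence_via_statsmodels(self):
        """The t of the slope is identical whichever variable is the
        regressor (independent check through OLS)."""
        import statsmodels.api as smapi

        rng = np.random.default_rng(0)
        x = rng.standard_normal(24)
        y = 0.5 * x + rng.standard_normal(24)
        t_ours = vstats.fit_vertexwise_glm(y[:, None], x).t[0]
        t_xy = smapi.OLS(y, smapi.add_constant(x)).fit().tvalues[1]
        t_yx = smapi.OLS(x, smapi.add_constant(y)).fit().tvalues[1]
        assert t_ours == pytest.approx(t_xy, abs=1e-10)
        assert t_ours == pytest.approx(t_yx, abs=1e-10)

    def test_perfect_fit(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        sm = vstats.fit_vertexwise_glm((2 * x + 1)[:, None], x)
        assert sm.t[0] > 1e6
        assert sm.p[0] < 1e-12

    def test_constant_vertex_flagged(self):
        x = np.array([1.0, 2, 3, 4])
        maps = np.column_stack([np.ones(4), x])
        sm = vstats.fit_vertexwise_glm(maps, x)
        assert sm.t[0] == 0 and sm.p[0] == 1.0
        assert 0 in sm.constant_vertices

    def test_null_p_uniform(self):
        """Independent null vertices: uncorrected p is Uniform(0,1)."""
        rng = np.random.default_rng(1)
        maps = rng.standard_normal((24, 10000))
        scores = rng.standard_normal(24)
        sm = vstats.fit_vertexwise_glm(maps, scores)
        assert ss.kstest(sm.p, "uniform").pvalue > 0.01


class TestRFT:
    def test_zero_map_no_clusters(self, sphere3):
        smap = vstats.StatMap(t=np.zeros(len(sphere3.vertices)), df=22,
                              p=np.ones(len(sphere3.vertices)))
        assert vstats.rft_cluster_correction(smap, sphere3, fwhm=0.5) == []

    def test_fwhm_zero_rejected(self, sphere3):
        smap = vstats.StatMap(t=np.zeros(len(sphere3.vertices)), df=22,
                              p=np.ones(len(sphere3.vertices)))
        with pytest.raises(ValueError):
            vstats.rft_cluster_correction(smap, sphere3, fwhm=0.0)

    def test_cluster_p_monotone_in_extent(self, sphere3):
        """Bigger suprathreshold blob, all else equal -> smaller p."""
        v = np.asarray(sphere3.vertices)
        ps = []
        for radius in (0.25, 0.45):
            t = np.where(np.arccos(np.clip(v @ v[0], -1, 1)) < radius, 6.0, 0.0)
            smap = vstats.StatMap(t=t, df=22, p=np.ones(len(v)))
            res = vstats.rft_cluster_correction(smap, sphere3, fwhm=0.5)
            assert len(res) == 1
            ps.append(res[0].p_rft)
        assert ps[1] < ps[0]

    def test_clusters_are_connected(self, sphere3):
        v = np.asarray(sphere3.vertices)
        # two antipodal blobs -> two separate clusters
        g1 = np.arccos(np.clip(v @ v[0], -1, 1)) < 0.3
        g2 = np.arccos(np.clip(v @ -v[0], -1, 1)) < 0.3
        t = np.where(g1 | g2, 6.0, 0.0)
        smap = vstats.StatMap(t=t, df=22, p=np.ones(len(v)))
        res = vstats.rft_cluster_correction(smap, sphere3, fwhm=0.5)
        assert len(res) == 2
        assert {frozenset(c.vertices.tolist()) for c in res} == \
            {frozenset(np.nonzero(g1)[0].tolist()),
             frozenset(np.nonzero(g2)[0].tolist())}


class TestPermutationOracle:
    def _bump_cohort(self, mesh, seed=0, gain=1.0):
        rng = np.random.default_rng(seed)
        n = 24
        scores = rng.standard_normal(n)
        v = np.asarray(mesh.vertices)
        profile = np.exp(-np.arccos(np.clip(v @ v[0], -1, 1)) ** 2 / 0.08)
        maps = (gain * np.outer(scores, profile)
                + 0.3 * rng.standard_normal((n, len(v))))
        return maps, scores

    def test_strong_signal_hits_floor(self, sphere3):
        maps, scores = self._bump_cohort(sphere3, gain=3.0)
        res = vstats.permutation_cluster_oracle(maps, scores, sphere3,
                                                n_perm=500, seed=3)
        best = min(c.p_perm for c in res)
        assert best == pytest.approx(1 / 501)

    def test_seed_determinism(self, sphere3):
        maps, scores = self._bump_cohort(sphere3, gain=1.0)
        a = vstats.permutation_cluster_oracle(maps, scores, sphere3,
                                              n_perm=500, seed=9)
        b = vstats.permutation_cluster_oracle(maps, scores, sphere3,
                                              n_perm=500, seed=9)
        assert [c.p_perm for c in a] == [c.p_perm for c in b]

    def test_min_permutations_enforced(self, sphere3):
        maps, scores = self._bump_cohort(sphere3)
        with pytest.raises(ValueError):
            vstats.permutation_cluster_oracle(maps, scores, sphere3, n_perm=100)


class TestPartialCorrelation:
    def _cluster(self, mesh, k=10):
        return vstats.ClusterResult(vertices=np.arange(k), extent_mm2=1.0,
                                    peak_t=0.0, p_rft=0.01)

    def test_matches_recursion_formula_oracle(self, sphere3):
        """r_xy.z from the correlation-matrix recursion, an independent
        route to the same quantity as two-stage residualization."""
        rng = np.random.default_rng(5)
        n = 30
        maps = rng.standard_normal((n, len(sphere3.vertices)))
        stai = rng.standard_normal(n)
        sds = 0.5 * stai + rng.standard_normal(n)
        cl = self._cluster(sphere3)
        r_ours, p_ours = vstats.cluster_partial_correlation(
            maps, cl, stai, sds, sphere3)
        w = vstats.vertex_areas(sphere3)[cl.vertices]
        avg = maps[:, cl.vertices] @ (w / w.sum())
        rxy = np.corrcoef(avg, stai)[0, 1]
        rxz = np.corrcoef(avg, sds)[0, 1]
        ryz = np.corrcoef(stai, sds)[0, 1]
        r_expect = (rxy - rxz * ryz) / np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
        assert r_ours == pytest.approx(r_expect, abs=1e-12)

    def test_matches_pingouin(self, sphere3):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(6)
        n = 40
        maps = rng.standard_normal((n, len(sphere3.vertices)))
        stai = rng.standard_normal(n)
        sds = 0.4 * stai + rng.standard_normal(n)
        cl = self._cluster(sphere3)
        r_ours, p_ours = vstats.cluster_partial_correlation(
            maps, cl, stai, sds, sphere3)
        w = vstats.vertex_areas(sphere3)[cl.vertices]
        df = pd.DataFrame({"avg": maps[:, cl.vertices] @ (w / w.sum()),
                           "stai": stai, "sds": sds})
        res = pg.partial_corr(df, x="avg", y="stai", covar="sds")
        assert r_ours == pytest.approx(float(res["r"].iloc[0]), abs=1e-9)
        assert p_ours == pytest.approx(float(res["p_val"].iloc[0]), abs=1e-9)

    def test_no_confounding_limit(self, sphere3):
        rng = np.random.default_rng(7)
        n = 2000
        maps = rng.standard_normal((n, len(sphere3.vertices)))
        stai = 0.3 * maps[:, :10].mean(axis=1) + rng.standard_normal(n)
        sds = rng.standard_normal(n)  # independent of both
        cl = self._cluster(sphere3)
        r_part, _ = vstats.cluster_partial_correlation(maps, cl, stai, sds,
                                                       sphere3)
        w = vstats.vertex_areas(sphere3)[cl.vertices]
        avg = maps[:, cl.vertices] @ (w / w.sum())
        r_simple = np.corrcoef(avg, stai)[0, 1]
        assert r_part == pytest.approx(r_simple, abs=0.05)

    def test_full_mediation_limit(self, sphere3):
        rng = np.random.default_rng(8)
        n = 500
        sds = rng.standard_normal(n)
        maps = np.tile(sds[:, None], (1, len(sphere3.vertices)))
        maps = maps + 1e-6 * rng.standard_normal(maps.shape)
        stai = rng.standard_normal(n)
        cl = self._cluster(sphere3)
        r_part, _ = vstats.cluster_partial_correlation(maps, cl, stai, sds,
                                                       sphere3)
        assert abs(r_part) < 0.1

    def test_constant_sds_warns(self, sphere3):
        rng = np.random.default_rng(9)
        maps = rng.standard_normal((10, len(sphere3.vertices)))
        stai = rng.standard_normal(10)
        with pytest.warns(UserWarning, match="constant"):
            vstats.cluster_partial_correlation(maps, self._cluster(sphere3),
                                               stai, np.ones(10), sphere3)
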