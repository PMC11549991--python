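"""Edge-wise GLM, supra-threshold components, permutation FWE inference."""

from itertools import combinations

import numpy as np
import pytest

from connstats import (
    SyntheticSpec,
    build_design,
    edgewise_glm_t,
    generate_cohort,
    nbs_test,
    supra_threshold_components,
    threshold_sweep_report,
)
from connstats.synth import default_effect_edges


def pooled_two_sample_t(a: np.ndarray, b: np.ndarray) -> float:
    """Textbook pooled-variance two-sample t (oracle)."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


class DSU:
    """Union-find oracle for connected components."""

    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


def dsu_components(t, threshold):
    n = t.shape[0]
    dsu = DSU(n)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if t[i, j] > threshold:
                dsu.union(i, j)
                edges.append((i, j))
    comps = {}
    for i, j in edges:
        comps.setdefault(dsu.find(i), []).append((i, j))
    return sorted((sorted(e) for e in comps.values()), key=len, reverse=True)


class TestEdgewiseGLM:
    def test_identical_groups_give_zero_t(self, make_connectome):
        import pandas as pd

        from connstats import CohortTable

        w = np.ones((4, 4)) - np.eye(4)
        conns = [make_connectome(w, f"s{i}") for i in range(6)]
        cohort = CohortTable(
            pd.DataFrame(
                {
                    "subject_id": [f"s{i}" for i in range(6)],
                    "group": ["noPAE"] * 3 + ["PAE_T1T3"] * 3,
                    "age": [7.0, 7.1, 7.2] * 2,
                    "sex": [0, 1, 0, 1, 0, 1],
                    "icv": [1500.0, 1520, 1480, 1510, 1490, 1530],
                }
            )
        )
        design = build_design(cohort, "noPAE", "PAE_T1T3")
        t = edgewise_glm_t(conns, design)
        assert np.all(t == 0.0)

    def test_covariate_free_design_matches_pooled_t(self, small_cohort):
        design = build_design(
            small_cohort.cohort, "noPAE", "PAE_T1T3", covariates=()
        )
        t = edgewise_glm_t(small_cohort.connectomes, design)
        groups = small_cohort.cohort.groups.to_numpy()
        iu = np.triu_indices(82, 1)
        rng = np.random.default_rng(0)
        for k in rng.choice(len(iu[0]), size=15, replace=False):
            i, j = iu[0][k], iu[1][k]
            y = np.array([c.weights[i, j] for c in small_cohort.connectomes])
            a = y[groups == "noPAE"]
            b = y[groups == "PAE_T1T3"]
            assert t[i, j] == pytest.approx(pooled_two_sample_t(a, b), rel=1e-9)

    def test_matches_statsmodels_with_covariates(self, small_cohort):
        import statsmodels.api as sm

        design = build_design(small_cohort.cohort, "noPAE", "PAE_T1T3")
        t = edgewise_glm_t(small_cohort.connectomes, design)
        i, j = 0, 1  # a planted effect edge
        y = np.array(
            [small_cohort.connectomes[s].weights[i, j] for s in design.subject_index]
        )
        fit = sm.OLS(y, design.x).fit()
        assert t[i, j] == pytest.approx(fit.tvalues[1], rel=1e-9)

    def test_planted_effect_raises_t_on_affected_edges(self, small_cohort):
        design = build_design(small_cohort.cohort, "noPAE", "PAE_T1T3")
        t = edgewise_glm_t(small_cohort.connectomes, design)
        edges = default_effect_edges(small_cohort.truth.partition_true)
        iu = np.triu_indices(82, 1)
        affected = np.mean([t[i, j] for i, j in edges])
        overall = t[iu].mean()
        assert affected > overall

    def test_rank_deficient_design_rejected(self, small_cohort):
        import pandas as pd

        from connstats import CohortTable

        df = small_cohort.cohort.table.copy()
        df["icv"] = 1500.0  # constant covariate -> collinear with intercept
        with pytest.raises(ValueError, match="rank"):
            build_design(CohortTable(df), "noPAE", "PAE_T1T3")


class TestComponents:
    def test_no_supra_threshold_edges_gives_empty_list(self):
        assert supra_threshold_components(np.zeros((5, 5)), 2.0) == []

    def test_five_edge_path_is_one_component(self):
        t = np.zeros((8, 8))
        for i in range(5):
            t[i, i + 1] = t[i + 1, i] = 3.0
        comps = supra_threshold_components(t, 2.0)
        assert len(comps) == 1
        assert comps[0].n_nodes == 6 and comps[0].n_edges == 5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.normal(size=(12, 12)) * 2
        t = np.triu(t, 1) + np.triu(t, 1).T
        got = supra_threshold_components(t, 2.0)
        want = dsu_components(t, 2.0)
        assert [sorted(c.edges) for c in got] == [
            [tuple(e) for e in comp] for comp in want
        ]

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            supra_threshold_components(np.zeros((3, 3)), 0.0)


def _tiny_cohort(n_per=4, effect=0.5, seed=0):
    spec = SyntheticSpec(
        n_nodes=12,
        partition_true=__import__("connstats").Partition(np.repeat([1, 2], 6)),
        hub_nodes=(0,),
        hub_boost=1.0,
        effect_edges=((0, 1), (0, 2), (1, 2)),
        effect_size=effect,
        noise_cv=0.3,
        icv_exponent=0.0,
    )
    return generate_cohort(spec, (n_per, 2, n_per), seed=seed)


class TestNBS:
    def test_exhaustive_p_matches_enumeration_oracle(self):
        """4-vs-4 cohort: all 70 relabelings enumerated independently."""
        cohort = _tiny_cohort()
        design = build_design(cohort.cohort, "noPAE", "PAE_T1T3", covariates=())
        res = nbs_test(cohort.connectomes, design, 2.0, n_perm=10**6, seed=0)
        assert res.exhaustive and res.n_perm == 70

        # independent oracle: pooled t per edge, DSU components, all C(8,4)
        conns = [cohort.connectomes[i] for i in design.subject_index]
        y = np.vstack([c.upper_values() for c in conns])
        n = conns[0].n_nodes

        def max_comp(indicator):
            tmat = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            for k in range(y.shape[1]):
                a = y[indicator == 1, k]
                b = y[indicator == 0, k]
                denom = (
                    ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                    / (len(a) + len(b) - 2)
                    * (1 / len(a) + 1 / len(b))
                )
                tv = 0.0 if denom == 0 else (a.mean() - b.mean()) / np.sqrt(denom)
                tmat[iu[0][k], iu[1][k]] = tmat[iu[1][k], iu[0][k]] = tv
            comps = dsu_components(tmat, 2.0)
            return len(comps[0]) if comps else 0

        obs = max_comp(design.x[:, 1])
        null = [
            max_comp(np.isin(np.arange(8), idx).astype(float))
            for idx in combinations(range(8), 4)
        ]
        for comp, p in zip(res.components, res.p_fwe):
            expect = sum(m >= comp.n_edges for m in null) / 70
            assert p == pytest.approx(expect)
        assert res.max_component_size == obs

    def test_p_floor_and_range(self):
        cohort = _tiny_cohort(n_per=6, effect=0.6, seed=1)
        design = build_design(cohort.cohort, "noPAE", "PAE_T1T3")
        res = nbs_test(cohort.connectomes, design, 2.1, n_perm=99, seed=2)
        assert np.all(res.p_fwe > 0) and np.all(res.p_fwe <= 1)
        assert np.all(res.p_fwe >= 1 / (res.n_perm + 1))

    def test_invariant_to_subject_ordering(self):
        cohort = _tiny_cohort(seed=3)
        design = build_design(cohort.cohort, "noPAE", "PAE_T1T3", covariates=())
        res = nbs_test(cohort.connectomes, design, 2.0, n_perm=10**6, seed=0)

        order = np.random.default_rng(1).permutation(len(cohort.cohort))
        ids = [cohort.cohort.subject_ids[i] for i in order]
        cohort_shuf = cohort.cohort.subset(ids)
        conns_shuf = [cohort.connectomes[i] for i in order]
        design2 = build_design(cohort_shuf, "noPAE", "PAE_T1T3", covariates=())
        res2 = nbs_test(conns_shuf, design2, 2.0, n_perm=10**6, seed=0)
        np.testing.assert_allclose(sorted(res.p_fwe), sorted(res2.p_fwe))

    def test_invariant_to_uniform_scaling_without_icv(self, make_connectome):
        cohort = _tiny_cohort(seed=4)
        design = build_design(cohort.cohort, "noPAE", "PAE_T1T3", covariates=("age", "sex"))
        res = nbs_test(cohort.connectomes, design, 2.0, n_perm=10**6, seed=0)
        scaled = [
            make_connectome(c.weights * 3.7, c.subject_id) for c in cohort.connectomes
        ]
        res2 = nbs_test(scaled, design, 2.0, n_perm=10**6, seed=0)
        np.testing.assert_allclose(res.p_fwe, res2.p_fwe)

    def test_max_component_monotone_in_threshold(self):
        cohort = _tiny_cohort(n_per=6, seed=5)
        design = build_design(cohort.cohort, "noPAE", "PAE_T1T3")
        sizes = [
            nbs_test(cohort.connectomes, design, thr, n_perm=5, seed=0).max_component_size
            for thr in (1.5, 2.0, 2.5, 3.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestSweepReport:
    def test_one_row_per_threshold(self):
        cohort = _tiny_cohort(n_per=5, seed=6)
        design = build_design(cohort.cohort, "noPAE", "PAE_T1T3")
        rep = threshold_sweep_report(
            cohort.connectomes, design, [2.1, 2.2, 2.3, 2.4, 2.5], n_perm=19, seed=0
        )
        assert len(rep) == 5
        assert rep["threshold"].tolist() == [2.1, 2.2, 2.3, 2.4, 2.5]

    def test_very_high_threshold_gives_dashes(self):
        cohort = _tiny_cohort(n_per=4, effect=0.0, seed=7)
        design = build_design(cohort.cohort, "noPAE", "PAE_T1T3")
        rep = threshold_sweep_report(
            cohort.connectomes, design, [50.0], n_perm=19, seed=0
        )
        assert rep.loc[0, ["nodes", "edges", "p"]].isna().all()

    def test_row_sizes_equal_direct_nbs_call(self):
        cohort = _tiny_cohort(n_per=5, seed=8)
        design = build_design(cohort.cohort, "noPAE", "PAE_T1T3")
        rep = threshold_sweep_report(
            cohort.connectomes, design, [2.0], n_perm=19, seed=0
        )
        direct = nbs_test(cohort.connectomes, design, 2.0, n_perm=19, seed=0)
        if direct.components:
            assert rep.loc[0, "edges"] == direct.components[0].n_edges
            assert rep.loc[0, "nodes"] == direct.components[0].n_nodes
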