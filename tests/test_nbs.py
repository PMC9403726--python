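"""Edgewise GLM, component extraction and permutation FWE behaviour."""

import numpy as np
import pandas as pd
import pytest

from neoconn.io import Connectome
from neoconn.nbs import (
    DesignSpec,
    T_CAP,
    default_sweep_thresholds,
    edgewise_glm,
    extract_components,
    nbs_test,
    sensitivity_sweep,
)
from neoconn.behavior import age_adjust

import oracles
from conftest import NBS_COVARIATES, make_cohort_frame


def _toy_connectomes(weights_per_subject, n_nodes, sids):
    """Connectomes with edge (0,1) set per subject, others fixed at 1."""
    conns = []
    for sid, w01 in zip(sids, weights_per_subject):
        w = np.ones((n_nodes, n_nodes)) - np.eye(n_nodes)
        w[0, 1] = w[1, 0] = w01
        conns.append(Connectome(sid, w, [f"n{i}" for i in range(n_nodes)]))
    return conns


def _adjusted(cohort, outcome="externalizing_raw"):
    adj = age_adjust(cohort[outcome], cohort["corrected_age_followup"])
    cohort = cohort.copy()
    cohort["score_adj"] = adj["age_adjusted"]
    return cohort


class TestDesignSpec:
    def test_predictor_cannot_be_covariate(self):
        with pytest.raises(ValueError):
            DesignSpec(predictor="x", covariates=("x",))

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            DesignSpec(predictor="x", alpha=1.5)


class TestEdgewiseGLM:
    def test_perfect_fit_capped_t_and_exact_beta(self):
        n = 8
        cohort = make_cohort_frame(n)
        pred = np.arange(n, dtype=float)
        cohort["score_adj"] = pred
        conns = _toy_connectomes(2 * pred + 5, 6, cohort["subject_id"])
        design = DesignSpec(predictor="score_adj", covariates=(), n_permutations=10)
        glm = edgewise_glm(cohort, conns, design)
        k = [tuple(p) for p in glm.pairs].index((0, 1))
        assert glm.beta[k] == pytest.approx(2.0)
        assert glm.t[k] == T_CAP

    def test_single_edge_matches_hand_ols(self):
        subjects = 6
        cohort = make_cohort_frame(subjects)
        pred = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        y01 = np.array([2.1, 5.9, 4.2, 10.3, 8.0, 12.5])
        cohort["score_adj"] = pred
        conns = _toy_connectomes(y01, 5, cohort["subject_id"])
        design = DesignSpec(predictor="score_adj", covariates=(), n_permutations=10)
        glm = edgewise_glm(cohort, conns, design)
        k = [tuple(p) for p in glm.pairs].index((0, 1))
        beta_o, t_o = oracles.ols_t([np.ones(subjects), pred], y01)
        assert glm.beta[k] == pytest.approx(beta_o)
        assert glm.t[k] == pytest.approx(t_o)

    def test_null_t_distribution_is_student(self, rng):
        # simulated null edges; t values should follow Student's t
        from scipy import stats

        n = 30
        cohort = make_cohort_frame(n, seed=4)
        cohort["score_adj"] = rng.normal(size=n)
        conns = []
        for sid in cohort["subject_id"]:
            w = np.zeros((16, 16))
            iu, ju = np.triu_indices(16, k=1)
            w[iu, ju] = rng.lognormal(2, 0.3, iu.size)
            w = w + w.T
            conns.append(Connectome(sid, w, [f"n{i}" for i in range(16)]))
        design = DesignSpec(predictor="score_adj", covariates=(), n_permutations=10)
        glm = edgewise_glm(cohort, conns, design)
        # weights are independent of the predictor: KS vs t(n-2) not extreme
        ks = stats.kstest(glm.t, stats.t(df=glm.df_resid).cdf)
        assert ks.pvalue > 1e-3

    def test_exchangeability_of_subject_order(self, planted_cohort, rng):
        cohort = _adjusted(planted_cohort.cohort)
        design = DesignSpec(
            predictor="score_adj", covariates=NBS_COVARIATES, n_permutations=10
        )
        glm1 = edgewise_glm(cohort, planted_cohort.connectomes, design)
        perm = rng.permutation(len(cohort))
        cohort2 = cohort.iloc[perm].reset_index(drop=True)
        conns2 = [planted_cohort.connectomes[i] for i in perm]
        glm2 = edgewise_glm(cohort2, conns2, design)
        np.testing.assert_allclose(glm1.t, glm2.t, atol=1e-8)

    def test_too_few_subjects_raises(self):
        cohort = make_cohort_frame(4)
        cohort["score_adj"] = [1.0, 2.0, 3.0, 4.0]
        conns = _toy_connectomes([1, 2, 3, 4], 4, cohort["subject_id"])
        design = DesignSpec(predictor="score_adj", covariates=NBS_COVARIATES)
        with pytest.raises(ValueError):
            edgewise_glm(cohort, conns, design)


class TestComponents:
    def test_path_and_isolated_edge(self):
        pairs = np.array([(0, 1), (1, 2), (2, 3), (5, 6), (8, 9)])
        t = np.array([-4.0, -4.0, -4.0, -4.0, -1.0])
        comps = extract_components(
            t, pairs, [f"n{i}" for i in range(10)], 3.1, "negative"
        )
        assert [c.extent for c in comps] == [3, 1]
        assert comps[0].nodes == ("n0", "n1", "n2", "n3")

    def test_no_supra_threshold_edges(self):
        pairs = np.array([(0, 1)])
        comps = extract_components(
            np.array([-1.0]), pairs, ["a", "b"], 3.1, "negative"
        )
        assert comps == []

    def test_all_edges_one_component(self):
        pairs = np.array([(0, 1), (1, 2), (0, 2)])
        comps = extract_components(
            np.array([5.0, 5.0, 5.0]), pairs, ["a", "b", "c"], 3.1, "positive"
        )
        assert len(comps) == 1 and comps[0].extent == 3

    def test_direction_sign_convention(self):
        pairs = np.array([(0, 1), (1, 2)])
        t = np.array([-4.0, 4.0])
        neg = extract_components(t, pairs, ["a", "b", "c"], 3.1, "negative")
        pos = extract_components(t, pairs, ["a", "b", "c"], 3.1, "positive")
        assert [c.edges[0] for c in neg] == [("a", "b")]
        assert [c.edges[0] for c in pos] == [("b", "c")]

    def test_matches_bfs_oracle_on_random_graphs(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 15))
            iu, ju = np.triu_indices(n, k=1)
            keep = rng.random(iu.size) < 0.3
            pairs = np.column_stack([iu[keep], ju[keep]])
            if pairs.size == 0:
                continue
            t = np.full(len(pairs), 5.0)
            comps = extract_components(
                t, pairs, [f"n{i:02d}" for i in range(n)], 3.1, "positive"
            )
            oracle = oracles.connected_components_bfs(
                [(int(a), int(b)) for a, b in pairs]
            )
            got = {frozenset(int(x[1:]) for x in c.nodes) for c in comps}
            assert got == set(oracle)


class TestPermutationTest:
    def test_seed_determinism(self, planted_cohort):
        cohort = _adjusted(planted_cohort.cohort)
        design = DesignSpec(
            predictor="score_adj", covariates=NBS_COVARIATES,
            n_permutations=50, seed=99,
        )
        r1 = nbs_test(cohort, planted_cohort.connectomes, design)
        r2 = nbs_test(cohort, planted_cohort.connectomes, design)
        np.testing.assert_array_equal(r1.null_max_extents, r2.null_max_extents)
        assert [c.p_fwe for c in r1.components] == [c.p_fwe for c in r2.components]

    def test_p_floor_is_one_over_nperm_plus_one(self, planted_cohort):
        cohort = _adjusted(planted_cohort.cohort)
        design = DesignSpec(
            predictor="score_adj", covariates=NBS_COVARIATES,
            n_permutations=200, seed=5,
        )
        res = nbs_test(cohort, planted_cohort.connectomes, design)
        top = res.components[0]
        if (res.null_max_extents < top.extent).all():
            assert top.p_fwe == pytest.approx(1 / 201)
        assert top.p_fwe >= 1 / 201

    def test_planted_subnetwork_detected(self, planted_cohort):
        cohort = _adjusted(planted_cohort.cohort)
        design = DesignSpec(
            predictor="score_adj", covariates=NBS_COVARIATES,
            n_permutations=200, seed=17,
        )
        res = nbs_test(cohort, planted_cohort.connectomes, design)
        assert res.significant
        truth = set(planted_cohort.truth["effect_edges"])
        rec = set(res.significant[0].edges)
        jaccard = len(rec & truth) / len(rec | truth)
        assert jaccard > 0.5


class TestSensitivitySweep:
    def test_default_grid_is_eleven_thresholds(self):
        th = default_sweep_thresholds()
        assert len(th) == 11
        assert th[0] == 2.5 and th[-1] == 3.5

    def test_extent_nonincreasing_and_shared_permutations(self, planted_cohort):
        cohort = _adjusted(planted_cohort.cohort)
        design = DesignSpec(
            predictor="score_adj", covariates=NBS_COVARIATES,
            n_permutations=50, seed=23,
        )
        sweep = sensitivity_sweep(
            cohort, planted_cohort.connectomes, design,
            thresholds=[2.5, 3.0, 3.5],
        )
        summary = sweep.summary()
        extents = summary["max_extent"].to_numpy()
        assert (np.diff(extents) <= 0).all()
        # planted effect stays significant across a contiguous band
        sig = summary["significant"].to_numpy()
        assert sig.any()
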