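import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import lineagescore as ls


def _clinical(time, event, index=None, **covs):
    idx = index if index is not None else [f"S{i}" for i in range(len(time))]
    return pd.DataFrame({"time": time, "event": event, **covs},
                        index=pd.Index(idx, name="sample_id"))


def _sim_survival(rng, x, beta, n, censor=0.02, baseline=0.05):
    hazard = baseline * np.exp(beta * x)
    t_event = rng.exponential(1 / hazard)
    t_cens = rng.exponential(1 / censor, n)
    return _clinical(np.minimum(t_event, t_cens), (t_event <= t_cens).astype(int))


class TestCox:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        n = 300
        x = rng.normal(size=n)
        clin = _sim_survival(rng, x, 0.8, n)
        res = ls.univariate_cox(pd.Series(x, index=clin.index, name="L"), clin)
        assert res.converged
        assert abs(res.coef - 0.8) < 3 * res.se
        assert res.hazard_ratio > 1

    def test_null_wald_p_uniform(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(200):
            n = 120
            x = rng.normal(size=n)
            clin = _sim_survival(rng, np.zeros(n), 0.0, n)
            res = ls.univariate_cox(pd.Series(x, index=clin.index), clin)
            ps.append(res.wald_p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_cls_flagged(self):
        rng = np.random.default_rng(2)
        clin = _sim_survival(rng, np.zeros(50), 0.0, 50)
        res = ls.univariate_cox(pd.Series(np.ones(50), index=clin.index), clin)
        assert not res.converged and "constant" in res.note

    def test_zero_events_flagged(self):
        clin = _clinical([1.0, 2.0, 3.0], [0, 0, 0])
        res = ls.univariate_cox(pd.Series([1.0, 2.0, 3.0], index=clin.index), clin)
        assert not res.converged and "events" in res.note

    def test_multivariate_recovery_with_independent_covariate(self):
        rng = np.random.default_rng(3)
        n = 400
        x = rng.normal(size=n)
        age = rng.normal(60, 10, n)
        hazard = 0.05 * np.exp(0.8 * x + 0.02 * (age - 60))
        t_event = rng.exponential(1 / hazard)
        clin = _clinical(t_event, np.ones(n, int), age=age)
        res = ls.multivariate_cox(
            pd.Series(x, index=clin.index), ["age"], clin
        )
        assert res.converged
        assert abs(res.coef - 0.8) < 3 * res.se

    def test_collinear_covariate_flagged(self):
        rng = np.random.default_rng(4)
        n = 80
        x = rng.normal(size=n)
        clin = _sim_survival(rng, x, 0.5, n)
        clin["copy"] = x
        res = ls.multivariate_cox(pd.Series(x, index=clin.index), ["copy"], clin)
        assert not res.converged

    def test_null_cls_stays_nonsignificant_next_to_strong_covariate(self):
        rng = np.random.default_rng(5)
        hits = 0
        n_runs = 60
        for _ in range(n_runs):
            n = 150
            x = rng.normal(size=n)  # zero-effect score
            strong = rng.normal(size=n)
            hazard = 0.05 * np.exp(1.2 * strong)
            clin = _clinical(rng.exponential(1 / hazard), np.ones(n, int),
                             strong=strong)
            res = ls.multivariate_cox(pd.Series(x, index=clin.index), ["strong"], clin)
            hits += res.wald_p < 0.05
        assert hits <= 0.10 * n_runs + 3  # ~alpha-level false positives only


class TestBH:
    def test_hand_worked_case(self):
        np.testing.assert_allclose(ls.adjust_bh([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(ls.adjust_bh([1.0, 1.0]), [1.0, 1.0])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(ls.adjust_bh([0.2]), [0.2])

    def test_empty_list(self):
        assert ls.adjust_bh([]).size == 0

    def test_matches_stepup_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.uniform(0.001, 1, size=rng.integers(1, 12))
            # independent step-up oracle
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                idx = order[rank - 1]
                running = min(running, p[idx] * m / rank)
                adj[idx] = running
            np.testing.assert_allclose(ls.adjust_bh(p), adj, atol=1e-12)

    def test_invariant_to_input_order(self):
        p = [0.04, 0.001, 0.3, 0.2]
        perm = [2, 0, 3, 1]
        a = ls.adjust_bh(p)
        b = ls.adjust_bh([p[i] for i in perm])
        np.testing.assert_allclose([a[i] for i in perm], b)


class TestDichotomizeAtMode:
    def test_unimodal_cutpoint_near_mode(self):
        rng = np.random.default_rng(7)
        labels, cut = ls.dichotomize_at_mode(rng.normal(0, 1, 2000))
        assert abs(cut) < 0.15
        assert 0 < labels.sum() < 2000

    def test_bimodal_cut_at_global_peak(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(-2, 0.5, 1400), rng.normal(2, 0.5, 600)])
        _, cut = ls.dichotomize_at_mode(x)
        assert abs(cut + 2) < 0.3

    def test_all_equal_errors(self):
        with pytest.raises(ValueError, match="identical"):
            ls.dichotomize_at_mode(np.ones(50))

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=200)
        _, cut1 = ls.dichotomize_at_mode(x)
        _, cut2 = ls.dichotomize_at_mode(x[rng.permutation(200)])
        assert cut1 == cut2

    def test_median_fallback(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=100)
        _, cut = ls.dichotomize_at_mode(x, fallback_median=True)
        assert cut == np.median(x)


class TestKMLogrank:
    def test_separated_hazards_detected(self):
        rng = np.random.default_rng(11)
        detected = 0
        for _ in range(40):
            n = 400
            labels = (rng.uniform(size=n) > 0.5).astype(int)
            hazard = 0.05 * np.where(labels, 3.0, 1.0)
            clin = _clinical(rng.exponential(1 / hazard), np.ones(n, int))
            res = ls.km_logrank(labels, clin)
            detected += res["p"] < 0.01
        assert detected >= 0.95 * 40 - 1

    def test_label_shuffle_null_uniform(self):
        rng = np.random.default_rng(12)
        n = 150
        clin = _clinical(rng.exponential(10, n), rng.integers(0, 2, n))
        ps = []
        for _ in range(200):
            labels = np.zeros(n, int)
            labels[rng.choice(n, n // 2, replace=False)] = 1
            ps.append(ls.km_logrank(labels, clin)["p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_curves_are_step_tables(self):
        rng = np.random.default_rng(13)
        n = 60
        labels = np.repeat([0, 1], n // 2)
        clin = _clinical(rng.exponential(5, n), np.ones(n, int))
        res = ls.km_logrank(labels, clin)
        for curve in res["curves"].values():
            s = curve["survival"].to_numpy()
            assert np.all(np.diff(s) <= 1e-12) and s[0] <= 1.0

    def test_single_group_errors(self):
        clin = _clinical([1, 2, 3], [1, 1, 0])
        with pytest.raises(ValueError, match="two"):
            ls.km_logrank(np.zeros(3, int), clin)

    def test_zero_events_errors(self):
        clin = _clinical([1, 2, 3, 4], [0, 0, 0, 0])
        with pytest.raises(ValueError, match="events"):
            ls.km_logrank(np.array([0, 0, 1, 1]), clin)


class TestSurvivalScan:
    def test_bh_family_is_converged_lineages(self):
        rng = np.random.default_rng(14)
        n = 200
        x1 = rng.normal(size=n)
        clin = _sim_survival(rng, x1, 1.0, n)
        cls = pd.DataFrame({"L1": x1, "L2": rng.normal(size=n),
                            "LCONST": np.ones(n)}, index=clin.index)
        out = ls.survival_scan(cls, clin)
        assert not out.loc["LCONST", "converged"]
        assert np.isnan(out.loc["LCONST", "adj_p"])
        ok = out[out["converged"]]
        np.testing.assert_allclose(
            ok["adj_p"], ls.adjust_bh(ok["wald_p"].to_numpy())
        )
        assert (ok["adj_p"] >= ok["wald_p"] - 1e-12).all()


class TestAnnotationCorrelation:
    def test_self_and_negated_annotation(self):
        rng = np.random.default_rng(15)
        cls = pd.DataFrame(rng.normal(size=(50, 3)), columns=["A", "B", "C"],
                           index=[f"S{i}" for i in range(50)])
        out = ls.annotation_correlation(cls, cls["A"])
        assert out.loc["A", "r"] == pytest.approx(1.0)
        assert out.loc["A", "rank"] == 1
        out2 = ls.annotation_correlation(cls, -cls["A"])
        assert out2.loc["A", "r"] == pytest.approx(-1.0)
        assert out2.loc["A", "rank"] == 3

    def test_independent_annotation_uncorrelated(self):
        rng = np.random.default_rng(16)
        cls = pd.DataFrame(rng.normal(size=(500, 5)),
                           index=[f"S{i}" for i in range(500)],
                           columns=list("ABCDE"))
        ann = pd.Series(rng.normal(size=500), index=cls.index)
        out = ls.annotation_correlation(cls, ann)
        assert np.abs(out["r"]).max() < 0.2

    def test_ranking_invariant_under_affine_annotation(self):
        rng = np.random.default_rng(17)
        cls = pd.DataFrame(rng.normal(size=(40, 4)),
                           index=[f"S{i}" for i in range(40)],
                           columns=list("ABCD"))
        ann = pd.Series(rng.normal(size=40), index=cls.index)
        a = ls.annotation_correlation(cls, ann)
        b = ls.annotation_correlation(cls, 3.5 * ann + 10)
        assert list(a.index) == list(b.index)
        np.testing.assert_allclose(a["r"], b["r"], atol=1e-12)

    def test_zero_variance_annotation_errors(self):
        cls = pd.DataFrame(np.random.default_rng(18).normal(size=(10, 2)),
                           index=[f"S{i}" for i in range(10)], columns=["A", "B"])
        with pytest.raises(ValueError, match="variance"):
            ls.annotation_correlation(cls, pd.Series(np.ones(10), index=cls.index))


class TestRankEnrichment:
    @staticmethod
    def _ranked(rs, names=None):
        names = names or [f"L{i}" for i in range(len(rs))]
        out = pd.DataFrame({"r": rs}, index=pd.Index(names, name="lineage"))
        return out.sort_values("r", ascending=False)

    def test_exact_top_enrichment_3v3(self):
        ranked = self._ranked([0.9, 0.8, 0.7, 0.1, 0.2, 0.3],
                              ["a", "b", "c", "x", "y", "z"])
        res = ls.rank_enrichment(ranked, ["a", "b", "c"])
        assert res["side"] == "top"
        assert res["p"] == pytest.approx(1 / 20)  # 1 of C(6,3) orderings
        assert res["method"] == "exact"

    def test_exact_single_member_top_of_ten(self):
        rs = np.linspace(1, 0.1, 10)
        ranked = self._ranked(rs)
        res = ls.rank_enrichment(ranked, ["L0"])
        assert res["p"] == pytest.approx(0.1)

    def test_bottom_side_detected(self):
        ranked = self._ranked([0.9, 0.8, 0.7, 0.1, 0.2, 0.3],
                              ["a", "b", "c", "x", "y", "z"])
        res = ls.rank_enrichment(ranked, ["x", "y", "z"])
        assert res["side"] == "bottom" and res["p"] == pytest.approx(1 / 20)

    def test_identical_groups_p_uniformish(self):
        rng = np.random.default_rng(19)
        ps = []
        for _ in range(300):
            ranked = self._ranked(rng.normal(size=12))
            ps.append(ls.rank_enrichment(ranked, ["L0", "L1", "L2"])["p"])
        # one-sided smaller-p selection halves the scale; just check no
        # systematic enrichment: median p should not be tiny
        assert np.median(ps) > 0.15

    def test_subtype_covering_all_errors(self):
        ranked = self._ranked([0.5, 0.4], ["a", "b"])
        with pytest.raises(ValueError, match="background"):
            ls.rank_enrichment(ranked, ["a", "b"])


class TestLIGroupTest:
    def test_shift_detected(self):
        rng = np.random.default_rng(20)
        hits = 0
        for _ in range(40):
            li = pd.Series(rng.normal(size=200),
                           index=[f"S{i}" for i in range(200)])
            cls = pd.Series(rng.normal(size=200), index=li.index)
            cls[li > li.median()] += 1.0  # 1-sd shift in the LI-high group
            hits += ls.li_group_test(cls, li)["p"] < 0.01
        assert hits >= 0.95 * 40 - 1

    def test_null_p_uniform(self):
        rng = np.random.default_rng(21)
        ps = []
        for _ in range(200):
            idx = [f"S{i}" for i in range(60)]
            li = pd.Series(rng.normal(size=60), index=idx)
            cls = pd.Series(rng.normal(size=60), index=idx)
            ps.append(ls.li_group_test(cls, li)["p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_tiny_group_errors(self):
        idx = [f"S{i}" for i in range(4)]
        li = pd.Series([1, 2, 3, 4.0], index=idx)
        cls = pd.Series([1, 1, 2, 2.0], index=idx)
        with pytest.raises(ValueError, match="degenerate"):
            ls.li_group_test(cls, li)


class TestBestMatchProfile:
    def test_identical_column_ranked_first(self):
        rng = np.random.default_rng(22)
        panel = pd.DataFrame(rng.normal(size=(300, 5)),
                             index=[f"G{i}" for i in range(300)],
                             columns=list("ABCDE"))
        out = ls.best_match_profile(panel["C"], panel)
        assert out.index[0] == "C" and out.loc["C", "r"] == pytest.approx(1.0)

    def test_negated_column_ranked_last(self):
        rng = np.random.default_rng(23)
        panel = pd.DataFrame(rng.normal(size=(300, 4)),
                             index=[f"G{i}" for i in range(300)],
                             columns=list("ABCD"))
        out = ls.best_match_profile(-panel["B"], panel)
        assert out.index[-1] == "B"

    def test_noisy_query_recovers_truth(self):
        rng = np.random.default_rng(24)
        panel = pd.DataFrame(rng.normal(size=(2000, 6)),
                             index=[f"G{i}" for i in range(2000)],
                             columns=list("ABCDEF"))
        wins = 0
        for _ in range(40):
            noisy = panel["D"] + rng.normal(0, 0.5, 2000)
            wins += ls.best_match_profile(noisy, panel).index[0] == "D"
        assert wins >= 0.95 * 40 - 1

    def test_insufficient_overlap_errors(self):
        panel = pd.DataFrame(np.eye(50), index=[f"G{i}" for i in range(50)])
        query = pd.Series(np.ones(50), index=[f"H{i}" for i in range(50)])
        with pytest.raises(ValueError, match="shared genes"):
            ls.best_match_profile(query, panel)
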