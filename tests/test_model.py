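"""CS scores, preranked GSEA vs brute-force oracle, screening, Cox/LASSO,
the linear scorer and its evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from irapass.io import (
    ClinicalTable,
    ExpressionTable,
    GeneSetCollection,
    PduiTable,
    ValidationError,
)
from irapass.model import (
    IrapassModel,
    correlation_score,
    evaluate,
    fit_scorer,
    lasso_cox,
    path_apa_score,
    preranked_gsea,
    published_model,
    screen_immune_events,
    univariate_cox,
)
from irapass.simulate import SimulationConfig, simulate_study


# ---------------------------------------------------------------------------
# Correlation score
# ---------------------------------------------------------------------------


class TestCorrelationScore:
    @staticmethod
    def _tables(gene_rows, event_rows, samples):
        expr = ExpressionTable(pd.DataFrame(
            gene_rows, index=[f"g{i}" for i in range(len(gene_rows))], columns=samples))
        pdui = PduiTable(pd.DataFrame(
            event_rows, index=[f"E{i}|chr1|{i+1}" for i in range(len(event_rows))],
            columns=samples))
        return expr, pdui

    def test_identical_vectors_hit_pseudocount_ceiling(self):
        samples = [f"s{i}" for i in range(30)]
        v = np.linspace(0.1, 0.9, 30)
        expr, pdui = self._tables([v * 10], [v], samples)
        prof = correlation_score(expr, pdui, samples)
        assert prof.cor.iloc[0, 0] == pytest.approx(1.0)
        # P ~ 0, so CS ~ -log10(1e-20) = 20
        assert prof.cs.iloc[0, 0] == pytest.approx(20.0, abs=0.5)

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(25)]
        g = rng.lognormal(size=25)
        a = rng.beta(5, 5, size=25)
        expr_pos, pdui = self._tables([g], [a], samples)
        expr_neg = ExpressionTable(pd.DataFrame([g.max() - g + 0.01], index=["g0"],
                                                columns=samples))
        cs_pos = correlation_score(expr_pos, pdui, samples).cs.iloc[0, 0]
        cs_neg = correlation_score(expr_neg, pdui, samples).cs.iloc[0, 0]
        assert cs_pos == pytest.approx(-cs_neg, abs=1e-9)

    def test_cs_bounded_by_twenty(self):
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(40)]
        expr, pdui = self._tables(rng.lognormal(size=(20, 40)),
                                  rng.beta(5, 5, size=(5, 40)), samples)
        prof = correlation_score(expr, pdui, samples)
        assert np.nanmax(np.abs(prof.cs.to_numpy())) <= 20.0 + 1e-9

    def test_constant_gene_gives_missing_cs(self):
        samples = [f"s{i}" for i in range(10)]
        expr, pdui = self._tables([[1.0] * 10], [np.linspace(0.1, 0.9, 10)], samples)
        prof = correlation_score(expr, pdui, samples)
        assert np.isnan(prof.cs.iloc[0, 0])

    def test_too_few_samples_errors(self):
        samples = ["s0", "s1"]
        expr, pdui = self._tables([[1.0, 2.0]], [[0.1, 0.2]], samples)
        with pytest.raises(ValidationError):
            correlation_score(expr, pdui, samples)


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------


def _oracle_es(ranked: pd.Series, members: set, weight: float) -> float:
    """Brute-force running sum walked gene by gene down the ranked list."""
    order = ranked.sort_values(ascending=False, kind="mergesort")
    genes = list(order.index)
    hits = [g for g in genes if g in members]
    n, nh = len(genes), len(hits)
    wsum = sum(abs(order[g]) ** weight for g in hits)
    run, best = 0.0, 0.0
    for g in genes:
        if g in members:
            run += (abs(order[g]) ** weight) / wsum if wsum > 0 else 1.0 / nh
        else:
            run -= 1.0 / (n - nh)
        if abs(run) > abs(best):
            best = run
    return best


class TestPrerankedGsea:
    def test_top_ranked_set_matches_ks_oracle_weight_zero(self):
        """3 top genes of a 10-gene universe, weight 0 = classic KS statistic."""
        ranked = pd.Series(np.linspace(5, -5, 10), index=[f"g{i}" for i in range(10)])
        sets = GeneSetCollection({"TOP": {"g0", "g1", "g2"}})
        res = preranked_gsea(ranked, sets, weight=0.0, n_perm=200, seed=1, min_size=3)
        assert res.loc["TOP", "es"] == pytest.approx(
            _oracle_es(ranked, {"g0", "g1", "g2"}, 0.0))
        # classic KS value for 3 leading hits: 3/3 - 0 = 1 at position 3
        assert res.loc["TOP", "es"] == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(8))
    def test_es_matches_oracle_on_random_fixtures(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(8, 16))
        ranked = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        size = int(rng.integers(5, max(6, n - 2)))
        members = set(rng.choice(ranked.index, size=size, replace=False))
        sets = GeneSetCollection({"S": members})
        res = preranked_gsea(ranked, sets, weight=1.0, n_perm=50, seed=trial,
                             min_size=5)
        assert res.loc["S", "es"] == pytest.approx(
            _oracle_es(ranked, members, 1.0), abs=1e-12)

    def test_whole_universe_set_warns_and_runs(self, caplog):
        ranked = pd.Series([3.0, 2.0, 1.0, -1.0, -2.0],
                           index=[f"g{i}" for i in range(5)])
        sets = GeneSetCollection({"ALL": set(ranked.index)})
        res = preranked_gsea(ranked, sets, n_perm=50, seed=0, min_size=5)
        assert "ALL" in res.index

    def test_small_sets_dropped(self):
        ranked = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        sets = GeneSetCollection({"TINY": {"g0", "g1"}})
        res = preranked_gsea(ranked, sets, n_perm=50, seed=0, min_size=5)
        assert len(res) == 0

    def test_null_pvalues_uniform(self):
        """Random rankings give ~uniform permutation p-values."""
        rng = np.random.default_rng(77)
        genes = [f"g{i}" for i in range(60)]
        sets = GeneSetCollection({
            f"P{j}": set(rng.choice(genes, size=10, replace=False)) for j in range(6)
        })
        ps = []
        for rep in range(40):
            ranked = pd.Series(rng.normal(size=60), index=genes)
            res = preranked_gsea(ranked, sets, n_perm=200, seed=rep)
            ps.extend(res["perm_p"].tolist())
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_missing_cs_rejected(self):
        ranked = pd.Series([1.0, np.nan], index=["a", "b"])
        with pytest.raises(ValidationError):
            preranked_gsea(ranked, GeneSetCollection({"S": {"a"}}))


class TestPathApaScore:
    def test_screen_boundary_value(self):
        assert path_apa_score(2.0, 0.0025) == pytest.approx(0.995)

    def test_negative_es_symmetry(self):
        assert path_apa_score(-1.5, 0.0025) == pytest.approx(-0.995)

    def test_midpoint_is_zero(self):
        assert path_apa_score(3.0, 0.5) == 0.0
        assert path_apa_score(-3.0, 0.5) == 0.0

    def test_zero_es_scores_zero(self):
        assert path_apa_score(0.0, 0.01) == 0.0

    @given(es=st.floats(min_value=0.01, max_value=5.0),
           p=st.floats(min_value=1e-4, max_value=1.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_odd_in_es_sign(self, es, p):
        assert path_apa_score(es, p) == pytest.approx(-path_apa_score(-es, p))


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------


def _assoc_row(event, pathway, nes, p, q):
    return {"event_id": event, "pathway": pathway, "size": 10, "es": np.sign(nes),
            "nes": nes, "perm_p": p, "fdr_q": q,
            "path_apa_score": path_apa_score(np.sign(nes), p)}


class TestScreenImmuneEvents:
    @staticmethod
    def _assoc(rows):
        return pd.DataFrame(rows)

    def test_opposite_nes_pair_retained(self):
        strong = [_assoc_row("E1|chr1|5", "PW", 2.1, 0.001, 0.01)]
        weak = [_assoc_row("E1|chr1|5", "PW", -1.8, 0.2, 0.4)]
        assoc = {
            "c1": {"responders": self._assoc(strong), "nonresponders": self._assoc(weak)},
            "c2": {"responders": self._assoc(strong), "nonresponders": self._assoc(weak)},
        }
        pairs, events = screen_immune_events(assoc)
        assert events == ["E1|chr1|5"]
        assert pairs["orientation"].iloc[0] == 1

    def test_same_sign_nes_dropped(self):
        a = [_assoc_row("E1|chr1|5", "PW", 2.1, 0.001, 0.01)]
        b = [_assoc_row("E1|chr1|5", "PW", 1.9, 0.3, 0.5)]
        assoc = {
            "c1": {"responders": self._assoc(a), "nonresponders": self._assoc(b)},
            "c2": {"responders": self._assoc(a), "nonresponders": self._assoc(b)},
        }
        _, events = screen_immune_events(assoc)
        assert events == []

    def test_orientation_must_match_across_cohorts(self):
        r = [_assoc_row("E1|chr1|5", "PW", 2.1, 0.001, 0.01)]
        n = [_assoc_row("E1|chr1|5", "PW", -1.8, 0.2, 0.4)]
        assoc = {
            "c1": {"responders": self._assoc(r), "nonresponders": self._assoc(n)},
            "c2": {"responders": self._assoc(n), "nonresponders": self._assoc(r)},
        }
        _, events = screen_immune_events(assoc)
        assert events == []

    def test_missing_table_errors(self):
        a = self._assoc([_assoc_row("E1|chr1|5", "PW", 2.1, 0.001, 0.01)])
        with pytest.raises(ValidationError):
            screen_immune_events({"c1": {"responders": a}, "c2": {"responders": a,
                                                                  "nonresponders": a}})


# ---------------------------------------------------------------------------
# Survival selection
# ---------------------------------------------------------------------------


def _survival_fixture(seed=0, n=120, informative=2, noise=8, beta=1.2):
    rng = np.random.default_rng(seed)
    x = pd.DataFrame(rng.beta(5, 5, size=(n, informative + noise)),
                     index=[f"s{i}" for i in range(n)],
                     columns=[f"f{i}" for i in range(informative + noise)])
    risk = beta * (x.iloc[:, :informative].sum(axis=1) - informative * 0.5)
    time = rng.exponential(1.0 / (0.01 * np.exp(risk)))
    censor = rng.exponential(300, size=n)
    os_time = pd.Series(np.minimum(time, censor) + 1, index=x.index)
    os_event = pd.Series((time <= censor).astype(int), index=x.index)
    return x, os_time, os_event


class TestUnivariateCox:
    def test_informative_feature_detected_with_correct_direction(self):
        # beta=4: log-HR spread ~0.6 per feature, well-powered at n=120
        x, t, e = _survival_fixture(seed=1, beta=4.0)
        res = univariate_cox(x, t, e)
        assert res.loc["f0", "p"] < 0.05
        assert res.loc["f0", "hr"] > 1.0  # higher feature -> higher hazard

    def test_null_feature_pvalues_roughly_uniform(self):
        ps = []
        for seed in range(8):
            x, t, e = _survival_fixture(seed=seed, informative=0, noise=5, beta=0.0)
            res = univariate_cox(x, t, e)
            ps.extend(res["p"].tolist())
        assert (np.array(ps) < 0.05).mean() < 0.2

    def test_constant_feature_skipped(self):
        x, t, e = _survival_fixture(seed=2)
        x["const"] = 0.5
        res = univariate_cox(x, t, e)
        assert "const" not in res.index

    def test_too_few_events_errors(self):
        x, t, e = _survival_fixture(seed=3)
        with pytest.raises(ValidationError):
            univariate_cox(x, t, e * 0)


class TestLassoCox:
    def test_recovers_informative_over_noise(self):
        hits, false = 0, 0
        for seed in range(5):
            x, t, e = _survival_fixture(seed=seed, n=105, informative=5, noise=15,
                                        beta=1.5)
            sel = lasso_cox(x, t, e, seed=seed)
            chosen = set(sel.index)
            hits += len(chosen & {f"f{i}" for i in range(5)})
            false += len(chosen - {f"f{i}" for i in range(5)})
        assert hits / 5 >= 3
        assert false / 5 <= 6

    def test_duplicated_features_not_both_kept_equal(self):
        x, t, e = _survival_fixture(seed=4, informative=1, noise=3)
        x["dup"] = x["f0"]
        sel = lasso_cox(x, t, e, seed=0)
        if {"f0", "dup"} <= set(sel.index):
            assert not np.isclose(sel.loc["f0", "coef"], sel.loc["dup", "coef"])

    def test_single_feature_rejected(self):
        x, t, e = _survival_fixture(seed=5, informative=1, noise=0)
        with pytest.raises(ValidationError):
            lasso_cox(x[["f0"]], t, e)


# ---------------------------------------------------------------------------
# Scorer
# ---------------------------------------------------------------------------


class TestPublishedModel:
    def test_has_ten_unique_features(self):
        model = published_model()
        assert model.n_features == 10
        assert len(set(model.features)) == 10
        assert model.intercept == 0.0

    def test_single_feature_returns_its_coefficient(self):
        model = published_model()
        for feat, coef in zip(model.features, model.coefficients):
            vec = {f: (1.0 if f == feat else 0.0) for f in model.features}
            assert model.score(vec).iloc[0] == pytest.approx(coef, abs=1e-12)

    def test_all_zero_features_score_zero(self):
        model = published_model()
        assert model.score({f: 0.0 for f in model.features}).iloc[0] == 0.0

    def test_missing_feature_errors_with_names(self):
        model = published_model()
        vec = {f: 0.5 for f in model.features[:-1]}
        with pytest.raises(ValidationError, match="TMEM63A"):
            model.score(vec)

    def test_score_is_linear(self):
        rng = np.random.default_rng(6)
        model = published_model()
        x = pd.DataFrame(rng.beta(5, 5, size=(10, 2)), index=model.features,
                         columns=["u", "v"])
        a, b = 0.3, 1.7
        combo = pd.DataFrame({"w": a * x["u"] + b * x["v"]})
        s = model.score(pd.concat([x, combo], axis=1))
        expected = a * s["u"] + b * s["v"] - (a + b - 1) * model.intercept
        assert s["w"] == pytest.approx(expected, abs=1e-9)


class TestFitScorer:
    @staticmethod
    def _separable(seed=0, n=60, p=4):
        rng = np.random.default_rng(seed)
        y = pd.Series(rng.random(n) < 0.4, index=[f"s{i}" for i in range(n)])
        x = pd.DataFrame(rng.beta(5, 5, size=(n, p)), index=y.index,
                         columns=[f"E{i}|chr1|{i+1}" for i in range(p)])
        x.iloc[:, 0] = np.where(y, 0.8, 0.2) + rng.normal(0, 0.01, n)
        x = x.clip(0, 1)
        return x, y

    def test_separable_data_trains_to_high_auc(self):
        from sklearn.metrics import roc_auc_score
        x, y = self._separable(seed=1)
        model, split = fit_scorer(x, y, seed=0)
        train = split["train_samples"]
        auc = roc_auc_score(y.loc[train], model.score(x.loc[train].T))
        assert auc > 0.99

    def test_refit_same_seed_identical(self):
        x, y = self._separable(seed=2)
        m1, s1 = fit_scorer(x, y, seed=5)
        m2, s2 = fit_scorer(x, y, seed=5)
        assert np.allclose(m1.coefficients, m2.coefficients)
        assert s1["train_samples"] == s2["train_samples"]

    def test_planted_weights_recovered(self):
        rng = np.random.default_rng(7)
        n, p = 400, 5
        w = np.array([2.0, -1.5, 1.0, 0.5, -2.5])
        x = pd.DataFrame(rng.beta(5, 5, size=(n, p)),
                         index=[f"s{i}" for i in range(n)],
                         columns=[f"E{i}|chr1|{i+1}" for i in range(p)])
        z = (x - 0.5) @ w + rng.normal(0, 0.3, n)
        y = pd.Series(z > 0, index=x.index)
        model, _ = fit_scorer(x, y, seed=0)
        cos = (model.coefficients @ w) / (
            np.linalg.norm(model.coefficients) * np.linalg.norm(w))
        assert cos >= 0.9

    def test_mlp_architecture_exports_linear_equivalent(self):
        x, y = self._separable(seed=3)
        model, _ = fit_scorer(x, y, architecture="mlp", seed=0)
        assert model.n_features == x.shape[1]
        from sklearn.metrics import roc_auc_score
        auc = roc_auc_score(y, model.score(x.T))
        assert auc > 0.9

    def test_too_few_samples_errors(self):
        x, y = self._separable(seed=4, n=8)
        with pytest.raises(ValidationError):
            fit_scorer(x, y)


class TestEvaluate:
    def test_scores_equal_labels_auc_one(self):
        y = pd.Series([0, 0, 1, 1], index=list("abcd"))
        ev = evaluate(pd.Series([0.0, 0.0, 1.0, 1.0], index=list("abcd")), response=y)
        assert ev.auc == 1.0

    def test_permuted_scores_auc_near_half(self):
        rng = np.random.default_rng(9)
        aucs = []
        for _ in range(20):
            y = pd.Series(rng.random(80) < 0.4, index=[f"s{i}" for i in range(80)])
            s = pd.Series(rng.normal(size=80), index=y.index)
            aucs.append(evaluate(s, response=y).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_single_class_skips_roc(self):
        y = pd.Series([1, 1, 1], index=list("abc"))
        ev = evaluate(pd.Series([0.1, 0.2, 0.3], index=list("abc")), response=y)
        assert ev.auc is None

    def test_survival_split_by_youden_cutoff(self):
        rng = np.random.default_rng(10)
        n = 132
        score = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        y = pd.Series(score + rng.normal(0, 0.8, n) > 0, index=score.index)
        # protective high score
        time = pd.Series(rng.exponential(1.0 / (0.01 * np.exp(-1.2 * score))) + 1,
                         index=score.index)
        event = pd.Series(1, index=score.index)
        ev = evaluate(score, response=y, os_time=time, os_event=event)
        assert ev.logrank_p < 0.05
        high = ev.groups == "high"
        assert time[high].median() > time[~high].median()
        assert ev.cox_summary is not None
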