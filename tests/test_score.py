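"""Sign grouping, Boruta, signature fitting and the subtraction score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m6apattern.core_io import ValidationError
from m6apattern.score import (
    assign_sign_groups,
    boruta_select,
    fit_signature,
    panel_comparison,
    response_analysis,
    score_samples,
)
from tests.conftest import make_matrix


def _anticorrelated_blocks(rng, n_samples=60, n_per_block=6, sd=0.1):
    f = rng.normal(size=n_samples)
    X = np.vstack(
        [f + rng.normal(0, sd, n_samples) for _ in range(n_per_block)]
        + [-f + rng.normal(0, sd, n_samples) for _ in range(n_per_block)]
    )
    genes = [f"UP{i}" for i in range(n_per_block)] + [f"DN{i}" for i in range(n_per_block)]
    return make_matrix(X + 6, genes=genes), f


class TestAssignSignGroups:
    def test_anticorrelated_blocks_split(self, rng):
        m, _ = _anticorrelated_blocks(rng)
        pos, neg = assign_sign_groups(m)
        groups = ({g[:2] for g in pos}, {g[:2] for g in neg})
        assert groups == ({"UP"}, {"DN"}) or groups == ({"DN"}, {"UP"})

    def test_orientation_prefers_larger_group(self, rng):
        f = rng.normal(size=80)
        X = np.vstack(
            [f + rng.normal(0, 0.1, 80) for _ in range(8)]
            + [-f + rng.normal(0, 0.1, 80) for _ in range(3)]
        )
        m = make_matrix(X, genes=[f"UP{i}" for i in range(8)] + [f"DN{i}" for i in range(3)])
        pos, neg = assign_sign_groups(m)
        assert len(pos) == 8 and {g[:2] for g in pos} == {"UP"}

    def test_uncorrelated_gene_dropped(self, rng):
        m, f = _anticorrelated_blocks(rng, n_samples=200)
        noise = rng.normal(6, 1, size=(1, 200))
        m2 = make_matrix(np.vstack([m.frame.to_numpy(), noise]),
                         genes=m.gene_ids + ["NOISE"])
        pos, neg = assign_sign_groups(m2)
        assert "NOISE" not in pos + neg

    def test_all_correlated_yields_empty_negative(self, rng):
        f = rng.normal(size=50)
        X = np.vstack([2 * f, 3 * f, f, 1.5 * f]) + 6
        m = make_matrix(X)
        pos, neg = assign_sign_groups(m)
        assert sorted(pos) == m.gene_ids and neg == []

    def test_all_dropped_is_an_error(self, rng):
        m = make_matrix(rng.normal(6, 1, size=(5, 300)))
        with pytest.raises(ValidationError, match="r_min"):
            assign_sign_groups(m, r_min=0.9)


class TestBoruta:
    def test_informative_feature_confirmed(self):
        confirmed_runs = 0
        for seed in range(10):
            gen = np.random.default_rng(seed)
            n = 60
            target = gen.normal(size=n)
            X = pd.DataFrame(gen.normal(size=(n, 20)),
                             columns=[f"noise{i}" for i in range(20)])
            X["signal"] = target + gen.normal(0, 0.05, n)
            res = boruta_select(X, target, max_iter=30, alpha=0.01, seed=seed,
                                n_trees=60)
            confirmed_runs += "signal" in res.confirmed
        assert confirmed_runs >= 9

    def test_pure_noise_rarely_confirmed(self):
        total = 0
        for seed in range(3):
            gen = np.random.default_rng(100 + seed)
            X = pd.DataFrame(gen.normal(size=(40, 50)))
            y = gen.normal(size=40)
            res = boruta_select(X, y, max_iter=30, alpha=0.01, seed=seed, n_trees=40)
            total += len(res.confirmed)
        assert total <= 2

    def test_too_few_iterations_confirm_nothing(self, rng):
        target = rng.normal(size=30)
        X = pd.DataFrame({"signal": target, "noise": rng.normal(size=30)})
        res = boruta_select(X, target, max_iter=5, alpha=0.01, seed=0, n_trees=30)
        # Binomial(5, 1/2) cannot reach two-sided p < 0.01
        assert res.confirmed == [] and res.rejected == []
        assert set(res.tentative) == {"signal", "noise"}
        assert "signal" in res.tentative_resolved

    def test_constant_target_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        with pytest.raises(ValidationError):
            boruta_select(X, np.ones(10))

    def test_seed_reproducible(self, rng):
        target = rng.normal(size=40)
        X = pd.DataFrame(rng.normal(size=(40, 10)))
        X.iloc[:, 0] = target + rng.normal(0, 0.1, 40)
        r1 = boruta_select(X, target, max_iter=15, seed=5, n_trees=30)
        r2 = boruta_select(X, target, max_iter=15, seed=5, n_trees=30)
        assert r1.hits == r2.hits and r1.confirmed == r2.confirmed


class TestFitAndScore:
    def test_two_gene_block_closed_form_loadings(self, rng):
        # two perfectly correlated unit-variance genes: PC1 = (1,1)/sqrt(2)
        f = rng.normal(size=200)
        f = (f - f.mean()) / f.std(ddof=0)
        m = make_matrix(np.vstack([f, f]) + 6, genes=["A", "B"])
        model = fit_signature(m, ["A", "B"], [])
        np.testing.assert_allclose(
            np.abs(model.positive.loadings), [1 / np.sqrt(2)] * 2, atol=1e-9
        )
        scores = model.positive.scores(m)
        # orientation: scores track the block mean positively
        assert np.corrcoef(scores, m.frame.mean(axis=0))[0, 1] > 0.99

    def test_empty_negative_block_reduces_to_positive_pc1(self, rng):
        m, _ = _anticorrelated_blocks(rng)
        model = fit_signature(m, [g for g in m.gene_ids if g.startswith("UP")], [])
        out = score_samples(model, m)
        np.testing.assert_allclose(out["score"], model.positive.scores(m))

    def test_refit_is_deterministic(self, rng):
        m, _ = _anticorrelated_blocks(rng)
        pos = [g for g in m.gene_ids if g.startswith("UP")]
        neg = [g for g in m.gene_ids if g.startswith("DN")]
        m1 = fit_signature(m, pos, neg)
        m2 = fit_signature(m, pos, neg)
        np.testing.assert_array_equal(m1.positive.loadings, m2.positive.loadings)
        np.testing.assert_array_equal(m1.negative.loadings, m2.negative.loadings)

    def test_median_split(self):
        scores = pd.DataFrame({"sample_id": list("abcd"), "score": [1.0, 2, 3, 4],
                               "group": ["low"] * 4})
        m, _ = _anticorrelated_blocks(np.random.default_rng(0))
        # median split computed by score_samples directly:
        model = fit_signature(m, [g for g in m.gene_ids if g.startswith("UP")],
                              [g for g in m.gene_ids if g.startswith("DN")])
        out = score_samples(model, m)
        n_high = (out["group"] == "high").sum()
        assert abs(n_high - (len(out) - n_high)) <= 1

    def test_swapping_blocks_negates_scores(self, rng):
        m, _ = _anticorrelated_blocks(rng)
        pos = [g for g in m.gene_ids if g.startswith("UP")]
        neg = [g for g in m.gene_ids if g.startswith("DN")]
        s1 = score_samples(fit_signature(m, pos, neg), m)["score"].to_numpy()
        s2 = score_samples(fit_signature(m, neg, pos), m)["score"].to_numpy()
        np.testing.assert_allclose(s1, -s2, atol=1e-9)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_antisymmetry_and_balance_on_random_inputs(self, seed):
        gen = np.random.default_rng(seed)
        n, p = 12, 6
        m = make_matrix(gen.normal(6, 1, size=(p, n)))
        pos, neg = m.gene_ids[:3], m.gene_ids[3:]
        s1 = score_samples(fit_signature(m, pos, neg), m)
        s2 = score_samples(fit_signature(m, neg, pos), m)
        np.testing.assert_allclose(s1["score"], -s2["score"], atol=1e-8)
        if len(set(np.round(s1["score"], 12))) == n:
            n_high = (s1["group"] == "high").sum()
            assert abs(n_high - (n - n_high)) <= 1

    def test_centering_absorbs_constant_gene_shift(self, rng):
        m, _ = _anticorrelated_blocks(rng)
        pos = [g for g in m.gene_ids if g.startswith("UP")]
        model1 = fit_signature(m, pos, [])
        shifted = m.frame.copy()
        shifted.loc["UP0"] += 7.0
        model2 = fit_signature(make_matrix(shifted.to_numpy(), genes=m.gene_ids), pos, [])
        np.testing.assert_allclose(
            model1.positive.scores(m),
            model2.positive.scores(make_matrix(shifted.to_numpy(), genes=m.gene_ids)),
            atol=1e-9,
        )

    def test_missing_model_gene_is_an_error(self, rng):
        m, _ = _anticorrelated_blocks(rng)
        model = fit_signature(m, [g for g in m.gene_ids if g.startswith("UP")], [])
        small = m.subset_genes(m.gene_ids[1:])
        with pytest.raises(ValidationError, match="UP0"):
            score_samples(model, small)


class TestResponseAnalysis:
    @staticmethod
    def _scores(vals, ids=None):
        ids = ids or [f"s{i}" for i in range(len(vals))]
        return pd.DataFrame({"sample_id": ids, "score": vals,
                             "group": ["low"] * len(vals)})

    def test_perfect_separation_auc_one(self):
        scores = self._scores([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        resp = pd.Series(["responder"] * 3 + ["non_responder"] * 3,
                         index=scores["sample_id"])
        out = response_analysis(scores, resp)
        assert out["roc_auc"] == 1.0
        assert out["median_responder"] < out["median_non_responder"]

    def test_permutation_null_p_uniform(self, rng):
        vals = rng.normal(size=40)
        scores = self._scores(vals)
        pvals = []
        for _ in range(200):
            resp = pd.Series(
                rng.permutation(["responder"] * 20 + ["non_responder"] * 20),
                index=scores["sample_id"],
            )
            pvals.append(response_analysis(scores, resp)["wilcoxon_p"])
        from scipy import stats

        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_one_class_absent_rejected(self):
        scores = self._scores([1.0, 2.0, 3.0, 4.0])
        resp = pd.Series(["responder"] * 4, index=scores["sample_id"])
        with pytest.raises(ValidationError):
            response_analysis(scores, resp)


class TestPanelComparison:
    def test_constant_gene_p_one_and_skipped_report(self, rng):
        X = rng.normal(6, 1, size=(3, 40))
        X[0] = 5.0
        m = make_matrix(X, genes=["FLAT", "G2", "G3"])
        groups = pd.Series(["high"] * 20 + ["low"] * 20, index=m.sample_ids)
        table, skipped = panel_comparison(m, groups, ["FLAT", "G2", "ABSENT"])
        assert skipped == ["ABSENT"]
        assert set(table["gene_id"]) == {"FLAT", "G2"}
        assert table.set_index("gene_id").loc["FLAT", "p_value"] == pytest.approx(1.0)

    def test_planted_difference_detected_with_sign(self, rng):
        n = 50
        X = np.vstack([
            np.r_[rng.normal(6, 1, n), rng.normal(8, 1, n)],  # higher in low group
            rng.normal(6, 1, 2 * n),
        ])
        m = make_matrix(X, genes=["CHK", "BG"])
        groups = pd.Series(["high"] * n + ["low"] * n, index=m.sample_ids)
        table, _ = panel_comparison(m, groups, ["CHK", "BG"])
        row = table.set_index("gene_id").loc["CHK"]
        assert row["q_value"] < 0.05
        assert row["median_diff_high_minus_low"] < 0

    def test_empty_panel_rejected(self, rng):
        m = make_matrix(rng.normal(size=(2, 8)))
        groups = pd.Series(["high"] * 4 + ["low"] * 4, index=m.sample_ids)
        with pytest.raises(ValidationError):
            panel_comparison(m, groups, ["NOPE"])


def test_end_to_end_score_recovers_latent_factor(small_cohort):
    """Fitted on the planted cohort's true signature genes, the score tracks
    the planted latent factor and orders the subgroups C > B > A."""
    _, expr, meta, truth = small_cohort
    ra = meta.loc[meta.disease_status == "RA", "sample_id"].tolist()
    signature = sorted(g for gs in truth.signature_sets.values() for g in gs)
    ra_expr = expr.subset_samples(ra)
    pos, neg = assign_sign_groups(ra_expr.subset_genes(signature))
    model = fit_signature(ra_expr, pos, neg)
    out = score_samples(model, ra_expr)
    s = out.set_index("sample_id")["score"]
    f = truth.latent_factor[s.index]
    assert abs(np.corrcoef(s, f)[0, 1]) > 0.8
    med = s.groupby(truth.cluster[s.index]).median()
    assert med["C"] > med["B"] > med["A"]
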