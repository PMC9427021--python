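"""Moderated-t shrinkage, DEG intersection and hypergeometric ORA."""

import shutil
import subprocess
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from m6apattern.core_io import GeneSetCollection, ValidationError
from m6apattern.deg import cluster_degs, moderated_ttest, ora_hypergeometric
from tests.conftest import make_matrix


def _two_group_matrix(rng, n_genes=50, n_a=5, n_b=5, sd=1.0):
    X = rng.normal(6, sd, size=(n_genes, n_a + n_b))
    m = make_matrix(X)
    return m, m.sample_ids[:n_a], m.sample_ids[n_a:]


class TestModeratedT:
    def test_equal_variances_reduce_to_ordinary_t(self, rng):
        # equal gene variances: shrinkage target equals every s2, a no-op
        n_a = n_b = 4
        base = rng.normal(size=n_a + n_b)
        X = np.vstack([base + off for off in rng.normal(0, 2, size=20)])
        m = make_matrix(X)
        out = moderated_ttest(m, m.sample_ids[:n_a], m.sample_ids[n_b:])
        for i, g in enumerate(m.gene_ids):
            t_ref = stats.ttest_ind(X[i, :n_a], X[i, n_a:], equal_var=True).statistic
            assert out.loc[i, "t_mod"] == pytest.approx(t_ref, abs=1e-9)

    def test_perfect_separation_single_gene(self):
        m = make_matrix([[0.0, 0.0, 0.0, 1.0, 1.0, 1.0]])
        out = moderated_ttest(m, m.sample_ids[:3], m.sample_ids[3:])
        assert abs(out.loc[0, "t_mod"]) > 1e3
        assert out.loc[0, "p_value"] < 1e-4
        assert bool(out.loc[0, "zero_variance"])

    def test_prior_recovery_and_null_uniformity(self):
        """Simulated null with known prior (d0=4, s0²=1): the fit recovers
        the prior and the p-values are uniform."""
        gen = np.random.default_rng(77)
        n_genes, n_a, n_b = 2000, 4, 4
        d0_true, s0_sq = 4.0, 1.0
        sigma_sq = d0_true * s0_sq / gen.chisquare(d0_true, size=n_genes)
        X = gen.normal(0.0, np.sqrt(sigma_sq)[:, None], size=(n_genes, n_a + n_b))
        m = make_matrix(X)
        out = moderated_ttest(m, m.sample_ids[:n_a], m.sample_ids[n_a:])
        assert out.loc[0, "d0"] == pytest.approx(d0_true, abs=1.0)
        assert out.loc[0, "s0_sq"] == pytest.approx(s0_sq, abs=0.2)
        assert stats.kstest(out["p_value"], "uniform").pvalue > 0.01

    def test_p_monotone_in_abs_t(self, rng):
        m, a, b = _two_group_matrix(rng)
        out = moderated_ttest(m, a, b).sort_values("p_value")
        assert out["t_mod"].abs().is_monotonic_decreasing

    def test_group_of_one_rejected(self, rng):
        m, a, b = _two_group_matrix(rng)
        with pytest.raises(ValidationError):
            moderated_ttest(m, a[:1], b)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_agrees_with_limma_oracle(self, rng, tmp_path):
        """Independent cross-check of the empirical-Bayes machinery against
        Bioconductor limma on a random two-group matrix."""
        n_a = n_b = 5
        X = rng.normal(6, 1, size=(120, n_a + n_b))
        X[:10, :n_a] += rng.uniform(0.5, 2.0, size=(10, 1))
        m = make_matrix(X)
        (tmp_path / "m.tsv").write_text(
            m.frame.to_csv(sep="\t", index_label="gene_id")
        )
        rcode = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{tmp_path}/m.tsv", row.names=1))
        design <- cbind(1, c(rep(1, {n_a}), rep(0, {n_b})))
        fit <- eBayes(lmFit(x, design))
        out <- data.frame(t=fit$t[,2], p=fit$p.value[,2], d0=fit$df.prior, s0=fit$s2.prior)
        write.csv(out, "{tmp_path}/limma.csv")
        """
        (tmp_path / "run.R").write_text(rcode)
        subprocess.run(["Rscript", str(tmp_path / "run.R")], check=True,
                       capture_output=True, timeout=300)
        ref = pd.read_csv(tmp_path / "limma.csv", index_col=0)
        out = moderated_ttest(m, m.sample_ids[:n_a], m.sample_ids[n_a:])
        assert out.loc[0, "d0"] == pytest.approx(ref["d0"].iloc[0], rel=0.1)
        assert out.loc[0, "s0_sq"] == pytest.approx(ref["s0"].iloc[0], rel=0.1)
        np.testing.assert_allclose(out["t_mod"], ref["t"].to_numpy(), rtol=0.05)
        np.testing.assert_allclose(out["p_value"], ref["p"].to_numpy(),
                                   rtol=0.2, atol=1e-4)


class TestClusterDegs:
    def test_vacuous_threshold_selects_everything(self, rng):
        m = make_matrix(rng.normal(size=(10, 9)))
        labels = pd.Series(["A"] * 3 + ["B"] * 3 + ["C"] * 3, index=m.sample_ids)
        _, shared, _ = cluster_degs(m, labels, p_cut=1.0)
        assert shared == set(m.gene_ids)

    def test_constant_gene_in_no_deg_set(self, rng):
        X = rng.normal(size=(5, 12))
        X[2] = 3.14
        m = make_matrix(X)
        labels = pd.Series(["A"] * 4 + ["B"] * 4 + ["C"] * 4, index=m.sample_ids)
        deg_sets, shared, _ = cluster_degs(m, labels, p_cut=0.05)
        for s in deg_sets.values():
            assert "G3" not in s

    def test_requires_three_clusters(self, rng):
        m = make_matrix(rng.normal(size=(4, 8)))
        labels = pd.Series(["A"] * 4 + ["B"] * 4, index=m.sample_ids)
        with pytest.raises(ValidationError):
            cluster_degs(m, labels)

    def test_planted_shared_degs_recovered(self, small_cohort):
        """Signature genes (shifted between all cluster pairs) populate the
        intersection; background genes stay out of it."""
        _, expr, meta, truth = small_cohort
        ra = meta.loc[meta.disease_status == "RA", "sample_id"].tolist()
        deg_sets, shared, _ = cluster_degs(
            expr.subset_samples(ra), truth.cluster[ra], p_cut=0.05
        )
        signature = {g for gs in truth.signature_sets.values() for g in gs}
        assert len(shared & signature) / len(signature) > 0.9
        background = {g for g in expr.gene_ids if g.startswith("BG")}
        assert len(shared & background) / len(background) < 0.05

    def test_gene_cluster_reclustering_reproduces_sample_clusters(self):
        """Consensus clustering of RA samples on the shared DEGs recovers
        the regulator-defined subgroups (three stable transcriptomic
        phenotypes). Run at study scale: in smaller cohorts the treated
        responder subpopulation (a quarter of samples, displaced on the
        same signature genes) legitimately competes with the third
        cluster for the k = 3 cut."""
        from sklearn.metrics import adjusted_rand_score

        from m6apattern.consensus import run_consensus
        from m6apattern.synthetic import SyntheticConfig, generate_cohort

        expr, meta, truth = generate_cohort(SyntheticConfig(seed=1))
        ra = meta.loc[meta.disease_status == "RA", "sample_id"].tolist()
        _, shared, _ = cluster_degs(expr.subset_samples(ra), truth.cluster[ra])
        X = expr.subset_samples(ra).subset_genes(sorted(shared)).frame.to_numpy().T
        res = run_consensus(X, H=60, seed=1)
        ari = adjusted_rand_score(truth.cluster[ra], res.labels_per_k[3])
        assert ari > 0.8

    def test_one_vs_rest_mode_runs(self, rng):
        m = make_matrix(rng.normal(size=(8, 9)))
        labels = pd.Series(["A"] * 3 + ["B"] * 3 + ["C"] * 3, index=m.sample_ids)
        deg_sets, _, _ = cluster_degs(m, labels, contrasts="one_vs_rest")
        assert set(deg_sets) == {"AvsRest", "BvsRest", "CvsRest"}


def brute_force_hypergeom_tail(N, K, n, k):
    from math import comb

    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)) / comb(N, n)


class TestOra:
    def test_hand_computed_tail(self):
        # N=20, K=5, n=5, k=4: p = (C(5,4)C(15,1) + C(5,5)C(15,0)) / C(20,5)
        universe = [f"G{i}" for i in range(20)]
        sets = GeneSetCollection({"S": universe[:5]})
        selected = universe[:4] + [universe[10]]
        out = ora_hypergeometric(selected, universe, sets)
        assert out.loc[0, "overlap"] == 4
        assert out.loc[0, "p_value"] == pytest.approx(76 / 15504, abs=1e-12)

    def test_matches_enumeration_for_small_universes(self, rng):
        for trial in range(30):
            gen = np.random.default_rng(trial)
            N = int(gen.integers(5, 26))
            universe = [f"G{i}" for i in range(N)]
            K = int(gen.integers(1, N))
            n = int(gen.integers(1, N))
            members = list(gen.choice(universe, size=K, replace=False))
            selected = list(gen.choice(universe, size=n, replace=False))
            out = ora_hypergeometric(selected, universe, GeneSetCollection({"S": members}))
            k = len(set(selected) & set(members))
            assert out.loc[0, "p_value"] == pytest.approx(
                brute_force_hypergeom_tail(N, K, n, k), abs=1e-10
            ), (N, K, n, k)

    def test_selected_equals_universe_is_degenerate(self):
        universe = [f"G{i}" for i in range(8)]
        out = ora_hypergeometric(universe, universe, GeneSetCollection({"S": universe[:3]}))
        # X = K deterministically, so P(X >= K) = 1
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_zero_overlap_p_at_most_one(self):
        universe = [f"G{i}" for i in range(10)]
        out = ora_hypergeometric(universe[5:7], universe, GeneSetCollection({"S": universe[:2]}))
        assert out.loc[0, "overlap"] == 0
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(ValidationError, match="GX"):
            ora_hypergeometric(["GX"], ["G1", "G2"], GeneSetCollection({"S": ["G1"]}))
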