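"""Filters, pairwise-contrast DEG signatures and backward elimination."""

import itertools
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import bcsubtype as bc
from bcsubtype.errors import ValidationError
from bcsubtype.features import fit_variance_prior


def _expr(rows, genes, samples):
    return bc.ExpressionMatrix(pd.DataFrame(rows, index=genes, columns=samples))


def _two_class_labels(n, switch):
    return {f"s{i:02d}": ("A" if i < switch else "B") for i in range(n)}


class TestFisher:
    def test_identical_class_means_score_zero(self):
        expr = _expr([[1.0, 2.0, 1.0, 2.0]], ["G1"], [f"s{i:02d}" for i in range(4)])
        assert bc.fisher_scores(expr, _two_class_labels(4, 2)).scores["G1"] == 0.0

    def test_hand_computed_value(self):
        # classes {0,2} vs {4,6}: between = 2*(1-3)^2 + 2*(5-3)^2 = 16,
        # within  = 2*1 + 2*1 = 4 (population variances) -> F = 4
        expr = _expr([[0.0, 2.0, 4.0, 6.0]], ["G1"], [f"s{i:02d}" for i in range(4)])
        assert bc.fisher_scores(expr, _two_class_labels(4, 2)).scores["G1"] == pytest.approx(4.0)

    def test_zero_within_variance_gives_large_finite_score(self):
        expr = _expr([[1.0, 1.0, 5.0, 5.0]], ["G1"], [f"s{i:02d}" for i in range(4)])
        score = bc.fisher_scores(expr, _two_class_labels(4, 2)).scores["G1"]
        assert np.isfinite(score) and score > 1e10

    def test_class_with_one_sample_errors(self):
        expr = _expr([[1.0, 2.0, 3.0]], ["G1"], ["s00", "s01", "s02"])
        with pytest.raises(ValidationError, match="1 sample"):
            bc.fisher_scores(expr, {"s00": "A", "s01": "A", "s02": "B"})


class TestMutualInformationAndChi2:
    def test_perfectly_aligned_binary_gene_is_one_bit_and_chi2_twenty(self):
        values = [0.0] * 10 + [1.0] * 10
        expr = _expr([values], ["G1"], [f"s{i:02d}" for i in range(20)])
        labels = _two_class_labels(20, 10)
        assert bc.mutual_information_scores(expr, labels, bins=2).scores["G1"] == pytest.approx(1.0)
        # contingency [[10,0],[0,10]], E=5 per cell: chi2 = 4 * 25/5 = 20
        assert bc.chi_squared_scores(expr, labels, bins=2).scores["G1"] == pytest.approx(20.0)

    def test_label_independent_gene_scores_near_zero(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=200)
        expr = _expr([values], ["G1"], [f"s{i:03d}" for i in range(200)])
        labels = {f"s{i:03d}": ("A" if i % 2 else "B") for i in range(200)}
        assert bc.mutual_information_scores(expr, labels).scores["G1"] < 0.05
        assert bc.chi_squared_scores(expr, labels).scores["G1"] < 12.0

    def test_constant_gene_scores_zero(self):
        expr = _expr([[3.0] * 8, list(range(8))], ["FLAT", "VAR"],
                     [f"s{i:02d}" for i in range(8)])
        labels = _two_class_labels(8, 4)
        assert bc.mutual_information_scores(expr, labels).scores["FLAT"] == 0.0
        assert bc.chi_squared_scores(expr, labels).scores["FLAT"] == 0.0

    def test_bins_below_two_rejected(self):
        expr = _expr([[1.0, 2.0]], ["G1"], ["s00", "s01"])
        with pytest.raises(ValidationError):
            bc.mutual_information_scores(expr, _two_class_labels(2, 1), bins=1)


class TestSpearmanLabelScores:
    def test_gene_ordered_with_one_class_indicator(self):
        # class A samples all below class B samples: |rho| equals the
        # rank-biserial-style correlation of that split
        values = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        expr = _expr([values], ["G1"], [f"s{i:02d}" for i in range(6)])
        labels = _two_class_labels(6, 3)
        score = bc.spearman_label_scores(expr, labels).scores["G1"]
        indicator = [0, 0, 0, 1, 1, 1]
        oracle = abs(np.corrcoef(pd.Series(values).rank(), pd.Series(indicator).rank())[0, 1])
        assert score == pytest.approx(oracle)
        assert score > 0.8

    def test_shuffled_labels_score_near_zero_and_constant_gene_zero(self):
        rng = np.random.default_rng(1)
        expr = _expr([rng.normal(size=100), [2.0] * 100], ["G1", "FLAT"],
                     [f"s{i:03d}" for i in range(100)])
        labels = {f"s{i:03d}": ("A" if i % 2 else "B") for i in range(100)}
        scores = bc.spearman_label_scores(expr, labels).scores
        assert scores["G1"] < 0.2
        assert scores["FLAT"] == 0.0


class TestTopK:
    def test_selection_and_tie_determinism(self):
        ranking = bc.FeatureRanking("demo", pd.Series({"A": 3.0, "B": 1.0, "C": 2.0}))
        assert bc.top_k(ranking, 2).genes == ("A", "C")
        tied = bc.FeatureRanking("demo", pd.Series({"Z": 1.0, "M": 1.0, "A": 1.0}))
        assert bc.top_k(tied, 2).genes == ("A", "M")
        assert bc.top_k(ranking, 3).genes == ("A", "C", "B")
        with pytest.raises(ValidationError):
            bc.top_k(ranking, 4)


class TestPairwiseDEG:
    def test_five_classes_yield_ten_contrasts(self, noiseless_cohort):
        cohort = noiseless_cohort
        # add noise so variances are defined
        rng = np.random.default_rng(0)
        noisy = bc.ExpressionMatrix(cohort.expression.values
                                    + rng.normal(0, 0.5, cohort.expression.shape))
        contrasts = bc.pairwise_deg(noisy, cohort.true_labels)
        assert len(contrasts) == 10
        assert len({c.class_pair for c in contrasts}) == 10

    def test_unmoderated_two_class_equals_plain_t_test(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(size=(20, 16))
        genes = [f"G{i:02d}" for i in range(20)]
        samples = [f"s{i:02d}" for i in range(16)]
        expr = _expr(mat, genes, samples)
        labels = _two_class_labels(16, 7)
        result = bc.pairwise_deg(expr, labels, moderation="none")[0]
        from scipy import stats as sps
        t_oracle, p_oracle = sps.ttest_ind(mat[:, :7], mat[:, 7:], axis=1)
        assert np.allclose(result.table["statistic"], t_oracle)
        assert np.allclose(result.table["p_value"], p_oracle)

    def test_null_data_bh_keeps_false_positives_near_alpha(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(400, 40))
        expr = _expr(mat, [f"G{i:03d}" for i in range(400)],
                     [f"s{i:02d}" for i in range(40)])
        labels = _two_class_labels(40, 20)
        result = bc.pairwise_deg(expr, labels, alpha=0.05)[0]
        assert len(result.significant_genes) / 400 <= 0.05

    def test_planted_shift_tops_its_own_contrast_only(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(size=(30, 40))
        labels = {f"s{i:02d}": ["A", "B", "C", "D"][i // 10] for i in range(40)}
        mat[0, :10] += 4.0   # gene G00 shifted in class A only vs B
        mat[0, 10:20] -= 4.0
        expr = _expr(mat, [f"G{i:02d}" for i in range(30)],
                     [f"s{i:02d}" for i in range(40)])
        contrasts = {c.class_pair: c for c in bc.pairwise_deg(expr, labels)}
        assert contrasts[("A", "B")].significant_genes[0] == "G00"
        assert "G00" not in contrasts[("C", "D")].significant_genes[:5]

    def test_moderated_t_matches_bioconductor_limma(self, tmp_path):
        rng = np.random.default_rng(7)
        n1, n2, g = 6, 8, 60
        sds = rng.uniform(0.3, 2.0, size=g)
        a = rng.normal(5, 1, size=(g, 1)) + rng.normal(0, sds[:, None], size=(g, n1))
        b = a[:, :1] + np.r_[np.full(10, 1.5), np.zeros(g - 10)][:, None] \
            + rng.normal(0, sds[:, None], size=(g, n2))
        mat = np.hstack([a, b])
        genes = [f"G{i:03d}" for i in range(g)]
        samples = [f"s{i:02d}" for i in range(n1 + n2)]
        df = pd.DataFrame(mat, index=genes, columns=samples)
        fixture = tmp_path / "fixture.tsv"
        df.to_csv(fixture, sep="\t")
        script = tmp_path / "check.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(limma))
            mat <- as.matrix(read.delim("{fixture}", row.names=1))
            group <- factor(c(rep("X", {n1}), rep("Y", {n2})), levels=c("Y", "X"))
            fit <- eBayes(lmFit(mat, model.matrix(~group)))
            out <- topTable(fit, coef=2, number=Inf, sort.by="none")
            write.table(data.frame(t=out$t, p=out$P.Value),
                        "{tmp_path}/limma.tsv", sep="\\t", quote=FALSE, row.names=FALSE)
        """))
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        oracle = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        labels = {s: ("X" if i < n1 else "Y") for i, s in enumerate(samples)}
        ours = bc.pairwise_deg(bc.ExpressionMatrix(df), labels)[0]
        assert np.allclose(ours.table["statistic"].to_numpy(), oracle["t"].to_numpy(),
                           rtol=1e-8)
        assert np.allclose(ours.table["p_value"].to_numpy(), oracle["p"].to_numpy(),
                           rtol=1e-6, atol=1e-12)

    def test_variance_prior_infinite_when_variances_homogeneous(self):
        d0, s0 = fit_variance_prior(np.full(100, 2.0), df=10)
        assert np.isinf(d0) and s0 == pytest.approx(2.0, rel=0.3)


@pytest.fixture(scope="module")
def planted_contrasts():
    config = bc.SimulationConfig(seed=0)
    pairs = list(itertools.combinations(config.classes, 2))
    config = bc.plant_pairwise_de(config, pairs, genes_per_pair=5, shift=2.0)
    cohort = bc.simulate_cohort(config)
    return cohort, bc.pairwise_deg(cohort.expression, cohort.true_labels)


class TestLimmaN:
    def test_saturation_when_n_exceeds_every_list(self):
        tables = []
        for pair, genes in [(("A", "B"), ["G1", "G2"]), (("A", "C"), ["G3"])]:
            table = pd.DataFrame({"statistic": [5.0] * len(genes),
                                  "p_value": [1e-6] * len(genes),
                                  "adj_p_value": [1e-5] * len(genes)}, index=genes)
            tables.append(bc.ContrastResult(pair, table, tuple(genes)))
        sig = bc.limma_n_signature(tables, 100)
        assert set(sig.genes) == {"G1", "G2", "G3"}

    def test_disjoint_top_lists_give_union_of_size_n_times_contrasts(self, planted_contrasts):
        cohort, contrasts = planted_contrasts
        sig1 = bc.limma_n_signature(contrasts, 1)
        assert len(sig1.genes) <= 10

    def test_recovers_planted_genes(self, planted_contrasts):
        cohort, contrasts = planted_contrasts
        sig = bc.limma_n_signature(contrasts, 50)
        planted = set(g for gs in cohort.planted_de_genes.values() for g in gs)
        recall = len(planted & set(sig.genes)) / len(planted)
        assert recall >= 0.9

    def test_monotone_in_n(self, planted_contrasts):
        _, contrasts = planted_contrasts
        previous: set[str] = set()
        for n in (5, 20, 50, 200):
            genes = set(bc.limma_n_signature(contrasts, n).genes)
            assert previous <= genes
            previous = genes

    def test_empty_lists_error(self):
        table = pd.DataFrame({"statistic": [], "p_value": [], "adj_p_value": []})
        with pytest.raises(ValidationError, match="empty"):
            bc.limma_n_signature([bc.ContrastResult(("A", "B"), table, ())], 10)


class TestBackwardElimination:
    def test_infinite_threshold_keeps_everything(self, bwe_fixture, bwe_trainer):
        expr, labels = bwe_fixture
        start = bc.GeneSignature("start", ("INFO", "NOISE"))
        out = bc.backward_elimination(expr, labels, start, bwe_trainer,
                                      gain_threshold=float("inf"), runs=2, seed=0)
        assert set(out.genes) == {"INFO", "NOISE"}

    def test_degrading_noise_gene_removed_in_every_run(self, bwe_fixture, bwe_trainer):
        expr, labels = bwe_fixture
        # premise check: dropping the noise gene improves CV accuracy
        assert bwe_trainer(expr.subset_genes(["INFO"]), labels) \
            > bwe_trainer(expr, labels) + 0.001
        start = bc.GeneSignature("start", ("INFO", "NOISE"))
        out = bc.backward_elimination(expr, labels, start, bwe_trainer,
                                      gain_threshold=0.001, runs=4, seed=0)
        assert out.genes == ("INFO",)
        for kept in out.provenance["kept_per_run"]:
            assert "NOISE" not in kept

    def test_union_and_subset_invariants(self, bwe_fixture, bwe_trainer):
        expr, labels = bwe_fixture
        start = bc.GeneSignature("start", ("INFO", "NOISE"))
        out = bc.backward_elimination(expr, labels, start, bwe_trainer,
                                      gain_threshold=0.001, runs=3, seed=1)
        kept_runs = [set(k) for k in out.provenance["kept_per_run"]]
        assert set(out.genes) <= set(start.genes)
        assert set.intersection(*kept_runs) <= set(out.genes)
        assert set(out.genes) == set.union(*kept_runs)

    def test_all_runs_failing_is_an_error(self, bwe_fixture):
        expr, labels = bwe_fixture

        def broken_trainer(_expr, _labels):
            raise RuntimeError("boom")

        start = bc.GeneSignature("start", ("INFO",))
        with pytest.raises(ValidationError, match="failed"):
            bc.backward_elimination(expr, labels, start, broken_trainer, runs=2, seed=0)
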