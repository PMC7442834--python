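"""Median and AWCA reference construction, pipeline and stability harness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import bcsubtype as bc
from bcsubtype.errors import ValidationError


def _annotations(er_map):
    return [bc.CohortAnnotations(sample_id=s, er_status=e) for s, e in er_map.items()]


class TestStratifiedSubset:
    @pytest.mark.parametrize("size,frac,n_pos,n_neg", [
        (10, 0.6, 6, 4),
        (400, 0.6, 240, 160),  # the 60/40 convention at the standard subset size
        (5, 0.5, 3, 2),        # round-half-up on the ER+ quota
    ])
    def test_quota_arithmetic(self, size, frac, n_pos, n_neg):
        anns = _annotations({f"p{i}": bc.ERStatus.POS for i in range(400)}
                            | {f"n{i}": bc.ERStatus.NEG for i in range(300)})
        subset = bc.sample_er_stratified_subset(anns, bc.SubsetSpec(size, frac, seed=0))
        assert len(subset) == size
        pos = sum(1 for s in subset if s.startswith("p"))
        assert (pos, size - pos) == (n_pos, n_neg)

    def test_insufficient_stratum_names_shortfall(self):
        anns = _annotations({f"p{i}": bc.ERStatus.POS for i in range(300)}
                            | {f"n{i}": bc.ERStatus.NEG for i in range(3)})
        with pytest.raises(ValidationError, match="ER-.*3.*160"):
            bc.sample_er_stratified_subset(anns, bc.SubsetSpec(400, 0.6, seed=0))

    def test_unknown_er_status_ineligible_and_seed_reproducible(self):
        anns = _annotations({"a": bc.ERStatus.POS, "b": bc.ERStatus.UNKNOWN,
                             "c": bc.ERStatus.NEG, "d": bc.ERStatus.POS})
        spec = bc.SubsetSpec(2, 0.5, seed=7)
        subset = bc.sample_er_stratified_subset(anns, spec)
        assert "b" not in subset
        assert subset == bc.sample_er_stratified_subset(anns, spec)


class TestMedianReference:
    def test_identical_subset_profiles_give_that_profile(self):
        df = pd.DataFrame({"s1": [1.0, 2.0], "s2": [1.0, 2.0], "s3": [9.0, 9.0]},
                          index=["G1", "G2"])
        ref = bc.build_median_reference(bc.ExpressionMatrix(df), ["s1", "s2"])
        assert list(ref.values) == [1.0, 2.0]

    def test_odd_and_even_counts_match_sort_and_pick_oracle(self):
        df = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [10.0], "s4": [3.0]},
                          index=["G1"])
        expr = bc.ExpressionMatrix(df)
        assert bc.build_median_reference(expr, ["s1", "s2", "s3"]).values["G1"] == 2.0
        assert bc.build_median_reference(expr, ["s1", "s2", "s3", "s4"]).values["G1"] == 2.5

    def test_single_sample_subset_is_that_sample(self):
        df = pd.DataFrame({"s1": [1.5, 2.5], "s2": [0.0, 0.0]}, index=["G1", "G2"])
        ref = bc.build_median_reference(bc.ExpressionMatrix(df), ["s1"])
        assert list(ref.values) == [1.5, 2.5]

    def test_unknown_sample_errors(self):
        df = pd.DataFrame({"s1": [1.0]}, index=["G1"])
        with pytest.raises(ValidationError):
            bc.build_median_reference(bc.ExpressionMatrix(df), ["nope"])


class TestAWCAReference:
    def test_outer_average_of_class_means(self):
        df = pd.DataFrame({"a1": [1.0], "a2": [3.0], "b1": [4.0]}, index=["G1"])
        calls = {"a1": "A", "a2": "A", "b1": "B"}
        ref = bc.build_awca_reference(bc.ExpressionMatrix(df), calls, min_class_size=1)
        assert ref.values["G1"] == 3.0  # mean(mean(1,3)=2, mean(4)=4)

    def test_excluded_class_dropped_from_outer_average(self):
        df = pd.DataFrame({"a": [2.0], "b": [4.0], "n": [100.0]}, index=["G1"])
        calls = {"a": "A", "b": "B", "n": "NORMAL"}
        ref = bc.build_awca_reference(bc.ExpressionMatrix(df), calls,
                                      excluded_classes={"NORMAL"}, min_class_size=1)
        assert ref.values["G1"] == 3.0

    def test_min_class_size_auto_exclusion(self):
        df = pd.DataFrame({f"a{i}": [float(i)] for i in range(3)}
                          | {f"b{i}": [10.0 + i] for i in range(3)} | {"c0": [99.0]},
                          index=["G1"])
        calls = {f"a{i}": "A" for i in range(3)} | {f"b{i}": "B" for i in range(3)} | {"c0": "C"}
        ref = bc.build_awca_reference(bc.ExpressionMatrix(df), calls, min_class_size=2)
        assert ref.values["G1"] == (1.0 + 11.0) / 2  # C dropped

    def test_fewer_than_two_retained_classes_errors_with_sizes(self):
        df = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["G1"])
        with pytest.raises(ValidationError, match="class sizes"):
            bc.build_awca_reference(bc.ExpressionMatrix(df), {"a": "A", "b": "B"},
                                    min_class_size=5)

    def test_triplicating_a_class_leaves_reference_bit_identical(self, default_cohort):
        cohort = default_cohort
        calls = {s: cohort.true_labels[s] for s in cohort.expression.samples}
        base = bc.build_awca_reference(cohort.expression, calls)
        luma = [s for s in cohort.expression.samples if calls[s] == "LUMA"]
        dup_frames = [cohort.expression.values]
        dup_calls = dict(calls)
        for copy in (1, 2):
            frame = cohort.expression.values[luma].copy()
            frame.columns = [f"{s}__dup{copy}" for s in luma]
            dup_frames.append(frame)
            dup_calls.update({f"{s}__dup{copy}": "LUMA" for s in luma})
        augmented = bc.ExpressionMatrix(pd.concat(dup_frames, axis=1))
        dup = bc.build_awca_reference(augmented, dup_calls)
        assert np.array_equal(base.values.to_numpy(), dup.values.to_numpy())

    def test_median_reference_lacks_duplication_invariance(self, default_cohort):
        # witness: skewed duplication of one class shifts per-gene medians
        cohort = default_cohort
        luma = [s for s in cohort.expression.samples if cohort.true_labels[s] == "LUMA"]
        frame = cohort.expression.values[luma].copy()
        frame.columns = [f"{s}__dup" for s in luma]
        augmented = bc.ExpressionMatrix(pd.concat([cohort.expression.values, frame], axis=1))
        base = bc.build_median_reference(cohort.expression, cohort.expression.samples)
        dup = bc.build_median_reference(augmented, augmented.samples)
        assert not np.array_equal(base.values.to_numpy(), dup.values.to_numpy())

    @given(st.integers(0, 2 ** 31 - 1))
    def test_sample_order_never_affects_references(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(5, 12)), index=[f"G{i}" for i in range(5)],
                          columns=[f"s{i}" for i in range(12)])
        calls = {f"s{i}": ("A" if i < 6 else "B") for i in range(12)}
        expr = bc.ExpressionMatrix(df)
        order = list(rng.permutation(df.columns))
        shuffled = expr.subset_samples(order)
        a1 = bc.build_awca_reference(expr, calls, min_class_size=1)
        a2 = bc.build_awca_reference(shuffled, calls, min_class_size=1)
        assert np.array_equal(a1.values.to_numpy(), a2.values.to_numpy())
        m1 = bc.build_median_reference(expr, df.columns[:7])
        m2 = bc.build_median_reference(shuffled, df.columns[:7])
        assert np.array_equal(m1.values.to_numpy(), m2.values.to_numpy())


class TestPipeline:
    def test_noiseless_cohort_recovers_all_labels(self, noiseless_cohort):
        cohort = noiseless_cohort
        result = bc.awca_pipeline(cohort.expression, list(cohort.annotations),
                                  cohort.planted_centroids, bc.SubsetSpec(60, seed=2))
        assert bc.concordance(result.calls, cohort.true_labels) == 100.0

    def test_same_seed_reproduces_reference_and_calls(self, default_cohort):
        cohort = default_cohort
        kwargs = dict(expr=cohort.expression, annotations=list(cohort.annotations),
                      centroids=cohort.planted_centroids, spec=bc.SubsetSpec(100, seed=5))
        a = bc.awca_pipeline(**kwargs)
        b = bc.awca_pipeline(**kwargs)
        assert np.array_equal(a.reference.values.to_numpy(), b.reference.values.to_numpy())
        assert all(x.call == y.call for x, y in zip(a.calls, b.calls))

    def test_awca_round_is_more_concordant_across_seeds_than_preliminary(self, default_cohort):
        cohort = default_cohort
        runs = [bc.awca_pipeline(cohort.expression, list(cohort.annotations),
                                 cohort.planted_centroids, bc.SubsetSpec(100, seed=s))
                for s in (101, 202)]
        prelim = bc.concordance(runs[0].preliminary_calls, runs[1].preliminary_calls)
        final = bc.concordance(runs[0].calls, runs[1].calls)
        assert final >= prelim

    def test_precomputed_labels_skip_preliminary_step(self, default_cohort):
        cohort = default_cohort
        result = bc.awca_pipeline(cohort.expression, None, cohort.planted_centroids,
                                  preliminary_labels=cohort.true_labels)
        assert result.preliminary_calls is None
        assert bc.concordance(result.calls, cohort.true_labels) > 90.0

    def test_small_subset_triggers_recommendation_warning(self, default_cohort):
        cohort = default_cohort
        with pytest.warns(UserWarning, match="recommended"):
            bc.awca_pipeline(cohort.expression, list(cohort.annotations),
                             cohort.planted_centroids, bc.SubsetSpec(30, seed=1))


class TestStabilityExperiment:
    def test_noiseless_cohort_yields_perfect_concordance(self, noiseless_cohort):
        cohort = noiseless_cohort
        report = bc.stability_experiment(
            cohort.expression, list(cohort.annotations), cohort.planted_centroids,
            sizes=[40], replicates=3, truth_labels=cohort.true_labels, seed=0)
        for cell in report.cells.values():
            assert cell.truth_concordances == [100.0, 100.0, 100.0]
            assert all(v == 100.0 for v in cell.pairwise_concordances)
            assert cell.pairwise_sd == 0.0

    def test_single_replicate_has_empty_pairwise_lists(self, noiseless_cohort):
        cohort = noiseless_cohort
        with pytest.warns(UserWarning, match="pairwise"):
            report = bc.stability_experiment(
                cohort.expression, list(cohort.annotations), cohort.planted_centroids,
                sizes=[40], replicates=1, truth_labels=cohort.true_labels, seed=0)
        for cell in report.cells.values():
            assert cell.pairwise_concordances == []

    def test_infeasible_size_is_skipped_and_counted(self, noiseless_cohort):
        cohort = noiseless_cohort
        report = bc.stability_experiment(
            cohort.expression, list(cohort.annotations), cohort.planted_centroids,
            sizes=[10_000], replicates=2, truth_labels=cohort.true_labels, seed=0)
        for cell in report.cells.values():
            assert cell.skipped == 2 and cell.truth_concordances == []
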