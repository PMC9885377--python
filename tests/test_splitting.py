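"""Split/transform ordering semantics and the leakage auditor."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlpitfalls import (
    ConfigurationError,
    LabeledTable,
    OrderingPolicy,
    PatchConfig,
    SplitKind,
    Subset,
    TabularConfig,
    Transform,
    When,
    augment,
    gen_patient_patches,
    gen_tabular,
    leakage_audit,
    materialize,
    oversample,
    select_top_features,
    split_grouped,
    split_random,
)
from mlpitfalls.errors import DegenerateDataError, InfeasibleSplitError
from mlpitfalls.splitting import feature_scores
from oracles import pooled_t_scores, spanning_id_count


class TestSplitRandom:
    def test_largest_remainder_sizes(self):
        table = gen_tabular(TabularConfig(n_patients=10, seed=0))
        split = split_random(table, (0.6, 0.2, 0.2), seed=1)
        assert split.sizes() == (6, 2, 2)
        assert not split.grouped

    def test_all_train_ratio(self):
        table = gen_tabular(TabularConfig(n_patients=10, seed=0))
        split = split_random(table, (1.0, 0.0, 0.0), seed=1)
        assert split.sizes() == (10, 0, 0)

    def test_bad_ratios_rejected(self):
        table = gen_tabular(TabularConfig(n_patients=10, seed=0))
        with pytest.raises(ConfigurationError):
            split_random(table, (0.5, 0.2, 0.2), seed=1)

    def test_row_level_split_scatters_patients(self):
        table = gen_patient_patches(
            PatchConfig(n_patients=10, patches_per_patient=200, seed=2)
        )
        split = split_random(table, seed=3)
        train, val, test = split.apply(table)
        audit = leakage_audit(train, val, test)
        assert audit["patient_id"] > 0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(4, 60), st.integers(0, 2**32 - 1))
    def test_partition_property(self, n, seed):
        table = gen_tabular(TabularConfig(n_patients=max(n, 4), seed=0))
        split = split_random(table, (0.6, 0.2, 0.2), seed=seed)
        assert sum(split.sizes()) == len(table)
        counts = np.bincount(split.subset_of, minlength=3)
        assert tuple(counts) == split.sizes()


class TestSplitGrouped:
    def test_group_sizes_and_row_counts(self):
        table = gen_patient_patches(
            PatchConfig(n_patients=10, patches_per_patient=200, seed=4)
        )
        split = split_grouped(table, (0.6, 0.2, 0.2), seed=5)
        assert split.sizes() == (1200, 400, 400)
        train, val, test = split.apply(table)
        assert leakage_audit(train, val, test) == {
            "provenance_id": 0,
            "patient_id": 0,
        }

    def test_three_groups_one_per_subset(self):
        table = gen_patient_patches(
            PatchConfig(n_patients=4, patches_per_patient=5, seed=6)
        ).take(range(15))  # keep 3 patients
        split = split_grouped(table, (0.34, 0.33, 0.33), seed=7)
        subsets_by_patient = {
            p: set(split.subset_of[table.patient_id == p]) for p in set(table.patient_id)
        }
        assert all(len(s) == 1 for s in subsets_by_patient.values())
        assert sorted(s.pop() for s in subsets_by_patient.values()) == [0, 1, 2]

    def test_too_few_groups_rejected(self):
        table = gen_tabular(TabularConfig(n_patients=4, seed=0)).take([0, 1])
        with pytest.raises(InfeasibleSplitError):
            split_grouped(table, (0.34, 0.33, 0.33), seed=0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_group_coherence_for_all_seeds(self, seed):
        table = gen_patient_patches(
            PatchConfig(n_patients=8, patches_per_patient=7, seed=1)
        )
        split = split_grouped(table, seed=seed)
        train, val, test = split.apply(table)
        assert leakage_audit(train, val, test)["patient_id"] == 0


class TestOversample:
    def test_balances_counts_exactly(self, imbalanced_table):
        out = oversample(imbalanced_table, seed=0)
        assert out.class_counts() == (90, 90)
        assert len(out) == 180
        # originals untouched, in order
        np.testing.assert_array_equal(
            out.features[:100], imbalanced_table.features
        )

    def test_duplicates_keep_origin_provenance(self, imbalanced_table):
        out = oversample(imbalanced_table, seed=0)
        dup = out.take(range(100, 180))
        assert set(dup.provenance_id) <= set(imbalanced_table.sample_id)
        assert (dup.labels == 1).all()

    def test_already_balanced_returned_unchanged(self):
        table = gen_tabular(TabularConfig(n_patients=50, class_fraction=0.5, seed=1))
        assert oversample(table, seed=0) is table

    def test_single_class_rejected(self, imbalanced_table):
        only_neg = imbalanced_table.take(np.flatnonzero(imbalanced_table.labels == 0))
        with pytest.raises(DegenerateDataError):
            oversample(only_neg)

    def test_duplicates_scatter_across_random_split(self, imbalanced_table):
        out = oversample(imbalanced_table, seed=0)
        train, val, test = split_random(out, seed=1).apply(out)
        assert leakage_audit(train, val, test)["provenance_id"] > 0


class TestAugment:
    def test_zero_copies_is_identity(self, tiny_table):
        assert augment(tiny_table, 0, 0.5, seed=0) is tiny_table

    def test_row_count_and_provenance(self):
        table = gen_tabular(TabularConfig(n_patients=100, seed=2))
        out = augment(table, 3, 0.1, seed=0)
        assert len(out) == 400
        assert len(set(out.provenance_id)) == 100

    def test_zero_jitter_copies_are_bitwise_equal(self, tiny_table):
        out = augment(tiny_table, 2, 0.0, seed=0)
        np.testing.assert_array_equal(out.features[6:12], tiny_table.features)
        np.testing.assert_array_equal(out.features[12:18], tiny_table.features)

    def test_copies_inherit_label_and_patient(self, tiny_table):
        out = augment(tiny_table, 1, 0.3, seed=0)
        np.testing.assert_array_equal(out.labels[6:], tiny_table.labels)
        assert list(out.patient_id[6:]) == list(tiny_table.patient_id)

    def test_negative_copies_rejected(self, tiny_table):
        with pytest.raises(ConfigurationError):
            augment(tiny_table, -1, 0.1)


class TestSelectTopFeatures:
    def test_label_feature_ranked_first(self, tiny_table):
        # feature_0 equals the label: zero pooled variance, maximal score
        assert select_top_features(tiny_table, 1)[0] == 0

    def test_ranking_matches_brute_force(self, tiny_table):
        ranked = select_top_features(tiny_table, 4)
        oracle = pooled_t_scores(tiny_table.features, tiny_table.labels)
        # ties broken by lower index: stable argsort on negated scores
        expected = np.array(sorted(range(4), key=lambda j: (-oracle[j], j)))
        np.testing.assert_array_equal(ranked, expected)
        assert feature_scores(tiny_table)[3] == 0.0  # constant feature scores 0

    def test_full_k_is_a_permutation(self, tiny_table):
        assert sorted(select_top_features(tiny_table, 4)) == [0, 1, 2, 3]

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(6, 50), st.integers(2, 20), st.integers(0, 2**32 - 1))
    def test_scores_match_brute_force_on_random_tables(self, n, p, seed):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, dtype=int)
        labels[: n // 2] = 1
        table = LabeledTable(
            features=rng.standard_normal((n, p)),
            labels=labels,
            patient_id=np.array([f"P{i}" for i in range(n)], dtype=object),
        )
        np.testing.assert_allclose(
            feature_scores(table),
            pooled_t_scores(table.features, table.labels),
            rtol=1e-10,
        )


class TestMaterializeAndAudit:
    def test_policy_none_is_a_plain_split(self, imbalanced_table):
        train, val, test, audit = materialize(
            imbalanced_table, OrderingPolicy(Transform.NONE), seed=0
        )
        assert len(train) + len(val) + len(test) == 100
        assert audit == {"provenance_id": 0, "patient_id": 0}

    def test_oversample_after_split_cannot_leak(self, imbalanced_table):
        _train, _val, _test, audit = materialize(
            imbalanced_table,
            OrderingPolicy(Transform.OVERSAMPLE, When.AFTER_SPLIT),
            seed=0,
        )
        assert audit["provenance_id"] == 0

    def test_oversample_before_split_leaks(self, imbalanced_table):
        _train, _val, _test, audit = materialize(
            imbalanced_table,
            OrderingPolicy(Transform.OVERSAMPLE, When.BEFORE_SPLIT),
            seed=0,
        )
        assert audit["provenance_id"] > 0

    def test_feature_selection_after_split_projects_val_and_test(self, tiny_table):
        train, val, test, _audit = materialize(
            tiny_table,
            OrderingPolicy(Transform.SELECT_FEATURES, When.AFTER_SPLIT),
            ratios=(0.5, 0.25, 0.25),
            k_features=2,
            seed=3,
        )
        assert train.n_features == val.n_features == test.n_features == 2

    def test_audit_equals_set_arithmetic_oracle(self):
        table = gen_tabular(TabularConfig(n_patients=100, class_fraction=0.1, seed=9))
        out = oversample(table, seed=1)
        train, val, test = split_random(out, seed=2).apply(out)
        audit = leakage_audit(train, val, test)
        assert audit["provenance_id"] == spanning_id_count(
            [list(t.provenance_id) for t in (train, val, test)]
        )
        assert audit["patient_id"] == spanning_id_count(
            [list(t.patient_id) for t in (train, val, test)]
        )

    def test_single_duplicate_across_subsets_counts_once(self, tiny_table):
        train = tiny_table.take([0, 1, 2])
        val = tiny_table.take([3])
        test = tiny_table.take([4, 5, 0])  # row 0 appears in TRAIN and TEST
        audit = leakage_audit(train, val, test)
        assert audit["provenance_id"] == 1


def test_subset_enum_covers_three_partitions():
    assert [s.name for s in Subset] == ["TRAIN", "VAL", "TEST"]
    assert SplitKind("random") is SplitKind.RANDOM
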