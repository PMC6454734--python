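"""Normalization, outlier, balance and redundancy contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cometa import (
    SyntheticConfig,
    augment_controls,
    batch_adjust,
    collapse_probes,
    detect_outliers,
    generate_disease,
    log2_transform,
    quantile_normalize,
    rank_study_quality,
    remove_redundant_samples,
    stabilize_counts,
)
from conftest import make_study


def frame(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=genes or [f"g{i}" for i in range(arr.shape[0])],
        columns=samples or [f"x{i}" for i in range(arr.shape[1])],
    )


class TestQuantileNormalize:
    def test_hand_example(self):
        out = quantile_normalize(frame([[1, 4], [2, 5], [3, 6]]))
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.to_numpy(), expected)

    def test_identical_columns_are_fixed_point(self):
        m = frame(np.tile([[3.0], [1.0], [2.0]], (1, 4)))
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    @settings(deadline=None, max_examples=25)
    @given(
        arrays(
            float,
            st.tuples(st.integers(3, 12), st.integers(2, 6)),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
        )
    )
    def test_columns_share_sorted_values_and_idempotence(self, arr):
        out = quantile_normalize(frame(arr))
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        np.testing.assert_allclose(
            sorted_cols - sorted_cols[:, :1], 0.0, atol=1e-9
        )
        twice = quantile_normalize(out)
        np.testing.assert_allclose(twice.to_numpy(), out.to_numpy(), atol=1e-10)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(frame([[1, np.nan], [2, 3]]))


class TestLog2Transform:
    def test_hand_example_and_monotonicity(self):
        out = log2_transform(frame([[1], [3], [7]]), offset=1)
        np.testing.assert_allclose(out.to_numpy().ravel(), [1, 2, 3])
        assert (np.diff(out.to_numpy().ravel()) > 0).all()

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log2_transform(frame([[0.0]]), offset=0)


class TestStabilizeCounts:
    def test_identical_samples_identical_output(self):
        m = frame([[10, 10], [20, 20], [5, 5]])
        out = stabilize_counts(m)
        np.testing.assert_allclose(out.iloc[:, 0], out.iloc[:, 1])

    def test_doubled_library_equalized(self):
        a = np.array([10.0, 20.0, 40.0])
        m = frame(np.column_stack([a, 2 * a]))
        out = stabilize_counts(m)
        # size factors (1/sqrt2, sqrt2) have ratio exactly 2
        np.testing.assert_allclose(out.iloc[:, 0], out.iloc[:, 1], rtol=1e-12)

    def test_zero_gene_retained_but_excluded_from_factors(self):
        m = frame([[10, 20], [0, 0], [5, 10]])
        out = stabilize_counts(m)
        assert out.shape == m.shape
        np.testing.assert_allclose(out.iloc[1], np.log2(1.0), atol=1e-12)
        np.testing.assert_allclose(out.iloc[0, 0], out.iloc[0, 1])

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            stabilize_counts(frame([[1, 0], [2, 0]]))


class TestCollapseProbes:
    def test_single_probe_per_gene_renamed_only(self):
        m = frame([[1, 2], [3, 4]], genes=["p1", "p2"])
        out = collapse_probes(m, {"p1": "GA", "p2": "GB"})
        assert list(out.index) == ["GA", "GB"]
        np.testing.assert_allclose(out.to_numpy(), m.to_numpy())

    def test_max_variance_probe_kept_and_unmapped_dropped(self):
        m = frame([[0, 4], [1, 2], [9, 9]], genes=["p_lo", "p_hi", "p_unmapped"])
        out = collapse_probes(m, {"p_lo": "G", "p_hi": "G"})
        # p_lo has variance 8, p_hi has variance 0.5
        np.testing.assert_allclose(out.loc["G"], [0, 4])

    def test_variance_tie_breaks_lexicographically(self):
        m = frame([[0, 2], [1, 3]], genes=["pb", "pa"])
        out = collapse_probes(m, {"pa": "G", "pb": "G"})
        np.testing.assert_allclose(out.loc["G"], [1, 3])  # pa sorts first

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValueError):
            collapse_probes(frame([[1, 2]]), {})


def _correlated_study(n_genes=400, n_per_group=6, noise=1.0, outlier_cols=(), seed=0):
    """Samples sharing a strong gene baseline; listed columns get huge noise."""
    rng = np.random.default_rng(seed)
    base = rng.normal(0, 4, n_genes)
    cols = []
    for j in range(2 * n_per_group):
        sd = 8.0 if j in outlier_cols else noise
        cols.append(base + rng.normal(0, sd, n_genes))
    groups = ["case"] * n_per_group + ["control"] * n_per_group
    return make_study(np.column_stack(cols), groups)


class TestDetectOutliers:
    def test_clean_group_untouched(self):
        st_ = _correlated_study(noise=0.5)
        kept, removed = detect_outliers(st_, threshold=0.9)
        assert removed == [] and kept.values.shape == st_.values.shape

    def test_single_planted_outlier_removed(self):
        st_ = _correlated_study(outlier_cols=(2,))
        kept, removed = detect_outliers(st_, threshold=0.9)
        assert removed == [st_.sample_ids()[2]]

    def test_two_outliers_removed_worst_first(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 4, 400)
        cols = [base + rng.normal(0, 0.5, 400) for _ in range(4)]
        cols.append(base + rng.normal(0, 6, 400))   # bad
        cols.append(rng.normal(0, 10, 400))         # worse (uncorrelated)
        study = make_study(np.column_stack(cols), ["case"] * 6)
        # give it controls so the contract's per-group precondition holds
        study = make_study(
            np.column_stack(cols + [base + rng.normal(0, 0.5, 400) for _ in range(2)]),
            ["case"] * 6 + ["control"] * 2,
        )
        kept, removed = detect_outliers(study, threshold=0.9)
        ids = study.sample_ids()
        assert removed == [ids[5], ids[4]]

    def test_planted_outliers_recovered_across_seeds(self):
        hits = 0
        for s in range(20):
            cfg = SyntheticConfig(
                n_genes=300, n_studies=1, n_cases_per_study=10,
                n_controls_per_study=10, frac_outliers=0.1, seed=s,
            )
            studies, truth = generate_disease(cfg)
            _, removed = detect_outliers(studies[0])
            hits += set(removed) == set(truth.outlier_samples)
        assert hits >= 19  # >= 95% of seeds


class TestBatchAdjust:
    def test_single_batch_unchanged(self):
        m = frame(np.random.default_rng(0).normal(size=(5, 4)))
        pd.testing.assert_frame_equal(batch_adjust(m, ["b1"] * 4), m)

    def test_constant_shift_removed(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(50, 6))
        shifted = np.column_stack([a[:, :3], a[:, 3:] + 5.0])
        out = batch_adjust(frame(shifted), ["b1"] * 3 + ["b2"] * 3)
        x = out.to_numpy()
        np.testing.assert_allclose(x[:, :3].mean(1), x[:, 3:].mean(1), atol=1e-10)

    def test_pooled_mean_preserved(self):
        rng = np.random.default_rng(2)
        m = frame(rng.normal(size=(40, 8)))
        out = batch_adjust(m, ["b1"] * 3 + ["b2"] * 5)
        np.testing.assert_allclose(
            out.mean(axis=1), m.mean(axis=1), atol=1e-8
        )

    def test_planted_batch_effect_no_longer_dominant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(100, 10))
        offset = rng.normal(0, 3, 100)
        a[:, 5:] += offset[:, None]
        labels = ["b1"] * 5 + ["b2"] * 5
        out = batch_adjust(frame(a), labels).to_numpy()
        # top variance axis should stop separating the batches after adjustment
        def batch_separation(x):
            u, s, vt = np.linalg.svd(x - x.mean(1, keepdims=True))
            pc1 = vt[0]
            return abs(pc1[:5].mean() - pc1[5:].mean())

        assert batch_separation(out) < batch_separation(a) / 2


class TestQualityAndRedundancy:
    def _three_studies(self):
        # target mean inter-sample correlations ~0.96/0.95/0.91 via the
        # baseline-variance to noise-variance ratio c = v/(v+1)
        studies = []
        for sid, corr, seed in (
            ("study_best", 0.96, 0), ("study_mid", 0.95, 1), ("study_low", 0.91, 2),
        ):
            v = corr / (1 - corr)
            rng = np.random.default_rng(seed)
            base = rng.normal(0, np.sqrt(v), 3000)
            cols = np.column_stack([base + rng.normal(0, 1, 3000) for _ in range(8)])
            studies.append(
                make_study(cols, ["case"] * 4 + ["control"] * 4, study_id=sid,
                           patient_ids=[f"{sid}_p{i}" for i in range(8)])
            )
        return studies

    def test_quality_order_matches_correlations(self):
        studies = self._three_studies()
        assert rank_study_quality(studies[::-1]) == [
            "study_best", "study_mid", "study_low",
        ]

    def test_single_study_ranks_itself(self):
        (s,) = [self._three_studies()[0]]
        assert rank_study_quality([s]) == [s.study_id]

    def test_tie_breaks_by_study_id(self):
        s1 = make_study(np.ones((4, 4)) + np.eye(4), ["case"] * 2 + ["control"] * 2, "sB")
        s2 = make_study(np.ones((4, 4)) + np.eye(4), ["case"] * 2 + ["control"] * 2, "sA")
        assert rank_study_quality([s1, s2]) == ["sA", "sB"]

    def test_no_shared_patients_drops_nothing(self):
        studies = self._three_studies()
        out = remove_redundant_samples(studies)
        for a, b in zip(studies, out):
            assert a.sample_ids() == b.sample_ids()

    def test_patient_kept_only_in_best_study(self):
        studies = self._three_studies()
        # plant one patient in all three, one in best+low only
        for st_ in studies:
            st_.samples.iloc[0, 0] = "shared_all"
        studies[0].samples.iloc[1, 0] = "shared_bl"
        studies[2].samples.iloc[1, 0] = "shared_bl"
        out = remove_redundant_samples(studies)
        counts = pd.concat([s.samples["patient_id"] for s in out]).value_counts()
        assert counts["shared_all"] == 1 and counts["shared_bl"] == 1
        assert "shared_all" in set(out[0].samples["patient_id"])
        # every patient appears exactly once across studies
        assert counts.max() == 1
        removed_total = sum(len(s.sample_ids()) for s in studies) - sum(
            len(s.sample_ids()) for s in out
        )
        assert removed_total == 3  # 2 extra copies of shared_all + 1 of shared_bl


class TestAugmentControls:
    def _study_and_pool(self, pool_sex=None, seed=0):
        rng = np.random.default_rng(seed)
        study = _correlated_study(seed=seed)
        pool_cols = np.column_stack(
            [rng.normal(0, 4, 400) + rng.normal(0, 1, 400) for _ in range(30)]
        )
        pool = make_study(
            pool_cols, ["control"] * 30, study_id="pool",
            patient_ids=[f"pool_p{i}" for i in range(30)],
            sexes=pool_sex,
        )
        return study, pool

    def test_zero_additions_is_identity(self):
        study, pool = self._study_and_pool()
        assert augment_controls(study, pool, 0) is study

    def test_balanced_pool_merges_and_tags_origin_batch(self):
        study, pool = self._study_and_pool()
        out = augment_controls(study, pool, 10, seed=1)
        assert out.values.shape[1] == study.values.shape[1] + 10
        assert set(out.samples["batch"]) == {study.study_id, "pool"}
        assert (out.samples["group"] == "control").sum() == 16

    def test_degenerate_pool_warns(self):
        study, pool = self._study_and_pool(pool_sex=["M"] * 30)
        with pytest.warns(UserWarning, match="no covariate-balanced draw"):
            augment_controls(study, pool, 30, seed=2, max_attempts=10)

    def test_case_samples_in_pool_rejected(self):
        study, _ = self._study_and_pool()
        with pytest.raises(ValueError):
            augment_controls(study, study, 2)
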