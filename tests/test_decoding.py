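"""Correlation classifier, t-ranking, and leave-one-run-out CV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohdecode import decoding as dec
from cohdecode import preprocess as pp
from cohdecode.preprocess import SampleSet
from cohdecode.simulate import AcquisitionParams, GroundTruth, RoiSpec, simulate_participant


def make_samples(patterns, labels, runs=None):
    patterns = np.asarray(patterns, dtype=float)
    n = len(patterns)
    return SampleSet(patterns=patterns, labels=np.asarray(labels),
                     run_index=np.asarray(runs if runs is not None else np.zeros(n, int)),
                     block_index=np.arange(n),
                     voxel_order=np.zeros((patterns.shape[1], 3), int))


class TestClassMeans:
    def test_single_sample_per_condition(self):
        ss = make_samples([[1, 2, 3], [4, 5, 6]], ["a", "b"])
        m = dec.class_means(ss)
        assert m["a"] == pytest.approx([1, 2, 3])
        assert m["b"] == pytest.approx([4, 5, 6])

    def test_opposite_samples_cancel(self):
        ss = make_samples([[1, -2, 3], [-1, 2, -3]], ["a", "a"])
        assert dec.class_means(ss)["a"] == pytest.approx([0, 0, 0])

    def test_matches_bruteforce_average(self):
        rng = np.random.default_rng(0)
        pats = rng.standard_normal((8, 5))
        labels = ["a", "b"] * 4
        m = dec.class_means(make_samples(pats, labels))
        for lab in ("a", "b"):
            rows = [p for p, l in zip(pats, labels) if l == lab]
            oracle = np.sum(rows, axis=0) / len(rows)
            assert m[lab] == pytest.approx(oracle, abs=1e-12)

    def test_missing_condition_errors(self):
        ss = make_samples([[1, 2, 3]], ["a"])
        with pytest.raises(ValueError, match="no training samples"):
            dec.class_means(ss, classes=("a", "b"))


class TestVoxelRanking:
    def test_hand_computed_pooled_t(self):
        # voxel 0: a=(1,1) b=(3,1) -> t = 1/1 = -1; voxel 1: a=(2,2) b=(4,2)
        a = np.array([[1.0, 2.0], [1.0, 2.0]])
        b = np.array([[3.0, 4.0], [1.0, 2.0]])
        t = dec.pooled_t(a, b)
        # pooled variance per voxel: (0 + 2) / 2 = 1 -> se = 1; d = -1
        assert t == pytest.approx([-1.0, -1.0])

    def test_constant_voxel_ranked_last(self):
        pats = np.array([[1.0, 0.0], [1.0, 0.1], [1.0, 1.0], [1.0, 1.1]])
        ss = make_samples(pats, ["a", "a", "b", "b"])
        order = dec.rank_voxels_by_t(ss, "a", "b")
        assert list(order) == [1, 0]  # constant voxel has |t| = 0

    def test_zero_variance_unequal_means_ranked_first(self):
        pats = np.array([[0.0, 0.0], [0.0, 2.0], [1.0, 5.0], [1.0, 9.0]])
        ss = make_samples(pats, ["a", "a", "b", "b"])
        order = dec.rank_voxels_by_t(ss, "a", "b")
        assert order[0] == 0  # infinite t beats any finite t

    def test_symmetric_in_class_labels(self):
        rng = np.random.default_rng(1)
        ss = make_samples(rng.standard_normal((10, 7)), ["a", "b"] * 5)
        assert np.array_equal(dec.rank_voxels_by_t(ss, "a", "b"),
                              dec.rank_voxels_by_t(ss, "b", "a"))

    def test_ties_broken_by_ascending_index(self):
        pats = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0],
                         [1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        pats += np.array([[0.1, 0, 0], [-0.1, 0, 0], [0.1, 0, 0], [-0.1, 0, 0]])
        ss = make_samples(pats, ["a", "a", "b", "b"])
        order = dec.rank_voxels_by_t(ss, "a", "b")
        assert list(order)[:2] == [1, 2]  # the two inf-t voxels, index order


class TestCorrelationClassifier:
    def test_assigns_to_more_correlated_mean(self):
        means = {"A": np.array([1.0, 2.0, 3.1]), "B": np.array([3.0, 2.0, 1.0])}
        assert dec.correlation_classify(np.array([1.0, 2.0, 3.0]), means) == "A"

    def test_own_class_mean_wins(self):
        rng = np.random.default_rng(2)
        mean_a = rng.standard_normal(20)
        means = {"A": mean_a, "B": rng.standard_normal(20)}
        assert dec.correlation_classify(mean_a.copy(), means) == "A"

    @given(gain=st.floats(0.1, 50.0), offset=st.floats(-10.0, 10.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_affine_transform(self, gain, offset):
        rng = np.random.default_rng(3)
        test = rng.standard_normal(12)
        means = {"A": rng.standard_normal(12), "B": rng.standard_normal(12)}
        assert (dec.correlation_classify(test, means)
                == dec.correlation_classify(gain * test + offset, means))

    def test_constant_pattern_flagged(self):
        means = {"A": np.full(4, 2.0), "B": np.full(4, 5.0)}
        with pytest.warns(UserWarning, match="undefined"):
            assert dec.correlation_classify(np.ones(4), means) is None

    def test_short_pattern_rejected(self):
        with pytest.raises(ValueError):
            dec.correlation_classify(np.array([1.0, 2.0]),
                                     {"A": np.array([1.0, 2.0])})


def synth_two_class(n_runs=8, per_run=2, n_vox=30, sep=0.0, noise=1.0, seed=0):
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(n_vox)
    pats, labels, runs = [], [], []
    for r in range(n_runs):
        for _ in range(per_run):
            for lab, s in (("acw", 1.0), ("cw", -1.0)):
                pats.append(s * sep * w + noise * rng.standard_normal(n_vox))
                labels.append(lab)
                runs.append(r)
    return make_samples(pats, labels, runs)


class TestLeaveOneRunOut:
    def test_one_fold_per_run(self):
        ss = synth_two_class()
        res = dec.leave_one_run_out(ss, dec.DecodingConfig(n_voxels_cutoff=30))
        assert len(res.fold_accuracies) == 8
        assert res.mean_accuracy == pytest.approx(res.fold_accuracies.mean())

    def test_perfect_separation_decodes_perfectly(self):
        ss = synth_two_class(sep=5.0, noise=0.01)
        res = dec.leave_one_run_out(ss, dec.DecodingConfig(n_voxels_cutoff=30))
        assert res.mean_accuracy == 1.0

    def test_cutoff_larger_than_roi_warns_and_uses_all(self):
        ss = synth_two_class(sep=5.0, noise=0.01)
        with pytest.warns(UserWarning, match="exceeds"):
            res = dec.leave_one_run_out(ss, dec.DecodingConfig(n_voxels_cutoff=500))
        assert res.mean_accuracy == 1.0

    def test_missing_class_in_a_run_rejected(self):
        ss = synth_two_class()
        bad = ss.subset(~((ss.run_index == 0) & (ss.labels == "acw")))
        with pytest.raises(ValueError, match="missing"):
            dec.leave_one_run_out(bad, dec.DecodingConfig(n_voxels_cutoff=10))

    def test_deterministic_rerun(self):
        ss = synth_two_class(sep=0.5, seed=4)
        cfg = dec.DecodingConfig(n_voxels_cutoff=20)
        a = dec.leave_one_run_out(ss, cfg)
        b = dec.leave_one_run_out(ss, cfg)
        assert np.array_equal(a.fold_accuracies, b.fold_accuracies)

    def test_accuracy_nondecreasing_in_effect_size(self):
        # same seeds across the effect grid: mean accuracy must ramp up
        grid = [0.0, 0.3, 0.8, 2.0]
        means = []
        for sep in grid:
            accs = [dec.leave_one_run_out(
                synth_two_class(sep=sep, seed=s),
                dec.DecodingConfig(n_voxels_cutoff=30)).mean_accuracy
                for s in range(6)]
            means.append(np.mean(accs))
        assert all(b >= a - 0.02 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0] + 0.3


class TestContextGrouping:
    def test_counts_double_per_class(self, default_participant):
        samples = pp.extract_samples(default_participant, "quadrant_curve")
        ctx = dec.group_by_context(samples)
        assert ctx.n_samples == samples.n_samples == 64
        labs, counts = np.unique(ctx.labels, return_counts=True)
        assert sorted(labs) == ["coherent", "incoherent"]
        assert (counts == 32).all()
        # patterns untouched, only labels rewritten
        assert np.array_equal(ctx.patterns, samples.patterns)

    def test_direction_subset_has_16_per_class(self, default_participant):
        samples = pp.extract_samples(default_participant, "quadrant_curve")
        coh = dec.select_context(samples, "coherent")
        assert coh.n_samples == 32
        assert sorted(set(coh.labels)) == ["coh_acw", "coh_cw"]

    def test_unknown_labels_rejected(self):
        ss = make_samples([[1, 2, 3]], ["weird"])
        with pytest.raises(ValueError):
            dec.group_by_context(ss)


class TestDecodingSuite:
    def test_grid_layout_and_determinism(self, default_participant):
        tab = dec.run_decoding_suite(default_participant,
                                     roi_names=["quadrant_curve", "element_curve"])
        # 2 ROIs x 3 comparisons x 8 folds
        assert len(tab) == 48
        assert set(tab.comparison) == set(dec.COMPARISONS)
        assert set(tab[tab.roi == "element_curve"].cutoff) == {28}
        assert set(tab[tab.roi == "quadrant_curve"].cutoff) == {150}
        tab2 = dec.run_decoding_suite(default_participant,
                                      roi_names=["quadrant_curve", "element_curve"])
        assert tab.equals(tab2)

    def test_empty_roi_list_gives_empty_table(self, default_participant):
        assert len(dec.run_decoding_suite(default_participant, roi_names=[])) == 0

    def test_default_effect_decodes_coherent_direction(self):
        # single participants are noisy; average a small cohort
        coh, inc = [], []
        for s in range(5):
            ds = pp.preprocess(simulate_participant(seed=300 + s), fwhm=5.0)
            tab = dec.run_decoding_suite(ds, roi_names=["quadrant_curve"])
            m = tab.groupby("comparison")["accuracy"].mean()
            coh.append(m["direction_coherent"])
            inc.append(m["direction_incoherent"])
        assert np.mean(coh) > 0.55
        assert np.mean(coh) > np.mean(inc)
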