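"""Unit and property tests for the challenge evaluation measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from leafseg import metrics
from conftest import random_label_map

label_maps = arrays(
    dtype=np.int8,
    shape=st.tuples(st.integers(1, 8), st.integers(1, 8)),
    elements=st.integers(0, 3),
)


def brute_force_best_dice(ar, gt):
    """Independent oracle: explicit double loop over all instance pairs."""
    ar_ids = [int(i) for i in np.unique(ar) if i > 0]
    gt_ids = [int(i) for i in np.unique(gt) if i > 0]
    if not ar_ids or not gt_ids:
        return 0.0
    per_instance = []
    for i in ar_ids:
        a = ar == i
        best = 0.0
        for j in gt_ids:
            b = gt == j
            inter = np.logical_and(a, b).sum()
            best = max(best, 2.0 * inter / (a.sum() + b.sum()))
        per_instance.append(best)
    return float(np.mean(per_instance))


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((5, 5), bool)
        m[1:3, 1:3] = True
        assert metrics.dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((5, 5), bool)
        b = np.zeros((5, 5), bool)
        a[0, 0] = True
        b[4, 4] = True
        assert metrics.dice(a, b) == 0.0

    def test_half_overlap_on_grid(self):
        # |a| = 4, |b| = 4, |a∩b| = 2 on a 4x4 grid -> 2*2/(4+4) = 0.5
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0:4] = True
        b[0, 2:4] = True
        b[1, 0:2] = True
        assert metrics.dice(a, b) == 0.5

    def test_empty_conventions(self):
        empty = np.zeros((3, 3), bool)
        full = np.ones((3, 3), bool)
        assert metrics.dice(empty, empty) == 1.0
        assert metrics.dice(empty, full) == 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            metrics.dice(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestBestDice:
    def test_identity_three_instances(self):
        m = np.zeros((6, 6), int)
        m[0:2, 0:2] = 1
        m[3:5, 0:2] = 2
        m[0:2, 3:5] = 3
        assert metrics.best_dice(m, m) == 1.0
        assert metrics.symmetric_best_dice(m, m) == 1.0

    def test_one_instance_vs_two_halves(self):
        # prediction covers the whole foreground as one leaf; truth splits it
        # into two equal leaves: Dice(whole, half) = 2A/(3A) = 2/3 each way.
        gt = np.zeros((4, 4), int)
        gt[:, :2] = 1
        gt[:, 2:] = 2
        ar = np.ones((4, 4), int)
        assert metrics.best_dice(ar, gt) == pytest.approx(2.0 / 3.0)
        assert metrics.best_dice(gt, ar) == pytest.approx(2.0 / 3.0)
        assert metrics.symmetric_best_dice(ar, gt) == pytest.approx(2.0 / 3.0)

    def test_zero_instances_scores_zero(self):
        empty = np.zeros((4, 4), int)
        some = np.ones((4, 4), int)
        assert metrics.best_dice(empty, some) == 0.0
        assert metrics.symmetric_best_dice(empty, some) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            a = random_label_map(rng)
            b = random_label_map(rng)
            assert metrics.best_dice(a, b) == pytest.approx(
                brute_force_best_dice(a, b), abs=1e-12
            )

    def test_sbd_bounds_and_symmetry(self, rng):
        for _ in range(50):
            a = random_label_map(rng)
            b = random_label_map(rng)
            sbd = metrics.symmetric_best_dice(a, b)
            assert sbd == metrics.symmetric_best_dice(b, a)
            assert sbd <= metrics.best_dice(a, b) + 1e-12
            assert sbd <= metrics.best_dice(b, a) + 1e-12

    def test_relabeling_invariance(self, rng):
        for _ in range(20):
            a = random_label_map(rng)
            b = random_label_map(rng)
            # permute positive ids of a
            ids = np.unique(a)
            ids = ids[ids > 0]
            if ids.size == 0:
                continue
            perm = rng.permutation(ids)
            lut = np.arange(a.max() + 1)
            lut[ids] = perm
            a2 = lut[a]
            assert metrics.best_dice(a2, b) == pytest.approx(metrics.best_dice(a, b))
            assert metrics.fgbg_dice(a2, b) == metrics.fgbg_dice(a, b)

    def test_translation_invariance(self, rng):
        a = random_label_map(rng, size=8)
        b = random_label_map(rng, size=8)
        pad = ((3, 1), (2, 4))
        a2 = np.pad(a, pad)
        b2 = np.pad(b, pad)
        assert metrics.best_dice(a2, b2) == pytest.approx(metrics.best_dice(a, b))
        assert metrics.symmetric_best_dice(a2, b2) == pytest.approx(
            metrics.symmetric_best_dice(a, b)
        )


class TestProperties:
    @given(a=label_maps)
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_self_comparison_is_perfect(self, a):
        if metrics.instance_ids(a).size:
            assert metrics.best_dice(a, a) == 1.0
            assert metrics.symmetric_best_dice(a, a) == 1.0
        assert metrics.fgbg_dice(a, a) == 1.0
        assert metrics.diff_fg(a, a) == 0

    @given(data=st.data(), a=label_maps)
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_pairwise_invariants(self, data, a):
        b = data.draw(
            arrays(dtype=np.int8, shape=st.just(a.shape), elements=st.integers(0, 3))
        )
        sbd = metrics.symmetric_best_dice(a, b)
        assert sbd == metrics.symmetric_best_dice(b, a)
        assert 0.0 <= sbd <= metrics.best_dice(a, b) + 1e-12
        assert metrics.best_dice(a, b) == pytest.approx(
            brute_force_best_dice(a, b), abs=1e-12
        )
        assert metrics.diff_fg(a, b) == -metrics.diff_fg(b, a)


class TestCounts:
    def test_diff_fg_signs(self):
        five = np.zeros((8, 8), int)
        for i in range(5):
            five[i, i] = i + 1
        three = np.zeros((8, 8), int)
        for i in range(3):
            three[i, i] = i + 1
        assert metrics.diff_fg(five, three) == 2
        assert metrics.diff_fg(three, five) == -2
        assert metrics.diff_fg(three, three) == 0
        assert metrics.abs_diff_fg(five, three) == 2
        assert metrics.abs_diff_fg(three, five) == 2

    def test_antisymmetry(self, rng):
        for _ in range(20):
            a = random_label_map(rng)
            b = random_label_map(rng)
            assert metrics.diff_fg(a, b) == -metrics.diff_fg(b, a)
            assert metrics.abs_diff_fg(a, b) == metrics.abs_diff_fg(b, a)
            assert metrics.abs_diff_fg(a, b) == abs(metrics.diff_fg(a, b))

    def test_noncontiguous_ids_counted_once(self):
        m = np.zeros((4, 4), int)
        m[0, 0] = 7
        m[2, 2] = 9
        assert metrics.instance_ids(m).tolist() == [7, 9]
        assert metrics.diff_fg(m, np.zeros((4, 4), int)) == 2


class TestFgbgDice:
    def test_partition_erased_by_binarisation(self):
        a = np.zeros((4, 4), int)
        a[:2] = 1
        a[2:] = 2
        b = np.zeros((4, 4), int)
        b[:] = 5
        assert metrics.fgbg_dice(a, b) == 1.0

    def test_all_background(self):
        z = np.zeros((4, 4), int)
        assert metrics.fgbg_dice(z, z) == 1.0


class TestEvaluateDataset:
    def test_perfect_pair(self, small_scene):
        rep = metrics.evaluate_dataset([(small_scene.labels, small_scene.labels)])
        agg = rep.aggregate
        assert agg["BD"] == agg["SBD"] == agg["FGBGDice"] == 1.0
        assert agg["DiffFG"] == agg["AbsDiffFG"] == 0.0

    def test_signed_counts_average(self):
        one = np.zeros((4, 4), int)
        one[0, 0] = 1
        two = one.copy()
        two[2, 2] = 2
        three = two.copy()
        three[3, 3] = 3
        rep = metrics.evaluate_dataset([(two, one), (two, three)])
        assert rep.aggregate["DiffFG"] == 0.0
        assert rep.aggregate["AbsDiffFG"] == 1.0
        for _, bd, sbd, fg, d, ad in rep.per_image:
            assert ad == abs(d)

    def test_duplicated_pairs_mean_invariance(self, small_scene):
        noisy = small_scene.labels.copy()
        noisy[noisy == 2] = 1
        one = metrics.evaluate_dataset([(noisy, small_scene.labels)])
        four = metrics.evaluate_dataset([(noisy, small_scene.labels)] * 4)
        for k in metrics.METRIC_NAMES:
            assert four.aggregate[k] == pytest.approx(one.aggregate[k])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            metrics.evaluate_dataset([])

    def test_percent_mode_and_csv(self, tmp_path, small_scene):
        rep = metrics.evaluate_dataset([(small_scene.labels, small_scene.labels)], percent=True)
        assert rep.aggregate["BD"] == 100.0
        out = tmp_path / "report.csv"
        rep.write_csv(out)
        lines = out.read_text().strip().splitlines()
        assert lines[0].startswith("image,BD,SBD")
        assert len(lines) == 3
        table = rep.format_table()
        assert "100.00" in table
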