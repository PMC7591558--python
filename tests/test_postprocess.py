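import itertools

import numpy as np
import pytest
from skimage.measure import label as cc_label

import endoleakseg as es
from endoleakseg.postprocess import PostprocessSpec
from endoleakseg.segmentation import SliceProbMap


def _pm(probs, cid="c", idx=0):
    return SliceProbMap(probs=np.asarray(probs, dtype=float), case_id=cid,
                        slice_index=idx)


def _const_map(peak, shape=(8, 8)):
    m = np.zeros(shape)
    m[0, 0] = peak
    return m


def _brute_force_f1_argmax(peaks, truth, grid):
    """Independent oracle: scan every grid point, tie-break to the highest."""
    best_f1, best_t = -1.0, None
    for t in sorted(grid):
        pred = peaks >= t
        tp = int((pred & truth).sum())
        fp = int((pred & ~truth).sum())
        fn = int((~pred & truth).sum())
        f1 = 0.0 if 2 * tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn)
        if f1 >= best_f1:
            best_f1, best_t = f1, t
    return best_t


class TestSelectThreshold:
    def test_singleton_grid(self):
        maps = [_pm(_const_map(0.9)), _pm(_const_map(0.1))]
        truth = [np.ones((8, 8)), np.zeros((8, 8))]
        thr, diag = es.select_threshold(maps, truth, [0.5])
        assert thr == 0.5 and diag["f1"] == 1.0

    def test_tie_breaks_toward_higher_threshold(self):
        maps = [_pm(_const_map(0.9)) for _ in range(3)] + \
               [_pm(_const_map(0.1)) for _ in range(3)]
        truth = [np.ones((8, 8))] * 3 + [np.zeros((8, 8))] * 3
        thr, diag = es.select_threshold(maps, truth, [0.2, 0.5, 0.8])
        assert thr == 0.8 and diag["f1"] == 1.0

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(0)
        grid = np.round(np.arange(0.1, 1.0, 0.1), 1)
        for _ in range(50):
            n = int(rng.integers(4, 12))
            peaks = np.round(rng.random(n), 2)
            truth = rng.random(n) < 0.5
            if not truth.any():
                truth[0] = True
            maps = [_pm(_const_map(p)) for p in peaks]
            tmasks = [np.ones((8, 8)) if t else np.zeros((8, 8)) for t in truth]
            thr, _ = es.select_threshold(maps, tmasks, grid)
            assert thr == _brute_force_f1_argmax(peaks, truth, grid)

    def test_requires_positive_slices(self):
        with pytest.raises(ValueError):
            es.select_threshold([_pm(_const_map(0.9))], [np.zeros((8, 8))], [0.5])


class TestSizeFilter:
    def test_small_component_removed(self):
        m = np.zeros((8, 8), dtype=np.uint8)
        m[0, :3] = 1  # 3-pixel component
        assert not es.size_filter(m, 5, 100).any()

    def test_bounds_inclusive(self):
        m = np.zeros((8, 8), dtype=np.uint8)
        m[0, :5] = 1
        assert es.size_filter(m, 5, 100).sum() == 5
        assert es.size_filter(m, 1, 5).sum() == 5

    def test_mixed_component_sizes(self):
        m = np.zeros((128, 128), dtype=np.uint8)
        m[0, :3] = 1                 # area 3: too small
        m[10:15, 10:20] = 1          # area 50: kept
        m[40:115, 40:115] = 1        # area 5625: too large
        out = es.size_filter(m, 5, 1000)
        assert out.sum() == 50 and out[12, 15] == 1

    def test_matches_brute_force_labeling(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            m = (rng.random((32, 32)) < 0.35).astype(np.uint8)
            lo, hi = 3, 30
            out = es.size_filter(m, lo, hi)
            lbl = cc_label(m, connectivity=1)
            expect = np.zeros_like(m)
            for k in range(1, lbl.max() + 1):
                comp = lbl == k
                if lo <= comp.sum() <= hi:
                    expect[comp] = 1
            assert np.array_equal(out, expect)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        m = (rng.random((32, 32)) < 0.3).astype(np.uint8)
        once = es.size_filter(m, 3, 40)
        assert np.array_equal(es.size_filter(once, 3, 40), once)


class TestCallSlices:
    def test_all_zero_map_negative(self):
        spec = PostprocessSpec(prob_threshold=0.5, min_area_px=5, max_area_px=1000)
        calls = es.call_slices([_pm(np.zeros((64, 64)))], spec)
        assert not calls[0].positive and calls[0].surviving_area_px == 0

    def test_surviving_blob_positive(self):
        probs = np.zeros((64, 64))
        probs[10:15, 10:20] = 0.9  # 50-px blob
        spec = PostprocessSpec(prob_threshold=0.5, min_area_px=5, max_area_px=1000)
        calls = es.call_slices([_pm(probs)], spec)
        assert calls[0].positive and calls[0].surviving_area_px == 50

    def test_oversized_blob_negative(self):
        probs = np.zeros((128, 128))
        probs[10:110, 10:60] = 0.9  # 5000-px blob
        spec = PostprocessSpec(prob_threshold=0.5, min_area_px=5, max_area_px=1000)
        assert not es.call_slices([_pm(probs)], spec)[0].positive

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(8)
        probs = rng.random((64, 64))
        prev = None
        for t in (0.3, 0.5, 0.7, 0.9):
            spec = PostprocessSpec(prob_threshold=t, min_area_px=1, max_area_px=4096)
            area = es.call_slices([_pm(probs)], spec)[0].surviving_area_px
            if prev is not None:
                assert area <= prev
            prev = area


class TestDecideCase:
    @staticmethod
    def _calls(pos_indices, n=50, cid="c"):
        return [es.SliceCall(case_id=cid, slice_index=i, positive=i in pos_indices,
                             surviving_area_px=10 if i in pos_indices else 0)
                for i in range(n)]

    def test_all_negative(self):
        spec = PostprocessSpec(case_rule="count", case_k=1)
        d = es.decide_case(self._calls(set()), spec)
        assert not d.positive and d.n_positive_slices == 0

    def test_run_rule_consecutive(self):
        spec = PostprocessSpec(case_rule="run", case_k=3)
        d = es.decide_case(self._calls({10, 11, 12}), spec)
        assert d.positive and d.longest_run == 3

    def test_count_vs_run_on_scattered_positives(self):
        calls = self._calls({4, 40})
        count = es.decide_case(calls, PostprocessSpec(case_rule="count", case_k=2))
        run = es.decide_case(calls, PostprocessSpec(case_rule="run", case_k=2))
        assert count.positive and not run.positive
        assert run.longest_run == 1 and run.n_positive_slices == 2

    def test_case_k_monotonicity(self):
        calls = self._calls({3, 4, 5, 9})
        prev = True
        for k in range(1, 7):
            d = es.decide_case(calls, PostprocessSpec(case_rule="run", case_k=k))
            assert prev or not d.positive  # raising k never flips neg -> pos
            prev = d.positive

    def test_enumeration_oracle_both_rules(self):
        """Exhaustively compare both rules against direct enumeration on all
        positive patterns over 6 slices."""
        for bits in itertools.product([0, 1], repeat=6):
            pos = {i for i, b in enumerate(bits) if b}
            calls = self._calls(pos, n=6)
            for k in (1, 2, 3):
                got_c = es.decide_case(
                    calls, PostprocessSpec(case_rule="count", case_k=k)).positive
                assert got_c == (len(pos) >= k)
                runs = [len(s) for s in
                        "".join("p" if b else "." for b in bits).split(".")]
                got_r = es.decide_case(
                    calls, PostprocessSpec(case_rule="run", case_k=k)).positive
                assert got_r == (max(runs) >= k)

    def test_mixed_case_ids_rejected(self):
        calls = [es.SliceCall("a", 0, False, 0), es.SliceCall("b", 1, False, 0)]
        with pytest.raises(ValueError):
            es.decide_case(calls, PostprocessSpec())
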