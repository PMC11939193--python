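"""IoU / localization rate / significant rate against brute-force oracles."""

import numpy as np
import pytest

from bcgnet.augment import JPeakSet
from bcgnet.gradcam import HeatMap
from bcgnet.region_metrics import (NeighborhoodSet, SignificantSet, iou,
                                   localization_rate, neighborhoods,
                                   region_metrics, significant_rate,
                                   significant_set, sweep_window_sizes)

# ---------------------------------------------------------------- oracles


def brute_significant(weights, threshold=0.5):
    return {i for i, w in enumerate(weights) if w > threshold}


def brute_ranges(peak_list, radius, length):
    return [set(range(p - radius, p + radius + 1)) for p in peak_list
            if p - radius >= 0 and p + radius < length]


def brute_iou(sig, ranges):
    nbr = set().union(*ranges) if ranges else set()
    union = sig | nbr
    if not union:
        return None
    return len(sig & nbr) / len(union)


def brute_lr(sig, ranges, window, length):
    nbr = set().union(*ranges) if ranges else set()
    hits = misses = 0
    for c in range(length // window):
        chunk = set(range(c * window, (c + 1) * window))
        if len(chunk & sig) > window / 2:
            if len(chunk & nbr) > window / 2:
                hits += 1
            else:
                misses += 1
    if hits + misses == 0:
        return None
    return hits / (hits + misses)


def brute_sr(sig, ranges):
    if not ranges:
        return None
    pos = sum(1 for r in ranges if len(r & sig) > len(r) / 2)
    return pos / len(ranges)


def _random_instance(rng, length=60, radius=3):
    weights = rng.random(length)
    n_peaks = rng.integers(0, 5)
    peaks = np.sort(rng.choice(length, size=n_peaks, replace=False)) \
        if n_peaks else np.array([], dtype=int)
    # enforce strictly increasing (choice without replace is enough)
    hm = HeatMap(weights, target_class=1, layer="x")
    ps = JPeakSet(peaks, length)
    return hm, ps, radius


# ----------------------------------------------------------------- tests


class TestSignificantSet:
    def test_all_below_threshold_empty(self):
        hm = HeatMap(np.full(10, 0.4), 1, "x")
        assert significant_set(hm).indices.size == 0

    def test_exact_half_excluded(self):
        hm = HeatMap(np.array([0.5, 0.500001, 1.0]), 1, "x")
        np.testing.assert_array_equal(significant_set(hm).indices, [1, 2])

    def test_unnormalized_rejected(self):
        hm = HeatMap(np.ones(4), 1, "x", normalized=False)
        with pytest.raises(ValueError):
            significant_set(hm)


class TestSingleMetrics:
    def test_identical_sets_give_unit_iou(self):
        sig = SignificantSet(np.arange(10, 20), 50)
        nbr = NeighborhoodSet([(10, 20)], 50, radius=4)
        assert iou(sig, nbr) == (1.0, True)

    def test_disjoint_sets_give_zero_iou(self):
        sig = SignificantSet(np.arange(0, 5), 50)
        nbr = NeighborhoodSet([(30, 40)], 50, radius=4)
        assert iou(sig, nbr) == (0.0, True)

    def test_worked_overlap_example(self):
        # |S| = 40, |N| = 40, overlap 30 -> 30/50
        sig = SignificantSet(np.arange(0, 40), 200)
        nbr = NeighborhoodSet([(10, 50)], 200, radius=19)
        value, defined = iou(sig, nbr)
        assert defined and value == pytest.approx(0.6)

    def test_empty_union_undefined(self):
        value, defined = iou(SignificantSet(np.array([], dtype=int), 50),
                             NeighborhoodSet([], 50, 3))
        assert not defined and np.isnan(value)

    def test_lr_no_significant_chunks_undefined(self):
        sig = SignificantSet(np.array([], dtype=int), 100)
        nbr = NeighborhoodSet([(10, 31)], 100, 10)
        value, defined, h, m = localization_rate(sig, nbr)
        assert not defined and h == 0 and m == 0

    def test_lr_all_hits(self):
        sig = SignificantSet(np.arange(0, 21), 105)
        nbr = NeighborhoodSet([(0, 21)], 105, 10)
        value, defined, h, m = localization_rate(sig, nbr)
        assert defined and value == 1.0 and (h, m) == (1, 0)

    def test_sr_counts_each_region_separately(self):
        sig = SignificantSet(np.arange(0, 21), 100)
        nbr = NeighborhoodSet([(0, 21), (40, 61)], 100, 10)
        value, defined, p, n = significant_rate(sig, nbr)
        assert defined and value == 0.5 and (p, n) == (1, 1)

    def test_sr_no_regions_undefined(self):
        value, defined, p, n = significant_rate(
            SignificantSet(np.arange(5), 50), NeighborhoodSet([], 50, 3))
        assert not defined


class TestBruteForceEquivalence:
    def test_thousand_random_instances_agree_exactly(self):
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(1000):
            hm, ps, radius = _random_instance(rng)
            sig = significant_set(hm)
            nbr = neighborhoods(ps, radius)
            sig_b = brute_significant(hm.weights)
            assert set(sig.indices.tolist()) == sig_b
            ranges = brute_ranges(ps.indices.tolist(), radius, hm.weights.size)
            res = region_metrics(hm, ps, radius)
            for got, defined, want in (
                    (res.iou, res.iou_defined, brute_iou(sig_b, ranges)),
                    (res.localization_rate, res.lr_defined,
                     brute_lr(sig_b, ranges, 2 * radius + 1, hm.weights.size)),
                    (res.significant_rate, res.sr_defined,
                     brute_sr(sig_b, ranges))):
                if want is None:
                    assert not defined
                else:
                    assert defined and got == want
                    checked += 1
        assert checked > 1000  # plenty of defined cases exercised

    def test_intersection_monotone_in_radius(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            hm, ps, radius = _random_instance(rng, length=80, radius=2)
            sig = significant_set(hm)
            small = sig.mask() & neighborhoods(ps, radius).mask()
            large = sig.mask() & neighborhoods(ps, radius + 1).mask()
            # enlarging neighborhoods can only drop boundary peaks; compare
            # on peaks kept by both
            kept = neighborhoods(ps, radius + 1)
            if len(kept.ranges) == len(neighborhoods(ps, radius).ranges):
                assert large.sum() >= small.sum()

    def test_unit_iou_iff_sets_equal(self):
        rng = np.random.default_rng(5)
        seen_equal = False
        for _ in range(500):
            hm, ps, radius = _random_instance(rng, length=40, radius=2)
            sig = significant_set(hm)
            nbr = neighborhoods(ps, radius)
            value, defined = iou(sig, nbr)
            if defined:
                equal = np.array_equal(sig.mask(), nbr.mask())
                assert (value == 1.0) == equal
                seen_equal |= equal
        # also construct the equal case explicitly
        hm = HeatMap(np.r_[np.ones(5), np.zeros(15)] * 0.9, 1, "x")
        ps = JPeakSet(np.array([2]), 20)
        assert iou(significant_set(hm), neighborhoods(ps, 2))[0] == 1.0


class TestSweep:
    def _stores(self):
        rng = np.random.default_rng(11)
        hms, pss = {}, {}
        for i in range(6):
            w = rng.random(200)
            hms[f"s/{i}"] = HeatMap(w, 1, "x")
            pss[f"s/{i}"] = JPeakSet(np.sort(rng.choice(np.arange(30, 170),
                                                        4, replace=False)), 200)
        return hms, pss

    def test_window_radius_pairs_match_published_sweep(self):
        hms, pss = self._stores()
        table = sweep_window_sizes(hms, pss, (21, 31, 41, 51))
        assert list(zip(table["window"], table["radius"])) == [
            (21, 10), (31, 15), (41, 20), (51, 25)]

    def test_single_segment_table_equals_its_metrics(self):
        hms, pss = self._stores()
        sid = "s/0"
        table = sweep_window_sizes({sid: hms[sid]}, {sid: pss[sid]}, (31,))
        res = region_metrics(hms[sid], pss[sid], 15)
        assert table.loc[0, "IoU"] == pytest.approx(res.iou)

    def test_order_invariance(self):
        hms, pss = self._stores()
        a = sweep_window_sizes(hms, pss, (21, 31))
        rev = dict(reversed(list(hms.items())))
        b = sweep_window_sizes(rev, pss, (21, 31))
        assert a.equals(b)

    def test_id_mismatch_names_missing(self):
        hms, pss = self._stores()
        del pss["s/3"]
        with pytest.raises(KeyError, match="s/3"):
            sweep_window_sizes(hms, pss)
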