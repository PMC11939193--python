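"""Heat-map / J-peak region-correlation metrics: IoU, LR, SR.

A sample is *significant* when its normalized heat-map weight strictly
exceeds 0.5.  With ``S`` the significant set and ``N`` the union of
J-peak neighborhoods (windows of ``2*radius + 1`` samples centred on each
in-bounds peak):

* IoU = |S ∩ N| / |S ∪ N| — global overlap;
* LR  = H / (H + M): the segment is partitioned into consecutive chunks
  of the window length; a chunk is significant when more than 50% of its
  samples are significant, and such a chunk is a *hit* when more than 50%
  of its samples fall inside a neighborhood;
* SR  = P / (P + N): a neighborhood region is *positive* when more than
  50% of its samples are significant.

All comparisons are strict ("exceeds"); 0/0 cases are flagged undefined
and excluded from cohort averages rather than coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .augment import JPeakSet
from .gradcam import HeatMap


@dataclass
class SignificantSet:
    """Sample indices whose normalized heat-map weight exceeds the threshold."""

    indices: np.ndarray
    segment_length: int
    threshold: float = 0.5

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)

    def mask(self) -> np.ndarray:
        m = np.zeros(self.segment_length, dtype=bool)
        m[self.indices] = True
        return m


@dataclass
class NeighborhoodSet:
    """Union of J-peak neighborhood ranges [p-radius, p+radius]."""

    ranges: list[tuple[int, int]]   # half-open [start, stop)
    segment_length: int
    radius: int

    @property
    def window(self) -> int:
        return 2 * self.radius + 1

    def mask(self) -> np.ndarray:
        m = np.zeros(self.segment_length, dtype=bool)
        for a, b in self.ranges:
            m[a:b] = True
        return m


@dataclass
class RegionMetricsResult:
    iou: float
    localization_rate: float
    significant_rate: float
    iou_defined: bool
    lr_defined: bool
    sr_defined: bool
    hits: int = 0
    misses: int = 0
    positive_regions: int = 0
    negative_regions: int = 0


def significant_set(heatmap: HeatMap, threshold: float = 0.5) -> SignificantSet:
    if not heatmap.normalized:
        raise ValueError("significant_set requires a normalized heat-map")
    idx = np.flatnonzero(heatmap.weights > threshold)
    return SignificantSet(idx, len(heatmap), threshold)


def neighborhoods(peaks: JPeakSet, radius: int) -> NeighborhoodSet:
    """Build neighborhood ranges, dropping peaks whose window crosses an edge."""
    n = peaks.segment_length
    ranges = [(int(p - radius), int(p + radius + 1))
              for p in peaks.indices if p - radius >= 0 and p + radius < n]
    return NeighborhoodSet(ranges, n, radius)


def iou(sig: SignificantSet, nbr: NeighborhoodSet) -> tuple[float, bool]:
    """|S ∩ N| / |S ∪ N|; undefined (nan, False) when the union is empty."""
    s, m = sig.mask(), nbr.mask()
    union = np.count_nonzero(s | m)
    if union == 0:
        return float("nan"), False
    return np.count_nonzero(s & m) / union, True


def localization_rate(sig: SignificantSet, nbr: NeighborhoodSet,
                      window: int | None = None
                      ) -> tuple[float, bool, int, int]:
    """Hit fraction of the significant chunks; (value, defined, H, M)."""
    window = nbr.window if window is None else window
    if window < 1:
        raise ValueError("window must be >= 1")
    s, m = sig.mask(), nbr.mask()
    n_chunks = sig.segment_length // window  # trailing partial chunk dropped
    hits = misses = 0
    for c in range(n_chunks):
        chunk = slice(c * window, (c + 1) * window)
        if np.count_nonzero(s[chunk]) * 2 > window:       # strict > 50%
            if np.count_nonzero(m[chunk]) * 2 > window:
                hits += 1
            else:
                misses += 1
    total = hits + misses
    if total == 0:
        return float("nan"), False, hits, misses
    return hits / total, True, hits, misses


def significant_rate(sig: SignificantSet, nbr: NeighborhoodSet
                     ) -> tuple[float, bool, int, int]:
    """Fraction of neighborhood regions that are majority-significant.

    Regions are counted separately even when they overlap; returns
    (value, defined, P, N).
    """
    s = sig.mask()
    pos = neg = 0
    for a, b in nbr.ranges:
        size = b - a
        if np.count_nonzero(s[a:b]) * 2 > size:
            pos += 1
        else:
            neg += 1
    total = pos + neg
    if total == 0:
        return float("nan"), False, pos, neg
    return pos / total, True, pos, neg


def region_metrics(heatmap: HeatMap, peaks: JPeakSet, radius: int,
                   threshold: float = 0.5) -> RegionMetricsResult:
    """All three metrics for one segment."""
    sig = significant_set(heatmap, threshold)
    nbr = neighborhoods(peaks, radius)
    iou_v, iou_d = iou(sig, nbr)
    lr_v, lr_d, h, m = localization_rate(sig, nbr)
    sr_v, sr_d, p, n = significant_rate(sig, nbr)
    return RegionMetricsResult(iou_v, lr_v, sr_v, iou_d, lr_d, sr_d,
                               h, m, p, n)


def sweep_window_sizes(heatmap_store: dict[str, HeatMap],
                       peak_store: dict[str, JPeakSet],
                       window_sizes=(21, 31, 41, 51),
                       threshold: float = 0.5) -> pd.DataFrame:
    """Per-window mean IoU/LR/SR over a cohort of segments.

    Window sizes must be odd (window = 2*radius + 1).  Undefined
    per-segment values are excluded from the means and counted in
    ``n_undefined``.  Rows are independent of segment ordering.
    """
    missing = sorted(set(heatmap_store) ^ set(peak_store))
    if missing:
        raise KeyError(f"heat-map and peak stores disagree on ids: {missing}")
    rows = []
    for window in window_sizes:
        if window % 2 != 1 or window < 3:
            raise ValueError(f"window size {window} is not odd and >= 3")
        radius = (window - 1) // 2
        ious, lrs, srs = [], [], []
        n_undef = 0
        for sid in sorted(heatmap_store):
            res = region_metrics(heatmap_store[sid], peak_store[sid], radius,
                                 threshold)
            for value, defined, acc in ((res.iou, res.iou_defined, ious),
                                        (res.localization_rate, res.lr_defined, lrs),
                                        (res.significant_rate, res.sr_defined, srs)):
                if defined:
                    acc.append(value)
                else:
                    n_undef += 1
        rows.append({
            "window": window, "radius": radius,
            "LR": float(np.mean(lrs)) if lrs else float("nan"),
            "IoU": float(np.mean(ious)) if ious else float("nan"),
            "SR": float(np.mean(srs)) if srs else float("nan"),
            "n_undefined": n_undef,
        })
    return pd.DataFrame(rows)
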