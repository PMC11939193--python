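"""J-peak detection, neighborhood extraction and data augmentation.

The heat-map-guided augmentation replaces each z-scored 10 s segment by
the concatenation of fixed-radius windows around its detected J-peaks
(ascending in time), padded or truncated to a fixed number of beats so
every model input has the same length ``max_beats * (2*radius + 1)``.

The detector makes the informal "comparison of neighboring values within
a localized range" precise: a sample is a J-peak iff it is the strict
maximum over ``+/- local_range``, its amplitude exceeds ``prominence_min``
z-units, and it lies at least ``min_separation`` from any higher accepted
peak (greedy by descending amplitude).  Plateau ties resolve to the
leftmost sample.

Jittering, scaling and time-warping are included as the traditional
augmentation baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d

from .signal_core import BcgSegment, SignalError


@dataclass
class AugmentationConfig:
    radius: int = 15                  # samples either side of the J-peak
    min_separation: float = 0.4       # s; ~150 bpm ceiling between peaks
    local_range: float = 0.3          # s; strict-max window half-width
    prominence_min: float = 0.5       # z-units; minimum peak amplitude
    boundary_policy: str = "drop"     # windows crossing edges are dropped
    max_beats: int = 12               # fixed beat budget per segment
    pad_value: float = 0.0

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.boundary_policy != "drop":
            raise ValueError("only the 'drop' boundary policy is supported")

    @property
    def window(self) -> int:
        return 2 * self.radius + 1


@dataclass
class JPeakSet:
    """Ordered J-peak sample indices within one segment."""

    indices: np.ndarray
    segment_length: int
    config: AugmentationConfig | None = None

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if self.indices.size and (self.indices[0] < 0
                                  or self.indices[-1] >= self.segment_length):
            raise ValueError("peak index outside segment bounds")

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class AugmentedSegment:
    """Concatenated J-peak windows, padded/truncated to a fixed length."""

    samples: np.ndarray
    n_windows: int
    radius: int
    source: BcgSegment | None = None
    no_peaks: bool = False  # warning flag: nothing detected, all padding

    def __len__(self) -> int:
        return self.samples.size


def detect_j_peaks(segment: BcgSegment,
                   config: AugmentationConfig | None = None) -> JPeakSet:
    """Locate J-peaks in a z-scored segment (empty result is legal)."""
    if not segment.normalized:
        raise SignalError("detect_j_peaks expects a z-scored segment")
    config = config or AugmentationConfig()
    x = segment.samples
    n = x.size
    half = max(int(round(config.local_range * segment.sampling_rate)), 1)
    win_max = maximum_filter1d(x, size=2 * half + 1, mode="constant",
                               cval=-np.inf)
    cand = np.flatnonzero((x >= win_max) & (x > config.prominence_min))
    # strict max with leftmost plateau resolution: drop a candidate whose
    # window contains an equal value to its left
    keep = []
    for i in cand:
        lo = max(i - half, 0)
        if not np.any(x[lo:i] == x[i]):
            keep.append(i)
    # greedy minimum separation, highest amplitude first (ties: leftmost)
    min_sep = int(round(config.min_separation * segment.sampling_rate))
    order = sorted(keep, key=lambda i: (-x[i], i))
    accepted: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_sep for j in accepted):
            accepted.append(i)
    return JPeakSet(np.array(sorted(accepted), dtype=np.int64), n, config)


def extract_neighborhoods(segment: BcgSegment, peaks: JPeakSet,
                          radius: int) -> list[np.ndarray]:
    """Windows ``samples[p-radius .. p+radius]`` for in-bounds peaks, ascending."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    n = len(segment)
    return [segment.samples[p - radius:p + radius + 1].copy()
            for p in peaks.indices
            if p - radius >= 0 and p + radius < n]


def augment_segment(segment: BcgSegment,
                    config: AugmentationConfig | None = None) -> AugmentedSegment:
    """Detect, extract and concatenate J-peak neighborhoods.

    Output length is always ``max_beats * (2*radius + 1)``; segments with
    fewer detected beats are padded with ``pad_value``, segments with more
    keep the earliest ``max_beats`` windows.  A segment with no detected
    peaks yields all padding with the ``no_peaks`` flag raised.
    """
    config = config or AugmentationConfig()
    peaks = detect_j_peaks(segment, config)
    windows = extract_neighborhoods(segment, peaks, config.radius)[:config.max_beats]
    width = config.window
    total = config.max_beats * width
    out = np.full(total, config.pad_value, dtype=np.float64)
    if windows:
        stacked = np.concatenate(windows)
        out[:stacked.size] = stacked
    return AugmentedSegment(out, n_windows=len(windows), radius=config.radius,
                            source=segment, no_peaks=not windows)


def _seg_with(segment: BcgSegment, samples: np.ndarray) -> BcgSegment:
    return replace(segment, samples=samples, normalized=False)


def jitter(segment: BcgSegment, sd: float, seed: int) -> BcgSegment:
    """Add i.i.d. Gaussian noise of standard deviation ``sd``."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return _seg_with(segment, segment.samples.copy())
    rng = np.random.default_rng(seed)
    return _seg_with(segment, segment.samples + rng.normal(0.0, sd, len(segment)))


def scale(segment: BcgSegment, factor_sd: float, seed: int) -> BcgSegment:
    """Multiply by a single draw from Normal(1, factor_sd)."""
    if factor_sd < 0:
        raise ValueError("factor_sd must be >= 0")
    if factor_sd == 0:
        return _seg_with(segment, segment.samples.copy())
    rng = np.random.default_rng(seed)
    return _seg_with(segment, segment.samples * rng.normal(1.0, factor_sd))


def time_warp(segment: BcgSegment, n_knots: int, warp_sd: float,
              seed: int) -> BcgSegment:
    """Smooth monotone time remap from Gaussian-perturbed anchors.

    ``warp_sd`` is the anchor perturbation as a fraction of the knot
    spacing.  Non-monotone draws are retried with a fresh sub-seed (at
    most 10 attempts).  Output length equals input length.
    """
    if n_knots < 1:
        raise ValueError("n_knots must be >= 1")
    if warp_sd < 0:
        raise ValueError("warp_sd must be >= 0")
    x = segment.samples
    n = x.size
    if warp_sd == 0:
        return _seg_with(segment, x.copy())
    anchors = np.linspace(0, n - 1, n_knots + 2)
    spacing = anchors[1] - anchors[0]
    for attempt in range(10):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        src = anchors.copy()
        src[1:-1] += rng.normal(0.0, warp_sd * spacing, n_knots)
        if np.all(np.diff(src) > 0):
            break
    else:
        raise RuntimeError("time_warp: no monotone anchor map in 10 attempts")
    # piecewise-linear map target position -> source position, then resample
    positions = np.interp(np.arange(n), anchors, src)
    return _seg_with(segment, np.interp(positions, np.arange(n), x))


def match_count(detected: Sequence[int], truth: Sequence[int],
                tolerance: int = 3) -> int:
    """Greedy one-to-one matches between detected and true peak indices."""
    used = set()
    tp = 0
    for d in detected:
        best, best_gap = None, tolerance + 1
        for k, t in enumerate(truth):
            if k in used:
                continue
            gap = abs(d - t)
            if gap <= tolerance and gap < best_gap:
                best, best_gap = k, gap
        if best is not None:
            used.add(best)
            tp += 1
    return tp


def detection_scores(detected: Sequence[int], truth: Sequence[int],
                     tolerance: int = 3) -> tuple[float, float]:
    """Precision/recall of detected vs true peak indices (one-to-one)."""
    detected = list(detected)
    truth = list(truth)
    if not detected and not truth:
        return 1.0, 1.0
    tp = match_count(detected, truth, tolerance)
    precision = tp / len(detected) if detected else 1.0
    recall = tp / len(truth) if truth else 1.0
    return precision, recall
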