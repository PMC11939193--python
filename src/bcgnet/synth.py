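"""Seeded synthetic BCG cohort generator with ground-truth J-peaks.

Each heartbeat is a sum of Gaussian bumps, one per labelled deflection of
the BCG beat complex (G, H, I, J, K, L, M, N), with the J wave the
dominant positive peak.  A recording is an overlap-add of beats whose
inter-beat intervals jitter around ``60 / mean_hr`` (heart-rate
variability), plus a respiratory baseline sinusoid and white Gaussian
noise.  Subject-level mean heart rates are drawn from the two
class-conditional distributions of the cohort the pipeline targets:
hypertensive 77.10 +/- 9.20 bpm, normotensive controls 73.60 +/- 8.30 bpm.

Classes also differ in morphology through ``morphology_shift``: the knob
deepens the K wave and compresses the systolic (G-K) interval, so that
class evidence is present inside the beat complex itself, not only in the
beat rate.  This morphological contrast is a construct of the simulator
(real hypertensive BCG morphology is far subtler); it exists so that
end-to-end classification tests are well-posed at small sample sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal_core import (LABEL_CONTROL, LABEL_HYPERTENSIVE, BcgRecord,
                          BcgSegment, DatasetManifest, ManifestEntry,
                          segment_record, write_record, zscore_normalize)

# Class-conditional heart-rate distributions (bpm): mean, sd between subjects.
HR_HYPERTENSIVE = (77.10, 9.20)
HR_CONTROL = (73.60, 8.30)

# Per-wave layout of one beat: (name, offset s from beat onset, amplitude
# in z-units, Gaussian width s).  Relative constraints: offsets increase
# G..N and J is the dominant positive deflection.
_BASE_WAVES = [
    ("G", 0.06, -0.20, 0.025),
    ("H", 0.13, 0.45, 0.030),
    ("I", 0.19, -0.60, 0.030),
    ("J", 0.26, 1.00, 0.030),
    ("K", 0.33, -0.50, 0.035),
    ("L", 0.41, 0.25, 0.040),
    ("M", 0.48, -0.15, 0.045),
    ("N", 0.55, 0.08, 0.045),
]
_SYSTOLIC = {"G", "H", "I", "J", "K"}
# morphology_shift = 1 deepens K by this factor and shortens G-K offsets.
K_DEPTH_GAIN = 0.4
SYSTOLIC_COMPRESSION = 0.08

MIN_INTERVAL_S = 0.33
MAX_INTERVAL_S = 1.5


@dataclass
class BeatTemplate:
    """Sum-of-Gaussians beat: components are (name, offset, amplitude, width)."""

    components: list[tuple[str, float, float, float]]
    duration: float

    def __post_init__(self):
        offsets = [c[1] for c in self.components]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("wave offsets must be strictly increasing G..N")
        j_amp = dict((c[0], c[2]) for c in self.components)["J"]
        for name, _, amp, _ in self.components:
            if name != "J" and amp > 0 and amp >= j_amp:
                raise ValueError("J must be the dominant positive wave")

    @property
    def j_offset(self) -> float:
        return next(c[1] for c in self.components if c[0] == "J")

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the template at times ``t`` (seconds from beat onset)."""
        t = np.asarray(t, dtype=np.float64)
        out = np.zeros_like(t)
        for _, off, amp, width in self.components:
            out += amp * np.exp(-0.5 * ((t - off) / width) ** 2)
        return out


def default_beat_template(morphology_shift: float = 0.0) -> BeatTemplate:
    """Beat template with a class-deformation knob in [0, 1].

    ``morphology_shift`` scales the K-wave depth by ``1 + 0.4*shift`` and
    the systolic (G-K) offsets by ``1 - 0.08*shift``.
    """
    if not 0.0 <= morphology_shift <= 1.0:
        raise ValueError("morphology_shift must lie in [0, 1]")
    comps = []
    for name, off, amp, width in _BASE_WAVES:
        if name in _SYSTOLIC:
            off = off * (1.0 - SYSTOLIC_COMPRESSION * morphology_shift)
        if name == "K":
            amp = amp * (1.0 + K_DEPTH_GAIN * morphology_shift)
        comps.append((name, off, amp, width))
    return BeatTemplate(comps, duration=0.65)


@dataclass
class SubjectParams:
    label: int
    mean_hr: float
    hr_sd_between_beats: float = 3.0
    noise_sd: float = 0.1
    respiration_amplitude: float = 0.3
    respiration_freq: float = 0.25
    morphology_shift: float = 0.0

    def __post_init__(self):
        if not 40.0 <= self.mean_hr <= 180.0:
            raise ValueError(f"mean_hr {self.mean_hr} outside [40, 180] bpm")
        for name in ("hr_sd_between_beats", "noise_sd", "respiration_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Per-record truth: global J-peak sample indices and the drawn rate."""

    j_peak_indices: np.ndarray
    mean_hr: float

    def __post_init__(self):
        self.j_peak_indices = np.asarray(self.j_peak_indices, dtype=np.int64)
        if np.any(np.diff(self.j_peak_indices) <= 0):
            raise ValueError("J-peak indices must be strictly increasing")


def simulate_record(params: SubjectParams, duration: float = 60.0,
                    sampling_rate: float = 100.0, seed=0,
                    subject_id: str = "synthetic") -> tuple[BcgRecord, GroundTruth]:
    """Synthesize one recording; identical seeds give bit-identical output.

    ``seed`` may be an integer or a ``numpy.random.SeedSequence``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    fs = sampling_rate
    n = int(round(duration * fs))
    template = default_beat_template(params.morphology_shift)

    mean_interval = 60.0 / params.mean_hr
    interval_sd = 60.0 * params.hr_sd_between_beats / params.mean_hr ** 2

    onsets = []
    t = 0.0
    while t < duration:
        onsets.append(t)
        iv = rng.normal(mean_interval, interval_sd) if interval_sd > 0 else mean_interval
        t += float(np.clip(iv, MIN_INTERVAL_S, MAX_INTERVAL_S))

    clean = np.zeros(n)
    nominal_j = []
    for onset in onsets:
        i0 = max(int(np.floor(onset * fs)), 0)
        i1 = min(int(np.ceil((onset + template.duration) * fs)) + 1, n)
        if i1 <= i0:
            continue
        idx = np.arange(i0, i1)
        clean[i0:i1] += template.waveform(idx / fs - onset)
        nominal_j.append((onset + template.j_offset) * fs)

    # ground truth = local argmax of the clean beat train around the nominal
    # J position (sampling can shift the discrete maximum by a sample)
    j_indices = []
    for nom in nominal_j:
        c = int(round(nom))
        lo, hi = max(c - 5, 0), min(c + 6, n)
        if hi <= lo:
            continue
        j_indices.append(lo + int(np.argmax(clean[lo:hi])))
    j_indices = np.array(sorted(set(j_indices)), dtype=np.int64)

    x = clean
    if params.respiration_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        tgrid = np.arange(n) / fs
        x = x + params.respiration_amplitude * np.sin(
            2.0 * np.pi * params.respiration_freq * tgrid + phase)
    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd, n)

    record = BcgRecord(x, sampling_rate=fs, subject_id=subject_id,
                       label=params.label)
    return record, GroundTruth(j_indices, params.mean_hr)


@dataclass
class SubjectData:
    subject_id: str
    params: SubjectParams
    record: BcgRecord
    ground_truth: GroundTruth


@dataclass
class Cohort:
    subjects: list[SubjectData] = field(default_factory=list)
    seed: int | None = None

    def manifest(self, directory: str = ".") -> DatasetManifest:
        entries = [ManifestEntry(str(Path(directory) / f"{s.subject_id}.txt"),
                                 s.subject_id, s.record.label,
                                 s.record.sampling_rate)
                   for s in self.subjects]
        return DatasetManifest(entries, provenance="bcgnet synthetic cohort",
                               seed=self.seed)

    def save(self, out_dir) -> DatasetManifest:
        """Write signal files, manifest.json and ground_truth.json."""
        out = Path(out_dir)
        sig_dir = out / "signals"
        sig_dir.mkdir(parents=True, exist_ok=True)
        for s in self.subjects:
            write_record(sig_dir / f"{s.subject_id}.txt", s.record,
                         header=f"subject {s.subject_id}")
        manifest = self.manifest(str(sig_dir))
        manifest.save(out / "manifest.json")
        truth = {s.subject_id: [int(i) for i in s.ground_truth.j_peak_indices]
                 for s in self.subjects}
        (out / "ground_truth.json").write_text(json.dumps(truth))
        return manifest


def _child_seed(master_seed: int, *counters: int) -> np.random.SeedSequence:
    """Deterministic child seed: the master seed plus a counter path.

    A full ``SeedSequence`` is returned (not a truncated integer) so child
    streams keep their full entropy.
    """
    return np.random.SeedSequence([int(master_seed), *map(int, counters)])


def simulate_cohort(n_hypertensive: int, n_control: int,
                    duration: float = 60.0, sampling_rate: float = 100.0,
                    seed: int = 0, hr_sd_between_beats: float = 3.0,
                    noise_sd: float = 0.1, respiration_amplitude: float = 0.3,
                    respiration_freq: float = 0.25,
                    morphology_shift_hypertensive: float = 1.0,
                    morphology_shift_control: float = 0.0) -> Cohort:
    """Simulate a labelled cohort; hypertensive subjects come first.

    Subject mean heart rates are drawn from Normal(77.10, 9.20) bpm for the
    hypertensive class and Normal(73.60, 8.30) bpm for controls (clipped to
    the physiological range [40, 180]); per-subject seeds derive from the
    master seed and the subject counter.
    """
    if n_hypertensive < 0 or n_control < 0:
        raise ValueError("cohort sizes must be non-negative")
    subjects = []
    specs = ([(LABEL_HYPERTENSIVE, HR_HYPERTENSIVE, morphology_shift_hypertensive)]
             * n_hypertensive
             + [(LABEL_CONTROL, HR_CONTROL, morphology_shift_control)] * n_control)
    for i, (label, (mu, sd), shift) in enumerate(specs):
        rng = np.random.default_rng(_child_seed(seed, i))
        mean_hr = float(np.clip(rng.normal(mu, sd), 40.0, 180.0))
        params = SubjectParams(label=label, mean_hr=mean_hr,
                               hr_sd_between_beats=hr_sd_between_beats,
                               noise_sd=noise_sd,
                               respiration_amplitude=respiration_amplitude,
                               respiration_freq=respiration_freq,
                               morphology_shift=shift)
        tag = "hpt" if label == LABEL_HYPERTENSIVE else "ctl"
        sid = f"{tag}{i:04d}"
        record, truth = simulate_record(params, duration, sampling_rate,
                                        seed=_child_seed(seed, i, 1),
                                        subject_id=sid)
        subjects.append(SubjectData(sid, params, record, truth))
    return Cohort(subjects, seed=seed)


def cohort_segments(cohort: Cohort, segment_seconds: float = 10.0,
                    normalize: bool = True
                    ) -> tuple[list[BcgSegment], list[np.ndarray]]:
    """Segment every recording and map ground-truth J-peaks into windows.

    Returns the segments (z-scored when ``normalize``) and, per segment,
    the J-peak indices re-based to the segment's own sample axis.
    """
    segments: list[BcgSegment] = []
    truths: list[np.ndarray] = []
    for s in cohort.subjects:
        win = int(round(segment_seconds * s.record.sampling_rate))
        segs = segment_record(s.record, segment_seconds)
        gt = s.ground_truth.j_peak_indices
        for seg in segs:
            lo = seg.segment_index * win
            local = gt[(gt >= lo) & (gt < lo + win)] - lo
            segments.append(zscore_normalize(seg) if normalize else seg)
            truths.append(local.astype(np.int64))
    return segments, truths
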