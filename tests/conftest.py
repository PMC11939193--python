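import numpy as np
import pytest

from bcgnet.model import BHNet, BHNetConfig
from bcgnet.synth import SubjectParams, cohort_segments, simulate_cohort, simulate_record
from bcgnet.train_eval import TrainConfig, segments_to_arrays, train_model


def tiny_config(seed: int = 0, **overrides) -> BHNetConfig:
    """A minimal valid architecture for fast unit tests."""
    defaults = dict(input_length=64, n_stacks=1, stem_filters=4,
                    filter_schedule=(4,), extra_filters=4,
                    scale_lengths=(4, 2), fusion_bottleneck=2, seed=seed)
    defaults.update(overrides)
    return BHNetConfig(**defaults)


@pytest.fixture()
def clean_segment():
    """One noise-free z-scored 10 s segment with its ground-truth J-peaks."""
    params = SubjectParams(label=0, mean_hr=72.0, hr_sd_between_beats=2.0,
                           noise_sd=0.0, respiration_amplitude=0.0)
    record, truth = simulate_record(params, duration=20.0, seed=5)
    from bcgnet.signal_core import segment_record, zscore_normalize
    seg = zscore_normalize(segment_record(record, 10.0)[0])
    gt = truth.j_peak_indices[truth.j_peak_indices < 1000]
    return seg, gt


@pytest.fixture(scope="session")
def e2e():
    """Shared end-to-end artifact: a 2000-segment synthetic cohort and a
    reduced (3-stack) network trained on it with a subject-wise split.

    Session-scoped because training dominates the suite's runtime; every
    consumer treats the contents as read-only.
    """
    cohort = simulate_cohort(10, 10, duration=1000.0, seed=42)
    segments, truths = cohort_segments(cohort)
    x, y, groups = segments_to_arrays(segments)
    subjects = np.unique(groups)
    held_out = set(list(subjects[:2]) + list(subjects[10:12]))
    test_mask = np.isin(groups, list(held_out))
    model = BHNet(BHNetConfig.reduced(3, seed=0))
    config = TrainConfig(learning_rate=1e-3, max_epochs=4, seed=0)
    history = train_model(model, (x[~test_mask], y[~test_mask]),
                          (x[test_mask], y[test_mask]), config)
    return {
        "cohort": cohort, "segments": segments, "truths": truths,
        "x": x, "y": y, "groups": groups, "test_mask": test_mask,
        "model": model, "history": history,
    }
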