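"""1D Grad-CAM saliency maps over BCG segments.

The class-activation map for a target class is the ReLU of the
channel-weighted sum of a convolutional layer's activations, where the
channel weights are the positionwise mean of the gradient of the
pre-SoftMax logit with respect to those activations.  The raw map is
linearly up-sampled to the input length and min-max normalized to [0, 1]
(an all-zero map is returned unchanged with a ``degenerate`` flag rather
than divided by zero).  The model is evaluated in inference mode, so
dropout is disabled and normalization layers use running statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import functional as F
from .nn.autograd import backward
from .signal_core import BcgSegment


@dataclass
class HeatMap:
    weights: np.ndarray
    target_class: int
    layer: str
    normalized: bool = True
    degenerate: bool = False

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)

    def __len__(self) -> int:
        return self.weights.size


def compute_heatmap(model, segment, target_class: int,
                    layer: str | None = None) -> HeatMap:
    """Grad-CAM heat-map of one segment for ``target_class``.

    ``model`` must populate ``model.activations`` during ``forward`` and
    expose ``default_cam_layer``; ``layer`` selects which cached
    activation to explain (default: the last convolutional feature map).
    """
    x = segment.samples if isinstance(segment, BcgSegment) else np.asarray(segment)
    x = x.reshape(1, 1, -1)
    was_training = model.training
    model.eval()
    try:
        model.forward(x)
        layer = layer or model.default_cam_layer
        acts = model.activations
        if layer not in acts:
            raise KeyError(
                f"layer {layer!r} not found; valid ids: {sorted(acts)}")
        a = acts[layer]
        logits = acts["logits"]
        seed = np.zeros_like(logits.data)
        seed[0, target_class] = 1.0
        model.zero_grad()
        a.grad = None
        backward(logits, seed)
        grad = a.grad
        if grad is None:
            raise ValueError(f"layer {layer!r} received no gradient")
        channel_w = grad.mean(axis=2, keepdims=True)           # (1, C, 1)
        raw = np.maximum((channel_w * a.data).sum(axis=1), 0.0)[0]  # (l,)
        model.zero_grad()
    finally:
        if was_training:
            model.train()
    mat = F.interp_matrix(raw.size, x.shape[2])
    up = raw.astype(np.float64) @ mat
    top = up.max()
    if top <= 0.0:
        return HeatMap(np.zeros_like(up), target_class, layer, degenerate=True)
    lo = up.min()
    if top == lo:  # constant positive map: every sample maximally salient
        return HeatMap(np.ones_like(up), target_class, layer)
    return HeatMap((up - lo) / (top - lo), target_class, layer)


def batch_heatmaps(model, segments, target: str = "predicted-class",
                   fixed_class: int = 1, layer: str | None = None,
                   batch_size: int = 256) -> dict[str, HeatMap]:
    """One heat-map per segment, keyed by segment id.

    ``target`` is either ``"predicted-class"`` (explain the argmax class
    of each segment) or ``"fixed-class"`` (explain ``fixed_class``).
    """
    if target not in ("predicted-class", "fixed-class"):
        raise ValueError(f"unknown target mode {target!r}")
    segments = list(segments)
    if target == "predicted-class":
        xs = np.stack([s.samples for s in segments])
        preds = model.predict_proba(xs, batch_size=batch_size).argmax(axis=1)
    else:
        preds = np.full(len(segments), fixed_class)
    store: dict[str, HeatMap] = {}
    for seg, cls in zip(segments, preds):
        try:
            store[seg.segment_id] = compute_heatmap(model, seg, int(cls), layer)
        except Exception as exc:
            raise RuntimeError(f"heat-map failed for segment {seg.segment_id}") from exc
    return store


def save_heatmaps(store: dict[str, HeatMap], path, precision: int = 6) -> None:
    """JSON store: one record per segment with rounded weights."""
    payload = {
        sid: {"target_class": hm.target_class, "layer": hm.layer,
              "degenerate": hm.degenerate,
              "weights": [round(float(w), precision) for w in hm.weights]}
        for sid, hm in store.items()
    }
    Path(path).write_text(json.dumps(payload))


def load_heatmaps(path) -> dict[str, HeatMap]:
    raw = json.loads(Path(path).read_text())
    return {
        sid: HeatMap(np.array(rec["weights"]), rec["target_class"],
                     rec["layer"], degenerate=rec["degenerate"])
        for sid, rec in raw.items()
    }
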