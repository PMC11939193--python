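"""BH-Net: multi-scale residual 1D CNN with channel-attention fusion.

Architecture overview (for a 1000-sample, 10 s @ 100 Hz input):

* stem: two stride-2 convolutions (kernel 19) with BatchNorm + GELU in
  between -> length 250, 16 channels;
* 7 stacks of [residual block, pooling residual block]; a residual block
  is two repeats of BatchNorm -> GELU -> dropout(0.1) -> conv(kernel 17,
  stride 1, zero 'same' padding) with an additive skip (1x1 projection
  when the channel count changes); the pooling variant appends a stride-2
  ceil-mode max pool.  Channels follow (16, 32, 32, 48, 48, 64, 64), and
  one extra residual block (64 channels) closes the trunk;
* four multi-scale taps: the outputs of the three stacks before the last
  one and of the extra block (lengths 16, 8, 4, 2 for a 1000-sample
  input), each adaptive-average-pooled to the fixed scale lengths
  (16, 8, 4, 2) so the default geometry is the identity;
* per-tap MS-CAM refinement: global channel context omega (GAP ->
  conv C->32 -> GELU -> conv 32->C -> BatchNorm) broadcast-added to the
  positionwise local context L (same bottleneck applied per position),
  squashed by a sigmoid and multiplied elementwise into the tap;
* head: refined taps linearly up-sampled to the longest scale length,
  channel-concatenated, flattened and mapped by one fully connected layer
  to two logits with SoftMax.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import functional as F
from .nn.autograd import Tensor


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class BHNetConfig:
    input_length: int = 1000
    n_stacks: int = 7
    stem_kernel: int = 19
    stem_stride: int = 2
    stem_filters: int = 16
    block_kernel: int = 17
    filter_schedule: tuple[int, ...] = (16, 32, 32, 48, 48, 64, 64)
    extra_filters: int = 64
    dropout: float = 0.1
    pool_kernel: int = 2
    pool_stride: int = 2
    scale_lengths: tuple[int, ...] = (16, 8, 4, 2)
    fusion_bottleneck: int = 32
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if len(self.filter_schedule) != self.n_stacks:
            raise ConfigurationError("filter_schedule length must equal n_stacks")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must lie in [0, 1)")
        sl = self.scale_lengths
        if any(b >= a for a, b in zip(sl, sl[1:])) or any(s < 1 for s in sl):
            raise ConfigurationError("scale_lengths must be strictly decreasing, >= 1")
        if len(sl) != self.n_taps:
            raise ConfigurationError(
                f"need {self.n_taps} scale_lengths for {self.n_stacks} stacks, got {len(sl)}")
        chain = self.length_chain()
        if min(chain) < 1:
            raise ConfigurationError(
                f"input_length {self.input_length} collapses below one sample: {chain}")

    @property
    def n_taps(self) -> int:
        return min(3, self.n_stacks) + 1

    def length_chain(self) -> list[int]:
        """Feature-map length after the stem and after each stack."""
        pad = (self.stem_kernel - 1) // 2
        length = self.input_length
        for _ in range(2):
            if length + 2 * pad < self.stem_kernel:
                raise ConfigurationError("input too short for the stem kernel")
            length = (length + 2 * pad - self.stem_kernel) // self.stem_stride + 1
        chain = [length]
        for _ in range(self.n_stacks):
            length = -(-length // self.pool_stride)  # ceil-mode pooling
            chain.append(length)
        return chain

    def tap_stack_indices(self) -> list[int]:
        """0-based stack indices whose outputs feed the multi-scale taps.

        The extra residual block supplies the final tap in addition.
        """
        n = self.n_stacks
        if n >= 4:
            return [n - 4, n - 3, n - 2]
        return list(range(n))

    @classmethod
    def reduced(cls, n_stacks: int = 3, input_length: int = 1000,
                seed: int = 0, **overrides) -> "BHNetConfig":
        """A shallow variant for desk-scale experiments."""
        schedule = cls.__dataclass_fields__["filter_schedule"].default[:n_stacks]
        return cls(input_length=input_length, n_stacks=n_stacks,
                   filter_schedule=schedule, extra_filters=schedule[-1],
                   seed=seed, **overrides)


@dataclass
class FusionContext:
    """Intermediate quantities of one MS-CAM application (NumPy views)."""

    global_context: np.ndarray   # omega, (N, C, 1)
    local_context: np.ndarray    # L, (N, C, length)
    attention: np.ndarray        # sigmoid(omega + L), in (0, 1)
    refined: np.ndarray          # X * attention


class ResidualBlock(nn.Module):
    def __init__(self, cin: int, cout: int, kernel: int, dropout_p: float,
                 rng, drop_rng, dtype=np.float32):
        super().__init__()
        self.bn1 = nn.BatchNorm1d(cin, dtype=dtype)
        self.conv1 = nn.Conv1d(cin, cout, kernel, rng, padding="same", dtype=dtype)
        self.bn2 = nn.BatchNorm1d(cout, dtype=dtype)
        self.conv2 = nn.Conv1d(cout, cout, kernel, rng, padding="same", dtype=dtype)
        self.drop1 = nn.Dropout(dropout_p, drop_rng)
        self.drop2 = nn.Dropout(dropout_p, drop_rng)
        self.proj = (nn.Conv1d(cin, cout, 1, rng, dtype=dtype)
                     if cin != cout else None)

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1.forward(self.drop1.forward(F.gelu(self.bn1.forward(x))))
        h = self.conv2.forward(self.drop2.forward(F.gelu(self.bn2.forward(h))))
        skip = self.proj.forward(x) if self.proj is not None else x
        return F.add(h, skip)


class PoolingResidualBlock(nn.Module):
    def __init__(self, cin: int, cout: int, kernel: int, dropout_p: float,
                 rng, drop_rng, pool_kernel: int = 2, pool_stride: int = 2,
                 dtype=np.float32):
        super().__init__()
        self.block = ResidualBlock(cin, cout, kernel, dropout_p, rng, drop_rng,
                                   dtype)
        self.pool_kernel = pool_kernel
        self.pool_stride = pool_stride

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool1d(self.block.forward(x), self.pool_kernel,
                            self.pool_stride)


class MSCAM(nn.Module):
    """Multi-scale channel attention: omega = B(Conv(G(Conv(g(X))))),
    L the positionwise analogue, X' = X * sigmoid(omega broadcast+ L)."""

    def __init__(self, channels: int, bottleneck: int, rng, dtype=np.float32):
        super().__init__()
        self.g_conv1 = nn.Conv1d(channels, bottleneck, 1, rng, dtype=dtype)
        self.g_conv2 = nn.Conv1d(bottleneck, channels, 1, rng, dtype=dtype)
        self.g_bn = nn.BatchNorm1d(channels, dtype=dtype)
        self.l_conv1 = nn.Conv1d(channels, bottleneck, 1, rng, dtype=dtype)
        self.l_conv2 = nn.Conv1d(bottleneck, channels, 1, rng, dtype=dtype)
        self.l_bn = nn.BatchNorm1d(channels, dtype=dtype)
        self.channels = channels
        self.last_context: FusionContext | None = None

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.channels:
            raise ValueError(
                f"MS-CAM expects {self.channels} channels, got {x.data.shape[1]}")
        gap = F.adaptive_avg_pool1d(x, 1)
        omega = self.g_bn.forward(self.g_conv2.forward(F.gelu(self.g_conv1.forward(gap))))
        local = self.l_bn.forward(self.l_conv2.forward(F.gelu(self.l_conv1.forward(x))))
        attention = F.sigmoid(F.add(omega, local))
        refined = F.mul(x, attention)
        self.last_context = FusionContext(omega.data, local.data,
                                          attention.data, refined.data)
        return refined


def ms_cam_fuse(module: MSCAM, x) -> FusionContext:
    """Apply one MS-CAM module to ``x`` (N, C, L) and expose the contexts."""
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    module.forward(t)
    return module.last_context


class BHNet(nn.Module):
    """The full classifier; ``forward`` returns class probabilities and
    caches named intermediate activations in ``self.activations`` (used by
    Grad-CAM and by tests)."""

    default_cam_layer = "extra_block"

    def __init__(self, config: BHNetConfig, dtype=np.float32):
        super().__init__()
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
        drop_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        c = config
        self.stem_conv1 = nn.Conv1d(1, c.stem_filters, c.stem_kernel, rng,
                                    stride=c.stem_stride, padding="same", dtype=dtype)
        self.stem_bn = nn.BatchNorm1d(c.stem_filters, dtype=dtype)
        self.stem_conv2 = nn.Conv1d(c.stem_filters, c.stem_filters, c.stem_kernel,
                                    rng, stride=c.stem_stride, padding="same", dtype=dtype)
        prev = c.stem_filters
        for i, ch in enumerate(c.filter_schedule):
            setattr(self, f"stack{i}_res",
                    ResidualBlock(prev, ch, c.block_kernel, c.dropout, rng,
                                  drop_rng, dtype))
            setattr(self, f"stack{i}_pool",
                    PoolingResidualBlock(ch, ch, c.block_kernel, c.dropout, rng,
                                         drop_rng, c.pool_kernel, c.pool_stride,
                                         dtype))
            prev = ch
        self.extra_block = ResidualBlock(prev, c.extra_filters, c.block_kernel,
                                         c.dropout, rng, drop_rng, dtype)

        tap_idx = c.tap_stack_indices()
        tap_channels = [c.filter_schedule[i] for i in tap_idx] + [c.extra_filters]
        self._tap_idx = tap_idx
        self.tap_channels = tap_channels
        for t, ch in enumerate(tap_channels):
            setattr(self, f"mscam{t}", MSCAM(ch, c.fusion_bottleneck, rng, dtype))
        head_in = sum(tap_channels) * c.scale_lengths[0]
        self.head = nn.Linear(head_in, c.n_classes, rng, dtype=dtype)
        self.activations: dict[str, Tensor] = {}

    def forward(self, x) -> Tensor:
        c = self.config
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.dtype))
        if x.data.ndim == 2:
            x = F.reshape(x, (x.data.shape[0], 1, x.data.shape[1]))
        if x.data.shape[2] != c.input_length:
            raise ValueError(
                f"expected input length {c.input_length}, got {x.data.shape[2]}")
        acts = self.activations = {}
        h = self.stem_conv2.forward(F.gelu(self.stem_bn.forward(
            self.stem_conv1.forward(x))))
        acts["stem"] = h
        stack_outs = []
        for i in range(c.n_stacks):
            h = getattr(self, f"stack{i}_res").forward(h)
            h = getattr(self, f"stack{i}_pool").forward(h)
            acts[f"stack_{i + 1}"] = h
            stack_outs.append(h)
        h = self.extra_block.forward(h)
        acts["extra_block"] = h

        taps = [stack_outs[i] for i in self._tap_idx] + [h]
        refined = []
        for t, tap in enumerate(taps):
            pooled = F.adaptive_avg_pool1d(tap, c.scale_lengths[t])
            acts[f"tap{t}_pooled"] = pooled
            r = getattr(self, f"mscam{t}").forward(pooled)
            acts[f"tap{t}_refined"] = r
            refined.append(F.interp_resize(r, c.scale_lengths[0]))
        fused = F.concat(refined, axis=1)
        acts["fused"] = fused
        flat = F.reshape(fused, (fused.data.shape[0], -1))
        logits = self.head.forward(flat)
        acts["logits"] = logits
        probs = F.softmax(logits, axis=1)
        acts["probs"] = probs
        return probs

    def predict_proba(self, x, batch_size: int = 256) -> np.ndarray:
        """Evaluation-mode class probabilities for an array of segments."""
        was_training = self.training
        self.eval()
        x = np.asarray(x, dtype=self.dtype)
        out = [self.forward(x[i:i + batch_size]).data
               for i in range(0, x.shape[0], batch_size)]
        if was_training:
            self.train()
        return np.concatenate(out, axis=0)


def build_model(config: BHNetConfig) -> BHNet:
    return BHNet(config)


def count_parameters(model: nn.Module) -> int:
    return nn.count_parameters(model)


def save_model(model: BHNet, path) -> None:
    """Serialized weights (.npz) with a JSON config sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    path.with_suffix(".json").write_text(json.dumps(asdict(model.config)))


def load_model(path) -> BHNet:
    path = Path(path)
    cfg_raw = json.loads(path.with_suffix(".json").read_text())
    cfg_raw["filter_schedule"] = tuple(cfg_raw["filter_schedule"])
    cfg_raw["scale_lengths"] = tuple(cfg_raw["scale_lengths"])
    model = BHNet(BHNetConfig(**cfg_raw))
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
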