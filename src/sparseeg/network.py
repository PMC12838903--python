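"""Multi-scale spatio-temporal CNN for sparse-channel EEG windows.

The network has four stages:

* **temporal** — three parallel valid convolutions with kernel widths
  ``floor(m^i · f)`` (i = 1..3, m = 0.5 by default), 128 filters each,
  leaky rectification and width-8 average pooling; the pooled maps are
  concatenated along the time axis and batch-normalized.
* **spatial** — a global kernel spanning all channels and a local kernel of
  ``floor(m · c)`` rows, 15 filters each, leaky rectification and width-2
  average pooling; branch outputs are concatenated along the spatial axis.
* **fusion** — a stack of separable-convolution blocks (depthwise then
  pointwise), batch norm, rectification and max pooling; after the first
  block the map is flattened into a single-channel 1-D sequence and three
  1-D separable blocks grow the channel count to 32/64/128.
* **head** — three affine layers (hidden sizes 64 and 16) with batch norm,
  rectification and dropout, ending in a softmax over the classes.

Analytic shape functions mirror the executed network stage by stage; they
are the single source of truth for layer sizing and are cross-checked
against observed forward shapes in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import nn

VARIANTS = ("full", "no_temporal_multiscale", "no_spatial_multiscale", "no_fusion")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``n_channels`` (c) and ``window_len`` (f, samples per 1-s window) follow
    the data geometry; the remaining defaults give the reference
    architecture for 4 × 128 inputs.
    """

    n_channels: int = 4
    window_len: int = 128
    scale: float = 0.5
    n_temporal_scales: int = 3
    temporal_filters: int = 128
    temporal_pool: int = 8
    spatial_filters: int = 15
    spatial_pool: int = 2
    fusion_channels: tuple[int, ...] = (15, 32, 64, 128)
    fusion_kernel: int = 3
    fusion_pool: tuple[int, ...] = (4, 2, 2, 2)
    hidden: tuple[int, ...] = (64, 16)
    n_classes: int = 2
    dropout: float = 0.5
    negative_slope: float = 0.01
    variant: str = "full"

    def __post_init__(self) -> None:
        if not (0.0 < self.scale < 1.0):
            raise ValueError("scale must lie in (0, 1)")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if len(self.fusion_channels) != len(self.fusion_pool):
            raise ValueError("fusion_channels and fusion_pool must have equal length")

    def with_variant(self, variant: str) -> "NetworkConfig":
        return replace(self, variant=variant)


def temporal_kernel_widths(f: int, m: float = 0.5, n: int = 3) -> list[int]:
    """Kernel widths ``floor(m^i · f)`` for i = 1..n."""
    if f < 2:
        raise ValueError("window length must be at least 2")
    if not (0.0 < m < 1.0):
        raise ValueError("scale factor m must lie in (0, 1)")
    if n < 1:
        raise ValueError("need at least one scale")
    widths = [math.floor(m**i * f) for i in range(1, n + 1)]
    if any(w < 1 for w in widths):
        raise ValueError(f"kernel widths {widths} include a degenerate (<1) width")
    return widths


# ---------------------------------------------------------------------------
# analytic shape functions (batch axis omitted)
# ---------------------------------------------------------------------------


def _active_widths(cfg: NetworkConfig) -> list[int]:
    widths = temporal_kernel_widths(cfg.window_len, cfg.scale, cfg.n_temporal_scales)
    return widths[:1] if cfg.variant == "no_temporal_multiscale" else widths


def temporal_output_shape(cfg: NetworkConfig) -> tuple[int, int, int]:
    """(filters, channels, time) after the temporal stage."""
    times = [(cfg.window_len - w + 1) // cfg.temporal_pool for w in _active_widths(cfg)]
    if any(t < 1 for t in times):
        raise ValueError(f"temporal pooling leaves an empty branch: lengths {times}")
    return (cfg.temporal_filters, cfg.n_channels, sum(times))


def local_spatial_kernel(cfg: NetworkConfig) -> int:
    k = math.floor(cfg.scale * cfg.n_channels)
    if k < 1 or k > cfg.n_channels:
        raise ValueError(f"local spatial kernel {k} invalid for c={cfg.n_channels}")
    return k


def spatial_output_shape(cfg: NetworkConfig) -> tuple[int, int, int]:
    """(filters, rows, time) after the spatial stage: the global branch
    contributes one row, the local branch c − floor(m·c) + 1 rows."""
    _, c, t_in = temporal_output_shape(cfg)
    t_out = t_in // cfg.spatial_pool
    if t_out < 1:
        raise ValueError("spatial pooling leaves no time steps")
    if cfg.variant == "no_spatial_multiscale":
        rows = 1
    else:
        rows = 1 + (c - local_spatial_kernel(cfg) + 1)
    return (cfg.spatial_filters, rows, t_out)


def fusion_output_shape(cfg: NetworkConfig) -> tuple[int, int]:
    """(channels, length) after the fusion stage."""
    _, rows, t = spatial_output_shape(cfg)
    k = cfg.fusion_kernel
    # the first (2-D) depthwise kernel spans spatial rows; clamp it when a
    # variant leaves fewer rows than the nominal kernel
    k1 = min(k, rows)
    rows1 = rows - k1 + 1
    t1 = t // cfg.fusion_pool[0]
    if t1 < 1:
        raise ValueError("first fusion pool leaves no time steps")
    length = cfg.fusion_channels[0] * rows1 * t1
    for ch, pool in zip(cfg.fusion_channels[1:], cfg.fusion_pool[1:]):
        length = length - k + 1
        if length < 1:
            raise ValueError("fusion block input shorter than its kernel")
        length //= pool
        if length < 1:
            raise ValueError("fusion pooling leaves an empty sequence")
    return (cfg.fusion_channels[-1], length)


def head_input_size(cfg: NetworkConfig) -> int:
    if cfg.variant == "no_fusion":
        filt, rows, t = spatial_output_shape(cfg)
        return filt * rows * t
    ch, length = fusion_output_shape(cfg)
    return ch * length


def shape_trace(cfg: NetworkConfig) -> dict[str, tuple[int, ...]]:
    """Closed-form per-stage output shapes (without the batch axis)."""
    trace = {
        "input": (1, cfg.n_channels, cfg.window_len),
        "temporal": temporal_output_shape(cfg),
        "spatial": spatial_output_shape(cfg),
    }
    if cfg.variant != "no_fusion":
        trace["fusion"] = fusion_output_shape(cfg)
    trace["head"] = (cfg.n_classes,)
    return trace


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class EmotionNet:
    """The four-stage CNN with named stages ``temporal``, ``spatial``,
    ``fusion`` (absent in the no-fusion variant) and ``head``.

    The feature extractor (everything before the head) and the classifier
    head can be addressed separately, which the teacher/student adaptation
    relies on.
    """

    FEATURE_STAGES = ("temporal", "spatial", "fusion")

    def __init__(self, config: NetworkConfig, seed: int = 42):
        self.config = config
        self.seed = seed
        shape_trace(config)  # validate sizing up front
        root_ss = np.random.SeedSequence(seed)
        init_rng = np.random.default_rng(root_ss.spawn(1)[0])
        self.stages: dict[str, nn.Layer] = {}
        self.stages["temporal"] = self._build_temporal(config, init_rng)
        self.stages["spatial"] = self._build_spatial(config, init_rng)
        if config.variant != "no_fusion":
            self.stages["fusion"] = self._build_fusion(config, init_rng)
        self.stages["head"] = self._build_head(config, init_rng, dropout_seed=(seed, 1))
        self.history: list[dict] = []

    # -- builders ----------------------------------------------------------

    @staticmethod
    def _build_temporal(cfg: NetworkConfig, rng) -> nn.Layer:
        branches = [
            nn.Sequential(
                [
                    nn.Conv2d(1, cfg.temporal_filters, (1, w), rng),
                    nn.LeakyReLU(cfg.negative_slope),
                    nn.AvgPoolTime(cfg.temporal_pool),
                ]
            )
            for w in _active_widths(cfg)
        ]
        return nn.Sequential(
            [nn.ConcatBranches(branches, axis=3), nn.BatchNorm(cfg.temporal_filters)]
        )

    @staticmethod
    def _build_spatial(cfg: NetworkConfig, rng) -> nn.Layer:
        def branch(kernel_rows: int) -> nn.Layer:
            return nn.Sequential(
                [
                    nn.Conv2d(cfg.temporal_filters, cfg.spatial_filters, (kernel_rows, 1), rng),
                    nn.LeakyReLU(cfg.negative_slope),
                    nn.AvgPoolTime(cfg.spatial_pool),
                ]
            )

        branches = [branch(cfg.n_channels)]  # global kernel
        if cfg.variant != "no_spatial_multiscale":
            branches.append(branch(local_spatial_kernel(cfg)))  # local kernel
        return nn.Sequential(
            [nn.ConcatBranches(branches, axis=2), nn.BatchNorm(cfg.spatial_filters)]
        )

    @staticmethod
    def _build_fusion(cfg: NetworkConfig, rng) -> nn.Layer:
        k = cfg.fusion_kernel
        k1 = min(k, spatial_output_shape(cfg)[1])
        layers: list[nn.Layer] = [
            # block 1: 2-D separable over (space, time)
            nn.DepthwiseConv2d(cfg.spatial_filters, (k1, 1), rng),
            nn.Conv2d(cfg.spatial_filters, cfg.fusion_channels[0], (1, 1), rng),
            nn.BatchNorm(cfg.fusion_channels[0]),
            nn.ReLU(),
            nn.MaxPoolTime(cfg.fusion_pool[0]),
            nn.FlattenToSequence(),
        ]
        in_ch = 1
        for ch, pool in zip(cfg.fusion_channels[1:], cfg.fusion_pool[1:]):
            layers += [
                nn.DepthwiseConv2d(in_ch, (1, k), rng),
                nn.Conv2d(in_ch, ch, (1, 1), rng),
                nn.BatchNorm(ch),
                nn.ReLU(),
                nn.MaxPoolTime(pool),
            ]
            in_ch = ch
        return nn.Sequential(layers)

    @staticmethod
    def _build_head(cfg: NetworkConfig, rng, dropout_seed) -> nn.Layer:
        drop_rng = np.random.default_rng(np.random.SeedSequence(dropout_seed[0], spawn_key=(0xD0, dropout_seed[1])))
        sizes = [head_input_size(cfg), *cfg.hidden]
        layers: list[nn.Layer] = [nn.Flatten()]
        for a, b in zip(sizes[:-1], sizes[1:]):
            layers += [
                nn.Linear(a, b, rng),
                nn.BatchNorm(b),
                nn.ReLU(),
                nn.Dropout(cfg.dropout, drop_rng),
            ]
        layers.append(nn.Linear(sizes[-1], cfg.n_classes, rng))
        return nn.Sequential(layers)

    # -- execution ---------------------------------------------------------

    def stage_names(self) -> list[str]:
        return list(self.stages)

    def _as_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=nn.layers.DTYPE)
        if X.ndim == 3:  # (B, c, f) → (B, 1, c, f)
            X = X[:, None, :, :]
        if X.ndim != 4:
            raise ValueError(f"expected (batch, c, f) or (batch, 1, c, f), got {X.shape}")
        return X

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits of shape (batch, n_classes)."""
        h = self._as_input(X)
        for stage in self.stages.values():
            h = stage.forward(h, training=training)
        return h

    def backward(self, grad_logits: np.ndarray) -> None:
        g = np.asarray(grad_logits, dtype=nn.layers.DTYPE)
        for stage in reversed(self.stages.values()):
            g = stage.backward(g)

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Eval-mode class probabilities; rows sum to 1."""
        X = self._as_input(X)
        outs = [softmax(self.forward(X[i : i + batch_size])) for i in range(0, len(X), batch_size)]
        return np.concatenate(outs) if outs else np.empty((0, self.config.n_classes))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- parameter plumbing ------------------------------------------------

    def param_refs(self) -> list[tuple[nn.Layer, str]]:
        return [ref for stage in self.stages.values() for ref in nn.param_refs(stage)]

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, stage in self.stages.items():
            out.update(nn.state_dict(stage, prefix=name))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, stage in self.stages.items():
            nn.load_state_dict(stage, state, prefix=name)

    def feature_state(self) -> dict[str, np.ndarray]:
        return {
            k: v
            for k, v in self.state_dict().items()
            if k.split(".")[0].split(":")[0] in self.FEATURE_STAGES
        }

    def head_state(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.state_dict().items() if k.startswith("head")}

    def clone(self) -> "EmotionNet":
        other = EmotionNet(self.config, seed=self.seed)
        other.load_state_dict(self.state_dict())
        return other

    def reinit_head(self, seed: int) -> None:
        """Fresh random classifier head (feature stages untouched)."""
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0x4EAD,)))
        self.stages["head"] = self._build_head(self.config, rng, dropout_seed=(seed, 2))

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for k in sorted(self.state_dict()):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.state_dict()[k]).tobytes())
        return h.hexdigest()


def make_variant(config: NetworkConfig, drop: str | None, seed: int = 42) -> EmotionNet:
    """Build an ablation variant: drop ∈ {'mtcl', 'mscl', 'ffl', None}.

    'mtcl' keeps only the largest temporal kernel, 'mscl' keeps only the
    global spatial kernel, 'ffl' feeds the spatial output straight into the
    classifier head.
    """
    mapping = {
        None: "full",
        "none": "full",
        "mtcl": "no_temporal_multiscale",
        "mscl": "no_spatial_multiscale",
        "ffl": "no_fusion",
    }
    if drop not in mapping:
        raise ValueError(f"unknown ablation tag {drop!r}; choose from {sorted(mapping, key=str)}")
    return EmotionNet(config.with_variant(mapping[drop]), seed=seed)
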