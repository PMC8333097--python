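"""Frame classifier assembly.

The architecture follows the raw-waveform speaker-recognition recipe this
package adapts to bird calls: a first convolutional layer over the raw
frame — either a sinc-parameterized band-pass bank (two learnable cutoff
parameters per filter) or an unconstrained standard convolution of the same
shape — followed by further 1-d convolutions with layer normalization and
max pooling, three fully connected leaky-ReLU layers with batch
normalization, and a LogSoftmax output emitting per-frame class
log-posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import layers as L
from .sinc import mel_init

__all__ = ["NetConfig", "FrameClassifier", "build_model", "forward"]


@dataclass
class NetConfig:
    """Architecture and framing hyperparameters.

    ``cw_len_ms``/``cw_shift_ms`` are the analysis window length and shift
    in milliseconds; a frame holds ``round(cw_len_ms * fs / 1000)`` samples.
    """

    n_classes: int
    fs: int = 44100
    frontend: str = "sinc"              # "sinc" | "standard_conv"
    n_filt_1: int = 80
    len_filt_1: int = 251
    conv_layers: list[tuple[int, int]] = field(
        default_factory=lambda: [(60, 5), (60, 5)])
    pool_len: int = 3
    fc_layers: list[int] = field(default_factory=lambda: [2048, 2048, 2048])
    cw_len_ms: float = 10.0
    cw_shift_ms: float = 1.0
    leaky_slope: float = 0.2
    fc_dropout: float = 0.0
    input_layernorm: bool = True
    mel_f_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("classification needs at least 2 classes")
        if self.frontend not in ("sinc", "standard_conv"):
            raise ValueError(f"unknown frontend {self.frontend!r}")
        self.conv_layers = [tuple(c) for c in self.conv_layers]
        if self.frame_samples < self.len_filt_1:
            raise ValueError(
                f"frame of {self.frame_samples} samples is shorter than the "
                f"first-layer filter length {self.len_filt_1}")

    @property
    def frame_samples(self) -> int:
        return int(round(self.cw_len_ms * self.fs / 1000.0))

    @property
    def shift_samples(self) -> int:
        return max(1, int(round(self.cw_shift_ms * self.fs / 1000.0)))

    # YAML round-trip -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


class FrameClassifier:
    """A built model: maps (batch, frame_samples) to log-posterior rows."""

    def __init__(self, cfg: NetConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        frame = cfg.frame_samples
        stack: list[L.Layer] = []
        if cfg.input_layernorm:
            stack.append(L.LayerNorm((1, frame)))

        # frontend (bias-free in both variants so the parameter counts are
        # exactly 2*n_filt vs n_filt*len_filt)
        if cfg.frontend == "sinc":
            bands = mel_init(cfg.n_filt_1, cfg.fs, cfg.mel_f_min)
            p_low = np.array([b[0] for b in bands])
            p_band = np.array([b[1] - b[0] for b in bands])
            self.frontend = L.SincConv1d(cfg.n_filt_1, cfg.len_filt_1,
                                         cfg.fs, p_low, p_band)
        else:
            self.frontend = L.Conv1d(1, cfg.n_filt_1, cfg.len_filt_1,
                                     rng, bias=False)
        stack.append(self.frontend)
        length = frame - cfg.len_filt_1 + 1
        length //= cfg.pool_len
        stack += [L.MaxPool1d(cfg.pool_len),
                  L.LayerNorm((cfg.n_filt_1, length)),
                  L.LeakyReLU(cfg.leaky_slope)]
        channels = cfg.n_filt_1

        for n_f, len_f in cfg.conv_layers:
            if length - len_f + 1 < cfg.pool_len:
                raise ValueError(
                    "frame too short for the configured conv/pool stack")
            stack.append(L.Conv1d(channels, n_f, len_f, rng))
            length = (length - len_f + 1) // cfg.pool_len
            stack += [L.MaxPool1d(cfg.pool_len),
                      L.LayerNorm((n_f, length)),
                      L.LeakyReLU(cfg.leaky_slope)]
            channels = n_f

        stack.append(L.Flatten())
        n_in = channels * length
        drop_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed + 1))
        for width in cfg.fc_layers:
            stack += [L.Linear(n_in, width, rng),
                      L.BatchNorm1d(width),
                      L.LeakyReLU(cfg.leaky_slope)]
            if cfg.fc_dropout > 0:
                stack.append(L.Dropout(cfg.fc_dropout, drop_rng))
            n_in = width
        stack += [L.Linear(n_in, cfg.n_classes, rng), L.LogSoftmax()]
        self.net = L.Sequential(stack)

    # ------------------------------------------------------------------
    def forward(self, frames: np.ndarray, training: bool = False) -> np.ndarray:
        frames = np.asarray(frames, dtype=np.float64)
        if frames.ndim == 1:
            frames = frames[None, :]
        if frames.shape[1] != self.cfg.frame_samples:
            raise ValueError(
                f"expected frames of {self.cfg.frame_samples} samples, "
                f"got {frames.shape[1]}")
        return self.net.forward(frames[:, None, :], training)

    def backward(self, dlogp: np.ndarray) -> None:
        self.net.backward(dlogp)

    def predict_log_proba(self, frames: np.ndarray,
                          batch_size: int = 1024) -> np.ndarray:
        """Eval-mode log-posteriors, chunked to bound memory."""
        frames = np.asarray(frames, dtype=np.float64)
        out = [self.forward(frames[i:i + batch_size], training=False)
               for i in range(0, len(frames), batch_size)]
        return np.concatenate(out, axis=0)

    # introspection ----------------------------------------------------
    def n_params(self) -> int:
        return self.net.n_params()

    def frontend_n_params(self) -> int:
        return self.frontend.n_params()

    # checkpointing ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.net.layers):
            for name, p in layer.params.items():
                arrays[f"{i}.{name}"] = p
            if isinstance(layer, L.BatchNorm1d):
                arrays[f"{i}.running_mean"] = layer.running_mean
                arrays[f"{i}.running_var"] = layer.running_var
        np.savez(str(path), __config__=np.array(yaml.safe_dump(asdict(self.cfg))),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "FrameClassifier":
        with np.load(str(path), allow_pickle=False) as data:
            cfg = NetConfig(**yaml.safe_load(str(data["__config__"])))
            model = cls(cfg)
            for i, layer in enumerate(model.net.layers):
                for name in layer.params:
                    layer.params[name][...] = data[f"{i}.{name}"]
                if isinstance(layer, L.BatchNorm1d):
                    layer.running_mean[...] = data[f"{i}.running_mean"]
                    layer.running_var[...] = data[f"{i}.running_var"]
        return model


def build_model(cfg: NetConfig) -> FrameClassifier:
    """Build the frame classifier described by ``cfg``."""
    return FrameClassifier(cfg)


def forward(model: FrameClassifier, frames: np.ndarray) -> np.ndarray:
    """Eval-mode frame log-posteriors (deterministic; dropout/BN frozen)."""
    return model.predict_log_proba(frames)
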