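"""Frame sampling, augmentation, and the RMSprop training loop.

Training draws fixed-length waveform frames (default 10 ms) from randomly
chosen training items; each frame inherits its item's class.  In the cut
dialect an item is a cropped segment file and the window start is uniform
over valid positions; in the uncut dialect an item is (recording, start,
duration) and calls shorter than the frame are completed with surrounding
audio, the call placed uniformly at random but wholly contained.  A random
per-frame amplification emulates level variation between recordings.

Separate named RNG streams drive item choice, window placement and
amplification, so ablations change one factor at a time and disabling the
amplification leaves the sampled window positions untouched.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .audio import read_wav
from .labels import DatasetSplit, ListItem
from .layers import RMSprop, nll_loss
from .network import FrameClassifier, NetConfig

__all__ = ["TrainConfig", "AudioCache", "extract_frame", "random_amplify",
           "tile_frames", "train", "history_to_csv", "history_from_csv"]


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 128
    n_epochs: int = 200
    batches_per_epoch: int = 800
    amp_factor: float = 0.2       # gain ~ U(1-a, 1+a); 0 disables
    eval_every: int = 10          # epochs between test-set evaluations
    rmsprop_alpha: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class AudioCache:
    """Lazy per-path waveform cache (the corpora are small enough to hold)."""

    def __init__(self, root: str | Path = ".") -> None:
        self.root = Path(root)
        self._store: dict[str, np.ndarray] = {}
        self.fs: int | None = None

    def get(self, path: str) -> np.ndarray:
        if path not in self._store:
            fs, samples = read_wav(self.root / path)
            if self.fs is None:
                self.fs = fs
            elif fs != self.fs:
                raise ValueError(f"{path}: sampling rate {fs} differs from "
                                 f"corpus rate {self.fs}")
            self._store[path] = samples
        return self._store[path]


def extract_frame(item: ListItem, frame_len: int, fs: int,
                  rng: np.random.Generator, cache: AudioCache) -> np.ndarray:
    """Draw one training frame of ``frame_len`` samples for ``item``."""
    x = cache.get(item.path)
    if item.start is None:  # cut dialect: the file *is* the call
        if x.size < frame_len:
            raise ValueError(
                f"{item.path}: segment of {x.size} samples is shorter than "
                f"the {frame_len}-sample frame (should be excluded upstream)")
        s = int(rng.integers(0, x.size - frame_len + 1))
        return x[s:s + frame_len]

    # uncut dialect: select within the labeled call, completing short calls
    # with surrounding audio
    i0 = round(item.start * fs)
    n = round(item.duration * fs)
    if x.size < frame_len:
        raise ValueError(f"{item.path}: file shorter than one frame")
    if n >= frame_len:
        s = i0 + int(rng.integers(0, n - frame_len + 1))
    else:
        lo = max(0, i0 + n - frame_len)
        hi = min(i0, x.size - frame_len)
        s = int(rng.integers(lo, hi + 1))
    return x[s:s + frame_len]


def random_amplify(frame: np.ndarray, amp_factor: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Scale the whole frame by one gain drawn from U(1-a, 1+a)."""
    if not 0.0 <= amp_factor < 1.0:
        raise ValueError("amp_factor must lie in [0, 1)")
    if amp_factor == 0.0:
        return frame
    return frame * rng.uniform(1.0 - amp_factor, 1.0 + amp_factor)


def tile_frames(item: ListItem, frame_len: int, shift: int, fs: int,
                cache: AudioCache) -> np.ndarray:
    """Deterministic frame tiling of an item for evaluation.

    Frames start at stride ``shift`` over the call; a call shorter than one
    frame yields a single frame with the call centered (clipped to the file
    bounds) so it is wholly contained.
    """
    x = cache.get(item.path)
    if item.start is None:
        i0, n = 0, x.size
    else:
        i0, n = round(item.start * fs), round(item.duration * fs)
    if n >= frame_len:
        starts = i0 + np.arange(0, n - frame_len + 1, shift)
    else:
        if x.size < frame_len:
            raise ValueError(f"{item.path}: yields zero full frames")
        s = min(max(0, i0 + (n - frame_len) // 2), x.size - frame_len)
        starts = np.array([s])
    idx = starts[:, None] + np.arange(frame_len)[None, :]
    return x[idx]


def _sample_batch(items: list[ListItem], tcfg: TrainConfig, frame_len: int,
                  fs: int, cache: AudioCache, rng_item, rng_win,
                  rng_amp) -> tuple[np.ndarray, np.ndarray]:
    picks = rng_item.integers(0, len(items), size=tcfg.batch_size)
    frames = np.empty((tcfg.batch_size, frame_len))
    labels = np.empty(tcfg.batch_size, dtype=int)
    for row, i in enumerate(picks):
        item = items[int(i)]
        frame = extract_frame(item, frame_len, fs, rng_win, cache)
        frames[row] = random_amplify(frame, tcfg.amp_factor, rng_amp)
        labels[row] = item.class_index
    return frames, labels


def train(model: FrameClassifier, split: DatasetSplit, tcfg: TrainConfig,
          ncfg: NetConfig, root: str | Path = ".",
          verbose: bool = False) -> tuple[FrameClassifier, list[dict]]:
    """Run the optimization loop; returns the model and per-epoch history.

    History rows carry the mean training loss and, every ``eval_every``
    epochs (and at the last epoch), the file-level test accuracy obtained
    by frame-posterior voting.  Fully reproducible given the seeds.
    """
    from .evaluation import classify_file  # local import to avoid a cycle

    if not split.train:
        raise ValueError("empty training split")
    if len({it.class_index for it in split.train}) < 2:
        raise ValueError("training split must contain at least 2 classes")

    ss = np.random.SeedSequence(tcfg.seed)
    rng_item, rng_win, rng_amp = [np.random.default_rng(c)
                                  for c in ss.spawn(3)]
    cache = AudioCache(root)
    frame_len = ncfg.frame_samples
    opt = RMSprop(model.net, lr=tcfg.learning_rate, alpha=tcfg.rmsprop_alpha)
    history: list[dict] = []

    for epoch in range(1, tcfg.n_epochs + 1):
        losses = np.empty(tcfg.batches_per_epoch)
        for b in range(tcfg.batches_per_epoch):
            frames, labels = _sample_batch(
                split.train, tcfg, frame_len, ncfg.fs, cache,
                rng_item, rng_win, rng_amp)
            logp = model.forward(frames, training=True)
            loss, dlogp = nll_loss(logp, labels)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch} batch {b}; "
                    "inspect learning rate / input scaling")
            model.backward(dlogp)
            opt.step()
            losses[b] = loss

        test_acc = float("nan")
        if split.test and (epoch % tcfg.eval_every == 0
                           or epoch == tcfg.n_epochs):
            correct = sum(
                classify_file(model, item, cache)[0] == item.class_index
                for item in split.test)
            test_acc = correct / len(split.test)
        history.append({"epoch": epoch, "loss": float(losses.mean()),
                        "test_accuracy": test_acc})
        if verbose:
            print(f"epoch {epoch:3d}  loss {losses.mean():.4f}"
                  f"  test_acc {test_acc:.3f}")
    return model, history


def history_to_csv(history: list[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "loss",
                                                "test_accuracy"])
        writer.writeheader()
        writer.writerows(history)


def history_from_csv(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return [{"epoch": int(r["epoch"]), "loss": float(r["loss"]),
                 "test_accuracy": float(r["test_accuracy"])}
                for r in csv.DictReader(fh)]
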