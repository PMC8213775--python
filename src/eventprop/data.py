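"""Datasets and spike-latency encoding.

The Yin-Yang task is a two-dimensional, three-class, non-linearly
separable benchmark: points are drawn uniformly on a disc that two
interlocking semicircular lobes split into "yin" and "yang" regions,
with two small dots on the vertical midline forming a third class.  A
shallow (linear) classifier tops out around 64% accuracy on it, so high
accuracy requires a hidden layer and error backpropagation.

Analog values are converted to spikes by latency coding: a value in
[0, 1] becomes a single spike in the window [0, t_max], plus a fixed
bias spike.  MNIST images map each sufficiently bright pixel to one
latency-coded spike.
"""

from __future__ import annotations

import gzip
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import InputSpikeTrain

__all__ = [
    "YinYangConfig",
    "EncodingConfig",
    "yinyang_class",
    "generate_yinyang",
    "encode_yinyang",
    "encode_mnist",
    "drop_spikes",
    "read_idx",
    "load_mnist",
]

CLASS_NAMES = ("yin", "yang", "dot")


@dataclass
class YinYangConfig:
    """Geometry of the yin-yang disc (coordinates live in
    [0, 2*r_big] and are rescaled to [0, 1])."""

    r_big: float = 0.5
    r_small: float = 0.1


@dataclass
class EncodingConfig:
    """Latency-coding parameters.

    ``t_max`` is the encoding window (ms): value v -> spike at v*t_max
    for Yin-Yang coordinates, or (1 - v/255)*t_max for pixels under the
    default brighter-spikes-earlier convention (``invert_mnist`` flips
    it; the direction is a convention, not dictated by the task).
    ``t_bias`` is the fixed bias-spike time; ``p_drop`` the training-time
    probability of deleting each input spike.
    """

    t_max: float = 30.0
    t_bias: float = 0.0
    p_drop: float = 0.0
    invert_mnist: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_drop < 1.0:
            raise ValueError("p_drop must lie in [0, 1)")


def _dist(x, y, cx, cy):
    return np.sqrt((x - cx) ** 2 + (y - cy) ** 2)


def yinyang_class(x: float, y: float,
                  geom: YinYangConfig | None = None) -> int:
    """Class of a point given in un-normalised coordinates [0, 2*r_big].

    0 = yin, 1 = yang, 2 = dot.  The dots are discs of radius r_small
    centred at (r_big/2, r_big) and (3*r_big/2, r_big); the yin region is
    the union of the right dot disc, the left lobe annulus and the upper
    half-plane outside the right lobe.
    """
    geom = geom or YinYangConfig()
    rb, rs = geom.r_big, geom.r_small
    d_right = _dist(x, y, 1.5 * rb, rb)
    d_left = _dist(x, y, 0.5 * rb, rb)
    if d_right < rs or d_left < rs:
        return 2
    is_yin = (d_right <= rs
              or (rs < d_left <= 0.5 * rb)
              or (y > rb and d_right > 0.5 * rb))
    return 0 if is_yin else 1


def generate_yinyang(n: int, seed: int,
                     geom: YinYangConfig | None = None):
    """Class-balanced rejection sampling of the yin-yang disc.

    Cycles the target class 0, 1, 2, ... and rejection-samples uniform
    points on the disc until one of the target class is found, so the
    class counts differ by at most one.  Deterministic given ``seed``.

    Returns ``(xy, labels)``: coordinates scaled to [0, 1]^2 and integer
    classes.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    geom = geom or YinYangConfig()
    rng = np.random.default_rng(seed)
    rb = geom.r_big
    xy = np.empty((n, 2))
    labels = np.empty(n, dtype=int)
    for i in range(n):
        goal = i % 3
        while True:
            x, y = rng.random(2) * 2.0 * rb
            if _dist(x, y, rb, rb) > rb:
                continue
            c = yinyang_class(x, y, geom)
            if c == goal:
                break
        xy[i] = (x / (2 * rb), y / (2 * rb))
        labels[i] = c
    return xy, labels


def encode_yinyang(x: float, y: float,
                   cfg: EncodingConfig) -> InputSpikeTrain:
    """Five-channel latency code: (x, 1-x, y, 1-y) -> spike times scaled
    by t_max on channels 0..3, plus a bias spike on channel 4."""
    if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
        raise ValueError("coordinates must lie in [0, 1]")
    values = np.array([x, 1.0 - x, y, 1.0 - y])
    times = np.append(values * cfg.t_max, cfg.t_bias)
    channels = np.arange(5)
    return InputSpikeTrain(times, channels)


def encode_mnist(image: np.ndarray, cfg: EncodingConfig) -> InputSpikeTrain:
    """Latency-code one 28x28 grayscale image over 784 channels.

    Pixels with value 0 or 1 (out of 255) produce no spike; the rest
    spike at ``t_max * (1 - v/255)`` (brighter pixels earlier) or at
    ``t_max * v/255`` when ``invert_mnist`` is set.
    """
    flat = np.asarray(image, dtype=float).reshape(-1)
    channels = np.flatnonzero(flat >= 2)
    v = flat[channels] / 255.0
    times = cfg.t_max * (v if cfg.invert_mnist else 1.0 - v)
    return InputSpikeTrain(times, channels)


def drop_spikes(train: InputSpikeTrain, p_drop: float,
                seed: int) -> InputSpikeTrain:
    """Independently delete each spike with probability ``p_drop``
    (training-time regularisation); deterministic given ``seed``."""
    if not 0.0 <= p_drop < 1.0:
        raise ValueError("p_drop must lie in [0, 1)")
    if p_drop == 0.0 or len(train) == 0:
        return train
    rng = np.random.default_rng(seed)
    keep = rng.random(len(train)) >= p_drop
    return InputSpikeTrain(train.times[keep], train.channels[keep])


def read_idx(path: str | Path) -> np.ndarray:
    """Read an IDX (ubyte) file, optionally gzip-compressed."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rb") as f:
        zero, dtype_code, ndim = struct.unpack(">HBB", f.read(4))
        if zero != 0 or dtype_code != 0x08:
            raise ValueError(f"{path}: not an unsigned-byte IDX file")
        shape = struct.unpack(">" + "I" * ndim, f.read(4 * ndim))
        data = np.frombuffer(f.read(), dtype=np.uint8)
    return data.reshape(shape)


def load_mnist(directory: str | Path, split: str = "train"):
    """Load MNIST images and labels from IDX files in ``directory``.

    Looks for the standard filenames (``train-images-idx3-ubyte`` /
    ``t10k-images-idx3-ubyte`` etc.), plain or ``.gz``.  Files are never
    downloaded automatically.
    """
    prefix = {"train": "train", "test": "t10k"}[split]
    directory = Path(directory)

    def find(stem: str) -> Path:
        for suffix in ("", ".gz"):
            p = directory / (stem + suffix)
            if p.exists():
                return p
        raise FileNotFoundError(f"{stem}[.gz] not found in {directory}")

    images = read_idx(find(f"{prefix}-images-idx3-ubyte"))
    labels = read_idx(find(f"{prefix}-labels-idx1-ubyte"))
    return images, labels
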