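"""Synthetic inputs: labelled shape datasets, square stimuli, smoke training.

The dataset generator emulates a small Cifar-like corpus (32x32x3 images,
a handful of balanced classes) whose classes are built from oriented bars,
corner conjunctions and disks, so that multiplicative AND-units (horizontal
edge AND vertical edge -> corner) have something real to gain.  The square
stimulus is the probe used to quantify end-stopping: a centred bright or
dark square whose uniform interior (0D), straight edges (1D) and corners
(2D) are delimited by receptive-field-aware masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architectures import ArchitectureSpec, Network
from .nn import SGD

__all__ = ["SyntheticDatasetSpec", "make_synthetic_dataset",
           "SquareStimulus", "make_square_stimulus", "smoke_train"]

CLASS_NAMES = ("horizontal_bars", "vertical_bars", "corners", "disks")


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Recipe for a balanced, seed-deterministic labelled image set."""

    n_images: int = 512
    classes: int = 4
    side: int = 32
    channels: int = 3
    seed: int = 0
    noise_sigma: float = 0.05

    def __post_init__(self):
        if not 2 <= self.classes <= len(CLASS_NAMES):
            raise ValueError(f"classes must be in [2, {len(CLASS_NAMES)}]")


def _draw_hbar(img, rng, lo, hi):
    r = rng.integers(2, img.shape[0] - 4)
    t = rng.integers(2, 4)
    img[r:r + t, 2:-2] = rng.uniform(lo, hi)


def _draw_vbar(img, rng, lo, hi):
    c = rng.integers(2, img.shape[1] - 4)
    t = rng.integers(2, 4)
    img[2:-2, c:c + t] = rng.uniform(lo, hi)


def _draw_corner(img, rng, lo, hi):
    """An L-junction: a horizontal and a vertical segment meeting at a corner."""
    side = img.shape[0]
    r = rng.integers(4, side - 10)
    c = rng.integers(4, side - 10)
    length = rng.integers(6, 12)
    t = rng.integers(2, 4)
    val = rng.uniform(lo, hi)
    img[r:r + t, c:c + length] = val
    img[r:r + length, c:c + t] = val


def _draw_disk(img, rng, lo, hi):
    side = img.shape[0]
    rad = rng.integers(3, 7)
    cy = rng.integers(rad + 1, side - rad - 1)
    cx = rng.integers(rad + 1, side - rad - 1)
    yy, xx = np.ogrid[:side, :side]
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= rad ** 2] = rng.uniform(lo, hi)


_DRAWERS = (_draw_hbar, _draw_vbar, _draw_corner, _draw_disk)


def make_synthetic_dataset(spec: SyntheticDatasetSpec) -> tuple[np.ndarray, np.ndarray]:
    """Images ``(n, side, side, channels)`` in [0, 1] and integer labels.

    Classes are interleaved (0, 1, 2, ..., 0, 1, ...), so any prefix is
    balanced to within one image per class.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_images
    images = np.empty((n, spec.side, spec.side, spec.channels), dtype=np.float32)
    labels = (np.arange(n) % spec.classes).astype(np.int64)
    for i in range(n):
        base = np.full((spec.side, spec.side), rng.uniform(0.1, 0.3), dtype=np.float64)
        for _ in range(int(rng.integers(1, 4))):
            _DRAWERS[labels[i]](base, rng, 0.6, 1.0)
        tint = rng.uniform(0.7, 1.0, size=spec.channels)
        img = base[:, :, None] * tint[None, None, :]
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
        images[i] = np.clip(img, 0.0, 1.0)
    return images, labels


@dataclass
class SquareStimulus:
    """A centred square probe with 0D / 1D / 2D region masks.

    Masks are defined by what a unit with Chebyshev receptive-field radius
    ``radius`` sees: ``mask_0d`` marks positions whose receptive field lies
    entirely inside the square (uniform input), ``mask_1d`` positions seeing
    exactly one straight edge transition, ``mask_2d`` the four corner
    neighbourhoods seeing both a horizontal and a vertical transition.  The
    three masks are pairwise disjoint by construction.
    """

    image: np.ndarray
    polarity: str
    radius: int
    square_bounds: tuple[int, int, int, int]  # (r0, r1, c0, c1), inclusive
    mask_0d: np.ndarray = field(repr=False, default=None)
    mask_1d: np.ndarray = field(repr=False, default=None)
    mask_2d: np.ndarray = field(repr=False, default=None)

    @property
    def masks(self) -> dict[str, np.ndarray]:
        return {"0d": self.mask_0d, "1d": self.mask_1d, "2d": self.mask_2d}

    def to_batch(self, channels: int = 3) -> np.ndarray:
        """The stimulus as a 1-image batch ``[image, row, column, map]``."""
        return np.repeat(self.image[None, :, :, None], channels, axis=3)


def make_square_stimulus(side: int, square_side: int, polarity: str = "bright",
                         radius: int = 1) -> SquareStimulus:
    """Centred axis-aligned square at full contrast with region masks.

    ``bright`` puts a unit square on zero background, ``dark`` the inverse,
    so the two polarities sum to the all-ones image.
    """
    if polarity not in ("bright", "dark"):
        raise ValueError("polarity must be 'bright' or 'dark'")
    if square_side <= 2:
        raise ValueError("square_side must exceed 2 (degenerate square)")
    if square_side >= side:
        raise ValueError("square must fit inside the image")
    if square_side <= 2 * radius:
        raise ValueError("square too small for the receptive-field radius")
    r0 = (side - square_side) // 2
    r1 = r0 + square_side - 1
    c0, c1 = r0, r1
    img = np.zeros((side, side), dtype=np.float64)
    img[r0:r1 + 1, c0:c1 + 1] = 1.0
    if polarity == "dark":
        img = 1.0 - img

    r = radius
    idx = np.arange(side)
    # rows/cols whose +-r window stays inside the square span
    in_rows = (idx >= r0 + r) & (idx <= r1 - r)
    in_cols = (idx >= c0 + r) & (idx <= c1 - r)
    # rows/cols whose window straddles the top/bottom (left/right) transition
    edge_rows = ((idx >= r0 - r) & (idx <= r0 + r - 1)) | ((idx >= r1 - r + 1) & (idx <= r1 + r))
    edge_cols = ((idx >= c0 - r) & (idx <= c0 + r - 1)) | ((idx >= c1 - r + 1) & (idx <= c1 + r))

    mask_0d = in_rows[:, None] & in_cols[None, :]
    mask_2d = edge_rows[:, None] & edge_cols[None, :]
    mask_1d = (edge_rows[:, None] & in_cols[None, :]) | (in_rows[:, None] & edge_cols[None, :])
    return SquareStimulus(image=img, polarity=polarity, radius=radius,
                          square_bounds=(r0, r1, c0, c1),
                          mask_0d=mask_0d, mask_1d=mask_1d, mask_2d=mask_2d)


def smoke_train(arch: ArchitectureSpec | Network,
                dataset: tuple[np.ndarray, np.ndarray],
                steps: int = 200, seed: int = 0, lr: float = 0.05,
                batch_size: int = 32, momentum: float = 0.9,
                weight_decay: float = 0.0) -> tuple[list[float], Network]:
    """Short SGD run on a (images, labels) pair; returns (loss trace, network).

    Fully deterministic given ``seed`` (which also seeds the weight
    initialisation when ``arch`` is a spec).  Raises on divergence.
    """
    images, labels = dataset
    net = arch if isinstance(arch, Network) else Network(arch, seed=seed)
    if steps == 0:
        return [], net
    rng = np.random.default_rng(seed + 1)
    opt = SGD(net.params(), lr=lr, momentum=momentum, weight_decay=weight_decay)
    losses = []
    n = len(images)
    for _ in range(steps):
        idx = rng.choice(n, size=min(batch_size, n), replace=False)
        loss = net.loss(images[idx], labels[idx], train=True)
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged at step {len(losses)}: loss={loss}")
        net.loss_backward()
        opt.step()
        opt.zero_grad()
        losses.append(loss)
    return losses, net
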