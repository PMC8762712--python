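"""Characterising FP-units: filter angle, hyperselectivity, entropy, end-stopping.

An FP-unit multiplies the rectified responses of two filters ``v`` and ``g``.
The angle ``gamma = angle(v, g)`` governs how AND-like the unit is:

* ``gamma = 0`` degenerates to a squared linear response — the iso-response
  contours in the plane spanned by the optimal stimulus and an orthogonal
  direction are straight lines (zero curvature), as for any
  linear-nonlinear (LN) neuron;
* larger ``gamma`` bends the exo-origin contours away from the origin; the
  quadratic coefficient of a fit to the contour quantifies this
  *hyperselectivity*.  For unit-norm filters at response level ``c`` the
  small-``t`` curvature is ``sin^2(gamma/2) / (2 sqrt(c) cos(gamma/2))``.

The remaining analyses are empirical: the Shannon entropy of a unit's
feature-map values over an image batch (sparser responses -> lower entropy)
and the degree of end-stopping ``1 - mean(1D) / mean(2D)`` measured on
bright/dark square stimuli, with units classed as end-stopped spectrum,
0D-responders, or non-responders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architectures import ArchitectureSpec, Network, fp_neuron_depths
from .data import SquareStimulus, make_square_stimulus
from .fp_block import FilterPairVec

__all__ = [
    "gamma_angle", "orthogonal_to", "optimal_stimulus", "pair_response",
    "ContourSample", "iso_response_contour", "curvature_coefficient",
    "feature_map_entropy", "StimulusResponseSummary", "end_stopping_degree",
    "NeuronReport", "neuron_census", "census_frame", "receptive_field",
]

#: default zero-response threshold, as a fraction of the batch-max activation
ZERO_THRESHOLD_FRAC = 1e-4


def _as_pair(pair) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pair, FilterPairVec):
        return np.asarray(pair.v, float).ravel(), np.asarray(pair.g, float).ravel()
    v, g = pair
    return np.asarray(v, float).ravel(), np.asarray(g, float).ravel()


def gamma_angle(pair) -> float:
    """Angle between the vectorised filters, in [0, pi]; NaN for a zero filter."""
    v, g = _as_pair(pair)
    nv, ng = np.linalg.norm(v), np.linalg.norm(g)
    if nv == 0.0 or ng == 0.0:
        return float("nan")
    return float(np.arccos(np.clip(v @ g / (nv * ng), -1.0, 1.0)))


def orthogonal_to(x_opt: np.ndarray, seed: int = 0) -> np.ndarray:
    """A reproducible unit vector orthogonal to ``x_opt`` (Gram-Schmidt)."""
    x = np.asarray(x_opt, float).ravel()
    nx = np.linalg.norm(x)
    if nx == 0.0:
        raise ValueError("x_opt must be nonzero")
    xhat = x / nx
    rng = np.random.default_rng(seed)
    while True:
        z = rng.standard_normal(x.size)
        z = z - (z @ xhat) * xhat
        nz = np.linalg.norm(z)
        if nz > 1e-8:
            return z / nz


def optimal_stimulus(pair) -> np.ndarray:
    """Unit input direction maximising the product response: the filter bisector."""
    v, g = _as_pair(pair)
    b = v / np.linalg.norm(v) + g / np.linalg.norm(g)
    nb = np.linalg.norm(b)
    if nb < 1e-12:
        raise ValueError("optimal stimulus undefined for antiparallel filters (gamma = pi)")
    return b / nb


def pair_response(pair, x: np.ndarray, rectify: bool = True) -> np.ndarray:
    """Simplified FP-unit response with unit-normalised filters.

    ``F(x) = ReLU(x . v) * ReLU(x . g)`` (ReLUs dropped if ``rectify`` is
    False).  ``x`` may carry leading batch dimensions.
    """
    v, g = _as_pair(pair)
    v = v / np.linalg.norm(v)
    g = g / np.linalg.norm(g)
    a = np.asarray(x, float) @ v
    b = np.asarray(x, float) @ g
    if rectify:
        a, b = np.maximum(a, 0.0), np.maximum(b, 0.0)
    return a * b


@dataclass
class ContourSample:
    """Points (t, y) of one iso-response contour.

    ``y`` runs along the optimal-stimulus axis, ``t`` along the orthogonal
    axis; every point evaluates to the stored level within grid tolerance.
    """

    level: float
    points: np.ndarray  # (n, 2) columns (t, y)


def iso_response_contour(pair, level: float, t_max: float = 0.5, n_t: int = 201,
                         y_max: float | None = None, n_y: int = 2001,
                         seed: int = 0) -> ContourSample:
    """Numerically extract the level-``level`` contour nearest the optimal axis.

    The response is evaluated on a (t, y) grid in the plane spanned by the
    optimal stimulus and an in-plane orthogonal direction; for each ``t`` the
    smallest ``y > 0`` with response ``level`` is located by linear
    interpolation between grid samples.  Columns never reaching the level
    contribute no point (an empty contour if the level is unreachable).
    """
    if level <= 0:
        raise ValueError("contour level must be positive")
    v, g = _as_pair(pair)
    vh, gh = v / np.linalg.norm(v), g / np.linalg.norm(g)
    x_opt = optimal_stimulus((vh, gh))
    d = vh - gh
    nd = np.linalg.norm(d)
    if nd > 1e-8:
        t_axis = d / nd  # in span(v, g), orthogonal to the bisector
    else:
        t_axis = orthogonal_to(x_opt, seed=seed)
    gamma = gamma_angle((vh, gh))
    if y_max is None:
        y_max = 4.0 * np.sqrt(level) / max(np.cos(gamma / 2.0), 1e-6)
    ts = np.linspace(-t_max, t_max, n_t)
    ys = np.linspace(0.0, y_max, n_y)
    # response on the full grid: x = y * x_opt + t * t_axis
    grid = ys[None, :, None] * x_opt[None, None, :] + ts[:, None, None] * t_axis[None, None, :]
    resp = pair_response((vh, gh), grid)  # (n_t, n_y)
    points = []
    for i, t in enumerate(ts):
        row = resp[i]
        above = np.nonzero(row >= level)[0]
        if above.size == 0 or above[0] == 0:
            continue
        j = above[0]
        y0, y1 = ys[j - 1], ys[j]
        f0, f1 = row[j - 1], row[j]
        y = y0 + (level - f0) * (y1 - y0) / (f1 - f0)
        points.append((t, y))
    return ContourSample(level=level, points=np.asarray(points, dtype=float).reshape(-1, 2))


def curvature_coefficient(contour: ContourSample, window: float | None = None) -> float | None:
    """Quadratic coefficient of a least-squares fit ``y(t) = a t^2 + b t + c0``.

    Fit over ``|t| <= window`` (all points if None).  Returns None when fewer
    than five points span t = 0.
    """
    pts = contour.points
    if window is not None and len(pts):
        pts = pts[np.abs(pts[:, 0]) <= window]
    if len(pts) < 5 or pts[:, 0].min() >= 0 or pts[:, 0].max() <= 0:
        return None
    a, _, _ = np.polyfit(pts[:, 0], pts[:, 1], 2)
    return float(a)


def feature_map_entropy(activations: np.ndarray, bins: int = 32) -> float:
    """Shannon entropy (bits) of min-max-normalised activation samples.

    Values are pooled, scaled to [0, 1] by the sample min/max, and binned
    into ``bins`` equal-width bins; all-equal samples carry 0 bits.  Bounded
    by ``log2(bins)`` and invariant under positive affine rescaling.
    """
    x = np.asarray(activations, float).ravel()
    if x.size == 0:
        raise ValueError("need at least one sample")
    if bins < 2:
        raise ValueError("need at least two bins")
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return 0.0
    counts, _ = np.histogram((x - lo) / (hi - lo), bins=bins, range=(0.0, 1.0))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


@dataclass(frozen=True)
class StimulusResponseSummary:
    """Mean post-ReLU response of one unit over the three stimulus regions."""

    mean_0d: float
    mean_1d: float
    mean_2d: float
    polarity: str


def end_stopping_degree(summary_bright: StimulusResponseSummary,
                        summary_dark: StimulusResponseSummary,
                        zero_threshold: float) -> tuple[float | None, str]:
    """Degree ``1 - 1D/2D`` with ON/OFF pooling and the three-way neuron classes.

    Bright and dark responses are pooled per region by the maximum.  A unit
    with all pooled means at or below ``zero_threshold`` is a
    ``non_responder``; one whose 0D mean exceeds half its 2D mean is a
    ``zero_d_responder``; otherwise the degree (at most 1, and exactly 1
    when the pooled 1D mean is 0) is returned with class
    ``end_stopped_spectrum``.  The degenerate case of edge response without
    corner response is classed ``edge_responder`` with undefined degree.
    """
    m0 = max(summary_bright.mean_0d, summary_dark.mean_0d)
    m1 = max(summary_bright.mean_1d, summary_dark.mean_1d)
    m2 = max(summary_bright.mean_2d, summary_dark.mean_2d)
    if m0 <= zero_threshold and m1 <= zero_threshold and m2 <= zero_threshold:
        return None, "non_responder"
    if m0 > 0.5 * m2:
        return None, "zero_d_responder"
    if m2 <= zero_threshold:
        return None, "edge_responder"
    return 1.0 - m1 / m2, "end_stopped_spectrum"


# ---------------------------------------------------------------------------
# receptive fields and the census

_STEM_LAYERS = {"cifar": [(3, 1)], "imagenet": [(7, 2), (3, 2)], "mbv2": [(3, 2)]}


def _block_layers(kind: str, stride: int, expansion) -> list[tuple[int, int]]:
    if kind in ("basic", "pyramid"):
        return [(3, stride), (3, 1)]
    if kind == "bottleneck":
        return [(1, 1), (3, stride), (1, 1)]
    if kind == "inverted_residual":
        pre = [] if expansion == 1 else [(1, 1)]
        return pre + [(3, stride), (1, 1)]
    if kind == "fp":
        return [(1, 1), (3, stride), (1, 1)]
    raise ValueError(kind)


def receptive_field(spec: ArchitectureSpec, stack: int, block: int) -> tuple[int, int]:
    """(radius, cumulative stride) of the FP-unit responses (T2) of a block.

    Counts the stem, all preceding blocks, and the block's own expansion and
    depthwise stages; the radius is half the receptive-field extent in input
    pixels, the stride maps the T2 grid back onto the image grid.
    """
    layers = list(_STEM_LAYERS[spec.stem])
    for i, st in enumerate(spec.stacks):
        for j, b in enumerate(st):
            if i == stack and j == block:
                layers += [(1, 1), (3, b.stride)]  # expansion + depthwise -> T2
                rf, jump = 1, 1
                for k, s in layers:
                    rf += (k - 1) * jump
                    jump *= s
                return rf // 2, jump
            layers += _block_layers(b.kind, b.stride, b.expansion)
    raise ValueError(f"no block at stack {stack}, block {block}")


@dataclass
class NeuronReport:
    """Everything measured about one FP-unit."""

    stack: int
    block: int
    map_index: int
    gamma: float
    curvature: float | None
    entropy: float
    endstop_degree: float | None
    endstop_class: str
    depth: int              # convolution layers up to and including this unit's block
    mean_0d: float
    mean_1d: float
    mean_2d: float
    rf_radius: int
    grid_stride: int


def _collect_t2(net: Network, images: np.ndarray, batch: int = 64) -> dict[tuple[int, int], np.ndarray]:
    """T2 tensors of every FP-block over an image batch, keyed (stack, block)."""
    blocks = net.fp_blocks()
    for _, _, layer in blocks:
        layer.capture = True
    chunks: dict[tuple[int, int], list[np.ndarray]] = {(i, j): [] for i, j, _ in blocks}
    for k in range(0, len(images), batch):
        net.forward(images[k:k + batch], train=False)
        for i, j, layer in blocks:
            chunks[(i, j)].append(layer.last_t2)
    for _, _, layer in blocks:
        layer.capture = False
        layer.last_t2 = None
    return {key: np.concatenate(parts, axis=0) for key, parts in chunks.items()}


def _region_means(t2_map: np.ndarray, stim: SquareStimulus, stride: int) -> tuple[float, float, float]:
    """Mask means of one unit's response map on the layer grid."""
    means = []
    for key in ("0d", "1d", "2d"):
        m = stim.masks[key][::stride, ::stride]
        h = min(m.shape[0], t2_map.shape[0])
        w = min(m.shape[1], t2_map.shape[1])
        m, t = m[:h, :w], t2_map[:h, :w]
        means.append(float(t[m].mean()) if m.any() else 0.0)
    return tuple(means)


def neuron_census(net: Network, images: np.ndarray,
                  bins: int = 32, contour_level: float = 0.25,
                  zero_threshold_frac: float = ZERO_THRESHOLD_FRAC,
                  with_curvature: bool = True) -> list[NeuronReport]:
    """One :class:`NeuronReport` per FP-unit of the network.

    ``images`` is the natural-image batch for the entropy estimate (>= 256
    recommended).  End-stopping is probed with bright and dark centred
    squares occupying half the input side; each block's masks use its own
    receptive-field radius, clamped so the stimulus geometry stays valid,
    and are downsampled to the block's grid by its cumulative stride.
    Deterministic given the network weights and image batch.
    """
    spec = net.spec
    blocks = net.fp_blocks()
    if not blocks:
        return []
    depths = fp_neuron_depths(spec)
    t2_nat = _collect_t2(net, images)

    side = spec.input_size[0]
    square = side // 2
    reports: list[NeuronReport] = []
    for (i, j, layer), depth in zip(blocks, depths):
        radius, stride = receptive_field(spec, i, j)
        radius = min(radius, (square - 1) // 2)  # keep the 0D region nonempty
        stims = {p: make_square_stimulus(side, square, p, radius) for p in ("bright", "dark")}
        t2_stim = {}
        layer.capture = True
        for p, stim in stims.items():
            net.forward(stim.to_batch(spec.input_size[2]), train=False)
            t2_stim[p] = layer.last_t2[0]  # (e, h, w)
        layer.capture = False
        layer.last_t2 = None
        block_max = max(float(t2_stim[p].max()) for p in stims)
        thr = zero_threshold_frac * block_max
        nat = t2_nat[(i, j)]  # (n, e, h, w)
        for m in range(layer.n_pairs):
            pair = (layer.filters_v[m].ravel(), layer.filters_g[m].ravel())
            gamma = gamma_angle(pair)
            curvature = None
            if with_curvature and np.isfinite(gamma) and gamma < np.pi - 1e-6:
                contour = iso_response_contour(pair, contour_level, t_max=0.12, n_t=61)
                curvature = curvature_coefficient(contour, window=0.1)
            entropy = feature_map_entropy(nat[:, m], bins=bins)
            summaries = {}
            for p in ("bright", "dark"):
                m0, m1, m2 = _region_means(t2_stim[p][m], stims[p], stride)
                summaries[p] = StimulusResponseSummary(m0, m1, m2, p)
            degree, cls = end_stopping_degree(summaries["bright"], summaries["dark"], thr)
            pooled = [max(summaries["bright"].mean_0d, summaries["dark"].mean_0d),
                      max(summaries["bright"].mean_1d, summaries["dark"].mean_1d),
                      max(summaries["bright"].mean_2d, summaries["dark"].mean_2d)]
            reports.append(NeuronReport(
                stack=i, block=j, map_index=m, gamma=gamma, curvature=curvature,
                entropy=entropy, endstop_degree=degree, endstop_class=cls,
                depth=depth, mean_0d=pooled[0], mean_1d=pooled[1], mean_2d=pooled[2],
                rf_radius=radius, grid_stride=stride))
    return reports


def census_frame(reports: list[NeuronReport]):
    """The census as a pandas DataFrame (one row per FP-unit)."""
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in reports])
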