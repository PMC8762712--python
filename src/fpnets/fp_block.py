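"""The feature-product (FP) block as composable array operations.

An FP-unit models an end-stopped visual neuron: it multiplies the rectified,
instance-normalised outputs of two learned 3x3 filters applied to the same
feature map, implementing an AND-combination of two features (for example,
"horizontal edge AND vertical edge" responds to corners).  The FP-block wraps
a bank of such units between two pointwise (1x1) linear combinations and an
optional residual connection:

    T0 (h, w, d_in)
      -> 1x1 combination + ReLU              -> T1 (h, w, e),  e = round(q * d_out)
      -> per map m: correlate with V_m, G_m (stride s), standardise each
         result by its own spatial mean/std, rectify, multiply
                                             -> T2 (h/s, w/s, e)
      -> 1x1 combination                     -> T3 (h/s, w/s, d_out)
      -> + T0 (identity residual, only when shapes match)  -> Tout

All feature tensors here follow the ``[row, column, map]`` axis convention.
Convolution is cross-correlation with same-padding (pad 1 for the 3x3
kernels); the stride is applied in the depthwise stage.  The normalising
standard deviation is stabilised as ``sigma + SIGMA_EPS`` so constant maps
never divide by zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: Stabiliser added to the instance standard deviation before dividing.
SIGMA_EPS = 1e-5


@dataclass(frozen=True)
class FPBlockConfig:
    """Shape configuration of one FP-block.

    ``q`` is the expansion factor controlling the number of internal filter
    pairs, ``round(q * d_out)``; ``stride`` subsamples in the depthwise
    stage; the kernel size is fixed at 3 (larger kernels bring nothing).
    """

    d_in: int
    d_out: int
    q: float = 1.0
    stride: int = 1
    kernel: int = 3

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if self.kernel != 3:
            raise ValueError("only 3x3 kernels are supported")
        if self.n_pairs < 1:
            raise ValueError("round(q * d_out) must be >= 1")

    @property
    def n_pairs(self) -> int:
        """Number of filter pairs / FP-units in the block."""
        return int(round(self.q * self.d_out))


@dataclass
class FPBlockParams:
    """All learned weights of one FP-block.

    ``expansion``:  (n_pairs, d_in) pointwise combination weights.
    ``filters_v`` / ``filters_g``:  (n_pairs, k, k) depthwise filter pairs.
    ``projection``: (d_out, n_pairs) pointwise projection weights.
    """

    expansion: np.ndarray
    filters_v: np.ndarray
    filters_g: np.ndarray
    projection: np.ndarray
    config: FPBlockConfig = field(default=None)  # type: ignore[assignment]

    def filter_pair(self, m: int) -> "FilterPairVec":
        """Vectorised filter pair of unit ``m``."""
        return FilterPairVec(self.filters_v[m].ravel().copy(),
                             self.filters_g[m].ravel().copy())


@dataclass(frozen=True)
class NormStats:
    """Spatial mean and standard deviation of one filtered feature map."""

    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class FilterPairVec:
    """A vectorised filter pair (v, g), each of length k^2."""

    v: np.ndarray
    g: np.ndarray

    def __post_init__(self):
        if np.shape(self.v) != np.shape(self.g):
            raise ValueError("v and g must have equal length")


def _check_tensor(t: np.ndarray, name: str = "tensor") -> np.ndarray:
    t = np.asarray(t)
    if t.ndim != 3:
        raise ValueError(f"{name} must be 3-D [row, column, map], got shape {t.shape}")
    if not np.all(np.isfinite(t)):
        raise ValueError(f"{name} contains non-finite entries")
    return t


def pointwise_combine(t0: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Linearly combine the input maps at each pixel and rectify.

    Equivalent to a 1x1 convolution with weight matrix ``weights`` of shape
    ``(m_out, d_in)`` followed by a ReLU.
    """
    t0 = _check_tensor(t0, "T0")
    weights = np.asarray(weights)
    if weights.ndim != 2 or weights.shape[1] != t0.shape[2]:
        raise ValueError(
            f"weights shape {weights.shape} incompatible with input depth {t0.shape[2]}")
    return np.maximum(t0 @ weights.T, 0.0)


def depthwise_filter(fmap: np.ndarray, filt: np.ndarray, stride: int = 1) -> np.ndarray:
    """Correlate a single feature map with a k x k filter, same-padding.

    Output spatial size is ``(ceil(h / stride), ceil(w / stride))``; with
    stride 1 an interior output pixel is the inner product of the filter with
    the patch centred on it.
    """
    fmap = np.asarray(fmap)
    filt = np.asarray(filt)
    if fmap.ndim != 2 or filt.ndim != 2 or filt.shape[0] != filt.shape[1]:
        raise ValueError("expected a 2-D map and a square 2-D filter")
    k = filt.shape[0]
    p = (k - 1) // 2
    xp = np.pad(fmap, p)
    cols = sliding_window_view(xp, (k, k))[::stride, ::stride]
    return np.einsum("ijuv,uv->ij", cols, filt, optimize=True)


def instance_stats(filtered: np.ndarray) -> NormStats:
    """Spatial mean and standard deviation of an (already strided) map.

    The mean over the subsampled grid equals the ``s^2 / (h w)``-normalised
    sum over the retained positions.
    """
    filtered = np.asarray(filtered)
    return NormStats(mu=float(filtered.mean()), sigma=float(filtered.std()))


def feature_product(rv: np.ndarray, rg: np.ndarray, sv: NormStats, sg: NormStats,
                    eps: float = SIGMA_EPS) -> np.ndarray:
    """The FP-unit response map: product of two centred, rectified responses.

    ``out = ReLU(rv - mu_v) * ReLU(rg - mu_g) / ((sigma_v + eps)(sigma_g + eps))``,
    elementwise and everywhere >= 0.
    """
    rv, rg = np.asarray(rv), np.asarray(rg)
    if rv.shape != rg.shape:
        raise ValueError("the two filtered maps must have equal shape")
    num = np.maximum(rv - sv.mu, 0.0) * np.maximum(rg - sg.mu, 0.0)
    return num / ((sv.sigma + eps) * (sg.sigma + eps))


def project_and_residual(t2: np.ndarray, projection: np.ndarray, t0: np.ndarray,
                         shortcut=None) -> np.ndarray:
    """Pointwise projection of T2 followed by the residual connection.

    ``shortcut`` controls the skip path when T0 and T3 shapes differ:
    ``None`` uses the identity when shapes match and raises otherwise;
    ``False`` omits the residual (the convention of the strided /
    width-changing blocks in the host networks); a callable is applied to T0.
    """
    t2 = _check_tensor(t2, "T2")
    t0 = _check_tensor(t0, "T0")
    projection = np.asarray(projection)
    if projection.ndim != 2 or projection.shape[1] != t2.shape[2]:
        raise ValueError(
            f"projection shape {projection.shape} incompatible with T2 depth {t2.shape[2]}")
    t3 = t2 @ projection.T
    if shortcut is False:
        return t3
    if shortcut is None:
        if t0.shape != t3.shape:
            raise ValueError(
                f"residual shapes differ ({t0.shape} vs {t3.shape}) and no shortcut configured")
        return t0 + t3
    return shortcut(t0) + t3


def fp_block_forward(t0: np.ndarray, params: FPBlockParams,
                     config: FPBlockConfig) -> np.ndarray:
    """Full FP-block forward pass, the exact composition of the operations above.

    The residual is the identity when input and output shapes match and is
    omitted otherwise (stride 2 or ``d_in != d_out``).
    """
    t0 = _check_tensor(t0, "T0")
    if t0.shape[2] != config.d_in:
        raise ValueError(f"T0 depth {t0.shape[2]} != configured d_in {config.d_in}")
    t1 = pointwise_combine(t0, params.expansion)
    maps = []
    for m in range(config.n_pairs):
        rv = depthwise_filter(t1[:, :, m], params.filters_v[m], stride=config.stride)
        rg = depthwise_filter(t1[:, :, m], params.filters_g[m], stride=config.stride)
        maps.append(feature_product(rv, rg, instance_stats(rv), instance_stats(rg)))
    t2 = np.stack(maps, axis=2)
    matches = (config.stride == 1 and config.d_in == config.d_out)
    return project_and_residual(t2, params.projection, t0,
                                shortcut=None if matches else False)


def init_fp_block(config: FPBlockConfig, seed: int) -> FPBlockParams:
    """Reproducible He-style initialisation of all FP-block weights."""
    rng = np.random.default_rng(seed)
    e, k = config.n_pairs, config.kernel
    expansion = rng.standard_normal((e, config.d_in)) * np.sqrt(2.0 / config.d_in)
    filters_v = rng.standard_normal((e, k, k)) * np.sqrt(2.0 / (k * k))
    filters_g = rng.standard_normal((e, k, k)) * np.sqrt(2.0 / (k * k))
    projection = rng.standard_normal((config.d_out, e)) * np.sqrt(1.0 / e)
    return FPBlockParams(expansion, filters_v, filters_g, projection, config)


def num_parameters(config: FPBlockConfig) -> int:
    """Trainable scalar count of one FP-block (no bias, no norm parameters)."""
    e, k = config.n_pairs, config.kernel
    return e * config.d_in + 2 * e * k * k + config.d_out * e


def save_fp_block(path, params: FPBlockParams) -> None:
    """Write FP-block parameters to an ``.npz`` checkpoint (round-trip exact)."""
    c = params.config
    np.savez(path, expansion=params.expansion, filters_v=params.filters_v,
             filters_g=params.filters_g, projection=params.projection,
             config=np.array([c.d_in, c.d_out, c.q, c.stride, c.kernel]))


def load_fp_block(path) -> FPBlockParams:
    with np.load(path) as z:
        d_in, d_out, q, stride, kernel = z["config"]
        config = FPBlockConfig(int(d_in), int(d_out), float(q), int(stride), int(kernel))
        return FPBlockParams(z["expansion"], z["filters_v"], z["filters_g"],
                             z["projection"], config)
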