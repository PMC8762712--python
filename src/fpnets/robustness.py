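"""Adversarial and compression robustness: FGSM, CIGA, changed predictions, JPEG.

Two attacks under an infinity-norm budget ``epsilon`` (image-intensity
units, e.g. 1/255):

* FGSM adds ``epsilon * sign(gradient)`` in one step — optimal for a linear
  scorer, where even a tiny ``epsilon`` moves the output by roughly
  ``epsilon * n * mean|w|``;
* CIGA (clipped iterative gradient ascent) takes repeated gradient steps of
  size ``tau`` and clips the accumulated perturbation to the epsilon box
  after every step.  On a hyperselective product unit its path must first
  curve onto the optimal-stimulus line, which is why such units need far
  more iterations than an LN-unit to approach the box optimum.

Robustness across classifiers is compared by the fraction of *changed*
predictions under a perturbation, which accuracy differences cannot
confound.  JPEG test sets recompress each image at quality ``Q``; quality
100 denotes the original image itself.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .architectures import Network

__all__ = [
    "AttackConfig", "LNNeuronToy", "FPNeuronToy", "toy_fp_response_and_gradient",
    "fgsm_attack", "CIGAResult", "ciga_attack", "steps_to_value",
    "changed_predictions", "jpeg_testset", "jpeg_codec_info",
]


@dataclass(frozen=True)
class AttackConfig:
    """Attack budget: epsilon box, step size, iterations, attack kind."""

    epsilon: float
    tau: float | None = None
    iterations: int = 1
    kind: str = "fgsm"

    def __post_init__(self):
        if self.kind not in ("fgsm", "ciga"):
            raise ValueError("kind must be 'fgsm' or 'ciga'")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.kind == "ciga":
            if self.tau is None or self.tau <= 0:
                raise ValueError("ciga needs a positive step size tau")
            if self.iterations < 1:
                raise ValueError("ciga needs at least one iteration")


@dataclass(frozen=True)
class LNNeuronToy:
    """Linear-nonlinear toy neuron ``f(x) = rho(w . x)`` (identity rho here)."""

    w: np.ndarray

    def response_and_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        w = np.asarray(self.w, float)
        return float(w @ np.asarray(x, float)), w.copy()

    def __call__(self, x):
        return self.response_and_gradient(x)


@dataclass(frozen=True)
class FPNeuronToy:
    """Simplified feature-product neuron ``F(x) = (x . v)(g . x)``.

    The gradient is ``(v . x) g + (g . x) v``; the ReLUs are dropped, which
    is exact whenever both projections are non-negative.
    """

    v: np.ndarray
    g: np.ndarray

    def response_and_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        v, g = np.asarray(self.v, float), np.asarray(self.g, float)
        x = np.asarray(x, float)
        a, b = float(v @ x), float(g @ x)
        return a * b, a * g + b * v

    def __call__(self, x):
        return self.response_and_gradient(x)


def toy_fp_response_and_gradient(neuron: FPNeuronToy, x: np.ndarray) -> tuple[float, np.ndarray]:
    """Value and gradient of the simplified FP-neuron at ``x``."""
    return neuron.response_and_gradient(x)


def fgsm_attack(model, x: np.ndarray, y=None, epsilon: float = 1 / 255,
                clip_range: tuple[float, float] | None = None) -> np.ndarray:
    """One-step fast-gradient-sign perturbation of ``x``.

    ``model`` is either a :class:`~fpnets.architectures.Network` — the
    gradient is then taken on the cross-entropy classification loss with the
    true labels ``y`` — or any callable ``x -> (value, gradient)`` for the
    single-neuron illustrative mode.  The output differs from ``x`` by at
    most ``epsilon`` per entry; optional clipping to a valid intensity range
    is off by default.
    """
    x = np.asarray(x, float)
    if isinstance(model, Network):
        if y is None:
            raise ValueError("attacking a network needs the true labels")
        grad = model.input_gradient(x, np.asarray(y))
    else:
        _, grad = model(x)
    out = x + epsilon * np.sign(grad)
    if clip_range is not None:
        out = np.clip(out, *clip_range)
    return out


@dataclass
class CIGAResult:
    """Final perturbation plus the logged iteration path and values."""

    eta: np.ndarray
    path: np.ndarray = field(repr=False)    # (iterations + 1, n) of eta iterates
    values: np.ndarray = field(repr=False)  # f(x + eta_i), same length as path


def ciga_attack(fn, x: np.ndarray, config: AttackConfig) -> CIGAResult:
    """Clipped iterative gradient ascent on a differentiable scalar function.

    ``fn(x) -> (value, gradient)``.  Starting from ``eta = 0``, each step
    adds ``tau * gradient(x + eta)`` and clips every coordinate of the
    accumulated perturbation to ``[-epsilon, epsilon]``; the box constraint
    is asserted after every iterate.
    """
    if config.kind != "ciga":
        raise ValueError("config.kind must be 'ciga'")
    x = np.asarray(x, float)
    eps, tau = config.epsilon, config.tau
    eta = np.zeros_like(x)
    path = [eta.copy()]
    values = [fn(x)[0]]
    for i in range(config.iterations):
        _, grad = fn(x + eta)
        if not np.all(np.isfinite(grad)):
            raise RuntimeError(f"non-finite gradient at CIGA iteration {i}")
        eta = np.clip(eta + tau * grad, -eps, eps)
        assert np.max(np.abs(eta)) <= eps + 1e-12
        path.append(eta.copy())
        values.append(fn(x + eta)[0])
    return CIGAResult(eta=eta, path=np.asarray(path), values=np.asarray(values))


def steps_to_value(fn, x: np.ndarray, config: AttackConfig, target: float) -> int | None:
    """First CIGA iteration whose value reaches ``target`` (None if never)."""
    result = ciga_attack(fn, x, config)
    hits = np.nonzero(result.values >= target)[0]
    return int(hits[0]) if hits.size else None


def changed_predictions(f, gamma_fn, inputs: np.ndarray, batch: int = 256) -> float:
    """Fraction of inputs whose predicted class changes under a perturbation.

    ``f`` is a classifier (a :class:`Network` or a callable mapping an image
    batch to integer labels) and ``gamma_fn`` maps an image batch to its
    perturbed version.  Invariant to input ordering.
    """
    inputs = np.asarray(inputs)
    if len(inputs) == 0:
        raise ValueError("inputs must be nonempty")
    predict = f.predict if isinstance(f, Network) else f
    changed = 0
    for k in range(0, len(inputs), batch):
        chunk = inputs[k:k + batch]
        changed += int((predict(chunk) != predict(gamma_fn(chunk))).sum())
    return changed / len(inputs)


def jpeg_codec_info(quality: int) -> dict:
    """Identity of the JPEG codec used (quantisation tables vary by encoder)."""
    import PIL

    return {"codec": "Pillow baseline JPEG", "library_version": PIL.__version__,
            "quality": int(quality), "identity_at_100": True}


def jpeg_testset(images: np.ndarray, quality: int) -> np.ndarray:
    """JPEG encode/decode round trip of an image batch at the given quality.

    ``images`` is ``(n, h, w, 3)`` float in [0, 1] (or uint8).  Quality 100
    denotes the original images and short-circuits to an exact copy;
    dimensions are always preserved.
    """
    from PIL import Image

    if not 1 <= quality <= 100:
        raise ValueError("quality must be in 1..100")
    images = np.asarray(images)
    if images.ndim != 4 or images.shape[3] != 3:
        raise ValueError("expected an (n, h, w, 3) image batch")
    if quality == 100:
        return images.copy()
    was_float = np.issubdtype(images.dtype, np.floating)
    out = np.empty_like(images)
    for i, img in enumerate(images):
        arr = (np.clip(img, 0, 1) * 255).round().astype(np.uint8) if was_float else img
        buf = io.BytesIO()
        Image.fromarray(arr, mode="RGB").save(buf, format="JPEG", quality=int(quality))
        buf.seek(0)
        dec = np.asarray(Image.open(buf).convert("RGB"))
        out[i] = dec.astype(images.dtype) / 255.0 if was_float else dec
    return out
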