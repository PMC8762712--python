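"""Architecture specifications, builders, the FP design rule, and networks.

A network is described by an :class:`ArchitectureSpec`: a stem, an ordered
list of *stacks* (segments that process one spatial scale; every stack after
the first is entered through a stride-2 block), and a classification head.
The FP transform ``fp_transform(spec, q)`` substitutes each stack's first
block with an FP-block of identical input/output dimensions and stride —
the rule that turns a ResNet or MobileNet into an FP-net.

Builders cover the four baseline families:

* ``build_resnet_cifar(N)`` — 3 stacks of N basic blocks, widths 16/32/64,
  32x32x3 input, 10 classes (ResNet-20/32/44/56 for N = 3/5/7/9);
* ``build_pyrblocknet(N)`` — same layout with pyramid blocks;
* ``build_resnet50()`` — 4 stacks of 3/4/6/3 bottlenecks, ImageNet head;
* ``build_mobilenet_v2()`` — six stacks of inverted-residual blocks.

``count_parameters`` reproduces the published totals (ResNet-50 25.6 M,
MobileNet-V2 3.5 M) and certifies the FP-block arithmetic (FP-net-50 at
q=1: 26.0 M, q=0.8: 24.3 M, FP-MobileNet at q=3: 3.5 M).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .blocks import (BasicBlock, BottleneckBlock, FPBlockLayer,
                     InvertedResidualBlock, PyramidBlock)

__all__ = [
    "BlockSpec", "ArchitectureSpec",
    "build_resnet_cifar", "build_pyrblocknet", "build_resnet50",
    "build_mobilenet_v2", "fp_transform", "count_parameters",
    "Network", "forward", "fp_neuron_depths",
]

BLOCK_KINDS = ("basic", "pyramid", "bottleneck", "inverted_residual", "fp")

#: convolution layers contributed by one block of each kind
_CONV_LAYERS = {"basic": 2, "pyramid": 2, "bottleneck": 3, "fp": 3}


@dataclass(frozen=True)
class BlockSpec:
    """One block: kind, widths, stride and (for fp / inverted residual) expansion."""

    kind: str
    d_in: int
    d_out: int
    stride: int = 1
    expansion: float | None = None  # q for fp, t for inverted_residual
    mid: int | None = None          # bottleneck middle width

    def __post_init__(self):
        if self.kind not in BLOCK_KINDS:
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")

    @property
    def conv_layers(self) -> int:
        if self.kind == "inverted_residual":
            return 2 if self.expansion == 1 else 3
        return _CONV_LAYERS[self.kind]


@dataclass
class ArchitectureSpec:
    name: str
    family: str                      # resnet_cifar | pyrblocknet | resnet50 | mobilenet_v2
    input_size: tuple[int, int, int]  # (h, w, channels)
    num_classes: int
    stem: str                        # cifar | imagenet | mbv2
    stacks: list[list[BlockSpec]] = field(default_factory=list)
    head: str = "avgpool_fc"         # avgpool_fc | mbv2
    fp_q: float | None = None

    @property
    def blocks(self) -> list[BlockSpec]:
        return [b for stack in self.stacks for b in stack]

    @property
    def depth(self) -> int:
        """Number of convolution + linear layers (the ResNet naming count)."""
        stem_convs = 1
        head_linears = 1
        return stem_convs + sum(b.conv_layers for b in self.blocks) + head_linears


def _cifar_stacks(n: int, kind: str) -> list[list[BlockSpec]]:
    if n < 1:
        raise ValueError("need at least one block per stack")
    widths = [16, 32, 64]
    stacks = []
    d_in = 16
    for i, w in enumerate(widths):
        stack = []
        for j in range(n):
            stride = 2 if (i > 0 and j == 0) else 1
            stack.append(BlockSpec(kind, d_in, w, stride))
            d_in = w
        stacks.append(stack)
    return stacks


def build_resnet_cifar(n: int = 5) -> ArchitectureSpec:
    """ResNet-(6N+2) for Cifar-10: three stacks of N basic blocks."""
    return ArchitectureSpec(name=f"ResNet-{6 * n + 2}", family="resnet_cifar",
                            input_size=(32, 32, 3), num_classes=10, stem="cifar",
                            stacks=_cifar_stacks(n, "basic"))


def build_pyrblocknet(n: int = 5) -> ArchitectureSpec:
    """PyrBlockNet-(6N+2): the Cifar ResNet layout with pyramid blocks."""
    return ArchitectureSpec(name=f"PyrBlockNet-{6 * n + 2}", family="pyrblocknet",
                            input_size=(32, 32, 3), num_classes=10, stem="cifar",
                            stacks=_cifar_stacks(n, "pyramid"))


def build_resnet50() -> ArchitectureSpec:
    """Canonical ResNet-50: 4 stacks of 3/4/6/3 bottleneck blocks."""
    layout = [(64, 256, 3, 1), (256, 512, 4, 2), (512, 1024, 6, 2), (1024, 2048, 3, 2)]
    stacks = []
    for d_in, d_out, n, s in layout:
        stack = [BlockSpec("bottleneck", d_in, d_out, s, mid=d_out // 4)]
        stack += [BlockSpec("bottleneck", d_out, d_out, 1, mid=d_out // 4)
                  for _ in range(n - 1)]
        stacks.append(stack)
    return ArchitectureSpec(name="ResNet-50", family="resnet50",
                            input_size=(224, 224, 3), num_classes=1000,
                            stem="imagenet", stacks=stacks)


def build_mobilenet_v2() -> ArchitectureSpec:
    """Canonical MobileNet-V2 (width 1.0) grouped into six stacks.

    The inverted-residual schedule (t, c, n, s) = (1,16,1,1), (6,24,2,2),
    (6,32,3,2), (6,64,4,2), (6,96,3,1), (6,160,3,2), (6,320,1,1) is grouped
    by spatial scale into six stacks; the 96-wide stage continues the
    64-wide stack at 14x14, and the final width expansion to 320 forms its
    own (stride-1) stack.
    """
    schedule = [  # list of stacks, each a list of (t, d_out, stride)
        [(1, 16, 1)],
        [(6, 24, 2), (6, 24, 1)],
        [(6, 32, 2), (6, 32, 1), (6, 32, 1)],
        [(6, 64, 2), (6, 64, 1), (6, 64, 1), (6, 64, 1),
         (6, 96, 1), (6, 96, 1), (6, 96, 1)],
        [(6, 160, 2), (6, 160, 1), (6, 160, 1)],
        [(6, 320, 1)],
    ]
    stacks = []
    d_in = 32
    for group in schedule:
        stack = []
        for t, d_out, s in group:
            stack.append(BlockSpec("inverted_residual", d_in, d_out, s, expansion=t))
            d_in = d_out
        stacks.append(stack)
    return ArchitectureSpec(name="MobileNet-V2", family="mobilenet_v2",
                            input_size=(224, 224, 3), num_classes=1000,
                            stem="mbv2", stacks=stacks, head="mbv2")


_FP_NAMES = {"resnet50": "FP-net-50", "mobilenet_v2": "FP-MobileNet"}


def fp_transform(spec: ArchitectureSpec, q: float = 1.0) -> ArchitectureSpec:
    """Apply the FP design rule: replace each stack's first block by an FP-block.

    Input/output widths and stride of the replaced block are preserved; all
    other blocks are untouched.  Cifar-family names follow the convention
    that each FP-block adds one convolution layer (e.g. PyrBlockNet-20 with
    three stacks becomes FP-net-23).
    """
    out = copy.deepcopy(spec)
    for stack in out.stacks:
        b = stack[0]
        stack[0] = BlockSpec("fp", b.d_in, b.d_out, b.stride, expansion=q)
    if spec.family in _FP_NAMES:
        out.name = _FP_NAMES[spec.family]
    elif spec.family == "pyrblocknet":
        out.name = f"FP-net-{out.depth}"
    elif spec.family == "resnet_cifar":
        out.name = f"FP-net-basic-{out.depth}"
    else:
        out.name = "FP-" + spec.name
    out.fp_q = q
    return out


def fp_neuron_depths(spec: ArchitectureSpec) -> list[int]:
    """Convolution-layer depth of each FP-block's units (T2).

    Counts the stem convolution, every convolution of the preceding blocks,
    and the FP-block's own 1x1 expansion.  For the FP-net-50 this yields
    2, 11, 23 and 41; for the FP-net-59, 2, 21 and 40.
    """
    depths = []
    count = 1  # stem convolution
    for block in spec.blocks:
        if block.kind == "fp":
            depths.append(count + 1)
        count += block.conv_layers
    return depths


# ---------------------------------------------------------------------------
# instantiation


def _make_block(b: BlockSpec, rng, dtype):
    if b.kind == "basic":
        return BasicBlock(b.d_in, b.d_out, b.stride, rng=rng, dtype=dtype)
    if b.kind == "pyramid":
        return PyramidBlock(b.d_in, b.d_out, b.stride, rng=rng, dtype=dtype)
    if b.kind == "bottleneck":
        return BottleneckBlock(b.d_in, b.d_out, b.stride, mid=b.mid, rng=rng, dtype=dtype)
    if b.kind == "inverted_residual":
        return InvertedResidualBlock(b.d_in, b.d_out, b.stride, t=int(b.expansion), rng=rng, dtype=dtype)
    if b.kind == "fp":
        return FPBlockLayer(b.d_in, b.d_out, b.stride, q=b.expansion, rng=rng, dtype=dtype)
    raise ValueError(b.kind)


class Network(nn.Layer):
    """An instantiated architecture: stem, stacks of blocks, head.

    Public image batches follow the ``[image, row, column, map]`` layout and
    are transposed to NCHW internally.  Construction is deterministic given
    ``seed``.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        c_img = spec.input_size[2]
        if spec.stem == "cifar":
            self.stem = nn.Sequential(nn.Conv2d(c_img, 16, 3, 1, rng=rng, dtype=dtype),
                                      nn.BatchNorm2d(16, dtype=dtype), nn.ReLU())
        elif spec.stem == "imagenet":
            self.stem = nn.Sequential(nn.Conv2d(c_img, 64, 7, 2, pad=3, rng=rng, dtype=dtype),
                                      nn.BatchNorm2d(64, dtype=dtype), nn.ReLU(),
                                      nn.MaxPool2d(3, 2, 1))
        elif spec.stem == "mbv2":
            self.stem = nn.Sequential(nn.Conv2d(c_img, 32, 3, 2, rng=rng, dtype=dtype),
                                      nn.BatchNorm2d(32, dtype=dtype), nn.ReLU6())
        else:
            raise ValueError(spec.stem)
        self.stack_layers = [[_make_block(b, rng, dtype) for b in stack]
                             for stack in spec.stacks]
        last = spec.blocks[-1].d_out
        if spec.head == "mbv2":
            self.head_conv = nn.Sequential(nn.Conv2d(last, 1280, 1, 1, pad=0, rng=rng, dtype=dtype),
                                           nn.BatchNorm2d(1280, dtype=dtype), nn.ReLU6())
            last = 1280
        else:
            self.head_conv = None
        self.pool = nn.GlobalAvgPool()
        self.fc = nn.Linear(last, spec.num_classes, bias=True, rng=rng, dtype=dtype)
        self.loss_fn = nn.SoftmaxCrossEntropy()

    # -- structure ---------------------------------------------------------
    def params(self):
        out = self.stem.params()
        for stack in self.stack_layers:
            for block in stack:
                out.extend(block.params())
        if self.head_conv is not None:
            out.extend(self.head_conv.params())
        out.extend(self.fc.params())
        return out

    def fp_blocks(self) -> list[tuple[int, int, FPBlockLayer]]:
        """All FP-block layers as (stack index, block index, layer)."""
        found = []
        for i, stack in enumerate(self.stack_layers):
            for j, block in enumerate(stack):
                if isinstance(block, FPBlockLayer):
                    found.append((i, j, block))
        return found

    # -- passes ------------------------------------------------------------
    def _to_nchw(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=self.dtype)
        if x.ndim != 4:
            raise ValueError("expected a batch [image, row, column, map]")
        if np.isnan(x).any():
            raise ValueError("input contains NaN")
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def forward(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        """Class scores (logits), one row per image."""
        x = self._to_nchw(images)
        x = self.stem.forward(x, train=train)
        for stack in self.stack_layers:
            for block in stack:
                x = block.forward(x, train=train)
        if self.head_conv is not None:
            x = self.head_conv.forward(x, train=train)
        return self.fc.forward(self.pool.forward(x, train=train), train=train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backpropagate to the input; returns d(images) in [i, row, col, map]."""
        dx = self.pool.backward(self.fc.backward(dlogits))
        if self.head_conv is not None:
            dx = self.head_conv.backward(dx)
        for stack in reversed(self.stack_layers):
            for block in reversed(stack):
                dx = block.backward(dx)
        dx = self.stem.backward(dx)
        return dx.transpose(0, 2, 3, 1)

    def loss(self, images: np.ndarray, labels: np.ndarray, train: bool = False) -> float:
        return self.loss_fn.forward(self.forward(images, train=train), np.asarray(labels))

    def loss_backward(self) -> np.ndarray:
        return self.backward(self.loss_fn.backward())

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.forward(images, train=False).argmax(axis=1)

    def input_gradient(self, images: np.ndarray, labels: np.ndarray) -> np.ndarray:
        """Gradient of the mean cross-entropy loss with respect to the images."""
        self.loss(images, labels, train=False)
        return self.loss_backward()

    # -- serialization -----------------------------------------------------
    def _state_arrays(self):
        arrays = [p.value for p in self.params()]
        for layer in self._all_layers():
            if isinstance(layer, nn.BatchNorm2d):
                arrays += [layer.running_mean, layer.running_var]
        return arrays

    def _all_layers(self):
        def walk(layer):
            yield layer
            for v in layer.__dict__.values():
                if isinstance(v, nn.Layer):
                    yield from walk(v)
                elif isinstance(v, (list, tuple)):
                    for item in v:
                        if isinstance(item, nn.Layer):
                            yield from walk(item)
        yield from walk(self.stem)
        for stack in self.stack_layers:
            for block in stack:
                yield from walk(block)
        if self.head_conv is not None:
            yield from walk(self.head_conv)
        yield from walk(self.fc)

    def save(self, path) -> None:
        """Checkpoint to ``.npz`` plus an embedded JSON architecture record."""
        arrays = {f"a{i}": a for i, a in enumerate(self._state_arrays())}
        meta = json.dumps({"name": self.spec.name, "family": self.spec.family,
                           "fp_q": self.spec.fp_q,
                           "stacks": [[b.__dict__ for b in s] for s in self.spec.stacks],
                           "input_size": self.spec.input_size,
                           "num_classes": self.spec.num_classes,
                           "stem": self.spec.stem, "head": self.spec.head})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "Network":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            spec = ArchitectureSpec(
                name=meta["name"], family=meta["family"],
                input_size=tuple(meta["input_size"]), num_classes=meta["num_classes"],
                stem=meta["stem"], head=meta["head"], fp_q=meta["fp_q"],
                stacks=[[BlockSpec(**b) for b in s] for s in meta["stacks"]])
            net = cls(spec, seed=0)
            arrays = [z[f"a{i}"] for i in range(len(z.files) - 1)]
        targets = net._state_arrays()
        if len(arrays) != len(targets):
            raise ValueError("checkpoint does not match architecture")
        k = 0
        for p in net.params():
            p.value = arrays[k].copy()
            p.grad = np.zeros_like(p.value)
            k += 1
        for layer in net._all_layers():
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean = arrays[k].copy(); k += 1
                layer.running_var = arrays[k].copy(); k += 1
        return net


def count_parameters(arch: ArchitectureSpec | Network) -> int:
    """Total number of trainable scalars (seed-independent)."""
    net = arch if isinstance(arch, Network) else Network(arch, seed=0)
    return sum(p.size for p in net.params())


def forward(arch: ArchitectureSpec | Network, images: np.ndarray,
            seed: int = 0) -> np.ndarray:
    """Class scores of a batch; builds the network from a spec if needed."""
    net = arch if isinstance(arch, Network) else Network(arch, seed=seed)
    return net.forward(images, train=False)
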