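"""Network building blocks: Conv-BN-SiLU, partial convolution, CSP bottlenecks
(C3 and its lightweight variant), SPP/SPPF pooling and SimAM attention.

Every block carries an exact cost model: :meth:`~Block.cost` reports raw
primitive counts (conv multiply-accumulates plus elementwise op tallies) at a
given input resolution, and learnable parameters are discoverable through the
module tree.  The lightweight C3 variant replaces each bottleneck with a
partial 3x3 convolution followed by pointwise mixing:

    PConv(3x3, c_p = c/4, bare)  ->  1x1 conv (c -> 2c, BN + SiLU)
                                 ->  1x1 conv (2c -> c, bare)

with a residual add in the backbone form ("BottleNeck1") and none in the neck
form ("BottleNeck2").  This layout is the one whose summed parameter counts
reproduce the published module totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from ._nn import (Module, Parameter, Tensor, concat, conv2d, batch_norm2d,
                  max_pool2d)


class ConfigurationError(ValueError):
    """Raised for inconsistent layer configuration (channel mismatches etc.)."""


# ---------------------------------------------------------------------------
# cost model
# ---------------------------------------------------------------------------

@dataclass
class Cost:
    """Raw operation tallies for one block at a fixed input size.

    ``macs`` are convolution multiply-accumulates; the remaining fields count
    elements touched by each kind of elementwise work.  The profiling module
    converts these into FLOPs under a documented convention.
    """
    macs: int = 0
    bias_elems: int = 0
    bn_elems: int = 0
    act_elems: int = 0
    pool_cmps: int = 0
    add_elems: int = 0
    attn_elems: int = 0

    def __iadd__(self, other: "Cost") -> "Cost":
        for f in fields(self):
            setattr(self, f.name, getattr(self, f.name) + getattr(other, f.name))
        return self

    def __add__(self, other: "Cost") -> "Cost":
        out = Cost()
        out += self
        out += other
        return out


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class ConvSpec:
    k: int
    c_in: int
    c_out: int
    stride: int = 1
    has_bn: bool = True
    activation: str = "silu"
    padding: int | None = None      # defaults to k // 2 ("same" for odd k)

    def __post_init__(self):
        if self.k < 1 or self.c_in < 1 or self.c_out < 1 or self.stride < 1:
            raise ConfigurationError(f"invalid ConvSpec {self}")
        if self.padding is None:
            self.padding = self.k // 2


@dataclass
class PartialConvSpec:
    c: int
    c_p: int | None = None
    k: int = 3
    slice_position: str = "first"

    def __post_init__(self):
        if self.c_p is None:
            self.c_p = max(1, self.c // 4)
        if not 1 <= self.c_p <= self.c:
            raise ConfigurationError(
                f"PartialConvSpec: c_p={self.c_p} must satisfy 1 <= c_p <= c={self.c}")
        if self.slice_position not in ("first", "last"):
            raise ConfigurationError(f"slice_position must be first|last, got "
                                     f"{self.slice_position!r}")


@dataclass
class SimAMSpec:
    lam: float = 1e-4

    def __post_init__(self):
        if self.lam <= 0:
            raise ConfigurationError("SimAM lambda must be positive")


# ---------------------------------------------------------------------------
# helper
# ---------------------------------------------------------------------------

def _he_weight(rng: np.random.Generator, co: int, ci: int, k: int) -> np.ndarray:
    fan_in = ci * k * k
    std = math.sqrt(2.0 / fan_in)
    return (rng.standard_normal((co, ci, k, k)) * std).astype(np.float32)


def _ensure_batched(x):
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
    if t.ndim == 3:
        return t.reshape(1, *t.shape), True
    if t.ndim == 4:
        return t, False
    raise ConfigurationError(f"expected 3-D or 4-D feature map, got ndim={t.ndim}")


def _maybe_unbatch(t: Tensor, was_3d: bool) -> Tensor:
    return t.reshape(t.shape[1:]) if was_3d else t


_ACTS = {"silu", "identity", "sigmoid"}


class Block(Module):
    """Base class for blocks that expose the cost model."""

    name: str = ""

    def cost(self, h: int, w: int) -> tuple[Cost, int, int]:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# Conv-BN-activation
# ---------------------------------------------------------------------------

class Conv(Block):
    """k x k convolution with same padding, optional BatchNorm and activation.

    Under BN the conv bias is omitted (it would be absorbed by the BN shift);
    without BN a bias is learned.  BN uses eps=1e-3, momentum=0.03.
    """

    def __init__(self, spec: ConvSpec, rng: np.random.Generator | None = None,
                 name: str = ""):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        if spec.activation not in _ACTS:
            raise ConfigurationError(f"unknown activation {spec.activation!r}")
        self.spec = spec
        self.name = name
        self.weight = Parameter(_he_weight(rng, spec.c_out, spec.c_in, spec.k),
                                decay=True)
        if spec.has_bn:
            self.gamma = Parameter(np.ones(spec.c_out, dtype=np.float32))
            self.beta = Parameter(np.zeros(spec.c_out, dtype=np.float32))
            self.running_mean = np.zeros(spec.c_out, dtype=np.float32)
            self.running_var = np.ones(spec.c_out, dtype=np.float32)
        else:
            self.bias = Parameter(np.zeros(spec.c_out, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.spec.c_in:
            raise ConfigurationError(
                f"layer {self.name or 'Conv'}: expected {self.spec.c_in} input "
                f"channels, got {x.shape[1]}")
        s = self.spec
        if s.has_bn:
            y = conv2d(x, self.weight, None, stride=s.stride, padding=s.padding)
            y = batch_norm2d(y, self.gamma, self.beta, self.running_mean,
                             self.running_var, self.training)
        else:
            y = conv2d(x, self.weight, self.bias, stride=s.stride, padding=s.padding)
        if s.activation == "silu":
            y = y.silu()
        elif s.activation == "sigmoid":
            y = y.sigmoid()
        return y

    def cost(self, h: int, w: int) -> tuple[Cost, int, int]:
        s = self.spec
        ho = (h + 2 * s.padding - s.k) // s.stride + 1
        wo = (w + 2 * s.padding - s.k) // s.stride + 1
        n_out = s.c_out * ho * wo
        c = Cost(macs=s.k * s.k * s.c_in * n_out)
        if s.has_bn:
            c.bn_elems = n_out
        else:
            c.bias_elems = n_out
        if s.activation != "identity":
            c.act_elems = n_out
        return c, ho, wo


class PConv(Block):
    """Partial convolution: a k x k conv over a contiguous block of c_p
    channels; the remaining c - c_p channels pass through untouched.

    The conv itself is bare (no BN, no bias, no activation) so its cost is
    exactly h*w*k^2*c_p^2 multiply-accumulates.
    """

    def __init__(self, spec: PartialConvSpec, rng: np.random.Generator | None = None,
                 name: str = ""):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.spec = spec
        self.name = name
        self.weight = Parameter(_he_weight(rng, spec.c_p, spec.c_p, spec.k),
                                decay=True)

    def forward(self, x: Tensor) -> Tensor:
        s = self.spec
        if x.shape[1] != s.c:
            raise ConfigurationError(
                f"layer {self.name or 'PConv'}: expected {s.c} channels, "
                f"got {x.shape[1]}")
        if s.c_p == s.c:
            return conv2d(x, self.weight, None, stride=1)
        if s.slice_position == "first":
            part, rest = x[:, :s.c_p], x[:, s.c_p:]
            out = conv2d(part, self.weight, None, stride=1)
            return concat([out, rest], axis=1)
        part, rest = x[:, s.c - s.c_p:], x[:, :s.c - s.c_p]
        out = conv2d(part, self.weight, None, stride=1)
        return concat([rest, out], axis=1)

    def cost(self, h: int, w: int) -> tuple[Cost, int, int]:
        s = self.spec
        return Cost(macs=h * w * s.k * s.k * s.c_p * s.c_p), h, w


class Bottleneck(Block):
    """Standard CSP bottleneck: 1x1 conv then 3x3 conv, residual add when
    ``shortcut`` and channel counts match."""

    def __init__(self, c_in: int, c_out: int, shortcut: bool = True,
                 rng: np.random.Generator | None = None, name: str = ""):
        super().__init__()
        self.name = name
        self.cv1 = Conv(ConvSpec(1, c_in, c_out), rng, f"{name}.cv1")
        self.cv2 = Conv(ConvSpec(3, c_out, c_out), rng, f"{name}.cv2")
        self.add = shortcut and c_in == c_out

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y

    def cost(self, h: int, w: int) -> tuple[Cost, int, int]:
        c1, h, w = self.cv1.cost(h, w)
        c2, h, w = self.cv2.cost(h, w)
        c = c1 + c2
        if self.add:
            c.add_elems += self.cv2.spec.c_out * h * w
        return c, h, w


class BottleneckLight(Block):
    """Lightweight bottleneck: bare PConv(3x3, ratio 1/4) -> 1x1 expansion
    conv (BN+SiLU) -> bare 1x1 projection.  ``shortcut`` selects the backbone
    form (residual) vs the neck form (none)."""

    def __init__(self, c: int, shortcut: bool = True, partial_ratio: float = 0.25,
                 rng: np.random.Generator | None = None, name: str = ""):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.name = name
        c_p = max(1, int(c * partial_ratio))
        self.pconv = PConv(PartialConvSpec(c=c, c_p=c_p, k=3), rng, f"{name}.pconv")
        self.expand = Conv(ConvSpec(1, c, 2 * c), rng, f"{name}.expand")
        self.project = Parameter(_he_weight(rng, c, 2 * c, 1), decay=True)
        self.add = shortcut
        self.c = c

    def forward(self, x: Tensor) -> Tensor:
        y = self.pconv(x)
        y = self.expand(y)
        y = conv2d(y, self.project, None, stride=1)
        return x + y if self.add else y

    def cost(self, h: int, w: int) -> tuple[Cost, int, int]:
        c, _, _ = self.pconv.cost(h, w)
        ce, _, _ = self.expand.cost(h, w)
        c += ce
        c.macs += 2 * self.c * self.c * h * w
        if self.add:
            c.add_elems += self.c * h * w
        return c, h, w


class _C3Base(Block):
    """Cross-stage-partial block: two 1x1 entry convs, a bottleneck chain on
    one branch, concat, and a 1x1 closing conv."""

    def __init__(self, c_in: int, c_out: int, n: int, shortcut: bool,
                 make_bottleneck, rng=None, name: str = ""):
        super().__init__()
        if n < 1:
            raise ConfigurationError("C3 requires n >= 1 bottlenecks")
        c_ = c_out // 2
        self.name = name
        self.cv1 = Conv(ConvSpec(1, c_in, c_), rng, f"{name}.cv1")
        self.cv2 = Conv(ConvSpec(1, c_in, c_), rng, f"{name}.cv2")
        self.cv3 = Conv(ConvSpec(1, 2 * c_, c_out), rng, f"{name}.cv3")
        self.m = [make_bottleneck(c_, shortcut, rng, f"{name}.m.{i}")
                  for i in range(n)]

    def forward(self, x: Tensor) -> Tensor:
        y1 = self.cv1(x)
        for b in self.m:
            y1 = b(y1)
        y2 = self.cv2(x)
        return self.cv3(concat([y1, y2], axis=1))

    def cost(self, h: int, w: int) -> tuple[Cost, int, int]:
        c, _, _ = self.cv1.cost(h, w)
        c2, _, _ = self.cv2.cost(h, w)
        c += c2
        for b in self.m:
            cb, _, _ = b.cost(h, w)
            c += cb
        c3, _, _ = self.cv3.cost(h, w)
        c += c3
        return c, h, w


class C3(_C3Base):
    """C3 CSP block; shortcut=True is the backbone (CSP1_X) form, False the
    neck (CSP2_X) form."""

    def __init__(self, c_in: int, c_out: int, n: int = 1, shortcut: bool = True,
                 rng=None, name: str = ""):
        def mk(c_, sc, r, nm):
            return Bottleneck(c_, c_, sc, r, nm)
        super().__init__(c_in, c_out, n, shortcut, mk, rng, name)


class C3Light(_C3Base):
    """Drop-in C3 replacement with lightweight bottlenecks (see module docstring)."""

    def __init__(self, c_in: int, c_out: int, n: int = 1, shortcut: bool = True,
                 rng=None, name: str = ""):
        def mk(c_, sc, r, nm):
            return BottleneckLight(c_, sc, 0.25, r, nm)
        super().__init__(c_in, c_out, n, shortcut, mk, rng, name)


class SPPF(Block):
    """Fast spatial pyramid pooling: three chained k x k stride-1 max-pools,
    concatenated with the input (equivalent to SPP with pools k, 2k-1, 3k-2)."""

    def __init__(self, c_in: int, c_out: int, k: int = 5, rng=None, name: str = ""):
        super().__init__()
        if k % 2 == 0:
            raise ConfigurationError("SPPF pool size must be odd")
        c_ = c_in // 2
        self.k = k
        self.name = name
        self.cv1 = Conv(ConvSpec(1, c_in, c_), rng, f"{name}.cv1")
        self.cv2 = Conv(ConvSpec(1, 4 * c_, c_out), rng, f"{name}.cv2")

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        p1 = max_pool2d(y, self.k)
        p2 = max_pool2d(p1, self.k)
        p3 = max_pool2d(p2, self.k)
        return self.cv2(concat([y, p1, p2, p3], axis=1))

    def cost(self, h: int, w: int) -> tuple[Cost, int, int]:
        c, _, _ = self.cv1.cost(h, w)
        c_ = self.cv1.spec.c_out
        c.pool_cmps += 3 * (self.k * self.k - 1) * c_ * h * w
        c2, _, _ = self.cv2.cost(h, w)
        c += c2
        return c, h, w


class SPP(Block):
    """Reference spatial pyramid pooling with parallel pools (default 5/9/13);
    kept as the independent oracle for SPPF equivalence."""

    def __init__(self, c_in: int, c_out: int, ks=(5, 9, 13), rng=None, name: str = ""):
        super().__init__()
        c_ = c_in // 2
        self.ks = tuple(ks)
        self.name = name
        self.cv1 = Conv(ConvSpec(1, c_in, c_), rng, f"{name}.cv1")
        self.cv2 = Conv(ConvSpec(1, (len(ks) + 1) * c_, c_out), rng, f"{name}.cv2")

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        pools = [max_pool2d(y, k) for k in self.ks]
        return self.cv2(concat([y] + pools, axis=1))

    def cost(self, h: int, w: int) -> tuple[Cost, int, int]:
        c, _, _ = self.cv1.cost(h, w)
        c_ = self.cv1.spec.c_out
        for k in self.ks:
            c.pool_cmps += (k * k - 1) * c_ * h * w
        c2, _, _ = self.cv2.cost(h, w)
        c += c2
        return c, h, w


class SimAM(Block):
    """Parameter-free attention.  Per channel, with spatial mean mu and
    variance s2 (divisor h*w - 1):

        E = (x - mu)^2 / (4 * (s2 + lambda)) + 0.5
        out = x * sigmoid(E)

    Declares zero learnable parameters.  Raises on 1x1 spatial maps, where the
    variance is undefined.
    """

    def __init__(self, spec: SimAMSpec | None = None, name: str = ""):
        super().__init__()
        self.spec = spec or SimAMSpec()
        self.name = name

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        nhw = h * w
        if nhw < 2:
            raise ConfigurationError(
                f"layer {self.name or 'SimAM'}: needs h*w >= 2, got {h}x{w}")
        mu = x.mean(axis=(2, 3), keepdims=True)
        d = x - mu
        d2 = d * d
        s2 = d2.sum(axis=(2, 3), keepdims=True) * (1.0 / (nhw - 1))
        energy = d2 / ((s2 + self.spec.lam) * 4.0) + 0.5
        return x * energy.sigmoid()

    def cost(self, h: int, w: int) -> tuple[Cost, int, int]:
        # attn_elems is multiplied by a fixed per-element op count in profiling
        return Cost(attn_elems=0), h, w  # channel count unknown here

    def cost_for(self, c: int, h: int, w: int) -> Cost:
        return Cost(attn_elems=c * h * w)


# ---------------------------------------------------------------------------
# functional wrappers (spec-level operations)
# ---------------------------------------------------------------------------

def conv_bn_act(x, spec: ConvSpec, rng=None, module: Conv | None = None):
    """Apply a Conv-BN-activation block to a feature map (3-D or batched 4-D)."""
    m = module if module is not None else Conv(spec, rng)
    t, was_3d = _ensure_batched(x)
    return _maybe_unbatch(m(t), was_3d)


def pconv(x, spec: PartialConvSpec, rng=None, module: PConv | None = None):
    m = module if module is not None else PConv(spec, rng)
    t, was_3d = _ensure_batched(x)
    return _maybe_unbatch(m(t), was_3d)


def c3_block(x, c_out: int, n: int = 1, shortcut: bool = True, rng=None,
             module: C3 | None = None):
    t, was_3d = _ensure_batched(x)
    m = module if module is not None else C3(t.shape[1], c_out, n, shortcut, rng)
    return _maybe_unbatch(m(t), was_3d)


def c3_light_block(x, c_out: int, n: int = 1, shortcut: bool = True, rng=None,
                   module: C3Light | None = None):
    t, was_3d = _ensure_batched(x)
    m = module if module is not None else C3Light(t.shape[1], c_out, n, shortcut, rng)
    return _maybe_unbatch(m(t), was_3d)


def sppf(x, k: int = 5, rng=None, module: SPPF | None = None):
    t, was_3d = _ensure_batched(x)
    c = t.shape[1]
    m = module if module is not None else SPPF(c, c, k, rng)
    return _maybe_unbatch(m(t), was_3d)


def simam(x, spec: SimAMSpec | None = None):
    t, was_3d = _ensure_batched(x)
    return _maybe_unbatch(SimAM(spec)(t), was_3d)
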