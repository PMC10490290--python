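"""Assemble the detector as an explicit layer graph.

Two variants are built from one template (the YOLOv5 v7.0 P5 layer table with
a 6x6 stride-2 stem, CSP backbone + SPPF, CSP-PAN neck, three-scale anchored
head):

* ``baseline`` - standard C3 blocks throughout.
* ``cs``       - every C3 swapped for its lightweight form (residual
  bottlenecks in the backbone, none in the neck) and, unless disabled, one
  parameter-free SimAM attention node on each of the three neck outputs.

Depth/width multiples shrink bottleneck repeats and channel widths; channels
are rounded up to multiples of 8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import yaml

from ._nn import Module, Tensor, concat, upsample_nearest2
from .core_layers import (C3, C3Light, Conv, ConvSpec, Cost, SimAM, SimAMSpec,
                          SPPF, ConfigurationError)

# stock three-scale anchor set (pixel w,h at 640), strides 8/16/32
DEFAULT_ANCHORS = (
    ((10, 13), (16, 30), (33, 23)),
    ((30, 61), (62, 45), (59, 119)),
    ((116, 90), (156, 198), (373, 326)),
)

STRIDES = (8, 16, 32)


@dataclass
class ModelConfig:
    depth_multiple: float = 0.33
    width_multiple: float = 0.25
    nc: int = 80
    anchors: tuple = DEFAULT_ANCHORS
    variant: str = "baseline"
    input_size: int = 640
    use_simam: bool = True          # only relevant for variant="cs"
    simam_lambda: float = 1e-4
    conf_thr: float = 0.25
    iou_thr: float = 0.5
    on_indivisible: str = "fail"    # "fail" | "resize"

    def __post_init__(self):
        if self.variant not in ("baseline", "cs"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.nc < 1:
            raise ConfigurationError("nc must be positive")
        a = np.asarray(self.anchors, dtype=float)
        if a.shape != (3, 3, 2):
            raise ConfigurationError("anchors must be 3 scales x 3 (w,h) pairs")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["anchors"] = [[list(map(float, p)) for p in grp] for grp in self.anchors]
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        d = yaml.safe_load(text)
        if "anchors" in d:
            d["anchors"] = tuple(tuple(tuple(p) for p in grp) for grp in d["anchors"])
        return cls(**d)


@dataclass
class Detection:
    box: tuple          # (x1, y1, x2, y2) pixel corners
    confidence: float
    class_id: int


def _make_divisible(x: float, divisor: int = 8) -> int:
    import math
    return max(divisor, int(math.ceil(x / divisor) * divisor))


def _depth_gain(n: int, gd: float) -> int:
    return max(1, round(n * gd)) if n > 1 else n


class _Upsample(Module):
    def forward(self, x):
        return upsample_nearest2(x)


class Detect(Module):
    """Three 1x1 convs (with bias, no BN/act) producing 3*(5+nc) maps."""

    def __init__(self, channels, nc, rng, name="detect"):
        super().__init__()
        self.nc = nc
        self.no = 5 + nc
        self.name = name
        self.convs = [Conv(ConvSpec(1, c, 3 * self.no, has_bn=False,
                                    activation="identity"), rng, f"{name}.{i}")
                      for i, c in enumerate(channels)]
        # prior-friendly bias init: low objectness, uniform class logits
        for conv, s in zip(self.convs, STRIDES):
            b = conv.bias.data.reshape(3, self.no)
            b[:, 4] += np.log(8.0 / (640.0 / s) ** 2)
            if nc > 0:
                b[:, 5:] += np.log(0.6 / (nc - 0.99 + 1e-9)) if nc > 1 else -2.0
            conv.bias.data = b.reshape(-1)

    def forward(self, xs):
        outs = []
        for conv, x in zip(self.convs, xs):
            n, _, h, w = x.shape
            y = conv(x).reshape(n, 3, self.no, h, w).transpose(0, 1, 3, 4, 2)
            outs.append(y)
        return outs


@dataclass
class Node:
    index: int
    name: str
    module: object          # Block / _Upsample / None for concat
    src: object             # int, or list of ints for concat
    kind: str               # conv|c3|sppf|upsample|concat|simam
    c_out: int


class Model(Module):
    """Ordered layer graph with three-scale detection head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        gw, gd, nc = config.width_multiple, config.depth_multiple, config.nc
        light = config.variant == "cs"

        def ch(c):
            return _make_divisible(c * gw)

        self.nodes: list[Node] = []
        outs_c: list[int] = []

        def add(name, module, src, kind, c_out):
            self.nodes.append(Node(len(self.nodes), name, module, src, kind, c_out))
            outs_c.append(c_out)
            return len(self.nodes) - 1

        def conv(c_in, c_out, k, s, src=-1, pad=None):
            i = len(self.nodes)
            return add(f"conv{i}", Conv(ConvSpec(k, c_in, c_out, s, padding=pad),
                                        rng, f"conv{i}"), src, "conv", c_out)

        def c3(c_in, c_out, n, shortcut=True, src=-1):
            i = len(self.nodes)
            n = _depth_gain(n, gd)
            cls = C3Light if light else C3
            return add(f"c3_{i}", cls(c_in, c_out, n, shortcut, rng, f"c3_{i}"),
                       src, "c3", c_out)

        # backbone -------------------------------------------------------
        conv(3, ch(64), 6, 2, pad=2)              # 0  /2
        conv(ch(64), ch(128), 3, 2)               # 1  /4
        c3(ch(128), ch(128), 3)                   # 2
        conv(ch(128), ch(256), 3, 2)              # 3  /8
        p3 = c3(ch(256), ch(256), 6)              # 4
        conv(ch(256), ch(512), 3, 2)              # 5  /16
        p4 = c3(ch(512), ch(512), 9)              # 6
        conv(ch(512), ch(1024), 3, 2)             # 7  /32
        c3(ch(1024), ch(1024), 3)                 # 8
        add("sppf", SPPF(ch(1024), ch(1024), 5, rng, "sppf"), -1, "sppf", ch(1024))  # 9
        # neck (PAN) -----------------------------------------------------
        n10 = conv(ch(1024), ch(512), 1, 1)       # 10
        add("up11", _Upsample(), -1, "upsample", ch(512))          # 11
        add("cat12", None, [-1, p4], "concat", ch(512) * 2)        # 12
        h17_in = c3(ch(512) * 2, ch(512), 3, False)                # 13
        n14 = conv(ch(512), ch(256), 1, 1)        # 14
        add("up15", _Upsample(), -1, "upsample", ch(256))          # 15
        add("cat16", None, [-1, p3], "concat", ch(256) * 2)        # 16
        o3 = c3(ch(256) * 2, ch(256), 3, False)   # 17  (stride 8)
        conv(ch(256), ch(256), 3, 2)              # 18
        add("cat19", None, [-1, n14], "concat", ch(256) * 2)       # 19
        o4 = c3(ch(256) * 2, ch(512), 3, False)   # 20  (stride 16)
        conv(ch(512), ch(512), 3, 2)              # 21
        add("cat22", None, [-1, n10], "concat", ch(512) * 2)       # 22
        o5 = c3(ch(512) * 2, ch(1024), 3, False)  # 23  (stride 32)

        head_srcs = [o3, o4, o5]
        if light and config.use_simam:
            spec = SimAMSpec(config.simam_lambda)
            head_srcs = [add(f"simam_p{i + 3}", SimAM(spec, f"simam_p{i + 3}"),
                             s, "simam", outs_c[s])
                         for i, s in enumerate([o3, o4, o5])]
        self.head_srcs = head_srcs
        # expose node modules through a plain list so the generic parameter /
        # state walkers see them (Node itself is not a Module)
        self.layers = [n.module for n in self.nodes if isinstance(n.module, Module)]
        self.detect = Detect([outs_c[s] for s in head_srcs], nc, rng)
        self._validate()

    # -- structural checks -------------------------------------------------
    def _resolve(self, idx: int, src) -> list[int]:
        srcs = src if isinstance(src, list) else [src]
        return [s if s >= 0 else idx + s for s in srcs]

    def _validate(self):
        c_of = [n.c_out for n in self.nodes]
        for node in self.nodes:
            srcs = self._resolve(node.index, node.src)
            for s in srcs:
                if not 0 <= s < node.index and node.index > 0:
                    raise ConfigurationError(
                        f"node {node.name}: source {s} breaks DAG ordering")
            if node.kind == "concat":
                got = sum(c_of[s] for s in srcs)
                if got != node.c_out:
                    raise ConfigurationError(
                        f"node {node.name}: concat yields {got} channels, "
                        f"declared {node.c_out}")
            elif node.kind in ("conv", "c3", "sppf"):
                c_in = c_of[srcs[0]] if node.index > 0 else 3
                expected = (node.module.spec.c_in if node.kind == "conv"
                            else node.module.cv1.spec.c_in)
                if c_in != expected:
                    raise ConfigurationError(
                        f"node {node.name}: producer emits {c_in} channels, "
                        f"module expects {expected}")

    # -- forward -----------------------------------------------------------
    def forward(self, x) -> list:
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        if t.ndim == 3:
            t = t.reshape(1, *t.shape)
        _, _, h, w = t.shape
        if h % 32 or w % 32:
            if self.config.on_indivisible == "resize":
                t = _resize_to_multiple(t, 32)
            else:
                raise ConfigurationError(
                    f"input {h}x{w} not divisible by 32 (set on_indivisible="
                    f"'resize' to auto-resize)")
        cache: list = []
        for node in self.nodes:
            srcs = self._resolve(node.index, node.src)
            if node.index == 0:
                inp = t
            elif node.kind == "concat":
                inp = concat([cache[s] for s in srcs], axis=1)
            else:
                inp = cache[srcs[0]]
            if node.kind == "concat":
                cache.append(inp)
            else:
                cache.append(node.module(inp))
        return self.detect([cache[s] for s in self.head_srcs])

    # -- cost walk ---------------------------------------------------------
    def node_costs(self, input_size: int | None = None):
        """Yield (name, kind, params, Cost) for every node plus the head."""
        size = input_size or self.config.input_size
        hw: list[tuple[int, int]] = []
        c_of = [n.c_out for n in self.nodes]
        for node in self.nodes:
            srcs = self._resolve(node.index, node.src)
            h, w = (size, size) if node.index == 0 else hw[srcs[0]]
            if node.kind == "concat":
                cost, ho, wo = Cost(), h, w
            elif node.kind == "upsample":
                cost, ho, wo = Cost(), h * 2, w * 2
            elif node.kind == "simam":
                cost, ho, wo = node.module.cost_for(node.c_out, h, w), h, w
            else:
                cost, ho, wo = node.module.cost(h, w)
            hw.append((ho, wo))
            params = node.module.num_parameters() if isinstance(node.module, Module) else 0
            yield node.name, node.kind, params, cost
        for conv, src in zip(self.detect.convs, self.head_srcs):
            cost, _, _ = conv.cost(*hw[src])
            yield conv.name, "detect", conv.num_parameters(), cost

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        state = self.state_dict()
        meta = json.dumps({"config": yaml.safe_load(self.config.to_yaml())})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **state)

    @classmethod
    def load(cls, path) -> "Model":
        with np.load(path if str(path).endswith(".npz") else f"{path}.npz") as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            cfg_d = meta["config"]
            if "anchors" in cfg_d:
                cfg_d["anchors"] = tuple(tuple(tuple(p) for p in g)
                                         for g in cfg_d["anchors"])
            model = cls(ModelConfig(**cfg_d))
            model.load_state_dict({k: z[k] for k in z.files if k != "__meta__"})
        return model


def _resize_to_multiple(t: Tensor, m: int) -> Tensor:
    n, c, h, w = t.shape
    ho, wo = (h + m - 1) // m * m, (w + m - 1) // m * m
    yi = (np.arange(ho) * h / ho).astype(int)
    xi = (np.arange(wo) * w / wo).astype(int)
    return Tensor(t.data[:, :, yi][:, :, :, xi])


def build_model(config: ModelConfig, seed: int = 0) -> Model:
    """Build a detector graph from a configuration."""
    return Model(config, seed=seed)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _sigmoid(z):
    from scipy.special import expit
    return expit(z)


def decode_predictions(raw, config: ModelConfig, conf_thr: float | None = None,
                       iou_thr: float | None = None) -> list[list[Detection]]:
    """Decode raw per-scale predictions into pixel-space detections.

    ``raw`` is the list of three (N, 3, H, W, 5+nc) arrays/Tensors emitted by
    the model.  Returns one confidence-sorted detection list per image after
    class-agnostic greedy NMS.
    """
    conf_thr = config.conf_thr if conf_thr is None else conf_thr
    iou_thr = config.iou_thr if iou_thr is None else iou_thr
    if not (0 <= conf_thr <= 1 and 0 <= iou_thr <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    arrays = [r.data if isinstance(r, Tensor) else np.asarray(r) for r in raw]
    n = arrays[0].shape[0]
    anchors = np.asarray(config.anchors, dtype=np.float32)
    results = []
    for b in range(n):
        boxes, scores, classes = [], [], []
        for a_grp, stride, arr in zip(anchors, STRIDES, arrays):
            p = _sigmoid(arr[b])                       # (3, H, W, 5+nc)
            _, hh, ww, _ = p.shape
            gy, gx = np.mgrid[0:hh, 0:ww]
            xy = (p[..., :2] * 2.0 - 0.5 +
                  np.stack([gx, gy], axis=-1)[None]) * stride
            wh = (p[..., 2:4] * 2.0) ** 2 * a_grp[:, None, None, :]
            obj = p[..., 4]
            cls = p[..., 5:]
            cid = cls.argmax(axis=-1)
            conf = obj * np.take_along_axis(cls, cid[..., None], axis=-1)[..., 0]
            keep = conf >= conf_thr
            if keep.any():
                xy_k, wh_k = xy[keep], wh[keep]
                x1y1 = xy_k - wh_k / 2
                x2y2 = xy_k + wh_k / 2
                boxes.append(np.concatenate([x1y1, x2y2], axis=-1))
                scores.append(conf[keep])
                classes.append(cid[keep])
        if not boxes:
            results.append([])
            continue
        bx = np.concatenate(boxes)
        sc = np.concatenate(scores)
        cl = np.concatenate(classes)
        keep_idx = nms(bx, sc, iou_thr)
        results.append([Detection(tuple(bx[i].tolist()), float(sc[i]), int(cl[i]))
                        for i in keep_idx])
    return results


def box_iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of corner-format boxes, shapes (n,4) x (m,4) -> (n,m)."""
    a = np.atleast_2d(a).astype(float)
    b = np.atleast_2d(b).astype(float)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = np.prod(a[:, 2:] - a[:, :2], axis=1)
    area_b = np.prod(b[:, 2:] - b[:, :2], axis=1)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> list[int]:
    """Greedy NMS; descending confidence, ties broken by lower box index."""
    order = np.lexsort((np.arange(len(scores)), -scores))
    keep: list[int] = []
    suppressed = np.zeros(len(scores), dtype=bool)
    iou = box_iou_xyxy(boxes, boxes)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(int(i))
        suppressed |= iou[i] > iou_thr
        suppressed[i] = True
    return keep
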