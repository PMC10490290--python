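"""Annotation formats, augmentation, dataset splitting and anchor generation.

Pascal VOC XML and YOLO TXT are the two label dialects: VOC stores integer
pixel corners (0-based, half-open after conversion), YOLO stores normalized
center/size boxes, one ``class cx cy w h`` line per object with six decimals.

The augmentation menu is the eight-method table used to expand the source
images: two blurs, a colorspace (hue) shift, brightness, Gaussian noise, both
flips and a down-scaling zoom.  Pixel-only methods leave boxes untouched;
flips mirror the normalized centers; zoom rescales pixels while normalized
boxes are unchanged.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation data."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VOCObject:
    name: str
    xmin: int
    ymin: int
    xmax: int
    ymax: int


@dataclass
class VOCAnnotation:
    filename: str
    width: int
    height: int
    depth: int
    objects: list[VOCObject] = field(default_factory=list)

    def validate(self) -> "VOCAnnotation":
        for o in self.objects:
            if not (o.xmin < o.xmax <= self.width and o.ymin < o.ymax <= self.height):
                raise AnnotationError(
                    f"{self.filename}: box ({o.xmin},{o.ymin})-({o.xmax},{o.ymax}) "
                    f"violates 0 <= min < max <= image size "
                    f"({self.width}x{self.height})")
        return self


@dataclass
class NormBox:
    """YOLO label unit: class id plus normalized center/size in [0, 1]."""
    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def validate(self) -> "NormBox":
        if not (0 < self.w <= 1 and 0 < self.h <= 1):
            raise AnnotationError(f"degenerate box size {self.w}x{self.h}")
        if not (0 <= self.cx <= 1 and 0 <= self.cy <= 1):
            raise AnnotationError(f"center ({self.cx},{self.cy}) outside unit square")
        return self

    def as_tuple(self):
        return (self.class_id, self.cx, self.cy, self.w, self.h)


# ---------------------------------------------------------------------------
# VOC XML
# ---------------------------------------------------------------------------

def _req(node, tag, path):
    child = node.find(tag)
    if child is None or (child.text is None and len(child) == 0):
        raise AnnotationError(f"{path}: missing <{tag}>")
    return child


def read_voc_annotation(source) -> VOCAnnotation:
    """Parse a Pascal VOC XML document (path, file object or XML string)."""
    text = None
    path = "<xml>"
    if isinstance(source, (str, Path)) and os.path.exists(str(source)):
        path = str(source)
        text = Path(source).read_text()
    elif isinstance(source, (str, bytes)):
        text = source if isinstance(source, str) else source.decode()
    else:
        text = source.read()
    try:
        root = ET.fromstring(text)
    except ET.ParseError as e:
        raise AnnotationError(f"{path}: not well-formed XML ({e})") from None
    size = _req(root, "size", path)
    ann = VOCAnnotation(
        filename=(root.findtext("filename") or "").strip(),
        width=int(_req(size, "width", path).text),
        height=int(_req(size, "height", path).text),
        depth=int(size.findtext("depth", "3")),
    )
    for obj in root.iter("object"):
        bb = _req(obj, "bndbox", path)
        ann.objects.append(VOCObject(
            name=(obj.findtext("name") or "").strip(),
            xmin=round(float(_req(bb, "xmin", path).text)),
            ymin=round(float(_req(bb, "ymin", path).text)),
            xmax=round(float(_req(bb, "xmax", path).text)),
            ymax=round(float(_req(bb, "ymax", path).text)),
        ))
    return ann.validate()


def write_voc_annotation(ann: VOCAnnotation, path) -> None:
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = ann.filename
    size = ET.SubElement(root, "size")
    for tag, val in (("width", ann.width), ("height", ann.height),
                     ("depth", ann.depth)):
        ET.SubElement(size, tag).text = str(val)
    for o in ann.objects:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = o.name
        bb = ET.SubElement(obj, "bndbox")
        for tag, val in (("xmin", o.xmin), ("ymin", o.ymin),
                         ("xmax", o.xmax), ("ymax", o.ymax)):
            ET.SubElement(bb, tag).text = str(val)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode")


# ---------------------------------------------------------------------------
# VOC <-> YOLO
# ---------------------------------------------------------------------------

def voc_to_yolo(ann: VOCAnnotation, class_map: dict[str, int]) -> list[NormBox]:
    ann.validate()
    unknown = sorted({o.name for o in ann.objects} - set(class_map))
    if unknown:
        raise AnnotationError(f"{ann.filename}: unmapped class names {unknown}")
    out = []
    for o in ann.objects:
        out.append(NormBox(
            class_id=class_map[o.name],
            cx=(o.xmin + o.xmax) / 2.0 / ann.width,
            cy=(o.ymin + o.ymax) / 2.0 / ann.height,
            w=(o.xmax - o.xmin) / ann.width,
            h=(o.ymax - o.ymin) / ann.height,
        ).validate())
    return out


def yolo_to_voc(boxes: list[NormBox], width: int, height: int,
                class_names: list[str], filename: str = "") -> VOCAnnotation:
    ann = VOCAnnotation(filename=filename, width=width, height=height, depth=3)
    for b in boxes:
        b.validate()
        ann.objects.append(VOCObject(
            name=class_names[b.class_id],
            xmin=round((b.cx - b.w / 2) * width),
            ymin=round((b.cy - b.h / 2) * height),
            xmax=round((b.cx + b.w / 2) * width),
            ymax=round((b.cy + b.h / 2) * height),
        ))
    return ann.validate()


def write_yolo_txt(path, boxes: list[NormBox]) -> None:
    lines = [f"{b.validate().class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}"
             for b in boxes]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_txt(path) -> list[NormBox]:
    boxes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 5:
            raise AnnotationError(f"{path}:{lineno}: expected 5 fields, "
                                  f"got {len(parts)}")
        try:
            boxes.append(NormBox(int(parts[0]), *map(float, parts[1:])).validate())
        except ValueError as e:
            raise AnnotationError(f"{path}:{lineno}: {e}") from None
    return boxes


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_image(path, img: np.ndarray) -> None:
    Image.fromarray(np.asarray(img, dtype=np.uint8)).save(path)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

AUGMENTATION_RANGES = {
    "gaussian_blur": (0.5, 3.0),    # sigma, pixels
    "average_blur": (2, 11),        # kernel size, pixels
    "colorspace": (10, 50),         # hue shift, degrees
    "brightness": (-50, 50),        # additive offset, grey levels
    "gaussian_noise": 3,            # sigma, grey levels
    "hflip": 1,
    "vflip": 1,
    "resize": (0.5, 0.8),           # scale factor
}


@dataclass
class AugmentationSpec:
    method: str
    params: object = None

    def __post_init__(self):
        if self.method not in AUGMENTATION_RANGES:
            raise AnnotationError(f"unknown augmentation method {self.method!r}")
        if self.params is None:
            self.params = AUGMENTATION_RANGES[self.method]


def default_augmentations() -> list[AugmentationSpec]:
    return [AugmentationSpec(m) for m in AUGMENTATION_RANGES]


def _rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    # vectorized RGB->HSV on [0,1] floats (h in [0,1])
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    mx = img.max(axis=-1)
    mn = img.min(axis=-1)
    diff = mx - mn
    safe = np.where(diff == 0, 1.0, diff)
    h = np.where(mx == r, (g - b) / safe % 6,
                 np.where(mx == g, (b - r) / safe + 2, (r - g) / safe + 4)) / 6.0
    h = np.where(diff == 0, 0.0, h)
    s = np.where(mx == 0, 0.0, diff / np.where(mx == 0, 1.0, mx))
    return np.stack([h, s, mx], axis=-1)


def _hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    h, s, v = hsv[..., 0] * 6.0, hsv[..., 1], hsv[..., 2]
    i = np.floor(h).astype(int) % 6
    f = h - np.floor(h)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    choices = np.stack([
        np.stack([v, t, p], -1), np.stack([q, v, p], -1),
        np.stack([p, v, t], -1), np.stack([p, q, v], -1),
        np.stack([t, p, v], -1), np.stack([v, p, q], -1)], axis=0)
    return np.take_along_axis(choices, i[None, ..., None], axis=0)[0]


def _sample(rng: np.random.Generator, rng_spec, integer=False):
    lo, hi = rng_spec
    if integer:
        return int(rng.integers(lo, hi + 1))
    return float(rng.uniform(lo, hi))


def augment_sample(image: np.ndarray, boxes: list[NormBox],
                   spec: AugmentationSpec, seed: int):
    """Apply one augmentation; returns (image, boxes), reproducible per seed."""
    rng = np.random.default_rng(seed)
    img = np.asarray(image)
    method, prm = spec.method, spec.params

    if method == "gaussian_blur":
        sigma = _sample(rng, prm)
        out = ndimage.gaussian_filter(img.astype(np.float32), (sigma, sigma, 0))
        return np.clip(out, 0, 255).astype(np.uint8), list(boxes)
    if method == "average_blur":
        k = _sample(rng, prm, integer=True)
        out = ndimage.uniform_filter(img.astype(np.float32), (k, k, 1))
        return np.clip(out, 0, 255).astype(np.uint8), list(boxes)
    if method == "colorspace":
        shift = _sample(rng, prm) / 360.0
        hsv = _rgb_to_hsv(img.astype(np.float32) / 255.0)
        hsv[..., 0] = (hsv[..., 0] + shift) % 1.0
        out = _hsv_to_rgb(hsv) * 255.0
        return np.clip(out, 0, 255).astype(np.uint8), list(boxes)
    if method == "brightness":
        delta = _sample(rng, prm)
        out = img.astype(np.float32) + delta
        return np.clip(out, 0, 255).astype(np.uint8), list(boxes)
    if method == "gaussian_noise":
        sigma = float(prm)
        out = img.astype(np.float32) + rng.normal(0, sigma, img.shape)
        return np.clip(out, 0, 255).astype(np.uint8), list(boxes)
    if method == "hflip":
        out = img[:, ::-1].copy()
        return out, [NormBox(b.class_id, 1.0 - b.cx, b.cy, b.w, b.h) for b in boxes]
    if method == "vflip":
        out = img[::-1].copy()
        return out, [NormBox(b.class_id, b.cx, 1.0 - b.cy, b.w, b.h) for b in boxes]
    if method == "resize":
        f = _sample(rng, prm)
        h, w = img.shape[:2]
        nh, nw = max(1, round(h * f)), max(1, round(w * f))
        out = np.asarray(Image.fromarray(img).resize((nw, nh), Image.BILINEAR))
        return out, list(boxes)
    raise AnnotationError(f"unknown augmentation method {method!r}")


def augmentation_schedule(n_originals: int, target_total: int) -> list[int]:
    """Per-image augmented-copy counts so originals + copies == target_total.

    Non-integral expansion factors are handled by a largest-remainder
    schedule: every image receives floor(m) - 1 copies and the first images
    (in order) receive one extra until the target is met.
    """
    if target_total < n_originals:
        raise ValueError("target_total must be >= number of originals")
    extra_total = target_total - n_originals
    base, rem = divmod(extra_total, n_originals)
    return [base + (1 if i < rem else 0) for i in range(n_originals)]


def build_augmented_dataset(originals, specs: list[AugmentationSpec],
                            multiplier: float, seed: int, out_dir) -> list[str]:
    """Write originals plus (multiplier - 1) augmented copies each.

    ``originals`` is a list of (name, image, boxes).  A fractional multiplier
    is resolved by :func:`augmentation_schedule`.  Returns the written stems.
    """
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    target = round(len(originals) * multiplier)
    schedule = augmentation_schedule(len(originals), target)
    rng = np.random.default_rng(seed)
    stems: list[str] = []

    def emit(stem, img, boxes):
        if stem in stems:
            raise FileExistsError(f"output name collision: {stem}")
        write_image(out_dir / f"{stem}.png", img)
        write_yolo_txt(out_dir / f"{stem}.txt", boxes)
        stems.append(stem)

    for (name, img, boxes), n_copies in zip(originals, schedule):
        emit(name, img, boxes)
        for j in range(n_copies):
            spec = specs[int(rng.integers(len(specs)))]
            aug_img, aug_boxes = augment_sample(img, boxes, spec,
                                                int(rng.integers(2 ** 31)))
            emit(f"{name}_aug{j}", aug_img, aug_boxes)
    return stems


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(items, ratios=(8, 1, 1), seed: int = 0):
    """Shuffled, disjoint, exhaustive (train, val, test) split.

    Validation/test sizes are round(n * r / sum(r)); the remainder goes to
    train.  The split depends only on the multiset of items and the seed, not
    on their input order.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    items = sorted(items, key=repr)
    n = len(items)
    if n < len(ratios):
        raise ValueError(f"cannot split {n} items into {len(ratios)} parts")
    total = sum(ratios)
    n_val = round(n * ratios[1] / total)
    n_test = round(n * ratios[2] / total)
    perm = np.random.default_rng(seed).permutation(n)
    shuffled = [items[i] for i in perm]
    train = shuffled[:n - n_val - n_test]
    val = shuffled[n - n_val - n_test:n - n_test]
    test = shuffled[n - n_test:]
    return train, val, test


# ---------------------------------------------------------------------------
# k-means anchors
# ---------------------------------------------------------------------------

@dataclass
class AnchorSet:
    """Nine (w, h) pixel anchors sorted ascending by area, grouped 3 per scale."""
    anchors: np.ndarray     # (9, 2)

    def __post_init__(self):
        self.anchors = np.asarray(self.anchors, dtype=float)
        if (self.anchors <= 0).any():
            raise ValueError("anchor dimensions must be positive")

    @property
    def groups(self) -> tuple:
        return tuple(tuple(map(tuple, self.anchors[i:i + 3]))
                     for i in range(0, len(self.anchors), 3))


def _wh_iou(wh: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Aspect-aware IoU of (w,h) pairs against centroids, as if co-centered."""
    inter = (np.minimum(wh[:, None, 0], centroids[None, :, 0])
             * np.minimum(wh[:, None, 1], centroids[None, :, 1]))
    union = wh.prod(axis=1)[:, None] + centroids.prod(axis=1)[None] - inter
    return inter / np.maximum(union, 1e-12)


def _lloyd(wh: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int = 300):
    idx = rng.choice(len(wh), size=k, replace=False)
    centroids = wh[idx].astype(float).copy()
    assign = np.full(len(wh), -1)
    for _ in range(max_iter):
        d = 1.0 - _wh_iou(wh, centroids)
        new_assign = d.argmin(axis=1)
        if (new_assign == assign).all():
            break
        assign = new_assign
        for j in range(k):
            members = wh[assign == j]
            if len(members):
                centroids[j] = members.mean(axis=0)
    cost = (1.0 - _wh_iou(wh, centroids)).min(axis=1).sum()
    return centroids, cost


def kmeans_anchors(boxes: list[NormBox], k: int = 9, img_size: int = 640,
                   seed: int = 0, n_restarts: int = 10) -> AnchorSet:
    """Lloyd's k-means on pixel (w, h) pairs under the 1 - IoU distance.

    Runs ``n_restarts`` seeded initializations and keeps the lowest-cost
    clustering.  Centroids are returned sorted by area (3 groups of 3 when
    k = 9, assigned to strides 8/16/32 by area tertile).
    """
    if len(boxes) < k:
        raise ValueError(f"need at least k={k} boxes, got {len(boxes)}")
    wh = np.array([[b.w * img_size, b.h * img_size] for b in boxes], dtype=float)
    if np.unique(wh, axis=0).shape[0] < k:
        import warnings
        warnings.warn("fewer distinct box shapes than k; centroids may repeat")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        centroids, cost = _lloyd(wh, k, rng)
        if best is None or cost < best[1] - 1e-12:
            best = (centroids, cost)
    centroids = best[0]
    order = np.argsort(centroids.prod(axis=1), kind="stable")
    return AnchorSet(centroids[order])
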