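"""Synthetic orchard scene generator.

Renders labeled scenes of shaded elliptical "apples" on a textured foliage
background, with optional branch-like occluder strips, lighting modes and
blur, so the detection pipeline (and a small training run) can be exercised
without any real imagery.  Ground truth is derived from per-apple visibility
masks: apples whose visible fraction falls below a threshold are culled, and
the surviving boxes are tight around the *visible* pixels.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data_io import (NormBox, VOCAnnotation, VOCObject, write_image,
                      write_voc_annotation, write_yolo_txt)

LIGHTING_MODES = ("day", "dark", "overexposed")


class SceneConfigError(ValueError):
    pass


@dataclass
class SceneConfig:
    image_size: int = 160
    apple_count: tuple[int, int] = (2, 5)
    radius: tuple[int, int] = (14, 30)
    occluder_density: float = 0.0       # expected occluder strips per scene
    lighting: str = "day"
    blur_sigma: float = 0.0
    min_visible_fraction: float = 0.25
    class_name: str = "apple"

    def __post_init__(self):
        if self.apple_count[0] > self.apple_count[1] or self.apple_count[0] < 0:
            raise SceneConfigError(f"empty apple count range {self.apple_count}")
        if self.radius[0] > self.radius[1] or self.radius[0] < 1:
            raise SceneConfigError(f"empty radius range {self.radius}")
        if 2 * self.radius[1] > self.image_size:
            raise SceneConfigError(
                f"apple diameter up to {2 * self.radius[1]} exceeds image size "
                f"{self.image_size}")
        if self.lighting not in LIGHTING_MODES:
            raise SceneConfigError(f"lighting must be one of {LIGHTING_MODES}")
        if not 0 < self.min_visible_fraction <= 1:
            raise SceneConfigError("min_visible_fraction must be in (0, 1]")


def _background(size: int, rng: np.random.Generator) -> np.ndarray:
    noise = rng.random((size, size, 3)).astype(np.float32)
    tex = ndimage.gaussian_filter(noise, (size / 20, size / 20, 0))
    tex = (tex - tex.min()) / max(np.ptp(tex), 1e-6)
    base = np.array([55, 95, 45], dtype=np.float32)       # foliage green
    img = base[None, None, :] * (0.6 + 0.8 * tex)
    return np.clip(img, 0, 255)


def _draw_apple(img: np.ndarray, mask: np.ndarray, cy: float, cx: float,
                ry: float, rx: float, rng: np.random.Generator) -> None:
    size = img.shape[0]
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    d = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    inside = d <= 1.0
    mask |= inside
    # radial shading toward the rim, slight per-apple color jitter
    shade = np.clip(1.0 - 0.55 * d, 0.35, 1.0)
    color = np.array([195 + rng.uniform(-25, 35), 35 + rng.uniform(0, 45),
                      35 + rng.uniform(0, 25)], dtype=np.float32)
    for ch in range(3):
        img[..., ch][inside] = color[ch] * shade[inside]
    # specular highlight in the upper-left quadrant
    hy, hx = cy - 0.35 * ry, cx - 0.35 * rx
    hd = ((yy - hy) / (0.3 * ry)) ** 2 + ((xx - hx) / (0.3 * rx)) ** 2
    spot = (hd <= 1.0) & inside
    img[spot] = np.clip(img[spot] + 140 * (1.0 - hd[spot, None]), 0, 255)


def _draw_occluder(img: np.ndarray, occ_mask: np.ndarray,
                   rng: np.random.Generator) -> None:
    """A branch-like strip: a quadratic bezier polyline with finite width."""
    size = img.shape[0]
    pts = rng.uniform(0, size, size=(3, 2))
    t = np.linspace(0, 1, 4 * size)[:, None]
    curve = ((1 - t) ** 2 * pts[0] + 2 * t * (1 - t) * pts[1] + t ** 2 * pts[2])
    width = rng.uniform(size / 40, size / 12)
    stroke = np.zeros((size, size), dtype=bool)
    ij = np.round(curve).astype(int)
    ij = ij[(ij[:, 0] >= 0) & (ij[:, 0] < size) & (ij[:, 1] >= 0) & (ij[:, 1] < size)]
    stroke[ij[:, 0], ij[:, 1]] = True
    stroke = ndimage.binary_dilation(stroke, iterations=max(1, int(width / 2)))
    occ_mask |= stroke
    color = np.array([90, 60, 30], dtype=np.float32) * rng.uniform(0.7, 1.2)
    img[stroke] = np.clip(color, 0, 255)


def _render(config: SceneConfig, seed: int):
    rng = np.random.default_rng(seed)
    size = config.image_size
    img = _background(size, rng)
    n_apples = int(rng.integers(config.apple_count[0], config.apple_count[1] + 1))
    apple_masks = []
    for _ in range(n_apples):
        r = rng.uniform(*config.radius)
        squash = rng.uniform(0.8, 1.2)
        ry, rx = r * squash, r / squash
        cy = rng.uniform(ry, size - ry)
        cx = rng.uniform(rx, size - rx)
        m = np.zeros((size, size), dtype=bool)
        _draw_apple(img, m, cy, cx, ry, rx, rng)
        apple_masks.append(m)
    # later apples occlude earlier ones
    covered = np.zeros((size, size), dtype=bool)
    visible_masks = []
    for m in reversed(apple_masks):
        visible_masks.append(m & ~covered)
        covered |= m
    visible_masks = visible_masks[::-1]

    occ = np.zeros((size, size), dtype=bool)
    n_occ = rng.poisson(config.occluder_density)
    for _ in range(n_occ):
        _draw_occluder(img, occ, rng)

    if config.lighting == "dark":
        img = img * 0.35
    elif config.lighting == "overexposed":
        img = np.clip(img * 1.7 + 30, 0, 255)
    if config.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, (config.blur_sigma,
                                            config.blur_sigma, 0))

    boxes: list[NormBox] = []
    kept_masks: list[np.ndarray] = []
    for full, vis in zip(apple_masks, visible_masks):
        vis = vis & ~occ
        total = int(full.sum())
        if total == 0:
            continue
        if vis.sum() / total < config.min_visible_fraction:
            continue
        ys, xs = np.nonzero(vis)
        x1, x2 = xs.min(), xs.max() + 1
        y1, y2 = ys.min(), ys.max() + 1
        boxes.append(NormBox(0, (x1 + x2) / 2 / size, (y1 + y2) / 2 / size,
                             (x2 - x1) / size, (y2 - y1) / size).validate())
        kept_masks.append(vis)
    return np.clip(img, 0, 255).astype(np.uint8), boxes, kept_masks


def generate_scene(config: SceneConfig, seed: int = 0):
    """Render one scene; returns (uint8 image, list of NormBox).

    Deterministic for a fixed (config, seed).  Boxes are tight to the visible
    extent of each apple after occlusion; apples with visible fraction below
    ``config.min_visible_fraction`` are dropped.
    """
    img, boxes, _ = _render(config, seed)
    return img, boxes


def scene_masks(config: SceneConfig, seed: int = 0):
    """Visible-pixel masks aligned with the boxes of :func:`generate_scene`."""
    return _render(config, seed)[2]


def generate_dataset(n: int, config: SceneConfig, seed: int, out_dir) -> dict:
    """Write ``n`` scenes as PNG + VOC XML + YOLO TXT with a JSON manifest."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    scene_seeds = [int(s) for s in root.integers(0, 2 ** 31, size=n)]
    entries = []
    for i, s in enumerate(scene_seeds):
        stem = f"scene_{i:05d}"
        img, boxes = generate_scene(config, s)
        write_image(out_dir / f"{stem}.png", img)
        write_yolo_txt(out_dir / f"{stem}.txt", boxes)
        ann = VOCAnnotation(filename=f"{stem}.png", width=config.image_size,
                            height=config.image_size, depth=3)
        sz = config.image_size
        for b in boxes:
            ann.objects.append(VOCObject(
                config.class_name,
                round((b.cx - b.w / 2) * sz), round((b.cy - b.h / 2) * sz),
                round((b.cx + b.w / 2) * sz), round((b.cy + b.h / 2) * sz)))
        write_voc_annotation(ann, out_dir / f"{stem}.xml")
        digest = hashlib.sha256(img.tobytes()).hexdigest()[:16]
        entries.append({"stem": stem, "seed": s, "n_boxes": len(boxes),
                        "sha256_16": digest})
    manifest = {"n": n, "seed": seed, "config": asdict(config),
                "scenes": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def easy_config(image_size: int = 160) -> SceneConfig:
    """Large, unoccluded, high-contrast apples — a solvable smoke benchmark.

    At most two apples per scene and a high visibility floor keep sliver
    boxes (mostly-hidden apples) out of the ground truth."""
    r_hi = max(3, image_size // 4)
    r_lo = max(2, image_size // 8)
    return SceneConfig(image_size=image_size, apple_count=(1, 2),
                       radius=(r_lo, r_hi), occluder_density=0.0,
                       lighting="day", blur_sigma=0.0,
                       min_visible_fraction=0.6)
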