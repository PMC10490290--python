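"""Training and evaluation: CIoU + BCE detection loss, anchor target
assignment, cosine learning-rate schedule, the SGD training loop and the
precision/recall/F1/AP/mAP metric suite.

Conventions (documented choices):

* AP integrates the precision-recall curve with all-point interpolation
  (monotone precision envelope, exact sum of recall-step areas); a 101-point
  variant is available behind a flag.
* Zero-denominator rules: precision = 0 when there are no detections,
  recall = 0 when there are no matches.
* With a single class the BCE class term is retained (weight configurable)
  so the loss keeps its three components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import SGD, Tensor, bce_with_logits, concat, no_grad
from .data_io import NormBox
from .model_builder import (Detection, Model, STRIDES, box_iou_xyxy,
                            decode_predictions)


@dataclass
class TrainParams:
    lr0: float = 0.01
    lr_floor: float = 0.0001
    weight_decay: float = 0.0001
    momentum: float = 0.937
    batch: int = 12
    epochs: int = 200
    conf_thr: float = 0.25
    iou_thr: float = 0.5
    input_size: int = 640
    nc: int = 1
    box_weight: float = 0.05
    obj_weight: float = 1.0
    cls_weight: float = 0.5
    anchor_t: float = 4.0
    obj_balance: tuple = (4.0, 1.0, 0.4)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __iadd__(self, other):
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        return self


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    ap50: float
    map50_95: float
    n_classes: int = 1
    counts: ConfusionCounts = field(default_factory=ConfusionCounts)

    def as_dict(self) -> dict:
        d = asdict(self)
        return d


# ---------------------------------------------------------------------------
# CIoU
# ---------------------------------------------------------------------------

_EPS = 1e-9


def _ciou_tensor(pred: Tensor, target: np.ndarray) -> Tensor:
    """Batched CIoU of center/size boxes; pred (n,4) Tensor, target (n,4)."""
    t = np.asarray(target, dtype=np.float32)
    px, py, pw, ph = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    tx, ty, tw, th = t[:, 0], t[:, 1], t[:, 2], t[:, 3]

    p_x1, p_x2 = px - pw * 0.5, px + pw * 0.5
    p_y1, p_y2 = py - ph * 0.5, py + ph * 0.5
    t_x1, t_x2 = tx - tw * 0.5, tx + tw * 0.5
    t_y1, t_y2 = ty - th * 0.5, ty + th * 0.5

    iw = p_x2.minimum(t_x2) - p_x1.maximum(t_x1)
    ih = p_y2.minimum(t_y2) - p_y1.maximum(t_y1)
    inter = iw.clamp(0) * ih.clamp(0)
    union = pw * ph + tw * th - inter
    iou = inter / (union + _EPS)

    cw = p_x2.maximum(t_x2) - p_x1.minimum(t_x1)
    chh = p_y2.maximum(t_y2) - p_y1.minimum(t_y1)
    c2 = cw * cw + chh * chh + _EPS
    rho2 = (px - tx) ** 2 + (py - ty) ** 2

    atan_t = np.arctan(tw / np.maximum(th, _EPS))
    v = (4.0 / math.pi ** 2) * ((pw / (ph + _EPS)).arctan() - atan_t) ** 2
    with np.errstate(all="ignore"):
        alpha = v.data / (1.0 - iou.data + v.data + _EPS)   # no grad through alpha
    return iou - rho2 / c2 - Tensor(alpha) * v


def ciou_loss(pred_box, target_box) -> float:
    """1 - CIoU for a single pair of (cx, cy, w, h) boxes; 0 iff identical.

    CIoU = IoU - rho^2 / c^2 - alpha * v, with rho the center distance, c the
    enclosing-box diagonal, v the aspect-ratio penalty and
    alpha = v / (1 - IoU + v).  Evaluated in float64.
    """
    px, py, pw, ph = map(float, pred_box)
    tx, ty, tw, th = map(float, target_box)
    if pw <= 0 or ph <= 0 or tw <= 0 or th <= 0:
        raise ValueError("boxes must have positive width and height")
    iw = min(px + pw / 2, tx + tw / 2) - max(px - pw / 2, tx - tw / 2)
    ih = min(py + ph / 2, ty + th / 2) - max(py - ph / 2, ty - th / 2)
    inter = max(iw, 0.0) * max(ih, 0.0)
    union = pw * ph + tw * th - inter
    iou = inter / union
    cw = max(px + pw / 2, tx + tw / 2) - min(px - pw / 2, tx - tw / 2)
    ch = max(py + ph / 2, ty + th / 2) - min(py - ph / 2, ty - th / 2)
    rho2 = (px - tx) ** 2 + (py - ty) ** 2
    c2 = cw ** 2 + ch ** 2
    v = (4.0 / math.pi ** 2) * (math.atan(tw / th) - math.atan(pw / ph)) ** 2
    alpha = v / (1.0 - iou + v) if v > 0 else 0.0
    return 1.0 - (iou - rho2 / c2 - alpha * v)


# ---------------------------------------------------------------------------
# target assignment
# ---------------------------------------------------------------------------

def build_targets(gt_per_image, anchors, img_size: int,
                  anchor_t: float = 4.0, neighbor_cells: bool = True):
    """Assign normalized GT boxes to anchors and grid cells per scale.

    Returns one dict per scale with index arrays ``b`` (image), ``a``
    (anchor), ``gj``/``gi`` (cell row/col) and the matched GT boxes in grid
    units (``txy`` absolute center, ``twh`` size) plus ``tcls``.  A GT box is
    assigned to every anchor whose w/h ratio test max(r, 1/r) < anchor_t at
    its own cell and, optionally, the two nearest neighbor cells.
    """
    anchors = np.asarray(anchors, dtype=np.float32)
    out = []
    # gather all gt rows: (img, cls, cx, cy, w, h) normalized
    rows = []
    for b, boxes in enumerate(gt_per_image):
        for box in boxes:
            cid, cx, cy, w, h = (box.as_tuple() if isinstance(box, NormBox)
                                 else tuple(box))
            rows.append((b, cid, cx, cy, w, h))
    gt = np.asarray(rows, dtype=np.float32).reshape(-1, 6)
    for scale, stride in enumerate(STRIDES):
        gw = img_size // stride
        a_grid = anchors[scale] / stride                    # anchor wh, grid units
        res = {"b": [], "a": [], "gj": [], "gi": [], "txy": [], "twh": [],
               "tcls": []}
        if gw < 1:
            out.append({k: np.asarray(v) for k, v in res.items()})
            continue
        for b, cid, cx, cy, w, h in gt:
            xy = np.array([cx, cy]) * gw
            wh = np.array([w, h]) * gw
            for ai, awh in enumerate(a_grid):
                r = wh / awh
                if max(r.max(), (1.0 / r).max()) >= anchor_t:
                    continue
                cells = [(int(xy[0]), int(xy[1]))]
                if neighbor_cells:
                    fx, fy = xy % 1.0
                    gi0, gj0 = int(xy[0]), int(xy[1])
                    if fx < 0.5 and xy[0] > 1:
                        cells.append((gi0 - 1, gj0))
                    if fx >= 0.5 and xy[0] < gw - 1:
                        cells.append((gi0 + 1, gj0))
                    if fy < 0.5 and xy[1] > 1:
                        cells.append((gi0, gj0 - 1))
                    if fy >= 0.5 and xy[1] < gw - 1:
                        cells.append((gi0, gj0 + 1))
                for gi, gj in cells:
                    gi = min(max(gi, 0), gw - 1)
                    gj = min(max(gj, 0), gw - 1)
                    res["b"].append(int(b))
                    res["a"].append(ai)
                    res["gj"].append(gj)
                    res["gi"].append(gi)
                    res["txy"].append(xy)
                    res["twh"].append(wh)
                    res["tcls"].append(int(cid))
        out.append({k: np.asarray(v) for k, v in res.items()})
    return out


# ---------------------------------------------------------------------------
# detection loss
# ---------------------------------------------------------------------------

def detection_loss(preds, targets, anchors, params: TrainParams):
    """Weighted CIoU box + BCE objectness + BCE class loss.

    ``preds`` is the list of per-scale (N, 3, H, W, 5+nc) Tensors; ``targets``
    comes from :func:`build_targets`.  Returns (scalar Tensor, components
    dict with plain floats).
    """
    anchors = np.asarray(anchors, dtype=np.float32)
    n_batch = preds[0].shape[0]
    box_terms, cls_terms = [], []
    obj_loss = None
    n_matched = 0
    for scale, (p, t) in enumerate(zip(preds, targets)):
        n, na, hh, ww, no = p.shape
        tobj = np.zeros((n, na, hh, ww), dtype=np.float32)
        if len(t["b"]):
            key = (t["b"], t["a"], t["gj"], t["gi"])
            ps = p[key]                                     # (m, 5+nc)
            if ps.shape[-1] != 5 + params.nc:
                raise ValueError(
                    f"prediction depth {ps.shape[-1]} != 5 + nc={params.nc}")
            cell = np.stack([t["gi"], t["gj"]], axis=1)   # (x, y) cell origins
            pxy = ps[:, 0:2].sigmoid() * 2.0 - 0.5 + Tensor(cell.astype(np.float32))
            a_wh = anchors[scale][t["a"]] / STRIDES[scale]
            pwh = (ps[:, 2:4].sigmoid() * 2.0) ** 2 * Tensor(a_wh)
            pbox = concat([pxy, pwh], axis=1)
            tbox = np.concatenate([t["txy"], t["twh"]], axis=1)
            ciou = _ciou_tensor(pbox, tbox)
            box_terms.append((1.0 - ciou).mean())
            tobj[key] = np.clip(ciou.data, 0, None)
            n_matched += len(t["b"])
            if params.nc >= 1:
                tcls = np.zeros((len(t["b"]), params.nc), dtype=np.float32)
                tcls[np.arange(len(t["b"])), t["tcls"]] = 1.0
                cls_terms.append(bce_with_logits(ps[:, 5:], tcls).mean())
        scale_obj = bce_with_logits(p[:, :, :, :, 4], tobj).mean()
        term = scale_obj * float(params.obj_balance[scale])
        obj_loss = term if obj_loss is None else obj_loss + term
    zero = Tensor(np.zeros(()))
    box_loss = sum(box_terms, zero) * (1.0 / max(len(box_terms), 1))
    cls_loss = sum(cls_terms, zero) * (1.0 / max(len(cls_terms), 1))
    total = (box_loss * params.box_weight + obj_loss * params.obj_weight
             + cls_loss * params.cls_weight) * float(n_batch)
    components = {"box": float(box_loss.data), "obj": float(obj_loss.data),
                  "cls": float(cls_loss.data), "total": float(total.data),
                  "n_matched": n_matched}
    return total, components


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def cosine_lr(epoch: int, params: TrainParams) -> float:
    """Cosine annealing from lr0 at epoch 0 to lr_floor at the final epoch."""
    if not 0 <= epoch <= params.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {params.epochs}]")
    span = params.lr0 - params.lr_floor
    return params.lr_floor + span * (1.0 + math.cos(math.pi * epoch / params.epochs)) / 2.0


# ---------------------------------------------------------------------------
# matching and metrics
# ---------------------------------------------------------------------------

def _det_box_conf(d):
    if isinstance(d, Detection):
        return np.asarray(d.box, dtype=float), d.confidence
    box, conf = d[0], d[1]
    return np.asarray(box, dtype=float), float(conf)


def match_detections(detections, ground_truth, iou_threshold: float) -> ConfusionCounts:
    """Greedy one-to-one matching at one IoU threshold.

    Detections are processed in descending confidence; each claims the
    unmatched GT box of highest IoU if that IoU reaches the threshold,
    otherwise it is a false positive.  Unclaimed GT boxes are false negatives.
    """
    gt = np.asarray(ground_truth, dtype=float).reshape(-1, 4)
    dets = sorted((( _det_box_conf(d)) for d in detections),
                  key=lambda bc: -bc[1])
    counts = ConfusionCounts(fn=len(gt))
    if not dets:
        return counts
    taken = np.zeros(len(gt), dtype=bool)
    for box, _ in dets:
        if len(gt) == 0:
            counts.fp += 1
            continue
        iou = box_iou_xyxy(box[None], gt)[0]
        iou[taken] = -1.0
        j = int(iou.argmax())
        if iou[j] >= iou_threshold:
            taken[j] = True
            counts.tp += 1
            counts.fn -= 1
        else:
            counts.fp += 1
    return counts


def precision_recall_f1(counts: ConfusionCounts) -> tuple[float, float, float]:
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def _match_records(per_image, iou_threshold: float):
    """(confidence, is_tp) records across a dataset plus the GT count.

    ``per_image`` is a list of (detections, gt_boxes_xyxy) pairs.  Detections
    are ranked globally by confidence; matching is greedy one-to-one within
    each image, highest-IoU-first, the standard AP protocol.
    """
    records = []
    n_gt = 0
    for dets, gts in per_image:
        gt = np.asarray(gts, dtype=float).reshape(-1, 4)
        n_gt += len(gt)
        taken = np.zeros(len(gt), dtype=bool)
        for d in sorted(dets, key=lambda d: -_det_box_conf(d)[1]):
            box, conf = _det_box_conf(d)
            tp = False
            if len(gt):
                iou = box_iou_xyxy(box[None], gt)[0]
                iou[taken] = -1.0
                j = int(iou.argmax())
                if iou[j] >= iou_threshold:
                    taken[j] = True
                    tp = True
            records.append((conf, tp))
    return records, n_gt


def ap_from_pr(per_image, iou_threshold: float = 0.5,
               interpolation: str = "all") -> float:
    """Average precision at one IoU threshold over a dataset.

    ``per_image``: list of (detections, gt_boxes_xyxy).  ``interpolation`` is
    "all" (exact area under the monotone precision envelope) or "101" (COCO
    style sampling at 101 recall points).
    """
    records, n_gt = _match_records(per_image, iou_threshold)
    if n_gt == 0:
        raise ValueError("AP undefined without ground-truth boxes")
    return ap_from_records(records, n_gt, interpolation)


def ap_from_records(records, n_gt: int, interpolation: str = "all") -> float:
    """AP from (confidence, is_tp) records and the ground-truth count."""
    if n_gt <= 0:
        raise ValueError("AP undefined without ground-truth boxes")
    if not records:
        return 0.0
    order = sorted(range(len(records)), key=lambda i: -records[i][0])
    tp = np.array([records[i][1] for i in order], dtype=float)
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
    # monotone envelope
    r = np.concatenate([[0.0], recall, [recall[-1]]])
    p = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    if interpolation == "101":
        grid = np.linspace(0, 1, 101)
        idx = np.searchsorted(r, grid, side="left")
        vals = np.where(idx < len(p), p[np.minimum(idx, len(p) - 1)], 0.0)
        vals[grid > recall[-1]] = 0.0
        return float(vals.mean())
    steps = np.nonzero(np.diff(r))[0]
    return float(np.sum((r[steps + 1] - r[steps]) * p[steps + 1]))


def map50_95(aps) -> float:
    """Mean of the APs computed at IoU 0.50 : 0.05 : 0.95 (ten thresholds)."""
    aps = list(aps)
    if len(aps) != 10:
        raise ValueError(f"expected 10 AP values (0.5:0.05:0.95), got {len(aps)}")
    return float(np.mean(aps))


IOU_SWEEP = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))


def evaluate_detections(per_image, params: TrainParams) -> MetricsReport:
    """Full metric suite from decoded detections and GT corner boxes."""
    counts = ConfusionCounts()
    for dets, gts in per_image:
        strong = [d for d in dets if _det_box_conf(d)[1] >= params.conf_thr]
        counts += match_detections(strong, gts, params.iou_thr)
    p, r, f1 = precision_recall_f1(counts)
    aps = [ap_from_pr(per_image, thr) for thr in IOU_SWEEP]
    return MetricsReport(precision=p, recall=r, f1=f1, ap50=aps[0],
                         map50_95=map50_95(aps), n_classes=params.nc,
                         counts=counts)


def _boxes_to_xyxy(boxes, size: int) -> np.ndarray:
    arr = np.array([[b.cx - b.w / 2, b.cy - b.h / 2, b.cx + b.w / 2,
                     b.cy + b.h / 2] for b in boxes], dtype=float).reshape(-1, 4)
    return arr * size


def evaluate_model(model: Model, dataset, params: TrainParams,
                   decode_conf: float = 0.001) -> MetricsReport:
    """Run the detector over (image, boxes) samples and score it.

    Decoding uses a low confidence floor so the PR curve is fully swept;
    precision/recall/F1 are computed at ``params.conf_thr``.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    model.eval()
    per_image = []
    with no_grad():
        for img, boxes in dataset:
            x = _image_to_input(img, params.input_size)
            raw = model(x[None])
            dets = decode_predictions(raw, model.config, conf_thr=decode_conf,
                                      iou_thr=params.iou_thr)[0]
            gts = _boxes_to_xyxy(boxes, params.input_size)
            per_image.append((dets, gts))
    return evaluate_detections(per_image, params)


def _image_to_input(img: np.ndarray, size: int) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim == 3 and arr.shape[-1] == 3:
        arr = arr.transpose(2, 0, 1)
    if arr.shape[1] != size or arr.shape[2] != size:
        yi = (np.arange(size) * arr.shape[1] / size).astype(int)
        xi = (np.arange(size) * arr.shape[2] / size).astype(int)
        arr = arr[:, yi][:, :, xi]
    return np.ascontiguousarray(arr, dtype=np.float32) / 255.0


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train_model(model: Model, train_set, val_set, params: TrainParams,
                seed: int = 0, warm_start: str | None = None,
                eval_every: int = 0, verbose: bool = False):
    """SGD training with cosine LR; returns (model, history).

    ``train_set``/``val_set`` are lists of (uint8 HWC image, list[NormBox]).
    ``warm_start`` optionally names a checkpoint to load before training
    (the transfer-learning hook; nothing is downloaded).  History rows carry
    per-epoch mean loss components and, if ``eval_every`` > 0, periodic
    validation metrics.
    """
    if not train_set:
        raise ValueError("training set is empty")
    if warm_start:
        state = Model.load(warm_start).state_dict()
        model.load_state_dict(state)
    rng = np.random.default_rng(seed)
    opt = SGD(model.parameters(), lr=params.lr0, momentum=params.momentum,
              weight_decay=params.weight_decay)
    anchors = np.asarray(model.config.anchors, dtype=np.float32)
    history = []
    for epoch in range(params.epochs):
        lr = cosine_lr(epoch, params)
        opt.lr = lr
        model.train()
        order = rng.permutation(len(train_set))
        sums = {"box": 0.0, "obj": 0.0, "cls": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, len(order), params.batch):
            idx = order[start:start + params.batch]
            imgs = np.stack([_image_to_input(train_set[i][0], params.input_size)
                             for i in idx])
            gts = [train_set[i][1] for i in idx]
            preds = model(imgs)
            targets = build_targets(gts, anchors, params.input_size,
                                    params.anchor_t)
            loss, comps = detection_loss(preds, targets, anchors, params)
            if not math.isfinite(comps["total"]):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {comps}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            for k in sums:
                sums[k] += comps[k]
            n_batches += 1
        row = {"epoch": epoch, "lr": lr,
               **{k: v / n_batches for k, v in sums.items()}}
        if eval_every and val_set and (epoch + 1) % eval_every == 0:
            rep = evaluate_model(model, val_set, params)
            row["val_ap50"] = rep.ap50
        history.append(row)
        if verbose:
            print(f"epoch {epoch:3d} lr {lr:.5f} "
                  + " ".join(f"{k} {row[k]:.4f}" for k in ("box", "obj", "cls")))
    return model, history
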