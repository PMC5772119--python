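"""Ground-truth matching for synthetic-slide benchmarks.

Matches detected particles to ground-truth objects by intersection-over-union
(IoU) so that recovery and false-detection rates can be computed on slides
where the exact object masks are known.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["iou_matrix", "match_to_ground_truth", "recovery_stats"]


def iou_matrix(gt_labels: np.ndarray, pred_labels: np.ndarray) -> pd.DataFrame:
    """IoU per (ground-truth label, predicted label) pair that overlaps.

    Computed from the joint histogram of the two label maps; rows
    (gt_label, pred_label, intersection, union, iou).
    """
    gt = np.asarray(gt_labels).ravel()
    pred = np.asarray(pred_labels).ravel()
    sel = (gt > 0) | (pred > 0)
    gt, pred = gt[sel], pred[sel]
    gt_counts = dict(zip(*np.unique(gt[gt > 0], return_counts=True)))
    pred_counts = dict(zip(*np.unique(pred[pred > 0], return_counts=True)))
    both = (gt > 0) & (pred > 0)
    key = gt[both].astype(np.int64) * (int(pred.max()) + 1) + pred[both]
    pairs, inter = np.unique(key, return_counts=True)
    rows = []
    base = int(pred.max()) + 1
    for k, i in zip(pairs, inter):
        g, p = int(k // base), int(k % base)
        union = gt_counts[g] + pred_counts[p] - i
        rows.append({"gt_label": g, "pred_label": p,
                     "intersection": int(i), "union": int(union),
                     "iou": float(i) / float(union)})
    return pd.DataFrame(rows, columns=["gt_label", "pred_label",
                                       "intersection", "union", "iou"])


def match_to_ground_truth(gt_labels: np.ndarray, pred_labels: np.ndarray,
                          iou_min: float = 0.7) -> pd.DataFrame:
    """Greedy one-to-one matching by descending IoU.

    Returns one row per ground-truth object: (gt_label, pred_label, iou,
    matched) where matched requires IoU ≥ ``iou_min``.
    """
    pairs = iou_matrix(gt_labels, pred_labels)
    pairs = pairs.sort_values("iou", ascending=False)
    used_pred: set[int] = set()
    best: dict[int, tuple[int, float]] = {}
    for _, row in pairs.iterrows():
        g, p = int(row["gt_label"]), int(row["pred_label"])
        if g in best or p in used_pred:
            continue
        best[g] = (p, float(row["iou"]))
        used_pred.add(p)
    rows = []
    for g in [int(v) for v in np.unique(gt_labels) if v > 0]:
        p, iou = best.get(g, (0, 0.0))
        rows.append({"gt_label": g, "pred_label": p, "iou": iou,
                     "matched": iou >= iou_min})
    return pd.DataFrame(rows, columns=["gt_label", "pred_label", "iou", "matched"])


def recovery_stats(truth, pred_labels: np.ndarray,
                   kinds: tuple[str, ...] = ("pellet", "fragment"),
                   iou_min: float = 0.7) -> dict:
    """Recovery and false-detection rates for one slide.

    ``truth`` is a GroundTruth; only ground-truth objects of the given kinds
    count as true particles.  A detected particle that matches no true
    object at IoU ≥ ``iou_min`` is a false detection.
    """
    true_labels = set(truth.labels_of_kind(*kinds))
    matches = match_to_ground_truth(truth.label_map, pred_labels, iou_min)
    true_rows = matches[matches["gt_label"].isin(true_labels)]
    n_true = len(true_rows)
    n_recovered = int(true_rows["matched"].sum())
    matched_preds = set(true_rows.loc[true_rows["matched"], "pred_label"])
    pred_ids = {int(v) for v in np.unique(pred_labels) if v > 0}
    n_false = len(pred_ids - matched_preds)
    return {
        "n_true": n_true,
        "n_recovered": n_recovered,
        "n_detected": len(pred_ids),
        "n_false": n_false,
    }
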