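"""Voxel- and lesion-level evaluation metrics.

Voxel level: Dice similarity coefficient (DSC), false-negative volume (FNV),
false-positive volume (FPV) and total metabolic tumour volume (TMTV), plus
Bland-Altman agreement between ground-truth and predicted TMTV.  FNV/FPV are
component-based: a ground-truth lesion contributes to FNV only if *no*
predicted component overlaps it, and a predicted component contributes to FPV
only if it overlaps no ground-truth lesion.

Lesion level: detection sensitivity (TP / ground-truth lesions) and precision
(TP / predicted components), per T/N/M category and pooled, and a taxonomy
tally of false positives by etiology class (physiologic / benign /
pathologic).

All percentages are rounded to one decimal, half away from zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CATEGORIES, LabelVolume, require_same_grid
from .lesion_analysis import Lesion, MatchResult


def round_pct(x: float, decimals: int = 1) -> float:
    """Round half away from zero (so 67.65 -> 67.7, not banker's 67.6)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    factor = 10**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class VoxelMetrics:
    dsc: float
    fnv_ml: float
    fpv_ml: float
    tmtv_gt_ml: float
    tmtv_pred_ml: float


@dataclass
class BlandAltmanResult:
    """Mean difference (bias) and limits of agreement (bias ± 1.96 sample SD)."""

    bias_ml: float
    loa_low_ml: float
    loa_high_ml: float
    n: int


def dice(gt_mask, pred_mask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) over binarized masks.

    Two empty masks are scored 1.0 (a correct negative), with a warning since
    the value is a convention rather than a measurement.
    """
    if isinstance(gt_mask, LabelVolume) and isinstance(pred_mask, LabelVolume):
        require_same_grid(gt_mask, pred_mask)
        a, b = gt_mask.binarized(), pred_mask.binarized()
    else:
        a = np.asarray(gt_mask) > 0
        b = np.asarray(pred_mask) > 0
        if a.shape != b.shape:
            raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        warnings.warn("dice of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def tmtv(lesions: list[Lesion]) -> float:
    """Total metabolic tumour volume: sum of lesion volumes in mL."""
    return float(sum(l.volume_ml for l in lesions))


def fnv(gt_lesions: list[Lesion], match: MatchResult) -> float:
    """Summed volume (mL) of ground-truth lesions with no overlapping prediction."""
    return float(sum(l.volume_ml for l in gt_lesions if l.lesion_id in match.fn_ids))


def fpv(pred_lesions: list[Lesion], match: MatchResult) -> float:
    """Summed volume (mL) of predicted components with no ground-truth overlap."""
    return float(sum(l.volume_ml for l in pred_lesions if l.lesion_id in match.fp_ids))


def voxel_metrics(gt_mask, pred_mask, gt_lesions, pred_lesions, match) -> VoxelMetrics:
    return VoxelMetrics(
        dsc=dice(gt_mask, pred_mask),
        fnv_ml=fnv(gt_lesions, match),
        fpv_ml=fpv(pred_lesions, match),
        tmtv_gt_ml=tmtv(gt_lesions),
        tmtv_pred_ml=tmtv(pred_lesions),
    )


def bland_altman(pairs) -> BlandAltmanResult:
    """Bland-Altman agreement for paired (gt, pred) TMTV values.

    Bias is mean(pred - gt); limits of agreement are bias ± 1.96 × sample
    (n−1) standard deviation of the differences.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("Bland-Altman requires at least 2 pairs")
    diffs = np.array([p - g for g, p in pairs], dtype=float)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(bias, bias - 1.96 * sd, bias + 1.96 * sd, len(diffs))


# ---------------------------------------------------------------------------
# lesion-level detection statistics


@dataclass
class DetectionStats:
    """Per-category and pooled detection counts with sensitivity/precision.

    ``table`` is indexed by category (T, N, M, pooled) with columns tp, fn,
    fp, sensitivity, precision and one-decimal percentage versions.  The
    pooled row is a micro-average over summed counts; ``macro_sensitivity``
    (mean of per-patient sensitivities, when patient-wise input was given) is
    reported alongside because pooled figures are sometimes averaged that way.
    A category with zero ground-truth lesions has undefined (NaN) sensitivity,
    never 0.
    """

    table: pd.DataFrame
    macro_sensitivity: float | None = None


def _stats_row(tp: int, fn: int, fp: int) -> dict:
    sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    prec = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    return {
        "tp": tp,
        "fn": fn,
        "fp": fp,
        "sensitivity": sens,
        "precision": prec,
        "sensitivity_pct": round_pct(100 * sens) if not math.isnan(sens) else float("nan"),
        "precision_pct": round_pct(100 * prec) if not math.isnan(prec) else float("nan"),
    }


def detection_stats_from_counts(counts: pd.DataFrame) -> DetectionStats:
    """Detection statistics from a per-category count table (tp, fn, fp)."""
    rows = {}
    for r in counts.itertuples():
        rows[r.category] = _stats_row(int(r.tp), int(r.fn), int(r.fp))
    rows["pooled"] = _stats_row(
        int(counts["tp"].sum()), int(counts["fn"].sum()), int(counts["fp"].sum())
    )
    return DetectionStats(pd.DataFrame(rows).T)


def detection_stats(cases, categories=CATEGORIES) -> DetectionStats:
    """Micro-averaged detection statistics over categorized match results.

    ``cases`` is an iterable of (gt_lesions, pred_lesions, match) triples, one
    per patient, where lesions carry their T/N/M category.  Sensitivity counts
    detected ground-truth lesions; precision counts matched predicted
    components, so a merged component detecting several lesions contributes
    once to precision's denominator.
    """
    counts = {c: {"tp": 0, "fn": 0, "fp": 0, "tp_pred": 0} for c in categories}
    per_patient_sens = []
    for gt_lesions, pred_lesions, match in cases:
        gt_by_id = {l.lesion_id: l for l in gt_lesions}
        pred_by_id = {l.lesion_id: l for l in pred_lesions}
        det = match.detected_gt_ids
        for l in gt_lesions:
            if l.category not in counts:
                continue
            counts[l.category]["tp" if l.lesion_id in det else "fn"] += 1
        for pid in match.matched_pred_ids:
            cat = pred_by_id[pid].category
            if cat in counts:
                counts[cat]["tp_pred"] += 1
        for pid in match.fp_ids:
            cat = pred_by_id[pid].category
            if cat in counts:
                counts[cat]["fp"] += 1
        n_gt = len(gt_lesions)
        if n_gt:
            per_patient_sens.append(len(det) / n_gt)

    rows = {}
    for c in categories:
        tp, fn, fp = counts[c]["tp"], counts[c]["fn"], counts[c]["fp"]
        tp_pred = counts[c]["tp_pred"]
        row = _stats_row(tp, fn, fp)
        prec = tp_pred / (tp_pred + fp) if (tp_pred + fp) > 0 else float("nan")
        row["precision"] = prec
        row["precision_pct"] = round_pct(100 * prec) if not math.isnan(prec) else float("nan")
        rows[c] = row
    tp = sum(counts[c]["tp"] for c in categories)
    fn = sum(counts[c]["fn"] for c in categories)
    fp = sum(counts[c]["fp"] for c in categories)
    tp_pred = sum(counts[c]["tp_pred"] for c in categories)
    pooled = _stats_row(tp, fn, fp)
    prec = tp_pred / (tp_pred + fp) if (tp_pred + fp) > 0 else float("nan")
    pooled["precision"] = prec
    pooled["precision_pct"] = round_pct(100 * prec) if not math.isnan(prec) else float("nan")
    rows["pooled"] = pooled
    macro = float(np.mean(per_patient_sens)) if per_patient_sens else None
    return DetectionStats(pd.DataFrame(rows).T, macro_sensitivity=macro)


# ---------------------------------------------------------------------------
# false-positive etiology taxonomy


@dataclass
class TaxonomyTally:
    """Counts and shares of false positives by etiology class and label."""

    by_class: pd.DataFrame  # index: class; columns: n, share_pct
    by_label: pd.DataFrame  # columns: etiology_class, etiology, n
    total: int


def taxonomy_tally(fp_lesions: list[Lesion]) -> TaxonomyTally:
    """Tally false-positive lesions by etiology class.

    Lesions without an etiology class are counted under "unannotated" rather
    than silently dropped.  Shares are one-decimal percentages of the total
    false-positive count.
    """
    classes, labels = [], []
    for l in fp_lesions:
        cls = l.etiology_class if l.etiology_class else "unannotated"
        classes.append(cls)
        labels.append((cls, l.etiology or "unannotated"))
    total = len(fp_lesions)
    order = ["physiologic", "benign", "pathologic", "unannotated"]
    counts = pd.Series(classes, dtype=object).value_counts() if classes else pd.Series(dtype=int)
    by_class = pd.DataFrame(
        {
            "n": [int(counts.get(c, 0)) for c in order],
            "share_pct": [
                round_pct(100 * counts.get(c, 0) / total) if total else float("nan")
                for c in order
            ],
        },
        index=order,
    )
    by_class = by_class[by_class["n"] > 0]
    by_label = (
        pd.DataFrame(labels, columns=["etiology_class", "etiology"])
        .value_counts()
        .rename("n")
        .reset_index()
        .sort_values(["etiology_class", "n"], ascending=[True, False])
        .reset_index(drop=True)
        if labels
        else pd.DataFrame(columns=["etiology_class", "etiology", "n"])
    )
    return TaxonomyTally(by_class=by_class, by_label=by_label, total=total)
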