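"""Lesion extraction, ground-truth/prediction matching, and categorization.

A *lesion* is one connected component of a positive label under a chosen 3D
adjacency (6, 18 or 26 neighbours).  Every predicted component counts as a
distinct lesion irrespective of size — no minimum-volume filter is applied.

Matching is overlap-based: a predicted component is a true positive if it
shares at least ``min_overlap_voxels`` with any ground-truth lesion, and a
ground-truth lesion is detected if any predicted component overlaps it.  One
predicted component overlapping several ground-truth lesions (e.g. a central
tumour fused with hilar nodes) detects all of them but is recorded as a merge
event; it still contributes only once to precision's denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import pdist

from .io_formats import (
    FormatError,
    LabelVolume,
    parse_invasion_flags,
    require_same_grid,
)

GROUND_TRUTH = "ground_truth"
PREDICTED = "predicted"

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class Lesion:
    """One connected component with clinical annotations.

    ``lesion_id`` is a deterministic sequential id (scan order of the first
    voxel); ``label_value`` keeps the original mask value so instance-labelled
    ground truth can be joined to its sidecar table.
    """

    lesion_id: int
    source: str
    voxel_count: int
    volume_ml: float
    label_value: int = 1
    coords: np.ndarray | None = None  # (n, 3) voxel indices
    grid_shape: tuple[int, int, int] | None = None
    category: str | None = None
    station_or_organ: str | None = None
    diameter_mm: float | None = None
    etiology_class: str | None = None
    etiology: str | None = None
    invasion_flags: tuple[str, ...] = ()


@dataclass
class MatchResult:
    """TP/FP/FN partition of ground-truth and predicted lesions.

    Invariants: every ground-truth lesion is either detected (appears in some
    ``tp_pairs``) or in ``fn_ids``; every predicted component is either
    matched or in ``fp_ids``.
    """

    tp_pairs: set[tuple[int, int]] = field(default_factory=set)
    fn_ids: set[int] = field(default_factory=set)
    fp_ids: set[int] = field(default_factory=set)
    merge_events: list[tuple[int, tuple[int, ...]]] = field(default_factory=list)
    overlap_voxels: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def detected_gt_ids(self) -> set[int]:
        return {g for g, _ in self.tp_pairs}

    @property
    def matched_pred_ids(self) -> set[int]:
        return {p for _, p in self.tp_pairs}


def extract_components(
    mask: LabelVolume, connectivity: int = 26, source: str = PREDICTED
) -> list[Lesion]:
    """Decompose a mask into lesions, one per connected component per label.

    Components are ordered (and numbered from 1) by the scan-order position of
    their first voxel, which makes the ids deterministic for a given mask and
    connectivity.
    """
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    voxels = mask.voxels
    found: list[tuple[int, int, np.ndarray]] = []  # (first_flat, label_value, coords)
    for value in np.unique(voxels):
        if value <= 0:
            continue
        labeled, n = ndimage.label(voxels == value, structure=_STRUCTS[connectivity])
        for comp in range(1, n + 1):
            coords = np.argwhere(labeled == comp)
            first_flat = int(np.ravel_multi_index(coords[0], voxels.shape))
            found.append((first_flat, int(value), coords))
    found.sort(key=lambda t: t[0])
    lesions = []
    for i, (_, value, coords) in enumerate(found, start=1):
        lesions.append(
            Lesion(
                lesion_id=i,
                source=source,
                voxel_count=len(coords),
                volume_ml=mask.volume_ml(len(coords)),
                label_value=value,
                coords=coords,
                grid_shape=mask.shape,
            )
        )
    return lesions


def _label_array(lesions: list[Lesion], shape) -> np.ndarray:
    arr = np.zeros(shape, dtype=np.int32)
    for les in lesions:
        arr[tuple(les.coords.T)] = les.lesion_id
    return arr


def match_lesions(
    gt: list[Lesion],
    pred: list[Lesion],
    min_overlap_voxels: int = 1,
    iou_threshold: float | None = None,
) -> MatchResult:
    """Partition lesions into TP pairs, false negatives and false positives.

    ``min_overlap_voxels`` is the qualifying overlap (default 1, the
    zero-overlap definition used by component-based FPV/FNV metrics).  An
    optional IoU threshold can be layered on top; it is off by default.
    """
    shapes = {l.grid_shape for l in gt + pred if l.grid_shape is not None}
    if len(shapes) > 1:
        raise FormatError(f"grid mismatch between lesion sets: {shapes}")
    result = MatchResult()
    if not gt or not pred:
        result.fn_ids = {l.lesion_id for l in gt}
        result.fp_ids = {l.lesion_id for l in pred}
        return result
    shape = shapes.pop()
    gt_arr = _label_array(gt, shape)
    pred_by_id = {l.lesion_id: l for l in pred}
    gt_by_id = {l.lesion_id: l for l in gt}

    overlaps: dict[int, dict[int, int]] = {}  # pred_id -> {gt_id: voxels}
    for les in pred:
        hits = gt_arr[tuple(les.coords.T)]
        ids, counts = np.unique(hits[hits > 0], return_counts=True)
        qualifying = {}
        for gid, cnt in zip(ids, counts):
            if cnt < min_overlap_voxels:
                continue
            if iou_threshold is not None:
                union = gt_by_id[int(gid)].voxel_count + les.voxel_count - int(cnt)
                if cnt / union < iou_threshold:
                    continue
            qualifying[int(gid)] = int(cnt)
        overlaps[les.lesion_id] = qualifying

    for pid, qualifying in overlaps.items():
        if not qualifying:
            result.fp_ids.add(pid)
            continue
        for gid, cnt in qualifying.items():
            result.tp_pairs.add((gid, pid))
            result.overlap_voxels[(gid, pid)] = cnt
        if len(qualifying) > 1:
            result.merge_events.append((pid, tuple(sorted(qualifying))))
    result.fn_ids = {l.lesion_id for l in gt} - result.detected_gt_ids
    return result


def attach_sidecar_metadata(lesions: list[Lesion], sidecar: pd.DataFrame | None) -> list[Lesion]:
    """Join sidecar annotations onto lesions.

    Ground-truth instance masks are joined on ``label_value`` (the instance
    id); binary predicted masks are joined on the deterministic ``lesion_id``.
    """
    if sidecar is None or len(sidecar) == 0:
        return lesions
    rows = {int(r.lesion_id): r for r in sidecar.itertuples()}
    out = []
    for les in lesions:
        key = les.label_value if les.source == GROUND_TRUTH else les.lesion_id
        row = rows.get(int(key))
        if row is None:
            out.append(les)
            continue
        out.append(
            replace(
                les,
                category=row.category if pd.notna(row.category) else les.category,
                station_or_organ=row.station_or_organ
                if pd.notna(row.station_or_organ)
                else les.station_or_organ,
                etiology_class=row.etiology_class
                if pd.notna(row.etiology_class)
                else les.etiology_class,
                etiology=row.etiology if pd.notna(row.etiology) else les.etiology,
                invasion_flags=parse_invasion_flags(row.invasion_flags),
            )
        )
    return out


def assign_category(
    pred_lesion: Lesion,
    match: MatchResult,
    compartment_map: LabelVolume | None,
    compartment_table: pd.DataFrame | None = None,
    gt_lesions: list[Lesion] | None = None,
    sidecar: pd.DataFrame | None = None,
) -> Lesion:
    """Assign a T/N/M category (and station/etiology) to a predicted lesion.

    Matched lesions inherit category, station and invasion flags from the
    ground-truth lesion with the largest overlap.  Unmatched (false-positive)
    lesions take the compartment holding the majority of their voxels, ties
    broken by the centroid's compartment; a false positive lying outside every
    compartment defaults to category M — the extrathoracic search space, where
    most spurious uptake is found.  False-positive etiology comes from the
    sidecar when provided, otherwise a "benign" placeholder is used and the
    lesion is flagged as unannotated.
    """
    pid = pred_lesion.lesion_id
    matched_gt = [g for (g, p) in match.tp_pairs if p == pid]
    if matched_gt and gt_lesions is not None:
        by_id = {l.lesion_id: l for l in gt_lesions}
        best = max(matched_gt, key=lambda g: match.overlap_voxels.get((g, pid), 0))
        src = by_id[best]
        return replace(
            pred_lesion,
            category=src.category,
            station_or_organ=src.station_or_organ,
            invasion_flags=src.invasion_flags,
            etiology_class=src.etiology_class or "tumour",
            etiology=src.etiology,
        )

    # false positive: locate by compartment
    category, station = "M", None
    if compartment_map is not None:
        hits = compartment_map.voxels[tuple(pred_lesion.coords.T)]
        ids, counts = np.unique(hits[hits > 0], return_counts=True)
        winner = None
        if len(ids):
            top = counts.max()
            tied = ids[counts == top]
            if len(tied) == 1:
                winner = int(tied[0])
            else:
                centroid = np.rint(pred_lesion.coords.mean(axis=0)).astype(int)
                centroid = np.minimum(
                    np.maximum(centroid, 0), np.array(compartment_map.shape) - 1
                )
                c = int(compartment_map.voxels[tuple(centroid)])
                winner = c if c in set(int(t) for t in tied) else int(sorted(tied)[0])
        if winner is not None and compartment_table is not None:
            row = compartment_table.set_index("compartment_id").loc[winner]
            category, station = str(row["category"]), row["station_or_organ"]

    etiology_class, etiology = "benign", "unannotated"
    if sidecar is not None and len(sidecar):
        rows = sidecar.set_index("lesion_id")
        if pid in rows.index:
            row = rows.loc[pid]
            if pd.notna(row["etiology_class"]):
                etiology_class = str(row["etiology_class"])
                etiology = str(row["etiology"]) if pd.notna(row["etiology"]) else None
            if pd.notna(row["category"]):
                category = str(row["category"])
            if pd.notna(row["station_or_organ"]):
                station = row["station_or_organ"]
    return replace(
        pred_lesion,
        category=category,
        station_or_organ=station,
        etiology_class=etiology_class,
        etiology=etiology,
    )


def measure_diameter(lesion: Lesion, spacing) -> float:
    """Maximal axial (in-plane) extent of a lesion in mm.

    Clinical T-size is read on axial sections, so the diameter is the maximum
    pairwise in-plane distance between voxel centres over all axial slices,
    plus one in-plane voxel width (a single voxel has diameter one voxel
    width, not zero).
    """
    if lesion.coords is None or len(lesion.coords) == 0:
        raise ValueError("cannot measure an empty lesion")
    sx, sy, sz = (float(s) for s in spacing)
    width = (sx + sy) / 2.0
    best = 0.0
    coords = lesion.coords
    for z in np.unique(coords[:, 2]):
        pts = coords[coords[:, 2] == z][:, :2].astype(float) * (sx, sy)
        if len(pts) == 1:
            continue
        best = max(best, float(pdist(pts).max()))
    return best + width


def categorize_predictions(
    pred_lesions: list[Lesion],
    match: MatchResult,
    gt_lesions: list[Lesion],
    compartment_map: LabelVolume | None,
    compartment_table: pd.DataFrame | None,
    sidecar: pd.DataFrame | None,
    spacing,
) -> list[Lesion]:
    """Categorize every predicted lesion and measure its axial diameter."""
    out = []
    for les in pred_lesions:
        les = assign_category(
            les, match, compartment_map, compartment_table, gt_lesions, sidecar
        )
        out.append(replace(les, diameter_mm=measure_diameter(les, spacing)))
    return out


def lesions_to_table(lesions: list[Lesion]) -> pd.DataFrame:
    """Flatten lesions to an exportable per-lesion table."""
    from .io_formats import format_invasion_flags

    return pd.DataFrame(
        [
            {
                "lesion_id": l.lesion_id,
                "source": l.source,
                "label_value": l.label_value,
                "voxel_count": l.voxel_count,
                "volume_ml": l.volume_ml,
                "category": l.category,
                "station_or_organ": l.station_or_organ,
                "diameter_mm": l.diameter_mm,
                "etiology_class": l.etiology_class,
                "etiology": l.etiology,
                "invasion_flags": format_invasion_flags(l.invasion_flags),
            }
            for l in lesions
        ]
    )
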