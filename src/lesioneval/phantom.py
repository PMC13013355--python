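"""Synthetic phantom cohorts of paired ground-truth / predicted lesion masks.

The phantom emulates the failure modes seen when automated whole-body PET/CT
lesion segmentations are read against expert ground truth, so the whole
evaluation pipeline (matching, metrics, staging, migration) can be exercised
without patient data:

* missed lesions (false negatives) deleted per T/N/M category at a set rate
* taxonomy-tagged spurious components (physiologic / benign / pathologic
  non-oncologic uptake) injected as false positives
* per-lesion boundary over-/under-segmentation (dilation / erosion, or a
  multiplicative volume bias)
* hilar merging: a central primary tumour fused with an adjacent N1 node by a
  bridging corridor, the classic central-tumour/hilar-node convergence error

Lesions are spheres, so diameter and volume are analytically known and every
downstream measurement has a closed-form oracle.  No intensity channel is
simulated: all in-scope computation operates on masks.  Every error operator
is recorded in an injection log; evaluation code must never read the log —
it exists so tests can compare recovered error sets against injected ones.

Determinism: one master seed; per-patient streams are derived by fixed
offsets, so identical (spec, config, seed) give byte-identical cohorts.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import __version__ as _version
from .io_formats import (
    LabelVolume,
    format_invasion_flags,
    write_label_volume,
    write_sidecar,
)
from .lesion_analysis import GROUND_TRUTH, Lesion, extract_components, measure_diameter


class PhantomConfigError(ValueError):
    """Invalid phantom specification (overlapping boxes, bad rates, ...)."""


class PlacementError(RuntimeError):
    """A lesion could not be placed after bounded retries."""


CountSpec = int | tuple[str, float]  # fixed count, or ("poisson", mean)


def _draw_count(spec: CountSpec, rng: np.random.Generator) -> int:
    if isinstance(spec, (int, np.integer)):
        if spec < 0:
            raise PhantomConfigError(f"negative lesion count {spec}")
        return int(spec)
    kind, mean = spec
    if kind != "poisson" or mean < 0:
        raise PhantomConfigError(f"unsupported count distribution {spec}")
    return int(rng.poisson(mean))


@dataclass
class Compartment:
    """An axis-aligned box standing in for an anatomical region.

    ``box`` is ((x0, x1), (y0, y1), (z0, z1)) in half-open voxel bounds.
    ``label`` is the nodal station or organ name used by the staging rules.
    """

    compartment_id: int
    category: str  # T, N or M
    label: str
    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    radius_range_mm: tuple[float, float] | None = None  # overrides spec default


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    compartments: list[Compartment] = field(default_factory=list)
    lesions_per_compartment: dict[int, CountSpec] = field(default_factory=dict)
    radius_range_mm: tuple[float, float] = (4.0, 8.0)
    invasion_probability: float = 0.1

    def validate(self) -> "PhantomSpec":
        if any(s <= 0 for s in self.grid_shape) or any(s <= 0 for s in self.voxel_spacing):
            raise PhantomConfigError("grid_shape and voxel_spacing must be positive")
        if not 0 <= self.invasion_probability <= 1:
            raise PhantomConfigError("invasion_probability must be in [0, 1]")
        occupied = np.zeros(self.grid_shape, dtype=bool)
        for comp in self.compartments:
            (x0, x1), (y0, y1), (z0, z1) = comp.box
            if not (0 <= x0 < x1 <= self.grid_shape[0]
                    and 0 <= y0 < y1 <= self.grid_shape[1]
                    and 0 <= z0 < z1 <= self.grid_shape[2]):
                raise PhantomConfigError(
                    f"compartment {comp.compartment_id} box {comp.box} outside grid"
                )
            region = occupied[x0:x1, y0:y1, z0:z1]
            if region.any():
                raise PhantomConfigError(
                    f"compartment {comp.compartment_id} overlaps another box"
                )
            region[:] = True
            rmin, rmax = comp.radius_range_mm or self.radius_range_mm
            if rmin <= 0 or rmax < rmin:
                raise PhantomConfigError(f"bad radius range ({rmin}, {rmax})")
            count = self.lesions_per_compartment.get(comp.compartment_id, 0)
            may_hold_lesions = count != 0
            margins = [math.ceil(rmax / s) for s in self.voxel_spacing]
            dims = (x1 - x0, y1 - y0, z1 - z0)
            if may_hold_lesions and any(d < 2 * m + 1 for d, m in zip(dims, margins)):
                raise PhantomConfigError(
                    f"compartment {comp.compartment_id}: max radius {rmax} mm "
                    f"does not fit box of {dims} voxels"
                )
        ids = [c.compartment_id for c in self.compartments]
        if len(set(ids)) != len(ids) or any(i <= 0 for i in ids):
            raise PhantomConfigError("compartment ids must be unique positive integers")
        return self


@dataclass
class FPSpec:
    """One class of injectable false positives."""

    category: str
    etiology_class: str  # physiologic | benign | pathologic
    etiology: str
    count: CountSpec = 1
    radius_range_mm: tuple[float, float] = (3.0, 7.0)


@dataclass
class ErrorInjectionConfig:
    fn_rate: float | dict[str, float] = 0.0
    fp_specs: list[FPSpec] = field(default_factory=list)
    dilate_voxels: int = 0
    erode_voxels: int = 0
    hilar_merge_rate: float = 0.0
    volume_bias: float = 1.0
    hilar_station_labels: tuple[str, ...] = ("ipsilateral_hilar",)

    def fn_rate_for(self, category: str) -> float:
        if isinstance(self.fn_rate, dict):
            return float(self.fn_rate.get(category, 0.0))
        return float(self.fn_rate)

    def validate(self) -> "ErrorInjectionConfig":
        rates = (
            list(self.fn_rate.values()) if isinstance(self.fn_rate, dict) else [self.fn_rate]
        )
        if any(not 0 <= r <= 1 for r in rates) or not 0 <= self.hilar_merge_rate <= 1:
            raise PhantomConfigError("rates must be in [0, 1]")
        if self.dilate_voxels < 0 or self.erode_voxels < 0:
            raise PhantomConfigError("dilate/erode must be non-negative")
        if self.volume_bias <= 0:
            raise PhantomConfigError("volume_bias must be positive")
        return self


@dataclass
class GtCase:
    patient_id: str
    gt_mask: LabelVolume
    compartment_map: LabelVolume
    lesion_table: pd.DataFrame
    compartment_categories: dict[int, str] = field(default_factory=dict)


@dataclass
class CaseBundle:
    patient_id: str
    gt_mask: LabelVolume
    pred_mask: LabelVolume
    compartment_map: LabelVolume
    lesion_table: pd.DataFrame
    pred_sidecar: pd.DataFrame
    injection_log: list[dict]
    compartment_table: pd.DataFrame | None = None


def default_phantom_spec() -> PhantomSpec:
    """A whole-body-like layout: primary tumour, nodal stations, distant organs.

    Grid 48³ at 4 mm isotropic spacing (a coarse whole-body field of view).
    One primary per patient; nodal and metastatic lesions follow Poisson
    counts so the cohort mixes early- and advanced-stage disease.
    """
    comps = [
        Compartment(1, "T", "right_lung_primary", ((4, 20), (8, 28), (24, 44)),
                    radius_range_mm=(5.0, 20.0)),
        Compartment(2, "N", "ipsilateral_hilar", ((20, 27), (12, 24), (26, 40))),
        Compartment(3, "N", "ipsilateral_lower_paratracheal_4", ((27, 34), (10, 22), (28, 42))),
        Compartment(4, "N", "subcarinal_7", ((27, 34), (24, 34), (26, 38))),
        Compartment(5, "N", "contralateral_mediastinal", ((34, 41), (10, 22), (28, 42))),
        Compartment(6, "M", "contralateral_pulmonary", ((34, 46), (24, 40), (24, 44))),
        Compartment(7, "M", "liver", ((4, 22), (8, 30), (6, 20))),
        Compartment(8, "M", "bone", ((24, 34), (34, 44), (2, 22))),
        Compartment(9, "M", "adrenal_gland", ((24, 34), (8, 20), (6, 16))),
    ]
    counts: dict[int, CountSpec] = {
        1: 1,
        2: ("poisson", 0.8),
        3: ("poisson", 0.5),
        4: ("poisson", 0.4),
        5: ("poisson", 0.25),
        6: ("poisson", 0.15),
        7: ("poisson", 0.2),
        8: ("poisson", 0.2),
        9: ("poisson", 0.1),
    }
    return PhantomSpec(compartments=comps, lesions_per_compartment=counts).validate()


def default_error_config() -> ErrorInjectionConfig:
    """Error rates patterned on a 306-patient expert re-read of automated
    NSCLC lesion predictions: per-category miss rates from the published
    sensitivity counts (T 14/425, N 25/853, M 30/578), per-patient false
    positives matching the published etiology tallies (e.g. 58 physiologic
    M-category FPs over 306 patients), and an 11.1% hilar-merge rate."""
    return ErrorInjectionConfig(
        fn_rate={"T": 14 / 425, "N": 25 / 853, "M": 30 / 578},
        fp_specs=[
            FPSpec("T", "pathologic", "pulmonary_inflammation", ("poisson", 18 / 306)),
            FPSpec("T", "benign", "dystelectasis", ("poisson", 4 / 306)),
            FPSpec("N", "benign", "reactive_lymph_node", ("poisson", 37 / 306)),
            FPSpec("M", "physiologic", "brown_adipose_tissue", ("poisson", 58 / 306)),
            FPSpec("M", "benign", "musculoskeletal_degeneration", ("poisson", 70 / 306)),
            FPSpec("M", "pathologic", "rib_fracture", ("poisson", 68 / 306)),
        ],
        hilar_merge_rate=0.111,
    ).validate()


# ---------------------------------------------------------------------------
# geometry helpers


def _ball_coords(center, radius_mm, spacing, shape) -> np.ndarray:
    """Voxel coordinates whose centres lie within radius_mm of the centre voxel."""
    margins = [math.ceil(radius_mm / s) for s in spacing]
    ranges = [
        np.arange(max(0, c - m), min(n, c + m + 1))
        for c, m, n in zip(center, margins, shape)
    ]
    gx, gy, gz = np.meshgrid(*ranges, indexing="ij")
    dx = (gx - center[0]) * spacing[0]
    dy = (gy - center[1]) * spacing[1]
    dz = (gz - center[2]) * spacing[2]
    inside = dx * dx + dy * dy + dz * dz <= radius_mm * radius_mm
    return np.stack([gx[inside], gy[inside], gz[inside]], axis=1)


def _block(blocked: np.ndarray, coords: np.ndarray, clearance: int = 1) -> None:
    """Mark coords plus a clearance shell so later lesions cannot touch them."""
    lo = np.maximum(coords.min(axis=0) - clearance, 0)
    hi = np.minimum(coords.max(axis=0) + clearance + 1, blocked.shape)
    patch = np.zeros(tuple(hi - lo), dtype=bool)
    patch[tuple((coords - lo).T)] = True
    patch = ndimage.binary_dilation(
        patch, structure=ndimage.generate_binary_structure(3, 3), iterations=clearance
    )
    blocked[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= patch


def build_compartment_map(spec: PhantomSpec) -> LabelVolume:
    """Render the compartment layout as a label volume (0 = background)."""
    spec.validate()
    vox = np.zeros(spec.grid_shape, dtype=np.uint16)
    for comp in spec.compartments:
        (x0, x1), (y0, y1), (z0, z1) = comp.box
        vox[x0:x1, y0:y1, z0:z1] = comp.compartment_id
    return LabelVolume(vox, spec.voxel_spacing)


def compartment_table(spec: PhantomSpec) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compartment_id": c.compartment_id,
                "category": c.category,
                "station_or_organ": c.label,
            }
            for c in spec.compartments
        ]
    )


def _place_sphere(rng, blocked, box, radius_mm, spacing, shape, retries=200):
    (x0, x1), (y0, y1), (z0, z1) = box
    margins = [math.ceil(radius_mm / s) for s in spacing]
    lows = [x0 + margins[0], y0 + margins[1], z0 + margins[2]]
    highs = [x1 - 1 - margins[0], y1 - 1 - margins[1], z1 - 1 - margins[2]]
    if any(h < l for l, h in zip(lows, highs)):
        raise PlacementError(f"radius {radius_mm} mm does not fit box {box}")
    for _ in range(retries):
        center = tuple(int(rng.integers(l, h + 1)) for l, h in zip(lows, highs))
        coords = _ball_coords(center, radius_mm, spacing, shape)
        if not blocked[tuple(coords.T)].any():
            return center, coords
    raise PlacementError(f"no room for a {radius_mm:.1f} mm lesion in box {box}")


INVADABLE_STRUCTURES = ("chest_wall", "mediastinum")


def sample_gt_case(spec: PhantomSpec, rng: np.random.Generator, patient_id: str) -> GtCase:
    """Place non-touching spheres in their compartments and tabulate them."""
    gt = np.zeros(spec.grid_shape, dtype=np.uint16)
    blocked = np.zeros(spec.grid_shape, dtype=bool)
    rows = []
    next_id = 1
    for comp in spec.compartments:
        n = _draw_count(spec.lesions_per_compartment.get(comp.compartment_id, 0), rng)
        rmin, rmax = comp.radius_range_mm or spec.radius_range_mm
        for _ in range(n):
            radius = float(rng.uniform(rmin, rmax))
            try:
                _, coords = _place_sphere(
                    rng, blocked, comp.box, radius, spec.voxel_spacing, spec.grid_shape
                )
            except PlacementError:
                # crowded compartment: one more bounded attempt at the smallest
                # admissible radius before giving up
                radius = float(rmin)
                _, coords = _place_sphere(
                    rng, blocked, comp.box, radius, spec.voxel_spacing, spec.grid_shape
                )
            gt[tuple(coords.T)] = next_id
            _block(blocked, coords)
            probe = Lesion(
                lesion_id=next_id, source=GROUND_TRUTH,
                voxel_count=len(coords), volume_ml=0.0, coords=coords,
            )
            invasion = ()
            if comp.category == "T" and rng.random() < spec.invasion_probability:
                invasion = (str(rng.choice(INVADABLE_STRUCTURES)),)
            rows.append(
                {
                    "lesion_id": next_id,
                    "category": comp.category,
                    "station_or_organ": comp.label,
                    "invasion_flags": format_invasion_flags(invasion),
                    "etiology_class": "tumour",
                    "etiology": None,
                    "diameter_mm": measure_diameter(probe, spec.voxel_spacing),
                }
            )
            next_id += 1
    table = pd.DataFrame(
        rows,
        columns=[
            "lesion_id", "category", "station_or_organ", "invasion_flags",
            "etiology_class", "etiology", "diameter_mm",
        ],
    )
    return GtCase(
        patient_id,
        LabelVolume(gt, spec.voxel_spacing),
        build_compartment_map(spec),
        table,
        {c.compartment_id: c.category for c in spec.compartments},
    )


def sample_gt_cohort(spec: PhantomSpec, n_patients: int, seed: int):
    """Deterministic ground-truth cohort; per-patient streams derived from seed."""
    if n_patients < 1:
        raise PhantomConfigError("n_patients must be >= 1")
    spec.validate()
    return [
        sample_gt_case(spec, np.random.default_rng([seed, i, 0]), f"P{i:04d}")
        for i in range(n_patients)
    ]


# ---------------------------------------------------------------------------
# error injection


def _perturb_component(coords, config, shape) -> np.ndarray:
    """Apply dilation/erosion and volume bias to one component; may empty it."""
    grow = config.dilate_voxels
    shrink = config.erode_voxels
    if grow == 0 and shrink == 0 and config.volume_bias == 1.0:
        return coords
    pad = grow + 8
    lo = np.maximum(coords.min(axis=0) - pad, 0)
    hi = np.minimum(coords.max(axis=0) + pad + 1, shape)
    patch = np.zeros(tuple(hi - lo), dtype=bool)
    patch[tuple((coords - lo).T)] = True
    struct = ndimage.generate_binary_structure(3, 3)
    if grow:
        patch = ndimage.binary_dilation(patch, struct, iterations=grow)
    if shrink:
        patch = ndimage.binary_erosion(patch, struct, iterations=shrink)
    if config.volume_bias != 1.0 and patch.any():
        target = max(0, round(config.volume_bias * len(coords)))
        for _ in range(16):
            count = int(patch.sum())
            if config.volume_bias > 1.0 and count < target:
                patch = ndimage.binary_dilation(patch, struct)
            elif config.volume_bias < 1.0 and count > target:
                nxt = ndimage.binary_erosion(patch, struct)
                if not nxt.any():
                    break
                patch = nxt
            else:
                break
    out = np.argwhere(patch)
    return out + lo if len(out) else out.reshape(0, 3)


def inject_errors(
    case: GtCase, config: ErrorInjectionConfig, seed
) -> tuple[LabelVolume, list[dict], pd.DataFrame]:
    """Derive a predicted mask from ground truth by applying error operators.

    Errors act on whole components: deletions (false negatives), injected
    taxonomy-tagged false positives, per-lesion boundary perturbation and
    hilar merges.  Every operation is logged with the lesion ids involved; a
    lesion annihilated by erosion is logged as an implicit deletion, never
    silently dropped.  Returns the binary predicted mask, the injection log,
    and a sidecar annotating each injected false-positive component.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    spacing = case.gt_mask.spacing
    shape = case.gt_mask.shape
    gt = case.gt_mask.voxels
    pred = np.zeros(shape, dtype=bool)
    log: list[dict] = []
    survivors: dict[int, np.ndarray] = {}

    by_id = {int(r.lesion_id): r for r in case.lesion_table.itertuples()}
    for lesion_id in sorted(by_id):
        row = by_id[lesion_id]
        coords = np.argwhere(gt == lesion_id)
        if rng.random() < config.fn_rate_for(row.category):
            log.append({"op": "delete_fn", "lesion_id": lesion_id,
                        "category": row.category})
            continue
        out = _perturb_component(coords, config, shape)
        if len(out) == 0:
            log.append({"op": "implicit_deletion", "lesion_id": lesion_id,
                        "category": row.category, "cause": "eroded_away"})
            continue
        pred[tuple(out.T)] = True
        survivors[lesion_id] = out
        log.append({"op": "keep", "lesion_id": lesion_id, "category": row.category,
                    "dilate": config.dilate_voxels, "erode": config.erode_voxels,
                    "volume_bias": config.volume_bias})

    # hilar merge: bridge a surviving primary to a surviving N1-station node
    if rng.random() < config.hilar_merge_rate:
        t_ids = [i for i in survivors if by_id[i].category == "T"]
        n1_ids = [
            i for i in survivors
            if by_id[i].category == "N"
            and by_id[i].station_or_organ in config.hilar_station_labels
        ]
        if t_ids and n1_ids:
            t_id = int(rng.choice(t_ids))
            n_id = int(rng.choice(n1_ids))
            a = survivors[t_id].mean(axis=0)
            b = survivors[n_id].mean(axis=0)
            steps = max(2, int(np.ceil(np.abs(b - a).max())) * 2 + 1)
            line = np.rint(np.linspace(a, b, steps)).astype(int)
            corridor = np.zeros(shape, dtype=bool)
            corridor[tuple(np.clip(line, 0, np.array(shape) - 1).T)] = True
            corridor = ndimage.binary_dilation(
                corridor, ndimage.generate_binary_structure(3, 3)
            )
            pred |= corridor
            log.append({"op": "hilar_merge", "lesion_ids": [t_id, n_id]})

    # taxonomy-tagged false positives
    blocked = ndimage.binary_dilation(
        (gt > 0) | pred, ndimage.generate_binary_structure(3, 3), iterations=2
    )
    # FP placement uses the compartment geometry of the case
    comp_ids = np.unique(case.compartment_map.voxels)
    boxes = {}
    for cid in comp_ids:
        if cid == 0:
            continue
        where = np.argwhere(case.compartment_map.voxels == cid)
        boxes[int(cid)] = tuple(
            (int(w.min()), int(w.max()) + 1) for w in where.T
        )
    cat_of = case.compartment_categories
    fp_centers: list[tuple[tuple[int, int, int], FPSpec]] = []
    for fp_spec in config.fp_specs:
        candidates = [cid for cid in boxes if cat_of.get(cid) == fp_spec.category]
        n = _draw_count(fp_spec.count, rng)
        for _ in range(n):
            if not candidates:
                log.append({"op": "fp_skipped", "reason": "no compartment",
                            "etiology": fp_spec.etiology})
                continue
            cid = int(rng.choice(candidates))
            radius = float(rng.uniform(*fp_spec.radius_range_mm))
            try:
                center, coords = _place_sphere(
                    rng, blocked, boxes[cid], radius, spacing, shape, retries=300
                )
            except PlacementError:
                log.append({"op": "fp_skipped", "reason": "no room",
                            "etiology": fp_spec.etiology})
                continue
            pred[tuple(coords.T)] = True
            _block(blocked, coords)
            fp_centers.append((center, fp_spec))
            log.append({"op": "inject_fp", "center": list(map(int, center)),
                        "category": fp_spec.category,
                        "etiology_class": fp_spec.etiology_class,
                        "etiology": fp_spec.etiology})

    pred_vol = LabelVolume(pred.astype(np.uint8), spacing)

    # annotate injected FP components by their deterministic component id
    sidecar_rows = []
    if fp_centers:
        components = extract_components(pred_vol, connectivity=26)
        comp_arr = np.zeros(shape, dtype=np.int32)
        for les in components:
            comp_arr[tuple(les.coords.T)] = les.lesion_id
        for center, fp_spec in fp_centers:
            sidecar_rows.append(
                {
                    "lesion_id": int(comp_arr[center]),
                    "category": fp_spec.category,
                    "station_or_organ": None,
                    "invasion_flags": "",
                    "etiology_class": fp_spec.etiology_class,
                    "etiology": fp_spec.etiology,
                    "diameter_mm": None,
                }
            )
    pred_sidecar = pd.DataFrame(
        sidecar_rows,
        columns=[
            "lesion_id", "category", "station_or_organ", "invasion_flags",
            "etiology_class", "etiology", "diameter_mm",
        ],
    )
    return pred_vol, log, pred_sidecar


def generate_cohort(
    spec: PhantomSpec,
    config: ErrorInjectionConfig,
    n_patients: int,
    seed: int,
) -> list[CaseBundle]:
    """Full synthetic cohort: ground truth, predictions and injection logs."""
    spec.validate()
    config.validate()
    bundles = []
    for i in range(n_patients):
        case = sample_gt_case(spec, np.random.default_rng([seed, i, 0]), f"P{i:04d}")
        pred, log, pred_sidecar = inject_errors(case, config, [seed, i, 1])
        bundles.append(
            CaseBundle(
                patient_id=case.patient_id,
                gt_mask=case.gt_mask,
                pred_mask=pred,
                compartment_map=case.compartment_map,
                lesion_table=case.lesion_table,
                pred_sidecar=pred_sidecar,
                injection_log=log,
                compartment_table=compartment_table(spec),
            )
        )
    return bundles


def verify_conservation(bundle: CaseBundle) -> None:
    """Check the bookkeeping invariants of a generated case.

    Ground-truth lesion count must equal survivors + logged deletions, and the
    number of injected false positives must match the log.
    """
    n_gt = len(bundle.lesion_table)
    kept = sum(1 for e in bundle.injection_log if e["op"] == "keep")
    deleted = sum(
        1 for e in bundle.injection_log if e["op"] in ("delete_fn", "implicit_deletion")
    )
    if kept + deleted != n_gt:
        raise AssertionError(
            f"{bundle.patient_id}: {n_gt} gt lesions but {kept} kept + {deleted} deleted"
        )
    injected = sum(1 for e in bundle.injection_log if e["op"] == "inject_fp")
    if injected != len(bundle.pred_sidecar):
        raise AssertionError(
            f"{bundle.patient_id}: {injected} injected FPs but "
            f"{len(bundle.pred_sidecar)} sidecar rows"
        )


# ---------------------------------------------------------------------------
# serialization


def spec_to_dict(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    d["lesions_per_compartment"] = {
        int(k): list(v) if isinstance(v, tuple) else int(v)
        for k, v in spec.lesions_per_compartment.items()
    }
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    comps = [
        Compartment(
            compartment_id=int(c["compartment_id"]),
            category=c["category"],
            label=c["label"],
            box=tuple(tuple(int(v) for v in pair) for pair in c["box"]),
            radius_range_mm=tuple(c["radius_range_mm"]) if c.get("radius_range_mm") else None,
        )
        for c in d.get("compartments", [])
    ]
    counts = {
        int(k): tuple(v) if isinstance(v, (list, tuple)) else int(v)
        for k, v in d.get("lesions_per_compartment", {}).items()
    }
    return PhantomSpec(
        grid_shape=tuple(d.get("grid_shape", (48, 48, 48))),
        voxel_spacing=tuple(d.get("voxel_spacing", (4.0, 4.0, 4.0))),
        compartments=comps,
        lesions_per_compartment=counts,
        radius_range_mm=tuple(d.get("radius_range_mm", (4.0, 8.0))),
        invasion_probability=float(d.get("invasion_probability", 0.1)),
    ).validate()


def config_to_dict(config: ErrorInjectionConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> ErrorInjectionConfig:
    fps = [
        FPSpec(
            category=f["category"],
            etiology_class=f["etiology_class"],
            etiology=f["etiology"],
            count=tuple(f["count"]) if isinstance(f["count"], (list, tuple)) else int(f["count"]),
            radius_range_mm=tuple(f.get("radius_range_mm", (3.0, 7.0))),
        )
        for f in d.get("fp_specs", [])
    ]
    fn = d.get("fn_rate", 0.0)
    return ErrorInjectionConfig(
        fn_rate=dict(fn) if isinstance(fn, dict) else float(fn),
        fp_specs=fps,
        dilate_voxels=int(d.get("dilate_voxels", 0)),
        erode_voxels=int(d.get("erode_voxels", 0)),
        hilar_merge_rate=float(d.get("hilar_merge_rate", 0.0)),
        volume_bias=float(d.get("volume_bias", 1.0)),
        hilar_station_labels=tuple(d.get("hilar_station_labels", ("ipsilateral_hilar",))),
    ).validate()


def write_cohort(
    bundles: list[CaseBundle],
    outdir: str | Path,
    spec: PhantomSpec,
    config: ErrorInjectionConfig,
    seed: int,
) -> Path:
    """Write a cohort to disk: per-patient NIfTIs, tables and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for b in bundles:
        pdir = outdir / b.patient_id
        pdir.mkdir(exist_ok=True)
        write_label_volume(b.gt_mask, pdir / "gt.nii.gz")
        write_label_volume(b.pred_mask, pdir / "pred.nii.gz")
        write_label_volume(b.compartment_map, pdir / "compartments.nii.gz")
        write_sidecar(b.lesion_table, pdir / "lesions.csv")
        write_sidecar(b.pred_sidecar, pdir / "pred_sidecar.csv")
        (pdir / "injection_log.json").write_text(json.dumps(b.injection_log, indent=1))
        for f in sorted(pdir.iterdir()):
            checksums[f"{b.patient_id}/{f.name}"] = hashlib.sha256(
                f.read_bytes()
            ).hexdigest()
    compartment_table_from_spec = compartment_table(spec)
    compartment_table_from_spec.to_csv(outdir / "compartment_table.csv", index=False)
    spec_dict = spec_to_dict(spec)
    config_dict = config_to_dict(config)
    config_blob = yaml.safe_dump({"phantom": spec_dict, "errors": config_dict})
    manifest = {
        "tool_version": _version,
        "seed": seed,
        "n_patients": len(bundles),
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "checksums": checksums,
    }
    (outdir / "config.yaml").write_text(config_blob)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
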