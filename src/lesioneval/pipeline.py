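"""End-to-end evaluation: masks in, metrics / stages / migration out.

``evaluate_case`` runs the full chain for one patient — component extraction,
overlap matching, voxel metrics, category assignment, independent staging of
the ground-truth and predicted lesion sets, and the migration record.
``evaluate_cohort`` aggregates cases into the cohort-level tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import LabelVolume, require_same_grid
from .lesion_analysis import (
    GROUND_TRUTH,
    Lesion,
    MatchResult,
    attach_sidecar_metadata,
    categorize_predictions,
    extract_components,
    match_lesions,
    measure_diameter,
)
from .metrics import (
    BlandAltmanResult,
    DetectionStats,
    TaxonomyTally,
    VoxelMetrics,
    bland_altman,
    detection_stats,
    round_pct,
    taxonomy_tally,
    voxel_metrics,
)
from .migration import (
    DEFAULT_BOUNDARIES,
    CohortMigrationSummary,
    DecisionBoundaries,
    MigrationRecord,
    make_record,
    summarize_cohort,
)
from .phantom import CaseBundle, compartment_table
from .staging import StageAssignment, StageRules, load_stage_rules, stage_patient


@dataclass
class CaseEvaluation:
    patient_id: str
    voxel: VoxelMetrics
    match: MatchResult
    gt_lesions: list[Lesion]
    pred_lesions: list[Lesion]
    gt_stage: StageAssignment
    pred_stage: StageAssignment
    migration: MigrationRecord


@dataclass
class CohortEvaluation:
    cases: list[CaseEvaluation]
    per_patient: pd.DataFrame
    detection: DetectionStats
    bland_altman: BlandAltmanResult | None
    m_fp_taxonomy: TaxonomyTally
    migration: CohortMigrationSummary

    def summary_dict(self) -> dict:
        """Pooled summary mirroring voxel -> lesion -> staging -> migration."""
        det = self.detection.table
        out = {
            "n_patients": len(self.cases),
            "voxel": {
                "mean_dsc": float(self.per_patient["dsc"].mean()),
                "mean_fnv_ml": float(self.per_patient["fnv_ml"].mean()),
                "mean_fpv_ml": float(self.per_patient["fpv_ml"].mean()),
            },
            "detection": {
                cat: {
                    "tp": int(det.loc[cat, "tp"]),
                    "fn": int(det.loc[cat, "fn"]),
                    "fp": int(det.loc[cat, "fp"]),
                    "sensitivity_pct": None
                    if pd.isna(det.loc[cat, "sensitivity_pct"])
                    else float(det.loc[cat, "sensitivity_pct"]),
                    "precision_pct": None
                    if pd.isna(det.loc[cat, "precision_pct"])
                    else float(det.loc[cat, "precision_pct"]),
                }
                for cat in det.index
            },
            "macro_sensitivity_pct": None
            if self.detection.macro_sensitivity is None
            else round_pct(100 * self.detection.macro_sensitivity),
            "m_fp_taxonomy": {
                cls: {"n": int(r["n"]), "share_pct": float(r["share_pct"])}
                for cls, r in self.m_fp_taxonomy.by_class.iterrows()
            },
            "migration": {
                "concordant": self.migration.concordant,
                "upstaged": self.migration.upstaged,
                "downstaged": self.migration.downstaged,
                "concordance_pct": self.migration.concordance_pct,
                "within_boundary": self.migration.within_boundary,
                "within_boundary_pct": self.migration.within_boundary_pct,
                "impact_table": self.migration.impact_table.to_dict("records"),
            },
        }
        if self.bland_altman is not None:
            out["voxel"]["tmtv_bias_ml"] = self.bland_altman.bias_ml
            out["voxel"]["tmtv_loa_ml"] = [
                self.bland_altman.loa_low_ml,
                self.bland_altman.loa_high_ml,
            ]
        return out


def evaluate_case(
    patient_id: str,
    gt_mask: LabelVolume,
    pred_mask: LabelVolume,
    rules: StageRules,
    compartment_map: LabelVolume | None = None,
    compartment_table: pd.DataFrame | None = None,
    gt_sidecar: pd.DataFrame | None = None,
    pred_sidecar: pd.DataFrame | None = None,
    connectivity: int = 26,
    min_overlap_voxels: int = 1,
    boundaries: DecisionBoundaries = DEFAULT_BOUNDARIES,
) -> CaseEvaluation:
    """Evaluate one ground-truth / prediction pair on a common grid."""
    require_same_grid(gt_mask, pred_mask)
    gt_lesions = extract_components(gt_mask, connectivity, source=GROUND_TRUTH)
    gt_lesions = attach_sidecar_metadata(gt_lesions, gt_sidecar)
    gt_lesions = [
        replace(l, diameter_mm=measure_diameter(l, gt_mask.spacing)) for l in gt_lesions
    ]
    pred_lesions = extract_components(pred_mask, connectivity)
    match = match_lesions(gt_lesions, pred_lesions, min_overlap_voxels)
    pred_lesions = categorize_predictions(
        pred_lesions, match, gt_lesions, compartment_map, compartment_table,
        pred_sidecar, pred_mask.spacing,
    )
    vm = voxel_metrics(gt_mask, pred_mask, gt_lesions, pred_lesions, match)
    gt_stage = stage_patient(gt_lesions, rules, patient_id)
    pred_stage = stage_patient(pred_lesions, rules, patient_id)
    record = make_record(patient_id, gt_stage.uicc, pred_stage.uicc, boundaries)
    return CaseEvaluation(
        patient_id=patient_id,
        voxel=vm,
        match=match,
        gt_lesions=gt_lesions,
        pred_lesions=pred_lesions,
        gt_stage=gt_stage,
        pred_stage=pred_stage,
        migration=record,
    )


def evaluate_bundle(bundle: CaseBundle, rules: StageRules, **kwargs) -> CaseEvaluation:
    """Evaluate a phantom case bundle (never reads its injection log)."""
    comp_table = bundle.compartment_table
    if comp_table is None:
        comp_table = pd.DataFrame(
            [
                {"compartment_id": cid, "category": cat, "station_or_organ": label}
                for cid, (cat, label) in _bundle_compartments(bundle).items()
            ]
        )
    return evaluate_case(
        bundle.patient_id,
        bundle.gt_mask,
        bundle.pred_mask,
        rules,
        compartment_map=bundle.compartment_map,
        compartment_table=comp_table,
        gt_sidecar=bundle.lesion_table,
        pred_sidecar=bundle.pred_sidecar,
        **kwargs,
    )


def _bundle_compartments(bundle: CaseBundle) -> dict[int, tuple[str, str]]:
    # compartment categories/stations are recoverable from the ground-truth
    # lesion table: lesions of a compartment share its station label
    out: dict[int, tuple[str, str]] = {}
    cmap = bundle.compartment_map.voxels
    for row in bundle.lesion_table.itertuples():
        coords = np.argwhere(bundle.gt_mask.voxels == int(row.lesion_id))
        if not len(coords):
            continue
        cid = int(cmap[tuple(coords[0])])
        if cid:
            out[cid] = (row.category, row.station_or_organ)
    # compartments without gt lesions stay unmapped; FPs there default to M
    return out


def evaluate_cohort(
    cases: list[CaseEvaluation], boundaries: DecisionBoundaries = DEFAULT_BOUNDARIES
) -> CohortEvaluation:
    """Aggregate per-case evaluations into the cohort report."""
    if not cases:
        raise ValueError("zero evaluable patients")
    rows = []
    for c in cases:
        rows.append(
            {
                "patient_id": c.patient_id,
                "dsc": c.voxel.dsc,
                "fnv_ml": c.voxel.fnv_ml,
                "fpv_ml": c.voxel.fpv_ml,
                "tmtv_gt_ml": c.voxel.tmtv_gt_ml,
                "tmtv_pred_ml": c.voxel.tmtv_pred_ml,
                "gt_t": c.gt_stage.t, "gt_n": c.gt_stage.n, "gt_m": c.gt_stage.m,
                "gt_uicc": c.gt_stage.uicc,
                "pred_t": c.pred_stage.t, "pred_n": c.pred_stage.n,
                "pred_m": c.pred_stage.m, "pred_uicc": c.pred_stage.uicc,
                "direction": c.migration.direction,
                "boundaries_crossed": c.migration.boundaries_crossed,
                "impact": c.migration.impact,
            }
        )
    per_patient = pd.DataFrame(rows)
    det = detection_stats([(c.gt_lesions, c.pred_lesions, c.match) for c in cases])
    ba = None
    if len(cases) >= 2:
        ba = bland_altman(
            [(c.voxel.tmtv_gt_ml, c.voxel.tmtv_pred_ml) for c in cases]
        )
    m_fps = [
        l
        for c in cases
        for l in c.pred_lesions
        if l.lesion_id in c.match.fp_ids and l.category == "M"
    ]
    migration = summarize_cohort(
        [c.migration for c in cases],
        [(c.gt_stage, c.pred_stage) for c in cases],
    )
    return CohortEvaluation(
        cases=cases,
        per_patient=per_patient,
        detection=det,
        bland_altman=ba,
        m_fp_taxonomy=taxonomy_tally(m_fps),
        migration=migration,
    )


def evaluate_phantom_cohort(
    bundles: list[CaseBundle],
    rules: StageRules | None = None,
    **kwargs,
) -> CohortEvaluation:
    """Convenience wrapper: evaluate a generated phantom cohort end to end."""
    rules = rules or load_stage_rules("ninth_edition")
    return evaluate_cohort([evaluate_bundle(b, rules, **kwargs) for b in bundles])
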