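"""Reference count tables from a 306-patient expert re-read of automated
NSCLC lesion predictions on whole-body FDG PET/CT.

These are fixed published inputs — per-category lesion detection counts, the
etiology breakdown of M-category false positives, false-negative metastatic
sites, and the cohort's stage-migration structure.  All ratio statistics
(sensitivity, precision, taxonomy shares, impact percentages) are *recomputed*
by the package from these counts; none of the derived percentages is stored
here.

The builders turn the counts into synthetic in-memory fixtures (lesion lists,
match results, stage pairs) that exercise the same code paths as image-derived
data.
"""

from __future__ import annotations

import pandas as pd

from .lesion_analysis import GROUND_TRUTH, PREDICTED, Lesion, MatchResult
from .migration import DecisionBoundaries, MigrationRecord, make_record

#: Per-category lesion detection counts (true positives, false negatives,
#: false positives) from the expert re-read.
DETECTION_COUNTS = pd.DataFrame(
    [
        {"category": "T", "tp": 411, "fn": 14, "fp": 22},
        {"category": "N", "tp": 828, "fn": 25, "fp": 37},
        {"category": "M", "tp": 548, "fn": 30, "fp": 196},
    ]
)

#: Etiology taxonomy of the 196 M-category false positives
#: (class, label, count).
M_FP_ETIOLOGY = [
    ("physiologic", "gastrointestinal_peristalsis", 15),
    ("physiologic", "urinary_excretion", 13),
    ("physiologic", "brown_adipose_tissue", 10),
    ("physiologic", "bone_activation", 8),
    ("physiologic", "oesophageal_peristalsis", 5),
    ("physiologic", "muscle_activation", 4),
    ("physiologic", "anal_sphincter", 2),
    ("physiologic", "renal_medulla", 1),
    ("benign", "musculoskeletal_degeneration", 39),
    ("benign", "distant_unspecific_lymph_node", 10),
    ("benign", "prostate_uptake", 8),
    ("benign", "fdg_paravasation", 7),
    ("benign", "benign_breast_lesion", 3),
    ("benign", "drainage_associated_uptake", 2),
    ("benign", "uterine_uptake", 1),
    ("pathologic", "rib_fracture", 15),
    ("pathologic", "pulmonary_inflammation", 14),
    ("pathologic", "vertebral_body_fracture", 7),
    ("pathologic", "thyroid_uptake", 7),
    ("pathologic", "kyphoplasty_uptake", 5),
    ("pathologic", "liver_lesion", 5),
    ("pathologic", "parotid_inflammation", 5),
    ("pathologic", "adrenal_adenoma", 4),
    ("pathologic", "skin_lesion", 3),
    ("pathologic", "colon_polyp", 3),
]

#: Missed metastatic lesions by site (30 M-category false negatives).
M_FN_SITES = [
    ("contralateral_pulmonary", 11),
    ("liver", 6),
    ("brain", 4),
    ("adrenal_gland", 3),
    ("distant_lymph_node", 2),
    ("peritoneal", 1),
    ("bone", 1),
    ("pleura", 1),
    ("kidney", 1),
]

#: Ground-truth -> predicted UICC stage pairs instantiating the cohort's
#: migration structure: 207 concordant, 26 discordant within a boundary band,
#: 56 crossing one decision boundary, 17 crossing both.  Representative stage
#: pairs are chosen per cell; the impact table depends only on the crossing
#: counts, and upward shifts concentrate on the IIIA/IIIB -> IVA edges the
#: cohort predominantly showed.
STAGE_MIGRATION_CELLS = [
    # concordant (None impact): 207 patients
    ("IA1", "IA1", 15), ("IA2", "IA2", 20), ("IA3", "IA3", 15),
    ("IB", "IB", 25), ("IIA", "IIA", 20), ("IIB", "IIB", 25),
    ("IIIA", "IIIA", 35), ("IIIB", "IIIB", 20), ("IIIC", "IIIC", 7),
    ("IVA", "IVA", 15), ("IVB", "IVB", 10),
    # discordant within a band (Low): 22 up, 4 down
    ("IIA", "IIB", 8), ("IIB", "IIIA", 7), ("IIIA", "IIIB", 7),
    ("IIIB", "IIIA", 2), ("IIB", "IIA", 2),
    # one boundary crossed (Moderate): 50 up, 6 down
    ("IIIA", "IVA", 20), ("IIIB", "IVA", 22), ("IB", "IIA", 8),
    ("IVA", "IIIB", 3), ("IIA", "IB", 3),
    # both boundaries crossed (High): 16 up, 1 down
    ("IB", "IVA", 10), ("IA3", "IVB", 6),
    ("IVA", "IB", 1),
]


def detection_fixture() -> list[tuple[list[Lesion], list[Lesion], MatchResult]]:
    """Synthetic categorized match results reproducing DETECTION_COUNTS.

    One pseudo-patient per category: tp one-to-one pairs, fn unmatched
    ground-truth lesions, fp unmatched predictions.  Lesions carry no voxel
    data — only the counts matter for detection statistics.
    """
    cases = []
    for row in DETECTION_COUNTS.itertuples():
        gt, pred = [], []
        match = MatchResult()
        for i in range(1, row.tp + row.fn + 1):
            gt.append(Lesion(i, GROUND_TRUTH, 1, 0.001, category=row.category))
        for j in range(1, row.tp + row.fp + 1):
            pred.append(Lesion(j, PREDICTED, 1, 0.001, category=row.category))
        for i in range(1, row.tp + 1):
            match.tp_pairs.add((i, i))
            match.overlap_voxels[(i, i)] = 1
        match.fn_ids = set(range(row.tp + 1, row.tp + row.fn + 1))
        match.fp_ids = set(range(row.tp + 1, row.tp + row.fp + 1))
        cases.append((gt, pred, match))
    return cases


def m_fp_lesion_fixture() -> list[Lesion]:
    """The 196 M-category false positives as etiology-tagged lesions."""
    lesions = []
    i = 1
    for cls, label, n in M_FP_ETIOLOGY:
        for _ in range(n):
            lesions.append(
                Lesion(i, PREDICTED, 1, 0.001, category="M",
                       etiology_class=cls, etiology=label)
            )
            i += 1
    return lesions


def m_fn_sidecar_rows() -> pd.DataFrame:
    """The missed-metastasis site list as a validated sidecar table."""
    rows = []
    i = 1
    for site, n in M_FN_SITES:
        for _ in range(n):
            rows.append(
                {"lesion_id": i, "category": "M", "station_or_organ": site,
                 "invasion_flags": "", "etiology_class": "tumour",
                 "etiology": None, "diameter_mm": None}
            )
            i += 1
    return pd.DataFrame(rows)


def stage_migration_cohort(
    boundaries: DecisionBoundaries | None = None,
) -> list[MigrationRecord]:
    """The 306-patient stage-pair cohort as per-patient migration records."""
    boundaries = boundaries or DecisionBoundaries()
    records = []
    i = 0
    for gt, pred, n in STAGE_MIGRATION_CELLS:
        for _ in range(n):
            records.append(make_record(f"R{i:04d}", gt, pred, boundaries))
            i += 1
    return records
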