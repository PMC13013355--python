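"""Stage-migration analysis: concordance, boundary crossings, clinical impact.

Ground-truth and predicted UICC stages are compared per patient on the ordinal
scale Occult < IA1 < IA2 < IA3 < IB < IIA < IIB < IIIA < IIIB < IIIC < IVA <
IVB.  A higher predicted stage is *upstaging*, a lower one *downstaging*.

Clinical relevance is graded against simplified decision boundaries, by
default IB|IIA (surgery with selective adjuvant therapy vs routine adjuvant
systemic treatment) and IIIC|IVA (potentially curative multimodal therapy vs
predominantly palliative systemic therapy):

* High      — migration across both boundaries
* Moderate  — migration across one boundary
* Low       — discordant but within the same boundary band
* None      — concordant staging
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .metrics import round_pct
from .staging import StageAssignment, collapse_n2

UICC_ORDER = [
    "Occult",
    "IA1",
    "IA2",
    "IA3",
    "IB",
    "IIA",
    "IIB",
    "IIIA",
    "IIIB",
    "IIIC",
    "IVA",
    "IVB",
]

IMPACT_LEVELS = ("None", "Low", "Moderate", "High")
DIRECTIONS = ("concordant", "upstaging", "downstaging")


def _stage_index(stage: str, order=None) -> int:
    order = order or UICC_ORDER
    try:
        return order.index(stage)
    except ValueError:
        raise ValueError(f"unknown UICC stage {stage!r}") from None


@dataclass(frozen=True)
class DecisionBoundaries:
    """Ordered stage transitions at which treatment strategy changes.

    Each boundary is the pair of adjacent stages it separates, e.g.
    ("IB", "IIA").
    """

    boundaries: tuple[tuple[str, str], ...] = (("IB", "IIA"), ("IIIC", "IVA"))
    stage_order: tuple[str, ...] = tuple(UICC_ORDER)

    def __post_init__(self) -> None:
        positions = []
        for low, high in self.boundaries:
            i, j = _stage_index(low, list(self.stage_order)), _stage_index(
                high, list(self.stage_order)
            )
            if j != i + 1:
                raise ValueError(f"boundary {low}|{high} is not between adjacent stages")
            positions.append(i + 0.5)
        if positions != sorted(set(positions)):
            raise ValueError("boundaries must be distinct and ordered")
        object.__setattr__(self, "_positions", tuple(positions))

    @property
    def positions(self) -> tuple[float, ...]:
        return self._positions


DEFAULT_BOUNDARIES = DecisionBoundaries()


def classify_migration(gt_stage: str, pred_stage: str) -> str:
    """concordant / upstaging (predicted higher) / downstaging (lower)."""
    i, j = _stage_index(gt_stage), _stage_index(pred_stage)
    if i == j:
        return "concordant"
    return "upstaging" if j > i else "downstaging"


def boundaries_crossed(
    gt_stage: str, pred_stage: str, boundaries: DecisionBoundaries = DEFAULT_BOUNDARIES
) -> int:
    """Number of decision boundaries strictly between the two stages."""
    i, j = _stage_index(gt_stage), _stage_index(pred_stage)
    lo, hi = min(i, j), max(i, j)
    return sum(1 for p in boundaries.positions if lo < p < hi)


def impact_level(n_crossed: int, direction: str) -> str:
    """Impact grade from boundary crossings: 2=High, 1=Moderate, 0=Low/None."""
    if direction == "concordant":
        return "None"
    return {2: "High", 1: "Moderate", 0: "Low"}[n_crossed]


@dataclass
class MigrationRecord:
    patient_id: str
    gt_stage: str
    pred_stage: str
    direction: str
    boundaries_crossed: int
    impact: str


def make_record(
    patient_id: str,
    gt_stage: str,
    pred_stage: str,
    boundaries: DecisionBoundaries = DEFAULT_BOUNDARIES,
) -> MigrationRecord:
    direction = classify_migration(gt_stage, pred_stage)
    crossed = boundaries_crossed(gt_stage, pred_stage, boundaries)
    return MigrationRecord(
        patient_id=patient_id,
        gt_stage=gt_stage,
        pred_stage=pred_stage,
        direction=direction,
        boundaries_crossed=crossed,
        impact=impact_level(crossed, direction),
    )


@dataclass
class CohortMigrationSummary:
    """Cohort-level migration tables.

    ``impact_table`` has one row per (impact, direction) cell with counts and
    one-decimal percentages of the full cohort.  ``confusion`` maps component
    name (t, n, m, uicc) to a ground-truth × predicted count matrix.
    ``sankey_edges`` lists (source stage, target stage, count) transitions.
    """

    n_patients: int
    impact_table: pd.DataFrame
    confusion: dict[str, pd.DataFrame] = field(default_factory=dict)
    sankey_edges: list[dict] = field(default_factory=list)
    concordant: int = 0
    upstaged: int = 0
    downstaged: int = 0
    within_boundary: int = 0

    @property
    def concordance_pct(self) -> float:
        return round_pct(100 * self.concordant / self.n_patients)

    @property
    def within_boundary_pct(self) -> float:
        return round_pct(100 * self.within_boundary / self.n_patients)


def _confusion_matrix(pairs, labels) -> pd.DataFrame:
    """Rows: ground truth; columns: predicted; marginals equal stage histograms."""
    seen = [l for l in labels if any(l in p for p in pairs)]
    mat = pd.DataFrame(0, index=seen, columns=seen, dtype=int)
    for gt, pred in pairs:
        mat.loc[gt, pred] += 1
    return mat


def summarize_cohort(
    records: list[MigrationRecord],
    stage_assignments: list[tuple[StageAssignment, StageAssignment]] | None = None,
    collapse_n2_categories: bool = False,
) -> CohortMigrationSummary:
    """Aggregate per-patient migration records into cohort tables."""
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient ids: {dupes}")
    n = len(records)
    rows = []
    for impact in IMPACT_LEVELS:
        dirs = ("concordant",) if impact == "None" else ("upstaging", "downstaging")
        for direction in dirs:
            count = sum(1 for r in records if r.impact == impact and r.direction == direction)
            rows.append(
                {
                    "impact": impact,
                    "direction": direction,
                    "n": count,
                    "pct": round_pct(100 * count / n) if n else float("nan"),
                }
            )
    impact_table = pd.DataFrame(rows)

    confusion: dict[str, pd.DataFrame] = {}
    if stage_assignments:
        t_labels = ["Tx", "T1a", "T1b", "T1c", "T2a", "T2b", "T3", "T4"]
        n_labels = (
            ["N0", "N1", "N2", "N3"]
            if collapse_n2_categories
            else ["N0", "N1", "N2a", "N2b", "N3"]
        )
        m_labels = ["M0", "M1a", "M1b", "M1c"]
        getters = {
            "t": (lambda a: a.t, t_labels),
            "n": (
                (lambda a: collapse_n2(a.n)) if collapse_n2_categories else (lambda a: a.n),
                n_labels,
            ),
            "m": (lambda a: a.m, m_labels),
            "uicc": (lambda a: a.uicc, UICC_ORDER),
        }
        for name, (get, labels) in getters.items():
            pairs = [(get(gt), get(pred)) for gt, pred in stage_assignments]
            confusion[name] = _confusion_matrix(pairs, labels)

    edges = (
        pd.DataFrame(
            [(r.gt_stage, r.pred_stage) for r in records], columns=["source", "target"]
        )
        .value_counts()
        .rename("count")
        .reset_index()
        .sort_values(["source", "target"])
    )
    sankey_edges = edges.to_dict("records")

    return CohortMigrationSummary(
        n_patients=n,
        impact_table=impact_table,
        confusion=confusion,
        sankey_edges=sankey_edges,
        concordant=sum(1 for r in records if r.direction == "concordant"),
        upstaged=sum(1 for r in records if r.direction == "upstaging"),
        downstaged=sum(1 for r in records if r.direction == "downstaging"),
        within_boundary=sum(1 for r in records if r.boundaries_crossed == 0),
    )
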