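"""Rule-based TNM categorization and UICC stage grouping.

Patient-level T, N and M categories are derived from a categorized lesion set
by explicit rules and mapped to a UICC stage group through a versioned lookup
table (builtin: the 9th edition for NSCLC, shipped as a YAML data file so a
different edition can be swapped in).

* T: largest T-lesion axial diameter via the size-threshold table, upgraded by
  any invasion flag (invasion flags come only from metadata — infiltration
  cannot be read off a binary mask).  No T lesion yields Tx: primaries can be
  PET-occult, so absence of an avid primary is "unassessable", not T0.
* N: nodal stations map to base levels N1/N2/N3; N2 is split into N2a (single
  involved N2 station) and N2b (multiple N2 stations); the maximum level wins.
* M: intrathoracic spread (contralateral lung, pleural/pericardial) is M1a; a
  single extrathoracic lesion M1b; multiple extrathoracic lesions M1c.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .lesion_analysis import Lesion


class StagingError(ValueError):
    """Raised for invalid rules files or unknown station/site labels."""


@dataclass
class StageRules:
    """Validated staging rule set: thresholds, maps and the UICC lookup."""

    version: str
    stage_order: list[str]
    t_order: list[str]
    n_order: list[str]
    m_order: list[str]
    t_size_thresholds: list[tuple[float | None, str]]  # (max_mm, category)
    invasion_map: dict[str, str]
    n_station_map: dict[str, str]
    m_intrathoracic_sites: set[str]
    m_extrathoracic_sites: set[str]
    uicc_lookup: dict[tuple[str, str, str], str]

    def stage_index(self, stage: str) -> int:
        return self.stage_order.index(stage)

    def lookup(self, t: str, n: str, m: str) -> str:
        try:
            return self.uicc_lookup[(t, n, m)]
        except KeyError:
            raise StagingError(f"no UICC stage for ({t}, {n}, {m})") from None


def _validate(rules: StageRules) -> StageRules:
    bounds = [b for b, _ in rules.t_size_thresholds if b is not None]
    if bounds != sorted(bounds) or len(set(bounds)) != len(bounds):
        raise StagingError(f"t_size_thresholds not strictly increasing: {bounds}")
    if rules.t_size_thresholds[-1][0] is not None:
        raise StagingError("t_size_thresholds must end with an unbounded category")
    for t, n, m in itertools.product(rules.t_order, rules.n_order, rules.m_order):
        if (t, n, m) not in rules.uicc_lookup:
            raise StagingError(f"uicc_lookup is not total: missing cell ({t}, {n}, {m})")
    for key, stage in rules.uicc_lookup.items():
        if stage not in rules.stage_order:
            raise StagingError(f"unknown stage {stage!r} at {key}")
    violations = monotonicity_violations(rules)
    if violations:
        raise StagingError(f"uicc_lookup not monotone, e.g. {violations[0]}")
    return rules


def monotonicity_violations(rules: StageRules) -> list[tuple]:
    """Cells where raising exactly one of T/N/M lowers the UICC stage.

    Exhaustive scan over the category grid; an empty list certifies the
    staging table is order-consistent.
    """
    out = []
    axes = {"t": rules.t_order, "n": rules.n_order, "m": rules.m_order}
    for t, n, m in itertools.product(rules.t_order, rules.n_order, rules.m_order):
        base = rules.stage_index(rules.lookup(t, n, m))
        for axis, order in axes.items():
            cur = {"t": t, "n": n, "m": m}
            i = order.index(cur[axis])
            if i + 1 >= len(order):
                continue
            cur[axis] = order[i + 1]
            nxt = rules.stage_index(rules.lookup(cur["t"], cur["n"], cur["m"]))
            if nxt < base:
                out.append(((t, n, m), axis, (cur["t"], cur["n"], cur["m"])))
    return out


def load_stage_rules(source: str | Path = "ninth_edition") -> StageRules:
    """Load a rules file (builtin id or path) and validate its invariants."""
    if isinstance(source, str) and not source.endswith((".yaml", ".yml", ".json")):
        text = (resources.files("lesioneval") / "data" / f"{source}.yaml").read_text()
    else:
        text = Path(source).read_text()
    raw = yaml.safe_load(text)
    lookup = {
        (t, n, m): stage
        for t, by_n in raw["uicc_lookup"].items()
        for n, by_m in by_n.items()
        for m, stage in by_m.items()
    }
    rules = StageRules(
        version=str(raw["version"]),
        stage_order=list(raw["stage_order"]),
        t_order=list(raw["t_order"]),
        n_order=list(raw["n_order"]),
        m_order=list(raw["m_order"]),
        t_size_thresholds=[
            (row["max_mm"], row["category"]) for row in raw["t_size_thresholds_mm"]
        ],
        invasion_map=dict(raw["invasion_map"]),
        n_station_map=dict(raw["n_station_map"]),
        m_intrathoracic_sites=set(raw["m_intrathoracic_sites"]),
        m_extrathoracic_sites=set(raw["m_extrathoracic_sites"]),
        uicc_lookup=lookup,
    )
    return _validate(rules)


@dataclass
class StageAssignment:
    """Per-patient T/N/M categories, UICC stage and driving lesions."""

    patient_id: str
    t: str
    n: str
    m: str
    uicc: str
    provenance: dict[str, list[int]] = field(default_factory=dict)


def _t_max(rules: StageRules, a: str, b: str) -> str:
    return a if rules.t_order.index(a) >= rules.t_order.index(b) else b


def derive_t(t_lesions: list[Lesion], rules: StageRules) -> tuple[str, list[int]]:
    """T category from the largest lesion's diameter, upgraded by invasion."""
    if not t_lesions:
        return "Tx", []
    largest = max(t_lesions, key=lambda l: (l.diameter_mm or 0.0, -l.lesion_id))
    d = largest.diameter_mm or 0.0
    category = rules.t_size_thresholds[-1][1]
    for bound, cat in rules.t_size_thresholds:
        if bound is not None and d <= bound:
            category = cat
            break
    drivers = [largest.lesion_id]
    for les in t_lesions:
        for flag in les.invasion_flags:
            if flag not in rules.invasion_map:
                raise StagingError(f"unknown invasion flag {flag!r}")
            upgraded = _t_max(rules, category, rules.invasion_map[flag])
            if upgraded != category:
                category = upgraded
                drivers.append(les.lesion_id)
    return category, sorted(set(drivers))


def derive_n(n_lesions: list[Lesion], rules: StageRules) -> tuple[str, list[int]]:
    """Maximum nodal level over involved stations; N2 split by station count."""
    if not n_lesions:
        return "N0", []
    levels: dict[str, list[Lesion]] = {"N1": [], "N2": [], "N3": []}
    for les in n_lesions:
        station = les.station_or_organ
        if station not in rules.n_station_map:
            raise StagingError(f"unknown nodal station {station!r}")
        levels[rules.n_station_map[station]].append(les)
    if levels["N3"]:
        return "N3", sorted(l.lesion_id for l in levels["N3"])
    if levels["N2"]:
        stations = {l.station_or_organ for l in levels["N2"]}
        cat = "N2a" if len(stations) == 1 else "N2b"
        return cat, sorted(l.lesion_id for l in levels["N2"])
    if levels["N1"]:
        return "N1", sorted(l.lesion_id for l in levels["N1"])
    return "N0", []


def derive_m(m_lesions: list[Lesion], rules: StageRules) -> tuple[str, list[int]]:
    """M0 / M1a (intrathoracic) / M1b (single extrathoracic) / M1c (multiple)."""
    if not m_lesions:
        return "M0", []
    intra, extra = [], []
    for les in m_lesions:
        site = les.station_or_organ
        if site in rules.m_intrathoracic_sites:
            intra.append(les)
        elif site in rules.m_extrathoracic_sites:
            extra.append(les)
        else:
            raise StagingError(f"unknown metastatic site {site!r}")
    if len(extra) >= 2:
        return "M1c", sorted(l.lesion_id for l in extra)
    if len(extra) == 1:
        return "M1b", [extra[0].lesion_id]
    return "M1a", sorted(l.lesion_id for l in intra)


def stage_patient(
    lesions: list[Lesion], rules: StageRules, patient_id: str = ""
) -> StageAssignment:
    """Compose T/N/M from a categorized lesion set and look up the UICC stage.

    Run independently on the ground-truth and the predicted lesion sets of a
    patient, so segmentation errors are carried forward into staging.
    """
    t_lesions = [l for l in lesions if l.category == "T"]
    n_lesions = [l for l in lesions if l.category == "N"]
    m_lesions = [l for l in lesions if l.category == "M"]
    t, t_ids = derive_t(t_lesions, rules)
    n, n_ids = derive_n(n_lesions, rules)
    m, m_ids = derive_m(m_lesions, rules)
    return StageAssignment(
        patient_id=patient_id,
        t=t,
        n=n,
        m=m,
        uicc=rules.lookup(t, n, m),
        provenance={"t": t_ids, "n": n_ids, "m": m_ids},
    )


def collapse_n2(category: str) -> str:
    """Collapse the 9th-edition N2a/N2b subdivision for reporting."""
    return "N2" if category in ("N2a", "N2b") else category


def assignments_to_table(assignments: list[StageAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"patient_id": a.patient_id, "t": a.t, "n": a.n, "m": a.m, "uicc": a.uicc}
            for a in assignments
        ]
    )
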