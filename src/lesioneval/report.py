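"""Write and render cohort evaluation reports.

``write_evaluation`` persists a CohortEvaluation as CSV/JSON files with full
provenance (tool version, rules version, config hash, seed).  ``render``
produces a human-readable summary, structured voxel metrics -> lesion errors
-> TNM confusion -> UICC migration/impact, as markdown or JSON carrying the
same numbers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .migration import IMPACT_LEVELS
from .pipeline import CohortEvaluation

SUMMARY_FILE = "summary.json"
REQUIRED_FILES = (SUMMARY_FILE, "per_patient.csv", "run.json")


class ReportError(ValueError):
    pass


def write_evaluation(
    ev: CohortEvaluation,
    outdir: str | Path,
    rules_version: str,
    seed: int | None = None,
    config: dict | None = None,
) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ev.per_patient.to_csv(outdir / "per_patient.csv", index=False)
    ev.detection.table.to_csv(outdir / "detection_stats.csv")
    ev.m_fp_taxonomy.by_class.to_csv(outdir / "m_fp_taxonomy.csv")
    ev.m_fp_taxonomy.by_label.to_csv(outdir / "m_fp_taxonomy_labels.csv", index=False)
    ev.migration.impact_table.to_csv(outdir / "impact_table.csv", index=False)
    for name, mat in ev.migration.confusion.items():
        mat.to_csv(outdir / f"confusion_{name}.csv")
    (outdir / "sankey_edges.json").write_text(
        json.dumps(ev.migration.sankey_edges, indent=1)
    )
    (outdir / SUMMARY_FILE).write_text(json.dumps(ev.summary_dict(), indent=1))
    config = config or {}
    run = {
        "tool_version": __version__,
        "rules_version": rules_version,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
    }
    (outdir / "run.json").write_text(json.dumps(run, indent=1))
    return outdir


def load_summary(results_dir: str | Path) -> dict:
    results_dir = Path(results_dir)
    missing = [f for f in REQUIRED_FILES if not (results_dir / f).exists()]
    if missing:
        raise ReportError(f"missing evaluation outputs in {results_dir}: {missing}")
    return json.loads((results_dir / SUMMARY_FILE).read_text())


def render(summary: dict, fmt: str = "md") -> str:
    """Render a summary dict as markdown or JSON (identical numbers)."""
    if fmt == "json":
        return json.dumps(summary, indent=1)
    if fmt != "md":
        raise ReportError(f"unknown format {fmt!r}")
    lines = [
        "# Cohort evaluation report",
        "",
        f"Patients: {summary['n_patients']}",
        "",
        "## Voxel metrics",
        "",
        f"- mean DSC: {summary['voxel']['mean_dsc']:.4f}",
        f"- mean FNV: {summary['voxel']['mean_fnv_ml']:.4f} mL",
        f"- mean FPV: {summary['voxel']['mean_fpv_ml']:.4f} mL",
    ]
    if "tmtv_bias_ml" in summary["voxel"]:
        lo, hi = summary["voxel"]["tmtv_loa_ml"]
        lines.append(
            f"- TMTV bias: {summary['voxel']['tmtv_bias_ml']:.4f} mL "
            f"(LoA {lo:.4f} to {hi:.4f} mL)"
        )
    lines += ["", "## Lesion detection", ""]
    lines.append("| category | tp | fn | fp | sensitivity % | precision % |")
    lines.append("|---|---|---|---|---|---|")
    for cat, row in summary["detection"].items():
        sens = "-" if row["sensitivity_pct"] is None else row["sensitivity_pct"]
        prec = "-" if row["precision_pct"] is None else row["precision_pct"]
        lines.append(
            f"| {cat} | {row['tp']} | {row['fn']} | {row['fp']} | {sens} | {prec} |"
        )
    lines += ["", "## M-category false-positive taxonomy", ""]
    lines.append("| etiology class | n | share % |")
    lines.append("|---|---|---|")
    for cls, row in summary["m_fp_taxonomy"].items():
        lines.append(f"| {cls} | {row['n']} | {row['share_pct']} |")
    mig = summary["migration"]
    lines += [
        "",
        "## UICC stage migration",
        "",
        f"- concordant: {mig['concordant']} ({mig['concordance_pct']}%)",
        f"- upstaged: {mig['upstaged']}; downstaged: {mig['downstaged']}",
        f"- within decision boundaries: {mig['within_boundary']} "
        f"({mig['within_boundary_pct']}%)",
        "",
        "| impact | direction | n | % |",
        "|---|---|---|---|",
    ]
    cells = {(r["impact"], r["direction"]): r for r in mig["impact_table"]}
    for impact in IMPACT_LEVELS:
        dirs = ("concordant",) if impact == "None" else ("upstaging", "downstaging")
        for d in dirs:
            r = cells.get((impact, d), {"n": 0, "pct": 0.0})
            lines.append(f"| {impact} | {d} | {r['n']} | {r['pct']} |")
    return "\n".join(lines) + "\n"
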