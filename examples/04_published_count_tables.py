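"""Recompute ratio statistics from the published 306-patient count tables.

The per-category detection counts, the M-category false-positive etiology
tallies, and the cohort's stage-migration cells are fixed published inputs;
every percentage below is recomputed by the package from those counts.
"""

from lesioneval import detection_stats, summarize_cohort, taxonomy_tally
from lesioneval.benchmarks import (
    detection_fixture,
    m_fp_lesion_fixture,
    stage_migration_cohort,
)

det = detection_stats(detection_fixture()).table
print("lesion detection (per category and pooled):")
print(det[["tp", "fn", "fp", "sensitivity_pct", "precision_pct"]].to_string())

tal = taxonomy_tally(m_fp_lesion_fixture())
print(f"\nM-category false-positive taxonomy (n={tal.total}):")
print(tal.by_class.to_string())

mig = summarize_cohort(stage_migration_cohort())
print("\nUICC stage-migration impact table:")
print(mig.impact_table.to_string(index=False))
print(
    f"\nconcordant {mig.concordant}/{mig.n_patients} ({mig.concordance_pct}%), "
    f"within decision boundaries {mig.within_boundary} ({mig.within_boundary_pct}%)"
)
print("\nSensitivity = TP / gt lesions; precision = TP / predictions; shares are")
print("percentages of all M-category false positives; impact grades count crossings")
print("of the IB|IIA and IIIC|IVA treatment boundaries.")
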