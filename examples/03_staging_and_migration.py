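"""Rule-based TNM/UICC staging and the clinical impact of one missed lesion.

Stages a patient from an annotated lesion set, then re-stages after deleting
the solitary liver metastasis — the hazardous false-negative downstaging
pathway where a palliative-stage patient looks curable.
"""

from lesioneval import load_stage_rules, make_record, stage_patient
from lesioneval.lesion_analysis import Lesion


def lesion(i, category, station=None, diameter=None, invasion=()):
    return Lesion(i, "ground_truth", 1, 0.5, category=category,
                  station_or_organ=station, diameter_mm=diameter,
                  invasion_flags=invasion)


rules = load_stage_rules("ninth_edition")

lesions = [
    lesion(1, "T", diameter=28.0),                      # 2.8 cm primary -> T1c
    lesion(2, "N", station="ipsilateral_hilar"),        # N1 node
    lesion(3, "M", station="liver"),                    # solitary metastasis -> M1b
]
truth = stage_patient(lesions, rules, "patient-1")
print(f"ground truth : {truth.t} {truth.n} {truth.m} -> UICC {truth.uicc}")

predicted = stage_patient(lesions[:2], rules, "patient-1")  # liver lesion missed
print(f"prediction   : {predicted.t} {predicted.n} {predicted.m} -> UICC {predicted.uicc}")

record = make_record("patient-1", truth.uicc, predicted.uicc)
print(
    f"migration    : {record.direction}, {record.boundaries_crossed} decision "
    f"boundary crossed -> impact {record.impact}"
)
print("\nMissing the solitary liver metastasis downstages IVA to IIA across the")
print("IIIC|IVA boundary: a palliative-intent patient would look operable.")
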