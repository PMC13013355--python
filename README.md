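# lesioneval

Task-aware evaluation of AI lesion segmentations in whole-body oncologic
PET/CT, aimed at researchers who need to know not just *how well a model
overlaps* an expert's masks, but *what its errors would do to the patient's
cancer stage*.

Voxel overlap metrics (Dice) reward bulk agreement and say little about the
clinically decisive failure modes of automated whole-body lesion
segmentation: a missed solitary metastasis, a spurious focus of benign uptake
read as distant disease, or a primary tumour fused with hilar nodes.
`lesioneval` evaluates paired ground-truth/predicted label volumes along the
whole chain from voxels to treatment-relevant stage:

1. **Voxel metrics** — Dice similarity coefficient (DSC = 2|A∩B|/(|A|+|B|)),
   component-based false-negative volume (FNV) and false-positive volume
   (FPV), total metabolic tumour volume (TMTV), and Bland–Altman agreement of
   TMTV (bias ± 1.96 SD limits of agreement).
2. **Lesion detection** — 3D connected components (6/18/26-connectivity) are
   matched by overlap; sensitivity = TP/(TP+FN) and precision = TP/(TP+FP)
   per T/N/M category and pooled, with merge events (one predicted component
   spanning several lesions) tracked explicitly, and false positives tallied
   by etiology class (physiologic / benign / pathologic non-oncologic).
3. **Rule-based staging** — patient-level T (size thresholds + invasion
   flags), N (nodal station map with the N2a/N2b single/multi-station split)
   and M (M1a/M1b/M1c) categories are derived independently from the
   ground-truth and predicted lesion sets and mapped to UICC stage groups
   through a versioned 9th-edition lookup table shipped as editable YAML.
4. **Stage migration** — per-patient up/down-staging, confusion matrices,
   Sankey transition edges, and clinical impact levels graded by crossings of
   the IB|IIA and IIIC|IVA treatment decision boundaries
   (High = both crossed, Moderate = one, Low = discordant within a band).

A **synthetic phantom module** generates paired mask cohorts with spherical
lesions across T/N/M compartments and injects controlled, fully logged
errors — deletions, taxonomy-tagged false positives, boundary
dilation/erosion, hilar merges — so every stage of the pipeline is testable
without patient data.

## Worked example

```python
from lesioneval import load_stage_rules, make_record, stage_patient
from lesioneval.lesion_analysis import Lesion

rules = load_stage_rules("ninth_edition")
lesions = [
    Lesion(1, "ground_truth", 1, 0.5, category="T", diameter_mm=28.0),
    Lesion(2, "ground_truth", 1, 0.5, category="N",
           station_or_organ="ipsilateral_hilar"),
    Lesion(3, "ground_truth", 1, 0.5, category="M", station_or_organ="liver"),
]
truth = stage_patient(lesions, rules)          # full lesion set
pred = stage_patient(lesions[:2], rules)       # liver metastasis missed
record = make_record("patient-1", truth.uicc, pred.uicc)
print(truth.uicc, pred.uicc, record.direction, record.impact)
```

prints

```
IVA IIA downstaging Moderate
```

A 2.8 cm primary (T1c) with a hilar node (N1) and a solitary liver metastasis
(M1b) is stage IVA; missing that one lesion yields T1c N1 M0 = IIA — a
downstaging across the IIIC|IVA boundary, i.e. a palliative-stage patient who
would look operable.  The `examples/` directory has one short script per
capability (phantom simulation, voxel/lesion metrics, staging and migration,
published count tables), each printing the numbers it computes.

## Command line

```bash
lesioneval simulate --out cohort/ --n 20 --seed 7      # synthetic cohort
lesioneval evaluate --cohort cohort/ --out results/    # full evaluation
lesioneval report --in results/ --format md            # human-readable summary
```

`evaluate` also accepts `--gt/--pred` directories of NIfTI files paired by
filename stem, with optional per-patient sidecar CSVs carrying lesion
annotations (category, nodal station/organ, invasion flags, etiology).

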