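# Methods

## Scope and model of the problem

`lesioneval` evaluates automated lesion segmentations of whole-body oncologic
FDG PET/CT against expert reference masks for the task of NSCLC TNM staging.
Inputs are paired 3D integer label volumes on a common grid (ground truth may
be instance-labelled; predictions may be binary), plus per-lesion metadata:
T/N/M category, nodal station or organ, invasion flags, and — for non-tumour
uptake — an etiology class and label.  Intensity data (SUV) is out of scope:
every computation operates on masks and metadata.

## Geometry and conventions

Volumes are canonicalized to RAS+ voxel ordering on read; ground truth and
prediction must share shape and spacing — mismatched grids are rejected, not
resampled, because silent interpolation would corrupt component-level
bookkeeping.  Voxel indices are 0-based, box extents half-open.  Volume in mL
is `voxel_count × voxel_volume_mm³ / 1000`.

A *lesion* is one connected component of a positive label under a chosen 3D
adjacency; the default is 26-connectivity (full 3D), the common choice in
challenge-style evaluation, and configurable because the convention is not
universal.  No minimum component size is applied: every predicted component
counts, however small.

Axial diameter is the maximum pairwise in-plane distance between voxel
centres over axial slices plus one in-plane voxel width (so a single voxel
has diameter one voxel width).  Clinical T-size is measured on axial
sections, which is why no 3D Feret diameter is used.  The added voxel width
makes the rasterized diameter of a sphere converge on its analytic diameter
to within one voxel.

## Matching and metrics

A predicted component is a true positive if it overlaps any ground-truth
lesion by at least `min_overlap_voxels` (default 1 — the zero-overlap
definition that component-based FNV/FPV imply).  An optional IoU threshold
can be layered on top but is off by default.  One predicted component
overlapping several ground-truth lesions detects all of them (each counts as
TP for sensitivity) but contributes once to precision's denominator, and the
event is recorded as a merge — the hilar-convergence failure mode is a
staging problem, not a detection failure.  False positives inherit the
compartment holding the majority of their voxels (ties broken by centroid);
a false positive outside every compartment defaults to category M, because
the extrathoracic search space is where spurious uptake concentrates.  A
false positive without a sidecar annotation is assigned a "benign"
placeholder etiology and explicitly flagged `unannotated`, never silently
dropped.

Dice of two empty masks is defined as 1.0 (a correct negative) and logged
with a warning; the value is a convention, not a measurement.  Bland–Altman
limits of agreement use the sample (n−1) standard deviation and the 1.96
multiplier.  Pooled detection statistics are micro-averages over summed
counts; a per-patient macro-average sensitivity is reported alongside since
pooled figures are sometimes averaged per patient, and the two differ.  A
category with zero ground-truth lesions has *undefined* sensitivity (NaN),
never 0.  All percentages round to one decimal, half away from zero.

Overlap-based matching is a proxy for reader-adjudicated truth: in a clinical
re-read, "true positive" means *interpreted as malignant*, which no overlap
rule can fully capture.  Results on real data should be read with that
caveat.

## Staging rules

The 9th-edition TNM tables are encoded in a versioned YAML data file
(`data/ninth_edition.yaml`) that is the single source of truth: T size cuts
(≤10/20/30/40/50/70 mm → T1a…T3, above → T4), an invasion-flag map (e.g.
chest wall → T3, mediastinum → T4), the nodal-station map with the N2a/N2b
single/multiple-station split, the M subdivisions (intrathoracic
contralateral/pleural → M1a, single extrathoracic → M1b, multiple → M1c), and
the full (T, N, M) → UICC lookup.  Loading validates totality over the
category cross-product, strictly increasing thresholds, and monotonicity:
raising exactly one of T/N/M never lowers the stage group.

Design choices where the rules leave room:

* **No primary yields Tx, not T0** — primaries can be PET-occult (e.g. lepidic
  T1mi adenocarcinoma), so an absent avid primary is "unassessable".
  Tx N0 M0 maps to the *Occult* stage group, placed below IA1 on the ordinal
  scale so migration arithmetic stays total; Tx with nodal or metastatic
  disease stages as the minimal T category would.
* **Invasion flags come only from metadata**, never inferred from masks:
  infiltration assessment requires anatomical CT correlation that a binary
  mask cannot provide.
* Predicted-lesion staging uses categories assigned by the matching step
  (inheritance for matched lesions, compartment majority for false
  positives), so segmentation errors are carried forward into staging rather
  than corrected.
* Both the subdivided (N2a/N2b) and a collapsed N2 reporting mode exist for
  confusion matrices, since either convention appears in practice.

## Migration and clinical impact

Stages are ordered Occult < IA1 < IA2 < IA3 < IB < IIA < IIB < IIIA < IIIB <
IIIC < IVA < IVB.  Decision boundaries default to IB|IIA (surgery with
selective adjuvant therapy vs routine adjuvant systemic therapy) and IIIC|IVA
(curative-intent multimodal vs predominantly palliative).  Impact is a pure
function of boundary crossings — High = 2, Moderate = 1, Low = discordant
with 0, None = concordant; treatment semantics are documentation, not
computation, because the impact table is fully determined by crossings.
Cohort percentages use the full cohort as denominator.

## The phantom generator

The generator emulates the study conditions of a clinical validation cohort,
not its images.  Lesions are rasterized spheres (centre-in-sphere rule)
placed without inter-lesion contact inside disjoint axis-aligned compartment
boxes standing in for the primary lung, nodal stations and distant organs.
Spheres make diameter and volume analytically known, so every downstream
measurement has a closed-form oracle.

Default conditions (grid 48³ at 4 mm isotropic — a coarse whole-body field of
view; radii 4–8 mm, primaries 5–20 mm so size-based T categories span
T1a–T2b): one primary per patient, Poisson lesion counts per nodal/metastatic
compartment chosen so roughly half the cohort is metastatic, as in a
treatment-naïve NSCLC staging population.  No published image-level lesion
size/count distributions exist for the reference cohort, so these defaults
are field-plausible placeholders rather than calibrated values.  The default
*error* profile, in contrast, is calibrated to published counts: per-category
miss rates 14/425 (T), 25/853 (N), 30/578 (M); per-patient false-positive
Poisson means from the published etiology tallies (e.g. 58 physiologic
M-category FPs / 306 patients); hilar-merge rate 11.1%.  Invasion flags are
drawn with probability 0.1 per primary.

Error operators act on whole components and are all logged: category-wise
deletions; dilation/erosion and a multiplicative volume bias per surviving
lesion (erosion that annihilates a lesion is logged as an implicit deletion);
a hilar merge realized as a 1-voxel-dilated corridor between the centroids of
a surviving primary and a surviving N1-station node; and taxonomy-tagged
spherical false positives placed in compartments of their category without
touching existing foreground.  The injection log and the per-component
false-positive sidecar exist for *tests and annotation*; the evaluator never
reads the log.

Determinism: one master seed, per-patient substreams by fixed offsets
(`[seed, patient, 0]` for ground truth, `[seed, patient, 1]` for injection),
so cohorts are byte-identical under regeneration and stable under partial
regeneration.

What passing phantom tests shows — and does not.  They verify the *measuring
instrument*: that matching, metrics, staging and migration recover exactly
the errors that were injected.  They do not validate performance on real
anatomy: spheres have no texture, no respiratory motion, no SUV ambiguity,
no reader disagreement, and compartment membership is exact rather than an
anatomical judgement.

## Problem sizes and numerical choices

The acceptance checks use 200 random ≤20³ mask pairs for oracle equivalence
(brute-force flood fill + voxel loops, independent of the scipy-based
implementation), a 50-patient zero-error cohort for end-to-end identity, and
a 200-patient cohort with deletion rate 0.2 and three Poisson false-positive
classes for recovery; the recovered deletion fraction is required to sit
within 3 binomial standard errors of the injected rate, and per-class
false-positive counts must match the injection log exactly.  Sphere placement
retries 200 times and then once more at the minimum radius before raising a
placement error.  Tie-breaks: compartment ties by centroid; equal-diameter
primaries by lower lesion id.  Degenerate inputs: empty masks give empty
lesion lists; both-empty Dice = 1.0; fewer than two TMTV pairs is an error
for Bland–Altman.

## Known limitations

* Overlap-based TP definition vs reader interpretation (above).
* The phantom's compartment geometry is schematic; station assignment of
  false positives in real data needs an anatomical atlas or human review.
* T-category derivation uses axial diameter of the rasterized mask; partial
  volume effects at coarse spacing can shift a lesion across a size cut.
* No support for DICOM-SEG/RTSTRUCT, resampling, SUV statistics, TLG, or
  surface-distance metrics (HD95) — out of scope by design.
* Treatment impact levels are a simplification: real decisions integrate
  performance status, comorbidity and molecular profile, which are not
  modelled.
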