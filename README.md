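# legcomp

Lower-extremity body composition from chemical-shift-encoded (Dixon) MRI:
semiautomated segmentation of subcutaneous adipose tissue (SAT) and skeletal
muscle, per-slice and decade-level composition metrics along the leg, Dice
validation, and rank-based group statistics.

**Who it is for.**  Researchers quantifying lower-extremity fat distribution
— e.g., distinguishing lipedema (disproportionate, bilateral subcutaneous
fat deposition in the legs) from obesity — from whole-body CSE-MRI, where
the fat-weighted, water-weighted and in-phase contrasts are already
reconstructed.  The package also ships a parametric two-leg phantom
generator with exact ground-truth labels, so the entire pipeline can be
exercised and validated without patient data.

## The method in brief

Each axial slice is partitioned in five deterministic steps:

1. leg boundary by Chan–Vese active contours on the in-phase image;
2. fat/water classification by locally adaptive mean thresholding, with a
   kernel side adapted to the anterior–posterior leg extent HBOX:
   `s = 2·⌊HBOX·¾ / 2⌋ + 1` (odd by construction) — robust to the bias
   fields that defeat a single global threshold in the extremities;
3. muscle: skin erosion (2×2), water-mask intersection, fat subtraction,
   small-object removal (<10 px), small-hole filling (<18 px), region-
   dependent closing (2 px calf / 4 px thigh), bone flood-fill;
4. SAT: fat minus filled muscle, 2 px opening, removal of round components
   (circularity 4πA/P² > 0.80, i.e., marrow) and small objects;
5. final muscle: subtraction of fat-weighted components not classified as
   SAT (intermuscular fat, marrow).

Per slice, SAT and muscle volumes (mL, both legs summed) and their ratio
are computed; slices are grouped into ten *decades* (10% of slices each,
decade 1 at the ankle) to normalize leg position across subjects.  Accuracy
is measured as the Dice similarity coefficient `DSC = 2|A∩G|/(|A|+|G|)` on
representative calf (decade 3) and thigh (decade 7) slices; groups are
compared with the Mann–Whitney U test (exact at small n, tie-corrected
normal approximation otherwise) and the effect size `r = |Z|/√N`.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Generate a 60-slice phantom, segment it, and validate against the truth:

```bash
legcomp phantom generate --seed 7 --n-slices 60 --out phantom/
legcomp segment --fat phantom/fat.nii.gz --water phantom/water.nii.gz \
    --inphase phantom/inphase.nii.gz --out seg/
legcomp evaluate --masks seg/masks.nii.gz --truth phantom/truth.nii.gz \
    --out dsc.json
```

`evaluate` prints the Dice of the automated SAT and muscle masks against
ground truth at the representative slices:

```json
{
  "calf":  {"slice": 15, "sat_dsc": 1.0,    "muscle_dsc": 1.0},
  "thigh": {"slice": 39, "sat_dsc": 0.9997, "muscle_dsc": 1.0}
}
```

`seg/slices.csv` holds per-slice metrics — e.g., slice 0 of this phantom:
HBOX 43 px, adaptive kernel 33 px, SAT 10.40 mL, muscle 7.67 mL, ratio
1.36, left-leg circumference 22.6 cm — and `seg/decades.csv` the decade
means (mean SAT volume rising 10.8 → 20.6 mL from ankle decade 1 to thigh
decade 10 as the leg widens).

A two-group analysis over a synthetic cohort (13 control-like vs 15
lipedema-like subjects, SAT thickened 1.75×):

```bash
legcomp phantom cohort --n-control 13 --n-lipedema 15 \
    --sat-multiplier 1.75 --n-slices 20 --seed 1 --out cohort/
legcomp study --cohort cohort/ --out study/ --plot
```

writes per-decade Mann–Whitney comparisons with effect sizes
(`study/study.json`), the DSC validation table, and a decade bar plot.  On
this synthetic cohort SAT volume and SAT-to-muscle ratio are significantly
elevated in every decade while muscle volume is not, and the ratio's effect
size exceeds limb circumference's — the discriminative pattern expected
when subcutaneous fat, not frame size or musculature, drives the group
difference.

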