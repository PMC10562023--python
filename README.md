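# vmatqa — virtual patient-specific QA for VMAT plans

Measurement-based patient-specific QA verifies, before treatment, that the
dose a linac delivers for a VMAT plan matches the planned dose, conventionally
by irradiating a detector phantom and computing gamma passing rates (GPR).
`vmatqa` implements the *virtual* alternative: a multi-branch convolutional
network that predicts a plan's GPR directly from the treatment plan and the
planned dose distribution, with no measurement.

The package is aimed at medical-physics researchers who want to study
plan-feature-based GPR prediction end to end: it covers DICOM RT-Plan/RT-Dose
ingestion, construction of the MLC leaf position map, a gamma engine, the
network and its training/evaluation protocol, and a synthetic plan/dose/label
simulator so every stage is testable without clinical data.

## The method

**MLC leaf position map (MLPM).** A single-arc VMAT plan is a sequence of
control points, each holding the positions of two opposing banks of 60 MLC
leaves. Arranging the 120 leaf coordinates of every control point as columns
gives a 2D image; each cell is mapped to the leaf's distance (mm) from its
pair's closed coordinate, so closed leaves read exactly 0. Leaf pairs closed
across the whole cohort are removed (120 → 110 rows at clinical scale),
giving a 110×178 image that encodes aperture shape and leaf motion over the
entire arc — including complexity structure that scalar metrics such as MCS
summarize away.

**Gamma passing rate.** For reference dose R and evaluated dose E the gamma
index at a point r is

    γ(r) = min_q sqrt( ((E(q) − R(r)) / (δ·D_max))² + (‖q − r‖ / Δ)² )

with dose tolerance δ (as a fraction of the global maximum D_max), DTA Δ, and
a 10% low-dose threshold; GPR is the percentage of points with γ ≤ 1. The
nine standard criteria {1,2,3}% × {1,2,3} mm form the network's output
vector.

**Network.** Each input image — sagittal/coronal/axial isocenter dose planes,
the MLPM, or an unrolled cylindrical surface dose — feeds a light branch of
three 3×3 convolution + 3×3/3 max-pool stages (16 channels) and an affine
embedding to 20 features. Branch embeddings are summed, pass a shared
ReLU → BatchNorm → Dropout(0.3) → Affine(20→20) trunk, and nine parallel
affine heads emit the nine GPRs. Three variants mirror the input study:
*model1* (three dose planes + MLPM), *model2* (dose planes only), *model3*
(surface dose only). Training: Adam, lr 0.001, batch 4, 200 epochs, MSE over
the nine outputs, 3:1 train/test split with 20% validation and 4-fold
cross-validation; the adopted weights are those of the best validation
epoch. The network is implemented directly on NumPy (the model has only
~10⁴–10⁵ parameters), with gradient correctness pinned by finite-difference
tests.

## Worked example

```bash
python examples/04_train_predict.py
```

```
trained on 32 plans; adopted epoch 199 (val loss 1.95e-04)
held-out 2%/2mm: MAE = 1.14%  Pearson r = +0.70
  measured  96.87%  predicted  96.53%
  measured 100.00%  predicted 101.88%
  measured  98.55%  predicted 100.42%
```

The MAE is the mean absolute gap between gamma-measured and predicted GPR on
held-out plans; the Pearson r says whether the model ranks delivery-fragile
plans below robust ones, which is the clinically useful property (a model
that always answers "98%" has a flattering MAE and a useless r). The other
examples build an MLPM from a DICOM plan (`01`), evaluate gamma criteria for
a perturbed delivery (`02`), and archive a labelled synthetic cohort (`03`).

A thin CLI wraps the same library calls:

```bash
vmatqa simulate --n 96 --seed 0 --out ds.h5
vmatqa train --dataset ds.h5 --variant model1 --seed 0 --out run/
vmatqa gamma --ref planned.npy --eval delivered.npy --dose-tol 2 --dta 2
```

## Scope

The package deliberately does not model dose calculation (doses enter as
grids), multi-arc plans, detector hardware geometry, or local-gamma /
DVH-based verification.
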