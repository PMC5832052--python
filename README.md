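# pqlung

Quantitative CT assessment of paraquat-induced acute lung injury.

Paraquat (PQ) poisoning damages the lung first: ground-glass opacity and
consolidation spread across serial CT scans, and how *fast* they spread
carries prognostic information. Plasma PQ assays — the standard
predictor — are not available in every hospital, whereas CT is. This
package implements an automated image-analysis chain that turns two
serial chest CT scans into a single prognostic number, the **ratio of
injured lung volume fractions**, for radiologists and emergency
physicians who need a lab-free severity estimate.

## Method

For each scan the chain is:

1. **Edge-preserving smoothing** — slice-wise Perona–Malik anisotropic
   diffusion (exponential conduction, κ = 50 HU, 10 iterations).
2. **Lung segmentation** — seeded region growing. A seed is placed in
   aerated lung near the pleura; a 40×40-pixel window centred on the
   seed supplies the local dynamic range, and a voxel joins the lung
   when it is connected to the seed and
   |CT(p) − CT(seed)| < 0.3·(CT_max − CT_min).
   Interior holes (vessels, dense injury) are filled so the whole-lung
   mask includes the tissue being graded.
3. **Tissue classification** — for every in-lung pixel, nine texture
   features over the 7×7 window (49 pixels): the pixel's HU value; mean,
   SD, max, min, skewness and kurtosis of the window; the 3-D mean-CT
   correlation rco = (P̄ⁿ − P̄ⁿ⁻¹)(P̄ⁿ − P̄ⁿ⁺¹), which flags
   partial-volume structures present on a single slice; and the air
   fraction, the share of window pixels below −825 HU. A feed-forward
   network with 18 sigmoid hidden units and a sigmoid output maps the
   standardized features to an injury probability (training capped at
   5000 iterations, 70/15/15 train/validation/test split).
4. **Vessel removal** — blood vessels share HU values with injured
   tissue; a multiscale Hessian (Frangi) filter scores tubular
   structures and the thresholded vessel mask is subtracted from the
   injury candidates.
5. **Volumetrics** — connected components smaller than 30 voxels are
   discarded; the injured lung volume fraction is
   f = V_injured / V_lung (voxel counts × voxel volume).

Given an admission scan and a follow-up scan the prognostic quantity is

    ratio = f_scan1 / f_scan2

Low values (injury grew quickly) indicate poor prognosis; values near 1
indicate stable disease.

A phantom generator (`pqlung.phantom`) renders synthetic thoraces —
air, soft-tissue body, two lung ellipsoids, textured injured regions,
tubular vessels — with exact ground-truth masks, so the whole chain is
testable without clinical data.

## Worked example

```python
from pqlung import phantom, pipeline, injury_classifier
from pqlung.lung_segmentation import auto_seeds

# train the tissue classifier on a labelled phantom
train_vol, truth = phantom.render_phantom(phantom.PhantomSpec(seed=101))
dataset = pipeline.build_training_dataset(train_vol, truth, max_per_class=1000)
model, report = injury_classifier.train(dataset, seed=1)

# a synthetic patient: injury grows from 35.4% to 78.1% of the lung
spec = phantom.PhantomSpec(seed=1, scan_id="patient")
(v1, t1), (v2, t2) = phantom.render_scan_pair(spec, target_fractions=(0.354, 0.781))
seeds = [[(s.slice, s.row, s.col) for s in auto_seeds(v)] for v in (v1, v2)]
result = pipeline.run_pipeline([v1, v2], seeds, model)
for scan in result.scans:
    v = scan.volumetrics
    print(f"{v.scan_id}: fraction {v.injured_fraction:.3f}")
print(f"ratio {result.ratio.ratio_2dp:.2f}")
```

prints

```
patient-scan1: fraction 0.398
patient-scan2: fraction 0.903
ratio 0.44
```

The two fractions are the estimated injured shares of the whole lung on
each scan (the per-pixel classifier spills slightly into the boundary
band around the injury, biasing both fractions upward); their ratio,
0.44 against a ground truth of 0.45, is the prognostic output — well
below 1, i.e. rapid progression.

The same workflow is scriptable from the shell via the `pqlung` CLI
(`phantom`, `train`, `classify`, `quantify`, `ratio`, `cohort-stats`,
`run` subcommands).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full chain from scratch: it renders a training phantom,
trains the classifier, renders a two-scan phantom patient with known
injured fractions, runs the pipeline on both scans, and prints the
per-scan volumetrics and the estimated prognostic ratio next to the
ground truth.
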