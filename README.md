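# ribalign

**CT-derived patient models and landmark-based rigid alignment for
rib-fracture localization, evaluated on a synthetic torso phantom.**

Surgical stabilization of rib fractures (SSRF) needs the surgeon to map
fractures seen on a preoperative CT onto the patient lying on the
operating table — in a different pose, with no skin-surface features to
anchor the mapping. Mixed-reality navigation systems solve this by
building a 3D patient model (skin + bone + fracture indicators) from
the CT and rigidly aligning it to the patient using a handful of bony
landmarks (suprasternal notch, acromioclavicular joints, xiphisternum,
…). `ribalign` re-implements that computational core as an ordinary
Python library and CLI, and replaces the physical phantom, patients and
headset optics with a seeded synthetic torso phantom, so that
registration accuracy, localization rate and error propagation can be
measured reproducibly on a desk.

## What is inside

| module | contents |
|---|---|
| `ribalign.phantom` | synthetic torso CT (ellipsoidal soft tissue, rib-shaped bone tubes, scanner bed), parametric bony landmarks, fracture sites on rib centerlines, seeded scan-to-OR pose change (bend + rigid + landmark noise) |
| `ribalign.segmentation` | CT series concatenation, scanner-bed removal, body mask at the 20 %-of-intensity-range threshold, HU-threshold bone mask, mask OR-combination |
| `ribalign.meshing` | Marching-Cubes surface extraction, uniform Laplacian smoothing, ambient-occlusion interior-face culling, quadric edge-collapse decimation, skin-perpendicular fracture indicators |
| `ribalign.registration` | SVD least-squares rigid alignment of paired landmark sets, brute-force Euler-grid verification oracle, closed-form expected target registration error (TRE) |
| `ribalign.evaluation` | geodesic / straight-line shortest surface distance, localization rate, mean ± SD accuracy summaries (cm), Welch t-test, one-way ANOVA + Tukey HSD |
| `ribalign.pipeline` | end-to-end experiments with config files, seed fan-out, manifests and rendered reports |

## The core computation

Given paired landmark sets `L_model` (clicked on the CT-derived skin
model) and `L_patient` (measured on the patient), the alignment is the
rigid transform minimising

```
argmin_{R,T}  Σᵢ ‖ L_patient,i − (R·L_model,i + T) ‖²
```

solved in closed form: center both sets on their centroids, form the
3×3 cross-covariance `H = Σᵢ p̃ᵢ q̃ᵢᵀ`, take its SVD `H = U S Vᵀ`, and set
`R = V·diag(1, 1, det(VUᵀ))·Uᵀ`, `T = q̄ − R·p̄`. The sign term guards
against reflections in (near-)planar landmark configurations; when it
fires the result is flagged `reflection_corrected`. Every fracture
site is then mapped through `(R, T)` and compared with its true
location by the shortest distance **along the skin surface** — the way
an intraoperative ruler measurement works.

## Worked example

```python
import ribalign as ra

spec = ra.PhantomSpec(voxel_spacing=(4.0, 4.0, 4.0), noise_sd=0.0, seed=20)
cfg = ra.ExperimentConfig(
    phantom=spec,
    deformations=[
        ra.DeformationSpec(),                                   # supine, no noise
        ra.DeformationSpec(rigid_rotation=(0, 0, 80),           # lateral decubitus,
                           rigid_translation=(30, 0, 0),        # 2 mm landmark noise
                           landmark_noise_sd=2.0),
    ],
    n_fractures=16, replicates=1, metric_mode="geodesic",
    skin_target_faces=None,
)
report = ra.run_experiment(cfg)
print(ra.report_render(report))
```

prints

```
ribalign experiment report (v0.1.0)
  phantom seed 20, 16 fractures, 2 position(s), 1 replicate(s), metric: geodesic
  overall: 0.09 +/- 0.13 cm over 32 measured records; localization rate 100.00% (32/32)
    position 0: 0.00 +/- 0.00 cm, rate 100.00%
    position 1: 0.17 +/- 0.13 cm, rate 100.00%
```

Position 0 is the control: the "patient" is exactly the scanned
phantom, so registration is the identity and every one of the 16
fractures is recovered with zero surface distance. Position 1 rotates
the phantom into a lateral position and corrupts each patient-side
landmark with 2 mm isotropic Gaussian noise; the induced fracture
localization error (mean 0.17 cm on the skin) is pure error
propagation through the five-landmark rigid fit.

The same stages are scriptable from a shell:

```bash
ribalign phantom  --config spec.yaml --seed 4 --out phantom/
ribalign segment  --in phantom/phantom.nii.gz --body --bone --out seg/
ribalign mesh     --mask seg/body.nii.gz --role skin --out skin.obj
ribalign register --model-landmarks lm_model.json \
                  --patient-landmarks lm_patient.json --out transform.json
ribalign evaluate --records records.csv --skin skin.obj --out report.json
ribalign pipeline --config experiment.yaml
```

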