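# mntrace

Quantification pipeline for **manganese-enhanced MRI (MEMRI) tract
tracing** in longitudinal small-animal studies, with a ground-truth phantom
generator for end-to-end validation.

Mn(II) is a calcium analog and T1 contrast agent: injected focally into a
brain region of a living animal, it enters active neurons, travels along
axons, and accumulates at distal projection targets. Imaging the same
animal before injection and at successive timepoints (here: pre, 30 min,
6 h, 24 h) turns intensity changes into a brain-wide map of anatomical
projections. `mntrace` implements the full analysis chain such a study
needs, for imaging scientists who want a tested, reproducible, scriptable
version of it:

1. **Phantom cohorts** (`mntrace.phantom`) — multi-subject, multi-timepoint
   synthetic brains with known rigid/nonlinear misalignment, bias fields,
   intensity scales, a biphasic injection bolus (hypo-intense core,
   hyper-intense halo, fading over 24 h), planted per-segment enhancements,
   and noise; every planted quantity is returned as ground truth.
2. **Normalization and alignment** (`mntrace.preprocess`) — skull-strip
   masking, robust log-polynomial bias-field correction estimated on the
   pre-injection image, modal intensity scaling, masked-NCC rigid
   registration, a two-pass **minimum deformation template** (MDT), and
   B-spline warps estimated on pre-injection images only and propagated
   unchanged to the contrast-enhanced sessions (*two-step* alignment — the
   bolus can never bias the geometry).
3. **Voxel-wise statistics** (`mntrace.statmap`) — paired within-group and
   pooled two-sample between-group t-maps on 0.3 mm-smoothed images with
   per-map Benjamini–Hochberg FDR thresholds.
4. **Quantification** (`mntrace.quantify`) — affine atlas alignment with
   inverse-matrix label mapping, per-segment **fractional accumulation
   volumes** (enhanced / total voxels, bilateral), segment-dynamics
   classification, hypo-core injection-site localization with stereotaxic
   ML/AP/DV conversion, and 3×3×3-voxel ROI time-course statistics.
5. **Orchestration** (`mntrace.pipeline`, `mntrace.config`, `mntrace` CLI) —
   one YAML config, one master seed, byte-reproducible tables, full
   provenance report.

## The statistics at the core

Per voxel \(v\), with subject images \(A_i, B_i\) (two timepoints of the
same subjects) or groups \(X, Y\):

* paired: \(d_i = A_i(v) - B_i(v)\), \(t = \bar d / (s_d/\sqrt{n})\),
  \(\mathrm{df} = n-1\), one-sided;
* two-sample: pooled-variance Student t, \(\mathrm{df} = n_X+n_Y-2\);
* FDR: Benjamini–Hochberg per contrast map over in-mask voxels — reject the
  \(k^*\) smallest p-values where \(k^* = \max\{k: p_{(k)} \le kq/m\}\);
  the realized critical t is the smallest t among rejected voxels;
* projection strength per atlas segment \(S\):
  \(\mathrm{FAV}(S) = |S \cap \text{suprathreshold}| / |S|\).

## Worked example

```python
from mntrace import PhantomSpec, simulate_cohorts
from mntrace.pipeline import preprocess_cohorts, analyze_study

spec = PhantomSpec(n_subjects_per_group=3, seed=7)   # reduced demo cohort
cohorts, truth = simulate_cohorts(spec)
pre = preprocess_cohorts(cohorts, seed=7)
study = analyze_study(pre, truth.atlas, roi_segments=["DS"])
```

prints (about five minutes; the full 10-subject study in
`analysis/study_config.yaml` takes ~8 minutes):

```
MDT pass-2 mean pairwise NCC: 0.994
ACA cohort 24h>30min: critical t = 14.73, 2422 suprathreshold voxels
  ACA   fractional accumulation volume = 0.22
  DS    fractional accumulation volume = 0.44
  RTN   fractional accumulation volume = 0.40
  SNr   fractional accumulation volume = 0.61
  LC    fractional accumulation volume = 0.33
  PAG   fractional accumulation volume = 0.56
  DMH   fractional accumulation volume = 0.34
  MBO   fractional accumulation volume = 0.34
ACA injection sites: ML +0.45±0.10, AP +0.15±0.26, DV -0.84±0.17 mm
```

Reading this: registration converged (aligned pre-injection images are
virtually identical at the analysis scale); the anterior cohort's 24h>30min
FDR map picks up accumulation in exactly the segments the generator
enhanced for that cohort — with only 3 subjects (df = 2) the map is
conservative, so fractions sit well below the ≥ 0.9 values the default
10-subject study reaches; and the localized injection sites cluster around
the planted stereotaxic plan (ML +0.5, AP +0.34, DV −0.81 mm, with
0.15 mm per-subject placement scatter).

The numbered drivers under `analysis/` run the same study from one config
and write NIfTI maps and CSV tables under `results/study/`:

```bash
python analysis/01_simulate_cohorts.py      # phantom sessions + truth manifest
python analysis/02_preprocess_align.py      # MDT + two-step alignment
python analysis/03_statistical_maps.py      # FDR t-maps, realized critical t
python analysis/04_quantify_accumulation.py # FAV tables, sites, dynamics, ROIs
python analysis/05_null_calibration.py      # realized FDR on 200 null cohorts
```

or equivalently `mntrace all --config analysis/study_config.yaml`.

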