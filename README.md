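# ventriflow

Left-ventricular (LV) 4-D flow component analysis: decompose the
end-diastolic LV blood volume into **direct flow (DF)**, **retained inflow
(RI)**, **delayed ejection (DE)** and **residual volume (RV)** by pathline
tracing of time-resolved 3-D phase-contrast (4-D flow) MRI velocity fields,
together with the preprocessing, valve-plane quantification, and two-group
cohort statistics that surround the method in a typical atrial-fibrillation
imaging study.

## Who this is for

Researchers working with intracardiac 4-D flow MRI who want an open,
testable implementation of LV flow-distribution analysis. Commercial
packages hide the particle tracing and its failure modes; here every stage
is a library function, and a synthetic phantom generator provides velocity
fields with *known* component ground truth so the whole chain can be
verified without patient data.

## The method

From each voxel centre of the LV segmentation at end-diastole a massless
particle is traced through the cyclic velocity field **v**(x, t) with
classical 4th-order Runge–Kutta integration — backward in time to the
isovolumetric relaxation (IVR) frame that marks diastole onset, and forward
to end-systole. The IVR frame is found where the combined transvalvular
transport |Q_mitral| + |Q_aortic| is minimal after the aortic systolic
peak, with Q obtained by lattice integration of **v**·**n** over each
tracked valve orifice. Whether the backward trace crosses the mitral plane
(*entered* during diastole) and the forward trace crosses the aortic plane
(*ejected* during systole) classifies each seed:

| entered | ejected | component |
|---------|---------|-----------|
| yes     | yes     | DF        |
| yes     | no      | RI        |
| no      | yes     | DE        |
| no      | no      | RV        |

Each seed carries one voxel volume; component fractions are percentages of
the total mapped end-diastolic volume and satisfy DF+RI+DE+RV = 100 exactly.
The recommended quality check compares mapped inflow (DF+RI) against mapped
outflow (DF+DE).

Supporting layers: static-tissue polynomial fitting removes eddy-current
(and folded-in Maxwell-term) background phase offsets; neighbourhood-median
voting undoes single VENC wraps; Du Bois BSA, biplane area–length LA
volume and standard LV volumetrics cover the clinical table; and a
statistics module implements Shapiro–Wilk-gated t / Mann–Whitney
comparisons, chi-square, Pearson correlation, OLS regression,
CHA₂DS₂-VASc scoring and caliper propensity-score matching.

## Worked example

Generate a tube phantom whose component split is known in closed form
(10-voxel LV segment, 1 voxel/frame flow, 8 diastolic + 8 systolic frames:
seeds shallower than 8 voxels enter, seeds deeper than 2 voxels eject →
60/20/20/0), then run the full pipeline on it:

```sh
$ ventriflow phantom --kind tube --out scratch/tube
wrote tube phantom to scratch/tube (truth DF/RI/DE/RV = [60.0, 20.0, 20.0, 0.0] %)

$ ventriflow run --in scratch/tube --out scratch/results
DF 60.00%  RI 20.00%  DE 20.00%  RV 0.00%  (QC pass)

$ ventriflow phases --in scratch/tube
t_ivr=0 t_ed=8 t_es=0
```

The pipeline recovers the analytic fractions exactly (RK4 is exact on this
field), detects the constructed diastole onset from the flux curves, and
the QC passes because mapped inflow (0.128 ml) equals mapped outflow.

The same in Python, on the ellipsoidal LV phantom whose ground truth comes
from a dense Euler advection oracle computed at build time:

```python
import ventriflow as vf

lv = vf.make_lv_phantom()          # EDV 160 ml, ESV 62 ml, 20 frames, 2 mm
res = vf.analyze(lv.field, lv.lv_mask, lv.mitral, lv.aortic, lv.phases)
print(res.pct_vector())            # [17.74 11.38  9.02 61.86]
print(lv.truth.pct_vector())       # [17.64 11.37  9.04 61.95]
```

The default tracer agrees with the 100-substep oracle within 0.1
percentage points on every component.

Cohort statistics on a synthetic two-group table drawn at the study's
group moments:

```sh
$ ventriflow match --seed 1
matched 27 pairs; SMD before {"age_years": 0.39, "weight_kg": 0.549, "bsa_m2": 0.586} after {"age_years": 0.038, "weight_kg": -0.03, "bsa_m2": 0.004}
```

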