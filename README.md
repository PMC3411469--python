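# lvremodel

Mapping **local left-ventricular remodeling** after reperfused myocardial
infarction from co-registered 3D cardiac MR volumes.

After an ST-elevation myocardial infarction, the left ventricle (LV) can
dilate progressively.  Global indices (end-diastolic volume, ejection
fraction) say *that* the ventricle remodels but not *where*.  This package
implements a 3D co-registration analysis that maps wall dilatation per point
on the epicardial surface and relates it to the severity of the local
ischemic injury:

1. **Segmentation** — a four-class probabilistic atlas (background, LV blood
   pool, LV wall, RV blood pool) is registered to the structural
   end-diastolic volume and the LV is segmented by expectation-maximization
   with Gaussian class intensities and the atlas as spatial prior.
2. **Infarct quantification** — the late-gadolinium-enhancement (LGE) volume
   is rigidly aligned to the structural stack; enhancing (infarcted) voxels
   are separated from remote myocardium by a two-component Gaussian mixture
   (the higher-mean component is infarct); transmural extent is the infarcted
   fraction along each epicardial-vertex-to-nearest-endocardial-vertex line;
   microvascular obstruction (MVO) is a low-signal core inside the infarct on
   early post-contrast images.
3. **Longitudinal tracking** — baseline and one-year follow-up volumes are
   rigidly aligned, then a free-form deformation (cubic B-spline lattice)
   maximizing normalized mutual information, guided by the segmentations,
   recovers the residual deformation of the ventricle.
4. **Remodeling statistic** — for each mesh vertex v with 1-ring neighbors
   N(v), local remodeling is the percentage change in mean neighbor
   separation under the recovered transform:

   ```
   d0(v) = mean_{u in N(v)} ||x_v - x_u||
   remodeling(v) = 100 * (d1(v) - d0(v)) / d0(v)
   ```

   It is exactly 100·(s−1) under a global similarity of ratio s, exactly 0
   under rigid motion, and independent of infarct size by construction.
5. **Cohort statistics** — paired t-test of infarct- vs remote-region
   remodeling, Welch t-tests by MVO and global-remodeling (>20 % EDV
   increase) status, and a one-way ANOVA of remodeling across
   transmural-extent bins; reported as mean ± SE with the 95 % CI of the
   difference and two-tailed P.

Patient images from such studies are not publicly deposited, so the package
includes a **synthetic phantom generator** (truncated-ellipsoid myocardial
shell, sectoral infarct of configurable transmurality, optional MVO core, and
a follow-up produced by a known smooth expansion of the infarct sector) whose
exact ground truth drives the test suite.  See `docs/methods.md` for the
model, parameter choices, and limitations.

## Worked example

Run the full analysis on a 20-subject synthetic cohort (two arms: sector
expansion s = 1.12 with MVO versus s = 1.02 without):

```sh
lvremodel cohort --out run/ --seed 0
```

which prints (abridged; the per-subject table is written to `run/cohort.csv`):

```
Cohort of 20 subjects (0 failed)
Local remodeling, infarct vs remote: infarct 1.02 vs remote 0.28 (diff 0.74, 95% CI 0.12 to 1.36, paired t=2.507, P=0.0214)
Infarct remodeling, MVO vs no MVO: MVO 2.02 vs no MVO 0.02 (diff 2.00, 95% CI 1.11 to 2.88, Welch t=5.097, P=0.0006)
ANOVA of remodeling across transmurality bins: F=1008.599, P=0
```

Reading: remodeling within infarcted myocardium (+1.0 %) exceeds remote
myocardium (+0.3 %, paired P = 0.02); infarcts with MVO dilate more than
those without; and dilatation grows with the transmural extent of infarction.
The recovered magnitudes are attenuated relative to the generator's true
expansion (see `docs/methods.md`, Known limitations) — the direction and
ordering of the effects are the validated quantities.

The same pipeline runs on real data: point the `cohort` subcommand at a
directory tree of per-subject NIfTI volumes (`baseline.nii.gz`,
`followup.nii.gz`, `lge.nii.gz`, `early.nii.gz` plus a `manifest.json`), or
use the library directly:

```python
import lvremodel as lv

spec = lv.PhantomSpec(transmural_fraction=0.8, expansion_factor=1.12, mvo=True)
subject = lv.make_subject(spec)
atlas = lv.make_atlas(spec)
result, rmap = lv.run_subject(subject, atlas, lv.PipelineConfig())
print(result.infarct_size_pct, result.remodeling_infarct_pct)
```

Per-vertex maps (wall thickness at both time points, transmural extent,
remodeling %, region label) can be exported as ASCII VTK or PLY meshes for
rendering.

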