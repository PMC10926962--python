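# lcmri

Quantitative MRI features of the **locus coeruleus (LC)** — the small paired
noradrenergic brainstem nucleus (≈2.5 mm diameter × 15 mm long) — and of
LC–hippocampus white-matter tracts, as used in vagus-nerve-stimulation (VNS)
response studies in drug-resistant epilepsy. The package implements the
quantification layer of such a study as a tested, reusable pipeline, and
pairs every stage with a seed-controlled synthetic-data generator with known
ground truth, so each estimator can be validated by parameter recovery.

## What it computes

**LC contrast** (structural integrity marker, from an MT-weighted slab).
For each side, the two raters' LC masks are intersected, the occupied axial
slices are ordered caudal→rostral and split 25 % caudal / 50 % medial /
25 % rostral, and per slice *i* a 5-voxel cross is centered on the
highest-intensity mask voxel (mean L̄C<sub>i</sub>) while a slice-matched
15×15-voxel pontine reference region anterior to the LC gives p̄ons<sub>i</sub>:

```
contrast = (1/n) Σ_{i=1..n} ( L̄C_i / p̄ons_i − 1 )
```

**LC activity** (auditory oddball fMRI). Rare target tones (~20 % of 220
stimuli, ISI 2.5 s) are convolved with a two-gamma HRF; the design adds six
motion regressors, a Fourier drift basis (all sine/cosine pairs with fewer
than 3 cycles per run) and an intercept, z-scores every non-intercept
column, and fits OLS to the mean ROI time course. The target beta is the
activity estimate; task accuracy is the percent of targets answered within
a response window.

**Tract microstructure.** A log-linear least-squares tensor fit on the
b ≤ 1000 s/mm² shell gives FA, MD = (λ₁+λ₂+λ₃)/3, AD = λ₁ and
RD = (λ₂+λ₃)/2; per-fascicle occupancy/volume-fraction maps from a
multi-compartment fit are aggregated as

```
wFVF = (ν₁·fvf₁ + ν₂·fvf₂) / (ν₁ + ν₂)
```

Streamlines (TRK/TCK) are filtered to 30–300 mm, voxelized, and each scalar
map is averaged over the traversed voxels.

**Group statistics.** Each LC metric is modelled by OLS on response group
or therapy duration, controlling for age, sex, ASM count, epilepsy duration
and benzodiazepine intake; Benjamini–Hochberg FDR is applied per metric
family and predictors are screened with VIF < 5. Demographic tables use
Mann–Whitney U (exact enumeration for pooled n ≤ 12) or Fisher exact tests.
The stimulation duty cycle is (ON + 4 s)/(ON + OFF).

## Worked example

```python
import numpy as np
from lcmri import synthio, lc_contrast, group_stats, tract_micro

# an LC phantom at MT-slab geometry (0.39 x 0.39 x 1.7 mm voxels),
# true contrast ratio 1.15 over the pons, image SNR 20
spec = synthio.PhantomSpec(contrast_ratio=1.15, noise_sd=5.0, seed=42)
vol, mask, _ = synthio.generate_lc_phantom(spec)
ref = lc_contrast.ReferenceSpec(anterior_offset=25)
for side, line in zip(("left", "right"), spec.lc_centerlines):
    m = synthio.rasterize_tube(line, spec.shape, spec.voxel_size, spec.lc_radius)
    r1, r2, dice = synthio.perturb_rater_masks(m, 1, seed=7)   # two raters
    res = lc_contrast.extract_contrast(vol, r1, r2, side=side, factor=1, ref_spec=ref)
    print(f"{side:>5}  dice={dice:.3f}  " + "  ".join(
        f"{p}={res.contrast(p):+.4f}" for p in ("caudal", "medial", "rostral", "whole")))

print("wFVF(0.6, 0.5, 0.4, 0.7) =", float(tract_micro.compute_wfvf(0.6, 0.5, 0.4, 0.7)))
print("Fisher sex p =", group_stats.fisher_exact([[6, 4], [7, 6]]))
dc = group_stats.duty_cycle(30, 300)
print(f"duty cycle (30 s ON / 300 s OFF) = {dc.value:.4f}  rapid={dc.rapid}")
```

prints

```
 left  dice=0.983  caudal=+0.1649  medial=+0.1305  rostral=+0.1777  whole=+0.1468
right  dice=0.983  caudal=+0.1204  medial=+0.1521  rostral=+0.1216  whole=+0.1396
wFVF(0.6, 0.5, 0.4, 0.7) = 0.58
Fisher sex p = 1.0
duty cycle (30 s ON / 300 s OFF) = 0.1030  rapid=False
```

The whole-LC contrasts (0.147 left, 0.140 right) recover the injected truth
of 0.15 to within the noise floor; with `noise_sd=0` the recovery is exact.
The Dice of 0.983 quantifies the simulated inter-rater disagreement. The
two-fascicle voxel with occupancies 0.6/0.4 and volume fractions 0.5/0.7
aggregates to wFVF 0.58, and a 6/4 vs 7/6 female/male split is as balanced
as a 2×2 table can be (p = 1.0).

## Command line

```bash
lcmri synth make-phantom --seed 1 --out ph/          # fixtures with truth records
lcmri contrast extract --mt ph/phantom.nii.gz \
      --mask-r1 ph/lc_mask_left.nii.gz --mask-r2 ph/lc_mask_left.nii.gz \
      --side left --out contrast.tsv
lcmri oddball design|fit|score ...                   # design dump, ROI beta, accuracy
lcmri tract fit-dti|wfvf|extract ...                 # scalar maps, tract means
lcmri stats lm|table1 ...                            # covariate LMs, demographics
lcmri demo --seed 1 --out demo/ && lcmri validate demo/
```

`lcmri demo` runs a full synthetic cohort (phantoms → contrast/beta/tract
metrics → group models) and writes TSV/NIfTI artifacts plus a manifest with
content hashes; a rerun with the same seed is byte-identical.

## Layout

```
src/lcmri/
  synthio.py      synthetic phantoms, BOLD, DWI, streamlines; format I/O
  lc_contrast.py  upsampling, mask intersection, subdivision, contrast
  oddball_glm.py  paradigm, HRF, design matrix, ROI GLM, accuracy
  tract_micro.py  DTI fit, scalars, wFVF, dilation, length filter, tract means
  group_stats.py  covariate LMs, BH-FDR, VIF, Fisher/Mann-Whitney, duty cycle
  workbench.py    end-to-end demo runs, validation, power simulation
  cli.py          `lcmri` command
docs/methods.md   model assumptions, defaults, numerical choices, limitations
```
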