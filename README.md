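# mwfmix

Lesion-mask-free characterization of white-matter myelin content from
myelin water fraction (MWF) maps, for neuroimaging researchers studying
demyelinating disease (multiple sclerosis in particular) who want a
whole-brain summary of WM damage that does not depend on anyone drawing or
editing lesion masks.

## The idea

A subject's pooled white-matter MWF values are right-skewed with one or
two peaks: lesional and "dirty" WM at low MWF, normal-appearing white
matter (NAWM) at high MWF.  `mwfmix` models the per-subject distribution
as a two-component gamma mixture

```
p(x) = λ Γ(x; α₁, β₁) + (1 − λ) Γ(x; α₂, β₂)
```

fitted by expectation maximization on the raw voxel values (no histogram
binning), with a single gamma as the null alternative, chosen against by a
penalized, bootstrap-calibrated likelihood ratio test.  Each subject is
reduced to three numbers: the component modes `m₁ = (α₁−1)β₁` and
`m₂ = (α₂−1)β₂` (positions of the abnormal-WM and NAWM peaks) and the
mixing ratio λ (proportion of abnormal-looking WM).

The package also provides:

* **ROI validation** — `ROI[m₁]` (WM voxels below `m₁`) and `ROI[m₂]`
  (above `m₂`) compared against lesion/NAWM masks by Dice coefficient
  `2|A∩B|/(|A|+|B|)` with Welch two-sample t-tests across subjects;
* **the classical mask route** for comparison — lesion masks from
  FLAIR-like intensities (CSF+lesion class ∩ WM, thresholded at the 30th
  percentile of the robust intensity range [p2, p98]), NAWM as the WM
  complement;
* **group models** — exhaustive predictor-subset search with shared-fold
  10-fold cross-validation, adjusted-R² comparison of the mixture
  predictors {m₁, m₂, λ} against the mask predictors {mean lesion MWF,
  mean NAWM MWF} (each plus age, gender, disease and treatment duration),
  LMG relative-importance decomposition of R², and coefficient
  interpretation as per-0.05 mm cortical-thickness deltas;
* **synthetic data** — seeded generators for labeled MWF volumes (ellipsoid
  WM, spherical lesions with dirty-WM rims, pooled WM exactly matching the
  generating mixture), FLAIR-like volumes, and cohort tables with known
  regression structure, so the entire pipeline is testable end to end.

## Worked example

```python
from mwfmix import (GammaMLE, GammaMixtureEM, penalized_lrt, summarize_fit,
                    make_mwf_volume, roi_from_modes, dice)
from mwfmix.simulate import VolumeSpec

vol = make_mwf_volume(VolumeSpec(seed=1))   # 64x64x32 synthetic subject
x = vol.wm_values()

single = GammaMLE().fit(x)
mixture = GammaMixtureEM().fit(x)
sel = penalized_lrt(single, mixture, x, n_bootstrap=39, seed=1)
print(f"penalized LRT: statistic = {sel.statistic:.1f}, "
      f"p = {sel.p_value:.3f} -> {sel.chosen}")

m1, m2, lam = summarize_fit(mixture)
print(f"reduction: m1 = {m1:.3f}, m2 = {m2:.3f}, lambda = {lam:.3f}")

roi1, roi2 = roi_from_modes(vol, m1, m2)
print(f"Dice(lesion, ROI[m1]) = {dice(vol.lesion, roi1):.3f}")
print(f"Dice(lesion, ROI[m2]) = {dice(vol.lesion, roi2):.3f}")
print(f"Dice(NAWM,   ROI[m2]) = {dice(vol.nawm, roi2):.3f}")
```

prints

```
penalized LRT: statistic = 1958.5, p = 0.025 -> mixture
reduction: m1 = 0.067, m2 = 0.172, lambda = 0.286
Dice(lesion, ROI[m1]) = 0.584
Dice(lesion, ROI[m2]) = 0.039
Dice(NAWM,   ROI[m2]) = 0.717
```

The volume was generated from a mixture with modes 0.06/0.17 and λ = 0.25,
so the fit recovers the generating parameters to within the estimator's
sampling spread (λ is weakly identified for strongly overlapping
components; see `docs/methods.md`).  The selection test rejects the single
gamma at the bootstrap floor (p = 1/(B+1) with B = 39).  The Dice pattern —
lesion mask close to `ROI[m₁]`, NAWM close to `ROI[m₂]`, with the NAWM
overlap larger because small lesion volumes bound the lesion Dice — is the
signature that justifies reading `m₁` as lesional/dirty WM and `m₂` as
NAWM.

A coefficient of 4.72 mm per MWF unit for `m₂` means a 0.05 mm cortical
thickness decrease corresponds to an `m₂` decrease of
`delta_for_thickness_change(4.72) ≈ 0.011`:

```python
from mwfmix import delta_for_thickness_change
from mwfmix.regression import round_sig
round_sig(delta_for_thickness_change(4.72), 2)   # 0.011
```

## Command line

```bash
mwfmix simulate volume --out subj0/ --seed 1      # NIfTI volume + masks + FLAIR
mwfmix simulate cohort --group RRMS --out cohort.csv
mwfmix fit --mwf subj0/mwf.nii.gz --wm subj0/wm.nii.gz --out fit.json --bootstrap 199
mwfmix dice --cohort-dir subjects/ --ref lesion --out dice.csv
mwfmix cohort --table cohort.csv --predictor-set gamma --out model.json
mwfmix study --config config.json --out bundle/   # full desk-scale study
```

## Layout

```
src/mwfmix/
  mixture.py     gamma components, single-gamma MLE, EM mixture fit,
                 penalized bootstrap LRT, (m1, m2, lambda) summary
  masks.py       LabeledVolume (NIfTI I/O), threshold lesion masks, NAWM,
                 mode-derived ROIs, Dice, Welch group comparison
  regression.py  OLS, exhaustive-subset CV selection, LMG importance,
                 Welch t-test, coefficient interpretation
  simulate.py    volume / FLAIR / cohort generators and their specs
  pipeline.py    per-subject reduction and the full study bundle
  cli.py         the `mwfmix` command
docs/methods.md  model, estimation, calibration and design notes
```
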