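# truenet — triplanar ensemble U-Net WMH segmentation

White matter hyperintensities (WMH) are bright lesions on FLAIR MRI of
presumed vascular origin, split clinically into periventricular (PWMH) and
deep (DWMH) lesions by the 10 mm distance-from-ventricles rule.  Deep
lesions are small, punctate and vastly outnumbered by background voxels,
which makes them the hard part of automated segmentation.

`truenet` implements a triplanar ensemble segmenter for co-registered,
brain-extracted FLAIR + T1 volume pairs: three independent shallow 2D
U-Nets — one per anatomical plane — whose reassembled 3D probability maps
are averaged, masked to white matter and thresholded at 0.5,

    P(x) = (P_axial(x) + P_sagittal(x) + P_coronal(x)) / 3,
    lesion(x) = [P(x) >= 0.5] · WM(x),

trained with a composite objective

    L = CE_w + DcL,
    CE_w = (1/N) Σ_x D_wei(x) · Σ_i y_i(x) (−log p_i(x)),
    DcL  = −2|M ∩ P| / (|M| + |P|),

where the spatial weight map `D_wei = D_vent + D_GM` (distance from the
ventricles plus distance from the cortical grey matter, in mm) up-weights
the deep white matter, and the Dice term rewards overlap on small lesions.
The networks, their backpropagation and Adam are implemented in numpy and
verified against finite differences; no GPU is required.

A synthetic brain-phantom generator (ellipsoidal brain, ventricle cavity,
GM/CSF shells, confluent periventricular + punctate deep lesions with
FLAIR/T1 contrast and noise) provides exact ground truth, so the entire
pipeline trains and evaluates on one CPU in minutes.  The evaluation module
covers the Dice similarity index (SI), voxel-wise TPR/FPR, 26-connected
cluster-wise TPR/precision/F1, absolute volume difference (AVD %), the
95th-percentile Hausdorff distance (H95, mm), and the PWMH/DWMH regional
split.

See `docs/methods.md` for the model, the loss, the phantom's scope and all
numerical conventions.

## Worked example

```python
from truenet import WMHSegmenter, PhantomSpec, generate_cohort, evaluate_case
from truenet.pipeline import DEMO_ESTIMATOR_PARAMS

cohort = generate_cohort(10, PhantomSpec(), seed=1)   # 64x64x24 @ 1x1x3 mm
train, test = cohort[:8], cohort[8:]

est = WMHSegmenter(random_state=1, **DEMO_ESTIMATOR_PARAMS)  # 4-channel nets
est.fit(train)
for case, report in zip(test, est.evaluate(test)):
    print(f"SI {report.si:.3f}  PWMH {report.per_region['pwmh'].si:.3f} "
          f"DWMH {report.per_region['dwmh'].si:.3f}  AVD {report.avd_percent:.1f}%")
```

Output from this exact run:

```
SI 0.919  PWMH 0.976 DWMH 0.853  AVD 15.0%
SI 0.982  PWMH 0.984 DWMH 0.913  AVD 3.6%
```

i.e. the scaled-down triplanar model segments the held-out phantoms with a
median Dice overlap of ~0.95, with good quality in both the periventricular
and the deep compartments.  The run takes a few minutes on one CPU.

The same experiment is available from the shell:

```bash
truenet demo --n 10 --seed 1
truenet phantom --out cases/ --n 3 --shape 64,64,24 --voxel 1,1,3 --seed 0
truenet train --data cases/ --out model/
truenet predict --model model/ --flair f.nii.gz --t1 t.nii.gz --masks m/ --out pred/
truenet evaluate --pred pred/lesion_mask.nii.gz --manual truth.nii.gz \
                 --brain brain.nii.gz --vent vent.nii.gz --out report.json
truenet ablate --n 10 --seeds 1,2,3 --out ablation.json
```

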