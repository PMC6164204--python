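# cytonuclei

Automated cell-nuclei segmentation for cytology images of pleural effusion.

Cytological examination of pleural fluid is a standard, minimally invasive
route to diagnosing malignant effusions, but reading the slides — finding and
judging every cell nucleus under the microscope — is slow and
observer-dependent. The first step of any computer-aided pipeline is
delineating the nuclei: on Pap-stained material they appear dark purple
against lighter cytoplasm and a bright background, so the problem reduces to
separating a dark foreground from a bright surround under noise, debris and
uneven illumination.

This package implements a complete three-stage segmentation framework and the
evaluation machinery to compare methods within it:

1. **Preprocessing** — grayscale conversion, optional resize, denoising
   (median / Gaussian / Laplacian-sharpen / adaptive Wiener / mean) and
   contrast enhancement (global histogram equalization / linear intensity
   adjustment / CLAHE), plus the two quality scores used to choose among
   them: PSNR = 10·log10(255²/MSE) and the contrast improvement index
   CII = C(enhanced)/C(original) with C the mean local Michelson contrast.
   The default chain is median 3×3 followed by CLAHE, which top the PSNR and
   CII rankings respectively on degraded images.
2. **Segmentation** — twelve interchangeable methods behind one registry:
   - six global histogram criteria: Otsu (min. within-class variance
     ω₀σ₀² + ω₁σ₁²), Isodata (fixed point of t ← (μ₀+μ₁)/2), Kapur maximum
     entropy (max. H₀(t)+H₁(t)), Li–Lee minimum cross entropy, fuzzy-entropy
     minimization, and Kittler–Illingworth minimum error
     (J = 1 + 2[P₁lnσ₁+P₂lnσ₂] − 2[P₁lnP₁+P₂lnP₂]);
   - local adaptive thresholding (pixel < local mean − offset, window 12);
   - three intensity-clustering methods: k-means (k = 2), fuzzy c-means
     (m = 2), and flat-kernel mean shift (bandwidth 0.2 on [0,1] intensity);
   - two energy minimizers: Chan–Vese active contour without edges, and a
     graph min cut solved as the convex continuous two-label relaxation
     min_u α∫|∇u| + ∫u(I−c_fg)² + (1−u)(I−c_bg)², α = 0.3.
   Nuclei are dark, so every method's foreground is its darkest class.
3. **Postprocessing** — remove connected components smaller than P = 1500 px
   (defined at the 1052×1052 working resolution, area-rescaled elsewhere),
   then morphological opening (disk R = 5) and closing (disk R = 12).

Evaluation covers pixel metrics (precision, recall, F-measure, Jaccard,
Dice = 2TP/(2TP+FP+FN)) and object-level detection: a ground-truth nucleus
counts as detected when the predicted mask covers strictly more than 60% of
its pixels; the nuclei detection rate (NDR) is the detected fraction, and the
abnormal NDR restricts it to nuclei flagged abnormal (enlarged) in the
annotations.

Because no public pleural-effusion dataset exists, the package ships a seeded
synthetic scene generator (`cytonuclei.synthetic`) producing cytology-like
images — dark elliptical nuclei with brighter cytoplasm halos on a bright
field, Gaussian noise, optional debris, and a labeled per-nucleus ground
truth including abnormal flags — so the whole framework is testable end to
end at desk scale.

## Worked example

```python
from cytonuclei import (SceneConfig, generate_scene, PipelineConfig,
                        run_method)

scene = generate_scene(SceneConfig(seed=1))   # 256x256, 8 nuclei, 2 abnormal
result = run_method(scene.image, gt=scene.gt_mask,
                    config=PipelineConfig(method="otsu"),
                    gt_labels=scene.gt_labels, gt_metadata=scene.nuclei)
m = result.metrics
print(f"dice={m.dice:.4f} precision={m.precision:.4f} recall={m.recall:.4f}")
print(f"detected {sum(r.detected for r in result.nuclei)}/{len(result.nuclei)} nuclei")
```

prints

```
dice=0.9735 precision=0.9784 recall=0.9686
detected 8/8 nuclei
```

i.e. the Otsu pipeline recovers 97% of nucleus pixels (by Dice overlap with
the ground-truth mask) and every one of the eight nuclei exceeds the 60%
coverage rule. The same run from the shell:

```bash
cytonuclei synth --n-images 1 --seed 1 --out scenes
cytonuclei segment --input scenes/scene_000.png --method otsu --out out
cytonuclei bench --methods otsu,kmeans,mean_shift,chan_vese,graph_cut \
                 --synthetic 10 --seed 1 --out bench
```

`bench` writes a per-image CSV and JSON report plus a per-method ranking by
mean Dice.

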