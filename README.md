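# morphedge

Self-adaptive morphological edge detection for 2-D grayscale images,
aimed at noisy medical content such as MRI cross-sections of the pelvis
(the motivating application is imaging of placenta previa, where edge
quality of the placenta/myometrium interface matters and raw images
carry heavy impulse-like noise).

Classical morphological gradients such as `p3 = g⊕J − gΘJ` (dilation
minus erosion by a structuring element `J`) respond to every bright or
dark impulse as if it were an edge. `morphedge` implements an anti-noise
alternative built from three ingredients:

1. **Cascaded gradients.** `q1 = (g∗J)∘J − (g∗J)ΘJ` and
   `q2 = (g∘J)⊕J − (g∘J)∗J` run a closing (`∗`) or opening (`∘`) first,
   which deletes dark and bright impulses respectively before the
   gradient is formed. The blend `Q = κ·max(q1,q2) + λ·min(q1,q2)`
   (κ+λ=1, default ½/½) suppresses both noise polarities.
2. **Direction weighting.** Squared gray-level differences between each
   pixel and its eight neighbors, accumulated over the image, yield
   weights `v1..v8` (summing to 1) for half-line structuring elements in
   the eight compass directions; `Q` is computed per direction and mixed
   as `Σ v_x·Q_x`, so directions along which the image actually varies
   dominate.
3. **Multiscale fusion.** The weighted response is computed at element
   scales 3, 5, 7, 9 (…, `2m+1`); a PSNR gate can stop the scale loop
   early, and the per-scale responses are fused by their pointwise mean
   (the multiscale operator `MuQ`).

The package also provides the evaluation stack used to study the
algorithm — MSE, PSNR (in both the pipeline's 256×256-numerator dialect
and the standard 255² dialect), SSIM, a diagnostic-concordance utility —
and a seeded generator of MRI-like phantoms with exact ground-truth edge
maps, which stands in for clinical images. See `docs/methods.md` for the
model, parameter choices, and limitations.

## Worked example

```python
import morphedge as me

# a seeded 128x128 pelvic-like phantom: 5% salt+pepper, sigma-5 Gaussian
phantom = me.generate(me.default_study_spec(seed=0))

# adaptive multiscale detection, gated against the clean reference
result = me.adaptive_detect(phantom.noisy, me.FusionConfig(),
                            reference=phantom.clean)
print([s for s, _, _ in result.per_scale], result.stop_reason)
print([round(p, 2) for _, _, p in result.per_scale])

report = me.evaluate_pair(result.fused.values, phantom.clean)
print(round(report.mse, 1), round(report.psnr, 2), round(report.ssim, 4))

# anti-noise operator vs plain gradient, precision at matched recall
se = me.make_structuring_element(3, "isotropic")
q  = me.precision_at_recall(me.combined_Q(phantom.noisy, se),
                            phantom.edge_truth, 0.75)
p3 = me.precision_at_recall(me.gradient_p(phantom.noisy, se, 3),
                            phantom.edge_truth, 0.75)
print(round(q, 2), round(p3, 2))
```

prints

```
[3, 5, 7, 9] m_max_reached
[8.52, 8.65, 8.77, 8.89]
8820.3 8.71 0.0079
0.99 0.33
```

Reading the numbers: the gate PSNR of the edge response against the
clean reference rises with scale (8.52 → 8.89 dB), so with the default
30 dB threshold the loop runs to `m_max` and fuses all four scales. At a
matched recall of 0.75 (1-pixel tolerance), the anti-noise operator `Q`
keeps precision 0.99 on the noisy phantom while the plain gradient `p3`
drops to 0.33 — `p3` fires on nearly every impulse, `Q` on almost none.

A concordance example from the motivating study: of 36 surgically
confirmed cases (19 complete, 11 partial, 6 marginal placenta previa),
image-based classification assigned two complete cases to the partial
class and matched the rest:

```python
import numpy as np
table = me.ConfusionTable(np.array([[17, 2, 0], [0, 11, 0], [0, 0, 6]]))
print(round(me.accuracy(table), 2))   # -> 94.44
```

## Command line

```
morphedge detect input.png --out out/ --kappa 0.5 --m-max 4 --psnr-threshold 30
morphedge simulate --out sim/ --seeds 50 --seed 0
morphedge evaluate processed.png reference.png --dialect paper
```

`detect` writes the fused edge map, per-scale maps and a JSON manifest
(scales used, weights, gate PSNR values, stop reason). `simulate` runs
the scale sweep on seeded noisy phantoms and writes a per-scale
MSE/PSNR/SSIM CSV plus monotone-trend verdicts. `evaluate` prints a
quality report for an image pair. Exit codes: 0 success, 2 validation
error, 3 I/O error; flags override config-file values, which override
defaults.

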