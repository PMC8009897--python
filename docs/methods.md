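# Methods

## The measurement problem

Scoliosis severity is graded from the angle of the lateral spinal curve on
an AP radiograph (<10° not scoliosis, 10–20° mild, 20–40° moderate, ≥40°
severe). All classical constructions — Cobb, Ferguson, Greenspan, Diab —
presuppose that the bounding (end) vertebrae and the apical vertebra have
been identified, and that identification is where human observers disagree.
`spinaxis` replaces the manual landmark step with two automatically
extracted descriptors: the medial axis (MA) and the central sacral line
(CSL). Everything downstream is deterministic geometry on those two curves.

## Pipeline model and assumptions

1. **Segmentation.** The vertebral column is assumed to be the largest
   bright, connected minority structure in the image. An optimum global
   threshold (maximizing between-class variance over the 256-bin histogram;
   ties resolved toward the lower cut) binarizes the image; a morphological
   closing (Euclidean disc, radius 5 px at the 925×475 working scale)
   merges vertebra blobs across intervertebral disc gaps; the largest
   8-connected component is kept and the original intensities are restored
   under it. Degenerate inputs raise typed errors: a constant image has no
   separating threshold; a foreground covering more than 35 % of the image
   means thresholding found no bright *minority* structure (a pure-noise
   background splits roughly in half and would otherwise yield a giant
   speckle cluster); a largest component under 500 px is speckle, not a
   column.
2. **Boundary.** The column border is the inner morphological gradient:
   the mask minus its erosion. The structuring element is a *Chebyshev*
   disc (a (2r+1)² square), chosen so the radius-1 band coincides exactly
   with the 8-neighbor border definition {p ∈ mask : some 8-neighbor ∉
   mask}. The largest border component is traced into an ordered, closed,
   clockwise contour by Moore-neighbor tracing (start: topmost-then-
   leftmost pixel; Jacob's stopping criterion). For a one-pixel border
   loop the trace reproduces the component's pixel set; where Chebyshev
   erosion leaves locally two-pixel-thick diagonal steps, interior pixels
   of those steps are skipped (the trace stays within the band and spans
   its full extent — all the medial-axis stage needs). Contour coordinates
   are then circularly smoothed with a Gaussian (σ = 3 px) and re-quantized.
3. **Axes.** For every row in the contour's vertical extent the MA sample
   is the midpoint of the outermost left/right contour crossings; rows
   without a crossing (possible after re-quantization) are filled by
   linear interpolation. The CSL is vertical by definition; because the
   anatomical definition (C1 center to S1 center) over-determines a
   vertical line, the implementation anchors it at the inferior (S1-end)
   MA sample, with `top` and `mean` anchors available as configuration.
   The displacement d(row) = MA_x − CSL_x is the deformity signal;
   positive d means the MA lies to the image-right of the CSL (patient
   side is not resolved — AP images are mirror-ambiguous without markers).
4. **Landmarks.** Scanning d top-to-bottom with tolerance ε = 2 px: a
   curve opens at the last row before |d| exceeds ε (SEV), closes where
   |d| returns to ≤ ε (IEV), and a sign change of d closes one curve and
   opens the next. Segments shorter than 30 rows (≈ 1.5 nominal vertebra
   heights) are discarded as noise blips; a curve still open at the bottom
   is closed at the last row and flagged `truncated`. The AV is the row of
   maximal |d| within the segment (ties to the smallest row); the pipeline
   additionally refines it by fitting a parabola to d over ±20 % of the
   segment span and taking the vertex — near the apex d is flat while the
   MA still ripples at the vertebra pitch, so the raw argmax wanders along
   the plateau, whereas the vertex of a fit spanning a full ripple period
   is stable to a few rows. Landmarks are assigned nominal vertebral
   levels by dividing the column extent into 17 equal bands (T1…T12,
   L1…L5); real vertebra heights vary, so the labels are bookkeeping for
   agreement studies, never inputs to angle geometry.
5. **Curvature.** Tangent slopes dx/dy of the MA are local *quadratic*
   least-squares (Savitzky–Golay) derivatives over a ±25-row window; a
   linear fit would systematically underestimate the slope exactly where
   Cobb tangents are taken — at slope extrema. Cobb takes the tangents at
   the rows of maximal |slope| within [SEV, AV] and [AV, IEV] (the most
   oblique, i.e. limiting, vertebrae; the literal segment-bound reading is
   available as `endpoint_rule="bounds"`). Ferguson is 180° minus the
   interior angle at the AV between rays to the end-vertebra centers, so a
   collinear spine scores 0°. The Greenspan index is Σ|d| over the segment
   divided by the end-to-end chord length — dimensionless, reported with
   no severity grade, and scale-invariant when geometries are compared at
   equal per-segment sample counts. Diab replaces each Ferguson end point
   by the mean MA position over three nominal vertebra bands at that curve
   end; the two three-band windows may overlap mid-segment (requiring
   disjoint windows would leave Diab undefined on mild short curves), but
   each must fit inside the segment. Severity bands are closed on the
   left: [10, 20) mild, [20, 40) moderate, ≥40 severe.

## Noise control: why the MA is smoothed, and by how much

The extracted MA carries a structured ripple of up to ±6 px at the
vertebra pitch: vertebral bodies are straight while the spine curves, so
endplate corners, disc-gap bridges and the closing operation make the
envelope midpoint oscillate around the true centerline. Differentiating
through that ripple is hopeless (tangent errors of ±0.18 slope units,
i.e. several degrees of Cobb). The pipeline therefore smooths the MA
x-series with a Gaussian whose σ defaults to a **quarter of the nominal
vertebra pitch** (column extent / 17, ≈ 13 rows at the working scale).
The choice sits at the knee of the ripple-vs-attenuation tradeoff: the
pitch-period ripple is attenuated several-fold, while a scoliotic curve —
whose wavelength is an order of magnitude longer — passes essentially
unchanged. Larger σ visibly attenuates the curve itself (and biases Cobb
low); smaller σ lets ripple through (and biases the max-|slope| search
high). On the phantom families the residual Cobb error is under 2°
against the analytic oracle across 15–40° targets.

The standalone Fourier resampler (`fft_interpolate`, zero-padded-spectrum
resampling) is kept as the densification hook (`fft_factor` in the
config, default 1, i.e. off): it changes sampling, not bandwidth, and is
not a substitute for the ripple suppression above.

## The phantom generator

A phantom encodes the study conditions the pipeline targets: 925×475-px
8-bit images, a column of 17 vertebrae (12 thoracic + 5 lumbar), and
deformities given as raised-cosine bumps of the midline —
amplitude·(1 + cos(π(y − c)/h))/2 on [c − h, c + h] — which are smooth,
compactly supported, and have closed-form value, slope (max π·A/(2h) at
the half-span inflections) and hence closed-form Cobb ≈ 2·atan(π·A/(2h)).
Vertebral bodies are rectangles (default 50 px wide, height ≈ 0.85 of the
pitch, the rest being disc gap) rotated to the local midline tangent, at
intensity ~200 over a ~60 background with additive Gaussian noise
(default σ = 10, clipped to [0, 255]); rendering is deterministic given
the `MidlineSpec` seed, and negating all amplitudes mirrors the image exactly
when the baseline sits on the image centerline. Intensity levels and the
noise model are free choices — no quantitative intensity statistics exist
to calibrate against — picked so the column/background contrast (~140)
dominates the noise as it does on diagnostic film.

Ground truth is computed by `analytic_angles`, which applies the *same*
geometric constructions as the curvature module to the exact midline,
with one deliberate difference: its tangent window defaults to a tight
5 rows, because on exact data a wide window only adds third-derivative
bias at the slope extrema (≈ 0.5° at a 40° curve for the pipeline's
25-row window). `amplitude_for_cobb` inverts the analytic construction
numerically (and lands on or a hair above the requested angle, so the
severity band of the analytic value is never at the mercy of the root
residual).

What the phantoms do **not** emulate: ribs, pelvis, soft tissue and
exposure gradients; vertebral axial rotation and wedging; varying
vertebra heights; image blur. Passing the phantom suite therefore shows
that the geometry chain is correct and noise-stable under the stated
model, not that segmentation would survive clutter on clinical films.
Two consequences worth knowing: at these noise levels the Otsu mask is
*bit-identical across noise seeds* (background N(60,10) essentially never
crosses the ~130 threshold), so pipeline outputs are seed-invariant; and
SEV/IEV row estimates are soft by nature — |d| crosses ε where its
gradient is shallow, so extraction ripple moves the detected onset rows
by up to ~half a vertebra (the apex, by contrast, localizes to a few
rows after refinement; level *labels* quantize to vertebra bands anyway).

## Reliability harness

Cohen's kappa is computed unweighted from the full contingency table over
the union label alphabet: κ = (p₀ − pₑ)/(1 − pₑ), undefined (typed error)
when both raters are constant on the same label. Landmark labels are
treated as nominal; the CSV schema (`case_id,landmark,label`) supports
either vertebral-level or correct/incorrect alphabets. Verbal bands
(0.7–0.9 "good", >0.9 "excellent") are reporting conventions only.
Reproducing any clinical study's kappa values would require that study's
radiographs and observers; the package ships the harness and, in the
acceptance script, a clearly-labelled *synthetic* two-rater simulation
(50 cases, 15 % one-level disagreements) as a worked example of the
workflow.

## Numerical and interface choices

- Coordinates are 0-based pixels, row 0 superior, x rightward; all
  tunables live in one `PipelineConfig` (YAML-serializable), and
  `run_pipeline` is deterministic for a fixed image + config — the only
  randomness in the package is the phantom seed.
- Threshold ties break toward the lower cut; contour tracing starts at
  the topmost-then-leftmost pixel and runs clockwise; boundary-component
  ties break by raster order of the first pixel; apex ties break toward
  the smallest row. Every tie rule is fixed so outputs are reproducible.
- Stage failures surface as `StageError` naming the stage; a straight
  spine is a *result* (zero segments, a "no scoliotic curve" note), not
  an error. Per-method construction failures on a detected segment (e.g.
  Diab on a segment too short for its bands) are reported as NaN values
  for that method, not a pipeline abort.
- Problem sizes in the test and acceptance suites (5 straight phantoms,
  3 × 5 single-curve runs, 2 S-curves, 1000 null kappa pairs of n = 50)
  were chosen to exercise every claim at the native image scale while
  keeping a full run in the tens of seconds.

## Known limitations

- The MA is a boundary-midpoint centerline, not a true centroid chain;
  at high tilt the envelope midpoint is biased a few pixels toward the
  curve's concave side (straight bodies chord-cut the curved midline),
  which is the main residual Cobb error term (≈ 2° at a 40° curve).
- Vertebra-level labels assume equal vertebra heights.
- The severity classifier applies the Cobb-derived bands to whichever
  angle it is given; only the Cobb value should be graded clinically.
- No vertebral rotation, no lateral (kyphosis/lordosis) views, no
  curve-type taxonomy beyond single- vs double-curve structure.
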