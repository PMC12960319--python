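# Methods

This note documents the models, conventions and numerical choices behind
`mdrquant`, and what the synthetic benchmarks do and do not demonstrate.

## The MDR statistic

For one mediolateral-oblique (MLO) mammogram with a four-class tissue mask
(background, fat, gland, pectoral muscle), the mammographic dense rate is

    D_mj = mean intensity over pectoral pixels
    A_gl = number of gland pixels
    A_d  = number of gland pixels with intensity strictly greater than D_mj
    MDR  = A_d / A_gl

The pectoral muscle acts as an in-image intensity reference: because the
threshold is derived from the same image it is applied to, MDR requires no
cross-image calibration and is invariant under affine intensity rescalings
applied jointly to the whole image (threshold and gland intensities move
together). This is what makes the statistic usable on vendor-processed
("for presentation") mammograms, where volumetric physics models that need
raw data are not applicable.

Comparisons are done on the normalized [0, 1] scale at native float
precision, with no epsilon. The strict inequality (`>`) is the MDR
definition; the quantitative reading of the Japanese breast-composition
atlas counts pixels *at or above* the reference, so `compute_mdr` exposes
an `inequality={'gt','ge'}` switch, default `'gt'`. The two differ only for
pixels exactly equal to D_mj, which for continuous-valued images is a
measure-zero event.

MDR is computed per image (per breast side). Averaging a woman's two sides
is an optional cohort-layer pre-step (`average_lateralities`), off by
default, since per-age statistics count images.

Composition categories use the atlas cut-offs on the percent scale:
<10% fatty, 10–<50% scattered, 50–<80% heterogeneous, ≥80% extreme dense;
the last two jointly constitute "dense breasts".

## Segmentation model

A classic U-Net: `depth` encoder levels of two 3×3 conv + ReLU layers with
2×2 max-pooling, a bottleneck block, and a mirrored decoder using
nearest-neighbour upsampling with skip-connection concatenation; a final
1×1 convolution yields 4-class logits, and prediction is the per-pixel
argmax (ties break to the lowest class index, deterministically). Channel
width doubles per level from `base_channels`.

The network and its training loop are implemented directly on numpy
(`mdrquant.nn`): convolutions lower to one GEMM per kernel tap in
channels-last layout, backward passes are hand-written and verified against
finite differences, and optimization is Adam on a softmax cross-entropy
loss (optionally combined with soft-DICE). Training is deterministic given
`TrainConfig.seed` on a single device. Max-pooling routes gradients to the
first maximal element of each window, a deterministic subgradient choice
that differs from two-sided finite differences only at exact ties.

Defaults mirror the full protocol (100 epochs, 320×384 input, 4 levels,
16 base channels). The phantom benchmark uses a thin variant — 160×192,
2 levels, 8 base channels, batch 4, learning rate 3e-3, 10 epochs — chosen
so a full 240/60 train/test run takes a few minutes on one CPU core while
still saturating performance on the phantom distribution (pooled test macro
DICE ≥ 0.99 in practice, against the ≥ 0.90 requirement).

Evaluation: DICE per tissue class is `2|X∩Y|/(|X|+|Y|)`; when both masks
are empty for a class it is defined as 1.0, when exactly one is empty, 0.0.
The per-epoch history reports each class pooled over all test pixels plus
the unweighted (macro) mean over the three tissue classes, background
excluded. Published single-number DICE values for such models rarely state
the aggregation rule; we report all components so any convention can be
read off.

Resampling to the model size uses bilinear interpolation for images and
nearest-neighbour for masks (label preservation); anisotropic resizing (no
aspect-ratio padding) is the default, stated here as a deliberate choice.

## Synthetic phantoms

`generate_phantom` emulates the geometry a segmenter must learn from an
MLO view, with minimal shapes: a half-ellipse breast of fat against the
chest-wall edge, a right-triangle pectoral wedge touching the upper
chest-wall corner (area = `pectoral_fraction` of the image), and an
elliptical gland region (≈ `gland_fraction` of the breast). Left/right
laterality is realized by horizontal mirroring. Image dimensions must be
divisible by 16 (the deepest default downsampling).

Gland texture makes the ground-truth MDR controllable: exactly
`round(p · n_gland)` randomly chosen gland pixels are drawn from a bright
mode (realized pectoral mean + `gland_contrast`) and the rest from a dark
mode (mean − contrast), each with Gaussian noise clipped to stay strictly
on its side of the realized pectoral mean with a 0.005 margin. The
realized dense fraction therefore equals p to within half a pixel count
(and exactly 0 or 1 at the extremes), which makes parameter-recovery tests
structural rather than statistical. The 0.005 margin is ~330× the 16-bit
quantum, so PNG round trips cannot flip a pixel across the threshold;
intensities are quantized to the 16-bit grid at generation so file round
trips are bit-exact.

Default intensities (background 0.04, fat 0.35, pectoral 0.75, contrast
0.12, noise SD 0.02) give well-separated classes except gland-vs-pectoral,
which share the same mean intensity scale and are distinguishable only by
texture and position — deliberately, so the segmenter must learn more than
a threshold.

What the phantoms do *not* emulate: parenchymal texture, skin line and
nipple, compression artifacts, lesions, implants, vendor post-processing
differences. Passing the phantom benchmark demonstrates the pipeline's
machinery (data flow, training dynamics, metric correctness), not clinical
segmentation accuracy; the published accuracy of this approach rests on
annotated clinical images that no synthetic stand-in can replace.

## Synthetic longitudinal cohorts

`generate_cohort` emulates the two longitudinal patterns seen in screening
populations: a *rapidly declining* majority and a *persistently dense*
minority (`frac_persistent`, default 20%). Each subject enters at the lower
end of the age range (40, the screening entry age in Japan) and is examined
every `exam_interval_years` (default 5) years; each group follows a linear
trajectory `start − rate · (age − 40)` plus Gaussian exam noise
(`noise_sd`, default 2 percentage points), clamped to [0, 100].

Condition choices, made once: the declining group's rate is 1.33 %/yr (the
reported premenopausal population decline) with start values N(36.2, 7²) —
the mean is the reported age-40 median, and the SD is chosen so that
trajectories rarely hit the 0% floor inside the observation window, which
would flatten their fitted slopes; the persistent group declines at
0.1 %/yr from N(70, 10²). A reported cohort-wide "25.2% reduction" between
ages 40 and 59 is arithmetically inconsistent with the same report's median
endpoints (36.2 − 20.7 = 15.5 points); the generator uses the per-year rate
and treats neither figure as a target.

The trajectory classifier is an explicit, parameterized operational rule —
not a published criterion: least-squares slope ≤ −1.0 %/yr ⇒ rapidly
decreasing; mean level ≥ 50% with slope > −0.5 ⇒ persistently dense;
otherwise (including single-exam series) indeterminate. Under the default
generator conditions the two groups are separable by this rule with
expected accuracy ≈ 98–99% (slope standard error ≈ 0.13 %/yr at 5 exams
over 20 years with noise SD 2), comfortably above the 95% recovery target.

## Cohort analytics conventions

* Percentiles: linear interpolation between order statistics (numpy
  default); SD is population-style (ddof = 0), so a single image gives 0.
* Histograms: 10%-wide bins, last bin closed so MDR = 100 is counted;
  fractions sum to 1 by construction.
* Temporal differentiation: first difference of the median-by-age series,
  then a centered moving average (default 5-year window, odd widths only);
  edge windows shrink symmetrically. The median rather than the mean series
  is differentiated, since the median is what tracks the majority's
  decline; this is a documented default, configurable.
* Annualized decline between two (MDR, age) points is
  `(MDR_start − MDR_end)/(age_end − age_start)`, positive = decline.

## Numerical and I/O choices

* Images: 8/16-bit grayscale PNG/TIFF normalized by the bit depth maximum;
  RGB input is rejected rather than silently converted. DICOM (optional
  `pydicom` extra): MONOCHROME1 is inverted so higher always means denser.
* Masks: 8-bit indexed PNG over the palette {0,1,2,3}; out-of-palette
  values are an error.
* Result CSVs embed a configuration hash in a `#` comment header;
  percentages print with one decimal. Pipeline runs report a skip list so
  rows + skips always equal the number of candidate files.
* All randomness flows from explicit integer seeds via numpy Generators;
  reruns are bit-identical on the same platform.

## Problem sizes in the shipped benchmarks

The acceptance script and test suite train on 300 phantoms (240/60 split)
at 160×192 for 10 epochs, check operators against brute-force loop oracles
on 100 random instances, and use 200-subject cohorts (5 exams each) for
group recovery plus a 5000-subject single-age cross-section for histogram
calibration. These sizes were chosen as the smallest that make the
statistical checks stable.

## Known limitations

* The numpy U-Net trains on CPU only and is not meant for clinical-scale
  images or datasets; it exists to make the full pipeline executable and
  testable anywhere.
* Phantom separability means segmentation scores here are near-ceiling;
  they say nothing about inter-vendor robustness or annotation ambiguity.
* The trajectory rule's thresholds are operational defaults; on real
  longitudinal data they would need calibration against clinical outcomes.
* `EmptyRegionError` is raised when a predicted mask lacks gland or
  pectoral pixels; callers decide whether to skip or fail. The pipeline
  runner skips and reports.
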