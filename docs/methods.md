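# Methods

## The screen model

A colony-array screen is modeled as an endpoint measurement: each strain
*s* carries a true log growth ratio `L_s >= 0` (0 for all but planted hits),
and the size of one colony of strain *s* on plate *p* of plasmid *g* is

```
size = baseline * F_{g,p} * exp(-L_s * [g is experimental]) * eps
```

where `F_{g,p}` is a per-plate multiplicative scale factor and `eps` a
per-colony multiplicative noise term.  Both are lognormal with mean 1,
parameterized by their coefficient of variation (`plate_effect_cv`, default
0.1; `colony_noise_cv`, default 0.2).  The lognormal choice reflects that
colony sizes are positive and right-skewed; a cv of 0 yields exactly 1 so
that noiseless configurations are bit-exact.  Replicates are pinned as
contiguous square blocks (2×2 for 4 replicates, 4×4 for 16) on a 32×48 grid,
reproducing the pinning-robot upscaling that places 384 or 96 strains on one
1536-colony plate.  An optional multiplicative `edge_effect` on border cells
is available for robustness experiments but defaults to 1 (off): spatial
plate artifacts are otherwise not modeled.

The analysis inverts this model without knowing it: plate-median
normalization removes `F_{g,p}` exactly (dividing by the median divides out
any common factor), replicate means shrink `eps`, and

```
LGR_hat = ln(mean control / mean experimental)
```

estimates `L_s`.  With two control plasmids the control term is the
arithmetic mean of the two per-plasmid means.  At 16 replicates and cv 0.2
the standard error of a replicate mean is ≈ 0.2/4 = 0.05, so
`sd(LGR_hat) ≈ sqrt(0.05² + 0.05²/2) ≈ 0.061`; the hit threshold of 0.4 sits
more than 6 standard errors from a null strain, which is why null screens
produce essentially no false calls and planted effects of 0.8+ are never
missed.  The two calibration identities — LGR 1 ↔ experimental colony ≈ 37 %
of control, LGR 0.4 ↔ ≈ 67 % — are just `exp(-1)` and `exp(-0.4)`.

### Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `colony_noise_cv` | 0.2 | – | typical relative spread of replicate colony sizes on pinned arrays |
| `plate_effect_cv` | 0.1 | – | batch-to-batch growth variation; removed by normalization |
| `hit_lgr_threshold` | 0.4 | ln units | colonies < 2/3 of control; the field's convention |
| `retest_n` | 156 | strains | size of the strongest-interaction retest set |
| `min_replicates` | half the design | count | 2 of 4, 8 of 16 surviving replicates required |
| `zero_size_floor` | 0.01 | normalized size | caps the LGR of dead colonies (ln 100 ≈ 4.6) instead of emitting infinities |
| `baseline_size` | 100 | arbitrary | matches the scale of pixel-area measurements |

### Numerical choices

- **Median convention:** even-length plates use the mean of the two middle
  values.  After dividing by the median, a one-step fix-up division guards
  the "median is exactly 1.0" contract against the ulp-level rounding this
  convention can introduce.
- **Scale invariance:** rescaling a plate's raw sizes by a positive constant
  leaves every downstream LGR unchanged.  In floating point this is
  bit-exact for power-of-two factors (where the rescale itself is exact) and
  holds to ~1e-12 relative for arbitrary factors — the arbitrary-factor case
  cannot be bit-exact even in principle, because `fl(c·x)` are already
  different numbers.
- **z scores** use the sample (n−1) standard deviation over all strains with
  finite LGR; constant input is rejected as degenerate (detected by range,
  not by the floating sd, which pairwise summation can leave at ~1e-17).
- **Retest ties** at the selection boundary break by larger LGR, then
  lexical strain label, making runs reproducible.
- **Hit calls** use a strict inequality: LGR exactly 0.4 is not a hit.
- No multiple-testing correction is applied anywhere in the screen: the
  workflow's error control is the fixed threshold plus independent
  16-replicate retesting, and z scores are computed on LGRs (not raw
  ratios).  Growth-enhancing strains (negative LGR tail) are reported but
  never called.

## Plate rendering and colony quantification

Rendered scans place each colony as a filled disc at its grid position with
pixel area proportional to size (auto-scaled so the largest disc stays
inside its cell), at the physical 1536-array pitch of 2.25 mm mapped through
the scan resolution (300 dpi → 26.6 px).  Discs are rasterized at integer
pixel centres so equal sizes give identical pixel areas.

Grid detection thresholds the image at the midpoint between the background
and foreground histogram modes, projects the foreground onto each axis,
refines each projection peak by local centroid, assigns grid indices by
cumulative rounded peak spacing (robust to missing columns and to
pitch-estimate drift), and least-squares fits origin and pitch.  Measurement
then labels each half-open grid cell independently with 4-connectivity and
reports the largest component's pixel area as the size (ties break toward
the cell centre; integrated intensity is kept as a secondary column).  Area
is preferred over intensity because transmission scans saturate inside
colonies.  Against the generator's ground truth this recovers grid centres
to well under a pixel and ranks sizes with Spearman ≥ 0.99; agreement with
any particular legacy quantification suite is out of scope.

## Fluorescence quantification

Nuclei are segmented in the marker channel (tagged histone) by the same
bimodal-midpoint global threshold followed by 26-connected 3D components;
components below `min_voxels` (default 27 ≈ a 3×3×3 speck) are discarded.
For each nucleus a background shell is taken at in-plane chessboard distance
in `(offset, offset+thickness]` voxels (defaults 3 and 3) from the nuclear
boundary, computed per z-slice because the offset is specified in pixels and
the z sampling (300 nm) is coarser than x/y (205 nm); a physical-distance
mode is available.  "Three pixels" is interpreted as the gap between nucleus
and shell; the original analysis specified only the offset, so the shell
interpretation and its thickness are this package's declared defaults.
Shells exclude every labeled nucleus *and* every nucleus's offset buffer, so
neighbouring nuclei never contaminate a background estimate; a shell clipped
by the stack boundary (or empty) flags the measurement invalid rather than
silently biasing it.  The corrected value is

```
corrected_mean = mean(measure | nucleus) - mean(measure | shell)
```

reported as-is (it may be negative).  It is exactly invariant to adding a
constant to the measure channel and scales linearly with channel gain.
Sphere phantoms rasterize a voxel into a nucleus iff the voxel centre lies
within the radius in physical units — an unambiguous rule that a brute-force
enumeration oracle can check exactly.

## Count statistics

Fisher's exact test conditions on both margins and enumerates every 2×2
table consistent with them; the two-sided p is the total hypergeometric
probability of tables no more probable than the observed one
(probability-mass rule, the dominant convention).  Log-space pmf evaluation
with a 1e-9 relative tie tolerance keeps ulp-level pmf ties on the correct
side.  Binomial intervals default to Clopper–Pearson in beta-quantile form
(Wilson optional), since "binomial C.I." without qualification conventionally
means the exact interval.  Plasmid loss is `1 − selective/permissive`
clamped to [0, 1]; chromosome loss is the sectored-colony fraction with an
exact CI.  Replicate platings are pooled by summing counts (exact intervals
need pooled trials); per-replicate frequencies are reported alongside.

## What the generators do and do not emulate

The synthetic screens reproduce the statistical structure that the analysis
depends on — replicate-block layout, multiplicative plate effects, skewed
per-colony noise, dual control plasmids, planted effects of known size — and
the stacks reproduce anisotropic voxels, finite dynamic range and additive
sensor noise.  They do **not** model colony morphology, growth kinetics,
neighbour competition, lighting gradients, spatial edge artifacts (beyond
the optional uniform factor), optical blur/PSF, or non-spherical nuclei.
Passing tests therefore demonstrate that the estimators invert the stated
forward model at realistic noise levels, not that they are robust to every
artifact of real plates and microscopes.

## Known limitations

- Median normalization assumes well under half of a plate's colonies carry
  strong effects.  On dense retest plates (e.g. 10 strong hits among 50
  strains) the experimental plate's median is slightly depressed, inflating
  every LGR on it by up to ~0.06 ln units; this does not change any call at
  the 0.4 threshold but is visible in effect-size estimates.
- Grid detection requires at least one colony in every row and column;
  a fully empty lane raises a detection error rather than guessing.
- The suppression rule (mutant-background LGR ≤ threshold) is categorical,
  mirroring the field's language; a ratio criterion (mutant < half of
  wild-type) is provided but no formal strain×background interaction model
  is fitted.
- Problem sizes in tests and `scripts/acceptance.py` (e.g. 20 screen seeds,
  200 null seeds, 200k CI replicates) are chosen to make the Monte-Carlo
  error a small fraction of each tolerance while keeping a full run in the
  tens of seconds.
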