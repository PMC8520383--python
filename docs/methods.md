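# Methods

## Model and assumptions

The detector treats a vessel as a locally straight, tubular structure that is
darker than its surroundings in the green channel. On the inverted green
channel a vessel is a bright ridge, and the oriented line detector measures
ridge-ness as the difference between the mean intensity along a centered
discrete line of length `L` (12 orientations, 15° apart, covering the
half-circle) and the mean over the fixed 15×15 surrounding window. The
maximum over orientations is taken before the window mean is subtracted, so
the response at a vessel pixel is governed by the best-aligned line. Key
assumptions: vessels are approximately straight over 15 px; the background
varies slowly relative to the window; vessel width is in the 1–8 px range
covered by the scale set `{1, 3, 5, 7, 9, 11, 13, 15}`.

The scale split at `L = 9` reflects the width statistics of retinal vessels
(thin 3–4 px, thick 7–8 px). Small scales are detected on a locally enhanced
image, whose adaptive gain `A = min(C/(σ+s), cap)` grows where the 5×5
window is flat — exactly where faint thin vessels live; large scales are
detected on a globally enhanced image, a linear stretch about the in-FOV
mean that suppresses slow illumination drift and sharpens the main contours.
Per-scale responses are standardized (in-FOV mean 0, population sd 1) before
fusion so the equal-weight sum is not dominated by the scale with the widest
numeric range; the inverted green channel enters the fusion as one more
equal-weight term, anchoring the map to raw intensity.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| detector window `W` | 15 | px | fixed window for all scales; only `L` varies |
| scales `L` | 1,3,…,15 | px | line lengths; split small `<9` / large `≥9` |
| orientations | 12 × 15° | — | half-circle coverage, closed under 90° rotation |
| local window | 5 | px | neighborhood of the adaptive gain |
| local `C` | 3.0 | intensity | gain control; larger lifts flat-region detail more |
| local `s` | 1e-4 | intensity | stabilizer; keeps the gain finite on constant windows |
| local `gain_cap` | 5.0 | — | bounds `C/(σ+s)`, which otherwise explodes on flat regions and amplifies noise |
| global `c_g` | 1.0 | — | stretch about the in-FOV mean; 0 = identity |
| threshold | quantile q = 0.104 | — | top fraction of in-FOV fused values labeled vessel; the vessel density of expert fundus annotation |

`C` and `c_g` are empirical controls with no canonical published value; the
defaults were fixed once for intensities in [0, 1] and are exposed through
the config file (`enhance.local.*`, `enhance.global.c_g`) and the CLI. All
intensities are normalized to [0, 1]; the formulas are scale-free so only
the defaults of `C`, `s` depend on that choice.

## Numerical choices

- **Kernel discretization.** Line pixels are `round(k·(−sin θ, cos θ))` for
  `k = −(L−1)/2 … (L−1)/2` (θ from the +col axis, rows downward). When two
  `k` round to the same pixel, the later one is nudged along the line in
  ±0.25 steps until a free pixel appears; the negative half mirrors the
  positive half, so kernels are always symmetric under negation. Rounding is
  negation-symmetric: exact halves (e.g. `k·cos 60°`, whose float value
  straddles .5) are snapped within 1e-9 and rounded half away from zero,
  everything else half-to-even. This makes the kernel family exactly closed
  under 90° rotation, which the tests exploit.
- **Borders.** Window and line means use edge-inclusive (symmetric) reflect
  padding, avoiding the darkened rims that zero padding would turn into
  false line responses at the FOV edge. FOV-restricted means would be the
  principled alternative and are deliberately not implemented.
- **Standard deviations** (local gain, standardization) use the population
  denominator.
- **Thresholding.** Ties at the threshold are vessel. The quantile count
  `k = ceil(q·n − 1e-9)` so a mathematically integer `q·n` does not spill
  into the next rank. Degenerate all-equal maps raise under Otsu with a
  pointer to the quantile method. The fused map is *not* re-standardized
  before thresholding — the quantile rule is scale-free anyway.
- **Degenerate inputs.** Images below 32×32 are rejected (cannot host the
  15×15 window); empty FOVs and zero-variance responses raise with the
  scale and source image named.

## The phantom generator

Phantoms emulate the image properties the method responds to: a dark
background (green level 0.45) with a smooth planar illumination gradient
(amplitude 0.10; 0.25 in the `gradient` fixture), tubular vessels drawn as
rectangular cross-sections with 1-px antialiased edges (thin 3 px at
contrast 0.18, thick 7 px at 0.25 — contrasts chosen to sit near the low end
of what is visually obvious, since faint thin vessels are the hard case),
an optional 1-px bright central reflex restoring 80% of the contrast on the
centerline, additive Gaussian noise (sd 0.02 where used), and a circular
FOV of radius 58 in a 128×128 frame. Ground truth is the set of pixels whose
noise-free vessel coverage exceeds one half — for an axis-aligned segment of
width `w` spanning `n` columns that is exactly `w·n` pixels, which is what
makes the generator testable. Vessel layouts cover roughly 10% of the FOV,
matching the annotation density the default threshold presumes; the parallel
pair is geometrically capped below that and crosses the entire FOV, since a
pair that co-terminates in open field lets endpoint halos touch — a
different artifact than the along-gap merging that fixture probes.

What phantoms do **not** emulate: curved and branching vessels, the optic
disc and macula, lesions, camera vignetting beyond a planar ramp, sensor
quantization, or the width/contrast joint distribution of real vasculature.
Passing the phantom suite therefore demonstrates the geometric behavior of
the detector (orientation selectivity, scale selectivity, no merging of a
4-px-separated pair, no extra dilation at crossings) — not benchmark-level
accuracy on DRIVE/STARE, which depends on unpublished enhancement constants
and thresholds and on the databases themselves. The `benchmark` subcommand
exists for users who have the databases: it sweeps quantile thresholds and
reports per-image ACC/TPR/FPR.

## Problem sizes

The test suite and `scripts/acceptance.py` run on 128×128 phantoms (FOV ≈
10,600 px) and 32×32 random images for oracle comparisons; the
split-vs-baseline comparison averages ten noisy phantoms at matched
background FPR (1–10% grid in the tests, 5% in the acceptance script). The
full suite completes in a few seconds on one CPU; a 605×700 fundus image
segments in a few seconds as well.

## Known limitations

- The thresholding rule of published benchmark results on DRIVE/STARE is
  not recoverable; any comparison must sweep operating points.
- Forcing the 10.4% quantile on a scene with lower true vessel density
  necessarily labels background speckle; the quantile default encodes a
  prior about density, not a property of the detector.
- The detector has no explicit model of vessel curvature; strongly tortuous
  vessels lose response at large `L`.
- Diseased retinas (lesions, hemorrhages) violate the "vessels are the only
  elongated dark structures" assumption and are not a validated use case.
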