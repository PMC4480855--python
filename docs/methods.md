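# Methods

## Receptive fields and the cell grid

Monocular RFs are Gabor functions
ρ(x, y) = exp(−(ẋ² + ẏ²)/2σ²) · cos(2πf ẋ + φ), with (ẋ, ẏ) the
coordinates relative to the RF centre rotated into the preferred
orientation. The grid uses 8 orientations iπ/8, three sizes
σ ∈ {√2, 2, 2√2} px with f = 1/(2σ) (hence f ∈ {√2/4, 1/4, √2/8}
cycles/px and a scale-independent half-magnitude bandwidth of
log₂((π+√(2 ln 2))/(π−√(2 ln 2))) ≈ 1.14 octaves), two quadrature phases
{0, −π/2}, and preferred horizontal disparities 0..59 px. Phase disparity
and vertical disparity are fixed at zero, so the left/right kernels of a
cell share one profile and differ only in centre position. That yields
2880 simple cells (1440 complex pairs) for the luminance model and
34 560 (17 280) when three RF dominances and four colour channels are
added.

Numerical choices: kernels are truncated at radius ⌈3σ⌉ (beyond which the
envelope is < e^−4.5 of peak); the cosine kernel's DC term
(≈ exp(−π²/2) ≈ 0.007 relative) is documented, not removed — the
binocular correlation is a ratio in which it cancels. Sub-pixel RF
centres (centre dominance at odd disparities) are realised by evaluating
the closed-form Gabor at shifted coordinates, never by interpolating a
sampled kernel. Coordinates: x rightwards, y downwards, 0-based pixel
centres; positive disparity means the right-image pattern lies that many
pixels to the *left* of its left-image position, so x_R = x − Δx.

## Energy model and effective correlation

Per cell, M = v_L² + v_R², B = 2 v_L v_R. The two quadrature phases are
summed and both terms pooled with a normalised Gaussian of the *same* σ
as the simple cells (one grouping-cell definition is given, so the final
pooling of the ratio reuses that σ too); pooling is truncated at 3σ to
match the kernel support. The ratio is pooled once more to give ψ^sp.
Because convex pooling of values in [−1, 1] stays in [−1, 1], |ψ^sp| ≤ 1
everywhere; at matched disparity the ratio is identically 1 so the value
survives both poolings exactly.

Division guard: a pixel whose pooled monocular energy falls below 10⁻⁶ of
the field's mean is flagged low-energy, gets ψ = 0 and is excluded from
the validity mask. No ε is added to healthy denominators — a global ε
would bias matched-disparity ψ away from 1 by more than the 10⁻⁹ the
package guarantees.

Cost structure: the kernel profile does not depend on Δx, so each image
is convolved once per (σ, θ, φ) — FFT correlation with reflect padding —
and all 60 disparities reuse the maps at translated positions. The
validity mask excludes every pixel whose RF, disparity translation or
pooling support (⌈3σ⌉ + 2·⌈3σ⌉ per side, plus Δx_max in the shift
direction of the dominance) leaves the image; inside it the boundary
handling is immaterial.

## Training

For each stimulus disparity 0..59, `n_reps` random-dot pairs are drawn:
left pixels i.i.d. N(0,1), right a copy shifted by the disparity with the
uncovered columns refilled with fresh noise. ψ is evaluated *without*
spatial pooling at the stereogram centre only (averaging over stimuli
replaces spatial pooling), converted to Ψ = (1+ψ)u with u = 8 spikes
(uncorrelated baseline; 2u = 16 at perfect correlation), and averaged
into W. Training images are sized 2r+1 × 2(r + 59)+1 with r = ⌈3σ_max⌉ = 9
so that the centre RF and the matched-disparity right RF never touch the
filled gap; the matched-cell code entries are therefore exactly 16. The
full-scale run is 60 × 1000 stereograms (the package default),
and the test suite and acceptance script train at 200 reps/disparity,
which already recovers every disparity at ≥ 99 % of valid pixels.

One RNG stream per (disparity, repetition) is spawned from the master
seed, so partial runs are bit-reproducible. Training always uses left
dominance; the same W serves all dominances and channels at decode time,
since the correlation statistic is independent of how the RF pair is
anchored.

Tuning-curve shape: the learned rows peak exactly at the trained
disparity and fall to the uncorrelated baseline u away from it, but the
flanks oscillate (the disparity tuning of a position-shift energy cell is
Gabor-shaped, with sidelobes at the carrier period — ~2.8 px at the
finest scale). Tests therefore assert the peak, the mean flank elevation
and the baseline, not monotone decay.

## Decoding

Each pixel's 1440-value code is compared with all 60 rows of W by Pearson
correlation, half-wave rectified (anti-correlated stimuli then match
nothing instead of matching a wrong disparity); the winner takes all,
ties resolving to the smallest (farthest) disparity. Zero-variance or
non-finite codes yield an all-zero match vector. Pearson's affine
invariance makes the decoder contrast-invariant and lets the
luminance-trained codes serve the colour channels unchanged.

## Colour and viewpoint layers

Channels: l = 0.2989R + 0.5870G + 0.1140B (perceptual luminance), plus
r = R+G/4+B/4, g = R/4+G+B/4, b = R/4+G/4+B (colour-predominant mixes).
Grayscale input replicates into affinely related channels, and the
colour path then reduces numerically to the luminance path (regression
tested). Per dominance the winner is taken jointly over (disparity,
channel), literally max over channels then first argmax over disparity.

Viewpoint fusion keeps the left map in place and gathers the centre map
at x + round(0.5·D_C(x,y)) and the right map at x + D_R(x,y) (rounding
half away from zero; maps are integer-valued). Median of the available
contributions; with two, their minimum (conservative, background-biased);
with none the pixel is inactive. Background correction counts active
pixels per disparity, normalises by d² (d = 0 is excluded from the
argmax — the heuristic's purpose is to de-prioritise *near* surfaces; an
all-zero map gets d_bck = 0), raises everything below the background
disparity to it, and fills inactive pixels along their row with the
minimum of the medians of the nearest active 5-pixel runs on either side.

## Line/edge disparity (monocular)

Eleven scales λ = 4..24 (step 2), σ = λ/2, 8 orientations. Even/odd
responses are the real/imaginary Gabor parts; the modulus models a
complex cell. Kernels here are DC-corrected (zero mean) and normalised by
the envelope area πσ² so moduli are comparable across scales and sit on
the image grey-level scale — the amplitude-match tolerance (2 grey levels
on [0, 255] images) presumes this. Lines are even-extrema with odd
zero-crossings along the dominant orientation's normal, edges the swap;
events below 5 % of the scale's maximum modulus are inhibited and 1-D
non-maximum suppression along the normal stands in for lateral
inhibition (events are assigned to the dominant orientation only — a
documented simplification of full cross-orientation inhibition).
Zero-crossings are located between adjacent samples and snapped to the
nearer one; extremum/crossing comparisons carry a 10⁻⁹-relative
tolerance because symmetric features produce exact two-sample plateaus
that FFT round-off would otherwise split.

Keypoints are end-stopped responses: |first| + |second| directional
derivative of the *dominant* channel's modulus along its line/edge
tangent, 3×3 non-maximum suppression, 5 % floor. Taking the tangent of
the dominant channel keeps straight line/edge interiors silent (the
modulus is constant along them) while terminations, corners and
crossings respond.

Correspondence: for every finest-scale left event, circular RFs of
radius 2λ_s at each scale accumulate, per candidate shift 0..59 of the
right maps, four measures — M1 same position/type/polarity, M2 any event
match, M3 modulus match within tolerance, M4 keypoint match within 3×3 —
normalised by the left event (M1–M3) or keypoint (M4) count in the same
RF. The score Σ_s (4M̄1 + M̄2 + M̄3 + 4M̄4) saturates at 110 on identical
pairs; the argmax over shifts (ties smallest) gives the sparse D^LE.
Cross-scale comparison happens within the same scale only.

## Border layers

Region enhancement (tolerances t = 1..5, each iterated to a fixpoint):
line/edge pixels whose N4-cluster medians of D^LE and the current dense
map agree within t adopt the dense cluster median; pixels never
reconciled have their N4 cluster overwritten with the line/edge value.
Output values always come from the two input maps.

Conspicuity is the maximum over four symmetric offset pairs (unit
horizontal/vertical steps and the two diagonals — exact unit length is
impossible for integer diagonal offsets, a documented deviation) of the
Euclidean distance across the four channels, floored at 10 % of its
maximum and thinned by 3-sample NMS along the winning direction. Border
cells activate where conspicuity is positive or a non-zero line/edge
disparity disagrees with the dense map. Far from any border (10 px), a
connected constant-disparity cluster no larger than the 10 px disc is
clamped to its 1-px perimeter ring's median if it is a peak, or raised to
the ring minimum if it is a depression. Near borders, a triplet of 3×3
median cells walks outward up to 25 px on each side along the border
normal (quantised to 4 directions from a 5×5 structure tensor,
degenerate ties → epipolar direction); at the first stable transition
(|Φ2−Φ3| ≥ 2, Φ2 = Φ1) the stable value Φ2 is propagated back to the
border — this flattens disparity between an object border and the next
genuine transition. A mask-aware circular median (radius 6 px,
implemented by cumulative value counting so borders renormalise
correctly) produces the final map. All thresholds are estimator
parameters with these defaults.

## Synthetic stimuli: what they do and do not show

The generator produces (a) uniform random-dot training pairs as above and
(b) layered scenes: a background plane and opaque noise-textured
rectangles (grey levels N(128, 40²) clipped to [0, 255]) at fronto-
parallel integer disparities, composited far-to-near with exact ground
truth and a geometrically derived half-occlusion mask. These stimuli have
ideal properties real stereo pairs lack: perfect rectification, exact
integer disparities, rich texture everywhere, no photometric asymmetry
between the eyes, no slanted or curved surfaces, and no specularity.
Passing tests on them demonstrates the correctness of the machinery
(encoding, decoding, fusion, border logic) and parameter recovery under
the model's own assumptions — not real-world benchmark performance, which
additionally depends on texture-poor regions, radiometric noise and
non-fronto-parallel geometry.

## Problem sizes

The test suite and acceptance script use 96×160 stereo pairs (large
enough that the decodable region after all support margins still holds
~2000 pixels with the full 60-disparity grid) and 200 training
repetitions per disparity; the full 1000-repetition training run is a
single function-call parameter away and scales linearly.

## Known limitations

Integer disparities only (no sub-pixel interpolation); no vertical
disparity; phase-disparity tuning deliberately fixed at zero; the
simplified inhibition schemes above; the Eq-style viewpoint gather uses
each pixel's own disparity estimate as the shift, which is approximate
near discontinuities (the median fusion and background correction absorb
most of the resulting artefacts); the background heuristic assumes the
background is the largest far surface.
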