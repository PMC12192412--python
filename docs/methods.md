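# Methods

## Problem setting

The package tracks the centre of the iris through short visible-light
videos of one eye, pre-cropped to a fixed region of interest (ROI). All
coordinates are pixels relative to the ROI's top-left corner (origin
`(0, 0)`, x rightward, y downward, 0-based). Centres are stored as floats:
manual annotation of such footage is typically done at half-pixel
precision, and the synthetic ground truth is exact sub-pixel. Frames are
sampled every k-th frame (default k = 10; at 30 fps this is an effective
3 Hz analysis rate) and converted to grayscale with ITU-R BT.601 luma
weights (0.299, 0.587, 0.114) — the conversion is a convention choice; any
fixed luma keeps the dark-iris/light-sclera contrast that both trackers
rely on.

## CHT_ACM

Per frame:

1. **Morphology.** One grayscale erosion followed by one dilation with a
   3×3 elliptical structuring element — an opening of the brightness
   signal. Opening absorbs small bright specular glints; the companion
   closing (dilation first) removes thin dark structures such as lashes
   instead. The pair, order, kernel shape/size and iteration counts are
   configurable (`MorphologyConfig`); the defaults are deliberately mild
   because the circle selection rule (below) already rejects most
   lash-induced false circles.
2. **Snake.** A morphological Chan-Vese active contour, initialised as a
   circle (the best raw CHT candidate when one exists, else a circle of
   radius 0.4 × min(frame dims) at the frame centre). Chan-Vese was chosen
   over edge-based snake energies because it is region-driven and
   parameter-light: the only knobs are the iteration cap (200), the
   smoothing strength (1) and a convergence tolerance. Evolution runs in
   10-iteration chunks and stops early once the mean per-iteration boundary
   displacement (changed pixels / boundary pixels / iteration) drops below
   0.1. A level set that empties or floods the frame raises a collapse
   error, which the detection chain converts into a failed frame; a
   constant (forceless) image returns the regularised initial circle with
   `converged=False`.
3. **Refined crop.** The snake's bounding box, padded by 20 px and clipped
   to the frame.
4. **Binarisation.** Otsu's between-class-variance threshold on the crop
   histogram, applied as `pixel >= t → white (255)`. The reported threshold
   is placed at the midpoint of the empty intensity gap above the Otsu
   value so that the `>=` convention is exactly equivalent to
   scikit-image's `> t` foreground rule. Constant crops are flagged
   degenerate and fail the frame.
5. **CHT.** Edge map: 3×3 Sobel L1 gradient magnitude, hysteresis
   thresholding at (90, 180) on the raw 0–255 gradient scale, thinned to
   single-pixel width. This reproduces the OpenCV `HoughCircles`
   convention, where `param1 = 180` is an upper threshold on that gradient
   scale (a Gaussian-derivative edge detector would need a rescaled,
   meaningless threshold). Votes accumulate per radius (15–50 px); local
   maxima with ≥ 10 raw votes become candidates, and centres are kept
   ≥ 40 px apart by greedy suppression in vote order (ties broken by y,
   then x, then radius, so the output is deterministic).
6. **Selection.** For each candidate, the white fraction = white pixels
   inside the discrete disc {(px−cx)² + (py−cy)² ≤ r²} / disc area. A
   candidate qualifies as the iris only if its white fraction is < 0.60.
   The 60% rule is interpreted as a *fraction* of the circle area rather
   than an absolute sum of white-pixel values: absolute sums scale with
   circle area and image size, which would make the threshold meaningless
   across radii. Among qualifying candidates the lowest white fraction
   wins, then the highest vote count, then the smallest centre y. A frame
   with no qualifying candidate is marked invalid; the run continues.

## CHT_TM

Frame 0 runs CHT_ACM and cuts a square template of side 2r centred on the
detected iris (integer-rounded centre), with a circular mask of radius r
centred in the patch. The circle must lie fully inside the frame (an
"intact" iris); otherwise tracking aborts with a diagnostic, since no
template exists to carry forward. The template is never updated.

Every later frame computes a similarity at all placements of the template.
The default similarity is **masked zero-mean normalised cross-correlation**
(NCC): only pixels under the mask contribute, and both patch and window are
centred and normalised under the mask, so scores live in [−1, 1] and are
illumination-invariant. The raw product-sum cross-correlation is available
(`matching.method: ccorr`) but is dominated by bright regions, which
contradicts selecting the darkest region afterwards. Placements scoring
within 98% of the per-frame maximum are kept as candidates; the candidate
whose circular region (radius = template iris radius, at the implied
centre) has the lowest mean intensity becomes the iris centre, with ties
going to the higher similarity. Sub-pixel refinement is deliberately not
applied — placements are integer pixels, which bounds the quantisation
error at ~0.5 px, below the half-pixel precision of manual annotation.

Numerics: the three correlation maps (window sum, window sum of squares,
masked-template correlation) are computed by direct sliding-window
`einsum` when the total multiply-add count is ≤ 2·10⁶ (exact to ~1e−15,
used by the oracle comparisons) and by FFT convolution otherwise (~1e−12,
used at production sizes). Window variances are clamped at zero before the
square root; placements with near-zero variance score 0, and a
zero-variance template yields an empty candidate list (degenerate frame).

**Validity.** A frame is invalid when matching is degenerate or the best
NCC falls below an absolute floor of 0.5. This automates what a human
rater does manually (discarding blink frames); flags are recorded in the
trajectory, never silently dropped. The floor is configurable; 0.5 sits
far below the ≥ 0.9 scores seen on open-eye frames and above the ≈ 0.1–0.3
scores on closed-lid frames, so it is not delicate.

## Metrics

MAE, MPE, RMSE and Pearson r/t/p are computed per axis over frames valid
in *both* trajectory and ground truth (pairwise exclusion). MPE divides by
the raw pixel coordinate plus ε (default 1e−6 px, configurable), which
makes it origin-dependent — a quirk of the convention this package
replicates for comparability; the ε exists purely to guard division when a
coordinate is 0. The p-value is the two-tailed Student-t survival function
with n − 2 degrees of freedom applied to t = r·√((n−2)/(1−r²)); |r| = 1 to
machine precision reports t = ±∞, p = 0 rather than dividing by zero, and
a constant series raises an explicit error from `pearson()` while
`evaluate()` degrades it to a `None` with a recorded reason — constant
series arise legitimately (the fixation task, or the y axis of a purely
horizontal movement). `compare_groups` renders reports in the long format
of condition-comparison tables (`x_CHT_TM`-style row labels, MAE / MPE /
RMSE / PCC_r columns) and flags the best value per metric across groups
sharing a (method, axis) row family.

## Synthetic scenes

The generator emulates the structure of a cropped visible-light eye
recording, not its photometry. Layers, back to front: skin (intensity
190), the palpebral aperture as a wide ellipse containing sclera (220),
the iris disc (brown 60 / green 110 / gray 140 — darkest first, so brown
gives the easiest contrast), a pupil disc at 0.4× the iris radius
(intensity 25), seeded glints (2 bright discs of radius 2 inside the
iris), seeded lash strokes rising from the upper lid, and additive
Gaussian sensor noise (σ = 3) clipped to [0, 255]. Default geometry:
240×160 px ROI, iris radius 30 px — inside the detector's 15–50 px radius
window. Blink frames render fully closed lids (skin only).

Eyelid coverage is parameterised as the fraction of iris height occluded
at rest (defaults: 0.15 top, 0.10 bottom). The lids translate vertically
with the iris (gain `lid_follow = 1.0`): real upper lids ride on vertical
gaze, and a fixed aperture would implausibly swallow most of the iris at
the vertical-task extremes. The consequence is that occlusion is
approximately constant across a video, so occlusion *varies with the
coverage parameter* but not with gaze direction — adequate for studying
the occlusion mechanism, but milder than a real recording where lid
position fluctuates with fatigue and blink onset.

Task trajectories: linear tasks ramp out and back once (triangular
profile, peak displacement = amplitude, returning to the start on the
final frame); the circular task runs exactly one revolution (first point
= last); fixation holds the centre. Default amplitude 25 px. Frame count
= duration × fps (30 fps; 1 s or 5 s).

Determinism: one integer seed drives glint/lash geometry (per video) and
the noise stream (per frame, via `default_rng([seed, 1 + frame_index])`).
Identical configuration ⇒ bit-identical frames, trajectories and CSVs.

What passing on these scenes does **not** show: robustness to motion blur,
head motion, off-axis camera angles (elliptical iris projection), partial
lid closure mid-video, iris texture, shadows, or compression artefacts.
Errors measured here (~0.1–0.3 px MAE) are accordingly about an order of
magnitude smaller than on real handheld footage (~1.4–2 px); the synthetic
scenes validate the machinery and its failure modes, not field accuracy.

## Problem sizes

The test-suite and acceptance-script runs use 5 s videos at 30 fps sampled
every 10 frames (15 analysed frames per video), 3 scene seeds per task for
accuracy pooling, 5 seeds for the masking comparison, 50 discs for circle
recovery, and 100 consecutive frames for the runtime comparison — sizes
chosen so the whole validation completes in minutes on one CPU while
keeping every per-frame code path exercised.

## Known limitations

- No video-container decoding without an ffmpeg-backed imageio plugin;
  frame directories are the portable input format.
- The first frame must contain a detectable, fully-in-frame iris; there is
  no template re-acquisition after long occlusion.
- The CHT returns integer centres and radii; CHT_TM inherits integer
  placements. Sub-pixel accuracy is bounded, by design, at ~0.5 px.
- `min_dist` suppression is greedy in vote order, which is deterministic
  but not globally optimal for dense candidate fields.
- MPE is origin-dependent (see above); compare values only between
  trajectories expressed in the same ROI.
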