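# Methods

`embryoquant` implements two image-quantification procedures for
whole-mount zebrafish-style embryo micrographs, the group statistics
applied to their outputs, and a synthetic phantom generator that gives
every stage a known ground truth. This note records the models, the
parameters that matter, the numerical choices, and what validation on
phantoms does and does not establish.

## 1. Dorsoventral axis profiling (immunofluorescence)

**Procedure.** The input is a two-channel grayscale image: a signal
channel (an immunostain readout of BMP signaling such as
phospho-Smad1/5/8, imaged e.g. in Cy5) and a nuclear counterstain
(DAPI). A rectangular ROI is laid over the middle of the embryo with
the ventral–dorsal axis along one ROI dimension. For each position
along that axis, both channels are summed across the transverse
dimension (the semantics of ImageJ's *Plot Profile* on a rectangle).
Each embryo's profile is linearly resampled onto a common normalized
axis — ventral end at 0, dorsal end at 1 — and the per-position
signal/nuclear ratio is taken. Group curves report the per-position
mean ratio ± standard error of the mean (SEM).

**Assumptions.** The ROI spans the embryo from ventral edge to dorsal
edge, so the ROI endpoints are the alignment landmarks; alignment is
endpoint normalization plus linear stretch, with no cross-correlation
shift. The nuclear channel is treated as a flat normalizer: dividing
by it removes illumination and nuclear-density variation along the
axis.

**Parameters.**

| parameter | default | units | rationale |
|---|---|---|---|
| ROI height × width | 200 × 650 | px | the rectangle size used for the embryo micrographs this workflow targets |
| `target_bins` | 100 | bins | coarse enough to pool ~650-px profiles, fine enough to resolve a smooth gradient |
| `nuclear_floor` | 1e-6 × max(nuclear) | a.u. | masks background positions instead of producing division blow-ups; masked positions are excluded from group means |
| transverse aggregation | sum | — | matches Plot Profile on wide rectangles; a mean differs only by the constant ROI-height factor, which cancels in the ratio |

The "normalized intensity" is the signal/nuclear ratio only; no
further per-embryo rescaling is applied by default (a max-normalization
flag exists but is off, since the ratio is the quantity of interest and
rescaling would discard between-embryo amplitude differences).

## 2. Angular extent of a chromogenic expression domain

**Procedure.** The input is an RGB brightfield image of an embryo
carrying a purple (NBT/BCIP) in situ precipitate. Three steps:

1. *Thresholding.* Each pixel is classified as stain by an explicit
   RGB rule (`ThresholdRule`): optional per-channel bounds and linear
   scores `w·(R,G,B) + bias ≥ cutoff`, all of which must hold. The
   default rule for purple stain on 8-bit images is `B ≥ R` and
   `G < R` and mean channel intensity < 160, which rejects both white
   background and the warm-toned embryo body. The rule is a documented
   stand-in chosen for the default phantom palette, not a universal
   constant: it is a config object, logged with every run, and should
   be overridden per image set. A white-on-dark visualization of the
   mask is produced for manual review.
2. *Radial sums.* Within a manually traced ellipse around the embryo,
   the mask is summed along rays from the ellipse center to its
   boundary at `n_points = 360` equally spaced angles. Rays are
   sampled at unit-length steps (distances 1, 2, …, ⌊t_boundary⌋)
   with nearest-pixel lookup (`np.rint`, ties to even).
3. *Extent.* A bin is occupied when its radial sum exceeds
   `signal_min`; occupied bins × (360/n_points) gives occupied
   degrees, and dividing by 360 gives the extent fraction. Occupancy
   counts non-contiguous bins; the longest contiguous occupied arc
   (computed circularly) is reported alongside so both readings of
   "extent" are available when a domain is fragmented.

**Angle convention.** 0° along +x (image right), increasing
counter-clockwise (toward decreasing row index); `angle_offset_deg`
rotates the bin origin if another convention is required. For rotated
ellipses the sector and ray angles are image-frame angles; the
boundary distance is computed in the unrotated ellipse frame.

**Parameters.** `signal_min` defaults to 0 (any stained pixel on the
ray marks the bin); simulation configs with pixel noise use the
noise-robust value 2, which requires at least three stained samples on
a ray and suppresses bins lit by isolated false-positive pixels.
Ellipse input is manual (config/CLI), matching the traced-oval
procedure the pipeline reproduces.

## 3. Group statistics

Two-group comparisons use the two-sided homoscedastic (pooled-variance)
Student t-test with n_a + n_b − 2 degrees of freedom; a Welch variant
is available behind `equal_var=False` for sensitivity checks. Error
bars are SEM = s.d.(ddof=1)/√n. Degenerate inputs are defined rather
than fatal: zero pooled variance with equal means gives t = 0, p = 1;
zero pooled variance with unequal means is flagged and reported as
p = 0 with a warning. No multiple-testing correction is applied — each
call is a single pairwise comparison, and per-position profile
comparisons along the axis are deliberately out of scope.

At n = 3 vs 3 the exact permutation distribution cannot produce a
two-sided p below 0.1, so parametric and permutation p-values are only
expected to agree at moderate group sizes; the test suite checks the
agreement at n = 30 per group.

## 4. Synthetic phantoms

**Gradient phantom.** Inside a rectangular embryo region the nuclear
channel is constant (`nuclear_level`, default 100 a.u.) and the signal
channel is `nuclear_level × ratio_function(x)` with x the normalized
axis position, so the true ratio profile is known analytically.
Additive Gaussian noise (default validation level: s.d. 5 on a
100-a.u. nuclear level, i.e. 5% per pixel) is clipped at zero.

**In situ phantom.** An elliptical embryo (body color a warm tan) on a
white background, with a purple rim band of depth `stain_band_depth`
(default 35 px) restricted to an angular sector. A pixel is stained
when its image-frame angle lies in the half-open sector [start, end)
and it lies within the band depth of the boundary along its own ray.
The true extent fraction is the sector span / 360. Additive Gaussian
noise per channel (validation level: s.d. 10 on the 8-bit scale) is
clipped to [0, 255] and rounded.

**Sector snapping.** The batch generator realizes each requested
extent at the angular resolution of the downstream measurement: spans
are rounded to whole 1° bins and sector edges are placed on half-bin
offsets, midway between bin centers, and the returned ground truth is
the realized sector's extent. Together with the default geometry —
image 420 × 520 px, semi-axes 230 × 180 px, band depth 35 px, so all
stained pixels sit at radii ≥ ~145 px — this guarantees that
nearest-pixel ray sampling (rounding error ≤ √2/2 px, i.e. < 0.5° of
angle at those radii) cannot move a sample across a sector edge, and
noise-free recovery is exact at bin resolution. With smaller embryos
or unsnapped sectors, boundary bins can each be off by one — the ±1–2
bin tolerance quoted for small-geometry unit tests.

**What the phantoms do not emulate.** Optical blur, 3-D structure and
projection artifacts, chromogenic stain chemistry (graded stain
intensity, edge diffusion), non-elliptical embryo outlines, uneven
illumination, and segmentation error in the manually traced ellipse.
Passing the phantom battery therefore demonstrates that the
*measurement chain* is correct and noise-tolerant at realistic noise
levels, not that the default threshold rule or ellipse placement is
robust on any particular real image set.

## 5. Validation problem sizes

The shipped checks use: 100 phantoms for extent recovery (noise-free
and noisy); 20 random mask/ellipse pairs (≤ 200 px) for exact
ray-walk equivalence; 10 gradient phantoms per group for profile
recovery; 200 repetitions of the two-group expansion design at the
study-sized groups n = 14 vs 12 (true extents 0.35 vs 0.55,
between-embryo s.d. 0.05); and 10,000 simulated null pairs (n = 12,
14) for t-test calibration. These sizes make the full battery run in a
few minutes on one CPU while leaving Monte-Carlo error well below the
decision margins.

## 6. Known limitations

- The default RGB threshold rule is tuned to the phantom palette; real
  image sets need a rule chosen per batch (and the choice is logged,
  so it is auditable).
- Endpoint-based alignment assumes the ROI was placed edge-to-edge on
  each embryo; if the original procedure involved additional shift or
  stretch alignment, absolute positions may differ slightly between
  implementations.
- Radial sums use nearest-pixel sampling; sub-pixel interpolation
  would change sums by O(1) counts per ray and is intentionally not
  used, to keep the oracle equivalence exact and the behavior close to
  the plugin procedure it mirrors.
- Absolute profile values depend on the transverse sum convention
  (height-factor difference from a mean); only the ratio is
  convention-free.
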