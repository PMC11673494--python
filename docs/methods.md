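# Methods

`facemetry` evaluates how closely a reconstructed 3D facial surface
reproduces a reference surface scan, the way such comparisons are run in
clinical facial morphometry: rigid registration, region-wise surface
deviation, landmark deviation along anatomical axes, standard soft-tissue
measurements, and paired agreement statistics. It also contains the
shape-model machinery such reconstructions rest on — a linear PCA
morphable model with ridge landmark fitting and an iterative basis-
augmentation procedure — and a synthetic face generator that supplies
scan/reconstruction pairs with known ground truth.

All geometry is in millimetres, in right-handed coordinates with
X = subject's left, Y = superior, Z = anterior.

## Anatomical coordinate frame

The frame is built from soft-tissue landmarks only, since surface scans
expose no bony anatomy:

* **origin** — midpoint of the bilateral tragion (TraL, TraR);
* **horizontal plane** — least-squares plane through TraL, TraR and the
  two infraorbital points OrbL, OrbR, a soft-tissue proxy for the
  Frankfurt plane (true porion/orbitale are not available on a scan);
* **midsagittal plane** — least-squares plane through the midline
  landmarks (default N', Prn, Sn, Pg'; the list is configurable),
  constrained orthogonal to the horizontal plane.

X is the midsagittal normal signed toward TraL, Y the horizontal normal
signed toward the glabella, Z = X × Y checked to point toward the nose
tip. Axes are re-orthonormalized; an inconsistent orientation (Z away
from Prn) raises a degenerate-input error rather than silently flipping
an axis.

Frame equivariance — a common rigid transform of a pair changes no RMSE,
landmark deviation or measurement by more than 1e-6 — is enforced by
test.

## Registration

Registration follows two stages, the standard "pre-align then best fit"
protocol:

1. **Pre-alignment** — closed-form Kabsch/Horn rigid fit (no scaling) on
   a small matched landmark set, default bilateral exocanthion,
   pronasale and soft-tissue nasion.
2. **Best fit** — trimmed iterative-closest-point: exact
   point-to-triangle correspondences, the best 90% of correspondences
   kept per iteration (tolerating non-overlapping mesh borders), a
   closed-form rigid update, and a stop when the trimmed RMSE improves
   by less than 1e-6 mm or after 100 iterations. With the trimming set
   size fixed, the trimmed RMSE trace is non-increasing: re-matching can
   only shorten distances, trimming keeps the smallest, and the Kabsch
   update minimizes over rigid transforms.

Nearest-point queries are exact, not approximate: a kd-tree over
triangle centroids yields an upper bound from the nearest-centroid
triangle, and every triangle whose centroid lies within that bound plus
the largest centroid-to-vertex radius is scanned with a vectorized
point-triangle distance. The result equals a brute-force all-triangle
scan bit-for-bit (tested).

## Deviation analysis

Signed point-to-surface distances are measured from the reconstruction
vertices to the scan surface (the scan is the reference; the direction
is switchable). The sign is the side of the target surface normal.
Region-wise RMSE is computed over the nine facial regions — forehead,
nose, upper lip, lower lip, chin, left/right paranasal, left/right
cheek — plus the whole non-background face; empty regions report NaN,
never zero. Landmark deviations between scan and registered
reconstruction are expressed in the anatomical frame as absolute
components Dx, Dy, Dz and the Euclidean norm D. Color maps use a
diverging blue–green–red scale clamped at ±3 mm by default, written as
PLY vertex colors.

## Soft-tissue measurements

Nineteen items: six angles (nasolabial Prn–Sn–Ls, facial convexity
Gl–Sn–Pg', total facial convexity Gl–Prn–Pg', outer-canthal–nasal,
nasal N'–Prn–Sn, nasofrontal Gl–N'–Prn) and thirteen linear items.
Sagittal items (lip protrusions, vermilion thicknesses, mentolabial
furrow, philtral depth) are absolute differences of frame-Z coordinates.
Widths, heights and lengths are Euclidean distances between their two
landmarks, matching calliper practice; because "horizontal/vertical
distance" is ambiguous wording in the clinical literature, axis-projected
variants sit behind a `projected` flag. Angles are computed in 3D (not
projected to the sagittal plane). Philtral depth needs a midline floor
point that standard landmark sets lack; a dedicated `PhiF` landmark is
introduced and the depth defined sagittally against the midpoint of the
crista philtri ridge. Missing landmarks flag only their own items.

## Morphable model

Shapes are flattened vertex vectors `s = s_mean + S x` with an
orthonormal basis `S` (3N × k). Landmark fitting alternates a
closed-form Kabsch pose with the ridge solution
`x = (B'B + λI)^-1 B' r` on the pose-normalized landmark residual,
where `B` is the basis restricted to the mapped landmark rows; pose is
rigid only (no scale), keeping the evaluation millimetre-true. The
reported landmark loss is the mean squared 3D landmark distance (mm²);
the depth loss is its share along the model's anterior axis. Defaults:
λ = 0, 50 alternations, 1e-6 mm tolerance. The alternation converges
linearly, so recovery tests that probe machine-precision agreement pass
a tighter tolerance (1e-12, 500 iterations) through the same config.

### Basis augmentation

The augmentation step generates variants of existing shapes — nose and
mouth region swaps from donor shapes (feather-blended linearly over a
2 mm boundary band, since no blend rule is standard), small random
rotations, random rigid+scale transforms, and midsagittal mirrors
(paired on the transverse grid chart, an exact involution). The
iterative construction then draws a random test subset, repeatedly
appends the worst-fitting test shape to the collection, and recomputes
the k-component PCA basis.

The fit error driving selection is a λ=0 projection after rigid
alignment. The rigid normalization of each test shape is computed once
per outer round and held fixed across inner iterations; the error is
then exactly the distance to the affine hull of the collection, which
grows as shapes are appended — so with a spanning basis
(k ≥ collection − 1) the max-error trace is non-increasing by
construction. Re-aligning at every evaluation against the evolving mean
sacrifices this guarantee, which is why the round-fixed normalization
was chosen. Alignment starts from the better of the identity pose and a
Kabsch fit to the mean, so exactly-representable shapes keep a zero
residual. A requested k exceeding the collection's capacity truncates
the basis with a warning, not an error.

## Statistics

* **ICC** — two-way random-effects absolute agreement from ANOVA mean
  squares: single measures (MSR − MSE) / (MSR + (k−1)MSE + k(MSC−MSE)/n)
  and the average-measures form, with F-based confidence intervals
  (Satterthwaite df for the rater term). Both flavors are reported;
  values are cross-checked against `pingouin` in the test suite.
* **Paired t** — from raw pairs or from a printed mean ± SD of
  differences (t = m/(s/√n), df = n−1); two-sided p throughout. Zero
  variance with nonzero mean flags an infinite t with p = 0; all-zero
  differences flag a degenerate p = 1.
* **Mean CI** — mean ± t((1+level)/2, n−1) · sd/√n.
* **Normality gate** — Shapiro–Wilk via SciPy, 3 ≤ n ≤ 5000.
* **Sample size** — smallest n ≥ 2 whose two-sided paired-t power
  (noncentral t, df = n−1, noncentrality d√n) reaches the target, by
  exact integer scan. For d = 0.8, power 0.95, α = 0.05 this gives
  n = 23 (power 0.9469 at 22, 0.9558 at 23).
* No multiple-testing correction by default; a Bonferroni option exists
  in the measurement comparison. Differences below 1e-9 (numerical
  precision) are never starred.

## Synthetic data

The generator replaces clinical scans, which are not publicly deposited.

* **Template** — a heightfield over an elliptical face chart: a smooth
  dome with Gaussian features (brow, nasal bridge and tip, lips,
  mentolabial furrow, chin, cheeks), sampled on a grid that always
  contains the midline and the tragion level, so the canonical
  template's anatomical frame is exactly the identity. Proportions are
  adult-range (face height N'–Gn' ≈ 114 mm, outercanthal width ≈ 93 mm).
  All 25 named landmarks are snapped to grid vertices, i.e. lie exactly
  on the surface. A seeded sub-millimetre asymmetry field (4 smooth
  bumps, ≤ 0.1 mm each) keeps faces from being perfectly symmetric.
* **Regions** — landmark-anchored boundaries: forehead above the nasion
  level (which also absorbs the periorbital band, so the nine labels
  partition the face), a nose box bounded by the alar width between the
  subnasale and nasion levels, paranasal strips between nose and cheek,
  lips split at the stomion midline and bounded near the cheilions, chin
  below the sublabial level, cheeks elsewhere; off-oval vertices are
  background.
* **Morphable basis** — sums of Gaussian radial displacement bumps
  (widths 8–25 mm, random directions), orthonormalized by QR with a
  deterministic sign convention.
* **Scan/reconstruction pairs** — the scan is a coefficient draw
  (σ = 10, giving millimetre-scale inter-subject variation); the
  reconstruction displaces each region along vertex normals by its
  amplitude with fixed anatomical signs (brow/chin outward, cheeks
  inward — the characteristic error pattern of template-based
  reconstructions) and a smooth ±15% magnitude modulation, adds
  Gaussian normal noise (default SD 0.2 mm, the accuracy class of
  structured-light scanners), and applies the ground-truth rigid
  transform. Landmarks ride on their vertices.
* **Cohort conditions** — 23 subjects by default, misalignments up to
  10°/10 mm, and a per-subject amplitude scale ~ N(1, 0.19). The
  amplitude pattern (forehead 1.6 … lower lip 2.4 mm) was calibrated
  once so the full pipeline — deformation, noise, misalignment and
  best-fit registration — yields a whole-face RMSE of about
  2.0 ± 0.4 mm across subjects; it is a fixed study condition, not a
  per-run tuning knob.

What the generator does *not* emulate: realistic anatomical shape
statistics (the basis is smooth noise, not population PCA), texture,
self-occlusion, scanner artefacts such as holes or flyaway vertices, and
hair/eye interference. Passing tests therefore demonstrate correctness
of the geometry, registration and statistics pipeline under controlled
conditions, not reconstruction quality on real patients.

## Numerical choices

* Kabsch uses an SVD with a determinant correction, guaranteeing a
  proper rotation; collinear configurations raise a degenerate-input
  error.
* ICP keeps ⌈0.9 n⌉ correspondences (minimum 3); the trace tolerance is
  1e-9 in monotonicity assertions to absorb rounding.
* PCA bases come from `numpy.linalg.svd` of the centered collection;
  QR sign conventions are fixed for reproducibility across LAPACK
  builds.
* Every generator and pipeline output is a pure function of
  (parameters, seed); output files carry a header with version, seed
  and a config hash (output paths excluded from the hash), and reruns
  are byte-identical.

## Problem sizes

Tests run the template at grid resolution 16 (1,617 vertices, 3,072
triangles) and cohorts of 5–8 pairs; these sizes were chosen because
every geometric property being tested (exactness, recovery, invariance,
monotonicity) is resolution-independent, and they keep the suite fast.
The pipeline defaults are resolution 24 and 23 pairs.

## Known limitations

* The region geometry is this package's own operationalization;
  published region atlases differ and would shift per-region RMSE.
* The deviation direction (reconstruction → scan) is a convention;
  the symmetric alternative is computable but not the default.
* Ridge fitting assumes a known landmark-to-vertex map; no automatic
  landmark detection is provided.
* ICC reporting takes an explicit subjects × raters matrix; it does not
  guess rater/occasion layouts.
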