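# Methods

This note records the models, conventions and numerical choices behind
emvolscore, including the points where the underlying procedures are
genuinely open to interpretation and a choice had to be made.

## Maps, grids and transforms

A density map is a 3D scalar grid with per-axis voxel spacing (Å), a
physical origin (the position of voxel (0,0,0)), and optional nominal
resolution metadata. Files are read and written through gemmi in the
MRC2014/CCP4 dialect: modes 0/1/2 are accepted on read (mode 2, float32,
on write), the `mapc/mapr/maps` axis permutation is normalized to one
internal x-fastest storage order, and the origin is taken from the ORIGIN
header words, falling back to `nstart · spacing` when those are zero.
Round trips are bit-exact for float32 data. The MRC header carries no
resolution field, so resolution is supplied by the caller (CLI flags).

Rigid transforms act on physical coordinates, `p → R p + t`, with `R`
proper orthogonal to 1e-6. A fit transform maps the probe map's
coordinates into the target map's frame.

**Interpolation** is trilinear everywhere (monotone, fast, exact on
linear fields); samples outside a map's extent read as 0, consistent with
the assumption that everything outside the contour is background.

**Low-pass filtering** uses a Fourier-space Gaussian whose total
attenuation reaches half amplitude at spatial frequency 1/resolution.
Filtering is defined as filtering *to* a resolution: since Gaussian
variances add, a map already at resolution `r₀` is blurred only by the
increment needed to reach the target `r₁ > r₀` (`σ ∝ r`, so
`σ_inc² = σ(r₁)² − σ(r₀)²`). This makes the operation exactly idempotent
and lets a map pair be brought to a common resolution by filtering the
finer map with the right incremental kernel. Sharpening is refused. The
zero-frequency component is untouched, so the mean density is preserved
to machine precision.

**Common grid.** Scores compare voxels one-to-one, so before scoring a
pose both maps are resampled onto one grid covering the union of their
physical extents (the probe's transformed by the candidate pose). The
default spacing is a quarter of the coarser of the two nominal
resolutions — the resolution the pair is low-pass filtered to — which
samples the band-limited signal comfortably above Nyquist.

## Contour selection

The primary estimate converts molecular weight to volume at 1.21 Å³/Da
(average protein partial specific volume ≈ 0.73 cm³/g) and places the
threshold so the enclosed voxel volume matches, ties broken toward
including more voxels (a conservative envelope). Sanity is judged against
the density histogram: the background peak is the mode of a
Sturges-binned histogram (the estimator is unspecified in the source
procedure; histogram mode is standard EM practice), and σ is the RMS
deviation of all densities about that peak. A level is sane when it lies
in `[peak, peak + 5σ]`. The cascade: a sane mass-based level wins unless
an author level exists and disagrees by more than 3σ (then the author
level is trusted — deposited weights are often incomplete); an insane
mass level falls back to a sane author level; failing both, the threshold
is `peak + 1.5σ`. The returned `ContourSpec` records which branch fired
so users can audit or override it.

## Density scores

CCC is the Pearson correlation over all common-grid voxels; SCCC
restricts sums and means to the overlap region (voxels above contour in
both maps); SMOC is the product moment about zero there. Degenerate
inputs (empty or constant regions) raise a distinguishable no-overlap
error; the ensemble machinery ranks such fits last rather than
propagating NaNs.

Mutual information uses equal-width binning over each map's min–max
range within the evaluated region, with the *same* bin count for both
maps: `k = ⌈log₂ n⌉ + 1` by the Sturges rule on the region's voxel count
(the ceiling convention makes a typical 80³-voxel region give exactly
k = 20; the floor reading would give 19). The top edge is inclusive.
Entropies are base-2 with `0·log 0 = 0`. LMI is computed over the overlap
region; NMI is global over all common-grid voxels, with no contour
masking (whether any background masking should apply globally is
unspecified; none is the simplest reproducible choice), and equals
`(H_X + H_Y)/H_XY ∈ [1, 2]`. Bin edges are recorded for audit.

## Surface scores

Definition T selects voxels within ±10% of σ around the contour level;
A selects in-contour voxels with at least one background voxel among
their 26 neighbours (grid boundaries count as background); M computes an
*exposure* value per in-contour voxel — the mean of the binary contour
mask over three orthogonal 21-voxel windows centred on it, a multiset of
3·21 − 2 = 61 samples with the centre counted once and out-of-grid
samples 0 — and keeps voxels with exposure < 0.3. The 1D-window form of
the mean filter is directional: flat faces of large solids score high
(≈ 51/61 ≈ 0.84 on a half-space face) while thin or pointy features
score low, so definition M isolates strongly exposed structure. The
window (21) suits maps of ≥ ~100 voxels per axis and features a few
voxels to ~2 windows wide; it is a parameter.

The Chamfer distance is directional by default (mean distance from each
*target* surface point to its nearest probe point, via a k-d tree),
matching the convention that the normal-vector score also evaluates at
target surface points only; a symmetrized mean is available as an
option. The GDT-weighted variant uses cutoffs `D(i) = i·d_max/k` with
`d_max = 30 Å`, `k = 30` and weights `(k−i+1)/(k(k+1)/2)` on the
cumulative fractions, so the weights sum to 1, a perfect match scores 1
and points beyond 30 Å contribute 0.

Normals are normalized central-difference density gradients at surface
voxels. The normal-vector score is the mean of `arccos(n̂₁·n̂₂)/π` over
the target's surface points, with the dot product clipped to [−1, 1];
points where either gradient vanishes carry no direction and are
excluded from the mean (rather than being assigned the worst angle),
with the exclusion count reported.

## Overlap and combined scores

OVR = |A ∩ B| / min(|A|, |B|) over in-contour voxel sets, so a contoured
region fully containing the other scores 1. Combined scores put OVR on a
local score's scale using robust ensemble statistics:
`scale = MAD(local)/MAD(OVR)`, `shift = median(local) − median(OVR)`,
`OVRnorm = OVR·scale + shift`, and the combined score is the per-fit mean
of the local score and OVRnorm. The shift is applied with the *unscaled*
OVR median, exactly as the defining formulas read; a median-aligned
variant (`shift = median(local) − scale·median(OVR)`) is available behind
a flag, default off, since the defining formulas are ambiguous on this
point. `MAD(OVRnorm) = MAD(local)` holds to machine precision either
way. Combined scores are ensemble-level by construction: they are
refused for a single isolated fit. Fits with no overlap are excluded
from the median/MAD statistics and assigned the minimum combined score
of the valid fits.

## Pose evaluation

The relative pose of a fit against the reference is `Δ = ref⁻¹ ∘ fit`;
`r` is the norm of Δ's translation (Å) and `θ` the rotation angle from
`arccos((trace − 1)/2)` with the argument clamped to [−1, 1].
`ALCPS = 2π·r·θ/360` (θ in degrees) is minimized over point-group
symmetry operators applied to the reference (`s ∘ ref`); Cn/Dn/T/O/I
groups come from scipy's rotation groups (z principal axis). Analyses
use log₁₀(ALCPS) with a floor of −2.0 (an exact zero maps to the floor).
A fit is labeled correct when its log₁₀(ALCPS) is at or below a
user-chosen threshold; useful thresholds are dataset-specific and are
never hard-coded.

For ROC evaluation, fits scoring strictly above a threshold are called
positive; the sweep runs over all observed values plus ±∞ so the curve
spans (0,0)–(1,1), and the trapezoidal AUC then equals the normalized
Mann–Whitney U statistic with half credit for ties (asserted as an exact
identity in the tests). Precision is reported at the maximum-accuracy
threshold, ties broken toward higher precision. Distance-like scores
(Chamfer, normal-vector) are negated internally before the sweep so
"greater = better" holds uniformly; tables always report raw values.

## Synthetic phantoms

Phantom maps are sums of anisotropic 3D Gaussians evaluated at voxel
centers — the same family an external GMM fitter would use to abstract a
real map — plus additive white Gaussian background noise, all
deterministic under a seed. The nominal resolution enters as an extra
isotropic blur on every blob with the same σ-per-resolution constant the
low-pass filter uses, so phantom resolution and filtering are mutually
consistent. Defaults (6 blobs with principal σ of 4–9 Å scattered over
the central half of a 48³ grid at 2 Å spacing, 8 Å resolution, noise
σ = 0.02 against blob amplitudes ≈ 1) emulate a mid-size complex at
intermediate resolution with mild background noise; grid sizes are kept
modest so the full ensemble pipeline runs in seconds.

Map pairs with partial compositional overlap share a chosen fraction of
blobs (the rest replaced by fresh ones); the second map is recentred on
its own grid, as a deposited map would be, and the recentring shift is
folded into the returned ground-truth transform. Pose ensembles draw a
near cluster (default 1 Å / 2° perturbations) and a far cluster
(default 30 Å / 90°) around the reference — translations isotropic
Gaussian, rotation axes uniform with half-normal angles, applied about a
caller-supplied pivot (the structure center), since a fitter's wrong
poses reorient the molecule rather than sweep it off the map. The two
clusters separate by more than one log₁₀(ALCPS) unit at the default
scales.

What the phantoms do *not* emulate: CTF effects, solvent flattening,
resolution anisotropy, correlated (non-white) noise, and realistic
macromolecular envelopes from atomic coordinates. Passing tests
demonstrate the scores' correctness and their relative behaviour under
controlled overlap and pose error, not their absolute performance on
experimental reconstructions.

## Numerical details and limitations

- Contoured thresholds are compared with `≥` throughout, so contour
  masks are closed sets; binning assigns each region's maximum to the
  top bin.
- MI is clipped at 0 to absorb negative round-off of order 1e-15.
- Mass-based contouring on a map whose requested volume exceeds the grid
  returns the map minimum with a warning flag.
- The Gaussian-count heuristic floors the expected segment count before
  clamping to [3, 240]; the iterative segmentation procedure it stands in
  for has no closed form, and floor is the declared deterministic
  substitute.
- `surface_M` can legitimately find no points (bulky solids have no
  exposure below 0.3); this raises an extraction error that the pipeline
  converts to a missing (worst-ranked) score for that fit.
- Scoring assumes both maps carry meaningful density above their
  contours; maps dominated by noise defeat the contour cascade's
  assumptions (the sigma fallback still returns a finite threshold).
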