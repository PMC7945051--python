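# Methods

## Coordinate and unit conventions

Volumes are `(z, y, x)` arrays of cubic voxels; `z` is the slice index and,
after reorientation, the along-spike axis. Indices are 0-based and a voxel
at index *i* sits at physical position *i* · voxel_size_um / 1000 mm (the
voxel-centre convention used consistently by the voxeliser, the region
properties and the trait formulas). The default voxel edge is 77 µm.
Intensities are 16-bit unsigned; 8-bit inputs are widened without rescaling
so absolute thresholds keep their meaning. Voxel size is never read from
TIFF tags (tag dialects are unreliable) — it is always supplied explicitly.

## Segmentation

The grain/background contrast of ripe spikes is strongly bimodal, so the
global threshold is Otsu's criterion computed on the **full**
observed-intensity histogram, not an 8-bit rebin. Between-class variance is
compared in exact integer arithmetic (it is proportional to
(s₀n₁ − s₁n₀)²/(n₀n₁) for integer counts n and intensity sums s), and ties
resolve to the smallest threshold. This makes the threshold exactly
reproducible and directly checkable against an exhaustive rational-number
search, which the test suite does.

Despeckling uses a binary median filter over a size³ cubic neighbourhood
(default 3) with edge-repeating reflection at borders. For binary input the
cubic median equals a majority vote, which is computed with three separable
box correlations; the equivalence is verified against a literal
sort-and-take-middle oracle.

Touching grains are split by a marker-based watershed: Euclidean distance
transform of the foreground, markers from the h-maxima of the distance map
(depth h = 1 voxel, suppressing discretisation ripples along a grain's
medial ridge), then flooding of the negated distance map restricted to the
mask. A component whose maxima are all shallower than h receives a single
marker at its deepest voxel, so the output labels always partition the
foreground exactly. Each connected component is processed inside its own
padded bounding box — identical to a whole-volume run, since flooding never
crosses component boundaries, but linear in occupied volume rather than
grid size. Component ids are assigned by each component's lexicographically
smallest (z, y, x) voxel, making the whole stage deterministic.

Components below `min_grain_volume_mm3` (default 5 mm³ — roughly a seventh
of a typical 35 mm³ grain, far above noise speckle) are discarded. The
connectivity default is 26 because grains are compact blobs.

## Spikelet clustering

Grains are nodes; an edge joins *i* and *j* iff their centroid distance is
≤ D₁ **and** their along-spike offset is ≤ D₂. Spikelets are the connected
components, sorted by mean z (ties: smaller minimum grain id) and indexed
1..S bottom-to-top. D₂ ≤ D₁ is enforced, as a larger axial bound could
never contribute a link. The axial-offset reading of "relative position"
is a design choice: the alternative (encoding the left/right rank
alternation) would need a rachis model, while the axial rule is the minimal
criterion that separates consecutive spikelets, and it recovers the true
partition on every phantom whose internode spacing exceeds D₂ plus the
within-spikelet spread.

Defaults D₁ = 6 mm, D₂ = 3 mm were fixed from the geometry the phantoms
emulate (internode ≈ 4.3–4.8 mm at spikelet densities 2.1–2.3 cm⁻¹;
within-spikelet grain pitch ≈ 3.8 mm): D₂ falls between the within-spikelet
z spread (≤ 0.6 mm) and the internode, D₁ above the grain pitch and below
the next-but-one spikelet distance. `sweep_clustering` exposes the count
surface over a (D₁, D₂) grid; the count is monotone non-increasing in both
thresholds (edges only accumulate), so a stable plateau identifies usable
settings for other architectures.

## Traits

Spike length is the z-centroid difference between the extreme grains —
axial rather than 3D Euclidean distance, which makes it robust to lateral
offsets of the extreme grains and consistent with a "height". Spikelet
density divides the spikelet count by length in cm. All aggregates
(mean × count = total; volume fractions summing to 1) are asserted at
construction. Group-comparison statistics (ANOVA and normality tests) are
deliberately out of scope; the CSV outputs are laid out for any stats
package. Validation reports squared Pearson correlations and mean signed
differences per trait.

## Reorientation and cropping

Multi-spike scans are separated by cropping vertical cylindrical columns
(voxels outside the circular cross-section zeroed; the result is the
bounding box of the cylinder–volume intersection). Tilted spikes are
realigned by rotating the first principal component of the above-threshold
voxel cloud onto +z about the cloud centroid, with nearest-neighbour
resampling so intensities and labels stay discrete, output grid padded to
contain the rotated input. The alignment contract is 0.5°; measured
residuals on 10–15° tilts are below 0.1°, and the foreground voxel count is
preserved to well within the 5% nearest-neighbour tolerance. Tilts below
0.1° are returned unresampled — at that scale resampling noise exceeds the
correction. At least 100 foreground voxels are required to define an axis.

## Phantom generator

The generator emulates the object the pipeline is built for: a vertical
rachis with `n_spikelets` nodes at a fixed internode (default 4.5 mm),
alternating +y/−y ranks, each node carrying 1–5 ellipsoidal grains (default
semi-axes 3.3 × 1.6 × 1.6 mm ⇒ 35.4 mm³; count drawn from {2: 0.25,
3: 0.5, 4: 0.25}) placed side by side across the rachis with a uniform
±0.3 mm z jitter. Defaults reproduce field-realistic trait values: ~19
spikelets, ~85 mm spikes, ~2.2 spikelets/cm, ~35 mm³ grains, ~3
grains/spikelet. A `touching_fraction` of adjacent within-spikelet pairs is
moved into 0.1 mm overlap (voxel-connected necks the watershed must cut);
an optional whole-spike tilt rotates centres and grain axes about y.
Foreground/background intensities default to 5000/500 with optional
additive Gaussian noise, clipped to the 16-bit range. At the default 5%
noise level the classes are ~10 σ apart, so noise stresses the filtering
stages rather than the threshold — matching the clean reconstructions the
pipeline is designed for, and *not* emulating CT ring or beam-hardening
artefacts, partial-volume blur, or awns/glumes/rachis tissue. Passing
phantom tests therefore demonstrates correctness of the geometry processing
chain, not robustness to scanner artefacts.

Voxelisation marks a voxel foreground iff its centre lies inside an
ellipsoid (no anti-aliasing); overlap voxels go to the grain with the
smaller normalised ellipsoid coordinate. The volume is auto-sized to the
spike's bounding box plus a margin, so out-of-bounds grains cannot occur.
Everything is drawn from one seeded generator (geometry first, then a
derived noise stream), giving bit-identical volumes for identical specs.
Because a single placement's voxel-count error oscillates with sub-voxel
grid alignment, the resolution-convergence check measures the mean absolute
volume error over a fixed grid of sub-voxel placements at each voxel size
(77 → 40 → 20 µm), which decreases strictly (≈ 3.6 × 10⁻⁴ → 1.3 × 10⁻⁴ →
5.3 × 10⁻⁵ relative).

The multi-spike holder arranges independently generated spikes on a ring in
one volume (blocks must not overlap), mirroring a nine-sample scan; each
slot records its centre so the cylindrical crop can be tested to recover
each spike's voxels exactly.

## Problem sizes and numerical choices

Tests and the acceptance script use 19-spikelet × 3-grain phantoms at the
native 77 µm for ground-truth recovery (≈ 1200 × 160 × 210 voxel grids,
~13 s per spike end-to-end) and half-resolution (154 µm) or shorter spikes
for unit-level checks. Ten clean and ten noisy seeds run in about three
minutes. Determinism is exercised end-to-end: two runs of the pipeline on
the same volume must produce byte-identical CSVs and label maps.

## Known limitations

- Anisotropic voxels, proprietary scanner formats, and tomographic
  reconstruction are out of scope; input is reconstructed grayscale TIFF.
- The clustering operates on centroids only; pathological spikes whose
  internode is smaller than the within-spikelet z spread cannot be resolved
  by any (D₁, D₂).
- Grain length/width/depth axes and rank (left/right) assignment are not
  computed.
- The watershed h parameter trades over- against under-segmentation; h = 1
  voxel is tuned for convex grains ≥ ~15 voxels across and will over-split
  strongly non-convex objects.
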