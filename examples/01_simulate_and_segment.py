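"""Generate a synthetic wheat spike and segment its grains.

Builds a 19-spikelet phantom at 77 um resolution with mild noise, runs the
grain segmentation (Otsu -> median filter -> watershed -> size filter) and
compares the recovered grain count and volumes against the generator truth.
"""

import numpy as np

from spikect import PhantomSpec, compute_grain_props, generate_spike, segment_grains

spec = PhantomSpec(n_spikelets=19, grains_per_spikelet=3, noise_sd=250.0, seed=1)
volume, truth = generate_spike(spec)
print(f"phantom volume: {volume.shape} voxels at {volume.voxel_size_um} um")

labels = segment_grains(volume)
grains = compute_grain_props(labels)

volumes = np.array([g.volume_mm3 for g in grains])
print(f"segmented grains: {labels.n_labels} (truth: {truth.n_grains})")
print(f"mean grain volume: {volumes.mean():.1f} mm^3 "
      f"(analytic ellipsoid: {truth.grains.analytic_volume_mm3.iloc[0]:.1f} mm^3)")
# The counts should match exactly and mean volume sit within a fraction of a
# percent of the 35.4 mm^3 ellipsoid: segmentation loses only boundary voxels.
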