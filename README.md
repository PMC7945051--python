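# spikect

Quantifying wheat spike architecture from X-ray micro-CT scans.

Wheat yield is largely set by the number and size of grains per spike, which
in turn decompose into spikelets (the rachis-borne units, each bearing
several grains) and grains per spikelet. Manual spikelet phenotyping is
destructive and slow; micro-CT imaging sees every grain in 3D but leaves
open how to recover the *spikelet* level of organisation. `spikect`
implements a complete CT image-analysis pipeline for ripe wheat spikes:

1. **Grain segmentation** — Otsu thresholding of the 16-bit volume, a 3D
   binary median filter (size 3) for despeckling, connected-component
   labelling, and a marker-based 3D watershed on the Euclidean distance
   transform (markers = h-maxima, h = 1 voxel) that splits touching grains,
   followed by a physical-volume small-object filter.
2. **Spikelet detection** — grains *i*, *j* are linked when their centroids
   satisfy ‖cᵢ − cⱼ‖ ≤ D₁ **and** |zᵢ − zⱼ| ≤ D₂ (z = along-spike axis);
   spikelets are the connected components of this graph, indexed 1..S from
   the bottom of the spike. Defaults D₁ = 6 mm, D₂ = 3 mm suit typical
   spikelet densities of ~2.1–2.3 cm⁻¹; `sweep_clustering` maps the
   stability plateau for other architectures.
3. **Morphometric traits** — grain count and volumes (from voxel counts ×
   voxel volume), spike length (z distance between top and bottom grain
   centroids), spikelet count and density (spikelets per cm), grains and
   volume per spikelet, per-spikelet bottom-to-top profiles, and Pearson-r²
   validation against manual counts.
4. **Synthetic phantoms** — a generator that voxelises parametric spikes
   (alternating-rank spikelets on a rachis, ellipsoidal grains, optional
   noise, tilt and grain–grain contact) with exact ground truth, so every
   stage of the pipeline is testable without a scanner.

Geometry helpers (cylindrical cropping of multi-spike scans, PCA-based
reorientation of tilted spikes to vertical) cover the preprocessing steps
between reconstruction and analysis.

## Worked example

```python
from spikect import (PhantomSpec, generate_spike, segment_grains,
                     compute_grain_props, cluster_spikelets, spike_report)

volume, truth = generate_spike(PhantomSpec(n_spikelets=19, seed=2))
grains = compute_grain_props(segment_grains(volume))
spikelets = cluster_spikelets(grains)
print(spike_report(grains, spikelets).to_dict())
```

prints

```
{'grain_count': 51, 'total_grain_volume_mm3': 1802.771,
 'mean_grain_volume_mm3': 35.348, 'spike_length_mm': 81.209,
 'spikelet_count': 19, 'spikelet_density_per_cm': 2.340,
 'mean_grains_per_spikelet': 2.684, 'mean_volume_per_spikelet_mm3': 94.883}
```

— 51 grains of ~35.3 mm³ each in 19 spikelets over an 81 mm spike
(2.34 spikelets/cm), matching the phantom's ground truth exactly at the
count level and to ~0.1% in volume. The `examples/` scripts walk through
each capability (segmentation, clustering and the D₁/D₂ sweep, trait
reports, cohort validation) with commentary on the printed numbers.

## Command line

```bash
spikect simulate --n-spikelets 19 --seed 1 --out phantom/
spikect run --input phantom/volume.tif --voxel-size-um 77 --out results/
```

`run` writes the grain and spikelet label maps (16-bit TIFF), the grain
table, spikelet assignments, spike traits and spikelet profile CSVs, and a
manifest that reproduces the run. `segment`, `cluster`, `traits` and
`validate` expose the individual stages.

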