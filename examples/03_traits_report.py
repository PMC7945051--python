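"""Full trait extraction on one phantom spike.

Runs segmentation + clustering and prints the whole-spike morphometric
report and the per-spikelet profile (bottom-to-top distribution of grain
number and volume), the same tables the pipeline writes as CSV.
"""

from spikect import (
    PhantomSpec,
    cluster_spikelets,
    compute_grain_props,
    generate_spike,
    segment_grains,
    spike_report,
    spikelet_profile,
)

spec = PhantomSpec(n_spikelets=19, seed=2)
volume, truth = generate_spike(spec)
grains = compute_grain_props(segment_grains(volume))
spikelets = cluster_spikelets(grains)

report = spike_report(grains, spikelets)
for key, value in report.to_dict().items():
    print(f"{key:32s} {value:10.3f}" if isinstance(value, float) else f"{key:32s} {value:10d}")
# spike_length_mm is the z distance between top and bottom grain centroids;
# spikelet_density_per_cm = spikelets / (length in cm), ~2.2 for this geometry.

profile = spikelet_profile(grains, spikelets)
print(profile.head(5).to_string(index=False))
# volume_fraction_of_spike sums to 1 over the whole spike.
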