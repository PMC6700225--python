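"""Vary Golgi architecture: number of cisternae and transit time.

Reproduces the two architecture experiments on the synthetic reference:
re-binning enzymes over 2..10 cisternae at constant totals and total transit
time, and scaling the transit time at fixed four cisternae.  Heterogeneity
(number of distinct structures among 10,000 glycans) falls with more
cisternae while the oligomannose fraction rises; very short transit times
collapse heterogeneity, and very long ones funnel glycans into fully
sialylated endpoint structures.
"""

from golgisim import make_reference_config, sweep_cisternae, sweep_transit_time

config = make_reference_config()

print("cisternal-number sweep (totals and transit time fixed):")
sw = sweep_cisternae(config, n_list=(2, 4, 6, 8, 10), n_replicates=3, seed=11)
print(f"{'cisternae':>10s} {'structures':>11s} {'oligomannose':>13s}")
for n, het, oligo in zip(sw.axis_values, sw.heterogeneity_mean, sw.oligomannose_fraction):
    print(f"{n:>10d} {het:>11.0f} {100 * oligo:>12.1f}%")

print("\ntransit-time sweep (four cisternae):")
st = sweep_transit_time(config, factors=(0.1, 0.5, 1.0, 2.5, 3.3), n_replicates=3, seed=12)
print(f"{'time':>6s} {'structures':>11s} {'oligomannose':>13s} {'Fuc1GlcNAc4Man3Gal2NeuAc2':>26s}")
for f, het, oligo, ab in zip(
    st.axis_values, st.heterogeneity_mean, st.oligomannose_fraction, st.bi_sia2_abundance
):
    print(f"{f:>5.1f}x {het:>11.0f} {100 * oligo:>12.1f}% {100 * ab:>25.1f}%")
print(
    "\nthe fully sialylated bi-antennary glycan is absent at 0.1x and "
    "enriched at 3.3x: slow transit drives pathways onto terminal sialylated nodes"
)
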