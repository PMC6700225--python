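"""Simulate the wild-type-like reference Golgi and summarize its glycan profile.

Builds the synthetic reference configuration (four cisternae, cis-to-trans
enzyme gradients, oligomannose-rich entry mixture), pushes 10,000 glycans
through it one at a time with the Gillespie simulator, and prints the
profile summary a glycomics experiment would report.
"""

from golgisim import (
    class_fractions,
    heterogeneity,
    make_reference_config,
    mgat2_fucosylated_fraction,
    simulate_profile,
)

config = make_reference_config()
profile, flux = simulate_profile(config)

cf = class_fractions(profile)
print(f"simulated {config.n_glycans} glycans -> {heterogeneity(profile)} distinct structures")
print("class fractions (should contain oligomannose, hybrid and complex):")
for cls, frac in cf.category.items():
    print(f"  {cls:13s} {100 * frac:5.1f}%")
print("antennarity of the pool (0 = oligomannose, 2 = bi-antennary, ...):")
for k, frac in cf.antennarity.items():
    print(f"  {k} antennae    {100 * frac:5.1f}%")

top = sorted(profile.by_composition().items(), key=lambda kv: -kv[1])[:5]
print("five most abundant compositions:")
for comp, a in top:
    print(f"  {comp:28s} {100 * a:5.1f}%")

print(
    f"fucosylated Mgat2 substrates: {100 * mgat2_fucosylated_fraction(flux):.1f}% "
    "(how often core fucose precedes the second antenna)"
)
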