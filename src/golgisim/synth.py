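"""Synthetic WT-like Golgi parameter sets and ground-truth fixtures.

No fitted mammalian parameter set ships with this package, so every stage
is exercised against a synthetic reference configuration that emulates the
qualitative organization of a wild-type mammalian Golgi: cis-to-trans
enzyme localization gradients (trimming early, branching and capping late),
an oligomannose-rich entry mixture, and effective rates balanced so the
steady profile contains oligomannose, hybrid and bi/tri-antennary complex
species at the same time.

Two deliberate regime choices shape the defaults (see docs/methods.md):

* GalT keeps a cis-side shoulder (second cisterna) in addition to its
  trans peak.  Galactosylation of the Mgat1 arm upstream of the branching
  cisterna permanently blocks Mgat4, which caps attainable branching
  independently of how far Mgat4/5 rates are raised — the saturation
  phenomenon probed by the tetra-antennary engineering experiment.
* Mgat4/5 totals are set so that a 10-fold increase pushes their exposure
  in the branching cisterna deep into saturation, while wild-type exposure
  stays well below it.

The overall rate magnitude is not hand-picked: a bisection on a global
scale factor tunes the exact-solver oligomannose fraction to a target
(default 25%), which fixes absolute rates given the relative structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import GlycanProfile, GolgiConfig, class_fractions, exact_profile, simulate_profile
from .rules import ENZYMES

# Relative cis->trans localization weights (fractions per cisterna) and
# relative total effective rates; absolute magnitude comes from bisection.
DEFAULT_WEIGHTS: dict[str, tuple[float, ...]] = {
    "ManI": (0.62, 0.26, 0.08, 0.04),
    "Mgat1": (0.55, 0.30, 0.10, 0.05),
    "ManII": (0.25, 0.65, 0.08, 0.02),
    "Mgat2": (0.20, 0.76, 0.025, 0.015),
    "Fut8": (0.10, 0.55, 0.30, 0.05),
    "Mgat4": (0.0002, 0.0002, 0.9986, 0.001),
    "Mgat5": (0.0002, 0.0002, 0.9986, 0.001),
    "GalT": (0.02, 0.44, 0.003, 0.537),
    "SiaT": (0.02, 0.08, 0.30, 0.60),
}

DEFAULT_TOTALS: dict[str, float] = {
    "ManI": 10.0,
    "Mgat1": 4.0,
    "ManII": 16.0,
    "Mgat2": 12.0,
    "Fut8": 5.0,
    "Mgat4": 1.0,
    "Mgat5": 1.0,
    "GalT": 2.5,
    "SiaT": 4.0,
}

DEFAULT_ENTRY_MIX = {"Man9GlcNAc2": 0.65, "Man8GlcNAc2": 0.25, "GlcMan9GlcNAc2": 0.10}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a WT-like reference configuration."""

    seed: int = 0
    n_cisternae: int = 4
    residence_time: float = 1.0  # per cisterna, arbitrary units
    weights: dict[str, tuple[float, ...]] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    totals: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TOTALS))
    entry_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ENTRY_MIX))
    target_oligomannose: float = 0.25
    oligomannose_range: tuple[float, float] = (0.1, 0.5)
    n_glycans: int = 10000
    noise: float = 0.0


class TuningError(RuntimeError):
    pass


def _config_at_scale(spec: SyntheticSpec, scale: float) -> GolgiConfig:
    rates = {
        e: tuple(scale * spec.totals[e] * w for w in spec.weights[e]) for e in ENZYMES
    }
    return GolgiConfig(
        n_cisternae=spec.n_cisternae,
        residence_times=(spec.residence_time,) * spec.n_cisternae,
        rates=rates,
        entry_mix=dict(spec.entry_mix),
        n_glycans=spec.n_glycans,
        seed=spec.seed,
    )


def make_reference_config(spec: SyntheticSpec | None = None) -> GolgiConfig:
    """Build the WT-like reference, bisecting a global rate scale.

    The oligomannose fraction of the exact profile decreases monotonically
    with the scale; bisection pins it to ``spec.target_oligomannose``.  The
    result is deterministic for a given spec.
    """
    spec = spec if spec is not None else SyntheticSpec()

    def oligo(scale: float) -> float:
        return class_fractions(exact_profile(_config_at_scale(spec, scale))).category[
            "oligomannose"
        ]

    lo, hi = 0.02, 20.0
    if not (oligo(lo) > spec.target_oligomannose > oligo(hi)):
        raise TuningError("oligomannose target outside achievable range")
    for _ in range(40):
        mid = (lo * hi) ** 0.5
        if oligo(mid) > spec.target_oligomannose:
            lo = mid
        else:
            hi = mid
    config = _config_at_scale(spec, (lo * hi) ** 0.5)

    frac = class_fractions(exact_profile(config))
    o = frac.category["oligomannose"]
    if not spec.oligomannose_range[0] <= o <= spec.oligomannose_range[1]:
        raise TuningError(f"tuned oligomannose fraction {o:.3f} outside range")
    if frac.antennarity[2] <= 0 or frac.antennarity[3] <= 0:
        raise TuningError("reference profile lacks bi- or tri-antennary species")
    return config


def make_pseudo_observed(
    config: GolgiConfig, n: int | None = None, seed: int = 0, noise: float = 0.0
) -> GlycanProfile:
    """Sampled profile used as the 'observed' target in recovery tests.

    Optional Dirichlet resampling emulates measurement noise on relative
    abundances: with ``noise > 0`` the abundances are redrawn from
    ``Dirichlet(a_i / noise)``, so larger values mean noisier profiles.
    """
    run_config = GolgiConfig(
        n_cisternae=config.n_cisternae,
        residence_times=config.residence_times,
        rates=config.rates,
        entry_mix=config.entry_mix,
        n_glycans=config.n_glycans if n is None else n,
        seed=seed,
    )
    profile, _ = simulate_profile(run_config)
    if noise <= 0:
        return profile
    rng = np.random.Generator(np.random.Philox(key=[seed, 2**32]))
    codes = sorted(profile.abundance)
    alpha = np.array([profile.abundance[c] for c in codes]) / noise
    drawn = rng.dirichlet(alpha)
    abundance = {c: float(a) for c, a in zip(codes, drawn) if a > 0}
    total = sum(abundance.values())
    return GlycanProfile(
        abundance={c: a / total for c, a in abundance.items()}, n_sampled=profile.n_sampled
    )


def planted_perturbation(
    config: GolgiConfig, enzyme: str, fold_change: float = 1.0, cisterna_shift: int = 0
) -> GolgiConfig:
    """Reference config with a documented change to one enzyme.

    ``fold_change`` multiplies the enzyme's total effective rate;
    ``cisterna_shift`` moves its localization fractions trans-ward by whole
    cisternae (mass pushed past the last cisterna piles up there), with the
    total preserved.  Ground truth for parameter-recovery assertions.
    """
    if enzyme not in ENZYMES:
        raise ValueError(f"unknown enzyme {enzyme!r}")
    if fold_change < 0:
        raise ValueError("fold_change must be non-negative")
    n = config.n_cisternae
    row = np.array(config.rates[enzyme], dtype=float)
    total = row.sum()
    if total > 0:
        frac = row / total
    else:
        frac = np.full(n, 1.0 / n)
    shifted = np.zeros(n)
    for c, f in enumerate(frac):
        shifted[min(max(c + cisterna_shift, 0), n - 1)] += f
    new_row = tuple(float(x) for x in fold_change * total * shifted)
    rates = dict(config.rates)
    rates[enzyme] = new_row
    return config.with_rates(rates)


def make_random_config(
    seed: int,
    n_cisternae_range: tuple[int, int] = (2, 6),
    n_glycans: int = 10000,
) -> GolgiConfig:
    """A random valid configuration, for oracle-equivalence property tests.

    Rates are log-normal around magnitudes that keep event counts moderate;
    localizations, residence times and the entry mixture are all randomized.
    """
    rng = np.random.Generator(np.random.Philox(key=[seed, 1]))
    n = int(rng.integers(n_cisternae_range[0], n_cisternae_range[1] + 1))
    rates = {}
    for e in ENZYMES:
        base = DEFAULT_TOTALS[e] * float(rng.lognormal(-0.3, 0.7))
        w = rng.dirichlet(np.ones(n))
        rates[e] = tuple(float(base * x) for x in w)
    times = rng.uniform(0.5, 1.5, size=n)
    times = tuple(float(t) for t in times * (4.0 / times.sum()))
    mix = rng.dirichlet(np.array([6.5, 2.5, 1.0]))
    entry = {
        "Man9GlcNAc2": float(mix[0]),
        "Man8GlcNAc2": float(mix[1]),
        "GlcMan9GlcNAc2": float(mix[2]),
    }
    entry["Man9GlcNAc2"] += 1.0 - sum(entry.values())
    return GolgiConfig(
        n_cisternae=n,
        residence_times=times,
        rates=rates,
        entry_mix=entry,
        n_glycans=n_glycans,
        seed=seed,
    )
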