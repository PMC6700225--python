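"""In-silico experiments: architecture sweeps, target maximization, and
tetra-antennary engineering.

These are thin, reproducible pipeline stages over the simulation engine and
the ABC fitter.  All replicate seeds are derived deterministically from the
experiment seed, so every stage is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import (
    FluxRecord,
    GlycanProfile,
    GolgiConfig,
    class_fractions,
    exact_profile,
    heterogeneity,
    simulate_profile,
)
from .fitting import (
    AbcResult,
    PriorSpec,
    abc_smc,
    make_target_profile,
    rate_change_report,
)
from .glycans import Antenna, GlycanState, classify, composition
from .rules import ENZYMES

BI_SIA2_COMPOSITION = "Fuc1GlcNAc4Man3Gal2NeuAc2"

# Hypothetical engineering targets: fucosylated complex glycans with two or
# three antennae and partial or complete sialylation.  The third antenna of
# tri-Sia1 is Mgat5-derived and the single sialic acid sits on the Mgat1 arm;
# reported abundances aggregate over placement isomers of the same
# composition, so this choice only fixes which structure seeds the target.
TARGET_GLYCANS: dict[str, GlycanState] = {
    "bi-Sia1": GlycanState(man=3, armA=Antenna.SIA, armB=Antenna.GAL, fuc=1),
    "bi-Sia2": GlycanState(man=3, armA=Antenna.SIA, armB=Antenna.SIA, fuc=1),
    "tri-Sia1": GlycanState(
        man=3, armA=Antenna.SIA, armB=Antenna.GAL, arm6=Antenna.GAL, fuc=1
    ),
}


def _replicate_seed(seed: int, axis_index: int, replicate: int) -> int:
    return (seed * 1000003 + axis_index * 101 + replicate) % (2**31 - 1)


def redistribute_cisternae(config: GolgiConfig, new_n: int) -> GolgiConfig:
    """Re-bin per-enzyme rates onto ``new_n`` cisternae.

    Each enzyme's per-cisterna rates are treated as a piecewise-constant
    density on [0, 1], averaged over the new equal bins, then rescaled so the
    per-enzyme total is conserved exactly.  Total transit time is preserved
    and split equally.
    """
    if new_n < 1:
        raise ValueError("new_n must be >= 1")
    old_n = config.n_cisternae
    # overlap[i, j] = fraction of old bin i lying inside new bin j
    overlap = np.zeros((old_n, new_n))
    for i in range(old_n):
        a, b = i / old_n, (i + 1) / old_n
        for j in range(new_n):
            c, d = j / new_n, (j + 1) / new_n
            overlap[i, j] = max(0.0, min(b, d) - max(a, c)) * old_n
    rates = {}
    for e in ENZYMES:
        old = np.array(config.rates[e])
        new = old @ overlap
        total_old = old.sum()
        if new.sum() > 0:
            new *= total_old / new.sum()
        rates[e] = tuple(float(r) for r in new)
    total_time = config.total_time()
    return GolgiConfig(
        n_cisternae=new_n,
        residence_times=(total_time / new_n,) * new_n,
        rates=rates,
        entry_mix=config.entry_mix,
        n_glycans=config.n_glycans,
        seed=config.seed,
    )


@dataclass
class SweepResult:
    """Per-axis-value readouts of an architecture or transit-time sweep."""

    axis_name: str
    axis_values: list
    heterogeneity_mean: list[float] = field(default_factory=list)
    heterogeneity_sd: list[float] = field(default_factory=list)
    oligomannose_fraction: list[float] = field(default_factory=list)
    top_complex: list[list[tuple[str, float]]] = field(default_factory=list)
    bi_sia2_abundance: list[float] = field(default_factory=list)
    n_replicates: int = 3
    profiles: list[list[GlycanProfile]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        data = {
            self.axis_name: self.axis_values,
            "heterogeneity_mean": self.heterogeneity_mean,
            "heterogeneity_sd": self.heterogeneity_sd,
            "oligomannose_fraction": self.oligomannose_fraction,
            "top_complex": ["; ".join(f"{c}={a:.4f}" for c, a in t) for t in self.top_complex],
        }
        if self.bi_sia2_abundance:
            data["bi_sia2_abundance"] = self.bi_sia2_abundance
        return pd.DataFrame(data)


def _complex_composition_abundance(profile: GlycanProfile) -> dict[str, float]:
    out: dict[str, float] = {}
    for code, a in profile.abundance.items():
        state = GlycanState.from_code(code)
        if classify(state).category == "complex":
            comp = composition(state)
            out[comp] = out.get(comp, 0.0) + a
    return out


def _run_replicates(
    config: GolgiConfig, axis_index: int, n_replicates: int, seed: int
) -> list[GlycanProfile]:
    profiles = []
    for r in range(n_replicates):
        cfg = GolgiConfig(
            n_cisternae=config.n_cisternae,
            residence_times=config.residence_times,
            rates=config.rates,
            entry_mix=config.entry_mix,
            n_glycans=config.n_glycans,
            seed=_replicate_seed(seed, axis_index, r),
        )
        profile, _ = simulate_profile(cfg)
        profiles.append(profile)
    return profiles


def _summarize(result: SweepResult, profiles: list[GlycanProfile], track_bi_sia2: bool):
    het = [heterogeneity(p) for p in profiles]
    result.heterogeneity_mean.append(float(np.mean(het)))
    result.heterogeneity_sd.append(float(np.std(het, ddof=1)) if len(het) > 1 else 0.0)
    result.oligomannose_fraction.append(
        float(np.mean([class_fractions(p).category["oligomannose"] for p in profiles]))
    )
    comp_sum: dict[str, float] = {}
    for p in profiles:
        for c, a in _complex_composition_abundance(p).items():
            comp_sum[c] = comp_sum.get(c, 0.0) + a / len(profiles)
    top3 = sorted(comp_sum.items(), key=lambda kv: (-kv[1], kv[0]))[:3]
    result.top_complex.append(top3)
    if track_bi_sia2:
        result.bi_sia2_abundance.append(
            float(np.mean([p.by_composition().get(BI_SIA2_COMPOSITION, 0.0) for p in profiles]))
        )
    result.profiles.append(profiles)


def sweep_cisternae(
    config: GolgiConfig,
    n_list: tuple[int, ...] = tuple(range(1, 11)),
    n_replicates: int = 3,
    seed: int = 0,
) -> SweepResult:
    """Vary the number of cisternae at constant per-enzyme totals and total
    transit time, recording heterogeneity, oligomannose fraction and the top
    complex glycans."""
    result = SweepResult(axis_name="n_cisternae", axis_values=list(n_list), n_replicates=n_replicates)
    for i, n in enumerate(n_list):
        cfg = redistribute_cisternae(config, n)
        profiles = _run_replicates(cfg, i, n_replicates, seed)
        _summarize(result, profiles, track_bi_sia2=False)
    return result


def sweep_transit_time(
    config: GolgiConfig,
    factors: tuple[float, ...] = (0.1, 0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.3),
    n_replicates: int = 3,
    seed: int = 0,
) -> SweepResult:
    """Scale all residence times by each factor at fixed cisternal number,
    additionally tracking the fully sialylated bi-antennary glycan."""
    result = SweepResult(axis_name="time_factor", axis_values=list(factors), n_replicates=n_replicates)
    for i, f in enumerate(factors):
        cfg = GolgiConfig(
            n_cisternae=config.n_cisternae,
            residence_times=tuple(t * f for t in config.residence_times),
            rates=config.rates,
            entry_mix=config.entry_mix,
            n_glycans=config.n_glycans,
            seed=config.seed,
        )
        profiles = _run_replicates(cfg, i, n_replicates, seed)
        _summarize(result, profiles, track_bi_sia2=True)
    return result


@dataclass
class MaximizationResult:
    """Outcome of ABC-driven maximization of one target glycan."""

    target_name: str
    mode: str
    abc: AbcResult
    best_profile: GlycanProfile
    achieved_fraction: float  # target composition abundance / complex fraction
    achieved_abundance: float  # target composition abundance of total
    by_products: list[tuple[str, float]]  # top complex by-products (composition)
    oligomannose_pool: float
    rate_changes: pd.DataFrame


def maximize_target(
    target_name: str,
    mode: str,
    config: GolgiConfig,
    n_particles: int = 100,
    max_generations: int = 14,
    seed: int = 0,
    evaluator: str = "exact",
) -> MaximizationResult:
    """Fit rates/localization/transit/entry so the profile approaches a
    hypothetical profile in which the target is 100% of non-oligomannose
    glycans (oligomannose kept at its reference level)."""
    if target_name not in TARGET_GLYCANS:
        raise ValueError(f"unknown target {target_name!r}; options: {sorted(TARGET_GLYCANS)}")
    target_state = TARGET_GLYCANS[target_name]
    wt_profile = exact_profile(config)
    target_profile = make_target_profile(target_state, wt_profile)
    priors = PriorSpec(reference=config, mode=mode)
    abc = abc_smc(
        target_profile,
        priors,
        mode=mode,
        n_particles=n_particles,
        max_generations=max_generations,
        seed=seed,
        evaluator=evaluator,
    )
    best = abc.best_particle()
    best_profile = exact_profile(abc.particle_config(best))
    target_comp = composition(target_state)
    comp_ab = best_profile.by_composition()
    achieved_abundance = comp_ab.get(target_comp, 0.0)
    complex_fraction = class_fractions(best_profile).category["complex"]
    achieved = achieved_abundance / complex_fraction if complex_fraction > 0 else 0.0
    by_products = sorted(
        (
            (c, a)
            for c, a in _complex_composition_abundance(best_profile).items()
            if c != target_comp
        ),
        key=lambda kv: (-kv[1], kv[0]),
    )[:3]
    oligo = class_fractions(best_profile).category["oligomannose"]
    return MaximizationResult(
        target_name=target_name,
        mode=mode,
        abc=abc,
        best_profile=best_profile,
        achieved_fraction=achieved,
        achieved_abundance=achieved_abundance,
        by_products=by_products,
        oligomannose_pool=oligo,
        rate_changes=rate_change_report(abc, config),
    )


# Engineered localization: branching enzymes separated from GalT.
SEPARATED_LOCALIZATION = {
    "Mgat2": (0.0, 1.0, 0.0, 0.0),
    "Mgat4": (0.0, 0.0, 1.0, 0.0),
    "Mgat5": (0.0, 0.0, 1.0, 0.0),
    "GalT": (0.0, 0.0, 0.0, 1.0),
}

TETRA_SCENARIOS = ("wt", "mgat45_x10", "mgat45_x100", "separated", "separated_x10")


def apply_tetra_scenario(config: GolgiConfig, scenario: str) -> GolgiConfig:
    """Return the configuration for one tetra-antennary engineering scenario.

    Fold changes multiply the Mgat4/Mgat5 totals with their cisternal
    distribution preserved; 'separated' condenses Mgat2, Mgat4/5 and GalT
    into single distinct cisternae with totals unchanged.
    """
    if scenario not in TETRA_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; options: {TETRA_SCENARIOS}")
    rates = dict(config.rates)
    if scenario in ("separated", "separated_x10"):
        if config.n_cisternae != 4:
            raise ValueError("the separated localization is defined for 4 cisternae")
        for e, frac in SEPARATED_LOCALIZATION.items():
            total = sum(rates[e])
            rates[e] = tuple(total * f for f in frac)
    fold = {"mgat45_x10": 10.0, "mgat45_x100": 100.0, "separated_x10": 10.0}.get(scenario)
    if fold is not None:
        for e in ("Mgat4", "Mgat5"):
            rates[e] = tuple(r * fold for r in rates[e])
    return config.with_rates(rates)


@dataclass
class TetraResult:
    scenario: str
    tetra_fraction: float
    tri_fraction: float
    tetra_sd: float
    flux_competition: pd.DataFrame  # Mgat4 vs ManII/Mgat2 events per cisterna


def engineer_tetra(
    config: GolgiConfig,
    scenario: str,
    n_replicates: int = 3,
    seed: int = 0,
) -> TetraResult:
    """Simulate one engineering scenario, averaging class fractions over
    replicates and reporting the branching-vs-processing flux per cisterna."""
    cfg = apply_tetra_scenario(config, scenario)
    tetra, tri = [], []
    flux_rows: dict[tuple[str, int], int] = {}
    for r in range(n_replicates):
        run = GolgiConfig(
            n_cisternae=cfg.n_cisternae,
            residence_times=cfg.residence_times,
            rates=cfg.rates,
            entry_mix=cfg.entry_mix,
            n_glycans=cfg.n_glycans,
            seed=_replicate_seed(seed, TETRA_SCENARIOS.index(scenario), r),
        )
        profile, flux = simulate_profile(run)
        cf = class_fractions(profile)
        tetra.append(cf.antennarity[4])
        tri.append(cf.antennarity[3])
        for (enzyme, _sub, cist), k in flux.counts.items():
            if enzyme in ("Mgat4", "ManII", "Mgat2"):
                flux_rows[(enzyme, cist)] = flux_rows.get((enzyme, cist), 0) + k
    flux_df = pd.DataFrame(
        [
            {"enzyme": e, "cisterna": c, "events": k / n_replicates}
            for (e, c), k in sorted(flux_rows.items())
        ]
    )
    return TetraResult(
        scenario=scenario,
        tetra_fraction=float(np.mean(tetra)),
        tri_fraction=float(np.mean(tri)),
        tetra_sd=float(np.std(tetra, ddof=1)) if n_replicates > 1 else 0.0,
        flux_competition=flux_df,
    )
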