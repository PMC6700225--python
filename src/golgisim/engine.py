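"""Stochastic and exact simulation of glycan maturation through the Golgi.

Each glycan traverses the cisternae one at a time (no substrate
competition).  Within cisterna ``c`` the glycan undergoes a continuous-time
Markov jump process whose transition rates are the per-enzyme effective
rates ``rates[enzyme][c]`` times the site multiplicity of the applicable
rule; after ``residence_times[c]`` time units it moves on unchanged-state
to the next cisterna.  An event whose sampled waiting time would straddle
the cisternal boundary is discarded.

Because one molecule is simulated at a time, the whole process is a
single-particle CTMC over the enumerated reaction network, so the sampled
profile (:func:`simulate_profile`) can be validated against the exact
matrix-exponential propagation (:func:`exact_profile`).  Only rate x time
products matter: scaling all rates by ``c`` and dividing all residence
times by ``c`` leaves the exact profile unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import expm_multiply

from .glycans import ENTRY_GLYCANS, GlycanState, classify
from .network import CompiledNetwork, compile_network
from .rules import ENZYMES

Event = tuple[str, str, int]  # (enzyme, substrate state code, cisterna index)


@dataclass(frozen=True)
class GolgiConfig:
    """Cisternal architecture, effective enzymatic rates and entry mixture.

    ``rates`` maps each enzyme to a length-``n_cisternae`` array of effective
    rates (per arbitrary time unit); ``residence_times`` holds the time a
    glycan spends in each cisterna.  ``entry_mix`` gives the proportions of
    the ER-derived entry species.
    """

    n_cisternae: int
    residence_times: tuple[float, ...]
    rates: dict[str, tuple[float, ...]]
    entry_mix: dict[str, float]
    n_glycans: int = 10000
    seed: int = 0

    def __post_init__(self):
        if self.n_cisternae < 1:
            raise ValueError("n_cisternae must be >= 1")
        object.__setattr__(self, "residence_times", tuple(float(t) for t in self.residence_times))
        if len(self.residence_times) != self.n_cisternae:
            raise ValueError("residence_times length must equal n_cisternae")
        if any(t <= 0 for t in self.residence_times):
            raise ValueError("residence times must be positive")
        object.__setattr__(
            self, "rates", {e: tuple(float(r) for r in v) for e, v in self.rates.items()}
        )
        for enzyme, row in self.rates.items():
            if enzyme not in ENZYMES:
                raise ValueError(f"unknown enzyme in rates: {enzyme!r}")
            if len(row) != self.n_cisternae:
                raise ValueError(f"rates[{enzyme}] must have length {self.n_cisternae}")
            if any(r < 0 for r in row):
                raise ValueError(f"rates[{enzyme}] must be non-negative")
        for enzyme in ENZYMES:
            if enzyme not in self.rates:
                raise ValueError(f"missing rates for enzyme {enzyme}")
        object.__setattr__(
            self, "entry_mix", {k: float(v) for k, v in self.entry_mix.items()}
        )
        for name, p in self.entry_mix.items():
            if name not in ENTRY_GLYCANS:
                raise ValueError(f"unknown entry glycan {name!r}")
            if p < 0:
                raise ValueError("entry proportions must be non-negative")
        if abs(sum(self.entry_mix.values()) - 1.0) > 1e-9:
            raise ValueError("entry_mix must sum to 1")
        if self.n_glycans < 1:
            raise ValueError("n_glycans must be >= 1")

    def rate_matrix(self, enzymes: tuple[str, ...] = ENZYMES) -> np.ndarray:
        return np.array([self.rates[e] for e in enzymes], dtype=float)

    def total_rate(self, enzyme: str) -> float:
        return float(sum(self.rates[enzyme]))

    def total_time(self) -> float:
        return float(sum(self.residence_times))

    def with_rates(self, rates: dict[str, tuple[float, ...]]) -> "GolgiConfig":
        return GolgiConfig(
            n_cisternae=self.n_cisternae,
            residence_times=self.residence_times,
            rates=rates,
            entry_mix=self.entry_mix,
            n_glycans=self.n_glycans,
            seed=self.seed,
        )


@dataclass(frozen=True)
class GlycanProfile:
    """Normalized relative-abundance distribution over glycan state codes."""

    abundance: dict[str, float]
    n_sampled: int | None = None
    counts: dict[str, int] | None = None

    def __post_init__(self):
        if any(a < 0 for a in self.abundance.values()):
            raise ValueError("abundances must be non-negative")
        total = sum(self.abundance.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {total})")
        for code in self.abundance:
            GlycanState.from_code(code)  # raises on malformed keys

    def support(self) -> set[str]:
        return {c for c, a in self.abundance.items() if a > 0}

    def get(self, code: str) -> float:
        return self.abundance.get(code, 0.0)

    def by_composition(self) -> dict[str, float]:
        """Abundance aggregated over structural isomers of each composition."""
        from .glycans import composition

        out: dict[str, float] = {}
        for code, a in self.abundance.items():
            comp = composition(GlycanState.from_code(code))
            out[comp] = out.get(comp, 0.0) + a
        return out


@dataclass
class FluxRecord:
    """Event counts per (enzyme, substrate state code, cisterna index).

    ``entry_counts`` and ``final_counts`` make the per-species conservation
    identity checkable: entry + inflow - outflow = final, exactly, for every
    state.
    """

    counts: dict[tuple[str, str, int], int] = field(default_factory=dict)
    entry_counts: dict[str, int] = field(default_factory=dict)
    final_counts: dict[str, int] = field(default_factory=dict)
    transitions: dict[tuple[str, str], int] = field(default_factory=dict)

    def add_event(self, enzyme: str, substrate_code: str, cisterna: int) -> None:
        key = (enzyme, substrate_code, cisterna)
        self.counts[key] = self.counts.get(key, 0) + 1

    def add_transition(self, substrate_code: str, product_code: str) -> None:
        key = (substrate_code, product_code)
        self.transitions[key] = self.transitions.get(key, 0) + 1

    def enzyme_total(self, enzyme: str) -> int:
        return sum(n for (e, _, _), n in self.counts.items() if e == enzyme)


def _entry_state(name: str) -> GlycanState:
    return ENTRY_GLYCANS[name]


def glycan_rng(seed: int, index: int) -> np.random.Generator:
    """Counter-based RNG stream for glycan ``index``: reproducible under any
    execution order."""
    return np.random.Generator(np.random.Philox(key=[seed & 0xFFFFFFFFFFFFFFFF, index]))


def simulate_glycan(
    config: GolgiConfig,
    entry: GlycanState,
    rng: np.random.Generator,
    network: CompiledNetwork | None = None,
) -> tuple[GlycanState, list[Event]]:
    """Gillespie trajectory of one glycan through all cisternae.

    Returns the exiting state and the ordered event list.  A glycan whose
    total propensity is zero idles until the cisterna ends.
    """
    net = network if network is not None else compile_network()
    rate_matrix = config.rate_matrix(net.enzymes)
    idx = net.index[entry.code()]
    events: list[Event] = []
    exp = rng.exponential
    uni = rng.random
    for c in range(config.n_cisternae):
        remaining = config.residence_times[c]
        rates_c = rate_matrix[:, c]
        while True:
            edges = net.out_edges[idx]
            if not edges:
                break
            total = 0.0
            for ei, _ in edges:
                total += rates_c[ei]
            if total <= 0.0:
                break
            remaining -= exp() / total
            if remaining <= 0.0:
                break  # straddling event discarded; glycan exits
            u = uni() * total
            acc = 0.0
            for ei, pi in edges:
                acc += rates_c[ei]
                if u <= acc:
                    events.append((net.enzymes[ei], net.codes[idx], c))
                    idx = pi
                    break
    return net.states[idx], events


def simulate_profile(
    config: GolgiConfig,
    network: CompiledNetwork | None = None,
) -> tuple[GlycanProfile, FluxRecord]:
    """Simulate ``config.n_glycans`` independent glycans and aggregate.

    Entry species are drawn from ``entry_mix``; each glycan uses its own
    counter-based RNG stream keyed on ``(seed, glycan index)``, so the output
    is bit-reproducible for a given seed.
    """
    net = network if network is not None else compile_network()
    entry_names = sorted(config.entry_mix)
    entry_probs = np.array([config.entry_mix[n] for n in entry_names])
    entry_probs = entry_probs / entry_probs.sum()
    entry_states = [_entry_state(n) for n in entry_names]

    flux = FluxRecord()
    final_counts: dict[str, int] = {}
    for i in range(config.n_glycans):
        rng = glycan_rng(config.seed, i)
        which = int(rng.choice(len(entry_names), p=entry_probs))
        entry = entry_states[which]
        ecode = entry.code()
        flux.entry_counts[ecode] = flux.entry_counts.get(ecode, 0) + 1
        final, events = simulate_glycan(config, entry, rng, net)
        fcode = final.code()
        # the product of event j is the substrate of event j+1 within one
        # glycan's chain; the last product is the exit state
        for j, (enzyme, sub, cist) in enumerate(events):
            flux.add_event(enzyme, sub, cist)
            product = events[j + 1][1] if j + 1 < len(events) else fcode
            flux.add_transition(sub, product)
        final_counts[fcode] = final_counts.get(fcode, 0) + 1
    flux.final_counts = dict(final_counts)
    n = config.n_glycans
    profile = GlycanProfile(
        abundance={c: k / n for c, k in final_counts.items()},
        n_sampled=n,
        counts=final_counts,
    )
    return profile, flux


MAX_EXACT_STATES = 20000


def exact_profile(
    config: GolgiConfig,
    network: CompiledNetwork | None = None,
) -> GlycanProfile:
    """Exact exit-state distribution by matrix-exponential CTMC propagation.

    Builds the per-cisterna generator ``Q_c`` over the enumerated network
    (off-diagonal entry = effective rate x site multiplicity) and propagates
    the entry distribution: ``p_out = p_in . prod_c exp(Q_c t_c)``.
    """
    net = network if network is not None else compile_network()
    if net.n_states > MAX_EXACT_STATES:
        raise ValueError(f"state space too large for exact solve ({net.n_states})")
    n = net.n_states
    rate_matrix = config.rate_matrix(net.enzymes)

    src, dst, enz = [], [], []
    for i, edges in enumerate(net.out_edges):
        for ei, pi in edges:
            src.append(i)
            dst.append(pi)
            enz.append(ei)
    src = np.array(src, dtype=np.int64)
    dst = np.array(dst, dtype=np.int64)
    enz = np.array(enz, dtype=np.int64)

    p = np.zeros(n)
    for name, frac in config.entry_mix.items():
        p[net.index[_entry_state(name).code()]] += frac

    for c in range(config.n_cisternae):
        w = rate_matrix[enz, c]
        keep = w > 0
        if not keep.any():
            continue
        rows = np.concatenate([src[keep], src[keep]])
        cols = np.concatenate([dst[keep], src[keep]])
        vals = np.concatenate([w[keep], -w[keep]])
        q = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        p = expm_multiply(q.T.tocsc() * config.residence_times[c], p)
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    abundance = {net.codes[i]: float(p[i]) for i in np.nonzero(p > 1e-15)[0]}
    total = sum(abundance.values())
    abundance = {k: v / total for k, v in abundance.items()}
    return GlycanProfile(abundance=abundance, n_sampled=None)


# -- profile readouts ----------------------------------------------------


def heterogeneity(profile: GlycanProfile) -> int:
    """Number of distinct glycan structures observed (sampled count >= 1)."""
    return len(profile.support())


@dataclass(frozen=True)
class ClassFractions:
    category: dict[str, float]
    antennarity: dict[int, float]
    sialylation: dict[int, float]


def class_fractions(profile: GlycanProfile) -> ClassFractions:
    """Fractions by maturity class plus antennarity and sialylation marginals."""
    cat = {"oligomannose": 0.0, "hybrid": 0.0, "complex": 0.0}
    ant = {k: 0.0 for k in range(5)}
    sia = {k: 0.0 for k in range(5)}
    for code, a in profile.abundance.items():
        cls = classify(GlycanState.from_code(code))
        cat[cls.category] += a
        ant[cls.antennarity] += a
        sia[cls.sialylation] += a
    return ClassFractions(category=cat, antennarity=ant, sialylation=sia)


class NoMgat2EventsError(ValueError):
    pass


def mgat2_fucosylated_fraction(flux: FluxRecord) -> float:
    """Fraction of Mgat2 events whose substrate carried core fucose."""
    total = 0
    fucosylated = 0
    for (enzyme, sub, _c), k in flux.counts.items():
        if enzyme != "Mgat2":
            continue
        total += k
        if GlycanState.from_code(sub).fuc:
            fucosylated += k
    if total == 0:
        raise NoMgat2EventsError("flux record contains no Mgat2 events")
    return fucosylated / total


def check_flux_conservation(flux: FluxRecord) -> bool:
    """Exact integer bookkeeping: entry + inflow - outflow = final, per state."""
    inflow: dict[str, int] = {}
    outflow: dict[str, int] = {}
    for (sub, prod), k in flux.transitions.items():
        outflow[sub] = outflow.get(sub, 0) + k
        inflow[prod] = inflow.get(prod, 0) + k
    if sum(flux.transitions.values()) != sum(flux.counts.values()):
        return False
    states = set(flux.entry_counts) | set(inflow) | set(outflow) | set(flux.final_counts)
    for code in states:
        lhs = inflow.get(code, 0) - outflow.get(code, 0)
        rhs = flux.final_counts.get(code, 0) - flux.entry_counts.get(code, 0)
        if lhs != rhs:
            return False
    return True
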