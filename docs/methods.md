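# Methods

## Model

One N-glycan is tracked through `n` cisternae as a continuous-time Markov
jump process over a finite structure space.  The state records residual
glucose, the mannose count of the core, the maturation of up to four
GlcNAc-initiated antennae, and core fucosylation.  Nine enzymes act through
a rule table (`src/golgisim/data/rules.yaml`) that is data, not code:
predicates and actions are interpreted at load time, so pathway variants
are configuration edits.  Choices embedded in the default table:

- ManI removes the residual glucose of GlcMan9GlcNAc2 (no separate
  glucosidase is modelled) and trims mannoses one residue per event down to
  Man5; trimming requires the Mgat1 antenna to be absent.
- Antennae cannot be initiated before trimming reaches Man5 (Mgat1) and
  Man3 (Mgat2/4/5).  ManII is blocked once the Mgat2 antenna exists; Mgat5
  requires the Mgat2 antenna in ungalactosylated (GlcNAc) form; Mgat4
  additionally requires the Mgat1 arm still in GlcNAc form.  Galactosylating
  an arm therefore permanently blocks the branching enzyme that reads it —
  the competition between galactosylation and branching that drives the
  engineering results below.
- Fut8 requires the Mgat1 antenna as GlcNAc (fucosylation can precede the
  second antenna but not follow galactosylation of the first arm).
- GalT and SiaT are per-site rules: their propensity is the per-cisterna
  rate times the number of eligible antennae, and the acted antenna is
  chosen uniformly (maximum-entropy reading of site multiplicity).
- Bisecting GlcNAc (Mgat3) is outside the enzyme set.

Closure of the entry glycans under the table yields a DAG of 312 states and
799 edges.  Every event advances exactly one progress coordinate, so event
counts between two states are path-independent; this underlies the exact
flux-conservation bookkeeping.

## Simulation and the exact oracle

Within cisterna `c`, reaction `j` on state `x` has propensity
`a_j = k[e_j, c] · m_j(x)`; waiting times are exponential in the total
propensity, and an event whose waiting time crosses the cisternal boundary
is discarded (the glycan exits mid-wait).  Glycans are processed one at a
time — no substrate competition or secretory load — which makes the whole
process a single-molecule CTMC.  The engine therefore has two
interchangeable solvers:

- `simulate_profile`: Gillespie simulation of `n_glycans` (default 10,000)
  independent molecules, each with its own counter-based RNG stream
  (Philox keyed on `(seed, glycan index)`), so results are bit-reproducible
  and independent of execution order.  Event records give per-(enzyme,
  substrate, cisterna) fluxes with exact integer conservation.
- `exact_profile`: sparse generator matrices `Q_c` per cisterna and
  `p_out = p_in · Π_c exp(Q_c t_c)` via `scipy`'s `expm_multiply`.

Only rate × time products matter: scaling all rates by `c` and dividing all
residence times by `c` leaves `exact_profile` unchanged (checked to 1e-9
total variation).  The SSA is validated against the exact solver across
random configurations at the multinomial 3σ total-variation bound.

Units are arbitrary: the reference sets each cisternal residence time to 1,
so effective rates are "expected events per cisternal transit".

## Synthetic wild-type reference

No fitted mammalian parameter set is published with the model, so
`synth.make_reference_config` generates a documented stand-in with three
ingredients:

1. **Localization archetypes** (fractions of each enzyme's total rate per
   cisterna): trimming and antenna initiation cis-located (ManI, Mgat1
   peak in cisterna 1; ManII, Mgat2, Fut8 in cisterna 2), branching (Mgat4,
   Mgat5) confined almost entirely to cisterna 3, GalT bimodal with a
   cis-side shoulder in cisterna 2 and a trans peak in cisterna 4, SiaT
   trans-peaked.  All weights are strictly positive so multiplicative
   (variable-localization) fitting can move mass anywhere.
2. **Relative totals** chosen so processing is sequential: trimming fast,
   antenna initiation comfortably inside the transit, branching modest,
   capping partial at the reference transit time.
3. **A global rate scale fixed by bisection** so the exact profile's
   oligomannose fraction hits 25% (contract: within [0.1, 0.5]); the
   builder errors if the profile lacks bi- or tri-antennary complex
   species.

The sharp mid-Golgi localization of branching is a deliberate regime
choice, not a fitted fact.  Because Mgat4 reads the Mgat1 arm and Mgat5 the
Mgat2 arm, any galactosylation of those arms *upstream* of cisterna 3 (the
GalT cis shoulder) caps the branchable pool in a way no Mgat4/5
overexpression can recover, while within cisterna 3 a 10-fold rate increase
already saturates the eligible pool.  This yields the observed engineering
phenomenology: 100× Mgat4/5 gains nothing over 10×, whereas relocating GalT
away from the branching cisterna (the "separated" scenario) lifts the cap
and is synergistic with the rate increase.  With branching distributed
broadly instead, 100× keeps outcompeting galactosylation arm by arm and the
saturation disappears; users exploring that regime can simply pass their
own weights.

What the generator does *not* emulate: measurement error of real glycomics
(beyond optional Dirichlet resampling noise in `make_pseudo_observed`),
protein-site effects, donor-sugar dynamics, and inter-glycan competition.
Passing tests therefore demonstrate internal correctness and
qualitative-regime behaviour, not quantitative agreement with any cell
line.

## Architecture experiments

`redistribute_cisternae` treats each enzyme's per-cisterna rates as a
piecewise-constant density on [0, 1], averages it over the new equal bins,
and rescales to conserve the per-enzyme total exactly; total transit time
is preserved and split equally.  Because totals and total time are both
held fixed, each enzyme's rate × time exposure scales as `1/n` — with more
cisternae every enzyme sees the glycan more briefly, trimming and
maturation become less complete, oligomannose rises and heterogeneity
falls.  The transit-time sweep scales all residence times by a factor grid
(0.1–3.3, defaults chosen to bracket the collapse at short times and the
sialylated-node convergence at long times).

Sweeps run 3 replicates (matching the convention of reporting mean ± SD
over three simulations) of 10,000 glycans; heterogeneity is the *sampled*
support size (count ≥ 1), deliberately a finite-sample readout.

## ABC fitting

Parameters: per-enzyme total scale (fixed mode) or per-enzyme-per-cisterna
multipliers (variable mode), one transit-time scale, and the entry mixture.
Rates and time live in log space with log-normal priors whose median is the
reference value (σ = 1.0 for rates, 0.5 for time); the entry mixture has a
Dirichlet prior centred on the reference mix with concentration 50,
parameterized by additive log-ratios.  Priors are truncated at 3.5σ, which
keeps proposals biologically plausible and bounds the matrix-exponential
cost of a single evaluation.

The distance is L1 on relative abundances over the union of supports
(range 0–2).  By default particles are scored with the exact solver — a
documented approximation that removes simulation noise from the distance —
with a full-SSA evaluator available (`evaluator="ssa"`).

The sampler is an adaptive population Monte Carlo: generation 0 samples the
prior; each later generation sets its tolerance to the median of the
previous accepted distances (non-increasing by construction), resamples
ancestors uniformly from the particles already inside the new tolerance,
and perturbs with a multivariate Gaussian whose covariance is that
subpopulation's covariance, shrinkage-regularized (30% toward its
diagonal) and scaled by 0.1.  Termination: a generation cap, an
acceptance-rate floor, or failure to fill a generation.  The small kernel
scale trades posterior spread for reliable convergence in up to ~40
dimensions; the particle cloud is a kernel-smoothed approximate posterior
without importance re-weighting, and the package's summaries (posterior
medians of fold changes, best-particle profiles) are point summaries robust
to that approximation.  An importance-weighted variant was evaluated and
discarded: its prior/kernel weights degenerate in the variable-localization
parameterization.

Fixed-localization mode scales whole enzyme rows, so accepted particles
preserve the reference cisternal fractions exactly; variable mode frees
each (enzyme, cisterna) multiplier.  `normalize_rates_to_wt_time` exploits
scale invariance to report all fits at the reference transit time, as fold
changes of total effective rates.

Target profiles for glycoform maximization keep the oligomannose species
at their reference abundances and assign the entire remaining mass to the
target structure; the distance does not penalize particular by-products.
Reported "achieved" fractions aggregate structural isomers of the target's
composition and are normalized to the complex-class fraction.  The
tri-Sia1 target's seed structure places the third antenna on the Mgat5 arm
and the single sialic acid on the Mgat1 arm; isomer aggregation makes the
reported numbers insensitive to this choice.

## Recovery checks and degenerate inputs

Ground truth for fitting tests comes from `planted_perturbation` (fold
changes and trans-ward localization shifts with exact totals) and
`make_pseudo_observed` (seeded SSA profiles, optional Dirichlet noise).
The acceptance suite requires the planted GalT doubling to be recovered
within ×/÷2 in both modes with at least a fivefold tolerance reduction.

Degenerate cases are defined, not errors: zero total propensity idles the
glycan for the rest of the cisterna; an all-zero rate matrix returns the
entry mixture; a flux record without Mgat2 events raises a specific
exception rather than returning 0/0.  Profile I/O renormalizes sums within
1e-3 of 1 (with a warning) and rejects anything farther.

## Known limitations

- The state space hard-codes the four canonical antenna slots; poly-LacNAc
  extension, bisecting GlcNAc and antennary fucosylation are out of scope.
- The ABC posterior is approximate (kernel-smoothed, truncated priors);
  credible intervals should not be read off the particle cloud.
- Reported percentages depend on the synthetic reference regime and are
  not predictions for any real cell line; only the qualitative orderings
  and trends are claimed.
- The exact solver requires the enumerated network to fit in memory
  (guarded at 20,000 states); custom rule tables beyond that fall back to
  SSA only.
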