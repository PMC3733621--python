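# Methods

## Model form and assumptions

`gemkin` translates a metabolic network reconstruction into a kinetic model
using a reduced special case of generalized mass-action kinetics. The
reduction rests on normalization: metabolite concentrations and expression
levels are expressed relative to a reference condition, which makes
`c = 1, g = 1, r = v_ref` a steady state by construction and collapses all
rate constants into the reference flux distribution. The model therefore
needs no literature-derived kinetic constants; for steady-state analysis
the only inputs are the reference fluxes `v`, the reaction-level expression
ratios `g`, and a handful of global parameters.

Assumptions worth keeping in mind:

- relative changes in transcript abundance are taken as relative changes in
  enzyme activity (rates are exactly linear in `g`); post-translational
  regulation and allostery are not represented;
- irreversible reactions are product-inhibited, a surrogate for missing
  downstream regulation that lets downstream state influence pathway flux;
- lumped multi-step reactions damp their concentration sensitivity through
  the `1/gamma` exponent on the whole substrate/product ratio, where
  `gamma` is the number of lumped irreversible steps. This grouping is the
  one under which `gamma = 1` reduces to a plain ratio law and
  `gamma -> inf` yields the concentration-insensitive limit `r -> v g`;
- cofactor pairs are pooled into single species (ATP, NADH).

### The reversible split

A reversible reaction's net reference flux `v` is split as
`v_f = beta*|v|, v_b = (beta-1)*|v|` with the roles exchanged for `v < 0`,
so that both parts are nonnegative, `v_f - v_b = v` holds exactly, and the
larger part always carries the net direction. `beta = 1` degenerates to an
irreversible law. We use the absolute-value convention for negative fluxes
because the reference identity `r(1) = v` is the defining requirement of
the parameterization and must hold for either flux sign.

### Drains and growth

Biomass formation is represented by precursor drain fluxes rather than a
single biomass reaction. Amino-acid drains use

    r = v g * prod_i [A_i]^alpha * (min_j [A_j])^alpha

with `i` over the drain's consumed metabolites (one amino acid plus ATP)
and `j` over *all* amino acids: a shortage of any amino acid stalls protein
synthesis and hence every drain. Other drains omit the min term. The
growth rate is `mu = (lambda / X_MW) * sum_i phi_i r_i` over drains, with
`phi_i` the moles of carbon per mole of precursor. `X_MW` defaults to 1 in
normalized units, making `lambda` the single calibration constant that sets
`mu = D` at reference in the chemostat (see below). Note `mu` can be
positive even when individual drains stall.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `alpha` | kinetic order of drain fluxes | 0.1 | small: drains are nearly insensitive to precursor pools |
| `beta` | forward/backward split of reversibles | 30 | one global value; >= 1; overrides on parallel routes |
| `lambda` | growth-rate correction | calibrated | set so the reference culture grows at the dilution rate |
| `inhibition[rid]` | multiplicative inhibition factor | 1 | 1 = none, 0 = complete; multiplies the whole rate |
| `woa_uptake` | weak-organic-acid diffusive uptake | 0 | stress intensity in flux units |
| `atp_per_woa` | ATP cost per WOA taken up | 2 | one ATP each for proton and anion export |
| `m_i` | kinetic orders | 2 where coefficient is exactly 2, else 1 | non-integer (biomass-style) coefficients get 1 |

The WOA stress model is deliberately coarse: a fixed ATP drain of
`atp_per_woa * woa_uptake` on the pooled ATP balance. The export
stoichiometry is configurable because the true cost depends on transporter
usage.

## Data-derived parameterization

**Reference fluxes.** When only exchange/uptake-production rates are
measured, the reference distribution is estimated as the minimum-Euclidean-
norm flux vector satisfying `S v = 0`, the measured exchanges (hard
constraints, absolute tolerance 1e-6), and irreversibility. The solve is an
exact KKT system when no sign constraint binds; otherwise a sign-constrained
quadratic program (SLSQP) identifies the active set, which is then polished
by an exact equality-constrained solve. Conflicting measurements are
reported with per-constraint residuals before any sign handling, so the
diagnosis separates mass-balance inconsistency from irreversibility
conflicts.

**Expression ratios.** Raw intensity arrays are scaled to a mean of 150,
condition levels are per-gene medians over replicates, and the log-ratio is
de-trended by Lowess smoothing against the log-mean intensity (MA-style;
span 0.3 by default — the method name is standard, the span is this
package's choice). Per-gene ratios are aggregated to reactions through the
gene-association rules: AND nodes take the minimum child value (a complex
is limited by its scarcest subunit); OR nodes take the mean weighted by
reference intensities when available (isoenzyme capacities add); for a
lumped reaction whose top-level connective is AND, the genes are sequential
steps rather than subunits and the geometric mean is used, respecting the
multiplicative role of `g` along a lumped flux. Genes absent from the data
default to ratio 1 with a warning, keeping `g` total over reactions. These
conventions are isolated behind `aggregate_expression` so they can be
swapped wholesale.

**Beta on parallel routes.** Cycles of reversible reactions (detected on
the undirected graph of two-metabolite reversible conversions) must satisfy
a Wegscheider-style consistency: the product of `v_f/v_b` ratios around the
cycle, evaluated at reference, equals 1. Member betas are moved minimally
in log space (SLSQP with the cycle condition as an equality constraint);
when no `beta >= 1` assignment can satisfy a cycle, the global value is
kept and a warning names the cycle.

## Steady-state solving

The root of `S r(c) = 0` is sought in log-concentration coordinates, which
enforces positivity without constraints; `c = 1` is the start point because
conditions are perturbations of the reference. The search tries scipy's
hybrid Powell method, then Levenberg–Marquardt, then dynamic relaxation
(stiff LSODA integration of `C dc/dt = S r`) followed by a Newton polish.
Convergence requires a residual below `1e-9 * max(1, ||v||_inf)`. The
relaxation integrator doubles as an independent oracle: the two solvers are
required to agree to 1e-6 relative on seeded toy networks in the test
suite. Steady states are independent of the normalization concentrations
`C` (they only shape the transient), which is itself tested. Multiplicity
of steady states is not resolved; disagreement between the two solvers
would surface in the oracle tests.

## Chemostat layer

The culture-level model couples the intracellular steady state to two
balances: growth at the dilution rate, `mu(c) = D`, closed by letting the
extracellular substrate concentration `s` float (it feeds back on the
uptake kinetics), and the substrate balance
`D (feed - s) = q_glc(s, c) X`, which yields the biomass `X`. Calibration
sets `lambda = D / mu_raw(reference)` and
`feed = 1 + q_ref / D`, after which the reference culture sits exactly at
`X = 1, s = 1`. A condition is *washed out* when no solution exists with
`X` above a floor (1e-3 of reference by default) — in practice when the
required `s` exceeds the feed or the coupled system loses its root. Stress
boundaries (maximum tolerated inhibition depth; WOA uptake reducing
biomass to a given fraction, default 5%) are located by bisection to a
relative width of 1e-3, with the upper bracket grown geometrically for the
WOA case.

## Analyses

**Mechanism-of-action ranking.** Each intracellular reaction (forward and
backward rates of reversible reactions treated individually) is scaled by a
factor in [0.1, 10] chosen to minimize the sum of squared log-differences
between the re-solved concentrations and the observed ratios; the
optimization is a bounded scalar search on the log factor (tolerance 1e-3
in log space), warm-started from the baseline steady state. Results are
sorted by SSE normalized to the unperturbed model's SSE; the factor 1 is
always admissible, so normalized SSE never exceeds 1. Nonconverging
perturbations are flagged and ranked last; ties break by reaction id.

**NTC / NUC.** For a subset of reactions, the normalized tolerance (or
uptake) change is the symmetric average of the add-one-in and leave-one-out
effects of the subset's expression ratios on the stress boundary,
normalized by the total expression-driven boundary shift. The tolerance
measure for inhibition is the depth `1 - k*` so that more tolerant is
larger; any strictly monotone transform gives the same normalized score.
Subsets of size 2–3 give pair/triplet contributions. Reactions with unit
expression ratio score exactly 0 (short-circuited, no bisection noise), and
the full changed set scores exactly 1.

**Dose–response.** Biomass against a nondecreasing WOA uptake grid under
three expression scenarios: the measured ratios (GED), none (NoGED), and
log-scale extrapolation (`g -> g^2` by default). Washout is encoded as
biomass 0.

**Sensitivity sweeps** evaluate any SSE-style metric over a cartesian
parameter grid, flagging nonconverged points instead of failing.

## Synthetic fixtures

The fixture module generates all test inputs deterministically:

- **toys** (chain, diamond, branched): seeded reversibility and flux
  scales, optional ATP coupling, biomass drains and a maintenance valve;
  reference fluxes come from the package's own minimum-norm estimator, so
  every generated state satisfies `S v = 0` to machine precision;
- **a yeast-like network**: glycolysis, pentose phosphate pathway, TCA
  cycle, fermentative overflow (ethanol, glycerol, lactate, acetate),
  18 amino-acid synthesis pathways with lumped steps (`gamma` up to 6),
  18 amino-acid drains with the min-coupling, 6 generic precursor drains,
  and GPRs over 309 synthetic genes — sized to 75 internal metabolites and
  125 reactions, with the reference state scaled to a glucose uptake of
  6.09 and fermentation-dominant routing (respiratory reactions carry zero
  flux). The stoichiometry is this package's own construction: it matches
  the published counts, pathway composition and flux scale of the system it
  emulates, not any specific reconstruction, so tests against it check
  properties and constructed truths, never published condition-specific
  values;
- **a minimal chemostat toy** (substrate → A → B + 2 ATP, two ATP-coupled
  drains, an overflow branch and ATP maintenance) used for
  tolerance-contribution ground truth. Its design makes the washout
  boundary scale with the expression ratio of the stressed step, so NTC/NUC
  values of exactly 1 and 0 can be constructed. On the yeast-like fixture
  the inhibition-tolerance boundary is dominated by the steeply coupled
  serine→glycine schedule, which compresses expression effects below the
  bisection resolution — a fixture property, not a metric defect, and the
  reason the contribution metrics are validated on the toy.

Observation noise is multiplicative log-normal for concentrations (sd of
log values equals the CV, median-preserving) and additive with
`sd = cv * |v|` for fluxes, which may be negative.

What passing tests on these fixtures shows: the construction pipeline,
solvers and analyses are internally consistent, exact where exactness is
claimed, and able to recover planted ground truth under realistic noise.
What they do not show: agreement with any real organism's measured
condition-specific responses, which requires the corresponding experimental
inputs.

## Numerical choices and problem sizes

- residual tolerance `1e-9 * max(1, ||v||_inf)`; log-space clipping at
  `exp(±60)` guards intermediate overflow;
- bisection widths 1e-3 (relative) for all stress boundaries;
- golden-ratio-free bounded scalar minimization (Brent) for factor
  optimization, `xatol = 1e-3` on the log factor;
- relaxation horizon 1e5 time units, LSODA with `rtol 1e-10, atol 1e-12`;
- test problem sizes: toys of 3–15 internal metabolites; recovery studies
  use 20 seeded 5-metabolite chains; oracle equivalence uses 20 seeded
  toys; the yeast-like fixture (75 metabolites) is solved in tens of
  milliseconds and used for reference-identity, ranking and dose–response
  demonstrations.

## Known limitations

- No mechanistic saturation (Michaelis–Menten), allosteric regulation, or
  elementary-step decomposition; the product-inhibition surrogate can
  misrepresent reactions whose true control is allosteric.
- The WOA burden is a single lumped ATP cost; transporter expression
  changes are not modeled.
- Steady-state multiplicity is reported (via solver disagreement) but not
  resolved; no bifurcation analysis.
- Transient simulation exists only as an internal oracle; using it as a
  product feature would additionally require absolute metabolite
  concentrations (`C`).
- The GPR aggregation and flux-estimation conventions are reasonable
  defaults, not identified from data; both sit behind single functions so
  alternatives can be substituted.
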