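"""Synthetic networks, reference states and observations with known truth.

Stands in for real reconstructions and measurement sets so the whole
package is testable offline.  Two families:

* toy networks (chain / diamond / branched) — a few internal metabolites,
  seeded reversibility and flux scales, optional ATP coupling and biomass
  drains; used for closed-form and oracle-equivalence checks.
* a yeast-like network — a deterministic emulation of central carbon
  metabolism (glycolysis, PPP, TCA, fermentation) plus amino-acid synthesis
  and biomass drains, sized to 75 internal metabolites, 125 reactions and
  309 genes with a reference glucose uptake of 6.09, the scale of an
  anaerobic glucose-limited chemostat.  The stoichiometry is this package's
  own; only counts, pathway composition and flux scale follow the published
  system.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .network import Metabolite, Network, Reaction, parse_gpr, validate_network
from .parameterize import estimate_reference_fluxes
from .ratelaws import (
    ExpressionVector,
    KineticModel,
    RateParameters,
    ReferenceState,
    assemble_model,
)


class FixtureError(ValueError):
    """Unachievable fixture specification."""


@dataclass
class FixtureSpec:
    topology: str = "chain"
    n: int = 4
    branches: int = 1
    fraction_reversible: float = 0.0
    n_drains: int = 0
    seed: int = 0
    noise_cv: float = 0.0


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------


def add_noise(values: Mapping[str, float], cv: float, seed: int) -> dict[str, float]:
    """Multiplicative log-normal noise: sd of log values equals ``cv``.

    Median-preserving (no mean correction on the natural scale).
    """
    if cv < 0:
        raise FixtureError("cv must be nonnegative")
    keys = sorted(values)
    if cv == 0:
        return {k: float(values[k]) for k in keys}
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(len(keys))
    return {k: float(values[k] * np.exp(cv * zi)) for k, zi in zip(keys, z)}


def add_flux_noise(values: Mapping[str, float], cv: float, seed: int) -> dict[str, float]:
    """Additive Gaussian noise with sd = cv * |v| (fluxes may be negative)."""
    if cv < 0:
        raise FixtureError("cv must be nonnegative")
    keys = sorted(values)
    if cv == 0:
        return {k: float(values[k]) for k in keys}
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(len(keys))
    return {k: float(values[k] + cv * abs(values[k]) * zi) for k, zi in zip(keys, z)}


# ---------------------------------------------------------------------------
# toy networks
# ---------------------------------------------------------------------------


def make_toy_network(spec: FixtureSpec) -> tuple[Network, ReferenceState]:
    """Deterministic toy network and a consistent reference flux state."""
    if spec.topology == "chain":
        net = _chain_network(spec)
    elif spec.topology == "diamond":
        net = _diamond_network(spec)
    elif spec.topology == "branched":
        net = _branched_network(spec)
    elif spec.topology == "yeast_like":
        network, ref, _phi = make_yeast_like_fixture()
        return network, ref
    else:
        raise FixtureError(f"unknown topology {spec.topology!r}")
    problems = validate_network(net)
    if problems:  # pragma: no cover - generator bug guard
        raise FixtureError(f"generated network invalid: {problems}")
    ref = _toy_reference(net, spec)
    return net, ref


def _rng(spec: FixtureSpec) -> np.random.Generator:
    return np.random.default_rng(spec.seed)


def _chain_network(spec: FixtureSpec) -> Network:
    n = spec.n
    if n < 1:
        raise FixtureError("chain needs n >= 1")
    if spec.n_drains > n:
        raise FixtureError("more drains than chain metabolites")
    rng = _rng(spec)
    mets = [Metabolite("X_in", role="boundary"), Metabolite("X_out", role="boundary")]
    mets += [Metabolite(f"M{i}") for i in range(1, n + 1)]
    use_atp = spec.n_drains > 0
    if use_atp:
        mets.append(Metabolite("ATP"))
        mets.append(Metabolite("BIO", role="biomass-sink"))
    rxns = [Reaction("uptake", {"X_in": -1.0, "M1": 1.0})]
    atp_step = max(1, n // 2)
    for i in range(1, n):
        stoich = {f"M{i}": -1.0, f"M{i + 1}": 1.0}
        if use_atp and i == atp_step:
            stoich["ATP"] = 1.0
        reversible = bool(rng.random() < spec.fraction_reversible)
        rxns.append(
            Reaction(
                f"step{i}",
                stoich,
                reversible=reversible,
                kinetic_class="mass_action_reversible"
                if reversible
                else "mass_action_irreversible",
            )
        )
    rxns.append(Reaction("export", {f"M{n}": -1.0, "X_out": 1.0}))
    if use_atp:
        for d in range(spec.n_drains):
            met = f"M{n - d}"
            rxns.append(
                Reaction(
                    f"drain{d}",
                    {met: -1.0, "ATP": -1.0, "BIO": 1.0},
                    kinetic_class="amino_acid_drain" if d == 0 else "generic_drain",
                )
            )
        rxns.append(Reaction("maintenance", {"ATP": -1.0}))
    return Network(mets, rxns)


def _diamond_network(spec: FixtureSpec) -> Network:
    if spec.n < 4:
        raise FixtureError("diamond needs n >= 4 internal metabolites")
    reversible = spec.fraction_reversible > 0
    cls = "mass_action_reversible" if reversible else "mass_action_irreversible"
    mets = [
        Metabolite("X_in", role="boundary"),
        Metabolite("X_out", role="boundary"),
        Metabolite("A"),
        Metabolite("B1"),
        Metabolite("B2"),
        Metabolite("C"),
    ]
    rxns = [
        Reaction("uptake", {"X_in": -1.0, "A": 1.0}),
        Reaction("upper1", {"A": -1.0, "B1": 1.0}, reversible=reversible, kinetic_class=cls),
        Reaction("upper2", {"B1": -1.0, "C": 1.0}, reversible=reversible, kinetic_class=cls),
        Reaction("lower1", {"A": -1.0, "B2": 1.0}, reversible=reversible, kinetic_class=cls),
        Reaction("lower2", {"B2": -1.0, "C": 1.0}, reversible=reversible, kinetic_class=cls),
        Reaction("export", {"C": -1.0, "X_out": 1.0}),
    ]
    return Network(mets, rxns)


def _branched_network(spec: FixtureSpec) -> Network:
    b = spec.branches
    n_backbone = spec.n - b
    if n_backbone < 1 or b < 1:
        raise FixtureError("branched needs n > branches >= 1")
    rng = _rng(spec)
    chain_spec = FixtureSpec(
        topology="chain",
        n=n_backbone,
        fraction_reversible=spec.fraction_reversible,
        n_drains=spec.n_drains,
        seed=spec.seed,
    )
    base = _chain_network(chain_spec)
    mets = list(base.metabolites)
    rxns = list(base.reactions)
    anchors = rng.integers(1, n_backbone + 1, size=b)
    for k, a in enumerate(sorted(anchors)):
        mets.append(Metabolite(f"B{k}"))
        mets.append(Metabolite(f"B{k}_out", role="boundary"))
        rxns.append(Reaction(f"branch{k}", {f"M{a}": -1.0, f"B{k}": 1.0}))
        rxns.append(Reaction(f"branch{k}_out", {f"B{k}": -1.0, f"B{k}_out": 1.0}))
    return Network(mets, rxns)


def _toy_reference(net: Network, spec: FixtureSpec) -> ReferenceState:
    rng = np.random.default_rng(spec.seed + 1)
    uptake = float(rng.uniform(2.0, 8.0))
    fixed = {"uptake": uptake}
    n_drains = sum(1 for r in net.reactions if r.id.startswith("drain"))
    for d in range(n_drains):
        fixed[f"drain{d}"] = uptake * float(rng.uniform(0.02, 0.10))
    for r in net.reactions:
        if r.id.startswith("branch") and not r.id.endswith("_out"):
            fixed[r.id] = uptake * float(rng.uniform(0.05, 0.15))
    ref = estimate_reference_fluxes(net, fixed)
    return ref


# ---------------------------------------------------------------------------
# conditions with known ground truth
# ---------------------------------------------------------------------------


def make_condition(
    network: Network,
    ref: ReferenceState,
    perturbed: Mapping[str, float],
    seed: int = 0,
    noise_cv: float = 0.0,
    params: RateParameters | None = None,
):
    """Solve a fixture under known expression changes; emit noisy observations.

    Returns ``(expression, observed_concentration_ratios, observed_fluxes,
    truth)`` where ``truth`` holds the noise-free solution.
    """
    from .solver import solve_steady_state

    for rid in perturbed:
        if rid not in network._rxn_index:
            raise FixtureError(f"perturbed id {rid!r} not in network")
    g = ExpressionVector(g=dict(perturbed))
    model = assemble_model(network, ref, g, params)
    sol = solve_steady_state(model)
    obs_c = add_noise(sol.c, noise_cv, seed)
    obs_v = add_flux_noise(sol.r, noise_cv, seed + 1)
    return g, obs_c, obs_v, sol


# ---------------------------------------------------------------------------
# yeast-like fixture
# ---------------------------------------------------------------------------

# amino acids with their carbon counts (phi of the drain) and a relative
# weight in the biomass protein; the min-coupling of the drains runs over
# this set
_AMINO_ACIDS = [
    ("ALA", 3, 8.0), ("ARG", 6, 3.0), ("ASN", 4, 3.0), ("ASP", 4, 5.0),
    ("GLN", 5, 3.0), ("GLU", 5, 7.0), ("GLY", 2, 6.0), ("HIS", 6, 1.5),
    ("ILE", 6, 4.0), ("LEU", 6, 6.0), ("LYS", 6, 5.0), ("MET", 5, 1.5),
    ("PHE", 9, 3.0), ("PRO", 5, 3.0), ("SER", 3, 4.0), ("THR", 4, 4.0),
    ("TYR", 9, 2.5), ("VAL", 5, 5.0),
]

# (id, equation, gamma, class) — cofactor pairs pooled into ATP / NADH
_YEAST_REACTIONS: list[tuple[str, str, int, str]] = [
    # glucose uptake and glycolysis
    ("glk", "GLCx + ATP -> G6P", 1, ""),                      # EC 2.7.1.1 analog
    ("pgi", "G6P <-> F6P", 1, ""),
    ("pfk", "F6P + ATP -> FBP", 1, ""),
    ("fba", "FBP <-> DHAP + GAP", 1, ""),
    ("tpi", "DHAP <-> GAP", 1, ""),
    ("gapdh_pgk", "GAP <-> PG3 + NADH + ATP", 2, ""),         # lumped, 0 irrev steps? net rev
    ("gpm_eno", "PG3 <-> PEP", 2, ""),
    ("pyk", "PEP -> PYR + ATP", 1, ""),
    # fermentation and overflow
    ("pdc", "PYR -> ACD + CO2", 1, ""),                       # EC 4.1.1.1 analog
    ("adh", "ACD + NADH -> ETH", 1, ""),
    ("gpd_gpp", "DHAP + NADH -> GOL", 2, ""),
    ("ldh", "PYR + NADH -> LAC", 1, ""),
    ("ald", "ACD -> ACE + NADH", 1, ""),
    ("acs", "ACE + 2 ATP -> ACCOA", 1, ""),
    # TCA cycle and anaplerosis
    ("pdh", "PYR -> ACCOA + CO2 + NADH", 1, ""),
    ("cit", "ACCOA + OAA -> CIT", 1, ""),
    ("aco", "CIT <-> ICIT", 1, ""),
    ("idh", "ICIT -> AKG + CO2 + NADH", 1, ""),
    ("akgdh", "AKG -> SUC + CO2 + NADH + ATP", 2, ""),
    ("sdh", "SUC <-> FUM + NADH", 1, ""),
    ("fum", "FUM <-> MAL", 1, ""),
    ("mdh", "MAL <-> OAA + NADH", 1, ""),
    ("pyc", "PYR + ATP + CO2 -> OAA", 1, ""),
    ("fbp1", "FBP -> F6P", 1, ""),                            # gluconeogenic valve
    ("pck", "OAA + ATP -> PEP + CO2", 1, ""),
    # pentose phosphate pathway
    ("zwf", "G6P -> P6G + NADH", 1, ""),
    ("gnd", "P6G -> RU5P + CO2 + NADH", 1, ""),
    ("rpi", "RU5P <-> R5P", 1, ""),
    ("rpe", "RU5P <-> X5P", 1, ""),
    ("tkl1", "R5P + X5P <-> S7P + GAP", 1, ""),
    ("tal", "S7P + GAP <-> F6P + E4P", 1, ""),
    ("tkl2", "X5P + E4P <-> F6P + GAP", 1, ""),
    # oxidative phosphorylation (pooled) and maintenance
    ("oxp", "NADH -> ATP", 1, ""),
    ("atpm", "ATP -> SINKx", 1, ""),
    # one-carbon metabolism
    ("ser_gly", "SER <-> GLY + METTHF", 1, ""),
    ("gly_thr", "THR -> GLY + ACD", 1, ""),
    # amino-acid synthesis (lumped pathways; intermediates explicit where
    # the analyses address individual steps)
    ("ala_syn", "PYR + GLU -> ALA + AKG", 1, ""),
    ("asp_syn", "OAA + GLU -> ASP + AKG", 1, ""),
    ("asn_syn", "ASP + 2 ATP -> ASN", 1, ""),
    ("glu_syn", "AKG + NADH -> GLU", 1, ""),
    ("gln_syn", "GLU + ATP -> GLN", 1, ""),
    ("arg_syn1", "GLU + 2 ATP -> ORN", 3, ""),
    ("arg_syn2", "ORN + GLN + ATP -> ARG", 2, ""),
    ("pro_syn", "GLU + NADH -> PRO", 2, ""),
    ("ser_syn", "PG3 + GLU -> SER + AKG + NADH", 2, ""),
    ("thr_syn1", "ASP + ATP + 2 NADH -> HSER", 2, ""),
    ("thr_syn2", "HSER + ATP -> THR", 2, ""),
    ("met_syn", "HSER + METTHF + ACCOA + 2 ATP -> MET + ACE + 3 NADH", 3, ""),
    ("ile_syn", "THR + PYR + GLU + NADH -> ILE + AKG + CO2", 3, ""),
    ("val_syn", "2 PYR + GLU + NADH -> VAL + AKG + CO2", 3, ""),
    ("leu_syn", "2 PYR + ACCOA + GLU -> LEU + AKG + 2 CO2 + NADH", 4, ""),
    ("lys_syn", "AKG + ACCOA + GLU + 2 NADH + 2 ATP -> LYS", 4, ""),
    ("his_syn1", "R5P + METTHF + 2 ATP -> IAP", 3, ""),       # 3-AT target step here
    ("his_syn2", "IAP + GLU -> HIS + AKG + 2 NADH", 2, ""),
    ("chor_syn", "PEP + E4P + ATP + NADH -> CHOR", 6, ""),
    ("phe_syn", "CHOR + GLU -> PHE + AKG + CO2", 3, ""),
    ("tyr_syn", "CHOR + GLU -> TYR + AKG + CO2 + NADH", 3, ""),
    # exchanges and secretions (free sinks, self-regulating mass action)
    ("eth_ex", "ETH -> ETHx", 1, ""),
    ("gol_ex", "GOL -> GOLx", 1, ""),
    ("lac_ex", "LAC -> LACx", 1, ""),
    ("ace_ex", "ACE -> ACEx", 1, ""),
    ("co2_ex", "CO2 -> CO2x", 1, ""),
    ("pyr_ex", "PYR -> PYRx", 1, ""),
    ("suc_ex", "SUC -> SUCx", 1, ""),
]

# generic (non-amino-acid) biomass drains: id, equation, phi (mol C / mol)
_GENERIC_DRAINS = [
    ("carb_drain", "G6P + ATP -> CARBBIOx", 6.0),
    ("sto_drain", "G6P + 2 ATP -> STOBIOx", 6.0),
    ("cw_drain", "F6P + ATP -> CWBIOx", 6.0),
    ("lip_drain", "2 ACCOA + ATP + 2 NADH -> LIPBIOx", 4.0),
    ("rna_drain", "R5P + 2 ATP -> RNABIOx", 5.0),
    ("c1_drain", "METTHF + ATP -> C1BIOx", 1.0),
]

# lumped syntheses split into explicit sequential steps (padding toward the
# published metabolite count); each split adds one intermediate and one step
_SPLITS = [
    "arg_syn1", "pro_syn", "ser_syn", "thr_syn1", "met_syn", "ile_syn",
    "val_syn", "leu_syn", "lys_syn", "chor_syn", "phe_syn", "tyr_syn",
    "arg_syn2", "thr_syn2", "his_syn1", "his_syn2", "gapdh_pgk", "gpd_gpp",
    "asn_syn", "acs", "gln_syn", "pyc", "lys_syn_a", "leu_syn_a",
]

# isoenzyme duplicates (padding toward the published reaction count)
_DUPLICATES = [
    "pdc", "adh", "fba", "pfk", "pyk", "zwf", "ald", "ldh",
    "oxp", "pdh", "gnd", "cit", "pgi", "tpi", "rpe", "idh",
]

_TARGET_METS = 75
_TARGET_RXNS = 125
_TARGET_GENES = 309

# reference exchange rates (mmol/gDW/h scale of a glucose-limited anaerobic
# chemostat): uptake 6.09; ethanol, glycerol, lactate, acetate secretion
_REFERENCE_EXCHANGES = {
    "glk": 6.09,
    "eth_ex": 9.60,
    "gol_ex": 0.79,
    "lac_ex": 0.05,
    "ace_ex": 0.02,
}

_MINOR_SECRETIONS = {"pyr_ex": 0.03, "suc_ex": 0.02}

# carbon routed to biomass at reference: drains sized so that
# sum(phi_i * d_i) ~ the carbon not recovered in secreted products
_PROTEIN_CARBON = 3.2
_OTHER_CARBON = {
    "carb_drain": 0.45,
    "sto_drain": 0.12,
    "cw_drain": 0.18,
    "lip_drain": 0.22,
    "rna_drain": 0.10,
    "c1_drain": 0.03,
}


def _split_reaction(rxn: Reaction, inter_id: str) -> tuple[Reaction, Reaction]:
    """Split A + cofactors -> products into A -> I and I + cofactors -> products.

    The first consumed metabolite anchors the first step; everything else
    moves to the second.  Gamma is divided across the steps (at least 1 each).
    """
    subs = sorted(rxn.substrates)
    anchor = subs[0]
    g1 = max(1, rxn.gamma // 2)
    g2 = max(1, rxn.gamma - g1)
    s1 = {anchor: rxn.stoich[anchor], inter_id: 1.0}
    s2 = {inter_id: -1.0}
    for met, coeff in rxn.stoich.items():
        if met == anchor:
            continue
        s2[met] = coeff
    r1 = Reaction(
        f"{rxn.id}_a", s1, reversible=False, gamma=g1, lumped=g1 > 1,
        kinetic_class="mass_action_irreversible",
    )
    r2 = Reaction(
        f"{rxn.id}_b", s2, reversible=rxn.reversible, gamma=g2, lumped=g2 > 1,
        kinetic_class=rxn.kinetic_class,
    )
    return r1, r2


def _yeast_network() -> Network:
    reactions: list[Reaction] = []
    from .network import _reaction_from_record

    for rid, eq, gamma, klass in _YEAST_REACTIONS:
        reactions.append(_reaction_from_record(rid, eq, gamma, "", klass))
    for aa, _carbons, _w in _AMINO_ACIDS:
        reactions.append(
            _reaction_from_record(
                f"{aa.lower()}_drain", f"{aa} + ATP -> {aa}BIOx", 1, "",
                "amino_acid_drain",
            )
        )
    for rid, eq, _phi in _GENERIC_DRAINS:
        reactions.append(_reaction_from_record(rid, eq, 1, "", "generic_drain"))

    # split designated lumped reactions until the metabolite count is met
    by_id = {r.id: r for r in reactions}
    mets_now = _count_internal(reactions)
    for rid in _SPLITS:
        if mets_now >= _TARGET_METS:
            break
        rxn = by_id.pop(rid)
        idx = reactions.index(rxn)
        r1, r2 = _split_reaction(rxn, f"I_{rid.upper()}")
        reactions[idx : idx + 1] = [r1, r2]
        by_id[r1.id] = r1
        by_id[r2.id] = r2
        mets_now += 1
    assert mets_now == _TARGET_METS, f"metabolite padding reached {mets_now}"

    # duplicate isoenzyme reactions until the reaction count is met
    for rid in _DUPLICATES:
        if len(reactions) >= _TARGET_RXNS:
            break
        rxn = by_id[rid]
        dup = Reaction(
            f"{rid}_iso", dict(rxn.stoich), reversible=rxn.reversible,
            gamma=rxn.gamma, lumped=rxn.lumped, kinetic_class=rxn.kinetic_class,
        )
        reactions.insert(reactions.index(rxn) + 1, dup)
        by_id[dup.id] = dup
    assert len(reactions) == _TARGET_RXNS, f"reaction padding reached {len(reactions)}"

    internal = sorted(
        {m for r in reactions for m in r.stoich if not m.endswith("x")}
    )
    boundary = sorted(
        {m for r in reactions for m in r.stoich if m.endswith("x")}
    )
    mets = [Metabolite(m) for m in internal]
    mets += [
        Metabolite(m, role="biomass-sink" if m.endswith("BIOx") else "boundary")
        for m in boundary
    ]

    _attach_gprs(reactions)
    net = Network(mets, reactions)
    assert len(net.internal_ids) == _TARGET_METS
    assert len(net.genes()) == _TARGET_GENES, f"gene total {len(net.genes())}"
    problems = validate_network(net)
    if problems:  # pragma: no cover - generator bug guard
        raise FixtureError(f"yeast fixture invalid: {problems}")
    return net


def _count_internal(reactions: list[Reaction]) -> int:
    return len({m for r in reactions for m in r.stoich if not m.endswith("x")})


def _attach_gprs(reactions: list[Reaction]) -> None:
    """Synthetic gene associations: drains, exchanges and maintenance have
    none; the rest share 309 distinct genes with mixed AND/OR structure."""
    skip = {
        r.id
        for r in reactions
        if r.kinetic_class in ("amino_acid_drain", "generic_drain")
        or r.id.endswith("_ex")
        or r.id == "atpm"
    }
    assoc = [r for r in reactions if r.id not in skip]
    n_assoc = len(assoc)
    base = _TARGET_GENES // n_assoc
    extra = _TARGET_GENES - base * n_assoc
    gene_counter = 0

    def next_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"Y{gene_counter:03d}"

    for i, rxn in enumerate(sorted(assoc, key=lambda r: r.id)):
        size = base + (1 if i < extra else 0)
        genes = [next_gene() for _ in range(size)]
        if size == 1:
            text = genes[0]
        elif size == 2:
            text = f"{genes[0]} or {genes[1]}"
        elif size == 3:
            text = f"({genes[0]} and {genes[1]}) or {genes[2]}"
        else:
            half = size // 2
            left = " and ".join(genes[:half])
            right = " and ".join(genes[half:])
            text = f"({left}) or ({right})"
        rxn.gpr = parse_gpr(text)
    assert gene_counter == _TARGET_GENES


def make_yeast_like_fixture() -> tuple[Network, ReferenceState, dict[str, float]]:
    """Yeast-like network, consistent reference state, and the phi table.

    The reference flux state is the minimum-norm distribution consistent
    with the reference exchange rates (glucose uptake 6.09) and the biomass
    drain demands; CO2 export and internal routing float.
    """
    net = _yeast_network()
    phi = _phi_table()
    fixed = dict(_REFERENCE_EXCHANGES)
    fixed.update(_MINOR_SECRETIONS)
    fixed.update(_drain_demands())
    ref = estimate_reference_fluxes(net, fixed)
    # every internal metabolite must touch a flux-carrying reaction, or its
    # balance would be identically zero (singular steady-state Jacobian)
    live = {
        m
        for r in net.reactions
        if abs(ref.v[r.id]) > 1e-9
        for m in r.stoich
    }
    dead = [m for m in net.internal_ids if m not in live]
    assert not dead, f"internal metabolites with no flux-carrying reaction: {dead}"
    return net, ref, phi


def _phi_table() -> dict[str, float]:
    phi = {f"{aa.lower()}_drain": float(c) for aa, c, _w in _AMINO_ACIDS}
    phi.update({rid: p for rid, _eq, p in _GENERIC_DRAINS})
    return phi


def _drain_demands() -> dict[str, float]:
    total_w = sum(w for _aa, _c, w in _AMINO_ACIDS)
    demands = {}
    for aa, carbons, w in _AMINO_ACIDS:
        share = _PROTEIN_CARBON * (w / total_w)
        demands[f"{aa.lower()}_drain"] = share / carbons
    for rid, _eq, p in _GENERIC_DRAINS:
        demands[rid] = _OTHER_CARBON[rid] / p
    return demands


def yeast_model(
    expression: ExpressionVector | Mapping[str, float] | None = None,
    params: RateParameters | None = None,
) -> KineticModel:
    """Assembled kinetic model of the yeast-like fixture."""
    net, ref, phi = make_yeast_like_fixture()
    if params is None:
        params = RateParameters()
    if not params.phi:
        params = params.replace(phi=phi)
    return assemble_model(net, ref, expression, params)


# histidine-pathway inhibition target and the coupled serine->glycine step
HIS_TARGET = "his_syn1_b"
SER_GLY = "ser_gly"


def his_inhibition_family(
    base: KineticModel | None = None,
) -> "Callable[[float, ExpressionVector], KineticModel]":
    """Model family over the histidine-synthesis inhibition factor.

    ``build(k_his, expression)`` applies ``k_his`` to the targeted
    histidine-pathway step and the coupled (linearly scheduled) inhibition
    to the serine->glycine reaction.
    """
    from .analyses import inhibition_schedule

    if base is None:
        base = yeast_model()

    def build(k_his: float, expression: ExpressionVector) -> KineticModel:
        k_his = min(max(k_his, 1e-9), 1.0)
        params = base.params.replace(
            inhibition={
                HIS_TARGET: k_his,
                SER_GLY: inhibition_schedule(k_his),
            }
        )
        return base.with_params(params).with_expression(expression)

    return build


def woa_family(
    base: KineticModel | None = None,
) -> "Callable[[float, ExpressionVector], KineticModel]":
    """Model family over the weak-organic-acid uptake rate (ATP burden)."""
    if base is None:
        base = yeast_model()

    def build(woa_uptake: float, expression: ExpressionVector) -> KineticModel:
        params = base.params.replace(woa_uptake=float(max(woa_uptake, 0.0)))
        return base.with_params(params).with_expression(expression)

    return build


def chemostat_toy() -> tuple[KineticModel, "ChemostatSetup"]:
    """Minimal calibrated chemostat model with bounded stress compensation.

    Substrate -> A -> B + ATP with two biomass drains and ATP maintenance.
    Inhibiting the catalytic step forces the A pool (and hence the required
    substrate concentration) up roughly as 1/k, so the washout boundary
    scales with the expression ratio of the inhibited reaction — a
    controllable ground truth for tolerance-contribution metrics.
    """
    from .solver import ChemostatSetup, calibrate_chemostat

    mets = [
        Metabolite("GLCx", role="boundary"),
        Metabolite("A"),
        Metabolite("B"),
        Metabolite("ATP"),
        Metabolite("Wx", role="boundary"),
        Metabolite("BIOx", role="biomass-sink"),
    ]
    rxns = [
        Reaction("up", {"GLCx": -1.0, "A": 1.0}),
        Reaction("cat", {"A": -1.0, "B": 1.0, "ATP": 2.0}),
        Reaction(
            "drain_b",
            {"B": -1.0, "ATP": -1.0, "BIOx": 1.0},
            kinetic_class="amino_acid_drain",
        ),
        Reaction(
            "drain_c",
            {"B": -1.0, "ATP": -1.0, "BIOx": 1.0},
            kinetic_class="generic_drain",
        ),
        # overflow branch: lets the energy-producing step outrun the drains
        Reaction("spill", {"B": -1.0, "Wx": 1.0}),
        Reaction("maint", {"ATP": -1.0}),
    ]
    net = Network(mets, rxns)
    v = {"up": 3.0, "cat": 3.0, "drain_b": 1.0, "drain_c": 1.0,
         "spill": 1.0, "maint": 4.0}
    params = RateParameters(phi={"drain_b": 1.0, "drain_c": 1.0})
    model = assemble_model(net, v, None, params)
    setup = ChemostatSetup(
        dilution_rate=0.1, glucose_uptake_reaction="up", glucose_species="GLCx"
    )
    calibrate_chemostat(model, setup)
    return model, setup


def toy_inhibition_family(model: KineticModel):
    """Family over an inhibition factor on the toy's catalytic step."""

    def build(k: float, expression: ExpressionVector) -> KineticModel:
        k = min(max(k, 1e-9), 1.0)
        return model.with_params(
            model.params.replace(inhibition={"cat": k})
        ).with_expression(expression)

    return build


def toy_woa_family(model: KineticModel):
    """Family over the WOA uptake rate (ATP burden) on the toy."""

    def build(woa: float, expression: ExpressionVector) -> KineticModel:
        return model.with_params(
            model.params.replace(woa_uptake=float(max(woa, 0.0)))
        ).with_expression(expression)

    return build


def reference_chemostat(model: KineticModel | None = None):
    """Calibrated chemostat setup for the yeast-like fixture (D = 0.1 /h)."""
    from .solver import ChemostatSetup, calibrate_chemostat

    if model is None:
        model = yeast_model()
    setup = ChemostatSetup(
        dilution_rate=0.1,
        glucose_uptake_reaction="glk",
        glucose_species="GLCx",
    )
    calibrate_chemostat(model, setup)
    return model, setup
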