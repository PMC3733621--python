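"""Reduced generalized mass-action rate laws and kinetic-model assembly.

The rate expressions are a special case of GMA kinetics in which the rate
constant of every reaction collapses into its reference flux ``v``: with all
normalized concentrations at 1 and all expression ratios ``g`` at 1 the
model reproduces the reference flux distribution exactly.  Concentrations
are normalized by their (unknown) reference values, so the laws are written
in dimensionless ``c`` and the steady state is independent of absolute
concentrations.

Law forms
---------
* irreversible:  ``r = v * g * (prod [A]^m / prod [B]^m)^(1/gamma)`` —
  products inhibit, standing in for unknown downstream regulation; ``gamma``
  (number of irreversible steps lumped into the reaction) damps the
  concentration sensitivity of lumped reactions.
* reversible:    ``r = g * (v_f * prod [A]^m - v_b * prod [B]^m)`` with the
  forward/backward split ``v_f - v_b = v`` controlled by ``beta >= 1``.
* amino-acid drain: ``r = v * g * prod [A_i]^alpha * (min_j [A_j])^alpha``
  where j ranges over *all* amino acids — a shortage of any amino acid slows
  protein synthesis and hence every drain.
* generic drain: ``r = v * g * prod [A_i]^alpha``.
* growth rate:   ``mu = (lambda / X_MW) * sum_i phi_i * r_i`` over drains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .network import Network, Reaction


class RateLawError(ValueError):
    """Invalid input to a rate law (domain or configuration error)."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class RateParameters:
    """Condition-level fitting parameters of the kinetic model.

    alpha
        Kinetic order of the biomass drain fluxes (dimensionless, default
        0.1): small so drains are insensitive to precursor concentrations.
    beta_global / beta_overrides
        Forward/backward split of reversible reactions (>= 1; default 30).
        ``beta = 1`` degenerates to an irreversible law (zero backward rate).
    lambda_growth
        Correction factor on the growth rate (dimensionless, default 1);
        calibrated so the reference culture grows at the chemostat dilution
        rate.
    X_MW
        Biomass molecular weight; 1 in normalized units.
    phi
        Moles of carbon per mole of precursor for each biomass drain.
    inhibition
        Multiplicative inhibition factor per reaction id in (0, 1]:
        1 = no inhibition, 0 = complete.
    woa_uptake / atp_per_woa
        Weak-organic-acid diffusive uptake rate and the ATP cost of
        exporting one mole of it (proton plus anion pumping).
    """

    alpha: float = 0.1
    beta_global: float = 30.0
    beta_overrides: dict[str, float] = field(default_factory=dict)
    lambda_growth: float = 1.0
    X_MW: float = 1.0
    phi: dict[str, float] = field(default_factory=dict)
    inhibition: dict[str, float] = field(default_factory=dict)
    woa_uptake: float = 0.0
    atp_per_woa: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise RateLawError("alpha must be positive")
        if self.beta_global < 1:
            raise RateLawError("beta must be >= 1")
        for rid, b in self.beta_overrides.items():
            if b < 1:
                raise RateLawError(f"beta override for {rid} must be >= 1")
        for rid, k in self.inhibition.items():
            if not (0 < k <= 1):
                raise RateLawError(f"inhibition factor for {rid} must be in (0, 1]")
        if self.woa_uptake < 0 or self.atp_per_woa < 0:
            raise RateLawError("WOA uptake and ATP cost must be nonnegative")

    def beta(self, rid: str) -> float:
        return self.beta_overrides.get(rid, self.beta_global)

    def replace(self, **kw) -> "RateParameters":
        from dataclasses import replace as _replace

        kw.setdefault("beta_overrides", dict(self.beta_overrides))
        kw.setdefault("phi", dict(self.phi))
        kw.setdefault("inhibition", dict(self.inhibition))
        return _replace(self, **kw)


@dataclass
class ReferenceState:
    """Reference flux distribution with forward/backward parts for reversibles."""

    v: dict[str, float]
    v_f: dict[str, float] = field(default_factory=dict)
    v_b: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_fluxes(
        cls, network: Network, v: Mapping[str, float], params: RateParameters
    ) -> "ReferenceState":
        ref = cls(v=dict(v))
        for r in network.reactions:
            if r.reversible:
                vf, vb = split_reversible(ref.v.get(r.id, 0.0), params.beta(r.id))
                ref.v_f[r.id] = vf
                ref.v_b[r.id] = vb
        return ref


@dataclass
class ExpressionVector:
    """Reaction-level overall expression ratios; 1.0 where no gene association."""

    g: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, val in self.g.items():
            if val <= 0:
                raise RateLawError(f"expression ratio for {rid} must be positive")

    def __getitem__(self, rid: str) -> float:
        return self.g.get(rid, 1.0)

    def replace(self, updates: Mapping[str, float]) -> "ExpressionVector":
        g = dict(self.g)
        g.update(updates)
        return ExpressionVector(g=g)


# ---------------------------------------------------------------------------
# individual rate laws
# ---------------------------------------------------------------------------


def _check_conc(c: Mapping[str, float], mets) -> None:
    for m in mets:
        if c.get(m, 1.0) <= 0:
            raise RateLawError(f"nonpositive concentration for {m}")


def irreversible_rate(
    reaction: Reaction, v: float, g: float, c: Mapping[str, float]
) -> float:
    """Irreversible product-inhibited law ``v*g*(prod[A]^m / prod[B]^m)^(1/gamma)``.

    Metabolites absent from ``c`` are at the reference concentration 1.
    """
    if v < 0:
        raise RateLawError(f"reaction {reaction.id}: irreversible flux must be >= 0")
    _check_conc(c, reaction.stoich)
    log_ratio = 0.0
    for met, coeff in reaction.stoich.items():
        m = reaction.kinetic_orders[met]
        term = m * math.log(c.get(met, 1.0))
        log_ratio += -term if coeff > 0 else term
    return v * g * math.exp(log_ratio / reaction.gamma)


def split_reversible(v: float, beta: float) -> tuple[float, float]:
    """Split a net reference flux into nonnegative forward/backward parts.

    ``v > 0``: ``(beta*v, (beta-1)*v)``; ``v < 0``: ``((beta-1)*|v|, beta*|v|)``
    so the larger part always carries the net direction and
    ``v_f - v_b = v`` holds exactly.
    """
    if beta < 1:
        raise RateLawError("beta must be >= 1")
    if v == 0:
        return 0.0, 0.0
    a = abs(v)
    if v > 0:
        return beta * a, (beta - 1.0) * a
    return (beta - 1.0) * a, beta * a


def reversible_rate(
    reaction: Reaction, v_f: float, v_b: float, g: float, c: Mapping[str, float]
) -> float:
    """Reversible law ``g * (v_f * prod[A]^m - v_b * prod[B]^m)``."""
    if v_f < 0 or v_b < 0:
        raise RateLawError(f"reaction {reaction.id}: v_f and v_b must be >= 0")
    _check_conc(c, reaction.stoich)
    fwd = v_f
    bwd = v_b
    for met, coeff in reaction.stoich.items():
        m = reaction.kinetic_orders[met]
        conc = c.get(met, 1.0)
        if coeff < 0:
            fwd *= conc**m
        else:
            bwd *= conc**m
    return g * (fwd - bwd)


def amino_acid_drain_rate(
    reaction: Reaction,
    v: float,
    g: float,
    alpha: float,
    c: Mapping[str, float],
    all_amino_acids: set[str] | frozenset[str],
) -> float:
    """Amino-acid drain: consumed precursors at order alpha times the
    alpha-power of the lowest concentration over *all* amino acids."""
    if not all_amino_acids:
        raise RateLawError(
            f"reaction {reaction.id}: amino_acid_drain needs a nonempty amino-acid set"
        )
    if v < 0:
        raise RateLawError(f"reaction {reaction.id}: drain flux must be >= 0")
    _check_conc(c, reaction.substrates)
    _check_conc(c, all_amino_acids)
    rate = v * g
    for met in reaction.substrates:
        rate *= c.get(met, 1.0) ** alpha
    min_aa = min(c.get(a, 1.0) for a in all_amino_acids)
    return rate * min_aa**alpha


def generic_drain_rate(
    reaction: Reaction, v: float, g: float, alpha: float, c: Mapping[str, float]
) -> float:
    """Generic drain: consumed precursors at kinetic order alpha."""
    if v < 0:
        raise RateLawError(f"reaction {reaction.id}: drain flux must be >= 0")
    _check_conc(c, reaction.substrates)
    rate = v * g
    for met in reaction.substrates:
        rate *= c.get(met, 1.0) ** alpha
    return rate


def growth_rate(drain_rates: Mapping[str, float], params: RateParameters) -> float:
    """Growth rate ``mu = (lambda / X_MW) * sum phi_i * r_i`` over drain fluxes."""
    total = 0.0
    for rid, rate in drain_rates.items():
        if rid not in params.phi:
            raise RateLawError(f"no phi (carbon content) entry for drain {rid}")
        total += params.phi[rid] * rate
    return params.lambda_growth / params.X_MW * total


# ---------------------------------------------------------------------------
# assembled model
# ---------------------------------------------------------------------------


class KineticModel:
    """A network with reference fluxes, expression ratios and parameters,
    exposing the rate map ``r(c)`` and balance map ``f(c) = S @ r(c)``.

    The WOA stress enters as a fixed extra ATP consumption of
    ``atp_per_woa * woa_uptake`` on the ATP balance (export burden of the
    diffusing acid); inhibition factors multiply the full rate of the named
    reaction.
    """

    def __init__(
        self,
        network: Network,
        reference: ReferenceState,
        expression: ExpressionVector,
        params: RateParameters,
        amino_acids: set[str] | None = None,
        atp_id: str = "ATP",
    ):
        self.network = network
        self.reference = reference
        self.expression = expression
        self.params = params
        self.atp_id = atp_id
        if amino_acids is None:
            amino_acids = {
                m
                for r in network.reactions
                if r.kinetic_class == "amino_acid_drain"
                for m in r.substrates
                if m != atp_id
            }
        self.amino_acids = frozenset(amino_acids)
        self._S = network.stoichiometric_matrix()
        self._internal = network.internal_ids
        self._internal_index = {m: i for i, m in enumerate(self._internal)}
        for rid in params.inhibition:
            if rid not in network._rxn_index:
                raise RateLawError(f"inhibition factor for unknown reaction {rid!r}")
        for rid in params.beta_overrides:
            if rid not in network._rxn_index:
                raise RateLawError(f"beta override for unknown reaction {rid!r}")
        for r in network.reactions:
            if r.id not in reference.v:
                raise RateLawError(f"reference state lacks a flux for {r.id}")

    # -- evaluation --------------------------------------------------------

    @property
    def S(self) -> np.ndarray:
        return self._S

    @property
    def internal_ids(self) -> list[str]:
        return list(self._internal)

    def reaction_rate(self, reaction: Reaction, c: Mapping[str, float]) -> float:
        p = self.params
        v = self.reference.v[reaction.id]
        g = self.expression[reaction.id]
        k = p.inhibition.get(reaction.id, 1.0)
        cls = reaction.kinetic_class
        if cls == "mass_action_irreversible":
            rate = irreversible_rate(reaction, v, g, c)
        elif cls == "mass_action_reversible":
            rate = reversible_rate(
                reaction,
                self.reference.v_f.get(reaction.id, max(v, 0.0)),
                self.reference.v_b.get(reaction.id, max(-v, 0.0)),
                g,
                c,
            )
        elif cls == "amino_acid_drain":
            rate = amino_acid_drain_rate(reaction, v, g, p.alpha, c, self.amino_acids)
        elif cls == "generic_drain":
            rate = generic_drain_rate(reaction, v, g, p.alpha, c)
        elif cls == "fixed_exchange":
            rate = v * g
        else:  # pragma: no cover - guarded at Reaction construction
            raise RateLawError(f"unknown kinetic class {cls!r}")
        return k * rate

    def rates(self, c: Mapping[str, float]) -> dict[str, float]:
        return {r.id: self.reaction_rate(r, c) for r in self.network.reactions}

    def rate_vector(self, c: Mapping[str, float]) -> np.ndarray:
        return np.array([self.reaction_rate(r, c) for r in self.network.reactions])

    def balances(self, c: Mapping[str, float]) -> np.ndarray:
        """f(c) = S @ r(c), plus the fixed WOA ATP burden on the ATP row."""
        f = self._S @ self.rate_vector(c)
        if self.params.woa_uptake > 0 and self.atp_id in self._internal_index:
            f[self._internal_index[self.atp_id]] -= (
                self.params.atp_per_woa * self.params.woa_uptake
            )
        return f

    def drain_rates(self, c: Mapping[str, float]) -> dict[str, float]:
        return {
            r.id: self.reaction_rate(r, c)
            for r in self.network.reactions
            if r.kinetic_class in ("amino_acid_drain", "generic_drain")
        }

    def growth_rate(self, c: Mapping[str, float]) -> float:
        return growth_rate(self.drain_rates(c), self.params)

    # -- variations --------------------------------------------------------

    def with_expression(self, expression: ExpressionVector) -> "KineticModel":
        return KineticModel(
            self.network, self.reference, expression, self.params,
            set(self.amino_acids), self.atp_id,
        )

    def with_params(self, params: RateParameters) -> "KineticModel":
        ref = self.reference
        if params.beta_global != self.params.beta_global or (
            params.beta_overrides != self.params.beta_overrides
        ):
            ref = ReferenceState.from_fluxes(self.network, ref.v, params)
        return KineticModel(
            self.network, ref, self.expression, params,
            set(self.amino_acids), self.atp_id,
        )

    def with_rate_scaling(
        self, rid: str, factor: float, direction: str = "whole"
    ) -> "KineticModel":
        """Scale one reaction's rate (or one direction of a reversible one)."""
        rxn = self.network.reaction(rid)
        ref = ReferenceState(v=dict(self.reference.v),
                             v_f=dict(self.reference.v_f),
                             v_b=dict(self.reference.v_b))
        if direction == "whole" or not rxn.reversible:
            ref.v[rid] = ref.v[rid] * factor
            if rid in ref.v_f:
                ref.v_f[rid] *= factor
                ref.v_b[rid] *= factor
        elif direction == "forward":
            ref.v_f[rid] *= factor
            ref.v[rid] = ref.v_f[rid] - ref.v_b[rid]
        elif direction == "backward":
            ref.v_b[rid] *= factor
            ref.v[rid] = ref.v_f[rid] - ref.v_b[rid]
        else:
            raise RateLawError(f"unknown perturbation direction {direction!r}")
        return KineticModel(
            self.network, ref, self.expression, self.params,
            set(self.amino_acids), self.atp_id,
        )


def assemble_model(
    network: Network,
    reference: ReferenceState | Mapping[str, float],
    expression: ExpressionVector | Mapping[str, float] | None = None,
    params: RateParameters | None = None,
    **kw,
) -> KineticModel:
    """Build a :class:`KineticModel`; accepts plain mappings for convenience."""
    if params is None:
        params = RateParameters()
    if not isinstance(reference, ReferenceState):
        reference = ReferenceState.from_fluxes(network, reference, params)
    elif not reference.v_f and any(r.reversible for r in network.reactions):
        reference = ReferenceState.from_fluxes(network, reference.v, params)
    if expression is None:
        expression = ExpressionVector()
    elif not isinstance(expression, ExpressionVector):
        expression = ExpressionVector(g=dict(expression))
    return KineticModel(network, reference, expression, params, **kw)


# ---------------------------------------------------------------------------
# SBML formula rendering
# ---------------------------------------------------------------------------


def sbml_rate_formula(reaction: Reaction, v: float) -> str:
    """Render a reaction's rate law as an infix formula for MathML export."""
    subs = " * ".join(
        f"({m})^{reaction.kinetic_orders[m]:g}" for m in reaction.substrates
    ) or "1"
    prods = " * ".join(
        f"({m})^{reaction.kinetic_orders[m]:g}" for m in reaction.products
    ) or "1"
    cls = reaction.kinetic_class
    if cls == "mass_action_reversible":
        return f"g_{reaction.id} * (vf_{reaction.id} * {subs} - vb_{reaction.id} * {prods})"
    if cls in ("generic_drain", "amino_acid_drain"):
        return f"{v!r} * g_{reaction.id} * ({subs})^alpha"
    if cls == "fixed_exchange":
        return f"{v!r} * g_{reaction.id}"
    return f"{v!r} * g_{reaction.id} * (({subs}) / ({prods}))^(1 / {reaction.gamma})"
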