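"""Data-derived model parameters.

Turns raw measurements into the three parameter blocks the kinetic model
needs: a reference flux distribution (from exchange measurements via a
minimum-norm flux fit when no labeled-substrate estimate exists),
reaction-level expression ratios (microarray preprocessing plus GPR
aggregation), and per-reaction beta splits consistent on parallel
reversible routes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import GeneAssociation, Network
from .ratelaws import ExpressionVector, RateParameters, ReferenceState, split_reversible

logger = logging.getLogger(__name__)


class EstimationError(ValueError):
    """Measurements inconsistent or insufficient for parameter estimation."""


# ---------------------------------------------------------------------------
# microarray preprocessing
# ---------------------------------------------------------------------------


def preprocess_microarray(
    raw: pd.DataFrame,
    treatment_id: str,
    reference_id: str,
    lowess_span: float = 0.3,
) -> pd.Series:
    """Per-gene expression ratios (treatment / reference) from raw intensities.

    ``raw`` has genes as rows; columns are named ``<condition>`` or
    ``<condition>_<replicate>``.  Steps: scale every array to a mean
    intensity of 150.0, take the per-gene median over replicates of each
    condition, Lowess-smooth the log-ratio against the log-mean intensity
    (MA-style) and subtract the trend, then return the de-trended ratios.
    """
    if (raw <= 0).any().any():
        bad = raw.columns[(raw <= 0).any()].tolist()
        raise EstimationError(f"nonpositive intensities in arrays {bad}")

    scaled = raw * (150.0 / raw.mean(axis=0))

    def condition_level(cond: str) -> pd.Series:
        cols = [
            c
            for c in scaled.columns
            if c == cond or c.startswith(cond + "_")
        ]
        if not cols:
            raise EstimationError(f"no arrays found for condition {cond!r}")
        return scaled[cols].median(axis=1)

    treat = condition_level(treatment_id)
    ref = condition_level(reference_id)

    m = np.log2(treat / ref)
    a = 0.5 * np.log2(treat * ref)

    from statsmodels.nonparametric.smoothers_lowess import lowess

    order = np.argsort(a.values, kind="stable")
    fitted = np.zeros_like(m.values)
    if np.ptp(a.values) > 0:
        smoothed = lowess(
            m.values[order], a.values[order], frac=lowess_span, return_sorted=False
        )
        fitted[order] = smoothed
    # identical conditions: m == 0 everywhere and the fit is exactly 0
    ratios = np.power(2.0, m.values - fitted)
    return pd.Series(ratios, index=raw.index, name="ratio")


# ---------------------------------------------------------------------------
# GPR aggregation
# ---------------------------------------------------------------------------


def _aggregate_tree(
    node: GeneAssociation,
    ratios: Mapping[str, float],
    intensities: Mapping[str, float] | None,
    missing: set[str],
) -> float:
    if node.op is None:
        gene = node.gene or ""
        if gene not in ratios:
            missing.add(gene)
            return 1.0
        return float(ratios[gene])
    child_vals = [
        _aggregate_tree(ch, ratios, intensities, missing) for ch in node.children
    ]
    if node.op == "and":
        # complexes: the least-changed (limiting) subunit sets the capacity
        return min(child_vals)
    # isoenzymes: capacities add; weight by reference abundance when known
    if intensities is not None:
        weights = []
        for ch in node.children:
            genes = sorted(ch.genes())
            w = sum(float(intensities.get(g, 1.0)) for g in genes)
            weights.append(w)
        total = sum(weights)
        if total > 0:
            return sum(w * v for w, v in zip(weights, child_vals)) / total
    return sum(child_vals) / len(child_vals)


def aggregate_expression(
    network: Network,
    ratios: Mapping[str, float] | pd.Series,
    reference_intensities: Mapping[str, float] | pd.Series | None = None,
) -> ExpressionVector:
    """Reaction-level overall expression ratios from per-gene ratios.

    AND nodes take the minimum of their children; OR nodes a
    reference-intensity-weighted mean (unweighted when intensities are
    absent); reactions without a gene association get g = 1.  Genes missing
    from ``ratios`` default to 1.0 (no change) with a warning.
    """
    if isinstance(ratios, pd.Series):
        ratios = ratios.to_dict()
    if isinstance(reference_intensities, pd.Series):
        reference_intensities = reference_intensities.to_dict()
    g: dict[str, float] = {}
    missing: set[str] = set()
    for rxn in network.reactions:
        if rxn.gpr is None:
            continue
        if rxn.lumped and rxn.gpr.op == "and":
            # AND-connected genes of a lumped reaction are sequential steps,
            # not complex subunits: geometric mean respects the multiplicative
            # role of the expression ratio along the lumped flux
            vals = [
                _aggregate_tree(ch, ratios, reference_intensities, missing)
                for ch in rxn.gpr.children
            ]
            val = float(np.prod(vals)) ** (1.0 / len(vals))
        else:
            val = _aggregate_tree(rxn.gpr, ratios, reference_intensities, missing)
        if val <= 0:
            raise EstimationError(f"nonpositive aggregated ratio for {rxn.id}")
        g[rxn.id] = val
    if missing:
        logger.warning(
            "%d genes missing from expression data; defaulted to ratio 1.0 (%s%s)",
            len(missing),
            ", ".join(sorted(missing)[:5]),
            "..." if len(missing) > 5 else "",
        )
    return ExpressionVector(g=g)


# ---------------------------------------------------------------------------
# reference-flux estimation
# ---------------------------------------------------------------------------


@dataclass
class ExchangeMeasurements:
    """Measured exchange/drain rates, keyed by reaction id."""

    rates: dict[str, float]
    sd: dict[str, float] = field(default_factory=dict)


def estimate_reference_fluxes(
    network: Network,
    measured: ExchangeMeasurements | Mapping[str, float],
    tol: float = 1e-6,
) -> ReferenceState:
    """Minimum-norm flux distribution consistent with measured exchanges.

    Solves ``min sum v_j^2`` subject to ``S v = 0``, measured exchange
    fluxes fixed (within ``tol``) and ``v_j >= 0`` for irreversible
    reactions.  The quadratic program is solved without inequality
    constraints first (exact KKT solve); active-set iterations clamp any
    violated irreversibility bounds.
    """
    if isinstance(measured, ExchangeMeasurements):
        fixed = dict(measured.rates)
    else:
        fixed = dict(measured)
    rids = network.reaction_ids
    for rid in fixed:
        if rid not in network._rxn_index:
            raise EstimationError(f"measured flux for unknown reaction {rid!r}")
    S = network.stoichiometric_matrix()
    n = len(rids)
    idx = {rid: j for j, rid in enumerate(rids)}
    scale = max(1.0, max((abs(x) for x in fixed.values()), default=1.0))

    fixed_rows = np.zeros((len(fixed), n))
    fixed_rhs = np.zeros(len(fixed))
    for i, (rid, val) in enumerate(sorted(fixed.items())):
        fixed_rows[i, idx[rid]] = 1.0
        fixed_rhs[i] = val
    A = np.vstack([S, fixed_rows])
    b = np.concatenate([np.zeros(S.shape[0]), fixed_rhs])

    # consistency of the equality block alone (catches conflicting
    # measurements before the sign-constrained solve)
    v_ls, *_ = np.linalg.lstsq(A, b, rcond=None)
    residual = A @ v_ls - b
    if np.abs(residual).max() > max(tol, 1e-9 * scale):
        details = {
            rid: float(residual[S.shape[0] + i])
            for i, (rid, _val) in enumerate(sorted(fixed.items()))
            if abs(residual[S.shape[0] + i]) > tol
        }
        raise EstimationError(
            f"exchange measurements are inconsistent with mass balance; "
            f"infeasibility gap {np.abs(residual).max():.3g}, "
            f"per-constraint residuals {details}"
        )

    irreversible = np.array(
        [not network.reaction(rid).reversible for rid in rids]
    )

    def _kkt_min_norm(clamped: np.ndarray) -> np.ndarray:
        rows = [A]
        if clamped.any():
            C = np.zeros((int(clamped.sum()), n))
            for i, j in enumerate(np.flatnonzero(clamped)):
                C[i, j] = 1.0
            rows.append(C)
        Af = np.vstack(rows)
        bf = np.concatenate([b, np.zeros(Af.shape[0] - A.shape[0])])
        m = Af.shape[0]
        K = np.block([[2.0 * np.eye(n), Af.T], [Af, np.zeros((m, m))]])
        rhs = np.concatenate([np.zeros(n), bf])
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
        # one step of iterative refinement sharpens the balance residual
        sol += np.linalg.lstsq(K, rhs - K @ sol, rcond=None)[0]
        return sol[:n]

    v = _kkt_min_norm(np.zeros(n, dtype=bool))
    if np.any(v[irreversible] < -tol):
        # sign-constrained quadratic program, then an exact polish on the
        # active set it identifies
        from scipy.optimize import minimize

        bounds = [(0.0, None) if irr else (None, None) for irr in irreversible]
        res = minimize(
            lambda x: float(x @ x),
            np.clip(v, [bd[0] if bd[0] is not None else -np.inf for bd in bounds], np.inf),
            jac=lambda x: 2.0 * x,
            method="SLSQP",
            bounds=bounds,
            constraints=[{"type": "eq", "fun": lambda x: A @ x - b,
                          "jac": lambda x: A}],
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if not res.success and np.abs(A @ res.x - b).max() > max(tol, 1e-7 * scale):
            raise EstimationError(
                f"no flux distribution satisfies the measurements and "
                f"irreversibility (solver: {res.message})"
            )
        clamped = irreversible & (res.x < max(tol, 1e-7 * scale))
        for _ in range(10):
            v = _kkt_min_norm(clamped)
            bad = irreversible & (v < -tol)
            if not bad.any():
                break
            clamped = clamped | bad
        else:  # pragma: no cover - defensive
            raise EstimationError("active-set polish did not converge")
    if np.abs(A @ v - b).max() > max(tol, 1e-9 * scale):  # pragma: no cover
        raise EstimationError("flux estimate lost feasibility during polishing")
    v = np.where(np.abs(v) < 1e-12, 0.0, v)
    v[irreversible & (v < 0)] = 0.0
    return ReferenceState(v={rid: float(v[j]) for rid, j in idx.items()})


# ---------------------------------------------------------------------------
# beta assignment on parallel reversible routes
# ---------------------------------------------------------------------------


def _reversible_cycles(network: Network) -> list[list[tuple[str, int]]]:
    """Cycles of reversible reactions: lists of (reaction id, orientation).

    Built on the undirected multigraph whose edges are reversible reactions
    with exactly two internal metabolites; a cycle basis there enumerates the
    parallel-route loops that need thermodynamic consistency.
    """
    G = nx.MultiGraph()
    internal = set(network.internal_ids)
    for r in network.reactions:
        if not r.reversible:
            continue
        mets = [m for m in r.stoich if m in internal]
        if len(mets) != 2:
            continue
        subs = [m for m in mets if r.stoich[m] < 0]
        prods = [m for m in mets if r.stoich[m] > 0]
        if len(subs) == 1 and len(prods) == 1:
            G.add_edge(subs[0], prods[0], key=r.id)
    cycles = []
    # minimum_cycle_basis ignores multi-edges; handle 2-cycles explicitly
    seen_pairs: set[tuple[str, str]] = set()
    for u, v in G.edges():
        pair = tuple(sorted((u, v)))
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        keys = list(G[u][v])
        if len(keys) >= 2:
            for k in keys[1:]:
                cycles.append(_orient_cycle(network, [u, v, u], [keys[0], k]))
    simple = nx.Graph(G)
    for nodes in nx.cycle_basis(simple):
        if len(nodes) < 3:
            continue
        path = nodes + [nodes[0]]
        keys = []
        ok = True
        for a, b in zip(path[:-1], path[1:]):
            if b not in G[a]:
                ok = False
                break
            keys.append(next(iter(G[a][b])))
        if ok:
            cycles.append(_orient_cycle(network, path, keys))
    return cycles


def _orient_cycle(
    network: Network, path: Sequence[str], keys: Sequence[str]
) -> list[tuple[str, int]]:
    out = []
    for (a, b), rid in zip(zip(path[:-1], path[1:]), keys):
        rxn = network.reaction(rid)
        # +1 when traversing the edge in the reaction's forward direction
        sign = 1 if rxn.stoich.get(a, 0) < 0 else -1
        out.append((rid, sign))
    return out


def _log_ratio(v: float, beta: float) -> float:
    """log(v_f / v_b) for the beta split of flux v."""
    vf, vb = split_reversible(v, beta)
    if vf == 0 or vb == 0:
        return 0.0
    return float(np.log(vf / vb))


def assign_betas(
    network: Network,
    reference: ReferenceState | Mapping[str, float],
    beta_global: float = 30.0,
) -> dict[str, float]:
    """Beta overrides making parallel reversible routes thermodynamically tied.

    Around every cycle of reversible reactions the product of forward/
    backward rate ratios at reference must be 1 (Wegscheider condition).
    Member betas are moved minimally (least squares in log beta) to satisfy
    it; if no beta >= 1 assignment can, the cycle keeps ``beta_global`` with
    a warning.
    """
    if beta_global < 1:
        raise EstimationError("beta must be >= 1")
    v = reference.v if isinstance(reference, ReferenceState) else dict(reference)
    overrides: dict[str, float] = {}
    from scipy.optimize import minimize

    for cycle in _reversible_cycles(network):
        members = [rid for rid, _ in cycle if v.get(rid, 0.0) != 0.0]
        if not members:
            continue
        signs = {rid: s for rid, s in cycle}

        def cycle_gap(log_betas: np.ndarray) -> float:
            betas = 1.0 + np.exp(log_betas)  # beta > 1 by construction
            total = 0.0
            for rid, b in zip(members, betas):
                lr = _log_ratio(v[rid], b)
                # a negative net flux already flips v_f/v_b; orientation sign
                # accounts for traversal direction only
                total += signs[rid] * lr
            return total

        x0 = np.full(len(members), np.log(max(beta_global - 1.0, 1e-6)))

        res = minimize(
            lambda x: float(np.sum((x - x0) ** 2)),
            x0,
            jac=lambda x: 2.0 * (x - x0),
            method="SLSQP",
            constraints=[{"type": "eq", "fun": lambda x: cycle_gap(x)}],
            options={"maxiter": 500, "ftol": 1e-14},
        )
        gap = cycle_gap(res.x)
        if abs(gap) > 1e-6:
            logger.warning(
                "cycle %s: no beta >= 1 satisfies thermodynamic consistency "
                "(residual %.3g); keeping beta_global", members, gap
            )
            continue
        for rid, lb in zip(members, res.x):
            overrides[rid] = float(1.0 + np.exp(lb))
    return overrides


# ---------------------------------------------------------------------------
# expression manipulation
# ---------------------------------------------------------------------------


def extrapolate_expression(g: ExpressionVector, factor: float) -> ExpressionVector:
    """Scale expression ratios on the log scale: each g becomes g**factor."""
    return ExpressionVector(g={rid: val**factor for rid, val in g.g.items()})


def shuffle_expression(values, seed: int):
    """Randomly permute expression values (ratios or profile) under a seed."""
    rng = np.random.default_rng(seed)
    if isinstance(values, ExpressionVector):
        keys = sorted(values.g)
        vals = [values.g[k] for k in keys]
        perm = rng.permutation(len(vals))
        return ExpressionVector(g={k: vals[p] for k, p in zip(keys, perm)})
    if isinstance(values, pd.Series):
        perm = rng.permutation(len(values))
        return pd.Series(values.values[perm], index=values.index, name=values.name)
    keys = sorted(values)
    vals = [values[k] for k in keys]
    perm = rng.permutation(len(vals))
    return {k: vals[p] for k, p in zip(keys, perm)}
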