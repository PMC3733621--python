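"""Model-based analyses.

* mechanism-of-action ranking: perturb each intracellular reaction (forward
  and backward rates of reversible reactions individually) by the factor in
  [0.1, 10] that best explains observed concentration changes; reactions
  whose perturbation removes the most inconsistency rank first.
* tolerance contributions: NTC (normalized tolerance change, inhibition
  stress) and NUC (normalized uptake change, weak-organic-acid stress) —
  symmetric add-one-in / leave-one-out contributions of a reaction's
  expression change to stress tolerance, normalized by the total
  expression-driven tolerance gain.
* dose-response curves of biomass against WOA uptake under measured,
  absent, or log-scale-extrapolated expression changes.
* normalized SSE metrics, parameter sensitivity sweeps, and correlations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product as _iproduct
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import pearsonr

from .parameterize import extrapolate_expression
from .ratelaws import ExpressionVector, KineticModel
from .solver import (
    ChemostatSetup,
    SolverError,
    simulate_chemostat,
    solve_steady_state,
    washout_boundary,
)

logger = logging.getLogger(__name__)


class MetricError(ValueError):
    """Undefined analysis metric (empty overlap, zero denominator, ...)."""


# ---------------------------------------------------------------------------
# error metrics
# ---------------------------------------------------------------------------


def sse_log_concentrations(
    predicted: Mapping[str, float], observed: Mapping[str, float]
) -> float:
    """Sum of squared log-differences over the shared metabolite ids."""
    shared = sorted(set(predicted) & set(observed))
    if not shared:
        raise MetricError("no shared metabolite ids between prediction and data")
    total = 0.0
    for m in shared:
        p, o = predicted[m], observed[m]
        if p <= 0 or o <= 0:
            raise MetricError(f"nonpositive concentration ratio for {m}")
        total += (math.log(p) - math.log(o)) ** 2
    return total


def normalized_sse_fluxes(
    predicted: Mapping[str, float],
    experimental_treated: Mapping[str, float],
    experimental_reference: Mapping[str, float],
) -> float:
    """SSE of predictions against the treated culture, normalized by the SSE
    between the reference and treated experimental values; 1.0 corresponds
    to predicting the reference state."""
    shared = sorted(
        set(predicted) & set(experimental_treated) & set(experimental_reference)
    )
    if not shared:
        raise MetricError("no shared flux ids")
    num = sum((predicted[k] - experimental_treated[k]) ** 2 for k in shared)
    den = sum(
        (experimental_reference[k] - experimental_treated[k]) ** 2 for k in shared
    )
    if den == 0:
        raise MetricError("reference and treated measurements identical (SSE 0)")
    return num / den


def pearson_correlation(
    x: Sequence[float], y: Sequence[float], log_scale: bool = False
) -> float:
    """Product-moment correlation, optionally on logarithms."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise MetricError("need at least 3 paired values")
    if log_scale:
        if np.any(x <= 0) or np.any(y <= 0):
            raise MetricError("log-scale correlation needs positive values")
        x, y = np.log(x), np.log(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise MetricError("zero variance in correlation input")
    return float(pearsonr(x, y)[0])


# ---------------------------------------------------------------------------
# mechanism-of-action ranking
# ---------------------------------------------------------------------------


@dataclass
class PerturbationResult:
    reaction_id: str
    direction: str  # whole | forward | backward
    optimal_factor: float
    sse: float
    normalized_sse: float
    converged: bool = True


def _intracellular_scope(model: KineticModel) -> list[str]:
    internal = set(model.internal_ids)
    out = []
    for r in model.network.reactions:
        if r.kinetic_class == "fixed_exchange":
            continue
        touched = [m for m in r.stoich if m in internal]
        if touched:
            out.append(r.id)
    return out


def rank_targets(
    model: KineticModel,
    observed: Mapping[str, float],
    k_bounds: tuple[float, float] = (0.1, 10.0),
    scope: Iterable[str] | None = None,
    log_tol: float = 1e-3,
) -> list[PerturbationResult]:
    """Rank reactions by how much a single rate perturbation explains data.

    For each reaction in scope (each direction separately for reversible
    reactions) the scaling factor within ``k_bounds`` minimizing the
    log-concentration SSE of the re-solved steady state is found by bounded
    scalar search on the log factor; results are sorted ascending by SSE
    normalized to the unperturbed model's SSE, nonconverged cases last,
    ties broken by reaction id.
    """
    baseline = solve_steady_state(model)
    sse0 = sse_log_concentrations(baseline.c, observed)
    if scope is None:
        scope = _intracellular_scope(model)
    lo, hi = math.log(k_bounds[0]), math.log(k_bounds[1])

    results: list[PerturbationResult] = []
    for rid in scope:
        rxn = model.network.reaction(rid)
        directions = ("forward", "backward") if rxn.reversible else ("whole",)
        for direction in directions:
            warm = dict(baseline.c)

            def objective(logk: float) -> float:
                pert = model.with_rate_scaling(rid, math.exp(logk), direction)
                try:
                    sol = solve_steady_state(pert, start=warm)
                except SolverError:
                    return 1e6 + abs(logk)
                warm.update(sol.c)
                return sse_log_concentrations(sol.c, observed)

            res = minimize_scalar(
                objective, bounds=(lo, hi), method="bounded",
                options={"xatol": log_tol},
            )
            k_opt, sse_opt = float(math.exp(res.x)), float(res.fun)
            if sse_opt > sse0:  # factor 1 is always admissible
                k_opt, sse_opt = 1.0, sse0
            converged = sse_opt < 1e6
            results.append(
                PerturbationResult(
                    reaction_id=rid,
                    direction=direction,
                    optimal_factor=k_opt if converged else float("nan"),
                    sse=sse_opt if converged else float("inf"),
                    normalized_sse=(sse_opt / sse0) if (converged and sse0 > 0) else (
                        1.0 if converged else float("inf")
                    ),
                    converged=converged,
                )
            )
    results.sort(key=lambda p: (not p.converged, p.normalized_sse, p.reaction_id, p.direction))
    return results


def rank_table(results: Sequence[PerturbationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "reaction_id": p.reaction_id,
                "direction": p.direction,
                "optimal_factor": p.optimal_factor,
                "sse": p.sse,
                "normalized_sse": p.normalized_sse,
                "converged": p.converged,
            }
            for p in results
        ]
    )


# ---------------------------------------------------------------------------
# inhibition tolerance (NTC)
# ---------------------------------------------------------------------------


def inhibition_schedule(k_his: float, floor: float = 1e-6) -> float:
    """Coupled serine->glycine inhibition varying linearly with k_his.

    Interpolates through (1.0, 1.0) and (0.487, 0.0227): the histidine-
    pathway inhibitor also depletes the one-carbon cofactor feeding glycine
    synthesis, so both inhibitions deepen together.
    """
    slope = (1.0 - 0.0227) / (1.0 - 0.487)
    return max(floor, 1.0 + slope * (k_his - 1.0))


def tolerance_inhibition(
    build_model: Callable[[float, ExpressionVector], KineticModel],
    expression: ExpressionVector,
    setup: ChemostatSetup,
    rel_width: float = 1e-3,
) -> float:
    """Maximum tolerated inhibition depth ``1 - k_his`` before washout.

    ``build_model(k_his, expression)`` applies the inhibition (and any
    coupled schedule) to the model under the given expression state; the
    washout boundary over k_his in [0, 1] is located by bisection.
    """
    depth = washout_boundary(
        lambda level: build_model(1.0 - level, expression),
        setup,
        lo=0.0,
        hi=1.0,
        rel_width=rel_width,
    )
    if depth == 0.0:
        logger.warning("culture washes out already without inhibition; tolerance 0")
    return depth


def _subset_expression(
    g: ExpressionVector, subset: Iterable[str], keep: bool
) -> ExpressionVector:
    """Expression with only the subset's changes (keep=True) or all but them."""
    subset = set(subset)
    if keep:
        return ExpressionVector(g={rid: v for rid, v in g.g.items() if rid in subset})
    return ExpressionVector(g={rid: v for rid, v in g.g.items() if rid not in subset})


def _contribution(
    tolerance: Callable[[ExpressionVector], float],
    g: ExpressionVector,
    subset: Iterable[str],
    tol_ged: float | None,
    tol_noged: float | None,
) -> float:
    subset = sorted(set(subset))
    if tol_ged is None:
        tol_ged = tolerance(g)
    if tol_noged is None:
        tol_noged = tolerance(ExpressionVector())
    delta = tol_ged - tol_noged
    if delta == 0:
        raise MetricError(
            "expression changes do not move the tolerance (delta = 0); "
            "the normalized contribution is undefined"
        )
    if all(g[rid] == 1.0 for rid in subset):
        return 0.0
    tol_add = tolerance(_subset_expression(g, subset, keep=True))
    tol_drop = tolerance(_subset_expression(g, subset, keep=False))
    return 0.5 * ((tol_add - tol_noged) + (tol_ged - tol_drop)) / delta


def ntc(
    build_model: Callable[[float, ExpressionVector], KineticModel],
    g: ExpressionVector,
    subset: Iterable[str],
    setup: ChemostatSetup,
    rel_width: float = 1e-3,
    tol_ged: float | None = None,
    tol_noged: float | None = None,
) -> float:
    """Normalized tolerance change of a reaction subset under inhibition stress.

    Average of the add-one-in and leave-one-out tolerance changes for the
    subset's expression ratios, normalized by the total expression-driven
    tolerance gain.  Subsets of size 2-3 give pair/triplet contributions.
    """

    def tolerance(expr: ExpressionVector) -> float:
        return tolerance_inhibition(build_model, expr, setup, rel_width)

    return _contribution(tolerance, g, subset, tol_ged, tol_noged)


# ---------------------------------------------------------------------------
# WOA tolerance (NUC) and dose-response
# ---------------------------------------------------------------------------


def tolerance_woa(
    build_model: Callable[[float, ExpressionVector], KineticModel],
    expression: ExpressionVector,
    setup: ChemostatSetup,
    biomass_fraction: float = 0.05,
    uptake_cap: float = 1e3,
    rel_width: float = 1e-3,
) -> float:
    """WOA uptake rate that reduces biomass to the given fraction of reference.

    ``build_model(woa_uptake, expression)`` applies the uptake burden; the
    boundary is located by bisection on the uptake rate, growing the upper
    bracket geometrically up to ``uptake_cap``.
    """
    if not (0 < biomass_fraction < 1):
        raise MetricError("biomass_fraction must be in (0, 1)")

    def survives(level: float) -> bool:
        sol = simulate_chemostat(build_model(level, expression), setup)
        return (not sol.washed_out) and sol.biomass >= (
            biomass_fraction * setup.reference_biomass
        )

    if not survives(0.0):
        logger.warning("biomass below the fraction already at zero uptake; tolerance 0")
        return 0.0
    hi = 1.0
    while survives(hi) and hi < uptake_cap:
        hi *= 2.0
    lo = hi / 2.0 if hi > 1.0 else 0.0
    return washout_boundary(
        lambda level: build_model(level, expression),
        setup,
        lo=lo,
        hi=hi,
        rel_width=rel_width,
        floor_fraction=biomass_fraction,
    )


def nuc(
    build_model: Callable[[float, ExpressionVector], KineticModel],
    g: ExpressionVector,
    subset: Iterable[str],
    setup: ChemostatSetup,
    biomass_fraction: float = 0.05,
    rel_width: float = 1e-3,
    wur_ged: float | None = None,
    wur_noged: float | None = None,
) -> float:
    """Normalized uptake change: NTC algebra with the tolerated WOA uptake."""

    def tolerance(expr: ExpressionVector) -> float:
        return tolerance_woa(build_model, expr, setup, biomass_fraction,
                             rel_width=rel_width)

    return _contribution(tolerance, g, subset, wur_ged, wur_noged)


@dataclass
class DoseResponseCurve:
    uptake_grid: list[float]
    biomass: dict[str, list[float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.biomass, index=pd.Index(self.uptake_grid, name="uptake"))


def dose_response(
    build_model: Callable[[float, ExpressionVector], KineticModel],
    g: ExpressionVector,
    uptake_grid: Sequence[float],
    setup: ChemostatSetup,
    scenarios: Mapping[str, ExpressionVector] | None = None,
    extrapolation_factor: float = 2.0,
) -> DoseResponseCurve:
    """Biomass against WOA uptake for measured (GED), absent (No GED) and
    log-scale-extrapolated expression states; washout encoded as biomass 0."""
    grid = list(uptake_grid)
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise MetricError("uptake grid must be nondecreasing")
    if scenarios is None:
        scenarios = {
            "GED": g,
            "NoGED": ExpressionVector(),
            "extrapolated": extrapolate_expression(g, extrapolation_factor),
        }
    curve = DoseResponseCurve(uptake_grid=grid)
    for name, expr in scenarios.items():
        values = []
        for uptake in grid:
            sol = simulate_chemostat(build_model(uptake, expr), setup)
            values.append(0.0 if sol.washed_out else sol.biomass)
        curve.biomass[name] = values
    return curve


# ---------------------------------------------------------------------------
# sensitivity sweeps
# ---------------------------------------------------------------------------


def sensitivity_sweep(
    build_model: Callable[..., KineticModel],
    grid: Mapping[str, Sequence[float]],
    metric: Callable[[KineticModel], float],
) -> pd.DataFrame:
    """Evaluate a metric over the cartesian product of parameter values.

    ``build_model(**point)`` assembles the model at one grid point; rows
    where the metric raises a solver error are flagged nonconverged.
    """
    names = sorted(grid)
    rows = []
    for combo in _iproduct(*(grid[n] for n in names)):
        point = dict(zip(names, combo))
        row = dict(point)
        try:
            row["metric"] = metric(build_model(**point))
            row["converged"] = True
        except (SolverError, MetricError) as exc:
            row["metric"] = float("nan")
            row["converged"] = False
            logger.warning("sweep point %s failed: %s", point, exc)
        rows.append(row)
    return pd.DataFrame(rows, columns=names + ["metric", "converged"])
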