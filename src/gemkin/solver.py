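"""Steady-state and chemostat solving.

The steady state of the kinetic model is the root of ``f(c) = S r(c) = 0``
over internal metabolites.  The search runs in log-concentration
coordinates, which guarantees positivity without constraints; conditions
are perturbations of the reference so ``c = 1`` is the natural start.  A
damped Newton / trust-region root search is attempted first, with dynamic
relaxation (stiff ODE integration of ``C dc/dt = S r(c)``) as a fallback
and as an independent oracle, followed by a final polish.

The chemostat layer couples the intracellular model to the culture: the
growth rate must equal the dilution rate D, which is achieved by letting
the extracellular substrate concentration s float (it feeds back on the
uptake rate), and the biomass X follows from the substrate balance
``D (feed - s) = q_glc(s, c) X``.  Washout is the loss of any solution
with X above a small floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .ratelaws import KineticModel

logger = logging.getLogger(__name__)


class SolverError(RuntimeError):
    """Steady-state or chemostat solution not found."""

    def __init__(self, message: str, best=None, residual: float | None = None):
        super().__init__(message)
        self.best = best
        self.residual = residual


@dataclass
class SteadyStateSolution:
    c: dict[str, float]
    r: dict[str, float]
    residual_norm: float
    converged: bool
    iterations: int
    method: str = "root"

    def concentration_vector(self, ids) -> np.ndarray:
        return np.array([self.c[m] for m in ids])


@dataclass
class ChemostatSetup:
    """Chemostat context: dilution rate, feed, and the glucose coupling."""

    dilution_rate: float
    glucose_uptake_reaction: str
    glucose_species: str
    feed_glucose: float = 0.0  # set by calibrate_chemostat
    reference_biomass: float = 1.0
    biomass_floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.dilution_rate <= 0:
            raise ValueError("dilution rate must be positive")
        if not (0 < self.biomass_floor < 1):
            raise ValueError("biomass_floor must be in (0, 1)")


@dataclass
class ChemostatSolution:
    inner: SteadyStateSolution
    biomass: float
    extracellular_glucose: float
    washed_out: bool
    growth_rate: float


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------


def _scale(model: KineticModel) -> float:
    vmax = max((abs(v) for v in model.reference.v.values()), default=1.0)
    return max(1.0, vmax)


def _residual_fn(model: KineticModel, extra: Mapping[str, float] | None = None):
    ids = model.internal_ids

    def fn(x: np.ndarray) -> np.ndarray:
        c = dict(zip(ids, np.exp(np.clip(x, -60.0, 60.0))))
        if extra:
            c.update(extra)
        return model.balances(c)

    return fn


def solve_steady_state(
    model: KineticModel,
    start: Mapping[str, float] | None = None,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> SteadyStateSolution:
    """Root of ``S r(c) = 0`` in log-concentration space.

    Tries scipy's hybrid Powell and Levenberg-Marquardt root searches; if
    both stall, relaxes dynamically toward the attractor and re-polishes.
    Raises :class:`SolverError` (carrying the best iterate) on failure.
    """
    ids = model.internal_ids
    scale = _scale(model)
    target = tol * scale
    x0 = np.zeros(len(ids))
    if start is not None:
        x0 = np.log(np.array([start.get(m, 1.0) for m in ids]))
    fn = _residual_fn(model)

    best_x, best_res = x0, float(np.abs(fn(x0)).max())
    iterations = 0
    method_used = "start"
    if best_res > target:
        for method in ("hybr", "lm"):
            try:
                sol = root(fn, best_x, method=method, tol=tol * 1e-3)
            except Exception:  # pragma: no cover - scipy internals
                continue
            iterations += int(sol.nfev)
            res = float(np.abs(fn(sol.x)).max())
            if res < best_res:
                best_x, best_res, method_used = sol.x, res, method
            if best_res <= target:
                break

    if best_res > target:
        relaxed = _relax(model, np.exp(best_x), horizon=1e5, tol=tol)
        if relaxed is not None:
            x1 = np.log(relaxed)
            sol = root(fn, x1, method="hybr", tol=tol * 1e-3)
            iterations += int(sol.nfev)
            for cand in (sol.x, x1):
                res = float(np.abs(fn(cand)).max())
                if res < best_res:
                    best_x, best_res, method_used = cand, res, "relax+polish"

    c = dict(zip(ids, np.exp(best_x)))
    converged = best_res <= target
    solution = SteadyStateSolution(
        c=c,
        r=model.rates(c),
        residual_norm=best_res,
        converged=converged,
        iterations=iterations,
        method=method_used,
    )
    if not converged:
        raise SolverError(
            f"steady-state search did not converge (residual {best_res:.3g} "
            f"> {target:.3g})",
            best=solution,
            residual=best_res,
        )
    return solution


def _relax(
    model: KineticModel,
    c0: np.ndarray,
    horizon: float,
    tol: float,
    C: np.ndarray | None = None,
) -> np.ndarray | None:
    ids = model.internal_ids
    n = len(ids)
    Cvec = np.ones(n) if C is None else C
    lo, hi = 1e-9, 1e9

    def rhs(_t, y):
        c = dict(zip(ids, np.clip(y, lo, hi)))
        return model.balances(c) / Cvec

    try:
        out = solve_ivp(
            rhs, (0.0, horizon), c0, method="LSODA", rtol=1e-10, atol=1e-12,
            dense_output=False,
        )
    except Exception:  # pragma: no cover
        return None
    y = out.y[:, -1]
    if not np.all(np.isfinite(y)) or np.any(y <= lo * 2) or np.any(y >= hi / 2):
        return None
    return np.clip(y, lo, hi)


def relax_to_steady_state(
    model: KineticModel,
    c0: Mapping[str, float] | None = None,
    C: Mapping[str, float] | None = None,
    horizon: float = 1e5,
    tol: float = 1e-9,
) -> SteadyStateSolution:
    """Integrate ``C dc/dt = S r(c)`` until quiescence (independent oracle).

    Steady states are independent of the normalization concentrations ``C``;
    they only shape the transient.
    """
    ids = model.internal_ids
    y0 = np.ones(len(ids))
    if c0 is not None:
        y0 = np.array([c0.get(m, 1.0) for m in ids])
    Cvec = None
    if C is not None:
        Cvec = np.array([C.get(m, 1.0) for m in ids])
        if np.any(Cvec <= 0):
            raise SolverError("normalization concentrations must be positive")
    scale = _scale(model)
    y = _relax(model, y0, horizon, tol, Cvec)
    if y is None:
        raise SolverError("dynamic relaxation diverged (concentration out of bounds)")
    c = dict(zip(ids, y))
    res = float(np.abs(model.balances(c)).max())
    return SteadyStateSolution(
        c=c,
        r=model.rates(c),
        residual_norm=res,
        converged=res <= max(tol * scale, 1e-6 * scale),
        iterations=0,
        method="relaxation",
    )


# ---------------------------------------------------------------------------
# chemostat
# ---------------------------------------------------------------------------


def _chemostat_inner(
    model: KineticModel, setup: ChemostatSetup, tol: float
) -> tuple[SteadyStateSolution, float, float] | None:
    """Solve intracellular balances plus mu = D for (c, s); None if infeasible."""
    ids = model.internal_ids
    D = setup.dilution_rate
    fn_ids = ids + ["__s__"]

    def fn(x: np.ndarray) -> np.ndarray:
        xc = np.clip(x, -60.0, 60.0)
        c = dict(zip(ids, np.exp(xc[:-1])))
        s = float(np.exp(xc[-1]))
        c[setup.glucose_species] = s
        bal = model.balances(c)
        mu = model.growth_rate(c)
        return np.append(bal, (mu - D) / max(D, 1e-12))

    scale = _scale(model)
    x0 = np.zeros(len(fn_ids))
    best = None
    for attempt, guess in enumerate((x0, x0 + 0.5, x0 - 0.5)):
        try:
            sol = root(fn, guess, method="hybr", tol=1e-12)
        except Exception:  # pragma: no cover
            continue
        res = float(np.abs(fn(sol.x)).max())
        if best is None or res < best[1]:
            best = (sol.x, res)
        if res <= tol * scale:
            break
    if best is None or best[1] > tol * scale:
        return None
    x = best[0]
    c = dict(zip(ids, np.exp(x[:-1])))
    s = float(np.exp(x[-1]))
    c_full = dict(c)
    c_full[setup.glucose_species] = s
    rates = model.rates(c_full)
    inner = SteadyStateSolution(
        c=c,
        r=rates,
        residual_norm=best[1],
        converged=True,
        iterations=0,
        method="chemostat",
    )
    mu = model.growth_rate(c_full)
    return inner, s, mu


def simulate_chemostat(
    model: KineticModel, setup: ChemostatSetup, tol: float = 1e-9
) -> ChemostatSolution:
    """Joint culture steady state: balances, growth at D, substrate balance.

    Returns a washed-out solution (X = 0) when no steady state sustains a
    biomass of at least ``biomass_floor`` times the reference.
    """
    if setup.feed_glucose <= 0:
        raise SolverError(
            "feed_glucose not set; run calibrate_chemostat on the reference model"
        )
    got = _chemostat_inner(model, setup, tol)
    if got is None:
        return _washed_out(model, setup)
    inner, s, mu = got
    D = setup.dilution_rate
    q = inner.r[setup.glucose_uptake_reaction]
    if q <= 0 or s >= setup.feed_glucose:
        return _washed_out(model, setup)
    X = D * (setup.feed_glucose - s) / q
    if X < setup.biomass_floor * setup.reference_biomass:
        return _washed_out(model, setup)
    return ChemostatSolution(
        inner=inner,
        biomass=X,
        extracellular_glucose=s,
        washed_out=False,
        growth_rate=mu,
    )


def _washed_out(model: KineticModel, setup: ChemostatSetup) -> ChemostatSolution:
    empty = SteadyStateSolution(
        c={}, r={}, residual_norm=float("nan"), converged=False, iterations=0,
        method="washed_out",
    )
    return ChemostatSolution(
        inner=empty,
        biomass=0.0,
        extracellular_glucose=setup.feed_glucose,
        washed_out=True,
        growth_rate=0.0,
    )


def calibrate_chemostat(
    model: KineticModel, setup: ChemostatSetup
) -> tuple[float, float]:
    """Calibrate (lambda, feed) so the reference culture sits at X = 1, s = 1.

    lambda is the growth correction making the raw reference growth rate
    equal the dilution rate; the feed closes the substrate balance at the
    reference uptake.  Returns the calibrated ``(lambda, feed_glucose)`` and
    writes them into ``model.params`` / ``setup``.
    """
    ref = solve_steady_state(model)
    c = dict(ref.c)
    c[setup.glucose_species] = 1.0
    mu_raw = model.growth_rate(c) / model.params.lambda_growth
    if mu_raw <= 0:
        raise SolverError("reference growth rate is zero; cannot calibrate")
    lam = setup.dilution_rate / mu_raw
    q_ref = ref.r[setup.glucose_uptake_reaction]
    if q_ref <= 0:
        raise SolverError("reference glucose uptake is nonpositive; cannot calibrate")
    feed = 1.0 + q_ref * setup.reference_biomass / setup.dilution_rate
    model.params.lambda_growth = lam
    setup.feed_glucose = feed
    return lam, feed


# ---------------------------------------------------------------------------
# washout bisection helpers (shared by the tolerance analyses)
# ---------------------------------------------------------------------------


def washout_boundary(
    build_model,
    setup: ChemostatSetup,
    lo: float,
    hi: float,
    rel_width: float = 1e-3,
    floor_fraction: float | None = None,
) -> float:
    """Largest stress level in [lo, hi] the culture survives, by bisection.

    ``build_model(level)`` returns the stressed model; survival means a
    non-washed-out chemostat solution (with biomass above
    ``floor_fraction`` of reference when given).  Assumes survival is
    monotone in the level: survives at ``lo``; if it also survives at
    ``hi``, returns ``hi``.
    """

    def survives(level: float) -> bool:
        sol = simulate_chemostat(build_model(level), setup)
        if sol.washed_out:
            return False
        if floor_fraction is not None:
            return sol.biomass >= floor_fraction * setup.reference_biomass
        return True

    if not survives(lo):
        return lo
    if survives(hi):
        return hi
    a, b = lo, hi
    span = max(abs(hi - lo), 1e-12)
    while (b - a) > rel_width * span:
        mid = 0.5 * (a + b)
        if survives(mid):
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)
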