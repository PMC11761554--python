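"""Box-constrained trust-region conjugate-gradient (TRCG) least squares.

Each voxel is fit by minimizing ``||s - f(theta)||^2`` over the parameter
box.  The solver is a Gauss-Newton trust-region method whose quadratic
subproblem is solved by Steihaug conjugate gradients; proposed iterates
are projected onto the box and the acceptance ratio is re-evaluated with
the projected step.  One "NLS iteration" is one outer trust-region step
(one Jacobian evaluation plus one CG subproblem), which is the quantity
capped by the iteration budget.

Internally the parameters are scaled to the unit box
``x = (theta - lo) / (hi - lo)`` so the trust region is isotropic across
parameters whose natural units differ by orders of magnitude (relaxation
times in ms versus dimensionless fractions).

An optional Tikhonov penalty ``lam * ||(theta - mid) / (hi - lo)||^2``
pulling parameters toward their range midpoints turns the objective into
a simple regularized NLS (set ``penalty_weight > 0``).

The whole solver is vectorized over voxels: a map fit advances all still
active voxels in lock-step and drops voxels as they converge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .models import (
    ParamBounds,
    TSLSchedule,
    analytic_jacobian,
    default_bounds,
    evaluate,
    param_count,
    params_from_array,
)

__all__ = [
    "NLSConfig",
    "FitResult",
    "MapFitResult",
    "default_initial_guess",
    "initial_guess_table",
    "nls_fit_voxel",
    "nls_fit_map",
]

_MIN_RADIUS = 1e-13
_MAX_RADIUS = 1e3


@dataclass(frozen=True)
class NLSConfig:
    """Solver controls.

    ``max_iterations`` caps outer trust-region steps (2000 for reference
    fits).  ``penalty_weight`` enables the regularized-NLS option.
    """

    max_iterations: int = 2000
    initial_radius: float = 1.0
    cg_max_iter: int | None = None  # default: 5 * number of parameters
    accept_ratio: float = 0.05
    shrink_factor: float = 0.25
    grow_factor: float = 2.0
    grad_tol: float = 1e-10
    bounds: ParamBounds | None = None
    penalty_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if min(self.initial_radius, self.accept_ratio, self.shrink_factor,
               self.grow_factor, self.grad_tol) <= 0:
            raise ValueError("trust-region controls must be positive")
        if self.penalty_weight < 0:
            raise ValueError("penalty_weight must be >= 0")


@dataclass(frozen=True)
class FitResult:
    """Per-voxel fit outcome."""

    params: np.ndarray          # (p,) in natural units
    residual_norm: float        # ||s - f(theta)||_2
    iterations_used: int
    converged: bool
    residual_trace: np.ndarray | None = None

    def typed_params(self, model: str):
        return params_from_array(model, self.params)


@dataclass
class MapFitResult:
    """Voxel-wise fit outcomes over a signal table.

    Masked-out voxels carry NaN parameters, NaN residual norm, zero
    iterations and ``converged=False`` (sentinel results).
    """

    model: str
    params: np.ndarray          # (n, p); NaN rows where masked out
    residual_norm: np.ndarray   # (n,)
    iterations_used: np.ndarray # (n,)
    converged: np.ndarray       # (n,) bool
    mask: np.ndarray            # (n,) bool; False = not fitted

    def __len__(self) -> int:
        return self.params.shape[0]

    def __getitem__(self, i: int) -> FitResult:
        return FitResult(
            params=self.params[i],
            residual_norm=float(self.residual_norm[i]),
            iterations_used=int(self.iterations_used[i]),
            converged=bool(self.converged[i]),
        )


# ---------------------------------------------------------------------------
# initial guesses

def initial_guess_table(
    model: str,
    signals: np.ndarray,
    schedule: TSLSchedule,
    bounds: ParamBounds | None = None,
) -> np.ndarray:
    """Data-driven starting points for a table of signals.

    ME/SE: amplitude from the first sample and T from a log-linear
    regression of ``log(s)`` on ``t`` (beta starts at 1).  BE: amplitude
    from the first sample, ``phi_f = 0.5``, and the short/long times at the
    geometric midpoints of their ranges.  Rows whose samples are all
    non-positive fall back to the midpoint of the bounds (with a warning).
    """
    bounds = bounds or default_bounds(model)
    s = np.atleast_2d(np.asarray(signals, dtype=float))
    t = schedule.array
    if s.shape[1] != t.size:
        raise ValueError("signal length does not match schedule")
    n = s.shape[0]
    p = param_count(model)
    theta = np.empty((n, p), dtype=float)
    theta[:, 0] = s[:, 0]

    if model == "be":
        theta[:, 1] = 0.5
        theta[:, 2] = np.sqrt(bounds.lo[2] * bounds.hi[2])
        theta[:, 3] = np.sqrt(bounds.lo[3] * bounds.hi[3])
    else:
        # slope of log-signal vs t; T = -1/slope for decaying signals
        y = np.log(np.maximum(s, 1e-12))
        tc = t - t.mean()
        slope = (y @ tc) / (tc @ tc)
        with np.errstate(divide="ignore"):
            T_est = np.where(slope < 0, -1.0 / np.minimum(slope, -1e-300), np.inf)
        theta[:, 1] = T_est
        if model == "se":
            theta[:, 2] = 1.0

    bad = ~np.any(s > 0, axis=1)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} signal row(s) have no positive samples; "
            "falling back to midpoint-of-bounds initial guess",
            stacklevel=2,
        )
        theta[bad] = bounds.mid
    theta = np.clip(theta, bounds.lo, bounds.hi)
    if np.asarray(signals).ndim == 1:
        return theta[0]
    return theta


def default_initial_guess(
    model: str,
    signal: Sequence[float],
    schedule: TSLSchedule,
    bounds: ParamBounds | None = None,
):
    """Typed single-voxel starting point (see :func:`initial_guess_table`)."""
    theta = initial_guess_table(model, np.asarray(signal, dtype=float), schedule, bounds)
    return params_from_array(model, theta)


# ---------------------------------------------------------------------------
# batched Steihaug-CG trust-region core (unit-box scaled coordinates)

def _boundary_tau(d: np.ndarray, pdir: np.ndarray, radius: np.ndarray) -> np.ndarray:
    """Positive root of ||d + tau * pdir|| = radius, elementwise over rows."""
    a = np.sum(pdir * pdir, axis=1)
    b = 2.0 * np.sum(d * pdir, axis=1)
    c = np.sum(d * d, axis=1) - radius**2
    disc = np.maximum(b * b - 4.0 * a * c, 0.0)
    a = np.maximum(a, 1e-300)
    return (-b + np.sqrt(disc)) / (2.0 * a)


def _steihaug_cg(Js, g, lam, radius, max_cg, tol_sq):
    """Solve min_d g.d + 0.5 d.H.d, H = 2 Js^T Js + 2 lam I, ||d|| <= radius.

    All arguments are batched over the leading axis; returns the step d.
    """
    na, p = g.shape
    d = np.zeros_like(g)
    r = -g
    pdir = r.copy()
    rs = np.sum(r * r, axis=1)
    live = rs > tol_sq
    for _ in range(max_cg):
        if not np.any(live):
            break
        Jp = np.einsum("ntp,np->nt", Js, pdir)
        Hp = 2.0 * np.einsum("ntp,nt->np", Js, Jp) + 2.0 * lam * pdir
        curv = np.sum(pdir * Hp, axis=1)

        neg = live & (curv <= 0)
        if np.any(neg):
            tau = _boundary_tau(d[neg], pdir[neg], radius[neg])
            d[neg] += tau[:, None] * pdir[neg]
            live[neg] = False

        alpha = np.where(curv > 0, rs / np.maximum(curv, 1e-300), 0.0)
        d_new = d + alpha[:, None] * pdir
        crossed = live & (np.linalg.norm(d_new, axis=1) >= radius)
        if np.any(crossed):
            tau = _boundary_tau(d[crossed], pdir[crossed], radius[crossed])
            d[crossed] += tau[:, None] * pdir[crossed]
            live[crossed] = False

        adv = live
        d[adv] = d_new[adv]
        r[adv] -= alpha[adv, None] * Hp[adv]
        rs_new = np.sum(r * r, axis=1)
        live = live & (rs_new > tol_sq)
        beta = np.where(rs > 0, rs_new / np.maximum(rs, 1e-300), 0.0)
        pdir[adv] = r[adv] + beta[adv, None] * pdir[adv]
        rs = rs_new
    return d


def _fit_batch(
    signals: np.ndarray,
    schedule: TSLSchedule,
    model: str,
    inits: np.ndarray,
    config: NLSConfig,
    trace: bool = False,
):
    """Run the TRCG solver on every row; returns arrays keyed per voxel."""
    t = schedule.array
    s = np.atleast_2d(np.asarray(signals, dtype=float))
    if not np.all(np.isfinite(s)):
        raise ValueError("signals contain non-finite values")
    th0 = np.atleast_2d(np.asarray(inits, dtype=float))
    n, p = th0.shape
    if s.shape[0] != n:
        raise ValueError("signals and inits row counts disagree")
    if s.shape[1] != t.size:
        raise ValueError("signal length does not match schedule")
    if p != param_count(model):
        raise ValueError("init table has wrong parameter count")

    bounds = config.bounds or default_bounds(model)
    lo, rng_ = bounds.lo, bounds.range
    if np.any(th0 < bounds.lo - 1e-12) or np.any(th0 > bounds.hi + 1e-12):
        raise ValueError("initial guesses must lie within bounds")
    lam = config.penalty_weight
    max_cg = config.cg_max_iter if config.cg_max_iter is not None else 5 * p

    x = np.clip((th0 - lo) / rng_, 0.0, 1.0)

    def fwd(xa):
        return evaluate(model, lo + xa * rng_, t, check=False)

    f = fwd(x)
    r = s - f
    cost = np.sum(r * r, axis=1) + lam * np.sum((x - 0.5) ** 2, axis=1)

    radius = np.full(n, config.initial_radius)
    iters = np.zeros(n, dtype=int)
    converged = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)
    traces = [[np.linalg.norm(r[i])] for i in range(n)] if trace else None

    if config.max_iterations == 0:
        active[:] = False

    for _ in range(config.max_iterations):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        xa = x[idx]
        theta_a = lo + xa * rng_
        J = analytic_jacobian(model, theta_a, t, check=False)
        Js = J * rng_[None, None, :]
        ra = s[idx] - evaluate(model, theta_a, t, check=False)
        g = -2.0 * np.einsum("ntp,nt->np", Js, ra) + 2.0 * lam * (xa - 0.5)

        # projected-gradient stationarity on the unit box
        pg = xa - np.clip(xa - g, 0.0, 1.0)
        stat = np.max(np.abs(pg), axis=1) <= config.grad_tol
        if np.any(stat):
            sub = idx[stat]
            converged[sub] = True
            active[sub] = False
            keep = ~stat
            if not np.any(keep):
                continue
            idx, xa, g = idx[keep], xa[keep], g[keep]
            Js, ra = Js[keep], ra[keep]

        rad = radius[idx]
        d = _steihaug_cg(Js, g, lam, rad, max_cg, tol_sq=1e-28)

        x_prop = np.clip(xa + d, 0.0, 1.0)
        d_eff = x_prop - xa
        Jd = np.einsum("ntp,np->nt", Js, d_eff)
        pred = -(
            np.sum(g * d_eff, axis=1)
            + np.sum(Jd * Jd, axis=1)
            + lam * np.sum(d_eff * d_eff, axis=1)
        )
        f_prop = fwd(x_prop)
        r_prop = s[idx] - f_prop
        cost_prop = np.sum(r_prop * r_prop, axis=1) + lam * np.sum((x_prop - 0.5) ** 2, axis=1)
        actual = cost[idx] - cost_prop

        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(pred > 0, actual / np.maximum(pred, 1e-300), -np.inf)

        accept = (rho >= config.accept_ratio) & (actual > 0)
        acc_idx = idx[accept]
        x[acc_idx] = x_prop[accept]
        cost[acc_idx] = cost_prop[accept]

        hit_boundary = np.linalg.norm(d, axis=1) >= 0.99 * rad
        grow = (rho > 0.75) & hit_boundary
        shrink = rho < 0.25
        radius[idx[grow]] = np.minimum(radius[idx[grow]] * config.grow_factor, _MAX_RADIUS)
        radius[idx[shrink]] = radius[idx[shrink]] * config.shrink_factor

        iters[idx] += 1
        stalled = radius[idx] < _MIN_RADIUS
        active[idx[stalled]] = False

        if trace:
            for k, i in enumerate(idx):
                rn = np.sqrt(max(cost[i] - lam * np.sum((x[i] - 0.5) ** 2), 0.0))
                traces[i].append(rn)

    theta = lo + x * rng_
    f_final = fwd(x)
    res_norm = np.linalg.norm(s - f_final, axis=1)
    out = {
        "params": theta,
        "residual_norm": res_norm,
        "iterations_used": iters,
        "converged": converged,
    }
    if trace:
        out["traces"] = [np.asarray(tr) for tr in traces]
    return out


# ---------------------------------------------------------------------------
# public fitting API

def nls_fit_voxel(
    signal: Sequence[float],
    schedule: TSLSchedule,
    model: str,
    init,
    config: NLSConfig | None = None,
    trace: bool = True,
) -> FitResult:
    """Fit a single voxel signal; records the per-iteration residual trace."""
    config = config or NLSConfig()
    th0 = init.array if hasattr(init, "array") else np.asarray(init, dtype=float)
    out = _fit_batch(
        np.asarray(signal, dtype=float)[None, :], schedule, model,
        th0[None, :], config, trace=trace,
    )
    return FitResult(
        params=out["params"][0],
        residual_norm=float(out["residual_norm"][0]),
        iterations_used=int(out["iterations_used"][0]),
        converged=bool(out["converged"][0]),
        residual_trace=out["traces"][0] if trace else None,
    )


def nls_fit_map(
    signals: np.ndarray,
    schedule: TSLSchedule,
    model: str,
    inits: np.ndarray,
    config: NLSConfig | None = None,
    mask: np.ndarray | None = None,
) -> MapFitResult:
    """Fit every (unmasked) row of a signal table independently.

    Voxels are advanced in lock-step but are mathematically independent:
    the result for row i is identical to :func:`nls_fit_voxel` on row i.
    """
    config = config or NLSConfig()
    s = np.atleast_2d(np.asarray(signals, dtype=float))
    th0 = np.atleast_2d(np.asarray(inits, dtype=float))
    n = s.shape[0]
    if th0.shape[0] != n:
        raise ValueError("signals and inits row counts disagree")
    if mask is None:
        mask = np.ones(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (n,):
        raise ValueError("mask length does not match signal rows")

    p = param_count(model)
    params = np.full((n, p), np.nan)
    res = np.full(n, np.nan)
    iters = np.zeros(n, dtype=int)
    conv = np.zeros(n, dtype=bool)
    if np.any(mask):
        out = _fit_batch(s[mask], schedule, model, th0[mask], config)
        params[mask] = out["params"]
        res[mask] = out["residual_norm"]
        iters[mask] = out["iterations_used"]
        conv[mask] = out["converged"]
    return MapFitResult(
        model=model, params=params, residual_norm=res,
        iterations_used=iters, converged=conv, mask=mask,
    )
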