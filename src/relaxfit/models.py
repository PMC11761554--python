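"""Closed-form relaxation signal models and their analytic Jacobians.

Three voxel-wise decay models are supported, each mapping a parameter
vector ``theta`` and a spin-lock time schedule ``t`` (ms) to a magnitude
signal:

* mono-exponential (``"me"``):      f(t) = A exp(-t / T_me)
* bi-exponential  (``"be"``):       f(t) = A [(1-phi_f) exp(-t/T_s) + phi_f exp(-t/T_l)]
* stretched-exponential (``"se"``): f(t) = A exp(-(t / T_se)^beta)

All evaluation routines are vectorized over voxels: parameter tables are
``(n, p)`` arrays whose column order is fixed per model (see
``param_names``), signals are ``(n, T)`` arrays.  Time is always in
milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "MODEL_TAGS",
    "TSLSchedule",
    "DEFAULT_TSL_MS",
    "MEParams",
    "BEParams",
    "SEParams",
    "ParamBounds",
    "param_names",
    "param_count",
    "default_bounds",
    "evaluate",
    "evaluate_me",
    "evaluate_be",
    "evaluate_se",
    "analytic_jacobian",
    "clip_to_bounds",
    "validate_params",
]

MODEL_TAGS = ("me", "be", "se")

#: Spin-lock times of the six-TSL knee protocol, in ms.
DEFAULT_TSL_MS = (0.05, 0.6, 1.6, 6.0, 16.0, 36.0)

_PARAM_NAMES = {
    "me": ("A", "T_me"),
    "be": ("A", "phi_f", "T_s", "T_l"),
    "se": ("A", "T_se", "beta"),
}

# Fitting ranges: relaxation times 1-300 ms; the BE long component 5-300 ms,
# short component 0.5-4 ms, long fraction 0.01-0.99; beta 0.1-1.  The
# amplitude is bounded by (0, 2*max observed signal]; 2.0 is the default for
# unit-amplitude synthetic data and is rescaled for measured signals.
_DEFAULT_LOWER = {
    "me": (1e-6, 1.0),
    "be": (1e-6, 0.01, 0.5, 5.0),
    "se": (1e-6, 1.0, 0.1),
}
_DEFAULT_UPPER = {
    "me": (2.0, 300.0),
    "be": (2.0, 0.99, 4.0, 300.0),
    "se": (2.0, 300.0, 1.0),
}


class InvalidParameterError(ValueError):
    """A parameter vector violates its model's constraints."""


def _check_tag(model: str) -> str:
    if model not in MODEL_TAGS:
        raise ValueError(f"unknown model tag {model!r}; expected one of {MODEL_TAGS}")
    return model


def param_names(model: str) -> tuple[str, ...]:
    """Ordered parameter names for a model tag."""
    return _PARAM_NAMES[_check_tag(model)]


def param_count(model: str) -> int:
    return len(param_names(model))


@dataclass(frozen=True)
class TSLSchedule:
    """Ordered spin-lock times (ms) at which each voxel signal is sampled."""

    times: tuple[float, ...] = DEFAULT_TSL_MS

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("schedule needs at least two spin-lock times")
        if np.any(t <= 0):
            raise ValueError("all spin-lock times must be positive")
        if np.any(np.diff(t) <= 0):
            raise ValueError("spin-lock times must be strictly increasing")
        object.__setattr__(self, "times", tuple(float(x) for x in t))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class MEParams:
    """Mono-exponential parameters: amplitude and relaxation time (ms)."""

    A: float
    T_me: float

    model = "me"

    def __post_init__(self) -> None:
        if self.A <= 0 or self.T_me <= 0:
            raise InvalidParameterError("ME requires A > 0 and T_me > 0")

    @property
    def array(self) -> np.ndarray:
        return np.array([self.A, self.T_me], dtype=float)


@dataclass(frozen=True)
class BEParams:
    """Bi-exponential parameters.

    ``phi_f`` is the fraction of the long-relaxation compartment; the short
    and long relaxation times ``T_s < T_l`` are kept structurally disjoint
    (0.5-4 ms vs 5-300 ms under the default bounds).  ``phi_f`` values of
    exactly 0 or 1 are allowed for evaluating the single-compartment limits.
    """

    A: float
    phi_f: float
    T_s: float
    T_l: float

    model = "be"

    def __post_init__(self) -> None:
        if self.A <= 0 or self.T_s <= 0 or self.T_l <= 0:
            raise InvalidParameterError("BE requires positive A, T_s, T_l")
        if not 0.0 <= self.phi_f <= 1.0:
            raise InvalidParameterError("BE requires 0 <= phi_f <= 1")
        if self.T_s >= self.T_l:
            raise InvalidParameterError("BE requires T_s < T_l")

    @property
    def array(self) -> np.ndarray:
        return np.array([self.A, self.phi_f, self.T_s, self.T_l], dtype=float)


@dataclass(frozen=True)
class SEParams:
    """Stretched-exponential parameters; ``beta`` = 1 reduces to ME."""

    A: float
    T_se: float
    beta: float

    model = "se"

    def __post_init__(self) -> None:
        if self.A <= 0 or self.T_se <= 0:
            raise InvalidParameterError("SE requires A > 0 and T_se > 0")
        if not 0.0 < self.beta <= 1.0:
            raise InvalidParameterError("SE requires 0 < beta <= 1")

    @property
    def array(self) -> np.ndarray:
        return np.array([self.A, self.T_se, self.beta], dtype=float)


ModelParams = MEParams | BEParams | SEParams

_PARAM_CLS = {"me": MEParams, "be": BEParams, "se": SEParams}


def params_from_array(model: str, theta: Sequence[float]) -> ModelParams:
    """Build a typed parameter object from an ordered vector."""
    return _PARAM_CLS[_check_tag(model)](*(float(x) for x in theta))


@dataclass(frozen=True)
class ParamBounds:
    """Per-parameter box constraints, in each parameter's own units."""

    model: str
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        _check_tag(self.model)
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        p = param_count(self.model)
        if lo.shape != (p,) or hi.shape != (p,):
            raise ValueError(f"bounds for {self.model!r} need {p} entries per side")
        if np.any(lo >= hi):
            raise ValueError("lower bounds must be elementwise below upper bounds")
        object.__setattr__(self, "lower", tuple(float(x) for x in lo))
        object.__setattr__(self, "upper", tuple(float(x) for x in hi))

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.lower, dtype=float)

    @property
    def hi(self) -> np.ndarray:
        return np.asarray(self.upper, dtype=float)

    @property
    def range(self) -> np.ndarray:
        return self.hi - self.lo

    @property
    def mid(self) -> np.ndarray:
        return 0.5 * (self.lo + self.hi)

    def with_amplitude_cap(self, max_signal: float) -> "ParamBounds":
        """Rescale the amplitude box to (0, 2 * max observed signal]."""
        hi = list(self.upper)
        hi[0] = 2.0 * float(max_signal)
        return ParamBounds(self.model, self.lower, tuple(hi))


def default_bounds(model: str) -> ParamBounds:
    """The default fitting box for a model tag."""
    m = _check_tag(model)
    return ParamBounds(m, _DEFAULT_LOWER[m], _DEFAULT_UPPER[m])


def _as_table(theta, p: int) -> np.ndarray:
    th = np.atleast_2d(np.asarray(theta, dtype=float))
    if th.shape[1] != p:
        raise ValueError(f"parameter table must have {p} columns, got {th.shape[1]}")
    return th


def _theta_of(params) -> np.ndarray:
    if hasattr(params, "array"):
        return params.array
    return np.asarray(params, dtype=float)


def validate_params(model: str, theta) -> None:
    """Raise :class:`InvalidParameterError` on any invalid row."""
    m = _check_tag(model)
    th = _as_table(_theta_of(theta), param_count(m))
    if not np.all(np.isfinite(th)):
        raise InvalidParameterError("non-finite parameter value")
    if np.any(th[:, 0] <= 0):
        raise InvalidParameterError(f"{m}: amplitude A must be positive")
    if m == "me":
        if np.any(th[:, 1] <= 0):
            raise InvalidParameterError("me: T_me must be positive")
    elif m == "se":
        if np.any(th[:, 1] <= 0):
            raise InvalidParameterError("se: T_se must be positive")
        if np.any((th[:, 2] <= 0) | (th[:, 2] > 1)):
            raise InvalidParameterError("se: beta must be in (0, 1]")
    else:
        if np.any((th[:, 1] < 0) | (th[:, 1] > 1)):
            raise InvalidParameterError("be: phi_f must be in [0, 1]")
        if np.any(th[:, 2] <= 0) or np.any(th[:, 3] <= 0):
            raise InvalidParameterError("be: relaxation times must be positive")
        if np.any(th[:, 2] >= th[:, 3]):
            raise InvalidParameterError("be: requires T_s < T_l")


def _schedule_array(schedule) -> np.ndarray:
    if isinstance(schedule, TSLSchedule):
        return schedule.array
    return TSLSchedule(tuple(np.asarray(schedule, dtype=float))).array


def evaluate(model: str, theta, schedule, check: bool = True) -> np.ndarray:
    """Evaluate a relaxation model on a parameter table.

    Parameters
    ----------
    model
        One of ``"me"``, ``"be"``, ``"se"``.
    theta
        ``(n, p)`` table (or a single parameter object / vector).
    schedule
        :class:`TSLSchedule` or sequence of times in ms.

    Returns
    -------
    ``(n, T)`` signal table; a 1-D vector when a single vector was given.
    """
    m = _check_tag(model)
    t = _schedule_array(schedule)
    raw = _theta_of(theta)
    th = _as_table(raw, param_count(m))
    if check:
        validate_params(m, th)
    if m == "me":
        f = th[:, :1] * np.exp(-t[None, :] / th[:, 1:2])
    elif m == "se":
        f = th[:, :1] * np.exp(-((t[None, :] / th[:, 1:2]) ** th[:, 2:3]))
    else:
        short = np.exp(-t[None, :] / th[:, 2:3])
        long = np.exp(-t[None, :] / th[:, 3:4])
        f = th[:, :1] * ((1.0 - th[:, 1:2]) * short + th[:, 1:2] * long)
    if raw.ndim == 1:
        return f[0]
    return f


def evaluate_me(params, schedule) -> np.ndarray:
    return evaluate("me", params, schedule)


def evaluate_be(params, schedule) -> np.ndarray:
    return evaluate("be", params, schedule)


def evaluate_se(params, schedule) -> np.ndarray:
    return evaluate("se", params, schedule)


def analytic_jacobian(model: str, theta, schedule, check: bool = True) -> np.ndarray:
    """Partial derivatives of the model signal w.r.t. each parameter.

    Returns an ``(n, T, p)`` array (``(T, p)`` for a single vector), with
    columns ordered as in :func:`param_names`.
    """
    m = _check_tag(model)
    t = _schedule_array(schedule)
    raw = _theta_of(theta)
    th = _as_table(raw, param_count(m))
    if check:
        validate_params(m, th)
    n, T = th.shape[0], t.size
    J = np.empty((n, T, th.shape[1]), dtype=float)
    if m == "me":
        A, Tme = th[:, 0:1], th[:, 1:2]
        e = np.exp(-t[None, :] / Tme)
        J[:, :, 0] = e
        J[:, :, 1] = A * e * t[None, :] / Tme**2
    elif m == "se":
        A, Tse, beta = th[:, 0:1], th[:, 1:2], th[:, 2:3]
        u = (t[None, :] / Tse) ** beta
        e = np.exp(-u)
        J[:, :, 0] = e
        J[:, :, 1] = A * e * u * beta / Tse
        J[:, :, 2] = -A * e * u * np.log(t[None, :] / Tse)
    else:
        A, phi, Ts, Tl = th[:, 0:1], th[:, 1:2], th[:, 2:3], th[:, 3:4]
        es = np.exp(-t[None, :] / Ts)
        el = np.exp(-t[None, :] / Tl)
        J[:, :, 0] = (1.0 - phi) * es + phi * el
        J[:, :, 1] = A * (el - es)
        J[:, :, 2] = A * (1.0 - phi) * es * t[None, :] / Ts**2
        J[:, :, 3] = A * phi * el * t[None, :] / Tl**2
    if raw.ndim == 1:
        return J[0]
    return J


def clip_to_bounds(theta, bounds: ParamBounds):
    """Project a parameter table (or typed object) onto its box."""
    raw = _theta_of(theta)
    clipped = np.clip(np.atleast_2d(raw), bounds.lo, bounds.hi)
    if isinstance(theta, (MEParams, BEParams, SEParams)):
        return params_from_array(theta.model, clipped[0])
    if raw.ndim == 1:
        return clipped[0]
    return clipped
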