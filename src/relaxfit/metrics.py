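"""Evaluation metrics for voxel-wise parameter estimates.

Three metrics are used to compare fitting methods:

* **MNAD** (percent): median over voxels and parameters of the normalized
  absolute difference ``|ref - est| / |ref|``.
* **NRMSR** (dimensionless): mean over voxels of the residual norm between
  measured and model-predicted signals, normalized by the measured-signal
  norm.  Its floor is set by the measurement noise.
* **NRMSE** (percent): root-mean-squared parameter error normalized by the
  root-mean-squared reference magnitude.

By default the parameter subset ``P`` contains the relaxation parameters
only (T_me; T_se and beta; phi_f, T_s and T_l) and excludes the amplitude
A, which is a nuisance scale; pass ``include_amplitude=True`` (or an
explicit column list) to pool A as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import param_names

__all__ = ["EvaluationSet", "default_param_subset", "mnad", "nrmsr", "nrmse"]


def default_param_subset(model: str, include_amplitude: bool = False) -> list[int]:
    """Column indices entering MNAD/NRMSE (amplitude excluded by default)."""
    p = len(param_names(model))
    return list(range(p)) if include_amplitude else list(range(1, p))


@dataclass
class EvaluationSet:
    """Reference/estimated parameters and measured/predicted signals."""

    model: str
    reference_params: np.ndarray       # (n, p)
    estimated_params: np.ndarray       # (n, p)
    signals: np.ndarray | None = None        # (n, T) measured
    predicted_signals: np.ndarray | None = None  # (n, T) from estimates
    param_subset: list[int] | None = None

    def __post_init__(self) -> None:
        ref = np.atleast_2d(np.asarray(self.reference_params, dtype=float))
        est = np.atleast_2d(np.asarray(self.estimated_params, dtype=float))
        if ref.shape != est.shape:
            raise ValueError("reference and estimated parameter shapes disagree")
        self.reference_params, self.estimated_params = ref, est
        if self.param_subset is None:
            self.param_subset = default_param_subset(self.model)

    @property
    def _ref(self) -> np.ndarray:
        return self.reference_params[:, self.param_subset]

    @property
    def _est(self) -> np.ndarray:
        return self.estimated_params[:, self.param_subset]


def mnad(ev: EvaluationSet) -> float:
    """Median normalized absolute difference, in percent."""
    ref, est = ev._ref, ev._est
    zero = np.argwhere(ref == 0)
    if zero.size:
        i, p = zero[0]
        name = param_names(ev.model)[ev.param_subset[p]]
        raise ValueError(f"zero reference parameter at voxel {i}, parameter {name!r}")
    return float(100.0 * np.median(np.abs(ref - est) / np.abs(ref)))


def nrmsr(ev: EvaluationSet) -> float:
    """Mean normalized residual norm between measured and predicted signals."""
    if ev.signals is None or ev.predicted_signals is None:
        raise ValueError("nrmsr needs measured and predicted signals")
    s = np.atleast_2d(np.asarray(ev.signals, dtype=float))
    f = np.atleast_2d(np.asarray(ev.predicted_signals, dtype=float))
    if s.shape != f.shape:
        raise ValueError("signal table shapes disagree")
    norms = np.linalg.norm(s, axis=1)
    if np.any(norms == 0):
        raise ValueError(f"zero-norm measured signal at voxel {int(np.argmin(norms))}")
    return float(np.mean(np.linalg.norm(s - f, axis=1) / norms))


def nrmse(ev: EvaluationSet) -> float:
    """Normalized root-mean-squared parameter error, in percent."""
    ref, est = ev._ref, ev._est
    denom = np.mean(ref**2)
    if denom == 0:
        raise ValueError("all-zero reference parameters")
    return float(100.0 * np.sqrt(np.mean((ref - est) ** 2) / denom))
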