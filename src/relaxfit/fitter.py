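"""Voxel-wise neural fitter trained on synthetic signals.

A fully-connected network maps a normalized voxel signal (divided by its
first-TSL sample) to the relaxation parameters of one model.  Training
minimizes a physics-consistency loss

    sum_i [ gamma_s * ||s_i - f(theta_hat_i)||^2
            + gamma_theta * ||theta_n_i - theta_hat_n_i||^2 ]

where ``f`` is the closed-form relaxation model evaluated at the predicted
parameters (so the network is penalized for signal inconsistency exactly as
an NLS objective would be) and the parameter-error term is computed on
bound-normalized coordinates ``(theta - lo) / (hi - lo)`` so that
millisecond-scale relaxation times and dimensionless fractions weigh
equally.  Default weights are ``gamma_s = 10`` and ``gamma_theta = 1``.

The amplitude A is not a network output: normalization makes it
unidentifiable, and it is recovered at prediction time by the closed-form
least-squares scale between the measured signal and the unit-amplitude
model curve.  Network outputs are squashed onto the parameter box by a
logistic, so predictions are always within bounds.  One network is trained
per relaxation model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .models import (
    ParamBounds,
    TSLSchedule,
    analytic_jacobian,
    default_bounds,
    evaluate,
    param_count,
)
from .network import ACTIVATIONS, MLP, make_optimizer
from .synthetic import SyntheticDataset

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "TrainedFitter",
    "normalize_signal",
    "physics_loss",
    "train",
    "predict",
    "save_fitter",
    "load_fitter",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture: repeated linear/activation/dropout blocks + linear head."""

    num_blocks: int = 7
    width: int = 512
    activation: str = "relu"
    dropout_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.num_blocks < 1 or self.width < 1:
            raise ValueError("num_blocks and width must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam, lr 1e-3, 100 epochs, batches of 200)."""

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 200
    gamma_s: float = 10.0
    gamma_theta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma_s < 0 or self.gamma_theta < 0:
            raise ValueError("loss weights must be non-negative")
        if self.gamma_s == 0 and self.gamma_theta == 0:
            raise ValueError("at least one loss weight must be positive")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid epochs or batch size")


@dataclass
class TrainedFitter:
    """Learned voxel-wise mapping from normalized signal to bounded parameters.

    Carries everything needed to apply it: the network, the bounds used for
    output squashing, the schedule, and the input-normalization contract
    (divide the signal by its first-TSL sample).
    """

    model: str
    net: MLP
    spec: NetworkSpec
    bounds: ParamBounds
    schedule: TSLSchedule
    history: dict = field(default_factory=lambda: {"train_loss": [], "val_loss": []})
    best_epoch: int | None = None

    @property
    def n_outputs(self) -> int:
        return param_count(self.model) - 1  # amplitude is not an output


def normalize_signal(signal: np.ndarray) -> tuple[np.ndarray, float]:
    """Divide a signal by its first-TSL sample; returns (normalized, scale)."""
    s = np.asarray(signal, dtype=float)
    scale = float(s[0]) if s.ndim == 1 else None
    if s.ndim != 1:
        raise ValueError("normalize_signal expects a single voxel signal")
    if scale <= 0:
        raise ValueError("first-TSL sample must be positive to normalize")
    return s / scale, scale


def _normalize_table(signals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise normalization that tolerates non-positive first samples."""
    s = np.atleast_2d(np.asarray(signals, dtype=float))
    scale = np.where(np.abs(s[:, 0]) > 1e-12, np.abs(s[:, 0]), 1e-12)
    return s / scale[:, None], scale


def _squash(z: np.ndarray, lo: np.ndarray, rng_: np.ndarray) -> np.ndarray:
    sig = expit(z)
    return lo + rng_ * sig, sig


def physics_loss(
    signals: np.ndarray,
    true_params: np.ndarray,
    pred_params: np.ndarray,
    model: str,
    schedule: TSLSchedule,
    gamma_s: float = 10.0,
    gamma_theta: float = 1.0,
    bounds: ParamBounds | None = None,
    param_subset=None,
) -> float:
    """Signal-consistency + bound-normalized parameter-error loss (summed).

    ``param_subset`` selects the columns entering the parameter term
    (default: all columns of the tables given).
    """
    if gamma_s < 0 or gamma_theta < 0:
        raise ValueError("loss weights must be non-negative")
    bounds = bounds or default_bounds(model)
    s = np.atleast_2d(np.asarray(signals, dtype=float))
    th = np.atleast_2d(np.asarray(true_params, dtype=float))
    th_hat = np.atleast_2d(np.asarray(pred_params, dtype=float))
    if th.shape != th_hat.shape or s.shape[0] != th.shape[0]:
        raise ValueError("shape mismatch between signals and parameter tables")
    f_hat = evaluate(model, th_hat, schedule, check=False)
    sig_term = np.sum((s - f_hat) ** 2)
    cols = list(range(th.shape[1])) if param_subset is None else list(param_subset)
    lo, rng_ = bounds.lo[cols], bounds.range[cols]
    dn = (th[:, cols] - th_hat[:, cols]) / rng_
    return float(gamma_s * sig_term + gamma_theta * np.sum(dn * dn))


def _loss_and_dtheta(s, th_n_true, z, model, t, lo1, rng1, gamma_s, gamma_theta):
    """Loss (mean per voxel) and its gradient w.r.t. the pre-squash outputs.

    ``lo1``/``rng1`` are the bounds of the non-amplitude parameters; the
    amplitude is fixed at 1 (synthetic training signals have A = 1).
    """
    n = s.shape[0]
    theta_n, sig = _squash(z, lo1, rng1)  # natural units, (n, p-1)
    theta_full = np.concatenate([np.ones((n, 1)), theta_n], axis=1)
    f_hat = evaluate(model, theta_full, t, check=False)
    resid = f_hat - s
    dn = sig - th_n_true  # both in bound-normalized coordinates
    loss = (gamma_s * np.sum(resid**2) + gamma_theta * np.sum(dn**2)) / n

    J = analytic_jacobian(model, theta_full, t, check=False)[:, :, 1:]
    d_theta = 2.0 * gamma_s * np.einsum("ntp,nt->np", J, resid)  # w.r.t. natural units
    d_norm = d_theta * rng1 + 2.0 * gamma_theta * dn
    dz = d_norm * sig * (1.0 - sig) / n
    return loss, dz


def _eval_loss(net, s, th_n_true, model, t, lo1, rng1, gamma_s, gamma_theta):
    z, _ = net.forward(s / np.maximum(np.abs(s[:, :1]), 1e-12), train=False)
    loss, _ = _loss_and_dtheta(s, th_n_true, z, model, t, lo1, rng1, gamma_s, gamma_theta)
    return loss


def train(
    dataset: SyntheticDataset,
    net_spec: NetworkSpec | None = None,
    cfg: TrainConfig | None = None,
    bounds: ParamBounds | None = None,
) -> TrainedFitter:
    """Train a fitter on the dataset's train split, monitored on validation.

    Returns the fitter with the weights of the best-validation-loss epoch.
    Deterministic given ``cfg.seed`` (single-threaded NumPy).
    """
    net_spec = net_spec or NetworkSpec()
    cfg = cfg or TrainConfig()
    bounds = bounds or default_bounds(dataset.model)
    model, t = dataset.model, dataset.schedule.array
    p_out = param_count(model) - 1
    lo1, rng1 = bounds.lo[1:], bounds.range[1:]

    tr = dataset.subset("train")
    va = dataset.subset("val")
    if tr.n == 0 or va.n == 0:
        raise ValueError("dataset needs non-empty train and val splits")

    ss = np.random.SeedSequence(cfg.seed).spawn(2)
    rng_init = np.random.default_rng(ss[0])
    rng_train = np.random.default_rng(ss[1])

    sizes = [len(t)] + [net_spec.width] * net_spec.num_blocks + [p_out]
    net = MLP(sizes, net_spec.activation, net_spec.dropout_rate, rng_init)
    fitter = TrainedFitter(model, net, net_spec, bounds, dataset.schedule)
    if cfg.epochs == 0:
        return fitter

    opt = make_optimizer(cfg.optimizer, cfg.learning_rate)
    s_tr, th_tr = tr.signals, tr.params
    th_n_tr = (th_tr[:, 1:] - lo1) / rng1
    s_va, th_va = va.signals, va.params
    th_n_va = (th_va[:, 1:] - lo1) / rng1
    x_tr, _ = _normalize_table(s_tr)

    best_val = np.inf
    best_params = net.copy_params()
    best_epoch = 0
    n = s_tr.shape[0]
    for epoch in range(cfg.epochs):
        order = rng_train.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = x_tr[idx]
            out, cache = net.forward(xb, train=True, rng=rng_train)
            loss, dz = _loss_and_dtheta(
                s_tr[idx], th_n_tr[idx], out, model, t, lo1, rng1,
                cfg.gamma_s, cfg.gamma_theta,
            )
            grads = net.backward(cache, dz)
            opt.step(net.params, grads)
            ep_loss += loss * idx.size
        train_loss = ep_loss / n
        val_loss = _eval_loss(net, s_va, th_n_va, model, t, lo1, rng1,
                              cfg.gamma_s, cfg.gamma_theta)
        fitter.history["train_loss"].append(train_loss)
        fitter.history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_params = net.copy_params()
            best_epoch = epoch
    net.set_params(best_params)
    fitter.best_epoch = best_epoch
    return fitter


def predict(fitter: TrainedFitter, signals: np.ndarray) -> np.ndarray:
    """Predict a full parameter table (amplitude included) for signal rows.

    Each row is normalized by its first sample, passed through the network
    in evaluation mode (dropout off), squashed onto the bounds, and the
    amplitude is restored by the least-squares scale between the measured
    signal and the unit-amplitude model curve.  Prediction is deterministic
    and equivariant to positive rescaling of the input.
    """
    s_in = np.asarray(signals, dtype=float)
    s = np.atleast_2d(s_in)
    if s.shape[1] != len(fitter.schedule):
        raise ValueError("signal length does not match the fitter's schedule")
    x, _ = _normalize_table(s)
    z, _ = fitter.net.forward(x, train=False)
    lo1, rng1 = fitter.bounds.lo[1:], fitter.bounds.range[1:]
    theta_n, _ = _squash(z, lo1, rng1)
    n = s.shape[0]
    theta_full = np.concatenate([np.ones((n, 1)), theta_n], axis=1)
    f1 = evaluate(fitter.model, theta_full, fitter.schedule.array, check=False)
    amp = np.einsum("nt,nt->n", s, f1) / np.einsum("nt,nt->n", f1, f1)
    amp_hi = np.maximum(2.0 * np.max(np.abs(s), axis=1), 1e-12)
    theta_full[:, 0] = np.clip(amp, 1e-12, amp_hi)
    if s_in.ndim == 1:
        return theta_full[0]
    return theta_full


# ---------------------------------------------------------------------------
# serialization: weights in .npz, metadata in a JSON sidecar

def save_fitter(fitter: TrainedFitter, path: str | Path) -> Path:
    path = Path(path)
    arrays = {f"W{i}": W for i, W in enumerate(fitter.net.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(fitter.net.biases)})
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "model": fitter.model,
        "network": {
            "num_blocks": fitter.spec.num_blocks,
            "width": fitter.spec.width,
            "activation": fitter.spec.activation,
            "dropout_rate": fitter.spec.dropout_rate,
        },
        "bounds": {"lower": list(fitter.bounds.lower), "upper": list(fitter.bounds.upper)},
        "tsl_ms": list(fitter.schedule.times),
        "normalization": "signal divided by first-TSL sample",
        "history": fitter.history,
        "best_epoch": fitter.best_epoch,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path.with_suffix(".npz")


def load_fitter(path: str | Path) -> TrainedFitter:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = NetworkSpec(**meta["network"])
    model = meta["model"]
    bounds = ParamBounds(model, tuple(meta["bounds"]["lower"]), tuple(meta["bounds"]["upper"]))
    schedule = TSLSchedule(tuple(meta["tsl_ms"]))
    sizes = [len(schedule.times)] + [spec.width] * spec.num_blocks + [param_count(model) - 1]
    net = MLP(sizes, spec.activation, spec.dropout_rate, np.random.default_rng(0))
    with np.load(path.with_suffix(".npz")) as data:
        net.weights = [data[f"W{i}"] for i in range(len(net.weights))]
        net.biases = [data[f"b{i}"] for i in range(len(net.biases))]
    fitter = TrainedFitter(model, net, spec, bounds, schedule,
                           history=meta.get("history", {}), best_epoch=meta.get("best_epoch"))
    return fitter
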