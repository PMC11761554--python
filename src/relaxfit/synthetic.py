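"""Synthetic voxel-signal generation for training and evaluation.

Ground-truth parameters are drawn independently and uniformly from the
fitting ranges of each model, clean signals are produced by the closed-form
models, and magnitude noise is added on top.  Datasets carry a stratified
80:10:10 train/validation/test split, stratified by deciles of the model's
principal relaxation time (T_me, T_se, or the long component T_l), which is
the dominant determinant of signal shape.

The default noise model is additive Gaussian at 2% of the amplitude;
Rician magnitude noise is available as an option.  Amplitudes default to
A = 1 (a point-mass range), since the neural fitter normalizes signals and
treats the amplitude as a nuisance scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .models import (
    TSLSchedule,
    default_bounds,
    evaluate,
    param_names,
    validate_params,
)

__all__ = [
    "ParamPrior",
    "NoiseSpec",
    "SyntheticDataset",
    "sample_parameters",
    "synthesize_signals",
    "corrupt",
    "make_dataset",
    "principal_time_column",
    "save_dataset",
    "load_dataset",
]

#: Column index of the principal relaxation time per model.
_PRINCIPAL = {"me": 1, "se": 1, "be": 3}

SPLIT_LABELS = ("train", "val", "test")
SPLIT_FRACTIONS = (0.8, 0.1, 0.1)


def principal_time_column(model: str) -> int:
    """Index of the stratification variable (T_me / T_se / T_l)."""
    return _PRINCIPAL[model]


def _default_ranges(model: str) -> dict[str, tuple[float, float]]:
    b = default_bounds(model)
    ranges = {
        name: (lo, hi)
        for name, lo, hi in zip(param_names(model), b.lower, b.upper)
    }
    ranges["A"] = (1.0, 1.0)  # unit amplitude; scale is a nuisance for fitting
    return ranges


@dataclass(frozen=True)
class ParamPrior:
    """Independent uniform sampling ranges per parameter.

    Defaults are the fitting ranges (T1rho 1-300 ms; BE short 0.5-4 ms,
    long 5-300 ms, fraction 0.01-0.99; beta 0.1-1) with A fixed at 1.
    """

    model: str
    ranges: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        merged = _default_ranges(self.model)
        if self.ranges:
            unknown = set(self.ranges) - set(merged)
            if unknown:
                raise ValueError(f"unknown parameters in prior: {sorted(unknown)}")
            merged.update({k: (float(a), float(b)) for k, (a, b) in self.ranges.items()})
        for name, (a, b) in merged.items():
            if a > b:
                raise ValueError(f"prior range for {name} has lower > upper")
        object.__setattr__(self, "ranges", merged)

    @property
    def lo(self) -> np.ndarray:
        return np.array([self.ranges[n][0] for n in param_names(self.model)])

    @property
    def hi(self) -> np.ndarray:
        return np.array([self.ranges[n][1] for n in param_names(self.model)])


@dataclass(frozen=True)
class NoiseSpec:
    """Noise on the magnitude signal.

    ``sigma_rel`` is the noise standard deviation relative to the amplitude
    A; e.g. 0.02 means 2% of A.  ``kind`` is ``"gaussian"`` (additive),
    ``"rician"`` (magnitude of complex Gaussian) or ``"none"``.
    """

    kind: str = "gaussian"
    sigma_rel: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "rician", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be non-negative")


@dataclass
class SyntheticDataset:
    """Voxel signals with ground truth, noise spec, and split labels."""

    model: str
    schedule: TSLSchedule
    signals: np.ndarray        # (n, T) noisy
    clean_signals: np.ndarray  # (n, T)
    params: np.ndarray         # (n, p) ground truth
    noise: NoiseSpec
    split: np.ndarray          # (n,) strings in {"train","val","test"}
    seed: int

    def __post_init__(self) -> None:
        n = self.signals.shape[0]
        if not (self.clean_signals.shape[0] == n == self.params.shape[0] == self.split.shape[0]):
            raise ValueError("row counts of signals, params and split disagree")

    @property
    def n(self) -> int:
        return self.signals.shape[0]

    def indices(self, subset: str) -> np.ndarray:
        if subset not in SPLIT_LABELS:
            raise ValueError(f"unknown split {subset!r}")
        return np.flatnonzero(self.split == subset)

    def subset(self, subset: str) -> "SyntheticDataset":
        idx = self.indices(subset)
        return replace(
            self,
            signals=self.signals[idx],
            clean_signals=self.clean_signals[idx],
            params=self.params[idx],
            split=self.split[idx],
        )


def sample_parameters(prior: ParamPrior, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` parameter vectors i.i.d. uniform within the prior ranges.

    BE draws are valid by construction because the short and long ranges
    are disjoint (T_s < T_l structurally).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    lo, hi = prior.lo, prior.hi
    theta = rng.uniform(size=(n, lo.size)) * (hi - lo) + lo
    validate_params(prior.model, theta)
    return theta


def synthesize_signals(model: str, params: np.ndarray, schedule: TSLSchedule) -> np.ndarray:
    """Noise-free forward evaluation of a ground-truth parameter table."""
    return evaluate(model, params, schedule)


def corrupt(clean: np.ndarray, noise: NoiseSpec, amplitude=1.0) -> np.ndarray:
    """Add magnitude noise to clean signals, deterministically per seed.

    Gaussian: ``s = f + eps`` with ``eps ~ N(0, (sigma_rel*A)^2)``.
    Rician:   ``s = |f + eps1 + i*eps2|`` with independent Gaussian parts.
    """
    clean = np.atleast_2d(np.asarray(clean, dtype=float))
    if noise.kind == "none" or noise.sigma_rel == 0:
        return clean.copy()
    rng = np.random.default_rng(noise.seed)
    amp = np.asarray(amplitude, dtype=float)
    sigma = noise.sigma_rel * (amp[:, None] if amp.ndim else amp)
    if noise.kind == "gaussian":
        return clean + sigma * rng.standard_normal(clean.shape)
    # rician
    re = clean + sigma * rng.standard_normal(clean.shape)
    im = sigma * rng.standard_normal(clean.shape)
    return np.hypot(re, im)


def _stratified_split(strata_values: np.ndarray, seed: int) -> np.ndarray:
    """80:10:10 assignment, stratified by deciles of ``strata_values``."""
    n = strata_values.size
    edges = np.quantile(strata_values, np.linspace(0, 1, 11)[1:-1])
    bins = np.searchsorted(edges, strata_values, side="right")
    rng = np.random.default_rng(seed)
    split = np.empty(n, dtype="U5")
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        idx = idx[rng.permutation(idx.size)]
        m = idx.size
        n_train = int(round(SPLIT_FRACTIONS[0] * m))
        n_val = int(round(SPLIT_FRACTIONS[1] * m))
        split[idx[:n_train]] = "train"
        split[idx[n_train:n_train + n_val]] = "val"
        split[idx[n_train + n_val:]] = "test"
    return split


def make_dataset(
    model: str,
    n: int,
    prior: ParamPrior | None = None,
    noise: NoiseSpec | None = None,
    schedule: TSLSchedule | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Sample parameters, synthesize signals, add noise, and split.

    All randomness (parameter draws, noise, split shuffling) is derived
    from ``seed`` via independent child seeds, so regeneration with the
    same arguments is bit-identical.
    """
    if n < 10:
        raise ValueError("need n >= 10 to form a meaningful split")
    prior = prior or ParamPrior(model)
    if prior.model != model:
        raise ValueError("prior model tag does not match dataset model")
    schedule = schedule or TSLSchedule()
    seed_param, seed_noise, seed_split = (
        int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(3)
    )
    noise = noise if noise is not None else NoiseSpec(seed=seed_noise)
    if noise.seed == 0:
        noise = replace(noise, seed=seed_noise)
    theta = sample_parameters(prior, n, seed_param)
    clean = synthesize_signals(model, theta, schedule)
    noisy = corrupt(clean, noise, amplitude=theta[:, 0])
    split = _stratified_split(theta[:, principal_time_column(model)], seed_split)
    return SyntheticDataset(
        model=model,
        schedule=schedule,
        signals=noisy,
        clean_signals=clean,
        params=theta,
        noise=noise,
        split=split,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# persistence (HDF5 container: groups data/{signals,clean_signals,params},
# split stored as integer codes, metadata in root attrs)

_SPLIT_CODE = {label: i for i, label in enumerate(SPLIT_LABELS)}


def save_dataset(dataset: SyntheticDataset, path: str | Path) -> Path:
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("signals", data=dataset.signals)
        h5.create_dataset("clean_signals", data=dataset.clean_signals)
        h5.create_dataset("params", data=dataset.params)
        codes = np.array([_SPLIT_CODE[s] for s in dataset.split], dtype=np.int8)
        h5.create_dataset("split", data=codes)
        h5.attrs["meta"] = json.dumps(
            {
                "model": dataset.model,
                "tsl_ms": list(dataset.schedule.times),
                "noise": {
                    "kind": dataset.noise.kind,
                    "sigma_rel": dataset.noise.sigma_rel,
                    "seed": dataset.noise.seed,
                },
                "seed": dataset.seed,
                "param_names": list(param_names(dataset.model)),
            }
        )
    return path


def load_dataset(path: str | Path) -> SyntheticDataset:
    import h5py

    with h5py.File(path, "r") as h5:
        meta = json.loads(h5.attrs["meta"])
        codes = np.asarray(h5["split"])
        split = np.array([SPLIT_LABELS[c] for c in codes], dtype="U5")
        return SyntheticDataset(
            model=meta["model"],
            schedule=TSLSchedule(tuple(meta["tsl_ms"])),
            signals=np.asarray(h5["signals"]),
            clean_signals=np.asarray(h5["clean_signals"]),
            params=np.asarray(h5["params"]),
            noise=NoiseSpec(**meta["noise"]),
            split=split,
            seed=meta["seed"],
        )
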