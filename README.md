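# relaxfit

Voxel-wise multi-component T1ρ relaxometry fitting: mono- (ME), bi- (BE)
and stretched-exponential (SE) decay models fitted per voxel by a
box-constrained trust-region nonlinear least-squares (TRCG) solver, a
neural fitter trained purely on synthetic signals with a
physics-consistency loss, and the hybrid scheme that uses the network's
prediction as the NLS starting point and refines it for a fixed iteration
budget.

**Who it is for.** Researchers producing quantitative T1ρ (or analogous
multi-echo relaxation) parameter maps who need NLS-quality fits across
whole volumes without NLS-scale runtimes, and who want the training data
for the learned component to be synthetic — no reference maps required.

## The model and the method

Each voxel contributes a decay curve sampled at spin-lock times
t₁ < … < t_T (default: 0.05, 0.6, 1.6, 6, 16, 36 ms):

    s(t) = f(t, θ) + v,
    f = A·e^{−t/T}  (ME)   |   A·[(1−φf)e^{−t/Tₛ} + φf·e^{−t/Tₗ}]  (BE)
    |   A·e^{−(t/T)^β}  (SE)

The reference estimate is the box-constrained least-squares fit
θ̂ = argmin_θ Σₜ (s_t − f(t, θ))², solved by a Gauss–Newton trust-region
method with Steihaug-CG subproblems and analytic Jacobians, vectorized
across voxels.  The neural fitter F_w maps the normalized signal to
bounded parameters and is trained on synthetic draws θ ~ U(ranges) with
the loss Σᵢ [γs‖sᵢ − f(θ̂ᵢ)‖² + γθ‖θᵢ − θ̂ᵢ‖²] (γs = 10, γθ = 1; parameter
term on bound-normalized coordinates).  The hybrid fit runs
θ⁰ = F_w(s) followed by k trust-region iterations, with named budgets
k = 10 (`ultrafast`), 50 (`superfast`), 200/300 (`hdnls`, SE gets 300),
500 (`relaxed`).

Accuracy is summarized by MNAD (median normalized absolute parameter
difference, %), NRMSR (mean normalized residual norm, floored by noise)
and NRMSE.  See `docs/methods.md` for assumptions, numerical choices and
limitations.

## Worked example

```python
import numpy as np
from relaxfit import (make_dataset, NetworkSpec, TrainConfig, train,
                      VariantConfig, hdnls_fit, initial_guess_table,
                      nls_fit_map, NLSConfig, EvaluationSet, mnad, nrmsr, evaluate)

ds = make_dataset("me", 20_000, seed=7)          # 6-TSL protocol, 2% noise
fitter = train(ds, NetworkSpec(num_blocks=3, width=128),
               TrainConfig(epochs=20, seed=7))
test = ds.subset("test")

hybrid = hdnls_fit(test.signals, ds.schedule, "me", fitter, VariantConfig("hdnls"))
cold = nls_fit_map(test.signals, ds.schedule, "me",
                   initial_guess_table("me", test.signals, ds.schedule),
                   NLSConfig(max_iterations=2000))

for name, params in (("full NLS (2000 it)", cold.params), ("hybrid (200 it)", hybrid.params)):
    ev = EvaluationSet("me", test.params, params,
                       signals=test.signals,
                       predicted_signals=evaluate("me", params, ds.schedule, check=False))
    print(f"{name:>20}: MNAD = {mnad(ev):.2f}%   NRMSR = {nrmsr(ev):.3f}")
print(f"mean refinement iterations: {hybrid.iterations_used.mean():.1f} (cap 200)")
```

Output:

```
  full NLS (2000 it): MNAD = 6.29%   NRMSR = 0.017
     hybrid (200 it): MNAD = 6.29%   NRMSR = 0.017
mean refinement iterations: 13.0 (cap 200)
```

The hybrid fit matches the 2000-iteration reference to the displayed
precision while using 13 refinement iterations per voxel on average: the
median T1ρ error is 6.3% of the true value at 2% signal noise, and both
methods reach the noise-set residual floor (NRMSR ≈ 0.017 ≈ noise-only
level).

The same pipeline runs from the shell: `relaxfit simulate | train | fit |
sweep | evaluate` (see `relaxfit --help`); `fit` also accepts 4D NIfTI
volumes with a TSL list and optional mask, writing one 3D parameter map
per parameter plus a residual map.

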