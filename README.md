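# fpinv — inverse problem of the 1-D Fokker–Planck equation

`fpinv` recovers the **drift term g(x)** and **diffusion term h(x)** of a
one-dimensional, time-independent Fokker–Planck equation (FPE)

    ∂P(x,t)/∂t = ∂/∂x [ g(x) P(x,t) ] + ∂²/∂x² [ h(x) P(x,t) ]

directly from *noisy* observed probability-density sequences, while
simultaneously **denoising** the densities — no functional form of g or h is
assumed.  It is aimed at anyone who observes how a distribution evolves
(heat-flux fluctuations, DNA-bubble lengths, wealth distributions, …) and
wants the governing stochastic dynamics back out of the data, plus short-term
forecasts of future distributions.

## Method

On a uniform grid the FPE becomes `dP/dt = D1(g ⊙ P) + D2(h ⊙ P)` with fixed
finite-difference matrices `D1`, `D2`.  Observations enter as sequences
P_noisy(t) with entrywise multiplicative noise `(1 + Wξ)`, ξ ~ N(0,1).

1. **Initialization** — each frame is smoothed along x with a Savitzky–Golay
   filter (P̂⁰), and initial (ĝ⁰, ĥ⁰) come from a linear least-squares fit of
   the discrete FPE to finite-difference time derivatives of P̂⁰.
2. **Alternating training** — every residual uses the multi-offset Euler
   prediction `P̂_pred(t+iΔt) = P̂(t) + iΔt[D1(ĝ⊙P̂) + D2(ĥ⊙P̂)]`,
   i ∈ {−n,…,n}:
   * *terms step*: `L_gh = Σ_t Σ_i ‖P̂_pred(t+iΔt) − P̂(t+iΔt)‖²` is minimized
     over (ĝ, ĥ) with the densities fixed;
   * *density step*: `L_P = Σ_i ‖P̂_pred(t+iΔt) − P̂⁰(t+iΔt)‖²` is minimized
     over each P̂(t) independently with the terms fixed — the targets are
     always the fixed smoothed observations P̂⁰.

   Every loss is **quadratic** in its trainable argument, so the reference
   backend computes each step's exact minimizer by a linear solve; a plain
   gradient-descent backend is available for comparison.  Training stops when
   L_gh + L_P fails to improve for 20 consecutive iterations.
3. **Forecasting** — on a held-out sequence, the latest state is fitted from
   the trailing r+1 smoothed frames (offsets {−r,…,0}), then the f future
   distributions are single Euler extrapolations from that one state.

Recovery quality is scored with normalized L2 errors (E_P, E_g, E_h), their
interior-only variants (a per-bin t-test flags "boundary" bins whose density
is statistically below 1 % of the data maximum), and the forecast error
E_test per horizon.

Three classic systems are built in for fully reproducible simulation studies:

| name     | g(x)      | h(x)       | origin                        |
|----------|-----------|------------|-------------------------------|
| `flux`   | θx        | D          | Ornstein–Uhlenbeck heat flux  |
| `bubble` | μ/x − ε   | 1/2        | DNA-bubble (Bessel) dynamics  |
| `wealth` | x − m     | (λ/2)x²    | agent's-wealth economics      |

## Worked example

```python
import numpy as np
from fpinv import (DerivativeOperators, TrainConfig, boundary_mask,
                   compute_metrics, evaluate_forecasting, example_terms,
                   make_dataset, train)

ds = make_dataset("wealth", seed=0)          # 120 sequences, 50 frames, E_P ~ 0.01
ops = DerivativeOperators.build(ds.example.grid)
cfg = TrainConfig(n=2)                       # offsets {-2,...,2}, patience 20
state = train(ds, cfg, ops)

mask = boundary_mask(ds.train)
m = compute_metrics(state, ds.clean_train, example_terms(ds.example), mask)
print(f"stopped after {state.k} iterations")
print(f"E_P = {m.e_p:.4f}   (noisy data: ~0.01)")
print(f"E_g = {m.e_g:.3f}  (interior {m.e_g_interior:.3f})")
print(f"E_h = {m.e_h:.3f}  (interior {m.e_h_interior:.3f})")
et = evaluate_forecasting(ds, state.terms, ops, cfg.sg, r=cfg.n, f=5)
print(f"E_test horizon 1: {et[0,0]:.3f} +/- {et[0,1]:.3f}")
print(f"E_test horizon 5: {et[4,0]:.3f} +/- {et[4,1]:.3f}")
```

Output (about half a minute on one CPU core):

```
stopped after 29 iterations
E_P = 0.0022   (noisy data: ~0.01)
E_g = 1.494  (interior 0.061)
E_h = 0.107  (interior 0.040)
E_test horizon 1: 0.011 +/- 0.002
E_test horizon 5: 0.010 +/- 0.002
```

Reading it: training shrank the density error from the 1 % observation noise
to 0.22 %; in the well-observed interior of the wealth support the recovered
drift and diffusion are within ~6 % and ~4 % of the truth (the all-bins E_g
is dominated by edge bins the data never populates — see
`docs/methods.md`); one-step-ahead forecasts of held-out sequences sit at
the observation-noise floor, as they should.

The same pipeline is scriptable from the shell:

```bash
fpinv generate --example flux --seed 1 --out flux_data/
fpinv train --data flux_data/ --checkpoint flux.npz --trace trace.tsv
fpinv evaluate --data flux_data/ --checkpoint flux.npz
fpinv forecast --data flux_data/ --checkpoint flux.npz --n 2
fpinv report --example wealth --n 2 --n 4     # summary table + traces
```

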