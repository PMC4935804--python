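# nfkbpulse

Modelling and analysis of NF-κB/IκBα signalling dynamics under pulsatile
cytokine stimulation, for systems biologists studying how single cells
encode rapidly changing inflammatory inputs.

When cells are stimulated with short, well-spaced pulses of TNFα, almost
every cell activates NF-κB each time. At shorter pulse intervals (< 100
min) a *refractory state* appears: a cell-specific period after the first
pulse during which a second TNFα pulse fails to trigger NF-κB nuclear
translocation. The fraction of cells responding to the second pulse rises
from ~5 % at a 50-min interval to ~93 % at 100 min, the refractory period
varies between cells but is stable within a cell (and largely inherited by
daughter cells), and cells refractory to TNFα still respond to IL-1β.

`nfkbpulse` implements this biology as a tested, reusable pipeline:

* **Two-compartment ODE model** of one cell: cytokine-specific IKKK
  three-state cycles (neutral → active → inactive) inhibited divisively by
  the NF-κB-induced A20 feedback, a Hill-activated IKK cycle, and the core
  NF-κB/IκBα negative-feedback oscillator with nucleocytoplasmic shuttling.
  Per branch X ∈ {TNFα, IL-1β}:

  ```
  dIKKKa_X/dt = ka_X · TR_X(t) · IKKKn_X · kA20_X/(kA20_X + A20) − ki · IKKKa_X
  dIKKKi_X/dt = ki · IKKKa_X − m3 · IKKKi_X
  IKK activation = kact · IKKn · S² / (sIKKK² + S²),   S = IKKKa_T + IKKKa_I
  ```

  with NF-κB-driven Hill transcription (coefficient 2) of the IκBα and A20
  feedback genes. Conservation of each kinase pool and of total NF-κB holds
  by construction.
* **Population heterogeneity**: extrinsic noise (parameters distributed
  across cells but fixed per cell — imprinted states) and intrinsic noise
  (stochastic ON/OFF telegraph switching of the two feedback genes in a
  hybrid ODE/next-reaction simulation).
* **Quantile calibration**: the measured fraction-of-responding-cells
  curve is mapped onto the per-cell total-IKKK distribution — for each
  pulse interval Δ a response threshold θ(Δ) is found by bisection and the
  s.d. σ of the truncated Normal(μ = 10⁶, σ) is fitted so that
  P(IKKK > θ(Δ)) matches the measured fractions.
* **Trace analytics**: both responder rules (net nuclear NF-κB
  translocation > 15 % of total; non-positive IκBα gradient at
  stimulation), response fractions, refractory-period distributions,
  amplitude ratios, AUC, trough spacings, power-spectrum periods, 2-means
  responder clustering, sub-trajectory PCA and daughter-pair concordance.
* **Global sensitivity**: Latin hypercube sampling (±50 % around nominal,
  k slices) with Spearman rank correlation per parameter × output.
* **Synthetic data**: generators for reporter traces (model-driven or
  responder/non-responder mixtures), daughter pairs and panel count
  matrices, each returning ground-truth labels for end-to-end recovery
  tests.

## Worked example

```python
import numpy as np
from nfkbpulse import (ModelParameters, calibrate_ikkk_distribution,
                       calibrated_population, classify_responder_model,
                       parse_protocol, run_population, simulate_cell,
                       MEASURED_TT_FRACTIONS)
from nfkbpulse.protocols import two_pulse

params = ModelParameters()

# one 5-min 10 ng/ml TNFα pulse: trough and resynthesis peak of total IκBα
traj = simulate_cell(params, parse_protocol("T@0", t_end=420))
tot = traj.total_ikba / traj.total_ikba[0]
i_tr = int(np.argmin(tot[:60])); i_pk = i_tr + int(np.argmax(tot[i_tr:300]))
print(f"trough at {traj.t[i_tr]:.0f} min (depth {tot[i_tr]:.2f}), "
      f"peak at {traj.t[i_pk]:.0f} min ({tot[i_pk]:.2f}x baseline)")

# quantile calibration of the per-cell IKKK distribution
cal = calibrate_ikkk_distribution(MEASURED_TT_FRACTIONS, params)
print(f"calibrated sigma = {cal.sigma:.3g} molecules (mu = {cal.mu:.3g})")

# 300-cell population under paired TNFα pulses
cells = calibrated_population(300, seed=0, sigma=cal.sigma)
for delta in (100, 70, 60, 50):
    trajs = run_population(cells, two_pulse(delta, "TT", tail=60.0), base=params)
    frac = np.mean([classify_responder_model(t, delta)[0] for t in trajs])
    print(f"responders at {delta:>3d} min interval: {100*frac:.0f}%")
```

prints

```
trough at 17 min (depth 0.44), peak at 111 min (1.44x baseline)
calibrated sigma = 1.8e+05 molecules (mu = 1e+06)
responders at 100 min interval: 92%
responders at  70 min interval: 72%
responders at  60 min interval: 33%
responders at  50 min interval: 3%
```

The trough marks the synchronous IKK-driven degradation of IκBα, the peak
the NF-κB-driven resynthesis overshoot. The fitted σ ≈ 0.18 μ says that a
±18 % cell-to-cell spread in total IKKK is enough to reproduce the entire
measured responder-fraction curve: cells below the interval-specific
threshold θ(Δ) have not yet recovered enough neutral IKKK (given their
A20 load) to fire again.

A `nfkbpulse` command-line tool wraps the same functions
(`simulate`, `calibrate`, `population`, `sensitivity`, `classify`,
`refractory`, `period`, `pca`, `synth …`, `expression …`); see
`nfkbpulse --help`.

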