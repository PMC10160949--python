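# akinetics

Conformation-coupled kinetic modelling of substrate inhibition in adenylate
kinase (AK), with photon-by-photon two-state hidden-Markov inference of
LID-domain dynamics and the bulk-kinetics fits that connect the two.

## The scientific problem

AK catalyzes ATP + AMP ⇌ 2 ADP and is strongly inhibited by an excess of its
own substrate AMP. The inhibition is puzzling because AMP binds only at its
cognate NMP-domain site, yet single-molecule FRET shows that inhibitory AMP
concentrations *accelerate closing* of the ATP-binding LID domain —
an allosteric effect that overpopulates a closed, catalytically unproductive
state. This package implements a kinetic model that makes this mechanism
quantitative, together with the machinery a study of it needs:

* **`network`** — a ten-state continuous-time Markov model
  (`{E, ET, EM, ETM, ETMinh} × {open, closed}`) in which ATP binds only to
  open conformations, AMP binds to both, and the binding *order* decides the
  outcome: ATP-first yields the productive ternary complex ETM, AMP-first the
  unproductive ETMinh. The two interconvert only through their open states,
  and phosphotransfer (k_pt) occurs only from ETM^C. Steady-state turnover is
  `v = k_pt · p(ETM_C)`, obtained from the exact null space of the generator.
* **`gillespie`** — exact stochastic realizations of the same network (the
  brute-force oracle) and of isolated two-state open/closed switching.
* **`photons`** — a photon-by-photon two-state HMM for smFRET: exact
  likelihood of a photon channel sequence conditioned on arrival times via
  closed-form 2×2 propagators `exp(QΔt)`, maximum-likelihood estimation of
  `(k_open, k_close, E_open, E_closed)`, Viterbi state paths, and per-burst
  FRET-efficiency histograms.
* **`fits`** — the uncompetitive substrate-inhibition law
  `v = Vmax·S / (K_M + S·(1 + S/K_I))`, the screening ratio v(100 µM)/v(500 µM),
  and simple binding isotherms `y = y0 + (ymax−y0)·S/(C50+S)` whose plateau
  supplies the closing rate of the inhibited complex.
* **`sensitivity`** — closing-rate scans (preserving the equilibrium ratio
  K_C = k_close/k_open, or preserving the opening rate) and the
  ETM ⇌ ETMinh interconversion-rate scan.
* **`synthetic`** — seeded generators for every input: the default variant
  suite (WT, L107I, L82V, F86W) anchored to measured LID rates, noisy
  activity datasets, and Poisson photon/burst streams.
* **`io` / `cli`** — CSV/YAML formats and an `akinetics` command-line tool
  (`simulate-activity`, `fit-si`, `fit-isotherm`, `scan`, `simulate-photons`,
  `fit-hmm`, `histogram`, `fixtures`).

Fitting follows a statsmodels-style layout: model objects
(`UncompetitiveInhibition`, `BindingIsotherm`, `TwoStatePhotonHMM`,
`KineticNetworkModel`) built from data/parameters, with `fit()` returning a
results object exposing estimates, uncertainties and `summary()`.

## Worked example

```python
import numpy as np
import akinetics as ak

# 1) simulated activity curves of the four default variants vs AMP at 1 mM ATP
suite = ak.generate_variant_suite()
for name, params in suite.items():
    curve = ak.activity_vs_amp(params)          # 61-point grid, 1–10^4 µM
    print(name, round(ak.inhibition_index(curve), 4))

# 2) two-state rate inference from a synthetic 10 s photon stream at 50 kHz
truth = ak.TwoStateFretModel(k_open=2000, k_close=3000, E_open=0.37, E_closed=0.72)
traj = ak.simulate_photon_trajectory(truth, duration=10.0, photon_rate=50_000, seed=1)
print(ak.TwoStatePhotonHMM(traj).fit(n_restarts=3, seed=0).summary())

# 3) K_M/K_I from a noisy synthetic activity dataset
data = ak.generate_activity_dataset((100.0, 50.0, 300.0),
                                    np.geomspace(5, 5000, 12),
                                    noise_fraction=0.05, seed=1)
print(ak.fit_uncompetitive_si(data).summary())
```

This prints inhibition indices `WT 0.0054, L107I 0.0069, L82V 0.0259,
F86W 0.0` — the inhibited variants show an interior activity maximum
followed by decline with a strictly positive high-AMP plateau, ordered
L82V > L107I > WT, while the noninhibited F86W stays monotone. The HMM fit
recovers `k_open 1945 s^-1, k_close 2904 s^-1, E 0.369/0.718, closed
occupancy 0.599` from the 2000/3000, 0.37/0.72 ground truth, and the
substrate-inhibition fit returns `Vmax 99.2 ± 4, K_M 48.6 ± 2.9 µM,
K_I 309 µM` from the (100, 50, 300) truth; its screening ratio
v(100)/v(500) is 1.50, the above-1 signature of substrate inhibition.

See `docs/methods.md` for the model assumptions, parameter provenance
(measured anchors vs documented stand-ins) and numerical choices.

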