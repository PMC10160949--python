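# Methods

## The model

Adenylate kinase is described by a single conformational coordinate — the
ATP-binding LID domain, open (O) or closed (C) — for five ligation species:
apoenzyme E, binary complexes ET (ATP) and EM (AMP), and two ternary
complexes distinguished by binding order: ETM (ATP first, productive) and
ETMinh (AMP first, unproductive). The resulting ten-state continuous-time
Markov chain has exactly 25 transitions:

* open ⇌ closed exchange for each species, with one `(k_close, k_open)`
  pair per species;
* ATP association only from open conformations (E_O ⇌ ET_O,
  EM_O ⇌ ETMinh_O), because the closed LID occludes the ATP site;
* AMP association from both conformations (E ⇌ EM and ET ⇌ ETM in both
  O and C), because LID closure does not gate the NMP site;
* ETM_O ⇌ ETMinh_O interconversion (substrate reorientation is possible
  only while the LID is open);
* a single irreversible phosphotransfer ETM_C → E_O at rate `k_pt`.

Assumptions: free nucleotide concentrations are clamped (pseudo-first-order
binding, as in bulk initial-velocity assays); product release is
instantaneous and ADP species are not modelled, so catalysis is the single
lumped step `k_pt` and turnover equals `k_pt · p(ETM_C)`; the NMP-domain
conformation is not tracked; the inhibited closed complex ETMinh_C has no
exit of its own — it must open before converting or releasing ATP (an
optional `inhibited_closed_amp_release` flag adds ETMinh_C → ET_C for
exploration, off by default).

Substrate inhibition emerges structurally: at saturating ATP and rising
AMP, an increasing share of binding flux takes the AMP-first route into
ETMinh, whose closed state is a catalytic dead end; activity at high AMP is
limited by the escape rate `p_open(ETMinh) · k_conv` out of the inhibited
branch. Because escape requires the open conformation, any perturbation
that overpopulates the ETMinh closed state (higher K_C) deepens
inhibition — the mechanistic core of the package.

## Parameters

Units everywhere: concentrations µM, times s, first-order rates s⁻¹,
associations µM⁻¹s⁻¹.

**Measured anchors** (LID exchange from single-molecule FRET):

| quantity | value | note |
|---|---|---|
| k_close(ET)=k_close(ETM) | 27,307 s⁻¹ | ATP-bound closing |
| k_open(ET)=k_open(ETM) | 23,937 s⁻¹ | closed occupancy 0.533 |
| k_close(ETMinh), WT | 50,289 s⁻¹ | high-AMP asymptote of the closing-rate isotherm |
| closed occupancy of ETMinh | 0.635 / 0.648 / 0.755 | WT / L107I / L82V |
| k_pt | 500 s⁻¹ | phosphotransfer, shared by all variants |
| k_conv_fwd = k_conv_rev | 250 s⁻¹ | ETM_O ⇌ ETMinh_O, shared |
| E_open / E_closed | 0.37 / 0.72 | FRET efficiencies of the WT construct |

ET and ETM share one rate pair because single-molecule experiments cannot
distinguish them at non-inhibiting AMP. For the WT inhibited complex the
measured closing rate and the measured occupancy are mutually inconsistent
with an unchanged opening rate; since steady-state activity depends only on
the occupancy (see the fast-exchange invariance below), we keep both
measured values — k_close = 50,289 s⁻¹ and occupancy 0.635 — and let
k_open(ETMinh, WT) = 28,906 s⁻¹ be the dependent quantity. For L107I and
L82V the opening rate is held at 23,937 s⁻¹ (opening is experimentally
insensitive to AMP) and k_close follows from the occupancy. F86W shows no
closing enhancement: its ETMinh rates equal its ETM rates.

**Documented stand-ins** (not measured; fixed once at design time):

* apo E and EM conformational rates: k_close 5,000 / k_open 20,000 s⁻¹
  (closed occupancy 0.20 — the apoenzyme is mostly open, and AMP alone
  leaves the conformational distribution unchanged, so EM = E);
* binding: k_on_ATP 0.5 µM⁻¹s⁻¹, k_off_ATP 25 s⁻¹ (K_d 50 µM);
  k_on_AMP 0.04 µM⁻¹s⁻¹ (open = closed), k_off_AMP 4 s⁻¹ (K_d 100 µM).
  Equal open/closed AMP off-rates close the E_O–EM_O–EM_C–E_C thermodynamic
  cycle exactly (detailed balance requires
  k_off_closed = k_off_open · K_C(E)/K_C(EM), and K_C(E) = K_C(EM) here),
  so with `k_pt = 0` the default network satisfies detailed balance on every
  cycle — a property the tests exploit.

The binding stand-ins were calibrated once, by scanning physically plausible
ranges for the combination that reproduces the qualitative variant
contrasts at the default concentrations: an interior activity maximum with
a strictly positive high-AMP plateau for WT/L107I/L82V, a monotone
non-decreasing AMP curve for F86W, monotone ATP curves for all four, and
inhibition ordered L82V > L107I > WT. They are deliberately slower than
diffusion-limited association; with fast binding the AMP-first pathway
dominates so early that even F86W inhibits strongly, which contradicts the
observed phenotype.

**A structural property worth knowing:** with the occupancy anchors above
and a single shared interconversion rate of 250 s⁻¹, the inhibited branch
differs between variants only through `p_open(ETMinh)`, so the extra
residence time of the AMP-first route is `1/(p_open · k_conv)` and the
spread of inhibition indices across variants is intrinsically compressed
(defaults: WT 0.0054, L107I 0.0069, L82V 0.0259, F86W exactly 0 on the
default grid). The *ordering* and *signs* are robust; the *depth* of
inhibition is not a prediction of this parameterization — deep inhibition
with a flat F86W would require variant-specific interconversion rates,
which are not currently measurable. The interconversion scan quantifies
this: the index rises to ≈0.96 as k_conv → 0 and vanishes for
k_conv ≳ 10³ s⁻¹.

**Default grids** (the package's study conditions): AMP activity curves on
`geomspace(1, 10^4, 61)` µM at 1,000 µM ATP; ATP curves on
`geomspace(1, 10^5, 61)` µM at 1,000 µM AMP. The inhibition index
`1 − v(last)/max(v)` is defined on the curve it is given; ties in the
maximum resolve to the first maximal point. Closing-rate scans use 13
logarithmic factors over [0.1, 10]; the interconversion scan 10 logarithmic
points over [1, 10^5] s⁻¹.

## Synthetic data: what is and is not emulated

Activity datasets apply multiplicative Gaussian noise (CV =
`noise_fraction`, floored at zero) to rate-law or network-steady-state
velocities — the error structure of initial-velocity assays. Photon data
are generated exactly as the HMM assumes: a two-state Gillespie path,
photons as a homogeneous Poisson process, each photon's channel Bernoulli
with the efficiency of the state at its arrival time; bursts draw
exponential durations truncated so the expected photon count meets the
30-photon histogram threshold, and undersized bursts are discarded and
regenerated. Not emulated: background photons, donor leakage and detection
factors, state-dependent brightness, detector dead time, and
diffusion-shaped burst intensity profiles. Passing recovery tests therefore
demonstrates correctness of the estimators under their own model
assumptions — not robustness to the artifacts of real detectors, which
would need correction factors this package deliberately omits.

## Numerical choices

* **Steady states** by SVD null space of the generator transpose
  (`rcond = 1e-12`), normalized; a null space of dimension ≠ 1 raises a
  degenerate-model error (disconnected network). Negative entries beyond
  −1e-9 are rejected; smaller ones are clipped and renormalized.
* **Master-equation oracle** (tests only): `p0 · expm(Q·T)` with T set to
  40 relaxation times of the slowest non-stationary eigenmode.
* **Gillespie**: direct method in a numba kernel with a single seeded
  stream per trajectory; phosphotransfer jumps are counted as turnover
  events. The Monte-Carlo standard error of the event rate uses batch means
  (10 windows) rather than √N, which would understate the error of a
  correlated event stream.
* **Photon likelihood**: forward recursion over photons with closed-form
  2×2 propagators (analytic eigendecomposition of the two-state generator,
  not generic `expm`), renormalizing the forward vector at every photon and
  accumulating log norms, so streams of millions of photons do not
  underflow. Efficiencies pinned at 0/1 that contradict an observed photon
  yield −inf with a warning. Viterbi runs in log space with the same
  factorization; argmax ties break toward the open state.
* **HMM fitting**: Nelder–Mead over `(log k_open, log k_close,
  logit E_open, logit E_closed)`, 5 restarts by default with seeded
  log-space jitter around a data-driven start (efficiencies straddling the
  pooled proximity ratio; both rates at 5% of the photon detection rate).
  The `E_open < E_closed` convention resolves the exact label-swap symmetry
  of the likelihood. Identifiability is flagged when the occupancy-weighted
  efficiency separation `min(p, 1−p)·(E_closed − E_open)` falls below 0.02,
  which also catches fits that explain the data with a never-visited state.
  A default floor of 10⁴ photons guards rate estimation.
* **Substrate-inhibition fit**: relative (multiplicative-error) residuals;
  Vmax and K_M in log space; inhibition through `1/K_I ≥ 0` so
  Michaelis–Menten data sit on the boundary. K_I is reported as ∞ when
  `1/K_I` is within one standard error of zero, or — when the boundary
  optimum leaves no standard error — when `S_max/K_I < 10⁻⁶`. An optional
  residual-activity term `v_res·S/(K_M+S)` is available behind a flag, off
  by default. Isotherms fix the Hill exponent at 1 (flag for a free
  exponent) and fit C50 in log space.

## Validation problem sizes

The shipped validation studies use: 20 randomized parameter sets (default
rates perturbed by log-uniform factors in [1/3, 3]) for the steady-state
oracles, with 50 s Gillespie trajectories; 200 random photon cases of ≤12
photons for exact likelihood/Viterbi enumeration; 20 replicates of 10 s at
50 kHz (moderate exchange, 2,000/3,000 s⁻¹) and one 20 s stream at 200 kHz
(fast exchange, 23,937/27,307 s⁻¹) for rate recovery; 100 replicates at 5%
noise for K_I recovery and 50 at 3% noise for C50. These sizes make the
whole suite run in a few minutes on one CPU while keeping Monte-Carlo
margins comfortable.

## Known limitations

* No ADP species, reverse reaction, or product rebinding: the model
  addresses initial-velocity conditions only.
* The depth of simulated inhibition is compressed at the default shared
  interconversion rate (see above); variant contrasts are qualitative.
* The photon model ignores brightness differences between states; if real
  data had strong state-dependent count rates, rate estimates would be
  biased in ways these tests cannot reveal.
* Burst boundaries are taken as given; no burst search from raw timetags.
* Exact binding rate constants are stand-ins; quantities that depend only
  on occupancies and anchored rates (orderings, scan shapes, oracle
  agreements) are robust to them, absolute turnover values are not.
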