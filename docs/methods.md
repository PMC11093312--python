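# Methods

## Plant model

The pump is modelled as two well-mixed compartments: `x1`, the drug
concentration in the target region (the controlled output), and `x2`, the
concentration in the reservoir and ion bridge. Both obey

```
ẋ1 = D(x2 − x1) + a(u, x) − g·x1
ẋ2 = D(x1 − x2) + a(u, x)
```

where `D` (1/s) is the diffusive exchange rate, `g` (1/s) a leakage term
draining the target, and `a(u, x)` the electrophoretic actuation: a term
linear in the applied voltage `u` and Hill-saturated in the donor
concentration, `a = u·c·x_donor/(d + x_donor)`. The voltage axis is split
into four regions by thresholds `ε > 0` and `−ζ < 0`; the strongly biased
regions (`u > ε`, `u < −ζ`) use rate/half-max pairs `(c1, d1)`/`(c2, d2)`
and the weakly biased ones `(cc1, dd1)`/`(cc2, dd2)`, with the donor being
the reservoir for positive voltages and the target for negative ones.
Boundary points are assigned to the weak regions (`u = ε`, `u = 0`,
`u = −ζ` all fall in the low-magnitude regions).

Two idiosyncrasies of the model definition are kept verbatim and exposed as
switches rather than silently "fixed":

* the actuation term enters `ẋ2` with the **same** sign as `ẋ1`, so
  actuation does not conserve `x1 + x2` (a positive voltage grows both
  compartments). `conservative_actuation = true` negates the `ẋ2`
  contribution for users who want a mass-conserving variant.
* the strongly negative region pairs `d1` with the `ẋ1` equation but `d2`
  with `ẋ2`. `symmetric_denominators = true` uses `d2` in both.

Both default to the as-written behaviour. The vector field is discontinuous
across region boundaries; no continuity there is claimed or tested.

### Integration

Fixed-step classical RK4 with the control held constant over each
controller sampling period (zero-order hold — exactly what a sampled loop
applies physically), subdivided into 10 internal sub-steps per 1 s period
by default. Concentrations are clipped at zero after each internal
sub-step (and inside RK stages before evaluating Hill terms), because large
negative voltages can push the model into unphysical negative
concentrations. Non-finite states or controls raise immediately rather
than propagating NaNs. On a pure-decay configuration (`D = 0`, `u = 0`)
the integrator matches `x1(0)·e^{−gt}` to ~1e−13 relative at `dt = 0.01`,
comfortably inside the 1e−6 budget the test suite enforces.

### Parameter preset

No fitted parameter values for this model were ever published, so the
shipped `pump_insilico` preset is this package's own choice, picked once to
make the simulated experiment behave like the device it stands for: a
first-order-like response with time constant `1/(D+g) ≈ 17 s`, a passive
(zero-voltage) level well below the operating point, and an output that
reaches ≈17.5 for a saturated voltage of ≈1.05 V — inside the 1.5 V
in silico amplitude with headroom. Values: `D = 0.01`, `g = 0.05`,
`c1 = c2 = 1`, `cc1 = cc2 = 0.5`, `d* = dd* = 50`, `ε = ζ = 0.5 V`
(below the 0.5–2 V range the device is normally driven in), initial state
`x1 = 0`, `x2 = 50`. The nA-scale plant used for synthetic delivery logs
is the same preset with the concentration axis rescaled ×70 (rates,
half-maxima and state scale together, which rescales trajectories exactly;
70 ≈ 1200 nA / 17.5 puts the 1200 nA operating point at the same relative
position of the actuation range). These are simulation conventions, not
device measurements.

## Controller

Per 1 s sample `i ≥ 2` (the first sample only primes the error history and
applies `A_max·sin(u_init)`):

1. `e(i) = y(i) − r(i)`;
2. gain switch: `e > 0 → (K, ρ) = (κ1, ρ1)`, else `(κ2, ρ2)` — the branch
   condition is strict, so `e = 0` takes the else branch;
3. `ė = (e(i) − e(i−1))/T` (backward difference: causal, and consistent
   with starting at the second sample);
4. manifold `s = K·e + ė`;
5. switching rate `ν(i) = μ·ρ·sign(s·A_max·cos(u(i−1)))` with
   `sign(0) = 0` (no actuation exactly on the manifold) and `ν(1) = 0`
   (no pre-measurement information; the first trapezoid is a half-step);
6. trapezoidal integration `u(i) = u(i−1) + T·(ν(i) + ν(i−1))/2`;
7. actuating function `u_sat = A_max·sin(u)`.

`μ` is the experimentally determined sign of the plant input gain,
validated to ±1 and −1 by default (response monotonically increasing with
input). The `cos(u(i−1))` factor is the gradient of the actuating
nonlinearity: past a peak of the sine the control authority reverses and
the switching term reverses with it. The abstract plant quantities
(drift, input gain, disturbance) never appear numerically in the
controller — only `sign(g(x))` via `μ` and the actuating gradient via the
cosine.

Two structural guarantees follow and are machine-checked as properties:
`|u_sat| ≤ A_max` for every sample of every run, and the per-sample
control movement obeys `|u_sat(i) − u_sat(i−1)| ≤ A_max·T·(ρ(i)+ρ(i−1))/2`
(trapezoidal rate integration composed with the `A_max`-scaled,
1-Lipschitz sine), which is the quantitative form of the chattering
mitigation.

### PID baseline

Discrete positional PID on `e = r − y` (control-convention sign, so
positive gains push a low output up), trapezoidal integral,
backward-difference derivative, and an output clip to `[−A_max, +A_max]`
applied *after* the law with no anti-windup — deliberately modelling a
"hard limit" bolted on from outside. Its gains (`kp = 0.3`, `ki = 0.02`,
`kd = 0.05`) are this package's choice, tuned only so the loop operates
near the bound: the comparison made with the SMC is structural (whose raw
command violates the amplitude) and not a numeric benchmark.

## Closed-loop harness

Order per sample: measure → error → controller → apply, with the applied
voltage held for the full period. References: constant; steps
(`r0 − Δ·⌊t/period⌋`); linear decline (affine from `r0` to `r_end` across
the run). Optional zero-mean Gaussian measurement noise (default off) is
driven by a `numpy` generator seeded per run; identical seeds give
bit-identical traces. Experiment length defaults to `n = 1200` samples at
`T = 1 s`, matching both shipped controller presets.

## Dosimetry

Charge is the trapezoidal integral of the current trace (exact on affine
signals); moles of electrons are `Q/F` with `F = 96485.33212 C/mol`; drug
moles are `(η/100)·n_e/z`. The charge number defaults to `z = 1` (the drug
is singly protonated at the operating pH) and the molar mass to the
hydrochloride salt (345.79 g/mol) since the reservoir is loaded with the
hydrochloride; the free base (309.33 g/mol) is a documented alternative.
The known 0.45 mg ↔ 1200 nA dosing point comes from device calibration,
not from Faraday arithmetic at a fixed efficiency, so it is *not* computed
as an identity anywhere; calibration enters only through
`fit_calibration`, an OLS line through user-supplied
(charge-or-current, delivered-amount) points whose abscissa semantics are
the caller's.

## Log analytics

Logs carry `d` (reference), `err` (output − reference), `u` (applied
voltage) and `plot_timer` (s), one row per second; the output is
reconstructed as `d + err`. Column matching is case-insensitive and
ignores underscores/spaces (the deposited legend itself typesets the timer
name irregularly). Metrics: **average output** is the mean reconstructed
output over the *full* run (the experiment-wide delivery proxy), while
**steady-state relative error** is restricted to `plot_timer > 100 s` —
the documented settling window that lets a run starting from 0 nA reach
its reference. Its default definition is the per-sample mean of
`|err|/reference` in percent; an `aggregate` mode (`mean|err|/mean ref`)
is provided. The printed summary table of the original experiments does
not state which form produced its rounded percentages, and the deposited
logs needed to discriminate are not bundled here, so the per-sample form —
the stricter, more standard choice — is the default.

## Synthetic delivery logs

`ionloop.synthetic` regenerates the three experiment designs (constant
1200 nA; linear 1500→900 nA; steps 1500 −300 per 400 s; 1200 samples at
1 s) by running the in vitro controller preset against the ×70-rescaled
plant with Gaussian measurement noise of sd 25 nA — the order of
fluctuation the finite readout resolution and fast device transients
superimpose on a real current trace. These logs exercise every analysis
code path with realistic shapes: they settle within ~100 s, chatter about
the reference, and (like the real device) average *below* the reference
because the asymmetric gain pair corrects upward excursions roughly ten
times faster than downward ones. What they do not capture: device-to-device
variability, performance decay over the run, voltage quantization
(1.95 mV) and current quantization (0.125 nA), or correlated disturbance.
Passing tests on them validate the control law, the harness and the
analytics — not the physical device; their metric values characterize the
simulation and are reported as such by `scripts/acceptance.py`.

## Numerical and design notes

* Region dispatch covers the real line exactly once; tested on 1e5 random
  voltages against the raw inequalities.
* Error bands for the in silico tracking run (mean `|e| < 0.1`, max
  `|e| < 0.75` after 100 s) are regression bands calibrated once from the
  shipped preset's behaviour — no published numeric error exists for this
  experiment — and exist to catch regressions, not to claim accuracy.
* The in silico output is nominally a fluorescence-scale quantity while the
  model states are concentrations; the map between them is taken as the
  identity on `x1`, and the unit mismatch is acknowledged rather than
  modelled.
* `sign(0) = 0`, boundary-to-weak-region assignment, `ν(1) = 0`, and the
  strict `e > 0` branch are the tie-break conventions; each is unit-tested.
* Problem sizes in the test suite and acceptance script (120–1200-sample
  runs, 100-run randomized saturation study) are chosen to exercise every
  behaviour at full experiment length where it matters while keeping the
  whole suite in seconds.

## Known limitations

* The plant preset is qualitative; fitting it to data is out of scope, so
  simulated magnitudes (voltages, settling times) should not be read as
  device predictions.
* The weak-voltage regions are rarely exercised by the shipped presets
  (the loop operates mostly above `ε`); their dynamics are unit-tested but
  not stressed in closed loop.
* Replay of the deposited experimental logs requires the user to supply
  those files; the tests that assert their printed summary statistics fail
  until `data/supplementary/` is populated.
* No hardware I/O: the plant interface contract (`apply(u) -> y` once per
  period) is the seam where a device backend would plug in.
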