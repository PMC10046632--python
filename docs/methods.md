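# Methods

## Sensor model

A membrane-type surface stress sensor (MSS) channel is a polymer receptor
film whose gas sorption deforms a membrane instrumented with four
piezoresistors in a Wheatstone bridge. The simulator models each gas
component independently with single-mode first-order sorption kinetics:

    dq_i/dt = (K_i · c_i(t) − q_i) / τ_i,    q_i(0) = 0

where `c_i(t)` is the concentration delivered by the active valve segment,
`K_i` a dimensionless partition coefficient, and `τ_i` the sorption time
constant. This is the simplest model that reproduces the characteristic
behaviour of polymer-coated nanomechanical sensors under repeated
injections — an initial transient over the first few cycles followed by a
cycle-periodic steady state — while staying strictly linear. Real films
combine diffusion and viscoelastic stress relaxation with a spectrum of time
constants (typically 0.1–100 s); a multi-mode response can be emulated by
listing one pseudo-component per mode. The admissible τ range is bounded to
[0.05, 200] s by default: below half a sampling period the film response is
effectively instantaneous, far above the run length it is indistinguishable
from drift.

The film strain signal is `s(t) = Σ_i g_i q_i(t)` with signed responsivity
`g_i` (fractional resistance change per sorbed unit), and the readout is

    V_out = (V_B / 4) · (ΔR₁/R₁ − ΔR₂/R₂ + ΔR₃/R₃ − ΔR₄/R₄)

with the four arm changes given by a configurable weight pattern times
`s(t)`. The default pattern (+1, −1, +1, −1) gives `V_out = V_B · s(t)`; the
bridge operation is the single place where volts are converted to μV, and
everything downstream works in μV. The default bias is V_B = −1.0 V and the
sampling rate 100 Hz.

Integration uses the exact per-segment exponential update
`q(t₀+Δ) = Kc + (q(t₀) − Kc)·e^(−Δ/τ)` on the sampling grid, so results
carry no integrator tolerance. Samples sit at `t = k/f` for
`k = 0 … duration·f` inclusive; valve segments are half-open `[start, end)`
and the sample at a switch belongs to the new segment, which makes
segmentation unambiguous. Valve switching is instantaneous — the gas line's
dead volume is not modelled; a dead time could be added later as a pure
delay.

## Protocols

Both protocols alternate two flow paths every `interval` seconds (default
5 s) for `total_duration` (default 120 s), and both start with the
**Sample-2 path at t = 0**:

* **rDC**: Sample 2 and Sample 1 alternate directly, no purge.
* **normal**: the Sample-2 vial is empty, so the schedule alternates carrier
  air with the sample; Sample-1 injections start at 5, 15, …, 115 s exactly
  as in rDC mode.

Keeping the Sample-1 phase identical across protocols is what lets a single
analysis window serve both, and makes the linear-model superposition
identity `rdc(A,B) = normal(A) − normal(B) + rdc(B,B)` hold pointwise — the
baseline against which any nonlinear co-sorption enhancement in a real film
would register as a deviation (such nonlinear terms are deliberately not
modelled).

Measurement imperfections are additive and stationary: i.i.d. Gaussian noise
per sample, a linear baseline drift (thermal), and optionally a single
sinusoid standing in for non-Gaussian undulation from pumps/valves.
Seeds are mandatory explicit inputs everywhere; no global random state.

## Analysis pipeline

Defaults in parentheses; all are explicit parameters.

1. **Window** (55–115 s, half-open, boundaries on-grid): chosen so the
   window starts at a Sample-1 injection start and the transient has died
   away. A diagnostic `cycle_convergence` check reports the consecutive-cycle
   maximum change, which decays geometrically with ratio ≤ e^(−T_cycle/τ_max);
   it warns (never alters results) and, at its default 5% relative
   tolerance (≈ three time constants), fires within ⌈3·τ_max/T_cycle⌉ cycles.
2. **Segmentation** (10 s cycles, N = 6): a cycle spans [Sample-1 start,
   next Sample-1 start) = 5 s of Sample 1 followed by 5 s of Sample 2 (or
   carrier). Concatenating the cycles reproduces the window bit-exactly.
3. **Baseline correction**: per cycle, subtract the first sample, so every
   cycle reads 0 μV at the Sample-1 start. Offsets are removed; slopes are
   retained (no detrending).
4. **Averaging**: pointwise mean over the N cycles.
5. **Noise level**: ordinary least-squares straight line over the last
   second of the cycle (9.0–10.0 s, half-open, 100 samples at 100 Hz), RMS of
   the residuals with divisor n — the literal root-mean-square. The
   OLS-unbiased divisor n − 2 is available via `residual_dof=2`; for the
   100-sample default the two differ by 1%. The "raw" noise used for the
   theoretical scaling is the mean of the per-cycle noise levels.
6. **Signal intensity**: output(5 s) − output(0 s) of the averaged,
   baseline-corrected cycle, using the single grid samples (no smoothing).
   Intensity is kept signed internally; S/N uses its magnitude, since
   responsivity signs are a modelling convention.
7. **Theoretical noise**: raw noise / √N for a single trace; for a
   differenced pair of normal measurements, the quadrature sum
   √(σ_A² + σ_B²) of the two traces' theoretical levels.
8. **Replicate aggregation**: S/N is computed per measurement and the mean
   and sample standard deviation (ddof = 1) are taken afterwards; this is
   not the ratio of the mean intensity to the mean noise.

No low-pass or moving-average filter appears anywhere in the pipeline:
smoothing would attenuate the fast sorption response that carries most of
the kinetic information, and the averaging step already provides the noise
reduction.

## Synthetic study defaults

The default experiment emulates a two-similar-odors comparison at desk
scale: both sources carry a dominant humidity component (concentration 100,
arbitrary units), two shared base VOCs (10 each), and one distinct flavor
component per source (1 each) — the regime where interfering gases dominate
the raw response. Two films with contrasting kinetics are simulated: a
PPPO-like strong sorbent (τ = 0.5–8 s, stronger affinity for flavor A) and a
PS-like slower film (τ = 0.8–20 s, stronger affinity for flavor B), so the
two channels yield odor-difference signals of opposite sign. Gaussian noise
is σ = 2 μV, placing the raw single-cycle S/N around 4–8 so the averaging
benefit is visible but not trivial; drift is 0.05 μV/s; undulation is off by
default. Six replicates of {normal-A, normal-B, rDC} are generated per
channel with one seed per (replicate, protocol, channel) — 36
pairwise-distinct seeds spawned deterministically from the base seed — so
channel noise is independent, as it would be for two physical bridges.
None of these values is calibrated to real food VOC chemistry or
published polymer sorption data; they exercise the analysis, not reproduce
any instrument.

What the generator does *not* emulate — and what passing tests therefore do
not demonstrate about real data: non-Gaussian electronic noise beyond a
single sinusoid, humidity/temperature physics, flow and dead-volume
dynamics, film aging, and above all any nonlinear co-sorption interaction
between residual common VOCs and the distinct components. In this simulator
the rDC intensity exactly equals the difference of the normal intensities;
on real hardware a film/odor combination can break that equality, and this
linear baseline is precisely the reference an observed enhancement should be
measured against.

## Numerical and design notes

* Degenerate inputs: a zero noise floor makes S/N undefined; the summary
  reports the floor and S/N = NaN with a warning rather than ∞. With the
  zero-noise simulator the measured floor is not exactly zero but the tiny
  curvature of exponential tails inside the fit window (~10⁻³ μV).
* Trace CSVs serialize time with 4 decimals (exact at 100 Hz) and output
  with 6 significant digits; reading a written file is lossless thereafter.
  Metadata travels as `#`-prefixed header comments to keep traces
  single-file portable. Summary tables use 4 significant digits.
* Steady-cycle identities are verified with the analysis window moved to
  300–360 s of a 360 s run, where the slowest default component
  (τ = 20 s) has decayed below 10⁻⁶ of its initial transient; at the default
  55 s window its residual is ~10⁻⁴ relative, which is invisible under the
  default noise but matters for machine-precision checks.
* Monte-Carlo checks (averaging 1/√N law, quadrature propagation) use 200
  seeded trials of 6 × 1000-sample cycle sets — enough for the mean ratios
  to settle well inside the tolerances without noticeable runtime.

## Known limitations

Single-mode first-order kinetics per component; linear responsivity; no
cross-component interaction in the film; additive stationary noise; the
normal-protocol carrier is perfectly clean. The pipeline assumes the
analysis window is Sample-1-aligned and leaves window choice to the caller
(with the convergence check as a guard), mirroring how steady-state regions
are selected manually in practice.
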