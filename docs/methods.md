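# Methods

## Physical model

### Venturi flow–pressure relation

The tube has an entrance bore of diameter `d₁` and a throat of diameter
`d₂` (areas `Aᵢ = πdᵢ²/4`). For incompressible, inviscid flow,
Bernoulli plus continuity give

```
Q = A₂ √( 2Δp / (ρ (1 − (A₂/A₁)²)) ),      Δp = ρ (1 − (A₂/A₁)²) (Q/A₂)² / 2
```

with the throat area outside the radical and the squared throat/entrance
area ratio inside it — the only arrangement that yields real-valued
flows for `Δp > 0`. The pair is an exact algebraic inverse (round-trip
tested to 1e-9 relative). An optional discharge coefficient multiplies
the ideal flow; it defaults to 1.0, i.e. the model is ideal Bernoulli
plus an explicit friction correction rather than an empirically
calibrated orifice equation.

Defaults are the *as-printed* bores (27.8 mm / 9.8 mm): FDM printing
undersizes the designed 28/10 mm by roughly the nozzle tolerance, and
the processing must use the bores the air actually sees.

Air properties are fixed at 20 °C / 101.325 kPa: ρ = 1.204 kg/m³,
μ = 1.81 × 10⁻⁵ kg/(m·s). No temperature or humidity compensation is
applied.

### Flow regime

`Re = 4ρQ/(πdμ)`. `transition_flow` reproduces the design-time sweep:
flow ascending in 0.1 L/min steps from 0 to 50 L/min, transition = first
step with `Re > 2000` (strict inequality). For the 9.8 mm throat this is
13.9 L/min, in agreement with the closed form
`Q* = Re·πdμ/(4ρ) = 13.885 L/min` rounded up to the next sweep step.
Since forced expirations reach hundreds of L/min, the instrument
operates almost entirely in the turbulent regime, which motivates the
friction model below.

### Wall friction

3D-printed walls have ~10 μm layer roughness. The friction correction is
Darcy–Weisbach per instrumented section,

```
Δp_f = f · (L/d) · ρ v² / 2
```

summed over the entrance run (default length = one entrance diameter)
and the throat run (default 1.5 throat diameters — matching the minimum
BS divergent length; both lengths are configurable when the technical
drawing provides them). The friction factor `f` is the explicit Haaland
correlation with relative roughness `ε/d` for `Re ≥ 2000` and the
laminar `64/Re` law below. The model is exposed as a plain function so
an alternative correlation can be swapped in.

Magnitude: for the as-printed tube the friction/Venturi pressure ratio
peaks at ≈8% just above the transition (where the Haaland factor is
largest) and falls below 5% beyond ~70 L/min. In the laminar regime the
ratio formally diverges as `Q → 0` (friction is linear in `Q`, the
Venturi term quadratic), but both terms are then far below one ADC step
(~2.6 Pa), so laminar drag is irrelevant to the reported volumes.
`max_drag_fraction` therefore audits the ratio over the turbulent
working range only.

## Electronics chain

Forward (simulator) direction:

1. `Δp = Δp_venturi(Q) + Δp_friction(Q)` — the port-to-port pressure the
   sensor sees includes the wall loss, which is exactly what the inverse
   pipeline removes again.
2. Sensor: `V = V_s (0.09 · P_kPa + 0.04)` with `V_s = 5 V` — the
   published MPX5010 characteristic (0.2 V at zero pressure, 4.7 V at
   the 10 kPa full scale). The part is named in the device build but its
   transfer curve is not; the datasheet curve is the only defensible
   reconstruction and is isolated behind `SensorSpec` so a recalibrated
   curve can replace it. Pressures above 10 kPa clip (hardware
   saturation) and the clip count is reported, not hidden.
3. Divider: ×10/14.7 = ×1/1.47, keeping the 4.7 V sensor maximum below
   the 3.3 V ADC reference (4.7/1.47 = 3.2 V).
4. ADC: counts = round(V_divided · 4095 / 3.3), clipped to [0, 4095].
   The divisor is `n_levels − 1` so that count 4095 maps exactly to
   3.3 V; the nominal resolution 3.3/4096 ≈ 0.805 mV/step differs from
   this by <0.03%. With quantization disabled the simulator emits exact
   fractional counts for oracle tests.

Datasheet error fractions (accuracy ±5% FSS = ±0.225 V, linearity 0.2%
= 0.02 kPa, hysteresis 0.1% = 10 Pa) are carried as budget constants;
hysteresis is available as an optional bounded perturbation in the
simulator only and is off by default — the device treats these as error
budget, not as corrections.

The noise model applies, sensor-side: Gaussian voltage noise (default
σ = 5 mV, about half an ADC step after the divider — consistent with a
clean but unshielded breadboard build), an optional linear offset-drift
ramp (default 0, since the pipeline recalibrates every run), and the
quantizer. Identical seeds give byte-identical traces.

## Breath pipeline

1. **Offset calibration.** The acquisition protocol guarantees a quiet
   lead-in; the offset is the mean reconstructed sensor voltage over the
   first 500 samples. If the baseline standard deviation exceeds 3× the
   configured noise budget the run is rejected (the subject was already
   blowing). With σ = 5 mV noise the standard error over 500 samples is
   ~0.22 mV, i.e. ~0.5 Pa of pressure bias.
2. **Filtering.** Second-order zero-phase Butterworth low-pass at 25 Hz
   (applied forward and backward, so the effective order is four and
   the phase is exactly zero — peak timing shifts by <2 samples).
   25 Hz retains PEF dynamics at 1 kHz sampling while suppressing
   quantization and sensor noise. The 4% segmentation threshold is
   applied to the filtered flow (configurable).
3. **Inversion.** Counts → voltage (×1.47) → offset-subtracted pressure
   (negative values clamp to zero with a counter — baseline noise
   straddles the offset and the Venturi relation needs `Δp ≥ 0`) → ideal
   flow → friction correction by fixed-point passes
   `q ← flow_from_dp(Δp − Δp_friction(q))`. One pass moves the flow by
   well under 1% at spirometric magnitudes; the iteration count is
   configurable.
4. **Segmentation.** Anchor at the (first) flow maximum; walk outward
   until the flow drops below 4% of the maximum on either side. The
   threshold is relative, making segmentation invariant to uniform flow
   scaling; 4% is comparable to the residual noise floor and trims a
   negligible fraction of volume (for a half-sine stroke the trimmed
   tails hold ~0.08% of the volume). Segments touching the trace
   boundary produce a truncation warning.
5. **Metrics.** PEF = maximum in-segment flow. FVC = trapezoidal
   integral of flow over the segment. FEV₁ = integral over the first
   second from segment start, clamped to FVC for exhalations shorter
   than 1 s. Trapezoidal integration at the native 1 ms step is the
   minimal-assumption choice; its error is covered by the end-to-end
   recovery tests (0.5% bound, noise-free). Time zero is the segment
   start — the back-extrapolated time zero of clinical spirometry
   standards is deliberately not implemented, nor are
   manoeuvre-acceptability grading or predicted-value equations.

## Synthetic data: what it does and does not emulate

Pump strokes are half-sine by default (a hand-compressed pump starts
and stops smoothly; the closed-form peak `πV/(2T)` makes an oracle), or
trapezoidal; every stroke is renormalised so its trapezoidal integral
equals the requested volume to ~1e-6 L. Forced expirations are a linear
rise to PEF followed by an exponential decay whose time constant is
solved (Brent) so the integral equals the requested FVC — a minimal
two-parameter family with the right PEF-then-decay morphology.

These waveforms are *not* physiological: no inspiratory limb, no airway
collapse dynamics, no intra-subject variability, no disease-specific
shapes. Passing the recovery tests therefore demonstrates that the
signal chain is inverted correctly under realistic sensor noise — it
does not validate clinical accuracy on human manoeuvres, which requires
hardware and participants. Strokes fast enough to exceed the 10 kPa
sensor range (2 L in under ~0.33 s) saturate, report a nonzero clip
count, and recover a volume biased low; this mirrors the hardware and
is asserted, not hidden.

## Agreement statistics

- Error metrics with the reference device as the percentage
  denominator; signed quantities are device − reference.
- Bland–Altman with the conventional 1.96 multiplier and the sample
  (n−1) standard deviation of differences.
- Correlation gate: Shapiro–Wilk per series; Spearman if *either*
  series is non-normal at α = 0.05 (the conservative reading), Pearson
  otherwise.
- ICC(A-1) — McGraw & Wong two-way, absolute-agreement, single
  measurement:

  ```
  ICC = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E)),  k = 2
  ```

  with confidence intervals by the F-distribution method using
  Satterthwaite degrees of freedom, reported at 80/90/95/99% (nested by
  construction). Absolute agreement penalizes a systematic offset
  between devices, which a consistency-type ICC would ignore — the
  property that makes it the right estimator for device validation.
  Perfect agreement (MS_E = 0) returns ICC = 1 with degenerate
  intervals; zero total variance raises rather than fabricating a
  value.

## Problem sizes and determinism

The simulated pump experiment uses 30 strokes of 2 L with durations
uniform in 0.3–2.5 s — the bench protocol of the experiment it models —
at 1 kHz over 10,000-sample captures. All randomness flows through
`numpy.random.default_rng` seeded from a single experiment seed (the
per-stroke noise seeds are drawn from it), so every reported number is
exactly reproducible. Property batteries run at 100 random matrices for
the ICC oracle and 1,000 random datasets for the error-metric
inequalities.

## Known limitations

- The sensor transfer curve is the nominal datasheet characteristic; a
  real unit needs per-device calibration (the offset is calibrated per
  run, the slope is not).
- The friction model assumes fully developed pipe flow in short
  sections and ignores the converging/diverging transitions' local
  losses; it is a correction of at most ~8%, so errors in it are
  second-order.
- Compressibility, temperature and humidity effects are out of scope.
- Segmentation assumes a single expiratory effort per capture; multiple
  peaks resolve to the largest (first on ties).
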