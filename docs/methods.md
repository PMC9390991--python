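# Methods

## The model

`thermogrowth` simulates hypocotyl elongation of *Arabidopsis* seedlings
growing under diel square-wave light/temperature forcing, from the coupled
activities of four regulators plus a growth equation.  All activities are
dimensionless and scaled so that a wild-type channel multiplier is 1.0;
time is in hours, lengths in mm, temperature in °C (22 °C is the reference
throughout).

With `L(t) ∈ {0,1}` the light state, `T(t)` the temperature,
`q_B(T) = Q10_B^((T−22)/10)` and `q_E(T) = Q10_E^((T−22)/10)`:

```
dB/dt = L·k_pB·(g_B − B) − (L·k_rB + k_dB·q_B(T))·B
dE/dt = g_E·a_E·σ(t,T) − (d_E·q_E(T) + d_EC·C)·E
dC/dt = (C_∞(L,T)·g_C − C)/τ_C
dP/dt = g_P·a_P/(1 + (E/K_E)^h_E) − d_P·(1 + β_B·B)/(1 + β_C·C)·P
dH/dt = v0 + v_max·A^n_G/(1 + A^n_G)
  A    = (P/K_G)/(1 + B/K_Bg + E/K_Eg + Y/K_Yg)
  Y    = g_Y·Y0/(1 + C/K_C)                      (HY5 quasi-steady state)
```

- **phyB (B).**  Photoactivation fills a pool capped at `g_B`; reversion has
  a light-driven component and a thermal (dark-reversion) component that
  accelerates with a Q10 law — warmth depletes active phyB, fastest in
  darkness.  In continuous light the photoequilibrium is dominated by
  `k_pB`/`k_rB`, so warm nights, not warm days, are the main phyB channel.
- **ELF3 (E).**  Synthesis follows a clock-controlled transcriptional drive
  `σ = ρ(T)·[b_E + (1−b_E)·Π(t)]` with a bump `Π` of width `w_E` hours
  opening at dusk; `ρ(T) = min(1, e^{−ρ_E(T−22)})` damps transcription when
  warm.  Protein decay carries its own temperature factor `q_E` with
  `Q10_E < 1` in the reference set: warmth slows turnover more than it
  damps synthesis, so net ELF3 protein is *higher* at 28 °C during the day,
  matching the observed protein waveform, while the evening complex's
  growth-repressive output is overridden downstream by the phyB and COP1
  thermal channels.  In constant conditions (DD/LL) the clock free-runs and
  the bump is replaced by its 24-h mean under a reference 8-h photoperiod.
- **COP1 (C).**  Nuclear activity relaxes toward a target: saturated at
  `C_dark` at night regardless of temperature, and `C_light·e^{ε_C(T−22)}`
  in the day, capped at the night ceiling — COP1's thermal action is a
  daytime phenomenon.  `τ_C` is short (≈ 0.1 h) so the target is tracked
  closely.
- **PIF (P).**  One aggregate "PIF activity": transcription Hill-repressed
  by ELF3, removal enhanced by active phyB and suppressed by COP1
  (stabilization).  PIFs therefore peak at night and rise with warmth via
  both the B and C channels.
- **Growth (H).**  Elongation is a steep Hill function (`n_G = 6`) of a
  promoter-occupancy ratio `A` in which phyB, ELF3 and HY5 compete with PIF
  binding.  The steepness makes dark growth *saturated*: etiolated
  seedlings (WT, ELF3-overexpressors, COP1 overexpressors alike) grow at
  `v0 + v_max` regardless of regulator dosage, which is what makes dark
  lengths insensitive to most genotypes and dark thermal responses small.

Genotypes are constant multipliers `g_B, g_E, g_C, g_P, g_Y` on the five
channels (null = 0, hypomorph < 1, overexpressor > 1); double mutants are
component-wise products.  Hypomorph residual activities and overexpression
gains are fitted quantities.

### Timeline

Seeds get a 4-h light pulse then 20 h dark at 22 °C (germination
synchronization), then 5 days in the growth regime; time 0 is the start of
the growth phase, dawn anchors each 24-h cycle.  Simulations start at the
prelude from a dark-adapted state (B = 0; E, C, P at the dark constant-drive
steady state at 22 °C; H = H0), so genotype differences at t = 0 are
emergent, not asserted.  The light window is half-open `[dawn, dusk)`;
temperature steps (no ramp) at t = 0.  The headline readout is thermal
elongation ΔH = H(28 °C) − H(22 °C) at 5 days, per genotype and
photoperiod.

## Numerics

Two integration paths share the same breakpoints (every discontinuity of
L, T, or the ELF3 drive):

- the reference path restarts `scipy.integrate.solve_ivp` (RK45,
  rtol 1e−8 / atol 1e−10) on each smooth segment with forcing frozen at the
  segment midpoint, so no step straddles a switch and constant-forcing
  segments admit exact closed-form oracles (B, C, and — when `d_EC = 0` —
  E are linear with piecewise-constant coefficients);
- the fitting path is a numba-compiled fixed-step RK4 on the same
  segments (default substep 0.05 h; 0.25 h inside the annealer), with the
  substep shrunk to twice the reciprocal of the fastest local rate for
  explicit-stability margin.  The two paths agree to ≲ 5×10⁻⁴ mm on
  5-day endpoints, two orders of magnitude below the synthetic noise.

The entrained diel ELF3 profile is computed exactly as the fixed point of
the affine one-cycle propagation map (piecewise exponentials), avoiding
burn-in integration in the profile penalty.

Degenerate inputs are rejected loudly: zero decay rates, `K_C = 0`,
negative multipliers, times before the modeled timeline.  Hill exponents
are kept at integer values in the reference set (a standard modeling choice
that also keeps the compiled path on fast power branches).

## Fitting

The cost is a chi-square over dataset cells — `(model − mean)²/sd²` summed
over genotype × photoperiod × temperature — plus `λ_E` times a penalty
tying the normalized entrained ELF3 waveform to a target profile (units of
expression data are arbitrary, so only the waveform is constrained).

The optimizer is a single-chain simulated annealer: one-coordinate
Gaussian proposals (σ = 0.1 in log10 space) inside a log-box, Metropolis
acceptance, starting temperature calibrated from a probe of uphill move
sizes to hit a target initial acceptance (0.5), geometric cooling
(default 0.98 per 200 proposals, capped at 2×10⁵ proposals, early stop
below 1 % acceptance).  Infeasible proposals (bound/invariant violations,
blown-up dynamics) cost +∞ and are skipped; an infeasible random start is
resampled.  Restarts from split seeds give the ensemble; each chain may
first screen `n_init_probe` random starting points and begin from the best
(cheap basin selection).  Because a cold random start sometimes anneals
into a poor basin at desk budgets, a restart whose final cost exceeds
three times the best chain's (plus a small absolute slack) is recorded in
`FitResult.rejected` with a warning rather than entering the ensemble —
the ensemble is the set of *fits*, and failed chains stay visible for
diagnosis.  The data do not identify a unique parameter vector — they
constrain a manifold — so the package's recovery claim is about
*predictions*: ensemble members must agree with the truth on held-out
genotypes, not in parameter space.

Default log-box bounds are physiologic-range guesses per rate (three
decades around unity for dimensionless constants); the day COP1 target is
bounded by the night ceiling.

## Reference parameter set

No measured parameter values ship with the package.  The committed set in
`src/thermogrowth/data/reference_parameters.json` is *constructed*: a
hand-derived seed point (each channel sized from the qualitative reasoning
above) polished by the package's own annealer against hinge losses on the
margins of the qualitative checklist, plus soft anchors pinning the growth
scale to realistic 5-day seedling dimensions (dark ≈ 11 mm → landed at
8.6 mm, continuous light ≈ 1.5 mm, wild-type 8-h ΔH ≈ 2.5 mm), with a
fixed seed (`scripts/make_reference.py`).  It is a synthetic fixture whose
only claim is to satisfy every checklist item with margin; it is not a fit
to measured data.

## Qualitative checklist

Nine pattern groups encode the expected biology; "≈ 0" means within 10 %
of the wild-type 8-h ΔH (configurable `tol_frac`):

1. WT ΔH falls with day length (8 > 12 > 16 h) and vanishes in continuous
   light; 2. WT ΔH is much reduced in darkness; 3. phyB-9 and PIF4ox ΔH
   *rise* with day length; 4. cop1-4 and its double mutants show no ΔH at
   any day length (COP1 epistasis); 5. COP1-OE grows like WT in darkness
   (temperature-blind) but shows a large, dosage-monotone ΔH in continuous
   light; 6. PHYBox matches WT in darkness and recovers thermal response
   under 4-h light; 7. elf3-8 is tall at 22 °C in short days with residual
   ΔH; 8. ELF3ox is impaired at 16 h, WT-like at 8 h, and as tall as
   elf3-8 in darkness (dark saturation); 9. regulator dynamics — daytime
   ELF3 higher at 28 °C, PIF higher at night and when warm, phyB lower and
   faster-decaying when warm, COP1 saturated/temperature-blind at night
   but reduced and temperature-sensitive in the day.

## Synthetic data

The generator emulates the study design: 13 genotypes × {0, 8, 12, 16,
24} h light × {22, 28} °C, 14–112 seedlings per cell, per-seedling normal
noise with CV 10 % truncated at zero, reported as sample mean/SD/n with an
SD floor of 0.01 mm, and two cells dropped to emulate missingness.  The
validation composites (elf3-8 phyB-9, phyB-9 cop1-4, phyB-9 COP1-OE,
PHYBox COP1-OE) and the 4-h regime never enter training data.  What it
does **not** emulate: non-normal seedling-length distributions, batch or
plate effects, germination-timing covariance between cells, measurement
digitization.  Passing recovery tests therefore shows the inference
machinery is sound at realistic noise, not that the model fits real
measurements.

## Scaled-down study sizes

The acceptance study (tests and `scripts/acceptance.py`) frees the eight
parameters that carry the thermal channels (`k_dB`, `Q10_B`, `C_light`,
`ε_C`, `β_B`, `β_C`, `v_max`, `K_G`) plus the cop1-4 and COP1-OE gains,
holding structural constants at the reference — a deliberate desk-scale
design: 4 restarts × 10⁴ proposals with cooling 0.92 per 200 converge in
minutes while leaving the fit genuinely blind to the thermal-channel
values.  Held-out error is compared to the RMS of the injected per-cell
noise SD over the evaluation cells.

## Known limitations

- Blue-light receptors (cryptochromes) and phyA are absent; the model is a
  red-light/temperature caricature.
- No explicit circadian oscillator: the dusk bump is slaved to the light
  cycle, and constant conditions use a fixed free-running mean drive.
- One aggregate PIF variable: pif4 vs pifq differences are dosage only.
- Genotype multipliers are constant in time; overexpressors keep the
  wild-type diel waveform, merely scaled.
- The COP1→ELF3 destabilization term (`d_EC`) ships disabled (0) and
  untuned.
- Growth is endpoint-only; no growth-rate or spatial (cell-elongation)
  resolution.
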