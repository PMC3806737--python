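# Methods

## Physical model

The membrane is a fluid–fluid interface under tension spanning a rigid
circular aperture. Assumptions:

- Displacements are purely transverse (along the ultrasound axis) and
  small; the fluid is incompressible, so the convective term of the
  Navier–Stokes equation vanishes and the problem is linear.
- The aperture rim pins the membrane: u(±d/2, t) = 0. The
  fundamental standing wave therefore has wavelength 2d and spatial
  frequency q = π/d, and the interfacial pressure disturbance decays
  into the bulk as e^(−q|z|). This evanescent decay converts the bulk
  inertia and the pressure drive into the q-weighted terms of the 1-D
  displacement PDE
  ρ ∂v/∂t = q(P + 2γ u_xx) + 2η v_xx.
- The factor 2 on the tension and viscous terms comes from axial
  symmetry of the profile (the two transverse second derivatives are
  equal on the symmetry axis). This transcription is pinned down by a
  test asserting that the operator's fundamental-mode damping equals
  the analytic rate ηq²/ρ (`modal_characteristics`), and by the
  agreement of that rate (≈685 s⁻¹ for the reference configuration)
  with the damping observed in fitted transients.
- Total pressure is P₀ (hydrostatic) plus P_US gated between t_on and
  t_off; onset and offset are ideal steps by default because the
  radiation-force time course at stimulus edges is far faster than the
  membrane's response. Arbitrary intensity envelopes (values in [0, 1]
  multiplying P_US) are supported for modulated stimuli.
- The equilibrium shape solves 2γ u″ = −P₀; its closed form is the
  parabola (P₀/4γ)(d²/4 − x²), used throughout the tests as the
  independent oracle for the numerical boundary-value solve.

Not modelled (deliberately): interfacial (surface) viscosity — the
model is therefore wrong for cholesterol-rich membranes, whose response
is dominated by it; coupling to the solution/air interface above the
membrane; acoustic streaming; viscoelasticity of the solvent torus at
the rim (the rim is perfectly rigid here); tension changes during
stretch.

## Default parameters

| symbol | meaning | default | units |
|---|---|---|---|
| d | bilayer diameter | 120e-6 | m |
| γ | interfacial tension | 0.8e-3 | N/m |
| L₀ | resting hydrophobic thickness | 4e-9 | m |
| ε | core relative dielectric constant | 2 | — |
| ρ | solution density | 1000 | kg/m³ |
| η | solution viscosity | 1e-3 | Pa·s |
| c | sound speed | 1500 | m/s |
| P₀ | hydrostatic pressure | −70 | N/m² |
| P_US | radiation-force pressure | 0.15 | N/m² |

These are the standard experimental conditions for decane-containing
phospholipid bilayers in aqueous solution at room temperature: 4 nm is
typical of solvent-containing membranes, 0.8 mN/m sits inside the
reported 0.4–6.5 mN/m tension range for decane bilayers, negative P₀
reflects the usual solution-level imbalance (membrane bowed against
the propagation direction), and 0.15 N/m² is well below the 2I/c ≈
8.1 N/m² bound for a 0.61 W/cm² beam. With these values the resting
capacitance of the d = 120 µm membrane is ≈100 pF and its fundamental
mode is ≈850 Hz with ≈685 s⁻¹ damping.

## Numerics

- **Spatial discretization.** Uniform grid, default 201 nodes (odd, so
  x = 0 is a node), second-order central differences with Dirichlet
  boundaries. Doubling the node count changes the reported peak and
  steady-state center displacements by <0.5% (tested).
- **Time integration.** Implicit BDF (`scipy.integrate.solve_ivp`)
  with the exact sparse Jacobian, rtol 1e-8, atol 1e-14. The mode
  spectrum spans ω ∝ n and damping ∝ n² up to the grid limit, so the
  system is stiff. Integration restarts at t_on and t_off so the
  forcing discontinuity never sits inside an integrator step. Output
  sampling defaults to 10 µs (100 kHz), matching the recording rate.
- **Equilibrium solve.** Direct sparse solve of the tridiagonal
  boundary-value problem; the discrete residual is checked against
  a 1e-6·|P₀| threshold.
- **Area integral.** The x ≥ 0 half-profile is treated as the radial
  profile of a surface of revolution; a cubic spline supplies the
  slope, and adaptive Gauss–Kronrod quadrature evaluates
  ∫2πr√(1+u′²)dr to better than 1e-8 relative. The closed-form
  paraboloid area (πa/6h²)[(a²+4h²)^{3/2} − a³] is the test oracle.
  A planar arc-length reading of the integral was rejected because it
  does not reproduce the ~100 pF resting capacitance or the 0.16%
  steady-state area change of the reference configuration; the
  axisymmetric reading does.
- **dC/dt.** Centered differences at interior samples, one-sided at
  the ends (`np.gradient`).

## Waveform analysis

- **Initialization** (the fit itself is scipy's Levenberg–Marquardt):
  frequency from the dominant FFT peak of the windowed segment,
  damping from a log-linear fit to the analytic-signal (Hilbert)
  envelope, amplitude and phase from the analytic signal at the
  stimulus edge. Deterministic and derivative-free.
- **Fit window**: from the stimulus edge to where the envelope
  estimate falls below 2× the baseline noise SD, never shorter than
  two periods of the initial frequency estimate.
- **Canonical parameters**: f > 0, α > 0, φ folded into (−π/2, π/2]
  with the sign carried by the amplitude — the convention used in
  published fit tables, which resolves the (a, φ) ↔ (−a, φ±π)
  degeneracy. Off-response amplitudes are reported signed.
- **No-oscillation flag**: a fit whose amplitude is within 2× the
  baseline noise SD is flagged rather than reported — the behaviour
  expected of stiff, strongly damped (e.g. cholesterol) membranes.
- **Net ΔC, two estimators**: the closed-form improper integral of the
  fitted transient, ΔC = (a/V)(ω cos φ + α sin φ)/(α²+ω²), and direct
  cumulative integration of the baseline-subtracted current divided by
  V, averaged over the final 1 ms of the stimulus. They agree within
  5% on clean single-component transients; the direct estimator also
  reports any slow drift present in a trace (e.g. lipid exchange with
  the solvent torus), which the fit-based estimator excludes by
  construction. Only the primary damped-sine component is fitted;
  secondary components end up in the reported residual RMS.
- **Amplitude normalization and perimeter conversion**: both use power
  laws fitted in log space over the model sweep of bilayer diameters.
  The default diameter range, 0.1–1 mm, matches the aperture sizes of
  planar-bilayer rigs; the power law is a local approximation to a
  curved log-log relation, so widening the range degrades it (over
  0.1–1 mm the perimeter conversion is good to ~2%, and normalized
  amplitudes are flat to ~13% where raw amplitudes span 37×).

## Linear-response module

The PDE is linear in (u, v, P), so the On response to a step stimulus
characterizes the system completely. The impulse response is the
causal backward difference of the step response with h[0] = y[0]/Δt —
the exact discrete inverse of causal Riemann-sum convolution, so that
convolving h with a unit step reproduces the step response to machine
precision (a centered-difference derivative would leave a half-sample
phase error). Predictions for ramped intensity envelopes match direct
PDE simulation with the same time-varying forcing within 2% RMS
(tested at 0.5, 1 and 2 ms quadratic ramps).

## Acoustics

Plane-wave relations: I = p²/(2ρ₀c) for hydrophone pressure, and
I = ρ₀c·u²/8 for the peak velocity of a totally reflecting
(pressure-release) air/water interface, where the interface moves at
twice the incident particle velocity. All conversions are exact
inverses of one another. 2I/c bounds the steady radiation-force
pressure; configured P_US values are checked against it and a warning
is raised when they exceed it. Transducer-efficiency corrections and
beam modelling are out of scope.

## Synthetic data

`generate_onoff_trace` emulates averaged voltage-clamp records:
damped-sine On and Off transients (Off mirrored in polarity), sampled
at 100 kHz, with seeded white Gaussian baseline noise and an optional
causal 4th-order Bessel low-pass at 10 kHz (−3 dB), the hardware-typical
filter type; an optional slow exponential drift emulates capacitance
creep from lipid/torus exchange. `generate_model_trace` instead runs
the full physical pipeline and adds noise. Presets reproduce the
parameter scales of published example recordings (170-pF standard,
squalene, 30-pF and 1300-pF extremes).

What the generator does *not* emulate: correlated (1/f or line) noise,
amplifier/access-resistance dynamics, multi-mode oscillations,
trial-to-trial variability of membrane properties, and vibrometer
noise spectra beyond white noise. Passing recovery tests on these
traces therefore demonstrates estimator correctness under the stated
noise model, not robustness to every artifact of real recordings.
Note that the Bessel filter measurably distorts the fastest, most
strongly damped presets (it reduces the apparent amplitude and damping
of a 2.7-kHz, 1370 s⁻¹ transient); this is faithful to hardware, and
tests compare noisy fixtures against noiseless filtered references.

## Calibration

`calibrate_parameters` fits any subset of {γ, P₀, P_US} to observed
(C, amplitude, f, α) tuples by least squares on log-residuals. The
forward map is analytic — closed-form parabola equilibrium →
paraboloid area → capacitance (inverted per observation to recover
the diameter), modal frequency and damping, and a single-mode
amplitude a = |V·ΔC|(α²+ω²)/ω — rather than nested PDE solves, which
keeps each evaluation trivial and the optimization robust. This is
adequate because the observables are dominated by the fundamental
mode; recovering parameters from multi-mode PDE output would inherit
the same single-mode bias as the damped-sine fit itself.

## Problem sizes

Defaults used by the tests and the acceptance script: 201 spatial
nodes (101 where several solves are compared against each other),
25 ms simulated at 100 kHz output sampling (~2,500 samples), 100
replicates for fit-coverage studies, 20 for calibration recovery and
noise statistics. The reference run completes in a few seconds; the
whole test suite in about a minute.

## Known limitations

- Single-mode waveform analysis: traces with strong secondary modes
  are fitted only for their primary component.
- The power-law normalization and perimeter conversion are only as
  good as the power-law approximation over the chosen diameter range.
- The model cannot describe cholesterol-dominated membranes (no
  interfacial viscosity term) or configurations where coupling to the
  solution/air interface shapes the dynamics.
- Constant-volume electromechanics assumes purely elastic area
  changes; slow exchange with the solvent border appears only as an
  un-modelled drift that the direct ΔC estimator will report.
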