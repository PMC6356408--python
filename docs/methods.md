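# Methods

## The measurement principle

`vfret` models a microfluidic viscometer that reads out fluid viscosity
through vibrating Förster resonance energy transfer. A lumped spherical
donor particle is suspended at a steady-state height `d0` above an acceptor
layer inside an acoustically driven fluid. The acoustic wave oscillates the
fluid with displacement amplitude

    Uf_max = Pf / (2 π ρf f0 cf)

(`Pf` pressure amplitude, `ρf` fluid density, `f0` drive frequency, `cf`
sound speed). A particle of mass `mp` and diameter `dp` follows the fluid
only partially: with Stokes-drag relaxation time `τp = mp / (3 π μf dp)`,
the transmitted amplitude fraction is the entrainment coefficient
`ηp = 1 / √(1 + (ω0 τp)²)` and the particle lags the fluid by
`φp = arctan(ω0 τp)`, `ω0 = 2π f0`. Because `τp` contains the dynamic
viscosity `μf`, the particle's oscillation amplitude
`Up_max = ηp · Uf_max` is viscosity-dependent — more viscous fluids entrain
the particle more completely. The donor–acceptor distance is

    d(t) = d0 − Up_max · cos(ω0 t − φp),

and the acceptor emission per counting bin is `α · E(d(t)) + n(t)` with the
transfer efficiency `E(d) = kA R0⁶ / (d⁶ + kA R0⁶)` (`R0` Förster distance,
`kA` acceptors per donor), the photon budget
`α = Δt · ID · DB · σD · ΦA · ND · λDa / (h c)` and additive white Gaussian
noise `n(t)` of variance `σn² = α² · 10^(−SNR/10)` (worst-case SNR
referencing the maximum signal `α`). The sixth-power distance law makes the
waveform shape sharply informative about both `d0` and — through the
amplitude and phase — `μf`.

## Inverse procedure

Per measurement the estimator (i) folds `NT` periods of the raw series into
one period waveform (exact folding is guaranteed by choosing the effective
bin width `T/S` with `S = round(T/Δt)` bins per period, `S = 1000` at the
50 Hz / 20 µs reference point); (ii) keeps only samples whose *measured*
normalized count `N̄/α` is at least `E_min`, because the true efficiency is
unavailable at estimation time; rejects the measurement outright when fewer
than `round(S/12)` samples qualify (noise-dominated) or when the waveform
maximum reaches 0.99 (saturation: the donor oscillation reaches the
acceptor layer, which flattens the waveform top and destroys the viscosity
information; the simulator additionally flags such trajectories at
generation time and the estimator refuses them); (iii) fits `(d0, μf)` by
nonlinear least squares against the noiseless model evaluated at the kept
phase offsets. The final estimate averages the converged, accepted
measurements; every rejection is ledgered with its reason.

Numerical choices:

- The fit runs in scaled units (nm, mPa·s) so both unknowns are O(1–100);
  tolerances `ftol = xtol = gtol = 1e-14`. SciPy's trust-region reflective
  solver (the bounded member of the Levenberg–Marquardt family) is used
  because box bounds (`d0 ∈ [0.5 nm, 1 µm]`, `μf ∈ [0.1, 10] mPa·s` by
  default) keep the sixth-power term evaluable at all iterates.
- Fits terminating within 1e-8 (relative) of a bound are marked
  non-converged and excluded from the average: a boundary solution signals
  misspecification, not an estimate. Whether non-converged fits should
  enter the average at all is a genuinely open choice; exclusion was chosen
  because averaging garbage with signal only obscures both.
- Initial guesses: `μf` starts at the midpoint of the configured prior
  viscosity range (2.75 mPa·s for the default 0.5–5 mPa·s range), `d0` at
  `Up_max(μf_init)` plus the midpoint of the position-offset window
  (10.5 nm by default). Deterministic and unbiased within the stated
  priors.
- The efficiency filter is applied *after* folding, on the folded waveform:
  filtering raw noisy bins before folding would make the kept set
  noise-dependent per period and break the exact-fold alignment.
- Distances on touching trajectories are clamped at 0.1 nm in the forward
  model only, to keep `d⁶` finite; the estimator never fits such series.
- Minimum qualifying samples per period: 1/12 of a period. A 1/6-of-period
  variant is equally defensible (the sources for this design quote both);
  1/12 is the default and the fraction is configurable.

## Synthetic-data generator and study conditions

The simulator *is* the data source: there is no external data. Its defaults
are the study conditions throughout — water-like carrier fluid
(`ρf = 1000 kg/m³`, `cf = 1543 m/s`), viscosities spanning 0.5–5 mPa·s
(water ≈ 0.89, blood 3–4), drive `Pf ∈ [1, 20] Pa`, `f0 ∈ [10, 300] Hz`,
particle diameters 1–500 µm, `R0 = 10 nm` with `kA = 1` as the worst-case
pairing, `Δt = 20 µs` bins, `E_min = 0.01`, positions drawn uniformly
1–20 nm above `Up_max`, and protocol scale `NT = 1000`, `Nm = 20`,
`NMC = 20`. The particle density is not fixed by the model, so the
generator defaults to neutral buoyancy in water (`ρp = 1000 kg/m³`,
`mp = ρp π dp³/6`); both `ρp` and `mp` are configurable because the
absolute amplitude maps depend directly on the mass assumption.

What the generator emulates: viscosity-dependent entrainment, sixth-power
FRET distance dependence, per-bin Gaussian detection noise at a stated SNR,
and the uniform position search. What it does not: photophysics kinetics
(bleaching, self-quenching, donor excitation dynamics), Poisson counting
statistics (counts are real-valued Gaussian by construction; a Poisson mode
is deliberately not the default because the Gaussian channel is the stated
model), acoustic streaming/radiation forces, non-Newtonian rheology, and
flow. Passing tests therefore demonstrate the estimator's behavior under
the model's own assumptions, not instrument-grade performance on real
fluids.

Noise is i.i.d. per bin after `Δt` binning — an assumption, since the
physical photon stream is only approximately bin-independent. `ND` (donor
count) defaults to 1 and enters `α` linearly.

## Monte Carlo harness and problem sizes

The study grid crosses viscosities with SNR ∈ {10, 20, 30, 40} dB at the
reference operating point `Pf = 20 Pa`, `dp = 500 µm`, `f0 = 50 Hz`.
Seeding is hierarchical: `SeedSequence(master, spawn_key=(point,
replicate))`, so tables are byte-reproducible and adding sweep points never
perturbs existing replicates.

Routine runs and the acceptance script use a desk-scale protocol —
`NT = 200`, `Nm = 5`, `NMC = 5` — chosen as the package's own working
scale: the quantities of interest at this scale are trends (error
monotonically falling with SNR, error rising with `Up_max`), which are
already stable there, while the full `NT = 1000 / Nm = 20 / NMC = 20`
protocol remains available behind `--full`. The error metric is the mean
absolute relative viscosity error per (viscosity, SNR) point, alongside
bias and RMSE in mPa·s; rejection rates count both filtered measurements
and whole failed replicates.

## Known limitations

- With `Pf = 0` (or numerically vanishing `Up_max`) the waveform carries no
  viscosity information; the fit reports a near-singular Jacobian
  (condition number diagnostic) rather than pretending to an estimate.
- At 10 dB SNR the folded waveform's noise floor (σ ≈ 0.022 at `NT = 200`)
  is comparable to `E_min = 0.01`, so the sample filter itself becomes
  noisy; relative errors of tens of percent there are a property of the
  operating point, not of the solver.
- The saturation proxy (reject when the folded maximum ≥ 0.99) is a
  heuristic stand-in for the open problem of detecting `d0 ≤ Up_max` from
  data; it also rejects legitimate positions closer than ~4.7 nm above
  `Up_max` (where peak efficiency exceeds 0.99 with `R0 = 10 nm`), which
  slightly thins the usable measurement set but never biases the survivors.
- The small-particle assumption (`dp` much smaller than the acoustic
  wavelength) is checked and warned about, not enforced.
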