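# vfret — vibrating-FRET microfluidic viscometer

`vfret` simulates and inverts a viscosity sensor built on vibrating Förster
resonance energy transfer (VFRET). A spherical donor microparticle
suspended in a fluid channel is shaken by a low-frequency acoustic wave; an
acceptor layer sits a few tens of nanometres below. Because the particle's
entrainment in the oscillating fluid depends on the fluid's dynamic
viscosity μf, the donor–acceptor distance — and with it the FRET efficiency
read out as acceptor photon counts — carries a viscosity fingerprint. The
package provides the forward photon-count model, the inverse estimator that
recovers (d0, μf) from photon-count traces, and a Monte Carlo harness for
estimator-performance studies. It is aimed at sensor modelers and
point-of-care instrumentation designers who want to explore the design
space (drive frequency and pressure, particle size, dye pair, SNR) before
building hardware.

## Model

Fluid displacement amplitude and particle entrainment:

    Uf_max = Pf / (2π ρf f0 cf)
    τp     = mp / (3π μf dp)
    ηp     = 1 / √(1 + (ω0 τp)²),   φp = arctan(ω0 τp),   ω0 = 2π f0
    d(t)   = d0 − ηp Uf_max cos(ω0 t − φp)

Photon counts per bin Δt, with Förster distance R0 and kA acceptors per
donor:

    E(d)      = kA R0⁶ / (d⁶ + kA R0⁶)
    N(t)      = α E(d(t)) + n(t),     n ~ N(0, σn²),  SNR = α²/σn²
    α         = Δt ID DB σD ΦA ND λDa / (h c)

The estimator folds NT periods, discards samples below a measured
efficiency floor E_min (and whole measurements that saturate or keep too
few samples), fits (d0, μf) by bounded Levenberg–Marquardt-type nonlinear
least squares, and averages over Nm measurements taken at uniformly drawn
donor positions. See `docs/methods.md` for assumptions, defaults and
numerical choices.

## Worked example

Estimate a blood-like viscosity from ten noisy measurements at the
reference operating point (20 Pa drive at 50 Hz, 500 µm particle,
R0 = 10 nm, 30 dB SNR, 200 periods folded per measurement):

```python
import numpy as np
from vfret import (AcousticDrive, DonorParticle, EstimationProtocol,
                   FluidMedium, NoiseModel, estimate_measurements,
                   sample_positions, simulate_series, vibration_state)

fluid = FluidMedium(rho_f=1000.0, c_f=1543.0, mu_f=3.5e-3)   # blood-like
drive = AcousticDrive(P_f=20.0, f0=50.0)
particle = DonorParticle(d_p=500e-6, R0=10e-9)

vib = vibration_state(drive, fluid, particle)
print(f"Uf_max = {vib.Uf_max*1e9:.2f} nm, eta_p = {vib.eta_p:.3f}, "
      f"Up_max = {vib.Up_max*1e9:.2f} nm")

protocol = EstimationProtocol(NT=200, Nm=10)
rng = np.random.default_rng(7)
positions = sample_positions(protocol.Nm, vib.Up_max, protocol, rng)
series = [simulate_series(fluid, drive, particle, d0, protocol.NT,
                          noise=NoiseModel(snr_db=30.0), rng=rng)
          for d0 in positions]
report = estimate_measurements(series, fluid, drive, particle, protocol)
print(f"mu_hat = {report.mu_hat_final*1e3:.3f} mPa*s (truth 3.500), "
      f"d0_hat = {report.d0_hat_final*1e9:.2f} nm, "
      f"{report.n_used} used / {report.n_rejected} rejected "
      f"{report.rejection_reasons}")
```

Output:

```
Uf_max = 41.26 nm, eta_p = 0.626, Up_max = 25.82 nm
mu_hat = 3.496 mPa*s (truth 3.500), d0_hat = 39.01 nm, 9 used / 1 rejected {'touching': 1}
```

The fluid oscillates with a 41 nm amplitude of which the particle inherits
63% at this viscosity. From ten measurements, one landed close enough to
the acceptor layer that its waveform saturated and was rejected; the nine
survivors recover the viscosity to about 0.1%.

## Command line

```bash
vfret simulate   --config examples/reference.yaml --seed 7 --out series.csv
vfret estimate   --config examples/reference.yaml --out report.json series.csv
vfret montecarlo --config examples/reference.yaml --seed 1 --out mc/   # add --full for NT=1000/Nm=20/NMC=20
vfret sweep      --config examples/reference.yaml --out sweep/
```

`simulate` writes a photon-count trace (`t_s,counts` CSV) with a JSON truth
sidecar; `estimate` writes an `EstimateReport` as JSON plus a flat CSV (one
row per measurement, one summary row); `montecarlo` writes the tidy
replicate table (`sweep.csv`) and per-(viscosity, SNR) summaries
(`metrics.csv`/`metrics.json`: mean estimate, bias and RMSE in mPa·s, mean
relative error, rejection rate); `sweep` writes the displacement maps
(`quantity,f0_hz,Pf_pa,dp_um,mu_mPas,value_nm`). Configuration is a single
YAML file with an explicit `units:` block (see `examples/reference.yaml`);
all internal computation is SI.

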