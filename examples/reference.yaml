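# Reference operating point of the simulation study.
# All values are in the units declared by the `units:` block; omitted keys
# fall back to the same defaults, so an empty file reproduces this setup.

units:
  distance: nm            # R0, d0_min, d0_max
  particle_diameter: um   # d_p, dp_list
  viscosity: mPa_s        # mu_list, mu_grid  (water ~ 0.89, blood 3-4)
  time: us                # delta_t
  pressure: Pa
  frequency: Hz
  density: kg_m3
  sound_speed: m_s

# carrier fluid (water-like; viscosity itself is the estimand and is swept)
rho_f: 1000
c_f: 1543

# acoustic drive: 20 Pa at 50 Hz, the estimator-performance operating point
P_f: 20
f0: 50

# donor particle: 500 um neutrally buoyant lump; worst-case single-acceptor
# pairing with a 10 nm Foerster distance
d_p: 500
rho_p: 1000
R0: 10
k_A: 1

# photon counting: 20 us bins (1000 bins per 50 Hz period), unit photon
# budget (the estimator normalizes by alpha, so its absolute value is moot)
delta_t: 20
alpha: 1.0

# estimation protocol: fold 1000 periods, 20 measurements, drop samples
# below 1% measured efficiency, require 1/12 of a period to qualify,
# positions drawn 1-20 nm above the oscillation amplitude
NT: 1000
Nm: 20
E_min: 0.01
Nmin_fraction: 0.0833333333333333
d0_min: 1
d0_max: 20

# Monte Carlo study axes
NMC: 20
mu_list: [0.89, 3.5]
snr_list: [10, 20, 30, 40]
f0_list: [10, 20, 50, 100, 200, 300]
Pf_list: [1, 5, 10, 20]
dp_list: [1, 10, 100, 300, 500]
mu_grid: [0.5, 0.89, 2, 3.5, 5]
seed: 0
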