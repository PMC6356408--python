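"""Arbitrary-precision transcriptions of the closed-form sensor model.

These are deliberately independent of the package under test: each function
is a direct, single-expression transcription of the corresponding physics
formula evaluated with mpmath at 50 significant digits.  The full
photon-count expression is written with the entrainment coefficient and
phase lag expanded in terms of raw parameters
(eta_p = 3 mu dp / sqrt(9 mu^2 dp^2 + 4 f0^2 m^2),
phi_p = atan(2 f0 m / (3 mu dp))), so agreement with the package proves the
modular pipeline composes to the monolithic formula.
"""

import mpmath as mp

mp.mp.dps = 50


def uf_max(Pf, rho_f, f0, cf):
    return mp.mpf(Pf) / (2 * mp.pi * mp.mpf(rho_f) * mp.mpf(f0) * mp.mpf(cf))


def tau_p(m_p, mu_f, d_p):
    return mp.mpf(m_p) / (3 * mp.pi * mp.mpf(mu_f) * mp.mpf(d_p))


def entrainment(f0, tau):
    x = 2 * mp.pi * mp.mpf(f0) * mp.mpf(tau)
    return 1 / mp.sqrt(1 + x**2), mp.atan(x)


def fret_efficiency(d, R0, kA):
    d, R0, kA = mp.mpf(d), mp.mpf(R0), mp.mpf(kA)
    return kA * R0**6 / (d**6 + kA * R0**6)


def sphere_mass(d_p, rho_p):
    return mp.mpf(rho_p) * mp.pi * mp.mpf(d_p) ** 3 / 6


def alpha(delta_t, I_D, D_B, D_ext, Phi_A, N_D, lambda_Da):
    sigma_D = mp.mpf(D_ext) * mp.mpf("3.825e-25")
    h, c = mp.mpf("6.62e-34"), mp.mpf("3e8")
    return (
        mp.mpf(delta_t) * mp.mpf(I_D) * mp.mpf(D_B) * sigma_D
        * mp.mpf(Phi_A) * mp.mpf(N_D) * mp.mpf(lambda_Da) / (h * c)
    )


def noiseless_photon_count(t, a, kA, R0, d0, mu, dp, m_p, Pf, rho_f, f0, cf):
    """Monolithic noiseless count: alpha / (1 + (1/kA) ((d0 - ...)/R0)^6)."""
    t, a, kA, R0 = mp.mpf(t), mp.mpf(a), mp.mpf(kA), mp.mpf(R0)
    d0, mu, dp, m_p = mp.mpf(d0), mp.mpf(mu), mp.mpf(dp), mp.mpf(m_p)
    Pf, rho_f, f0, cf = mp.mpf(Pf), mp.mpf(rho_f), mp.mpf(f0), mp.mpf(cf)
    amp = (
        3 * mu * dp / mp.sqrt(9 * mu**2 * dp**2 + 4 * f0**2 * m_p**2)
    ) * Pf / (2 * mp.pi * rho_f * f0 * cf)
    phase = mp.atan(2 * f0 * m_p / (3 * mu * dp))
    d = d0 - amp * mp.cos(2 * mp.pi * f0 * t - phase)
    return a / (1 + (1 / kA) * (d / R0) ** 6)


def relerr(approx, exact):
    exact = mp.mpf(exact)
    if exact == 0:
        return abs(mp.mpf(approx))
    return float(abs((mp.mpf(approx) - exact) / exact))
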