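"""FRET efficiency, photon budget and the noisy photon-count forward model.

The observable of the viscometer is the acceptor emission photon count per
counting bin.  Its expected value is ``alpha * E_FRET(d(t))`` where ``alpha``
is the photon budget (expected counts per bin at unit transfer efficiency)
and ``E_FRET`` falls off with the sixth power of the donor–acceptor distance.
Detection noise is modelled as additive white Gaussian noise calibrated to a
worst-case signal-to-noise ratio SNR = alpha^2 / sigma_n^2; counts are kept
real-valued (no Poissonization, no clipping) as the continuous Gaussian
channel model prescribes.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .physics import (
    AcousticDrive,
    DonorParticle,
    FluidMedium,
    donor_acceptor_distance,
    vibration_state,
)

__all__ = [
    "PLANCK_CONSTANT",
    "SPEED_OF_LIGHT",
    "EXTINCTION_TO_CROSS_SECTION",
    "PhotonBudget",
    "NoiseModel",
    "MeasurementSeries",
    "fret_efficiency",
    "photon_budget_alpha",
    "noise_sigma_from_snr",
    "samples_per_period",
    "simulate_series",
]

# Rounded physical constants used throughout the photon-budget arithmetic.
PLANCK_CONSTANT = 6.62e-34  # [J*s]
SPEED_OF_LIGHT = 3.0e8      # [m/s]

#: converts a molar extinction coefficient [M^-1 cm^-1] into an absorption
#: cross section [m^2]: sigma = 1000 ln(10) / N_A * 1e-4 ~ 3.825e-25 per unit
EXTINCTION_TO_CROSS_SECTION = 3.825e-25

#: minimum samples per excitation period for the time grid to resolve the
#: oscillating efficiency waveform
MIN_SAMPLES_PER_PERIOD = 12

#: clamping floor for the donor-acceptor distance on touching trajectories,
#: keeps the d^6 term evaluable [m]
DISTANCE_FLOOR = 1.0e-10


@dataclass(frozen=True)
class PhotonBudget:
    """Everything that sets the expected photon count per bin.

    ``alpha = delta_t * I_D * D_B * sigma_D * Phi_A * N_D * lambda_Da / (h c)``
    with the absorption cross section ``sigma_D`` derived from the molar
    extinction coefficient ``D_ext``.  ``t_p`` is the total donor-excitation +
    transfer + acceptor-emission time (nanoseconds); the per-bin photon count
    model assumes ``delta_t >> t_p``.
    """

    delta_t: float            # photon-counting bin [s]
    I_D: float                # donor excitation intensity [W/m^2/nm]
    D_B: float                # donor excitation bandwidth [nm]
    D_ext: float              # donor extinction coefficient [M^-1 cm^-1]
    Phi_A: float              # acceptor quantum yield, (0, 1]
    lambda_Da: float          # donor excitation wavelength [m]
    N_D: float = 1.0          # number of donors contributing
    t_p: float = 10e-9        # single photon emission cycle time [s]

    def __post_init__(self) -> None:
        for name in ("delta_t", "I_D", "D_B", "D_ext", "Phi_A", "lambda_Da", "N_D"):
            value = getattr(self, name)
            if not (value > 0.0) or not math.isfinite(value):
                raise ValueError(f"{name} must be a positive finite number, got {value!r}")
        if self.Phi_A > 1.0:
            raise ValueError(f"Phi_A must be <= 1, got {self.Phi_A!r}")

    @property
    def sigma_D(self) -> float:
        """Donor absorption cross section [m^2]."""
        return self.D_ext * EXTINCTION_TO_CROSS_SECTION

    @property
    def alpha(self) -> float:
        return photon_budget_alpha(self)


def photon_budget_alpha(budget: PhotonBudget) -> float:
    """Expected photon count per bin at unit FRET efficiency.

    alpha = delta_t I_D D_B sigma_D Phi_A N_D / (h f_Da), with the donor
    excitation frequency f_Da = c / lambda_Da.  Linear in every factor.
    Warns when the counting bin is not much longer than one emission cycle.
    """
    if budget.delta_t < 100.0 * budget.t_p:
        warnings.warn(
            f"photon-counting bin delta_t={budget.delta_t:.3g} s is not >> the "
            f"emission cycle time t_p={budget.t_p:.3g} s; the per-bin count "
            "model assumes delta_t >> t_p",
            stacklevel=2,
        )
    f_Da = SPEED_OF_LIGHT / budget.lambda_Da
    return (
        budget.delta_t
        * budget.I_D
        * budget.D_B
        * budget.sigma_D
        * budget.Phi_A
        * budget.N_D
        / (PLANCK_CONSTANT * f_Da)
    )


def fret_efficiency(
    d: float | np.ndarray, R0: float, k_A: float = 1.0
) -> float | np.ndarray:
    """Transfer efficiency E = k_A R0^6 / (d^6 + k_A R0^6).

    The classic sixth-power Förster law with ``k_A`` identical acceptors
    coupled to one donor.  Strictly decreasing in ``d``; equals
    ``k_A / (1 + k_A)`` at ``d = R0`` (one acceptor: 1/2).
    """
    if R0 <= 0.0:
        raise ValueError(f"R0 must be > 0, got {R0!r}")
    if k_A < 1.0:
        raise ValueError(f"k_A must be >= 1, got {k_A!r}")
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr <= 0.0):
        raise ValueError("donor-acceptor distance must be > 0 (clamp upstream)")
    # 1 / (1 + (d/R0)^6 / k_A): numerically stable for d >> R0 and d << R0
    ratio6 = (d_arr / R0) ** 6
    out = 1.0 / (1.0 + ratio6 / k_A)
    return out if out.ndim else float(out)


def noise_sigma_from_snr(alpha: float, snr_db: float) -> float:
    """Noise standard deviation from SNR = alpha^2 / sigma_n^2 in dB.

    The SNR is referenced to the worst case (maximum signal = alpha), so
    sigma_n = alpha * 10^(-snr_db / 20).
    """
    if alpha <= 0.0:
        raise ValueError(f"alpha must be > 0, got {alpha!r}")
    return alpha * 10.0 ** (-snr_db / 20.0)


@dataclass(frozen=True)
class NoiseModel:
    """Additive white Gaussian detection noise calibrated by SNR [dB]."""

    snr_db: float | None = None  # None => noiseless
    seed: int | None = None

    def sigma(self, alpha: float) -> float:
        if self.snr_db is None:
            return 0.0
        return noise_sigma_from_snr(alpha, self.snr_db)


@dataclass
class MeasurementSeries:
    """One photon-count time series for a single steady-state position d0.

    ``counts`` are real-valued (Gaussian noise can push them negative).  The
    ``truth`` snapshot records every parameter the series was generated with,
    so estimator output can always be scored against ground truth.
    """

    t: np.ndarray          # uniform time grid [s]
    counts: np.ndarray     # photon counts per bin
    delta_t: float         # actual grid spacing [s] (period / S exactly)
    samples_per_period: int
    n_periods: int
    alpha: float
    truth: dict[str, Any]  # d0, mu_f, full parameter snapshot
    touching: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.t) != len(self.counts):
            raise ValueError("t and counts must have equal length")

    @property
    def efficiency(self) -> np.ndarray:
        """Counts normalized by the photon budget (measured-efficiency scale)."""
        return self.counts / self.alpha

    # -- serialization: CSV trace + JSON sidecar ---------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the trace as CSV (t_s, counts) and a .json truth sidecar."""
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["t_s", "counts"])
            for ti, ci in zip(self.t, self.counts):
                writer.writerow([repr(float(ti)), repr(float(ci))])
        sidecar = {
            "delta_t": self.delta_t,
            "samples_per_period": self.samples_per_period,
            "n_periods": self.n_periods,
            "alpha": self.alpha,
            "truth": self.truth,
            "touching": self.touching,
            "seed": self.seed,
        }
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeasurementSeries":
        path = Path(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        data = np.atleast_2d(data)
        with open(path.with_suffix(".json")) as fh:
            sidecar = json.load(fh)
        return cls(
            t=data[:, 0],
            counts=data[:, 1],
            delta_t=sidecar["delta_t"],
            samples_per_period=sidecar["samples_per_period"],
            n_periods=sidecar["n_periods"],
            alpha=sidecar["alpha"],
            truth=sidecar["truth"],
            touching=sidecar["touching"],
            seed=sidecar["seed"],
        )


def samples_per_period(f0: float, delta_t: float) -> int:
    """Number of counting bins per excitation period, S = round(T / delta_t).

    The effective bin width is then T / S so that an integer number of bins
    tiles the period exactly — period folding requires exact alignment.
    """
    S = round((1.0 / f0) / delta_t)
    if S < MIN_SAMPLES_PER_PERIOD:
        raise ValueError(
            f"only {S} samples per period for f0={f0} Hz, delta_t={delta_t} s; "
            f"need >= {MIN_SAMPLES_PER_PERIOD}"
        )
    return S


def simulate_series(
    fluid: FluidMedium,
    drive: AcousticDrive,
    particle: DonorParticle,
    d0: float,
    n_periods: int,
    *,
    delta_t: float = 20e-6,
    alpha: float | None = None,
    budget: PhotonBudget | None = None,
    noise: NoiseModel | None = None,
    snr_db: float | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    distance_floor: float = DISTANCE_FLOOR,
) -> MeasurementSeries:
    """Generate the noisy acceptor photon-count series for one position d0.

    The donor oscillates about ``d0`` with the viscosity-dependent amplitude
    and phase from :func:`vfret.physics.vibration_state`; each counting bin
    records ``alpha * E_FRET(d(t_k))`` plus i.i.d. Gaussian noise.  With zero
    noise the series equals the deterministic model exactly.

    ``alpha`` defaults to 1 (efficiency scale) unless a :class:`PhotonBudget`
    is supplied.  Noise can be given either as a :class:`NoiseModel` or as a
    bare ``snr_db``; omitting both yields a noiseless series.  Trajectories
    whose oscillation reaches the acceptor layer (``d0 <= Up_max``) are still
    generated — the distance is clamped at ``distance_floor`` — but flagged
    ``touching=True`` so the estimator can refuse them.
    """
    if n_periods < 1:
        raise ValueError(f"n_periods must be >= 1, got {n_periods!r}")
    if budget is not None:
        if alpha is not None:
            raise ValueError("give either alpha or budget, not both")
        alpha = budget.alpha
    elif alpha is None:
        alpha = 1.0
    if alpha <= 0.0:
        raise ValueError(f"alpha must be > 0, got {alpha!r}")

    if noise is None:
        noise = NoiseModel(snr_db=snr_db, seed=seed)
    elif snr_db is not None:
        raise ValueError("give either noise or snr_db, not both")
    sigma_n = noise.sigma(alpha)

    S = samples_per_period(drive.f0, delta_t)
    dt_eff = drive.period / S
    n_samples = n_periods * S
    t = np.arange(n_samples) * dt_eff

    vib = vibration_state(drive, fluid, particle)
    touching = vib.touches(d0)
    d = donor_acceptor_distance(d0, vib, drive, t)
    np.maximum(d, distance_floor, out=d)
    signal = alpha * fret_efficiency(d, particle.R0, particle.k_A)

    if sigma_n > 0.0:
        if rng is None:
            rng = np.random.default_rng(noise.seed if noise.seed is not None else seed)
        counts = signal + rng.normal(0.0, sigma_n, size=n_samples)
    else:
        counts = signal

    truth = {
        "d0": d0,
        "mu_f": fluid.mu_f,
        "rho_f": fluid.rho_f,
        "c_f": fluid.c_f,
        "P_f": drive.P_f,
        "f0": drive.f0,
        "d_p": particle.d_p,
        "m_p": particle.m_p,
        "R0": particle.R0,
        "k_A": particle.k_A,
        "alpha": alpha,
        "sigma_n": sigma_n,
        "snr_db": noise.snr_db,
        "Up_max": vib.Up_max,
        "eta_p": vib.eta_p,
        "phi_p": vib.phi_p,
    }
    return MeasurementSeries(
        t=t,
        counts=counts,
        delta_t=dt_eff,
        samples_per_period=S,
        n_periods=n_periods,
        alpha=alpha,
        truth=truth,
        touching=touching,
        seed=noise.seed if noise.seed is not None else seed,
    )
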