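"""Monte Carlo study harness: displacement sweeps and estimator performance.

Two kinds of study are orchestrated here.  The deterministic displacement
sweeps map the fluid and particle vibration amplitudes over grids of drive
frequency, pressure, particle size and viscosity — the design-space view of
the sensor.  The stochastic estimation study repeatedly simulates the full
measure-and-estimate cycle at chosen (viscosity, SNR) points and scores the
estimates against ground truth, yielding bias / RMSE / relative-error
summaries as a function of SNR.

Seeding is hierarchical: a master seed plus the (sweep-point, replicate)
index pair deterministically derives every child stream, so results are
bit-reproducible and adding sweep points does not perturb existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .estimator import EstimationProtocol, estimate_series, aggregate, sample_positions
from .photon import NoiseModel, simulate_series
from .physics import AcousticDrive, DonorParticle, FluidMedium, vibration_state

__all__ = [
    "ExperimentConfig",
    "SweepResult",
    "sweep_displacement",
    "run_estimation_study",
    "error_metrics",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """All physics + protocol parameters of one simulation study.

    Defaults reproduce the reference operating point of the estimator
    performance study (P_f = 20 Pa, d_p = 500 µm, f0 = 50 Hz, water-like
    carrier fluid, R0 = 10 nm worst-case single-acceptor pairing) with the
    full-scale protocol NT=1000, Nm=20, NMC=20.  :meth:`scaled_down` gives
    the desk-scale variant (NT=200, Nm=5, NMC=5) for quick runs.
    """

    # carrier fluid (viscosity is swept; this is the density/sound speed)
    rho_f: float = 1000.0         # [kg/m^3]
    c_f: float = 1543.0           # [m/s]
    # acoustic drive
    P_f: float = 20.0             # [Pa]
    f0: float = 50.0              # [Hz]
    # donor particle + FRET pairing
    d_p: float = 500e-6           # [m]
    rho_p: float = 1000.0         # [kg/m^3]
    R0: float = 10e-9             # [m]
    k_A: float = 1.0
    # photon counting
    delta_t: float = 20e-6        # [s]
    alpha: float = 1.0            # photons per bin at unit efficiency
    # estimation protocol scale
    NT: int = 1000
    Nm: int = 20
    NMC: int = 20
    E_min: float = 0.01
    Nmin_fraction: float = 1.0 / 12.0
    d0_min: float = 1e-9          # [m]
    d0_max: float = 20e-9         # [m]
    # sweep axes
    mu_list: tuple[float, ...] = (0.89e-3, 3.5e-3)      # [Pa*s] water, blood
    snr_list: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0)  # [dB]
    f0_list: tuple[float, ...] = (10.0, 20.0, 50.0, 100.0, 200.0, 300.0)  # [Hz]
    Pf_list: tuple[float, ...] = (1.0, 5.0, 10.0, 20.0)  # [Pa]
    dp_list: tuple[float, ...] = (1e-6, 10e-6, 100e-6, 300e-6, 500e-6)    # [m]
    mu_grid: tuple[float, ...] = (0.5e-3, 0.89e-3, 2e-3, 3.5e-3, 5e-3)    # [Pa*s]
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu_list", "snr_list", "f0_list", "Pf_list", "dp_list", "mu_grid"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if self.NT < 1 or self.Nm < 1 or self.NMC < 1:
            raise ValueError("NT, Nm and NMC must be >= 1")

    def scaled_down(self) -> "ExperimentConfig":
        """Desk-scale study: NT=200, Nm=5, NMC=5 (trends, not curves)."""
        return replace(self, NT=200, Nm=5, NMC=5)

    # -- object builders ---------------------------------------------------

    def fluid(self, mu_f: float) -> FluidMedium:
        return FluidMedium(rho_f=self.rho_f, c_f=self.c_f, mu_f=mu_f)

    def drive(self, f0: float | None = None, P_f: float | None = None) -> AcousticDrive:
        return AcousticDrive(
            P_f=self.P_f if P_f is None else P_f,
            f0=self.f0 if f0 is None else f0,
        )

    def particle(self, d_p: float | None = None) -> DonorParticle:
        return DonorParticle(
            d_p=self.d_p if d_p is None else d_p,
            R0=self.R0, k_A=self.k_A, rho_p=self.rho_p,
        )

    def protocol(self) -> EstimationProtocol:
        return EstimationProtocol(
            NT=self.NT, Nm=self.Nm, E_min=self.E_min,
            Nmin_fraction=self.Nmin_fraction,
            d0_min=self.d0_min, d0_max=self.d0_max,
        )


@dataclass
class SweepResult:
    """Tidy table: one row per (sweep point, replicate) with truth and errors."""

    table: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _child_rng(master_seed: int, point_index: int, replicate: int) -> np.random.Generator:
    """Derive a replicate's generator from (master seed, point, replicate).

    Uses a spawn-key construction so streams are independent and stable
    under adding sweep points or replicates.
    """
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(point_index, replicate))
    return np.random.default_rng(ss)


def sweep_displacement(config: ExperimentConfig) -> SweepResult:
    """Deterministic maps of Uf_max(f0, Pf) and Up_max(f0, dp, mu_f).

    No randomness is involved; the rows with quantity ``"Uf_max"`` span the
    (f0, Pf) grid while the ``"Up_max"`` rows span (f0, dp, mu_f) at the
    configured drive pressure.
    """
    rows: list[dict] = []
    for f0 in config.f0_list:
        for Pf in config.Pf_list:
            drive = AcousticDrive(P_f=Pf, f0=f0)
            vib = vibration_state(drive, config.fluid(config.mu_grid[0]), config.particle())
            rows.append({
                "quantity": "Uf_max", "f0_hz": f0, "Pf_pa": Pf,
                "dp_um": np.nan, "mu_mPas": np.nan,
                "value_nm": vib.Uf_max * 1e9,
            })
    for f0 in config.f0_list:
        for dp in config.dp_list:
            particle = config.particle(d_p=dp)
            for mu in config.mu_grid:
                vib = vibration_state(config.drive(f0=f0), config.fluid(mu), particle)
                rows.append({
                    "quantity": "Up_max", "f0_hz": f0, "Pf_pa": config.P_f,
                    "dp_um": dp * 1e6, "mu_mPas": mu * 1e3,
                    "value_nm": vib.Up_max * 1e9,
                })
    return SweepResult(table=pd.DataFrame(rows))


def _run_replicate(
    config: ExperimentConfig,
    mu_true: float,
    snr_db: float | None,
    rng: np.random.Generator,
) -> dict:
    """One Monte Carlo replicate: Nm measurements, full pipeline, aggregate."""
    fluid = config.fluid(mu_true)
    drive = config.drive()
    particle = config.particle()
    protocol = config.protocol()
    vib = vibration_state(drive, fluid, particle)
    positions = sample_positions(config.Nm, vib.Up_max, protocol, rng)
    results = []
    for d0 in positions:
        series = simulate_series(
            fluid, drive, particle, d0, protocol.NT,
            delta_t=config.delta_t, alpha=config.alpha,
            noise=NoiseModel(snr_db=snr_db), rng=rng,
        )
        results.append(estimate_series(series, fluid, drive, particle, protocol))
    report = aggregate(results)
    used_d0 = [
        d0 for d0, (sel, fit) in zip(positions, results)
        if sel.accepted and fit is not None and fit.converged
    ]
    d0_true_mean = float(np.mean(used_d0)) if used_d0 else np.nan
    return {
        "mu_hat_mPas": report.mu_hat_final * 1e3,
        "d0_hat_nm": report.d0_hat_final * 1e9,
        "d0_true_mean_nm": d0_true_mean * 1e9,
        "n_used": report.n_used,
        "n_rejected": report.n_rejected,
        "mu_abs_error_mPas": abs(report.mu_hat_final - mu_true) * 1e3,
        "mu_rel_error": abs(report.mu_hat_final - mu_true) / mu_true,
        "d0_abs_error_nm": abs(report.d0_hat_final - d0_true_mean) * 1e9,
        "d0_rel_error": abs(report.d0_hat_final - d0_true_mean) / d0_true_mean
        if d0_true_mean else np.nan,
    }


def run_estimation_study(config: ExperimentConfig) -> SweepResult:
    """Estimator performance over the (mu_f, SNR) grid, NMC replicates each.

    Every (viscosity, SNR) pair is replicated ``NMC`` times with independent
    child streams derived from the master seed; each replicate runs the full
    simulate → fold → filter → fit → aggregate cycle over ``Nm``
    measurements.  Failures of a whole replicate (no usable measurement) are
    recorded as rows with ``failed=True`` and NaN estimates; the study
    continues.
    """
    points = [(mu, snr) for mu in config.mu_list for snr in config.snr_list]
    rows: list[dict] = []
    for point_index, (mu_true, snr_db) in enumerate(points):
        for replicate in range(config.NMC):
            rng = _child_rng(config.seed, point_index, replicate)
            base = {
                "mu_true_mPas": mu_true * 1e3,
                "snr_db": snr_db,
                "replicate": replicate,
                "Pf_pa": config.P_f, "f0_hz": config.f0, "dp_um": config.d_p * 1e6,
                "NT": config.NT, "Nm": config.Nm,
            }
            try:
                rec = _run_replicate(config, mu_true, snr_db, rng)
                rows.append({**base, "failed": False, **rec})
            except RuntimeError as exc:
                rows.append({**base, "failed": True, "error": str(exc)})
    return SweepResult(table=pd.DataFrame(rows))


def error_metrics(result: SweepResult) -> pd.DataFrame:
    """Per-(viscosity, SNR) summary: mean estimate, bias, RMSE, rejection rate.

    Bias and RMSE are in mPa·s on the viscosity estimate; the mean relative
    error is dimensionless.  Failed replicates count toward the rejection
    rate but not the error statistics.
    """
    df = result.table
    if df.empty:
        raise ValueError("empty sweep result")
    ok = df[~df["failed"]].copy()
    out: list[dict] = []
    for (mu_true, snr), grp in df.groupby(["mu_true_mPas", "snr_db"], dropna=False, sort=True):
        g = ok[(ok["mu_true_mPas"] == mu_true) & (ok["snr_db"].eq(snr) if pd.notna(snr) else ok["snr_db"].isna())]
        err = g["mu_hat_mPas"] - mu_true
        total_meas = grp["Nm"].iloc[0] * len(grp)
        n_rejected = g["n_rejected"].sum() + grp["failed"].sum() * grp["Nm"].iloc[0]
        out.append({
            "mu_true_mPas": mu_true,
            "snr_db": snr,
            "n_replicates": len(grp),
            "n_failed": int(grp["failed"].sum()),
            "mean_mu_hat_mPas": float(g["mu_hat_mPas"].mean()) if len(g) else np.nan,
            "bias_mPas": float(err.mean()) if len(g) else np.nan,
            "rmse_mPas": float(np.sqrt(np.mean(err**2))) if len(g) else np.nan,
            "mean_rel_error": float(g["mu_rel_error"].mean()) if len(g) else np.nan,
            "mean_d0_rel_error": float(g["d0_rel_error"].mean()) if len(g) else np.nan,
            "rejection_rate": float(n_rejected / total_meas) if total_meas else np.nan,
        })
    return pd.DataFrame(out)
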