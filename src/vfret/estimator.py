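"""Inverse problem: recover (d0, mu_f) from folded photon-count waveforms.

The estimation pipeline per measurement is

1. fold-average ``NT`` periods of the raw series into one period waveform,
2. filter: drop samples whose measured efficiency is below ``E_min``,
   reject the whole measurement when too few samples qualify or when the
   waveform saturates (donor touching the acceptor layer),
3. fit the two free parameters (d0, mu_f) of the noiseless forward model to
   the kept samples by nonlinear least squares (Levenberg–Marquardt family;
   a trust-region reflective solver when box bounds are active),

and the final estimate is the arithmetic mean over the converged, accepted
measurements.  Everything the fit conditions on (drive, particle geometry,
fluid density/sound speed, photon budget) is assumed known to the operator;
only viscosity and the donor's steady-state position are unknown.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .photon import MeasurementSeries, fret_efficiency
from .physics import (
    AcousticDrive,
    DonorParticle,
    FluidMedium,
    donor_acceptor_distance,
    vibration_state,
)

__all__ = [
    "EstimationProtocol",
    "SampleSelection",
    "MeasurementFit",
    "EstimateReport",
    "fold_average",
    "select_samples",
    "sample_positions",
    "fit_measurement",
    "estimate_series",
    "aggregate",
    "estimate_measurements",
]

#: measured-efficiency level treated as saturation: a folded waveform whose
#: maximum reaches this is indistinguishable from a touching trajectory
SATURATION_EFFICIENCY = 0.99


@dataclass(frozen=True)
class EstimationProtocol:
    """Tuning knobs of the estimation procedure.

    ``NT`` periods are folded per measurement and ``Nm`` measurements (each
    at a fresh uniformly drawn position d0) are aggregated.  ``E_min`` is the
    minimum measured efficiency for a sample to enter the fit;
    ``Nmin_fraction`` the minimum qualifying fraction of a period for the
    measurement to be used at all.  Positions are drawn uniformly on
    ``[Up_max + d0_min, Up_max + d0_max]``.  Initial guesses default to the
    midpoint of the configured search ranges; fits terminating on a box
    bound are marked non-converged (a boundary solution signals
    misspecification, not an estimate).
    """

    NT: int = 1000
    Nm: int = 20
    E_min: float = 0.01
    Nmin_fraction: float = 1.0 / 12.0
    d0_min: float = 1e-9            # offset above Up_max [m]
    d0_max: float = 20e-9           # offset above Up_max [m]
    d0_initial: float | None = None  # [m]; default Up_max(mu_init) + mid offset
    mu_initial: float | None = None  # [Pa*s]; default midpoint of mu_search
    mu_search: tuple[float, float] = (0.5e-3, 5e-3)   # prior viscosity range [Pa*s]
    d0_bounds: tuple[float, float] = (0.5e-9, 1e-6)   # [m]
    mu_bounds: tuple[float, float] = (0.1e-3, 10e-3)  # [Pa*s]
    max_iter: int = 500
    tol: float = 1e-14

    def __post_init__(self) -> None:
        if self.NT < 1 or self.Nm < 1:
            raise ValueError("NT and Nm must be >= 1")
        if not (0.0 < self.E_min < 1.0):
            raise ValueError(f"E_min must be in (0, 1), got {self.E_min!r}")
        if not (0.0 < self.Nmin_fraction <= 1.0):
            raise ValueError(f"Nmin_fraction must be in (0, 1], got {self.Nmin_fraction!r}")
        if not (0.0 < self.d0_min < self.d0_max):
            raise ValueError("need 0 < d0_min < d0_max")
        for name in ("d0_bounds", "mu_bounds", "mu_search"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo < hi):
                raise ValueError(f"{name} must satisfy 0 < lo < hi")

    def default_mu_initial(self) -> float:
        return 0.5 * (self.mu_search[0] + self.mu_search[1])

    def min_samples(self, S: int) -> int:
        """Minimum qualifying samples for a waveform of S bins (inclusive)."""
        return round(self.Nmin_fraction * S)


@dataclass(frozen=True)
class SampleSelection:
    """Outcome of the per-measurement sample filter."""

    kept: np.ndarray        # indices into the folded waveform
    accepted: bool
    reason: str | None = None  # "too_few_samples" | "touching" when rejected


@dataclass
class MeasurementFit:
    """One measurement's fit: estimates, convergence and diagnostics."""

    d0_hat: float           # [m]
    mu_hat: float           # [Pa*s]
    converged: bool
    residual_norm: float
    n_samples_used: int
    at_bound: bool = False
    jacobian_cond: float = math.nan
    message: str = ""


@dataclass
class EstimateReport:
    """Aggregated estimate over Nm measurements with a rejection ledger."""

    per_measurement: list[dict]
    d0_hat_final: float     # [m]
    mu_hat_final: float     # [Pa*s]
    n_used: int
    n_rejected: int
    rejection_reasons: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "d0_hat_final": self.d0_hat_final,
                    "mu_hat_final": self.mu_hat_final,
                    "n_used": self.n_used,
                    "n_rejected": self.n_rejected,
                    "rejection_reasons": self.rejection_reasons,
                    "per_measurement": self.per_measurement,
                },
                fh,
                indent=2,
            )

    def to_csv(self, path: str | Path) -> None:
        """Flat CSV: one row per measurement plus one summary row."""
        cols = [
            "measurement", "accepted", "reason", "converged",
            "d0_hat_m", "mu_hat_pa_s", "residual_norm", "n_samples_used",
        ]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            for i, rec in enumerate(self.per_measurement):
                writer.writerow({
                    "measurement": i,
                    "accepted": rec["accepted"],
                    "reason": rec.get("reason"),
                    "converged": rec.get("converged"),
                    "d0_hat_m": rec.get("d0_hat"),
                    "mu_hat_pa_s": rec.get("mu_hat"),
                    "residual_norm": rec.get("residual_norm"),
                    "n_samples_used": rec.get("n_samples_used"),
                })
            writer.writerow({
                "measurement": "final",
                "accepted": self.n_used,
                "reason": f"rejected={self.n_rejected}",
                "converged": "",
                "d0_hat_m": self.d0_hat_final,
                "mu_hat_pa_s": self.mu_hat_final,
                "residual_norm": "",
                "n_samples_used": "",
            })


def fold_average(series: MeasurementSeries, NT: int) -> tuple[np.ndarray, np.ndarray]:
    """Average ``NT`` consecutive periods of the series at fixed phase.

    Returns ``(tau, waveform)`` where ``tau`` are the S phase offsets in
    ``[0, T)`` and ``waveform[j]`` is the mean of samples ``j, j+S, ...,
    j+(NT-1)S``.  Folding suppresses the per-bin noise variance by 1/NT
    while leaving the periodic signal untouched.
    """
    if NT < 1:
        raise ValueError(f"NT must be >= 1, got {NT!r}")
    S = series.samples_per_period
    if len(series.counts) < NT * S:
        raise ValueError(
            f"series holds {len(series.counts)} samples, need NT*S = {NT * S}"
        )
    folded = series.counts[: NT * S].reshape(NT, S).mean(axis=0)
    tau = series.t[:S].copy()
    return tau, folded


def select_samples(
    waveform: np.ndarray, alpha: float, protocol: EstimationProtocol
) -> SampleSelection:
    """Filter one folded waveform on the measured-efficiency scale.

    Keeps indices with ``waveform / alpha >= E_min``.  Rejects the whole
    measurement when fewer than ``round(Nmin_fraction * S)`` samples qualify
    (``"too_few_samples"``) or when the waveform saturates near unit
    efficiency (``"touching"`` — the donor reaching the acceptor layer
    yields a flat-topped, viscosity-uninformative waveform).
    """
    waveform = np.asarray(waveform, dtype=float)
    eff = waveform / alpha
    kept = np.flatnonzero(eff >= protocol.E_min)
    if eff.max(initial=-np.inf) >= SATURATION_EFFICIENCY:
        return SampleSelection(kept=kept, accepted=False, reason="touching")
    if len(kept) < protocol.min_samples(len(waveform)):
        return SampleSelection(kept=kept, accepted=False, reason="too_few_samples")
    return SampleSelection(kept=kept, accepted=True)


def sample_positions(
    Nm: int,
    Up_max: float,
    protocol: EstimationProtocol,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw Nm steady-state positions uniformly on [Up_max+d0_min, Up_max+d0_max].

    Emulates the physical search: the acceptor layer is repositioned between
    measurements, so d0 is random but always strictly above the oscillation
    amplitude computed at the true viscosity.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return Up_max + rng.uniform(protocol.d0_min, protocol.d0_max, size=Nm)


# -- nonlinear least-squares fit ------------------------------------------

# internal fit scaling: nm for d0, mPa*s for viscosity, so both unknowns are
# O(1..100) and the Jacobian is decently conditioned
_D0_SCALE = 1e-9
_MU_SCALE = 1e-3


def _model_efficiency(
    tau: np.ndarray,
    d0: float,
    mu_f: float,
    fluid: FluidMedium,
    drive: AcousticDrive,
    particle: DonorParticle,
) -> np.ndarray:
    """Noiseless forward model on the efficiency scale at phase offsets tau."""
    vib = vibration_state(drive, fluid.with_viscosity(mu_f), particle)
    d = donor_acceptor_distance(d0, vib, drive, tau)
    np.maximum(d, 1e-10, out=d)
    return fret_efficiency(d, particle.R0, particle.k_A)


def fit_measurement(
    tau: np.ndarray,
    waveform: np.ndarray,
    kept: np.ndarray,
    fluid: FluidMedium,
    drive: AcousticDrive,
    particle: DonorParticle,
    alpha: float,
    protocol: EstimationProtocol,
) -> MeasurementFit:
    """Fit (d0, mu_f) to one folded waveform by nonlinear least squares.

    Minimizes the sum of squared deviations between the measured normalized
    counts and the noiseless model over the kept samples, with box bounds on
    both parameters (trust-region reflective variant of Levenberg–Marquardt).
    The viscosity of ``fluid`` is ignored: it is the unknown.  A fit that
    terminates on a bound or fails the solver's convergence test is flagged
    ``converged=False`` and excluded from aggregation downstream.
    """
    tau = np.asarray(tau, dtype=float)
    kept = np.asarray(kept, dtype=int)
    if len(kept) == 0:
        raise ValueError("fit_measurement needs at least one kept sample")
    y = np.asarray(waveform, dtype=float)[kept] / alpha
    tk = tau[kept]

    mu0 = protocol.mu_initial if protocol.mu_initial is not None else protocol.default_mu_initial()
    if protocol.d0_initial is not None:
        d00 = protocol.d0_initial
    else:
        vib0 = vibration_state(drive, fluid.with_viscosity(mu0), particle)
        d00 = vib0.Up_max + 0.5 * (protocol.d0_min + protocol.d0_max)

    lo = np.array([protocol.d0_bounds[0] / _D0_SCALE, protocol.mu_bounds[0] / _MU_SCALE])
    hi = np.array([protocol.d0_bounds[1] / _D0_SCALE, protocol.mu_bounds[1] / _MU_SCALE])
    x0 = np.clip(np.array([d00 / _D0_SCALE, mu0 / _MU_SCALE]), lo, hi)

    def residuals(x: np.ndarray) -> np.ndarray:
        d0 = x[0] * _D0_SCALE
        mu = x[1] * _MU_SCALE
        return _model_efficiency(tk, d0, mu, fluid, drive, particle) - y

    result = least_squares(
        residuals,
        x0,
        bounds=(lo, hi),
        method="trf",
        ftol=protocol.tol,
        xtol=protocol.tol,
        gtol=protocol.tol,
        max_nfev=protocol.max_iter * 3,
    )

    d0_hat = result.x[0] * _D0_SCALE
    mu_hat = result.x[1] * _MU_SCALE
    # relative proximity to a box bound counts as "at bound"
    span = hi - lo
    at_bound = bool(
        np.any(result.x - lo < 1e-8 * span) or np.any(hi - result.x < 1e-8 * span)
    )
    try:
        cond = float(np.linalg.cond(result.jac))
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate Jacobian
        cond = math.inf
    converged = bool(result.status > 0) and not at_bound
    return MeasurementFit(
        d0_hat=d0_hat,
        mu_hat=mu_hat,
        converged=converged,
        residual_norm=float(np.linalg.norm(result.fun)),
        n_samples_used=len(kept),
        at_bound=at_bound,
        jacobian_cond=cond,
        message=result.message,
    )


def estimate_series(
    series: MeasurementSeries,
    fluid: FluidMedium,
    drive: AcousticDrive,
    particle: DonorParticle,
    protocol: EstimationProtocol,
) -> tuple[SampleSelection, MeasurementFit | None]:
    """Full single-measurement pipeline: fold, filter, fit.

    Series flagged as touching at generation time are refused outright; the
    filter additionally rejects saturated or sample-starved waveforms.
    Returns the selection verdict and the fit (``None`` when rejected).
    """
    if series.touching:
        return SampleSelection(kept=np.array([], dtype=int), accepted=False,
                               reason="touching"), None
    tau, waveform = fold_average(series, protocol.NT)
    selection = select_samples(waveform, series.alpha, protocol)
    if not selection.accepted:
        return selection, None
    fit = fit_measurement(
        tau, waveform, selection.kept, fluid, drive, particle, series.alpha, protocol
    )
    return selection, fit


def aggregate(
    results: Sequence[tuple[SampleSelection, MeasurementFit | None]],
) -> EstimateReport:
    """Average per-measurement estimates into the final (d0_hat, mu_hat).

    Finals are unweighted arithmetic means over measurements that were both
    accepted by the filter and converged in the fit; everything else lands
    in the rejection ledger with its reason.  Raises when no measurement is
    usable.
    """
    per: list[dict] = []
    d0s: list[float] = []
    mus: list[float] = []
    reasons: dict[str, int] = {}
    for selection, fit in results:
        rec: dict = {"accepted": selection.accepted}
        if not selection.accepted:
            rec["reason"] = selection.reason
            reasons[selection.reason or "unknown"] = reasons.get(selection.reason or "unknown", 0) + 1
        elif fit is not None:
            rec.update(
                converged=fit.converged,
                d0_hat=fit.d0_hat,
                mu_hat=fit.mu_hat,
                residual_norm=fit.residual_norm,
                n_samples_used=fit.n_samples_used,
            )
            if fit.converged:
                d0s.append(fit.d0_hat)
                mus.append(fit.mu_hat)
            else:
                reasons["not_converged"] = reasons.get("not_converged", 0) + 1
        per.append(rec)
    if not d0s:
        raise RuntimeError(
            f"no usable measurement out of {len(results)}; rejections: {reasons}"
        )
    return EstimateReport(
        per_measurement=per,
        d0_hat_final=float(np.mean(d0s)),
        mu_hat_final=float(np.mean(mus)),
        n_used=len(d0s),
        n_rejected=len(results) - len(d0s),
        rejection_reasons=reasons,
    )


def estimate_measurements(
    series_list: Sequence[MeasurementSeries],
    fluid: FluidMedium,
    drive: AcousticDrive,
    particle: DonorParticle,
    protocol: EstimationProtocol,
) -> EstimateReport:
    """Run the pipeline over a batch of measurements and aggregate."""
    results = [
        estimate_series(s, fluid, drive, particle, protocol) for s in series_list
    ]
    return aggregate(results)
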