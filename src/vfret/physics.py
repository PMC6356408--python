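"""Acoustic entrainment physics of a donor microparticle in a vibrating fluid.

A lumped spherical donor particle suspended in an acoustically driven fluid
is dragged along with the oscillating fluid.  How completely it follows the
fluid depends on the ratio of the drive's angular frequency to the particle's
Stokes-drag relaxation rate; the fraction transmitted is the entrainment
coefficient ``eta_p`` and the particle lags the fluid by the phase ``phi_p``.
Because the relaxation time depends on the fluid's dynamic viscosity, the
particle's vibration amplitude encodes the viscosity — this is the physical
handle the whole viscometer rests on.

All quantities in this module are SI (m, s, kg, Pa, Pa·s, rad).  Unit
conversion for human-facing configuration (nm, µm, mPa·s) happens at the
I/O boundary, never here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluidMedium",
    "AcousticDrive",
    "DonorParticle",
    "VibrationState",
    "fluid_displacement_amplitude",
    "sphere_mass",
    "particle_time_scale",
    "entrainment",
    "vibration_state",
    "donor_acceptor_distance",
]


def _require_positive(name: str, value: float) -> None:
    if not (value > 0.0) or not math.isfinite(value):
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class FluidMedium:
    """Carrier fluid: density, sound speed and dynamic viscosity.

    The dynamic viscosity ``mu_f`` is the estimand of the inverse problem;
    water is ~0.89e-3 Pa·s at room temperature, whole blood 3–4e-3 Pa·s.
    """

    rho_f: float  # mass density [kg/m^3]
    c_f: float    # sound speed [m/s]
    mu_f: float   # dynamic viscosity [Pa*s]

    def __post_init__(self) -> None:
        _require_positive("rho_f", self.rho_f)
        _require_positive("c_f", self.c_f)
        _require_positive("mu_f", self.mu_f)

    def with_viscosity(self, mu_f: float) -> "FluidMedium":
        """Copy of this fluid with a different viscosity (used by the fitter)."""
        return FluidMedium(rho_f=self.rho_f, c_f=self.c_f, mu_f=mu_f)


@dataclass(frozen=True)
class AcousticDrive:
    """Sinusoidal acoustic excitation: pressure amplitude and frequency."""

    P_f: float  # acoustic pressure amplitude [Pa]
    f0: float   # excitation frequency [Hz]

    def __post_init__(self) -> None:
        if self.P_f < 0.0 or not math.isfinite(self.P_f):
            raise ValueError(f"P_f must be >= 0, got {self.P_f!r}")
        _require_positive("f0", self.f0)

    @property
    def omega0(self) -> float:
        """Angular excitation frequency [rad/s]."""
        return 2.0 * math.pi * self.f0

    @property
    def period(self) -> float:
        """Excitation period T = 1/f0 [s]."""
        return 1.0 / self.f0


@dataclass(frozen=True)
class DonorParticle:
    """Lumped spherical donor particle plus its FRET pairing constants.

    The particle mass may be given directly (``m_p``) or derived from a
    particle density ``rho_p`` (default 1000 kg/m^3, i.e. neutrally buoyant
    in water).  ``R0`` is the Förster distance of the donor–acceptor pair and
    ``k_A`` the number of acceptors coupled to the donor.
    """

    d_p: float                    # diameter [m]
    R0: float                     # Förster distance [m]
    k_A: float = 1.0              # acceptors per donor
    rho_p: float = 1000.0         # particle density [kg/m^3]
    m_p: float = field(default=None)  # type: ignore[assignment]  # mass [kg]

    def __post_init__(self) -> None:
        _require_positive("d_p", self.d_p)
        _require_positive("R0", self.R0)
        if self.k_A < 1.0:
            raise ValueError(f"k_A must be >= 1, got {self.k_A!r}")
        if self.m_p is None:
            _require_positive("rho_p", self.rho_p)
            object.__setattr__(self, "m_p", sphere_mass(self.d_p, self.rho_p))
        else:
            _require_positive("m_p", self.m_p)


@dataclass(frozen=True)
class VibrationState:
    """Derived vibration quantities for one (fluid, drive, particle) triple."""

    Uf_max: float  # fluid displacement amplitude [m]
    tau_p: float   # particle Stokes relaxation time [s]
    eta_p: float   # entrainment coefficient, (0, 1]
    phi_p: float   # phase lag of particle behind fluid [rad], [0, pi/2)
    Up_max: float  # particle displacement amplitude = eta_p * Uf_max [m]

    def touches(self, d0: float) -> bool:
        """True when the oscillation reaches the acceptor layer (d0 <= Up_max)."""
        return d0 <= self.Up_max


def fluid_displacement_amplitude(drive: AcousticDrive, fluid: FluidMedium) -> float:
    """Maximum fluid displacement U_f,max = P_f / (2 pi rho_f f0 c_f).

    For a travelling plane acoustic wave of pressure amplitude ``P_f`` the
    fluid velocity amplitude is ``P_f / (rho_f c_f)``; dividing by the angular
    frequency gives the displacement amplitude.  Independent of any particle
    property, linear in ``P_f`` and hyperbolic in ``f0``.
    """
    return drive.P_f / (2.0 * math.pi * fluid.rho_f * drive.f0 * fluid.c_f)


def sphere_mass(d_p: float, rho_p: float) -> float:
    """Mass of a homogeneous sphere of diameter ``d_p`` and density ``rho_p``."""
    _require_positive("d_p", d_p)
    _require_positive("rho_p", rho_p)
    return rho_p * math.pi * d_p**3 / 6.0


def particle_time_scale(particle: DonorParticle, fluid: FluidMedium) -> float:
    """Stokes-drag relaxation time tau_p = m_p / (3 pi mu_f d_p) [s].

    The time over which Stokes drag (drag coefficient 3 pi mu_f d_p) damps
    the particle's velocity mismatch with the fluid.  Strictly decreasing in
    viscosity: thicker fluids grip the particle faster.
    """
    return particle.m_p / (3.0 * math.pi * fluid.mu_f * particle.d_p)


def entrainment(drive: AcousticDrive, tau_p: float) -> tuple[float, float]:
    """Entrainment coefficient and phase lag of a Stokes particle.

    For sinusoidal forcing at angular frequency ``omega0`` a particle with
    relaxation time ``tau_p`` oscillates with amplitude fraction

        eta_p = 1 / sqrt(1 + (omega0 tau_p)^2)

    of the fluid's, lagging by ``phi_p = arctan(omega0 tau_p)``.  A massless
    or slow-drive limit (omega0 tau_p -> 0) gives full entrainment (1, 0).
    """
    if tau_p < 0.0 or not math.isfinite(tau_p):
        raise ValueError(f"tau_p must be >= 0, got {tau_p!r}")
    x = drive.omega0 * tau_p
    return 1.0 / math.sqrt(1.0 + x * x), math.atan(x)


#: fraction of the acoustic wavelength above which the small-particle
#: (Stokes drag, uniform pressure) assumption becomes questionable
_WAVELENGTH_FRACTION = 0.1


def vibration_state(
    drive: AcousticDrive, fluid: FluidMedium, particle: DonorParticle
) -> VibrationState:
    """Compose the closed forms into the full vibration state.

    Warns when the particle diameter exceeds a tenth of the acoustic
    wavelength ``c_f / f0``, where the point-particle entrainment model
    stops being trustworthy.
    """
    wavelength = fluid.c_f / drive.f0
    if particle.d_p > _WAVELENGTH_FRACTION * wavelength:
        warnings.warn(
            f"particle diameter {particle.d_p:.3g} m exceeds "
            f"{_WAVELENGTH_FRACTION:g} of the acoustic wavelength "
            f"{wavelength:.3g} m; the small-particle entrainment model may "
            "not hold",
            stacklevel=2,
        )
    Uf_max = fluid_displacement_amplitude(drive, fluid)
    tau_p = particle_time_scale(particle, fluid)
    eta_p, phi_p = entrainment(drive, tau_p)
    return VibrationState(
        Uf_max=Uf_max, tau_p=tau_p, eta_p=eta_p, phi_p=phi_p, Up_max=eta_p * Uf_max
    )


def donor_acceptor_distance(
    d0: float,
    vib: VibrationState,
    drive: AcousticDrive,
    t: float | np.ndarray,
) -> np.ndarray:
    """Donor–acceptor distance d(t) = d0 - Up_max cos(omega0 t - phi_p).

    ``d0`` is the steady-state (suspended) position of the donor above the
    acceptor layer.  Values are returned as-is: when ``d0 <= Up_max`` the
    trajectory crosses zero at some phases — the caller decides how to flag
    or clamp that (see :func:`VibrationState.touches`).
    """
    if d0 <= 0.0:
        raise ValueError(f"d0 must be > 0, got {d0!r}")
    t = np.asarray(t, dtype=float)
    return d0 - vib.Up_max * np.cos(drive.omega0 * t - vib.phi_p)
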