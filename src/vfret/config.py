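"""Configuration loading, unit handling and fluorophore material presets.

Configuration lives in a single declarative YAML file whose numbers are in
human units (nm, µm, mPa·s, µs) declared by an explicit ``units:`` block;
conversion to SI happens once, at load time, and everything downstream is
SI.  Unknown keys, wrong units and out-of-range values are hard errors that
name the offending field.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from .montecarlo import ExperimentConfig
from .photon import PhotonBudget

__all__ = [
    "MaterialPreset",
    "MATERIALS",
    "FRET_PAIR_R0",
    "ConfigError",
    "load_config",
    "photon_budget_from_pair",
]


class ConfigError(ValueError):
    """Raised for any malformed configuration input."""


@dataclass(frozen=True)
class MaterialPreset:
    """Optical properties of one fluorophore, as tabulated for dye datasheets."""

    name: str
    role: str                       # "donor" | "acceptor"
    excitation_wavelength_nm: float
    emission_wavelength_nm: float
    extinction_coeff: float         # [M^-1 cm^-1]
    quantum_yield: float            # fraction
    fluorescence_lifetime_ns: float

    def __post_init__(self) -> None:
        if self.role not in ("donor", "acceptor"):
            raise ConfigError(f"role must be donor or acceptor, got {self.role!r}")
        for f in (
            "excitation_wavelength_nm", "emission_wavelength_nm",
            "extinction_coeff", "quantum_yield", "fluorescence_lifetime_ns",
        ):
            if getattr(self, f) <= 0:
                raise ConfigError(f"{self.name}: {f} must be positive")


#: shipped dye presets (fluorescein donor / TAMRA acceptor pair)
MATERIALS: dict[str, MaterialPreset] = {
    "fluorescein": MaterialPreset(
        name="fluorescein", role="donor",
        excitation_wavelength_nm=500.0, emission_wavelength_nm=515.0,
        extinction_coeff=7e4, quantum_yield=0.95, fluorescence_lifetime_ns=4.0,
    ),
    "tamra": MaterialPreset(
        name="tamra", role="acceptor",
        excitation_wavelength_nm=550.0, emission_wavelength_nm=577.0,
        extinction_coeff=9e4, quantum_yield=0.68, fluorescence_lifetime_ns=5.0,
    ),
}

#: Förster distances for shipped donor-acceptor pairs [m]
FRET_PAIR_R0: dict[str, float] = {
    "fluorescein-tamra": 5.5e-9,
}


def photon_budget_from_pair(
    donor: MaterialPreset,
    acceptor: MaterialPreset,
    *,
    delta_t: float,
    I_D: float,
    D_B: float,
    N_D: float = 1.0,
) -> PhotonBudget:
    """Assemble a photon budget from a donor/acceptor preset pair.

    The donor supplies the absorption (extinction coefficient, excitation
    wavelength); the acceptor supplies the emission quantum yield.
    """
    return PhotonBudget(
        delta_t=delta_t, I_D=I_D, D_B=D_B,
        D_ext=donor.extinction_coeff,
        Phi_A=acceptor.quantum_yield,
        lambda_Da=donor.excitation_wavelength_nm * 1e-9,
        N_D=N_D,
    )


# -- unit system -----------------------------------------------------------

# quantity kind -> {unit name: factor to SI}
_UNIT_TABLES: dict[str, dict[str, float]] = {
    "distance": {"nm": 1e-9, "um": 1e-6, "m": 1.0},
    "particle_diameter": {"nm": 1e-9, "um": 1e-6, "mm": 1e-3, "m": 1.0},
    "viscosity": {"mPa_s": 1e-3, "Pa_s": 1.0},
    "time": {"us": 1e-6, "ms": 1e-3, "s": 1.0},
    "pressure": {"Pa": 1.0, "kPa": 1e3},
    "frequency": {"Hz": 1.0, "kHz": 1e3},
    "density": {"kg_m3": 1.0, "g_cm3": 1e3},
    "sound_speed": {"m_s": 1.0},
}

_DEFAULT_UNITS: dict[str, str] = {
    "distance": "nm",
    "particle_diameter": "um",
    "viscosity": "mPa_s",
    "time": "us",
    "pressure": "Pa",
    "frequency": "Hz",
    "density": "kg_m3",
    "sound_speed": "m_s",
}

# config key -> (quantity kind or None for dimensionless, is_list)
_FIELDS: dict[str, tuple[str | None, bool]] = {
    "rho_f": ("density", False),
    "rho_p": ("density", False),
    "c_f": ("sound_speed", False),
    "P_f": ("pressure", False),
    "f0": ("frequency", False),
    "d_p": ("particle_diameter", False),
    "R0": ("distance", False),
    "k_A": (None, False),
    "delta_t": ("time", False),
    "alpha": (None, False),
    "NT": (None, False),
    "Nm": (None, False),
    "NMC": (None, False),
    "E_min": (None, False),
    "Nmin_fraction": (None, False),
    "d0_min": ("distance", False),
    "d0_max": ("distance", False),
    "mu_list": ("viscosity", True),
    "snr_list": (None, True),
    "f0_list": ("frequency", True),
    "Pf_list": ("pressure", True),
    "dp_list": ("particle_diameter", True),
    "mu_grid": ("viscosity", True),
    "seed": (None, False),
}

_INT_FIELDS = {"NT", "Nm", "NMC", "seed"}


def _resolve_units(units_block: dict[str, str]) -> dict[str, float]:
    factors = {}
    for kind, default in _DEFAULT_UNITS.items():
        unit = units_block.get(kind, default)
        table = _UNIT_TABLES[kind]
        if unit not in table:
            raise ConfigError(
                f"units.{kind}: unknown unit {unit!r}; choose from {sorted(table)}"
            )
        factors[kind] = table[unit]
    unknown = set(units_block) - set(_DEFAULT_UNITS)
    if unknown:
        raise ConfigError(f"units block has unknown quantity kinds: {sorted(unknown)}")
    return factors


def _convert(key: str, value: Any, factors: dict[str, float]) -> Any:
    kind, is_list = _FIELDS[key]
    scale = factors[kind] if kind else 1.0

    def one(v: Any) -> float | int:
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            raise ConfigError(f"{key}: expected a number, got {v!r}")
        if key in _INT_FIELDS:
            if v != int(v):
                raise ConfigError(f"{key}: expected an integer, got {v!r}")
            return int(v)
        return float(v) * scale

    if is_list:
        if not isinstance(value, (list, tuple)) or len(value) == 0:
            raise ConfigError(f"{key}: expected a non-empty list")
        return tuple(one(v) for v in value)
    return one(value)


def load_config(path: str | Path | None = None, data: dict | None = None) -> ExperimentConfig:
    """Load and validate a YAML experiment configuration.

    An empty (or absent) file yields the full set of defaults.  A
    ``preset:`` key naming a shipped donor–acceptor pair (e.g.
    ``fluorescein-tamra``) sets the Förster distance accordingly; an
    explicit ``R0`` in the same file overrides the preset.
    """
    if data is None:
        if path is None:
            raise ConfigError("give either a path or a data mapping")
        raw = yaml.safe_load(Path(path).read_text())
        data = {} if raw is None else raw
    if not isinstance(data, dict):
        raise ConfigError(f"top level of the config must be a mapping, got {type(data).__name__}")

    data = dict(data)
    units_block = data.pop("units", {})
    if not isinstance(units_block, dict):
        raise ConfigError("units must be a mapping of quantity kind to unit name")
    factors = _resolve_units(units_block)

    preset = data.pop("preset", None)
    kwargs: dict[str, Any] = {}
    if preset is not None:
        key = str(preset).lower()
        if key not in FRET_PAIR_R0:
            raise ConfigError(
                f"preset: unknown pair {preset!r}; available: {sorted(FRET_PAIR_R0)}"
            )
        kwargs["R0"] = FRET_PAIR_R0[key]

    unknown = set(data) - set(_FIELDS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key, value in data.items():
        kwargs[key] = _convert(key, value, factors)

    try:
        config = ExperimentConfig(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    # positivity checks that the dataclass cannot express field-by-field
    for name in ("rho_f", "rho_p", "c_f", "f0", "d_p", "R0", "delta_t", "alpha",
                 "E_min", "Nmin_fraction", "d0_min", "d0_max"):
        if getattr(config, name) <= 0:
            raise ConfigError(f"{name} must be positive, got {getattr(config, name)!r}")
    if config.P_f < 0:
        raise ConfigError(f"P_f must be >= 0, got {config.P_f!r}")
    if config.k_A < 1:
        raise ConfigError(f"k_A must be >= 1, got {config.k_A!r}")
    for name in ("mu_list", "mu_grid"):
        if any(v <= 0 for v in getattr(config, name)):
            raise ConfigError(f"{name} values must be positive")
    for name in ("f0_list", "Pf_list", "dp_list"):
        if any(v <= 0 for v in getattr(config, name)):
            raise ConfigError(f"{name} values must be positive")
    if config.d0_min >= config.d0_max:
        raise ConfigError("d0_min must be smaller than d0_max")
    return config
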