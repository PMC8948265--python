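"""Model parameter containers and strict YAML/JSON config loading.

All parameters are stored in SI units.  Config files use the lab-friendly
units that appear in the literature (micrometres, millitesla, millivolt,
nanometre Debye lengths) with unit-suffixed keys; conversion happens at
the boundary, nowhere else.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .constants import MU_0
from .errors import ConfigError, ParameterError

__all__ = [
    "BeadParams",
    "FluidParams",
    "FieldParams",
    "FitParams",
    "ModelParams",
    "default_params",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class BeadParams:
    """Superparamagnetic bead properties.

    Attributes
    ----------
    a : float
        Bead radius (m).
    rho_bead : float
        Bead density (kg/m^3).
    chi : float
        Real part of the magnetic susceptibility (dimensionless).
    chi_imag : float
        Imaginary part of the magnetic susceptibility (dimensionless).
    """

    a: float
    rho_bead: float
    chi: float
    chi_imag: float = 0.0

    def __post_init__(self) -> None:
        _require(self.a > 0, "bead radius a must be > 0")
        _require(self.rho_bead > 0, "bead density must be > 0")
        _require(self.chi > 0, "susceptibility chi must be > 0")
        _require(self.chi_imag >= 0, "imaginary susceptibility must be >= 0")

    @property
    def volume(self) -> float:
        """Bead volume nu = (4/3) pi a^3 (m^3), always derived."""
        return 4.0 / 3.0 * math.pi * self.a**3

    def mass(self, rho_fluid: float | None = None) -> float:
        """Single-bead mass (kg).

        With ``rho_fluid`` given, returns the buoyancy-corrected
        (effective) mass ``(rho_bead - rho_fluid) * volume`` appropriate
        for load/weight calculations of a submerged bead; otherwise the
        raw mass ``rho_bead * volume``.
        """
        rho = self.rho_bead if rho_fluid is None else self.rho_bead - rho_fluid
        return rho * self.volume


@dataclass(frozen=True)
class FluidParams:
    """Suspending-fluid and wall-interaction properties.

    ``debye_inv`` is kappa (1/m), the inverse Debye screening length;
    ``zeta_particle`` / ``zeta_wall`` are the particle and near-surface
    zeta potentials (V).
    """

    eta: float
    rho_fluid: float
    T: float
    eps_rel: float
    debye_inv: float
    zeta_particle: float
    zeta_wall: float

    def __post_init__(self) -> None:
        _require(self.eta > 0, "viscosity eta must be > 0")
        _require(self.rho_fluid > 0, "fluid density must be > 0")
        _require(self.T > 0, "temperature must be > 0")
        _require(self.eps_rel > 0, "relative permittivity must be > 0")
        _require(self.debye_inv > 0, "inverse Debye length must be > 0")
        _require(
            self.zeta_particle * self.zeta_wall > 0,
            "zeta potentials must be like-signed (repulsive wall interaction)",
        )


@dataclass(frozen=True)
class FieldParams:
    """Rotating magnetic field settings.

    The field is entered as a flux density B (T); the field strength
    H = B / mu_0 is what enters the formulas.  ``camber_deg`` is
    informational only — the model holds camber constant.
    """

    B: float
    freq: float
    camber_deg: float = 30.0

    def __post_init__(self) -> None:
        _require(self.B > 0, "flux density B must be > 0")
        _require(self.freq > 0, "field frequency must be > 0")

    @property
    def H(self) -> float:
        """Field strength H = B / mu_0 (A/m)."""
        return self.B / MU_0


@dataclass(frozen=True)
class FitParams:
    """Shape-correction fit constants.

    k1 scales the lubrication gap width (non-circularity of real
    wheels); k2 scales the translational drag (rough bead surface vs a
    smooth cylinder).
    """

    k1: float = 1.50
    k2: float = 3.11

    def __post_init__(self) -> None:
        _require(self.k1 > 0, "k1 must be > 0")
        _require(self.k2 > 0, "k2 must be > 0")


# --- config schema: section -> {yaml key: (dataclass field, SI scale)} ---
_SCHEMA: dict[str, dict[str, tuple[str, float]]] = {
    "bead": {
        "a_um": ("a", 1e-6),
        "rho_kg_m3": ("rho_bead", 1.0),
        "chi": ("chi", 1.0),
        "chi_imag": ("chi_imag", 1.0),
    },
    "fluid": {
        "eta_mPa_s": ("eta", 1e-3),
        "rho_kg_m3": ("rho_fluid", 1.0),
        "T_K": ("T", 1.0),
        "eps_rel": ("eps_rel", 1.0),
        "debye_nm": ("debye_inv", 1.0),  # inverted below
        "zeta_particle_mV": ("zeta_particle", 1e-3),
        "zeta_wall_mV": ("zeta_wall", 1e-3),
    },
    "field": {
        "B_mT": ("B", 1e-3),
        "freq_Hz": ("freq", 1.0),
        "camber_deg": ("camber_deg", 1.0),
    },
    "fit": {
        "k1": ("k1", 1.0),
        "k2": ("k2", 1.0),
    },
}
_SECTION_TYPES = {
    "bead": BeadParams,
    "fluid": FluidParams,
    "field": FieldParams,
    "fit": FitParams,
}


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set for the incline rolling model.

    ``buoyancy`` selects buoyancy-corrected bead mass for all weight
    terms (the default; beads operate submerged); set False for the
    literal raw-mass reading.
    """

    bead: BeadParams
    fluid: FluidParams
    field: FieldParams
    fit: FitParams = field(default_factory=FitParams)
    buoyancy: bool = True

    def bead_mass(self) -> float:
        """Per-bead mass entering weight terms (kg), honouring ``buoyancy``."""
        return self.bead.mass(self.fluid.rho_fluid if self.buoyancy else None)

    def with_fit(self, k1: float, k2: float) -> "ModelParams":
        """Copy with replaced fit constants (used by refitting routines)."""
        return replace(self, fit=FitParams(k1=k1, k2=k2))

    # ------------------------------------------------------------------
    @classmethod
    def from_dict(cls, cfg: Mapping[str, Any]) -> "ModelParams":
        """Build from a nested config mapping; unknown keys are rejected."""
        known_sections = set(_SCHEMA) | {"buoyancy"}
        unknown = set(cfg) - known_sections
        if unknown:
            raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for section, keys in _SCHEMA.items():
            raw = cfg.get(section)
            if raw is None:
                if section == "fit":
                    kwargs["fit"] = FitParams()
                    continue
                raise ConfigError(f"missing config section '{section}'")
            if not isinstance(raw, Mapping):
                raise ConfigError(f"config section '{section}' must be a mapping")
            bad = set(raw) - set(keys)
            if bad:
                raise ConfigError(
                    f"unknown key(s) in section '{section}': {sorted(bad)}"
                )
            fields: dict[str, float] = {}
            for yaml_key, (attr, scale) in keys.items():
                if yaml_key not in raw:
                    continue
                val = raw[yaml_key]
                if not isinstance(val, (int, float)) or isinstance(val, bool):
                    raise ConfigError(f"'{section}.{yaml_key}' must be a number")
                if yaml_key == "debye_nm":
                    if val <= 0:
                        raise ConfigError("'fluid.debye_nm' must be > 0")
                    fields[attr] = 1.0 / (val * 1e-9)
                else:
                    fields[attr] = val * scale
            try:
                kwargs[section] = _SECTION_TYPES[section](**fields)
            except TypeError as exc:  # missing required field
                raise ConfigError(f"section '{section}': {exc}") from exc
        buoyancy = cfg.get("buoyancy", True)
        if not isinstance(buoyancy, bool):
            raise ConfigError("'buoyancy' must be a boolean")
        kwargs["buoyancy"] = buoyancy
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        """Inverse of :meth:`from_dict` (lab units, unit-suffixed keys)."""
        return {
            "bead": {
                "a_um": self.bead.a / 1e-6,
                "rho_kg_m3": self.bead.rho_bead,
                "chi": self.bead.chi,
                "chi_imag": self.bead.chi_imag,
            },
            "fluid": {
                "eta_mPa_s": self.fluid.eta / 1e-3,
                "rho_kg_m3": self.fluid.rho_fluid,
                "T_K": self.fluid.T,
                "eps_rel": self.fluid.eps_rel,
                "debye_nm": 1.0 / self.fluid.debye_inv / 1e-9,
                "zeta_particle_mV": self.fluid.zeta_particle / 1e-3,
                "zeta_wall_mV": self.fluid.zeta_wall / 1e-3,
            },
            "field": {
                "B_mT": self.field.B / 1e-3,
                "freq_Hz": self.field.freq,
                "camber_deg": self.field.camber_deg,
            },
            "fit": {"k1": self.fit.k1, "k2": self.fit.k2},
            "buoyancy": self.buoyancy,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            cfg = json.loads(text)
        else:
            cfg = yaml.safe_load(text)
        if not isinstance(cfg, Mapping):
            raise ConfigError("config root must be a mapping")
        return cls.from_dict(cfg)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def default_params() -> ModelParams:
    """Shipped illustrative parameter set.

    Bead size/density, viscosity, field and the fit constants k1 = 1.50,
    k2 = 3.11 follow the experimental system; the electrostatic values
    (eps_rel 80, Debye length 10 nm, |zeta| 50 mV) and chi'' = 0.01 are
    order-of-magnitude illustrative defaults — override via config for
    quantitative work against a specific dataset.
    """
    return ModelParams(
        bead=BeadParams(a=2.25e-6, rho_bead=1600.0, chi=1.4, chi_imag=0.01),
        fluid=FluidParams(
            eta=1.0e-3,
            rho_fluid=1000.0,
            T=298.0,
            eps_rel=80.0,
            debye_inv=1.0 / 10e-9,
            zeta_particle=-50e-3,
            zeta_wall=-50e-3,
        ),
        field=FieldParams(B=3.7e-3, freq=40.0, camber_deg=30.0),
        fit=FitParams(k1=1.50, k2=3.11),
    )
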