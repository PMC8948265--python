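"""Single-wheel physics on inclined surfaces.

Force-balance model for a disc-like cluster of n beads spinning at
angular velocity omega and rolling on a thin lubricating fluid layer:

* normal direction: weight component W_y balanced by screened
  electrostatic wall repulsion, giving a closed-form gap width delta;
* propulsion direction: wet friction (shear of the lubrication layer)
  balanced against translational drag and the parallel weight
  component, giving a closed-form velocity V.

All functions accept scalars or numpy arrays for ``R`` and ``phi_deg``
and broadcast; angles are degrees at the interface, radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import EPS_0, G, K_B, MU_0
from .errors import AngleDomainError, InvalidRadiusError, PinnedWheelError
from .params import BeadParams, FieldParams, FluidParams, ModelParams

__all__ = [
    "ForceBreakdown",
    "DimensionlessGroups",
    "bead_number",
    "rotation_rate",
    "gap_width",
    "wheel_velocity",
    "velocity",
    "effective_incline",
    "dimensionless_groups",
    "force_breakdown",
]


@dataclass(frozen=True)
class ForceBreakdown:
    """Forces acting on a wheel at its solved operating point (SI, N)."""

    W_total: float
    W_x: float
    W_y: float
    F_es: float
    F_d: float
    F_f: float
    mu_k: float
    delta: float

    @property
    def residual(self) -> float:
        """Propulsion-direction balance residual F_f - F_d - W_x."""
        return self.F_f - self.F_d - self.W_x


@dataclass(frozen=True)
class DimensionlessGroups:
    """Peclet number, dipole strength and Mason number of a bead at a wheel edge."""

    Pe: float
    lam: float
    Mn: float
    gamma_dot: float
    l: float | None = None


def bead_number(R, a: float, hcp: bool = False):
    """Number of beads n in a wheel of radius R.

    Default is the quadratic estimate n = (R/a)^2; ``hcp=True`` scales
    by the 2-D hexagonal packing fraction pi/(2 sqrt 3) ~ 0.9069.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < a):
        raise InvalidRadiusError(f"wheel radius must be >= bead radius a={a}")
    n = (R / a) ** 2
    if hcp:
        n = n * (math.pi / (2.0 * math.sqrt(3.0)))
    return n if n.ndim else float(n)


def rotation_rate(R, bead: BeadParams, fluid: FluidParams, field: FieldParams):
    """Wheel angular velocity omega (rad/s) from the magnetic/viscous torque balance.

    omega = 3 n nu mu_0 chi'' H^2 / (32 eta R^3), with n = (R/a)^2, so
    omega scales as 1/R at fixed field and fluid.
    """
    if bead.chi_imag <= 0:
        raise InvalidRadiusError("rotation_rate requires chi_imag > 0")
    n = bead_number(R, bead.a)
    R = np.asarray(R, dtype=float)
    omega = (
        3.0 * n * bead.volume * MU_0 * bead.chi_imag * field.H**2
        / (32.0 * fluid.eta * R**3)
    )
    return omega if omega.ndim else float(omega)


def _check_phi(phi_deg) -> np.ndarray:
    phi = np.asarray(phi_deg, dtype=float)
    if np.any(np.abs(phi) >= 90.0):
        raise AngleDomainError("incline angle must satisfy -90 < phi < 90 deg")
    return phi


def _es_prefactor(params: ModelParams) -> float:
    """Contact-value electrostatic repulsion 4 pi eps eps0 a kappa z1 z2 (N)."""
    f = params.fluid
    return (
        4.0 * math.pi * f.eps_rel * EPS_0 * params.bead.a
        * f.debye_inv * f.zeta_particle * f.zeta_wall
    )


def gap_width(R, phi_deg, params: ModelParams):
    """Lubrication gap width delta (m) between wheel and wall.

    Closed form from balancing the normal weight component against the
    screened electrostatic repulsion:

        delta = k1 kappa^-1 ln( 4 pi eps eps0 a kappa z1 z2 / (m g n cos phi) )

    Raises :class:`PinnedWheelError` when the load exceeds the maximum
    (contact-value) repulsion, i.e. the log argument drops to <= 1.
    """
    phi = _check_phi(phi_deg)
    n = bead_number(R, params.bead.a)
    m = params.bead_mass()
    W_y = m * G * n * np.cos(np.deg2rad(phi))
    arg = _es_prefactor(params) / W_y
    if np.any(arg <= 1.0):
        raise PinnedWheelError(
            "load exceeds maximum electrostatic repulsion: wheel pinned to wall"
        )
    delta = params.fit.k1 / params.fluid.debye_inv * np.log(arg)
    return delta if np.ndim(delta) else float(delta)


def _drag_denominator(R, delta):
    """Cylinder-drag shape factor D = ln(2(R+delta)/R) - (1/4)(R/(R+delta))^2."""
    return np.log(2.0 * (R + delta) / R) - 0.25 * (R / (R + delta)) ** 2


def wheel_velocity(R, phi_deg, omega, params: ModelParams):
    """Wheel translational velocity V (m/s, signed; negative = downhill slip).

    Solves the linear propulsion-direction force balance
    F_f - F_d - W_x = 0 with F_f = eta a R (omega R - V) / delta and the
    cylinder drag F_d = k2 8 pi a eta V / D:

        V = (eta a R^2 omega / delta - m g n sin phi)
            / (eta a R / delta + 8 pi k2 a eta / D)
    """
    phi = _check_phi(phi_deg)
    R_arr = np.asarray(R, dtype=float)
    omega = np.asarray(omega, dtype=float)
    delta = gap_width(R, phi_deg, params)
    a = params.bead.a
    eta = params.fluid.eta
    n = bead_number(R, a)
    m = params.bead_mass()
    D = _drag_denominator(R_arr, delta)
    num = eta * a * R_arr**2 * omega / delta - m * G * n * np.sin(np.deg2rad(phi))
    den = eta * a * R_arr / delta + 8.0 * math.pi * params.fit.k2 * a * eta / D
    V = num / den
    return V if np.ndim(V) else float(V)


def velocity(R, phi_deg, params: ModelParams):
    """Convenience: V(R, phi) with omega supplied by :func:`rotation_rate`."""
    omega = rotation_rate(R, params.bead, params.fluid, params.field)
    return wheel_velocity(R, phi_deg, omega, params)


def effective_incline(phi_deg, phi_sb_deg):
    """Effective climbing angle under alternating (switchback) headings.

    phi_eff = asin( sin(phi) * cos(phi_sb) ), degrees in and out.
    """
    phi = np.asarray(phi_deg, dtype=float)
    sb = np.asarray(phi_sb_deg, dtype=float)
    if np.any(np.abs(phi) > 90.0):
        raise AngleDomainError("incline angle must be within [-90, 90] deg")
    if np.any((sb < 0.0) | (sb >= 90.0)):
        raise AngleDomainError("switchback angle must be within [0, 90) deg")
    out = np.rad2deg(np.arcsin(np.sin(np.deg2rad(phi)) * np.cos(np.deg2rad(sb))))
    return out if out.ndim else float(out)


def dimensionless_groups(
    gamma_dot: float | None = None,
    *,
    omega: float | None = None,
    R: float | None = None,
    l: float | None = None,
    bead: BeadParams,
    fluid: FluidParams,
    field: FieldParams,
) -> DimensionlessGroups:
    """Peclet number, dipole strength lambda, and Mason number.

    Provide either the shear rate ``gamma_dot`` directly, or
    ``(omega, R, l)`` from which the edge shear rate omega R / l is
    formed.  Mn = Pe / lam holds by construction:

        Pe  = 6 pi eta a^3 gamma_dot / kT
        lam = pi mu_0 a^3 chi^2 H^2 / (9 kT)
        Mn  = 54 eta gamma_dot / (mu_0 chi^2 H^2)
    """
    if gamma_dot is None:
        if omega is None or R is None or l is None:
            raise ValueError("provide gamma_dot or all of (omega, R, l)")
        gamma_dot = omega * R / l
    kT = K_B * fluid.T
    Pe = 6.0 * math.pi * fluid.eta * bead.a**3 * gamma_dot / kT
    lam = math.pi * MU_0 * bead.a**3 * bead.chi**2 * field.H**2 / (9.0 * kT)
    Mn = 54.0 * fluid.eta * gamma_dot / (MU_0 * bead.chi**2 * field.H**2)
    return DimensionlessGroups(Pe=Pe, lam=lam, Mn=Mn, gamma_dot=gamma_dot, l=l)


def force_breakdown(R, phi_deg, omega, V, params: ModelParams) -> ForceBreakdown:
    """All forces on a wheel rolling at velocity V on incline phi.

    At V = :func:`wheel_velocity` the propulsion residual F_f - F_d - W_x
    vanishes to round-off.  F_es is evaluated with the gap-shape factor
    k1 absorbed into the decay (exp(-kappa delta / k1)) so that the
    normal balance F_es = W_y holds at the solved gap.
    """
    phi = float(_check_phi(phi_deg))
    n = bead_number(R, params.bead.a)
    m = params.bead_mass()
    W = m * G * n
    W_y = W * math.cos(math.radians(phi))
    W_x = W * math.sin(math.radians(phi))
    delta = gap_width(R, phi, params)
    F_es = _es_prefactor(params) * math.exp(
        -params.fluid.debye_inv * delta / params.fit.k1
    )
    a, eta = params.bead.a, params.fluid.eta
    mu_k = eta * a * R * (omega * R - V) / (delta * W_y)
    F_f = mu_k * W_y
    D = _drag_denominator(R, delta)
    F_d = params.fit.k2 * 8.0 * math.pi * a * eta * V / D
    return ForceBreakdown(
        W_total=W, W_x=W_x, W_y=W_y, F_es=F_es, F_d=F_d, F_f=F_f,
        mu_k=mu_k, delta=delta,
    )
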