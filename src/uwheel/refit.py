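"""Recovery of the shape-correction fit constants k1, k2 from velocity data.

Given measured or synthetic (R, phi, V) triples, both constants are
refit jointly by nonlinear least squares on the closed-form incline
velocity model.  Residuals are scaled by the velocity magnitude so the
fit matches a multiplicative error model.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .params import ModelParams
from .physics import rotation_rate, wheel_velocity

__all__ = ["synth_velocity_dataset", "refit_k1_k2"]


def synth_velocity_dataset(
    params: ModelParams,
    n_r: int = 20,
    n_phi: int = 10,
    r_range: tuple[float, float] = (5e-6, 70e-6),
    phi_max: float = 80.0,
    noise: float = 0.02,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grid of (R, phi, V) with multiplicative Gaussian noise on V.

    Radii span ``r_range`` and inclines [0, phi_max] on an
    ``n_r x n_phi`` grid; each velocity is multiplied by
    ``1 + eps, eps ~ N(0, noise)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    radii = np.linspace(*r_range, n_r)
    phis = np.linspace(0.0, phi_max, n_phi)
    Rg, Pg = np.meshgrid(radii, phis, indexing="ij")
    R, phi = Rg.ravel(), Pg.ravel()
    omega = rotation_rate(R, params.bead, params.fluid, params.field)
    V = np.asarray(wheel_velocity(R, phi, omega, params))
    V_noisy = V * (1.0 + rng.normal(0.0, noise, size=V.shape))
    return R, phi, V_noisy


def refit_k1_k2(
    R: np.ndarray,
    phi: np.ndarray,
    V: np.ndarray,
    params: ModelParams,
    x0: tuple[float, float] = (1.0, 1.0),
) -> tuple[float, float]:
    """Jointly refit (k1, k2) by least squares against observed velocities.

    ``params`` supplies every other physical constant; its fit values
    are ignored.  Returns the recovered ``(k1, k2)``.
    """
    R = np.asarray(R, dtype=float)
    phi = np.asarray(phi, dtype=float)
    V = np.asarray(V, dtype=float)
    omega = rotation_rate(R, params.bead, params.fluid, params.field)
    scale = np.maximum(np.abs(V), np.abs(V).max() * 1e-3)

    def residuals(x: np.ndarray) -> np.ndarray:
        model = wheel_velocity(R, phi, omega, params.with_fit(x[0], x[1]))
        return (np.asarray(model) - V) / scale

    fit = least_squares(
        residuals, x0=np.asarray(x0), bounds=([1e-3, 1e-3], [np.inf, np.inf])
    )
    return float(fit.x[0]), float(fit.x[1])
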