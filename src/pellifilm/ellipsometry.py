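"""Null-ellipsometry film modelling and de Feijter adsorbed mass.

An adsorbed film in buffer on an oxidised silicon wafer is read out as a
(Ψ, Δ) pair, inverted to a homogeneous-slab refractive index and thickness
(n_f, d_f), and converted to the "dry" adsorbed amount with de Feijter's
equation

    Γ = (n_f − n_o) · d_f / (dn/dc),

which depends only on the product (n_f − n_o)·d_f and is therefore immune to
the classic thin-film n/d compensation ambiguity.  The forward model is the
standard multilayer Fresnel (characteristic-matrix) computation for the
ambient / film / SiO2 / Si stack.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "OpticalSlabStack",
    "DeFeijterParams",
    "DEFAULT_WAVELENGTH_NM",
    "DEFAULT_ANGLE_DEG",
    "de_feijter_mass",
    "psi_delta",
    "invert_film",
]

#: Xenon source filtered line used for the pellicle experiments.
DEFAULT_WAVELENGTH_NM = 442.9
DEFAULT_ANGLE_DEG = 68.0

#: Default substrate optical constants at 442.9 nm.
SI_INDEX = complex(4.62, -0.14)
SIO2_INDEX = 1.466
BUFFER_INDEX = 1.335


@dataclass(frozen=True)
class DeFeijterParams:
    """Ambient index and refractive-index increment (ml/g) of the adsorbate."""

    n_o: float = BUFFER_INDEX
    dndc: float = 0.18

    def __post_init__(self) -> None:
        if self.dndc <= 0:
            raise ValueError(f"dn/dc must be positive, got {self.dndc}")


@dataclass
class OpticalSlabStack:
    """Ambient / film / oxide / substrate optical stack (ellipsometry side).

    ``film`` and ``oxide`` are (refractive index, thickness in nm) pairs.  The
    substrate index may be complex (absorbing silicon).
    """

    ambient_index: float = BUFFER_INDEX
    film: tuple[float, float] = (BUFFER_INDEX, 0.0)
    oxide: tuple[float, float] = (SIO2_INDEX, 2.0)
    substrate_index: complex = SI_INDEX

    def __post_init__(self) -> None:
        for name in ("film", "oxide"):
            n, d = getattr(self, name)
            if d < 0:
                raise ValueError(f"{name} thickness must be >= 0, got {d}")
            if (n.real if isinstance(n, complex) else n) < 1:
                raise ValueError(f"{name} index must be >= 1 for a dielectric")


def de_feijter_mass(n_f: float, d_f_nm: float, params: DeFeijterParams) -> float:
    """Dry adsorbed amount Γ (mg/m²) from film index and thickness (nm).

    With d_f in nm and dn/dc in ml/g the unit conversion collapses to
    Γ[mg/m²] = (n_f − n_o)·d_f[nm] / (dn/dc)[ml/g].
    """
    if d_f_nm < 0:
        raise ValueError(f"film thickness must be >= 0, got {d_f_nm}")
    return (n_f - params.n_o) * d_f_nm / params.dndc


def _rho(stack: OpticalSlabStack, wavelength_nm: float, angle_deg: float) -> complex:
    """Complex ellipsometric ratio r_p / r_s for the multilayer stack."""
    if not 0.0 < angle_deg < 90.0:
        raise ValueError(f"angle of incidence must lie in (0, 90) deg, got {angle_deg}")
    n0 = complex(stack.ambient_index)
    theta0 = math.radians(angle_deg)
    kx = n0 * cmath.sin(theta0)  # conserved tangential index
    k0 = 2.0 * math.pi / wavelength_nm

    layers = [stack.film, stack.oxide]
    indices = [complex(n) for n, _ in layers] + [complex(stack.substrate_index)]
    thicknesses = [d for _, d in layers]

    def cos_theta(n: complex) -> complex:
        c = cmath.sqrt(1.0 - (kx / n) ** 2)
        # Decaying-wave branch for absorbing/evanescent media.
        if (n * c).imag > 0:
            c = -c
        return c

    r = {}
    for pol in ("s", "p"):
        def q_of(n: complex) -> complex:
            c = cos_theta(n)
            return n * c if pol == "s" else c / n

        m00, m01, m10, m11 = 1.0, 0.0, 0.0, 1.0
        for (n, d) in zip(indices[:-1], thicknesses):
            beta = k0 * n * cos_theta(n) * d
            q = q_of(n)
            c, s = cmath.cos(beta), cmath.sin(beta)
            a00, a01 = c, 1j * s / q
            a10, a11 = 1j * q * s, c
            m00, m01, m10, m11 = (
                m00 * a00 + m01 * a10,
                m00 * a01 + m01 * a11,
                m10 * a00 + m11 * a10,
                m10 * a01 + m11 * a11,
            )
        q0, qs = q_of(n0), q_of(indices[-1])
        num = q0 * (m00 + m01 * qs) - (m10 + m11 * qs)
        den = q0 * (m00 + m01 * qs) + (m10 + m11 * qs)
        r[pol] = num / den
    return r["p"] / r["s"]


def psi_delta(
    stack: OpticalSlabStack,
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM,
    angle_deg: float = DEFAULT_ANGLE_DEG,
) -> tuple[float, float]:
    """Ellipsometric angles (Ψ, Δ) in degrees for the slab stack.

    Ψ = atan|ρ|, Δ = arg ρ with ρ = r_p/r_s; Δ is reported in [0, 360).
    """
    rho = _rho(stack, wavelength_nm, angle_deg)
    psi = math.degrees(math.atan(abs(rho)))
    delta = math.degrees(cmath.phase(rho)) % 360.0
    return psi, delta


def invert_film(
    psi: float,
    delta: float,
    known: OpticalSlabStack,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((1.335, 1.60), (0.0, 300.0)),
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM,
    angle_deg: float = DEFAULT_ANGLE_DEG,
    grid: tuple[int, int] = (25, 61),
    residual_threshold: float = 1e-3,
):
    """Invert one (Ψ, Δ) reading to the film (n_f, d_f).

    ``known`` supplies ambient, oxide and substrate; the film slot is ignored.
    A coarse grid scan over the (n_f, d_f) bounds seeds a Nelder–Mead polish
    of |ρ_model − ρ_meas|².  Returns ``(n_f, d_f, residual, flags)``; flags
    may contain ``"ambiguous"`` (residual above threshold, e.g. thickness
    period ambiguity) or ``"index-unconstrained"`` (vanishing thickness, where
    n_f has no leverage).
    """
    rho_meas = cmath.rect(math.tan(math.radians(psi)), math.radians(delta))
    (n_lo, n_hi), (d_lo, d_hi) = bounds

    def cost(x) -> float:
        n_f, d_f = x
        if not (n_lo <= n_f <= n_hi and d_lo <= d_f <= d_hi):
            return 1e6
        stack = OpticalSlabStack(known.ambient_index, (n_f, d_f), known.oxide,
                                 known.substrate_index)
        return abs(_rho(stack, wavelength_nm, angle_deg) - rho_meas) ** 2

    best = None
    for n_f in np.linspace(n_lo, n_hi, grid[0]):
        for d_f in np.linspace(d_lo, d_hi, grid[1]):
            c = cost((n_f, d_f))
            if best is None or c < best[0]:
                best = (c, (n_f, d_f))
    sol = minimize(cost, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-16, "maxiter": 2000})
    n_f, d_f = float(sol.x[0]), float(sol.x[1])
    residual = float(sol.fun)
    flags: list[str] = []
    if residual > residual_threshold:
        flags.append("ambiguous")
    # A film is invisible along the whole (n_f - n_o) * d_f ~ 0 degeneracy:
    # both at vanishing thickness and at ambient-matched index.
    if d_f < 0.5 or abs(n_f - known.ambient_index) < 1e-3:
        flags.append("index-unconstrained")
    return n_f, d_f, residual, flags
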