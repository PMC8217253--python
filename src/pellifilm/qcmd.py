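"""QCM-D viscoelastic (Voigt) modelling of adsorbed pellicle films.

A quartz resonator immersed in buffer reports frequency shifts (Δf) and
dissipation shifts (ΔD) at its odd overtones.  A soft adsorbed film is
modelled as a single Voigt element — complex shear modulus G = μ + iωη — of
fixed density, loaded by a semi-infinite Newtonian liquid.  Within the
small-load approximation the complex frequency shift follows from the
acoustic load impedance at the crystal surface,

    Δf* = (i f0 / (π Z_q)) · (Z_L(film) − Z_L(bare liquid)),

with ΔD = 2·Im(Δf*)/f_n.  Fitting (thickness, viscosity, shear modulus) to
the overtone-resolved shifts yields the "wet" areal mass ρ_film·h, which
includes hydrodynamically coupled solvent.

Units follow SI internally: thickness m, density kg·m⁻³, viscosity Pa·s,
shear modulus Pa.  Δf is in Hz (raw, i.e. not divided by the overtone
number); ΔD in units of 1e-6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "QuartzCrystal",
    "ViscoelasticFilm",
    "BulkLiquid",
    "QcmdTrace",
    "PELLICLE_DENSITY",
    "voigt_response",
    "sauerbrey_mass",
    "fit_voigt",
    "segment_steps",
    "retention_ratio",
]

#: Density assumed for salivary pellicles when converting Voigt thickness to
#: areal mass (kg·m⁻³).
PELLICLE_DENSITY = 1080.0


@dataclass(frozen=True)
class QuartzCrystal:
    """Sensor constants of a Q-Sense-type 5 MHz crystal."""

    fundamental_frequency: float = 5.0e6  # Hz
    shear_impedance: float = 8.8e6  # kg m^-2 s^-1

    def __post_init__(self) -> None:
        if self.fundamental_frequency <= 0 or self.shear_impedance <= 0:
            raise ValueError("crystal constants must be positive")


@dataclass
class ViscoelasticFilm:
    """Single Voigt film: thickness (m), density (kg/m^3), viscosity (Pa s),
    elastic shear modulus (Pa)."""

    thickness: float
    density: float = PELLICLE_DENSITY
    viscosity: float = 1.5e-3
    shear_modulus: float = 1.0e5

    def __post_init__(self) -> None:
        for name in ("thickness", "density", "viscosity", "shear_modulus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def areal_mass(self) -> float:
        """Wet areal mass rho*h in mg/m^2."""
        return self.density * self.thickness * 1e6


@dataclass(frozen=True)
class BulkLiquid:
    """Newtonian bulk (PBS ~ water at 25 C)."""

    density: float = 1000.0
    viscosity: float = 8.9e-4

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("bulk properties must be positive")


@dataclass
class QcmdTrace:
    """Overtone-resolved Δf/ΔD time traces with step annotations.

    ``df`` maps overtone -> raw frequency shift (Hz); ``dd`` maps overtone ->
    dissipation shift (1e-6).  ``step_annotations`` is an ordered list of
    (label, start_time_s).
    """

    time: np.ndarray
    df: Mapping[int, np.ndarray]
    dd: Mapping[int, np.ndarray]
    step_annotations: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not self.df:
            raise ValueError("at least one overtone is required")
        self.df = {int(n): np.asarray(v, float) for n, v in self.df.items()}
        self.dd = {int(n): np.asarray(v, float) for n, v in self.dd.items()}

    @property
    def overtones(self) -> list[int]:
        return sorted(self.df)


def _load_impedance(
    thickness, viscosity, shear_modulus, density, bulk: BulkLiquid,
    crystal: QuartzCrystal, overtone: int,
):
    """Complex acoustic load impedance at the crystal face (transmission-line
    solution for film + semi-infinite Newtonian backing).  Accepts scalar or
    array film parameters."""
    omega = 2.0 * math.pi * overtone * crystal.fundamental_frequency
    z_bulk = np.sqrt(1j * omega * bulk.density * bulk.viscosity)
    h = np.asarray(thickness, dtype=float)
    g = np.asarray(shear_modulus, dtype=float) + 1j * omega * np.asarray(viscosity, float)
    z_film = np.sqrt(density * g)
    k = omega * np.sqrt(density / g)
    t = np.tan(k * h)
    z_in = z_film * (z_bulk + 1j * z_film * t) / (z_film + 1j * z_bulk * t)
    return np.where(h > 0, z_in, z_bulk)


def voigt_response(
    film: ViscoelasticFilm,
    bulk: BulkLiquid,
    crystal: QuartzCrystal,
    overtone: int,
):
    """(Δf, ΔD) of a Voigt film at one overtone, relative to the bare-liquid
    loaded crystal.

    Δf is the raw shift in Hz (negative for mass uptake); ΔD is in 1e-6.
    A zero-thickness film returns (0, 0) by construction.
    """
    if overtone <= 0 or overtone % 2 == 0:
        raise ValueError(f"overtone must be an odd positive integer, got {overtone}")
    f0 = crystal.fundamental_frequency
    z_l = _load_impedance(
        film.thickness, film.viscosity, film.shear_modulus, film.density,
        bulk, crystal, overtone,
    )
    z_ref = _load_impedance(0.0, film.viscosity, film.shear_modulus, film.density,
                            bulk, crystal, overtone)
    dfc = 1j * f0 / (math.pi * crystal.shear_impedance) * (z_l - z_ref)
    df = np.real(dfc)
    dd = 2.0 * np.imag(dfc) / (overtone * f0) * 1e6
    if np.ndim(df) == 0:
        return float(df), float(dd)
    return df, dd


def sauerbrey_mass(df: float, overtone: int, crystal: QuartzCrystal = QuartzCrystal()) -> float:
    """Rigid-limit areal mass (mg/m^2) from a raw frequency shift.

    m = -(Z_q / (2 f0^2)) * (df / n).  Used as a cross-check of the Voigt fit
    in the rigid thin-film regime.
    """
    if overtone <= 0 or overtone % 2 == 0:
        raise ValueError(f"overtone must be an odd positive integer, got {overtone}")
    f0 = crystal.fundamental_frequency
    mass_kg_m2 = -crystal.shear_impedance / (2.0 * f0**2) * (df / overtone)
    return mass_kg_m2 * 1e6


def retention_ratio(mass_before: float, mass_after: float) -> float:
    """Fraction of film mass remaining after a treatment: after / before."""
    if mass_before <= 0:
        raise ValueError(f"mass_before must be positive, got {mass_before}")
    return mass_after / mass_before


# ---------------------------------------------------------------------------
# Fitting

_H_BOUNDS = (1e-12, 2e-7)  # m
_ETA_BOUNDS = (2e-4, 5e-2)  # Pa s
_MU_BOUNDS = (1e2, 5e9)  # Pa


def _fit_point(
    df_obs: np.ndarray,
    dd_obs: np.ndarray,
    overtones: Sequence[int],
    bulk: BulkLiquid,
    crystal: QuartzCrystal,
    density: float,
    starts: np.ndarray,
    sigma_f: float,
    sigma_d: float,
):
    lo = np.log([_H_BOUNDS[0], _ETA_BOUNDS[0], _MU_BOUNDS[0]])
    hi = np.log([_H_BOUNDS[1], _ETA_BOUNDS[1], _MU_BOUNDS[1]])

    def residual(x):
        h, eta, mu = np.exp(x)
        res = np.empty(2 * len(overtones))
        for i, n in enumerate(overtones):
            z_l = _load_impedance(h, eta, mu, density, bulk, crystal, n)
            z_ref = _load_impedance(0.0, eta, mu, density, bulk, crystal, n)
            dfc = 1j * crystal.fundamental_frequency / (
                math.pi * crystal.shear_impedance) * (z_l - z_ref)
            res[2 * i] = (np.real(dfc) - df_obs[i]) / sigma_f
            res[2 * i + 1] = (2e6 * np.imag(dfc) / (n * crystal.fundamental_frequency)
                              - dd_obs[i]) / sigma_d
        return res

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(residual, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        cost, h = sol.cost, float(np.exp(sol.x[0]))
        # Ties between eta/mu-degenerate solutions break toward thinner films.
        if best is None or cost < best[0] - 1e-12 or (
                abs(cost - best[0]) <= 1e-12 and h < best[1]):
            best = (cost, h, sol)
    if best is not None:
        # A film is only accepted if it improves significantly on the no-film
        # model; otherwise the bulk-mimicking degeneracy (eta ~ bulk, mu -> 0,
        # arbitrary h) would assign spurious mass to pure-noise signals.
        cost0 = 0.5 * float(np.sum(residual(np.array([lo[0], *np.log([1.5e-3, 1e5])]))**2))
        if best[0] > cost0 - 3.0:
            return "no-film"
    return best


def fit_voigt(
    trace: QcmdTrace,
    window: tuple[float, float] | None = None,
    bulk: BulkLiquid = BulkLiquid(),
    crystal: QuartzCrystal = QuartzCrystal(),
    fixed_density: float = PELLICLE_DENSITY,
    seed: int = 0,
    max_fits: int = 500,
    n_starts: int = 5,
    sigma_f: float = 0.5,
    sigma_d: float = 0.2,
):
    """Fit a Voigt film (h, η, μ) to every (decimated) time point of a trace.

    All overtones present are fitted simultaneously; the film density is held
    fixed.  Each segment starts from ``n_starts`` seeded log-uniform initial
    guesses to escape the known η/μ degeneracy; subsequent points warm-start
    from their predecessor.  Returns ``(times, films, areal_mass, flags)``
    where ``areal_mass`` is ρ·h in mg/m² and ``flags`` marks non-converged
    points (the fit continues past them).
    """
    if len(trace.overtones) < 2:
        raise ValueError("at least two overtones are required for a Voigt fit")
    if fixed_density <= 0:
        raise ValueError("fixed_density must be positive")
    t = trace.time
    mask = np.ones_like(t, dtype=bool)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("window selects no samples")
    if idx.size > max_fits:
        idx = idx[np.linspace(0, idx.size - 1, max_fits).round().astype(int)]
        idx = np.unique(idx)

    rng = np.random.default_rng(seed)
    lo = np.log([_H_BOUNDS[0], _ETA_BOUNDS[0], _MU_BOUNDS[0]])
    hi = np.log([_H_BOUNDS[1], _ETA_BOUNDS[1], _MU_BOUNDS[1]])
    multi_starts = lo + (hi - lo) * rng.random((n_starts, 3))
    multi_starts[0] = np.log([1e-8, 1.5e-3, 1e5])  # generic soft-film start

    films, masses, flags, times = [], [], [], []
    prev_x = None
    overtones = trace.overtones
    for i in idx:
        df_obs = np.array([trace.df[n][i] for n in overtones])
        dd_obs = np.array([trace.dd[n][i] for n in overtones])
        starts = multi_starts if prev_x is None else np.vstack([prev_x, multi_starts])
        best = _fit_point(df_obs, dd_obs, overtones, bulk, crystal,
                          fixed_density, starts, sigma_f, sigma_d)
        if best == "no-film":
            films.append(ViscoelasticFilm(0.0, fixed_density))
            masses.append(0.0)
            flags.append(False)
            times.append(t[i])
            continue
        if best is None:
            films.append(ViscoelasticFilm(0.0, fixed_density))
            masses.append(np.nan)
            flags.append(True)
            times.append(t[i])
            continue
        _, _, sol = best
        h, eta, mu = np.exp(sol.x)
        prev_x = sol.x
        film = ViscoelasticFilm(h, fixed_density, eta, mu)
        films.append(film)
        masses.append(film.areal_mass)
        flags.append(not sol.success)
        times.append(t[i])
    return np.array(times), films, np.array(masses), np.array(flags)


def segment_steps(
    trace: QcmdTrace,
    schedule: Sequence[str] | None = None,
    plateau_fraction: float = 0.1,
):
    """Split a trace into its flow steps and compute plateau means.

    Steps come from the trace annotations (ordered (label, start) pairs); each
    step's plateau is its final ``plateau_fraction`` (default: last 10%).
    Returns a dict label -> {"window": (t0, t1), "plateau": (tp, t1),
    "df": {n: mean}, "dd": {n: mean}}.  If ``schedule`` is given, the
    annotations must contain every scheduled label, in order.
    """
    ann = trace.step_annotations
    if not ann:
        raise ValueError("trace carries no step annotations")
    labels = [a[0] for a in ann]
    if schedule is not None:
        missing = [s for s in schedule if s not in labels]
        if missing:
            raise ValueError(f"missing step annotation(s): {missing}")
        order = [labels.index(s) for s in schedule]
        if order != sorted(order):
            raise ValueError("annotated steps are out of schedule order")
    t = trace.time
    out = {}
    for i, (label, t0) in enumerate(ann):
        t1 = ann[i + 1][1] if i + 1 < len(ann) else t[-1]
        tp = t1 - plateau_fraction * (t1 - t0)
        # the next step's start sample belongs to the next step
        last = i + 1 == len(ann)
        sel = (t >= tp) & ((t <= t1) if last else (t < t1))
        if sel.sum() < 2:
            raise ValueError(
                f"step {label!r} is too short for a {plateau_fraction:.0%} plateau window"
            )
        out[label] = {
            "window": (t0, t1),
            "plateau": (tp, t1),
            "df": {n: float(trace.df[n][sel].mean()) for n in trace.overtones},
            "dd": {n: float(trace.dd[n][sel].mean()) for n in trace.overtones},
        }
    return out
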