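"""Seeded synthetic datasets for every pellicle-analysis technique.

Every generator is a pure function of (truth, noise specification, seed):
identical calls are bit-identical.  The default scenario truths encode the
structural picture the analyses are designed to resolve — a dense inner and a
diffuse, highly hydrated outer pellicle layer whose fate under surfactant
exposure differs by surfactant class:

* ``c12e5`` (nonionic): minor effect; outer layer essentially unchanged,
  inner hydration up by ~8 points, ~87% of the wet mass retained.
* ``capb`` (amphoteric): outer layer collapses ~3-fold (325 → 117 Å), steric
  decay length drops ~3-fold (12 → 4 nm), wet-mass retention drops below
  60%, surfactant retained mainly in the outer layer.
* ``sds`` (anionic reference): complete pellicle removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ellipsometry as ell
from .forcevolume import Cantilever, ForceRamp
from .materials import ContrastDefinition, standard_contrasts
from .qcmd import (
    PELLICLE_DENSITY,
    BulkLiquid,
    QcmdTrace,
    QuartzCrystal,
    ViscoelasticFilm,
    _load_impedance,
)
from .reflectometry import (
    ContrastMeasurement,
    PellicleLayer,
    PellicleTwoLayerModel,
    smeared_reflectivity,
    stack_from_model,
)

__all__ = [
    "NoiseSpec",
    "ScenarioTruth",
    "scenario",
    "default_q_grid",
    "gen_nr",
    "gen_qcmd",
    "gen_force_volume",
    "gen_ellipsometry",
    "DEFAULT_SCHEDULE",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise magnitudes for all four generators.

    relative_sigma — multiplicative reflectivity noise (counting statistics);
    background — reflectivity floor; detector_sigma — AFM detector noise in V
    (0.0025 V ≡ 0.05 nm at the 20 nm/V default sensitivity); trace_sigma_f /
    trace_sigma_d — QCM-D noise in Hz and 1e-6; nf_sigma / df_sigma —
    ellipsometry noise on n_f and d_f (nm).
    """

    relative_sigma: float = 0.02
    background: float = 1e-7
    detector_sigma: float = 0.0025
    trace_sigma_f: float = 0.2
    trace_sigma_d: float = 0.1
    nf_sigma: float = 1e-3
    df_sigma: float = 0.2

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


NOISELESS = NoiseSpec(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

#: QCM-D flow protocol: buffer baseline, saliva adsorption, buffer rinse,
#: surfactant exposure, final buffer rinse (durations in s).
DEFAULT_SCHEDULE: list[tuple[str, float]] = [
    ("baseline", 1800.0),
    ("saliva", 3600.0),
    ("rinse1", 3600.0),
    ("surfactant", 3600.0),
    ("rinse2", 3600.0),
]


def _film(mass_mg_m2: float, viscosity: float, shear_modulus: float) -> ViscoelasticFilm:
    return ViscoelasticFilm(mass_mg_m2 * 1e-6 / PELLICLE_DENSITY, PELLICLE_DENSITY,
                            viscosity, shear_modulus)


@dataclass
class ScenarioTruth:
    """Ground truth of one surfactant-exposure experiment across techniques."""

    name: str
    pellicle_before: PellicleTwoLayerModel
    pellicle_after: PellicleTwoLayerModel | None
    qcmd_films: Mapping[str, ViscoelasticFilm]
    ellipsometry_mass_before: float  # mg/m^2, dry
    ellipsometry_mass_after: float
    lambda_before: float  # nm
    lambda_after: float | None
    f0: float = 1.0  # nN
    hertz_prefactor: float = 1.0  # nN/nm^1.5
    n_contrasts_after: int = 3


def scenario(name: str) -> ScenarioTruth:
    """Default truths for the ``c12e5``, ``capb`` and ``sds`` scenarios."""
    before_c12e5 = PellicleTwoLayerModel(
        inner=PellicleLayer(46.0, 0.620, roughness=5.0),
        outer=PellicleLayer(286.0, 0.971, roughness=10.0),
        surfactant_sld=3.76,  # chain-deuterated C12E5
    )
    before_capb = PellicleTwoLayerModel(
        inner=PellicleLayer(46.0, 0.557, roughness=5.0),
        outer=PellicleLayer(325.0, 0.975, roughness=10.0),
        surfactant_sld=0.36,
    )
    pellicle_film = _film(15.0, 2.0e-3, 1.0e5)
    if name == "c12e5":
        after = PellicleTwoLayerModel(
            inner=PellicleLayer(45.0, 0.701, roughness=5.0, surfactant_fraction=0.08),
            outer=PellicleLayer(277.0, 0.980, roughness=10.0, surfactant_fraction=0.04),
            surfactant_sld=3.76,
        )
        return ScenarioTruth(
            name, before_c12e5, after,
            qcmd_films={
                "baseline": _film(0.0, 2.0e-3, 1.0e5),
                "saliva": pellicle_film,
                "rinse1": pellicle_film,
                "surfactant": _film(14.0, 2.0e-3, 1.2e5),
                "rinse2": _film(13.0, 2.0e-3, 1.2e5),
            },
            ellipsometry_mass_before=2.5,
            ellipsometry_mass_after=2.25,
            lambda_before=12.0,
            lambda_after=12.0,
        )
    if name == "capb":
        after = PellicleTwoLayerModel(
            inner=PellicleLayer(35.0, 0.544, roughness=5.0, surfactant_fraction=0.006),
            outer=PellicleLayer(117.0, 0.955, roughness=10.0, surfactant_fraction=0.08),
            surfactant_sld=0.36,
        )
        return ScenarioTruth(
            name, before_capb, after,
            qcmd_films={
                "baseline": _film(0.0, 2.0e-3, 1.0e5),
                "saliva": pellicle_film,
                "rinse1": pellicle_film,
                "surfactant": _film(10.0, 2.5e-3, 2.0e5),
                "rinse2": _film(8.0, 2.5e-3, 3.0e5),
            },
            ellipsometry_mass_before=2.5,
            ellipsometry_mass_after=2.12,
            lambda_before=12.0,
            lambda_after=4.0,
            n_contrasts_after=2,  # CAPB-treated pellicles: dPBS and hPBS only
        )
    if name == "sds":
        return ScenarioTruth(
            name, before_capb, None,
            qcmd_films={
                "baseline": _film(0.0, 2.0e-3, 1.0e5),
                "saliva": pellicle_film,
                "rinse1": pellicle_film,
                "surfactant": _film(1.0, 1.0e-3, 1.0e6),
                "rinse2": _film(0.0, 1.0e-3, 1.0e6),
            },
            ellipsometry_mass_before=2.5,
            ellipsometry_mass_after=0.0,
            lambda_before=12.0,
            lambda_after=None,
        )
    raise ValueError(f"unknown scenario {name!r}; expected c12e5, capb or sds")


# ---------------------------------------------------------------------------
# Neutron reflectivity


def default_q_grid(n: int = 120) -> np.ndarray:
    """Logarithmic q grid over the measured 0.01–0.3 Å^-1 range."""
    return np.logspace(np.log10(0.01), np.log10(0.3), n)


def gen_nr(
    truth: PellicleTwoLayerModel,
    contrasts: Sequence[ContrastDefinition] | None = None,
    q: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    dq_over_q: float = 0.04,
) -> list[ContrastMeasurement]:
    """Synthetic reflectivity curves of a pellicle model in several contrasts.

    Resolution-smeared model reflectivity plus a background floor, with
    multiplicative Gaussian counting noise (sigma = relative_sigma * R).  The
    quoted dr is the generating sigma.
    """
    if contrasts is None:
        contrasts = standard_contrasts()
    if q is None:
        q = default_q_grid()
    rng = np.random.default_rng(seed)
    out = []
    for contrast in contrasts:
        stack = stack_from_model(truth, contrast)
        r_clean = smeared_reflectivity(stack, q, dq_over_q) + noise.background
        sigma = noise.relative_sigma * r_clean
        r_noisy = r_clean * (1.0 + noise.relative_sigma * rng.standard_normal(q.size))
        r_noisy = np.clip(r_noisy, np.maximum(noise.background / 10.0, 1e-12), 1.0)
        dr = np.where(sigma > 0, sigma, np.maximum(1e-3 * r_clean, 1e-12))
        out.append(ContrastMeasurement(q, r_noisy, dr, contrast, dq_over_q,
                                       background=noise.background))
    return out


# ---------------------------------------------------------------------------
# QCM-D


def gen_qcmd(
    schedule: Sequence[tuple[str, float]] | None = None,
    truths: Mapping[str, ViscoelasticFilm] | None = None,
    kinetics_tau: float = 300.0,
    noise: NoiseSpec = NoiseSpec(),
    crystal: QuartzCrystal = QuartzCrystal(),
    bulk: BulkLiquid = BulkLiquid(),
    seed: int = 0,
    dt: float = 10.0,
    overtones: Sequence[int] = (3, 5, 7),
) -> QcmdTrace:
    """Synthetic overtone-resolved QCM-D trace for a stepwise flow protocol.

    Within each step the film parameters relax single-exponentially (time
    constant ``kinetics_tau``) from their value at the step start to the
    step's truth; signals follow the Voigt acoustic model plus Gaussian
    noise.  Step annotations are embedded in the trace.
    """
    if schedule is None:
        schedule = DEFAULT_SCHEDULE
    if truths is None:
        truths = scenario("capb").qcmd_films
    missing = [lab for lab, _ in schedule if lab not in truths]
    if missing:
        raise ValueError(f"no film truth for step(s) {missing}")
    rng = np.random.default_rng(seed)

    times, h, eta, mu, annotations = [], [], [], [], []
    t0 = 0.0
    state = np.array([0.0, truths[schedule[0][0]].viscosity,
                      truths[schedule[0][0]].shear_modulus])
    for label, duration in schedule:
        target = truths[label]
        goal = np.array([target.thickness, target.viscosity, target.shear_modulus])
        t_step = np.arange(0.0, duration, dt)
        decay = np.exp(-t_step / kinetics_tau)[:, None]
        vals = goal[None, :] + (state[None, :] - goal[None, :]) * decay
        times.append(t0 + t_step)
        h.append(vals[:, 0]); eta.append(vals[:, 1]); mu.append(vals[:, 2])
        annotations.append((label, t0))
        state = vals[-1]
        t0 += duration
    t = np.concatenate(times)
    h, eta, mu = np.concatenate(h), np.concatenate(eta), np.concatenate(mu)

    df, dd = {}, {}
    f0 = crystal.fundamental_frequency
    for n in overtones:
        z_l = _load_impedance(h, eta, mu, PELLICLE_DENSITY, bulk, crystal, n)
        z_ref = _load_impedance(0.0, eta, mu, PELLICLE_DENSITY, bulk, crystal, n)
        dfc = 1j * f0 / (np.pi * crystal.shear_impedance) * (z_l - z_ref)
        df[n] = np.real(dfc) + noise.trace_sigma_f * rng.standard_normal(t.size)
        dd[n] = (2e6 * np.imag(dfc) / (n * f0)
                 + noise.trace_sigma_d * rng.standard_normal(t.size))
    return QcmdTrace(t, df, dd, annotations)


# ---------------------------------------------------------------------------
# Force volume


def _truth_force(d: np.ndarray, lam: float | None, f0: float, b: float) -> np.ndarray:
    """Ground-truth tip–sample force law (nN): exponential steric tail for
    d > 0, Hertz indentation (continuously joined) for d <= 0.  ``lam=None``
    means no tail (bare/aggregate contact)."""
    tail = np.zeros_like(d) if lam is None else f0 * np.exp(-np.clip(d, 0, None) / lam)
    contact = (f0 if lam is not None else 0.0) + b * np.clip(-d, 0, None) ** 1.5
    return np.where(d > 0, tail, contact)


def gen_force_volume(
    lam: float | None,
    f0: float = 1.0,
    hertz_prefactor: float = 1.0,
    z0_jitter: float = 2.0,
    grid: tuple[int, int] = (64, 64),
    cantilever: Cantilever = Cantilever(),
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    aggregate_fraction: float = 0.0,
    n_samples: int = 800,
    z_range: float = 160.0,
    z0_base: float = 120.0,
) -> tuple[list[ForceRamp], ForceRamp, dict]:
    """Synthetic force-volume grid plus a rigid reference ramp.

    Each ramp's true force law is inverted through the cantilever force
    balance (k·x = F(d), d = z0 − piezo + x, solved by bisection — the purely
    repulsive law makes the equilibrium unique) to a (piezo, detector-signal)
    record with Gaussian detector noise and per-ramp contact-point jitter.
    A fraction of "aggregate" ramps (stiffer contact, no steric tail) can be
    mixed in.  Returns (ramps, reference_ramp, info) where info records which
    ramps are aggregates.
    """
    if f0 <= 0 or hertz_prefactor <= 0:
        raise ValueError("f0 and hertz_prefactor must be positive")
    if lam is not None and lam <= 0:
        raise ValueError("lam must be positive (or None for no tail)")
    rng = np.random.default_rng(seed)
    n_ramps = grid[0] * grid[1]
    piezo = np.linspace(0.0, z_range, n_samples)
    z0 = z0_base + z0_jitter * rng.standard_normal(n_ramps)
    is_aggregate = rng.random(n_ramps) < aggregate_fraction

    k = cantilever.spring_constant  # N/m == nN/nm
    # Bisection for deflection x >= 0 on g(x) = k x - F(z0 - p + x), monotone.
    x_lo = np.zeros((n_ramps, n_samples))
    x_hi = np.full((n_ramps, n_samples),
                   (f0 + hertz_prefactor * 10.0 * z_range**1.5) / k)
    z0c = z0[:, None]
    lam_r = np.where(is_aggregate, np.nan, np.nan if lam is None else lam)
    b_r = np.where(is_aggregate, 10.0 * hertz_prefactor, hertz_prefactor)

    def g(x):
        d = z0c - piezo[None, :] + x
        lamv = lam_r[:, None]
        tail = np.where(np.isnan(lamv), 0.0,
                        f0 * np.exp(-np.clip(d, 0, None) / np.where(np.isnan(lamv), 1.0, lamv)))
        pedestal = np.where(np.isnan(lamv), 0.0, f0)
        contact = pedestal + b_r[:, None] * np.clip(-d, 0, None) ** 1.5
        force = np.where(d > 0, tail, contact)
        return k * x - force

    for _ in range(60):
        mid = 0.5 * (x_lo + x_hi)
        gm = g(mid)
        x_hi = np.where(gm > 0, mid, x_hi)
        x_lo = np.where(gm > 0, x_lo, mid)
    x = 0.5 * (x_lo + x_hi)

    signal = (x / cantilever.deflection_sensitivity
              + noise.detector_sigma * rng.standard_normal(x.shape))
    ramps = [ForceRamp(piezo, signal[i]) for i in range(n_ramps)]

    x_ref = np.clip(piezo - z0_base, 0.0, None)
    ref_signal = (x_ref / cantilever.deflection_sensitivity
                  + 0.2 * noise.detector_sigma * rng.standard_normal(n_samples))
    reference = ForceRamp(piezo, ref_signal)
    info = {"z0": z0, "is_aggregate": is_aggregate}
    return ramps, reference, info


# ---------------------------------------------------------------------------
# Ellipsometry


def gen_ellipsometry(
    series: Sequence[tuple[float, float]],
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    mode: str = "nf-df",
    dt: float = 30.0,
    known: ell.OpticalSlabStack | None = None,
) -> pd.DataFrame:
    """Synthetic ellipsometry time series from a truth series of (n_f, d_f).

    ``mode="nf-df"`` emits instrument-processed columns (time_s, n_f, d_f_nm)
    with Gaussian noise; ``mode="psi-delta"`` emits raw (psi_deg, delta_deg)
    through the forward Fresnel model plus 0.01 deg angular noise.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(len(series)) * dt
    nf = np.array([s[0] for s in series], dtype=float)
    df = np.array([s[1] for s in series], dtype=float)
    if not np.all(np.isfinite(nf)) or not np.all(np.isfinite(df)):
        raise ValueError("truth series must be finite")
    if mode == "nf-df":
        return pd.DataFrame({
            "time_s": t,
            "n_f": nf + noise.nf_sigma * rng.standard_normal(t.size),
            "d_f_nm": df + noise.df_sigma * rng.standard_normal(t.size),
        })
    if mode == "psi-delta":
        known = known or ell.OpticalSlabStack()
        psi = np.empty(t.size)
        delta = np.empty(t.size)
        for i in range(t.size):
            stack = ell.OpticalSlabStack(known.ambient_index, (nf[i], df[i]),
                                         known.oxide, known.substrate_index)
            psi[i], delta[i] = ell.psi_delta(stack)
        psi += 0.01 * rng.standard_normal(t.size)
        delta += 0.01 * rng.standard_normal(t.size)
        return pd.DataFrame({"time_s": t, "psi_deg": psi, "delta_deg": delta})
    raise ValueError(f"unknown mode {mode!r}; expected 'nf-df' or 'psi-delta'")


def ellipsometry_truth_series(
    mass_mg_m2: float,
    d_f_nm: float = 30.0,
    n_points: int = 100,
    params: ell.DeFeijterParams = ell.DeFeijterParams(),
) -> list[tuple[float, float]]:
    """Constant (n_f, d_f) series carrying a prescribed dry areal mass."""
    n_f = params.n_o + mass_mg_m2 * params.dndc / d_f_nm if d_f_nm > 0 else params.n_o
    return [(n_f, d_f_nm)] * n_points
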