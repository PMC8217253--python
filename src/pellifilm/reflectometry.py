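"""Specular neutron reflectometry of the two-layer pellicle model.

A solid–liquid reflectometry experiment on an adsorbed film is modelled as a
stratified Si / SiO2 / inner layer / outer layer / solvent medium.  Each slab
carries a thickness, an SLD, a Gaussian interfacial roughness and a solvent
volume fraction; the pellicle slabs additionally resolve their dry content
into salivary material and surfactant.  Reflectivity is computed with the
Abelès (optical transfer-matrix) method with Névot–Croce roughness damping,
smeared with a Gaussian instrument resolution, and fitted by co-refining all
available solvent contrasts simultaneously.  Parameter uncertainties come
from an ensemble MCMC about the optimum.

Conventions
-----------
* SLDs are in 1e-6 Å^-2, thicknesses and roughnesses in Å, momentum transfer
  q in Å^-1.
* The neutron beam propagates through the silicon substrate (solid–liquid
  cell geometry): silicon is the semi-infinite incident medium and the
  solvent the semi-infinite backing.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import differential_evolution, least_squares

from .materials import ContrastDefinition

__all__ = [
    "Slab",
    "PellicleLayer",
    "PellicleTwoLayerModel",
    "ContrastMeasurement",
    "FitResult",
    "SI_SLD",
    "SIO2_SLD",
    "DEFAULT_SALIVARY_SLD",
    "layer_sld",
    "stack_from_model",
    "reflectivity",
    "smear",
    "smeared_reflectivity",
    "critical_edge",
    "corefine",
    "posterior_sample",
]

SI_SLD = 2.07
SIO2_SLD = 3.47
#: Dry SLD of hydrogenated salivary material (protein/glycoprotein mixture).
DEFAULT_SALIVARY_SLD = 2.0


@dataclass
class Slab:
    """One homogeneous slab: thickness (Å), SLD (1e-6 Å^-2), roughness of the
    interface to the preceding slab (Å) and solvent volume fraction."""

    thickness: float
    sld: float
    roughness: float = 0.0
    solvent_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError(f"slab thickness must be >= 0, got {self.thickness}")
        if self.roughness < 0:
            raise ValueError(f"roughness must be >= 0, got {self.roughness}")
        if not 0.0 <= self.solvent_fraction <= 1.0:
            raise ValueError(f"solvent_fraction must lie in [0, 1], got {self.solvent_fraction}")


@dataclass
class PellicleLayer:
    """One pellicle layer: thickness, hydration (solvent volume fraction) and
    the salivary/surfactant split of its dry content."""

    thickness: float
    hydration: float
    roughness: float = 5.0
    surfactant_fraction: float = 0.0
    salivary_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.salivary_fraction is None:
            self.salivary_fraction = 1.0 - self.surfactant_fraction
        if abs(self.salivary_fraction + self.surfactant_fraction - 1.0) > 1e-6:
            raise ValueError(
                "salivary_fraction + surfactant_fraction must equal 1, got "
                f"{self.salivary_fraction} + {self.surfactant_fraction}"
            )
        if not 0.0 <= self.hydration <= 1.0:
            raise ValueError(f"hydration must lie in [0, 1], got {self.hydration}")
        if self.thickness <= 0:
            raise ValueError(f"layer thickness must be > 0, got {self.thickness}")

    def set_surfactant_fraction(self, value: float) -> None:
        self.surfactant_fraction = float(value)
        self.salivary_fraction = 1.0 - float(value)


@dataclass
class PellicleTwoLayerModel:
    """Inner dense + outer diffuse pellicle layers on an oxidised Si block."""

    inner: PellicleLayer
    outer: PellicleLayer
    oxide: Slab = field(
        default_factory=lambda: Slab(thickness=12.0, sld=SIO2_SLD, roughness=3.0)
    )
    substrate_sld: float = SI_SLD
    salivary_sld: float = DEFAULT_SALIVARY_SLD
    surfactant_sld: float = 0.36
    solvent_roughness: float = 10.0

    def copy(self) -> "PellicleTwoLayerModel":
        return copy.deepcopy(self)


@dataclass
class ContrastMeasurement:
    """One reflectivity curve measured in one solvent contrast."""

    q: np.ndarray
    reflectivity: np.ndarray
    dr: np.ndarray
    contrast: ContrastDefinition
    dq_over_q: float = 0.04
    background: float = 0.0  # known incoherent background added to the model

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.reflectivity = np.asarray(self.reflectivity, dtype=float)
        self.dr = np.asarray(self.dr, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if self.q[0] < 0.005 or self.q[-1] > 0.5:
            raise ValueError("q grid must lie within [0.005, 0.5] Å^-1")
        if np.any(self.reflectivity <= 0) or np.any(self.reflectivity > 1 + 1e-9):
            raise ValueError("reflectivity must lie in (0, 1]")
        if np.any(self.dr <= 0):
            raise ValueError("dr must be positive")

    @property
    def n_points(self) -> int:
        return self.q.size


@dataclass
class FitResult:
    """Co-refinement outcome: best-fit model, misfit and credible intervals."""

    model: PellicleTwoLayerModel
    chi2: float
    n_points: int
    converged: bool
    message: str = ""
    parameter_intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    param_names: list[str] = field(default_factory=list)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)


def layer_sld(
    layer: PellicleLayer,
    solvent_sld: float,
    salivary_sld: float,
    surfactant_sld: float,
) -> float:
    """SLD of a hydrated pellicle layer.

    The layer is an incoherent volume mixture of solvent (fraction =
    hydration) and dry material, the latter split between salivary material
    and surfactant.
    """
    dry = layer.salivary_fraction * salivary_sld + layer.surfactant_fraction * surfactant_sld
    return layer.hydration * solvent_sld + (1.0 - layer.hydration) * dry


def stack_from_model(
    model: PellicleTwoLayerModel, contrast: ContrastDefinition
) -> list[Slab]:
    """Slab stack Si -> SiO2 -> inner -> outer -> solvent for one contrast.

    Thicknesses and roughnesses are contrast-invariant; only slab SLDs depend
    on the solvent.  The terminal solvent slab is semi-infinite (thickness 0
    by convention) with the outer/solvent roughness.
    """
    s = contrast.solvent_sld
    oxide_sld = (
        model.oxide.solvent_fraction * s + (1 - model.oxide.solvent_fraction) * model.oxide.sld
    )
    slabs = [
        Slab(0.0, model.substrate_sld),
        Slab(model.oxide.thickness, oxide_sld, model.oxide.roughness,
             model.oxide.solvent_fraction),
        Slab(model.inner.thickness,
             layer_sld(model.inner, s, model.salivary_sld, model.surfactant_sld),
             model.inner.roughness, model.inner.hydration),
        Slab(model.outer.thickness,
             layer_sld(model.outer, s, model.salivary_sld, model.surfactant_sld),
             model.outer.roughness, model.outer.hydration),
        Slab(0.0, s, model.solvent_roughness, 1.0),
    ]
    # Degenerate layers (zero thickness) are dropped, keeping the stack valid.
    return [slabs[0]] + [sl for sl in slabs[1:-1] if sl.thickness > 0] + [slabs[-1]]


def reflectivity(stack: Sequence[Slab], q: np.ndarray) -> np.ndarray:
    """Specular reflectivity of a slab stack by the Abelès matrix method.

    The first slab is the semi-infinite incident medium (silicon), the last
    the semi-infinite backing (solvent).  Gaussian interfacial roughness
    enters through Névot–Croce damping of each Fresnel coefficient.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    if len(stack) < 2:
        raise ValueError("stack needs at least one interface")
    sld = np.array([s.sld for s in stack]) * 1e-6  # Å^-2
    thick = np.array([s.thickness for s in stack])
    rough = np.array([s.roughness for s in stack])

    k0 = q[:, None] / 2.0
    # kz in each medium, relative to the incident medium.
    kz = np.sqrt((k0**2 - 4.0 * np.pi * (sld[None, :] - sld[0])).astype(complex))

    # Resultant 2x2 characteristic matrix, built interface by interface.
    m00 = np.ones_like(kz[:, 0])
    m01 = np.zeros_like(m00)
    m10 = np.zeros_like(m00)
    m11 = np.ones_like(m00)
    for j in range(len(stack) - 1):
        ki, kj = kz[:, j], kz[:, j + 1]
        r = (ki - kj) / (ki + kj) * np.exp(-2.0 * ki * kj * rough[j + 1] ** 2)
        beta = ki * thick[j] if j > 0 else np.zeros_like(ki)
        ep, em = np.exp(1j * beta), np.exp(-1j * beta)
        a00, a01 = ep, r * ep
        a10, a11 = r * em, em
        m00, m01, m10, m11 = (
            m00 * a00 + m01 * a10,
            m00 * a01 + m01 * a11,
            m10 * a00 + m11 * a10,
            m10 * a01 + m11 * a11,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        r_amp = m10 / m00
    refl = np.abs(r_amp) ** 2
    return np.minimum(refl.real, 1.0)


# Fixed quadrature for Gaussian resolution smearing: offsets in units of the
# per-point sigma, spanning ±3.5 sigma.
_SMEAR_X = np.linspace(-3.5, 3.5, 17)
_SMEAR_W = np.exp(-0.5 * _SMEAR_X**2)
_SMEAR_W = _SMEAR_W / _SMEAR_W.sum()
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.355


def smeared_reflectivity(
    stack: Sequence[Slab], q: np.ndarray, dq_over_q: float
) -> np.ndarray:
    """Model reflectivity convolved with a constant-dq/q Gaussian resolution.

    ``dq_over_q`` is the FWHM relative resolution; sigma = dq/q * q / 2.355.
    The model is re-evaluated on a quadrature grid around each q point, which
    is exact up to the quadrature order (no edge effects).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if dq_over_q < 0:
        raise ValueError("dq_over_q must be >= 0")
    if dq_over_q == 0:
        return reflectivity(stack, q)
    sigma = dq_over_q * q / _FWHM
    q_eval = q[:, None] + sigma[:, None] * _SMEAR_X[None, :]
    q_eval = np.maximum(q_eval, 1e-6)
    r = reflectivity(stack, q_eval.ravel()).reshape(q_eval.shape)
    return r @ _SMEAR_W


def smear(q: np.ndarray, r: np.ndarray, dq_over_q: float) -> np.ndarray:
    """Gaussian-smear a sampled reflectivity curve on its own grid.

    Convolution by quadrature with linear interpolation of the sampled curve
    (edge values clamped).  ``dq_over_q = 0`` returns the curve unchanged.
    Prefer :func:`smeared_reflectivity` when the model is available.
    """
    q = np.asarray(q, dtype=float)
    r = np.asarray(r, dtype=float)
    if dq_over_q < 0:
        raise ValueError("dq_over_q must be >= 0")
    if dq_over_q == 0:
        return r.copy()
    sigma = dq_over_q * q / _FWHM
    q_eval = q[:, None] + sigma[:, None] * _SMEAR_X[None, :]
    r_eval = np.interp(q_eval, q, r)
    return r_eval @ _SMEAR_W


def critical_edge(substrate_sld: float, solvent_sld: float) -> float:
    """Critical momentum transfer Qc = sqrt(16 pi dSLD) (Å^-1).

    Total reflection occurs below Qc when the backing SLD exceeds the
    incident-medium SLD; otherwise there is no edge and 0 is returned.
    SLD inputs are in 1e-6 Å^-2.
    """
    delta = (solvent_sld - substrate_sld) * 1e-6
    if delta <= 0:
        return 0.0
    return math.sqrt(16.0 * math.pi * delta)


# ---------------------------------------------------------------------------
# Co-refinement


_TRANSFORMS = {"thickness": "log", "roughness": "log", "hydration": "logit",
               "surfactant_fraction": "logit", "solvent_fraction": "logit",
               "solvent_roughness": "log", "sld": "linear"}


def _transform_kind(name: str) -> str:
    leaf = name.split(".")[-1]
    return _TRANSFORMS.get(leaf, "linear")


def _to_internal(value: float, kind: str) -> float:
    if kind == "log":
        return math.log(max(value, 1e-12))
    if kind == "logit":
        v = min(max(value, 1e-9), 1 - 1e-9)
        return math.log(v / (1 - v))
    return value


def _from_internal(x: float, kind: str) -> float:
    if kind == "log":
        return math.exp(x)
    if kind == "logit":
        return 1.0 / (1.0 + math.exp(-x))
    return x


def _get_param(model: PellicleTwoLayerModel, name: str) -> float:
    obj: object = model
    parts = name.split(".")
    for p in parts[:-1]:
        obj = getattr(obj, p)
    return float(getattr(obj, parts[-1]))


def _set_param(model: PellicleTwoLayerModel, name: str, value: float) -> None:
    obj: object = model
    parts = name.split(".")
    for p in parts[:-1]:
        obj = getattr(obj, p)
    if parts[-1] == "surfactant_fraction" and isinstance(obj, PellicleLayer):
        obj.set_surfactant_fraction(value)
    else:
        setattr(obj, parts[-1], float(value))


def _apply(model: PellicleTwoLayerModel, names: Sequence[str],
           x_internal: np.ndarray) -> PellicleTwoLayerModel:
    m = model.copy()
    for name, xi in zip(names, x_internal):
        _set_param(m, name, _from_internal(float(xi), _transform_kind(name)))
    return m


def _residuals(
    model: PellicleTwoLayerModel, measurements: Sequence[ContrastMeasurement]
) -> np.ndarray:
    res = []
    for meas in measurements:
        stack = stack_from_model(model, meas.contrast)
        r = smeared_reflectivity(stack, meas.q, meas.dq_over_q) + meas.background
        res.append((r - meas.reflectivity) / meas.dr)
    return np.concatenate(res)


def corefine(
    measurements: Sequence[ContrastMeasurement],
    model: PellicleTwoLayerModel,
    bounds: Mapping[str, tuple[float, float]],
    seed: int,
    maxiter: int = 200,
    popsize: int = 18,
) -> FitResult:
    """Co-refine a pellicle model against all contrasts simultaneously.

    All structural parameters are shared across contrasts; only solvent SLDs
    differ (held at their nominal values).  ``bounds`` maps dotted parameter
    paths (e.g. ``"outer.thickness"``, ``"inner.hydration"``) to (lo, hi);
    exactly those parameters are freed.  Optimisation is a seeded
    differential-evolution global search on transformed scales (log for
    lengths, logit for fractions) followed by a least-squares polish.
    """
    if not measurements:
        raise ValueError("at least one measurement is required")
    names = list(bounds)
    if not names:
        raise ValueError("no free parameters given")
    for name, (lo, hi) in bounds.items():
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"bounds for {name!r} must be finite with lo < hi")
    kinds = [_transform_kind(n) for n in names]
    internal_bounds = [
        (_to_internal(lo, k), _to_internal(hi, k))
        for (lo, hi), k in zip(bounds.values(), kinds)
    ]
    n_points = sum(m.n_points for m in measurements)

    def objective(x: np.ndarray) -> float:
        r = _residuals(_apply(model, names, x), measurements)
        return float(r @ r)

    de = differential_evolution(
        objective,
        internal_bounds,
        seed=seed,
        maxiter=maxiter,
        popsize=popsize,
        tol=1e-10,
        mutation=(0.5, 1.0),
        recombination=0.8,
        polish=False,
        init="sobol",
        updating="deferred",
    )
    x0 = np.clip(de.x, [b[0] for b in internal_bounds], [b[1] for b in internal_bounds])
    ls = least_squares(
        lambda x: _residuals(_apply(model, names, x), measurements),
        x0,
        bounds=([b[0] for b in internal_bounds], [b[1] for b in internal_bounds]),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
    )
    best_x = ls.x if 2.0 * ls.cost <= de.fun else x0
    chi2 = min(2.0 * ls.cost, de.fun) / n_points
    best = _apply(model, names, best_x)
    converged = bool(de.success or ls.success)
    return FitResult(
        model=best,
        chi2=chi2,
        n_points=n_points,
        converged=converged,
        message=de.message if not converged else "",
        param_names=names,
        bounds=dict(bounds),
    )


def posterior_sample(
    fit: FitResult,
    measurements: Sequence[ContrastMeasurement],
    seed: int,
    n_walkers: int = 32,
    n_steps: int = 400,
    burn: int | None = None,
) -> dict[str, tuple[float, float]]:
    """Ensemble-MCMC credible intervals about a converged co-refinement.

    Gaussian likelihood with the measurement uncertainties, uniform priors on
    the fit's bounds.  Returns (median, 1-sigma half-width) per parameter —
    half the 16th–84th percentile span — and stores them on ``fit``.
    A warning is attached if the mean acceptance fraction leaves [0.1, 0.9].
    """
    import emcee

    if not fit.converged:
        raise ValueError("posterior sampling requires a converged fit")
    names = fit.param_names
    lo = np.array([fit.bounds[n][0] for n in names])
    hi = np.array([fit.bounds[n][1] for n in names])
    center = np.array([_get_param(fit.model, n) for n in names])

    def log_prob(theta: np.ndarray) -> float:
        if np.any(theta < lo) or np.any(theta > hi):
            return -np.inf
        m = fit.model.copy()
        for n, v in zip(names, theta):
            _set_param(m, n, v)
        r = _residuals(m, measurements)
        return -0.5 * float(r @ r)

    rng = np.random.default_rng(seed)
    scale = 1e-3 * (hi - lo)
    p0 = np.clip(center + scale * rng.standard_normal((n_walkers, len(names))), lo, hi)
    sampler = emcee.EnsembleSampler(n_walkers, len(names), log_prob)
    state = np.random.mtrand.RandomState(seed)
    sampler.random_state = state.get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)
    if burn is None:
        burn = n_steps // 2
    chain = sampler.get_chain(discard=burn, flat=True)
    intervals: dict[str, tuple[float, float]] = {}
    for i, n in enumerate(names):
        med = float(np.median(chain[:, i]))
        q16, q84 = np.percentile(chain[:, i], [16, 84])
        intervals[n] = (med, float((q84 - q16) / 2.0))
    acc = float(np.mean(sampler.acceptance_fraction))
    if not 0.1 <= acc <= 0.9:
        fit.warnings.append(
            f"MCMC acceptance fraction {acc:.2f} outside [0.1, 0.9]; "
            "intervals may be unreliable"
        )
    fit.parameter_intervals = intervals
    return intervals
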