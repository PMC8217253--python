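"""AFM force-volume analysis of steric repulsion over pellicle films.

Each approach ramp of a force-volume grid is processed in four stages:

1. detector calibration — the deflection sensitivity (nm/V) is the inverse
   slope of the linear hard-contact region of a reference ramp on a rigid
   substrate;
2. contact-point determination — the contact region is fitted with the Hertz
   sphere–plane model F = B·δ^{3/2}, whose offset z0 anchors the distance
   origin;
3. conversion to force vs tip–sample distance using the cantilever spring
   constant, with d_ts = (z0 − piezo) + deflection (zero at contact,
   positive off-contact);
4. exponential steric fit F = F0·exp(−d_ts/λ) over the non-contact window
   d_ts > 5 nm, giving the characteristic decay length λ that measures the
   extension of the diffuse outer pellicle layer.

Accepted λ values are aggregated into a probability distribution per
condition; before/after treatment conditions are compared by the ratio of
median decay lengths with a bootstrap confidence interval.

Units: nm for lengths, V for detector readings, nN for forces; the spring
constant is given in N/m (numerically equal to nN/nm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import gaussian_kde

__all__ = [
    "ForceRamp",
    "Cantilever",
    "ForceCurve",
    "StericFit",
    "ForceVolumeResult",
    "deflection_sensitivity",
    "find_contact_hertz",
    "to_force_distance",
    "fit_steric",
    "analyze_volume",
    "condition_ratio",
]


@dataclass
class ForceRamp:
    """One approach ramp: piezo position (nm, increasing toward the sample)
    and raw detector signal (V)."""

    piezo_z: np.ndarray
    detector_signal: np.ndarray
    direction: str = "approach"

    def __post_init__(self) -> None:
        self.piezo_z = np.asarray(self.piezo_z, dtype=float)
        self.detector_signal = np.asarray(self.detector_signal, dtype=float)
        if self.direction != "approach":
            raise ValueError("only approach ramps are analysed")
        d = np.diff(self.piezo_z)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("piezo_z must be monotone")
        if self.piezo_z[0] > self.piezo_z[-1]:  # normalise to increasing
            self.piezo_z = self.piezo_z[::-1].copy()
            self.detector_signal = self.detector_signal[::-1].copy()


@dataclass(frozen=True)
class Cantilever:
    """Spring constant (N/m, an input — e.g. Sader-calibrated upstream) and
    deflection sensitivity (nm/V, from the reference-ramp calibration)."""

    spring_constant: float = 0.1
    deflection_sensitivity: float = 20.0

    def __post_init__(self) -> None:
        if self.spring_constant <= 0 or self.deflection_sensitivity <= 0:
            raise ValueError("cantilever constants must be positive")


@dataclass
class ForceCurve:
    """Force (nN) vs tip–sample distance (nm); d_ts = 0 at contact."""

    d_ts: np.ndarray
    force: np.ndarray

    def __post_init__(self) -> None:
        self.d_ts = np.asarray(self.d_ts, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if not np.all(np.isfinite(self.force)):
            raise ValueError("forces must be finite")


@dataclass
class StericFit:
    """Exponential decomposition F = f0·exp(−d_ts/λ) of the steric tail."""

    f0: float
    lambda_exp: float
    fit_window: tuple[float, float]
    rms_residual: float
    ok: bool = True
    reason: str = ""


@dataclass
class ForceVolumeResult:
    """Aggregated steric fits over a force-volume grid."""

    grid_shape: tuple[int, int]
    fits: list[StericFit]
    lambdas: np.ndarray
    hist_edges: np.ndarray
    hist_density: np.ndarray
    kde: object | None
    median_lambda: float
    iqr_lambda: tuple[float, float]
    n_excluded: int


def deflection_sensitivity(reference_ramp: ForceRamp, min_fraction: float = 0.2,
                           r2_threshold: float = 0.99) -> float:
    """Deflection sensitivity (nm/V) from a hard-contact reference ramp.

    The contact region is the trailing linear segment (detector signal vs
    piezo position) of at least ``min_fraction`` of the samples with the best
    R²; its inverse slope is the sensitivity.
    """
    z, v = reference_ramp.piezo_z, reference_ramp.detector_signal
    n = z.size
    min_len = max(int(min_fraction * n), 5)
    best = None
    for length in np.unique(np.linspace(min_len, int(0.6 * n), 9).astype(int)):
        zs, vs = z[-length:], v[-length:]
        slope, intercept = np.polyfit(zs, vs, 1)
        pred = slope * zs + intercept
        ss_res = float(np.sum((vs - pred) ** 2))
        ss_tot = float(np.sum((vs - vs.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        if best is None or r2 > best[0]:
            best = (r2, slope)
    r2, slope = best
    if r2 < r2_threshold or slope <= 0:
        raise ValueError(
            f"no linear hard-contact region found (best R² = {r2:.4f}); "
            "the reference ramp may never reach contact"
        )
    return 1.0 / slope


def _noise_floor(force: np.ndarray, baseline_fraction: float = 0.2) -> float:
    """Force noise level (nN) from the far-from-surface start of the ramp."""
    n = max(int(baseline_fraction * force.size), 5)
    return float(np.std(force[:n])) or 1e-6


def find_contact_hertz(
    piezo_z: np.ndarray,
    deflection_nm: np.ndarray,
    spring_constant: float,
    probe_radius: float | None = None,
    quality_threshold: float = 0.2,
):
    """Contact position z0 and Hertz prefactor B from a converted ramp.

    Fits F = B·δ^{3/2} (sphere–plane Hertz) with indentation
    δ = (piezo − z0) − deflection to the contact region, defined as samples
    with force above 5× the baseline noise floor; the window is re-selected
    once after the first z0 estimate.  The probe radius is not separated from
    the reduced modulus: B (nN/nm^1.5) is reported as-is.

    Returns ``(z0, B, quality)`` where quality is the relative RMS residual
    of the contact fit; a ramp whose contact force span is too small to
    locate raises ``ValueError`` (callers flag and exclude it).
    """
    z = np.asarray(piezo_z, dtype=float)
    defl = np.asarray(deflection_nm, dtype=float)
    force = spring_constant * defl
    sigma = _noise_floor(force)
    thresh = 5.0 * sigma
    above = force > thresh
    if above.sum() < 10 or force.max() < 10.0 * sigma:
        raise ValueError("no contact region: force never rises above the noise floor")

    z0_guess = z[np.argmax(above)]

    def make_residual(sel):
        zs, fs, ds = z[sel], force[sel], defl[sel]

        def residual(x):
            z0, log_b = x
            delta = (zs - z0) - ds
            model = np.exp(log_b) * np.clip(delta, 0.0, None) ** 1.5
            return model - fs

        return residual, fs

    sel = above
    x = np.array([z0_guess, 0.0])
    for _ in range(2):
        residual, fs = make_residual(sel)
        sol = least_squares(residual, x, xtol=1e-12, ftol=1e-12)
        x = sol.x
        sel = force > thresh  # window re-selection uses the force threshold only
    z0, b = float(x[0]), float(math.exp(x[1]))
    rms = float(np.sqrt(np.mean(residual(x) ** 2)))
    quality = rms / max(float(fs.max()), 1e-9)
    if quality > quality_threshold:
        raise ValueError(f"Hertz contact fit too poor (relative RMS {quality:.3f})")
    return z0, b, quality


def to_force_distance(ramp: ForceRamp, cantilever: Cantilever, z0: float) -> ForceCurve:
    """Convert a raw ramp to force vs tip–sample distance.

    deflection = signal·sensitivity, force = k·deflection and
    d_ts = (z0 − piezo) + deflection, so that d_ts stays ≈ 0 throughout hard
    contact (the deflection compensates the piezo travel) and is positive
    off-contact.
    """
    defl = ramp.detector_signal * cantilever.deflection_sensitivity
    force = cantilever.spring_constant * defl
    d_ts = (z0 - ramp.piezo_z) + defl
    return ForceCurve(d_ts, force)


def fit_steric(curve: ForceCurve, d_min: float = 5.0, min_samples: int = 20) -> StericFit:
    """Fit the exponential steric tail F = F0·exp(−d_ts/λ) for d_ts > d_min.

    Initialised by a log-linear regression on the clearly-positive part of
    the window, then polished by nonlinear least squares over the whole
    window.  Ramps whose window is dominated by non-positive forces, or whose
    fitted amplitude never exceeds the noise (no tail, e.g. a bare Hertz
    contact), are returned flagged ``ok=False``.
    """
    sel = curve.d_ts > d_min
    d, f = curve.d_ts[sel], curve.force[sel]
    order = np.argsort(d)
    d, f = d[order], f[order]
    sigma = _noise_floor(curve.force[np.argsort(-curve.d_ts)])
    window = (float(d_min), float(d.max()) if d.size else float(d_min))
    n_clearly_positive = int(np.sum(f > max(2.0 * sigma, 1e-9)))
    if d.size >= 5:
        # Upper window cutoff: where the (smoothed) force sinks into the noise.
        kernel = np.ones(5) / 5.0
        f_smooth = np.convolve(f, kernel, mode="same")
        significant = np.flatnonzero(f_smooth > sigma)
        if significant.size:
            d_max = d[significant[-1]]
            keep = d <= d_max
            d, f = d[keep], f[keep]
            window = (float(d_min), float(d_max))
    pos = f > max(2.0 * sigma, 1e-9)
    if d.size < min_samples or n_clearly_positive < min_samples // 2:
        return StericFit(0.0, np.nan, window, np.nan, ok=False,
                         reason="too few samples above the noise floor beyond d_min")
    if pos.mean() < 0.25:
        return StericFit(0.0, np.nan, window, np.nan, ok=False,
                         reason="non-positive forces dominate the fit window")
    slope, intercept = np.polyfit(d[pos], np.log(f[pos]), 1)
    if slope >= 0:
        slope = -1.0 / max(d[pos].max(), 1.0)
    lam0 = -1.0 / slope
    f00 = math.exp(intercept)

    def residual(x):
        log_f0, log_lam = x
        return np.exp(log_f0) * np.exp(-d / np.exp(log_lam)) - f

    sol = least_squares(residual, [math.log(max(f00, 1e-9)), math.log(lam0)],
                        xtol=1e-14, ftol=1e-14)
    f0, lam = math.exp(sol.x[0]), math.exp(sol.x[1])
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    amp_at_dmin = f0 * math.exp(-d_min / lam)
    if amp_at_dmin < 3.0 * sigma or not (0.1 < lam < 1e3):
        return StericFit(f0, lam, window, rms, ok=False,
                         reason="no resolvable exponential tail")
    return StericFit(f0, lam, window, rms, ok=True)


def analyze_volume(
    ramps: Sequence[ForceRamp],
    cantilever: Cantilever,
    probe_radius: float | None = None,
    d_min: float = 5.0,
    grid_shape: tuple[int, int] | None = None,
) -> ForceVolumeResult:
    """Run the full per-ramp pipeline over a force-volume grid.

    Each ramp passes through contact-point determination, force–distance
    conversion and the steric fit; ramps whose contact or tail fit fails are
    counted as exclusions.  Accepted decay lengths are summarised as a
    Freedman–Diaconis histogram (density-normalised), a Gaussian KDE, and a
    median with interquartile range.
    """
    if not ramps:
        raise ValueError("no ramps supplied")
    if grid_shape is None:
        side = int(round(math.sqrt(len(ramps))))
        grid_shape = (side, max(len(ramps) // max(side, 1), 1))
    fits: list[StericFit] = []
    for ramp in ramps:
        defl = ramp.detector_signal * cantilever.deflection_sensitivity
        try:
            z0, _, _ = find_contact_hertz(ramp.piezo_z, defl, cantilever.spring_constant,
                                          probe_radius)
            curve = to_force_distance(ramp, cantilever, z0)
            fits.append(fit_steric(curve, d_min=d_min))
        except ValueError as exc:
            fits.append(StericFit(0.0, np.nan, (d_min, d_min), np.nan,
                                  ok=False, reason=str(exc)))
    lambdas = np.array([f.lambda_exp for f in fits if f.ok])
    n_excluded = len(fits) - lambdas.size
    if lambdas.size == 0:
        raise ValueError("all ramps were flagged; no accepted steric fits")
    if lambdas.size > 1 and np.ptp(lambdas) > 0:
        q75, q25 = np.percentile(lambdas, [75, 25])
        bin_width = 2.0 * (q75 - q25) / lambdas.size ** (1.0 / 3.0)
        n_bins = max(int(np.ceil(np.ptp(lambdas) / bin_width)), 1) if bin_width > 0 else 10
        hist, edges = np.histogram(lambdas, bins=min(n_bins, 200), density=True)
        kde = gaussian_kde(lambdas) if lambdas.size > 5 else None
    else:  # point mass
        hist = np.array([1.0])
        edges = np.array([lambdas[0] - 0.5, lambdas[0] + 0.5])
        kde = None
    q25, q75 = (np.percentile(lambdas, [25, 75]) if lambdas.size > 1
                else (lambdas[0], lambdas[0]))
    return ForceVolumeResult(
        grid_shape=grid_shape,
        fits=fits,
        lambdas=lambdas,
        hist_edges=edges,
        hist_density=hist,
        kde=kde,
        median_lambda=float(np.median(lambdas)),
        iqr_lambda=(float(q25), float(q75)),
        n_excluded=n_excluded,
    )


def condition_ratio(
    before: ForceVolumeResult,
    after: ForceVolumeResult,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Fold change of the median decay length, before / after, with a seeded
    bootstrap 95% interval.  Antisymmetric by construction:
    ratio(A, B) · ratio(B, A) = 1."""
    ratio = before.median_lambda / after.median_lambda
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        b = rng.choice(before.lambdas, before.lambdas.size, replace=True)
        a = rng.choice(after.lambdas, after.lambdas.size, replace=True)
        boots[i] = np.median(b) / np.median(a)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(ratio), (float(lo), float(hi))
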