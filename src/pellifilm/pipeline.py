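"""Study orchestration: staged NR refinement, mass comparison, seeded demo.

`run_nr_study` reproduces the three-stage refinement strategy of a
solid–liquid pellicle experiment: the bare block is characterised first
(fixing the oxide), then the pellicle is co-refined across contrasts with no
surfactant allowed, and finally the treated pellicle is co-refined with the
surfactant content of each layer freed.  `run_mass_comparison` assembles the
wet (QCM-D) vs dry (ellipsometry) retention table.  `run_demo` generates
synthetic datasets for the three surfactant scenarios, runs every analysis,
and checks the recovered quantities against the generative truths.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import differential_evolution

from . import synthetic as syn
from .ellipsometry import DeFeijterParams, de_feijter_mass
from .forcevolume import Cantilever, analyze_volume, condition_ratio, deflection_sensitivity
from .materials import DPBS_SLD, HPBS_SLD, SMW_PBS_SLD, standard_contrasts
from .qcmd import QcmdTrace, fit_voigt, retention_ratio, segment_steps
from .reflectometry import (
    SIO2_SLD,
    ContrastMeasurement,
    FitResult,
    PellicleLayer,
    PellicleTwoLayerModel,
    Slab,
    corefine,
    posterior_sample,
    reflectivity,
    smeared_reflectivity,
)

__all__ = [
    "DEFAULT_PELLICLE_BOUNDS",
    "DEFAULT_TREATED_BOUNDS",
    "fit_oxide",
    "run_nr_study",
    "run_mass_comparison",
    "run_demo",
]

DEFAULT_PELLICLE_BOUNDS: dict[str, tuple[float, float]] = {
    "inner.thickness": (20.0, 80.0),
    "inner.hydration": (0.3, 0.9),
    "inner.roughness": (1.0, 20.0),
    "outer.thickness": (60.0, 600.0),
    "outer.hydration": (0.85, 0.999),
    "outer.roughness": (2.0, 40.0),
    "solvent_roughness": (2.0, 40.0),
}

DEFAULT_TREATED_BOUNDS: dict[str, tuple[float, float]] = {
    **DEFAULT_PELLICLE_BOUNDS,
    "inner.surfactant_fraction": (1e-4, 0.5),
    "outer.surfactant_fraction": (1e-4, 0.5),
}


def fit_oxide(
    measurements: Sequence[ContrastMeasurement],
    seed: int = 0,
    thickness_bounds: tuple[float, float] = (5.0, 40.0),
    roughness_bounds: tuple[float, float] = (1.0, 10.0),
    substrate_sld: float = 2.07,
    oxide_sld: float = SIO2_SLD,
) -> dict:
    """Characterise a bare block with a Si/SiO2/solvent model.

    Fits oxide thickness and the two interfacial roughnesses by a seeded
    global search co-refined over all contrasts.  Returns the oxide
    parameters to be held fixed in the pellicle stages.
    """

    def build(x):
        t, r1, r2 = x
        return t, r1, r2

    def objective(x):
        t, r1, r2 = build(x)
        total = 0.0
        for meas in measurements:
            stack = [
                Slab(0.0, substrate_sld),
                Slab(t, oxide_sld, r1),
                Slab(0.0, meas.contrast.solvent_sld, r2, 1.0),
            ]
            r = smeared_reflectivity(stack, meas.q, meas.dq_over_q) + meas.background
            total += float(np.sum(((r - meas.reflectivity) / meas.dr) ** 2))
        return total

    bounds = [thickness_bounds, roughness_bounds, roughness_bounds]
    result = differential_evolution(objective, bounds, seed=seed, maxiter=80,
                                    popsize=15, tol=1e-10, polish=True)
    t, r1, r2 = result.x
    n_points = sum(m.n_points for m in measurements)
    return {
        "thickness": float(t),
        "roughness": float(r1),
        "solvent_roughness": float(r2),
        "chi2": float(result.fun) / n_points,
        "converged": bool(result.success),
    }


def _layer_report(layer: PellicleLayer, intervals: Mapping, prefix: str) -> dict:
    def iv(key):
        return intervals.get(f"{prefix}.{key}")

    out = {
        "thickness_A": layer.thickness,
        "hydration_percent": 100.0 * layer.hydration,
        "salivary_content_percent": 100.0 * layer.salivary_fraction,
        "surfactant_content_percent": 100.0 * layer.surfactant_fraction,
    }
    for key, scale, label in [
        ("thickness", 1.0, "thickness_A"),
        ("hydration", 100.0, "hydration_percent"),
        ("surfactant_fraction", 100.0, "surfactant_content_percent"),
    ]:
        interval = iv(key)
        if interval is not None:
            out[label + "_err"] = scale * interval[1]
    return out


def run_nr_study(
    stages: Mapping[str, Sequence[ContrastMeasurement]],
    seed: int = 0,
    surfactant_sld: float = 0.36,
    salivary_sld: float = 2.0,
    maxiter: int = 150,
    mcmc_steps: int = 0,
    pellicle_bounds: Mapping[str, tuple[float, float]] | None = None,
    treated_bounds: Mapping[str, tuple[float, float]] | None = None,
) -> dict:
    """Three-stage NR refinement: bare block -> pellicle -> treated pellicle.

    ``stages`` maps stage names (``"bare"``, ``"pellicle"``, ``"treated"``;
    the first and last optional) to contrast measurement lists.  Earlier
    stages seed later ones: the bare fit fixes the oxide, the pellicle fit
    (surfactant held at zero) provides the starting structure for the treated
    fit (surfactant freed).  ``mcmc_steps > 0`` adds MCMC credible intervals.
    A non-converged stage is reported failed and later stages are skipped.
    """
    report: dict = {"stages": {}, "seed": seed}
    oxide = Slab(12.0, SIO2_SLD, 3.0)
    if "bare" in stages:
        bare = fit_oxide(stages["bare"], seed=seed)
        report["stages"]["bare"] = bare
        if not bare["converged"]:
            report["stages"]["bare"]["status"] = "failed"
            return report
        oxide = Slab(bare["thickness"], SIO2_SLD, bare["roughness"])

    if "pellicle" not in stages:
        return report

    start = PellicleTwoLayerModel(
        inner=PellicleLayer(40.0, 0.6, roughness=5.0),
        outer=PellicleLayer(250.0, 0.95, roughness=10.0),
        oxide=oxide,
        salivary_sld=salivary_sld,
        surfactant_sld=surfactant_sld,
    )
    fits: dict[str, FitResult] = {}
    for stage, bounds, free_surfactant in [
        ("pellicle", dict(pellicle_bounds or DEFAULT_PELLICLE_BOUNDS), False),
        ("treated", dict(treated_bounds or DEFAULT_TREATED_BOUNDS), True),
    ]:
        if stage not in stages:
            continue
        stage_seed = seed + (101 if stage == "pellicle" else 211)
        fit = corefine(stages[stage], start, bounds, seed=stage_seed, maxiter=maxiter)
        fits[stage] = fit
        if not fit.converged:
            report["stages"][stage] = {"status": "failed", "message": fit.message}
            return report
        intervals = {}
        if mcmc_steps > 0:
            intervals = posterior_sample(fit, stages[stage], seed=seed + 7,
                                         n_steps=mcmc_steps)
        report["stages"][stage] = {
            "status": "ok",
            "chi2": fit.chi2,
            "inner": _layer_report(fit.model.inner, intervals, "inner"),
            "outer": _layer_report(fit.model.outer, intervals, "outer"),
            "warnings": fit.warnings,
        }
        start = fit.model.copy()  # treated stage starts from the pellicle fit

    if "pellicle" in fits and "treated" in fits:
        report["outer_thickness_ratio"] = (
            fits["pellicle"].model.outer.thickness / fits["treated"].model.outer.thickness
        )
    return report


def run_mass_comparison(
    qcmd_results: Mapping[str, Sequence[tuple[float, float]]],
    ellipsometry_results: Mapping[str, Sequence[tuple[float, float]]],
) -> dict:
    """Wet vs dry retention table per surfactant.

    Each mapping gives, per surfactant, replicate (mass_before, mass_after)
    pairs.  Replicates are paired by order; a count mismatch between the two
    techniques is allowed (with a warning) since the techniques run on
    different samples.
    """
    table: dict = {"surfactants": {}, "warnings": []}
    for surfactant in sorted(set(qcmd_results) | set(ellipsometry_results)):
        wet = [retention_ratio(b, a) for b, a in qcmd_results.get(surfactant, [])]
        dry = [retention_ratio(b, a) for b, a in ellipsometry_results.get(surfactant, [])]
        if wet and dry and len(wet) != len(dry):
            table["warnings"].append(
                f"{surfactant}: {len(wet)} QCM-D vs {len(dry)} ellipsometry replicates; "
                "paired by order"
            )
        entry = {}
        if wet:
            entry["wet_retention_mean"] = float(np.mean(wet))
            entry["wet_retention_sd"] = float(np.std(wet, ddof=1)) if len(wet) > 1 else 0.0
        if dry:
            entry["dry_retention_mean"] = float(np.mean(dry))
            entry["dry_retention_sd"] = float(np.std(dry, ddof=1)) if len(dry) > 1 else 0.0
        table["surfactants"][surfactant] = entry
    return table


# ---------------------------------------------------------------------------
# End-to-end demo

_PROFILES = {
    "full": dict(fv_grid=(64, 64), nr_q=110, nr_maxiter=150, qcmd_fits=25),
    "reduced": dict(fv_grid=(16, 16), nr_q=80, nr_maxiter=80, qcmd_fits=8),
}


def _check(checks: list, name: str, value: float, target: float, tol: float) -> None:
    checks.append({
        "name": name,
        "value": float(value),
        "target": float(target),
        "tolerance": float(tol),
        "passed": bool(abs(value - target) <= tol),
    })


def _qcmd_plateau_mass(trace: QcmdTrace, step: str, seed: int, max_fits: int) -> float:
    seg = segment_steps(trace)[step]
    _, _, masses, _ = fit_voigt(trace, window=seg["plateau"], seed=seed,
                                max_fits=max_fits)
    return float(np.nanmean(masses))


def run_demo(seed: int = 1, profile: str = "full") -> dict:
    """Generate, analyse and verify all three surfactant scenarios.

    Runs the four technique pipelines on seeded synthetic data and checks the
    recovered quantities against the generative truths (contrast arithmetic,
    QCM-D/ellipsometry retentions, steric-length fold changes, NR outer-layer
    collapse).  Returns a JSON-serialisable report whose ``passed`` field is
    False if any check breached its tolerance.  ``profile="reduced"`` shrinks
    grid and iteration sizes for a faster run of the same pipeline.
    """
    if profile not in _PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected {sorted(_PROFILES)}")
    p = _PROFILES[profile]
    checks: list[dict] = []
    report: dict = {"seed": seed, "profile": profile, "checks": checks}

    # --- contrast arithmetic (printed solvent SLDs) ---
    _check(checks, "sld_hPBS", HPBS_SLD, -0.56, 0.005)
    _check(checks, "sld_dPBS", DPBS_SLD, 6.36, 0.005)
    _check(checks, "sld_smwPBS", SMW_PBS_SLD, 2.07, 0.005)

    scenarios = {name: syn.scenario(name) for name in ("c12e5", "capb", "sds")}

    # --- QCM-D wet masses and retentions ---
    wet_results: dict[str, list[tuple[float, float]]] = {}
    wet_retentions: dict[str, float] = {}
    for i, (name, sc) in enumerate(scenarios.items()):
        trace = syn.gen_qcmd(truths=sc.qcmd_films, seed=seed + 10 + i)
        before = _qcmd_plateau_mass(trace, "rinse1", seed + 20 + i, p["qcmd_fits"])
        after = _qcmd_plateau_mass(trace, "rinse2", seed + 30 + i, p["qcmd_fits"])
        wet_results[name] = [(before, after)]
        wet_retentions[name] = retention_ratio(before, after)
        truth_ret = (sc.qcmd_films["rinse2"].areal_mass
                     / sc.qcmd_films["rinse1"].areal_mass)
        _check(checks, f"qcmd_retention_{name}", wet_retentions[name], truth_ret, 0.05)
    checks.append({
        "name": "qcmd_capb_removes_more_than_c12e5",
        "value": wet_retentions["capb"],
        "target": wet_retentions["c12e5"],
        "tolerance": 0.0,
        "passed": bool(wet_retentions["capb"] < wet_retentions["c12e5"]),
    })

    # --- ellipsometry dry masses ---
    dry_results: dict[str, list[tuple[float, float]]] = {}
    params = DeFeijterParams()
    for i, (name, sc) in enumerate(scenarios.items()):
        masses = []
        for mass in (sc.ellipsometry_mass_before, sc.ellipsometry_mass_after):
            series = syn.ellipsometry_truth_series(mass)
            frame = syn.gen_ellipsometry(series, seed=seed + 40 + i)
            gammas = [de_feijter_mass(nf, df, params)
                      for nf, df in zip(frame["n_f"], frame["d_f_nm"])]
            masses.append(float(np.mean(gammas)))
        dry_results[name] = [(masses[0], masses[1])]
        truth_ret = sc.ellipsometry_mass_after / sc.ellipsometry_mass_before
        _check(checks, f"ellipsometry_retention_{name}",
               retention_ratio(masses[0], masses[1]), truth_ret, 0.02)

    report["mass_comparison"] = run_mass_comparison(wet_results, dry_results)
    capb = report["mass_comparison"]["surfactants"]["capb"]
    checks.append({
        "name": "capb_wet_removal_exceeds_dry_removal",
        "value": capb["wet_retention_mean"],
        "target": capb["dry_retention_mean"],
        "tolerance": 0.0,
        "passed": bool(capb["wet_retention_mean"] < capb["dry_retention_mean"]),
    })

    # --- force volume: steric decay-length fold changes ---
    report["force_volume"] = {}
    for i, name in enumerate(("capb", "c12e5")):
        sc = scenarios[name]
        results = []
        for j, lam in enumerate((sc.lambda_before, sc.lambda_after)):
            ramps, ref, _ = syn.gen_force_volume(
                lam, f0=sc.f0, hertz_prefactor=sc.hertz_prefactor,
                grid=p["fv_grid"], seed=seed + 50 + 10 * i + j)
            cant = Cantilever(0.1, deflection_sensitivity(ref))
            results.append(analyze_volume(ramps, cant))
        fold, ci = condition_ratio(results[0], results[1], seed=seed + 60 + i)
        report["force_volume"][name] = {
            "median_lambda_before_nm": results[0].median_lambda,
            "median_lambda_after_nm": results[1].median_lambda,
            "fold_change": fold,
            "fold_change_ci95": ci,
            "excluded": [results[0].n_excluded, results[1].n_excluded],
        }
        if name == "capb":
            _check(checks, "fv_capb_fold_change", fold, 3.0, 0.45)
        else:
            checks.append({
                "name": "fv_c12e5_fold_ci_contains_1",
                "value": fold,
                "target": 1.0,
                "tolerance": 0.0,
                "passed": bool(ci[0] <= 1.0 <= ci[1]),
            })

    # --- neutron reflectivity: outer-layer collapse ---
    report["nr"] = {}
    q = syn.default_q_grid(p["nr_q"])
    contrasts3 = standard_contrasts()
    for i, name in enumerate(("capb",) if profile == "reduced" else ("capb", "c12e5")):
        sc = scenarios[name]
        contrasts_after = (contrasts3 if sc.n_contrasts_after == 3
                           else [contrasts3[0], contrasts3[2]])
        meas = {
            "pellicle": syn.gen_nr(sc.pellicle_before, contrasts3, q,
                                   seed=seed + 70 + 2 * i),
            "treated": syn.gen_nr(sc.pellicle_after, contrasts_after, q,
                                  seed=seed + 71 + 2 * i),
        }
        study = run_nr_study(meas, seed=seed + 80 + i,
                             surfactant_sld=sc.pellicle_before.surfactant_sld,
                             maxiter=p["nr_maxiter"])
        report["nr"][name] = study
        truth_ratio = (sc.pellicle_before.outer.thickness
                       / sc.pellicle_after.outer.thickness)
        if "outer_thickness_ratio" in study:
            _check(checks, f"nr_outer_ratio_{name}", study["outer_thickness_ratio"],
                   truth_ratio, 0.15 * truth_ratio)
        else:
            checks.append({"name": f"nr_outer_ratio_{name}", "value": float("nan"),
                           "target": truth_ratio, "tolerance": 0.15 * truth_ratio,
                           "passed": False})

    report["passed"] = all(c["passed"] for c in checks)
    report["failed_checks"] = [c["name"] for c in checks if not c["passed"]]
    return report
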