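# Methods

This note documents the physical models, numerical choices and synthetic
study conditions behind `pellifilm`, and what passing its tests does and
does not demonstrate.

## Neutron reflectometry

**Model.** The solid–liquid interface is a stratified
Si / SiO₂ / inner pellicle layer / outer pellicle layer / solvent medium.
Each slab carries thickness (Å), SLD (10⁻⁶ Å⁻²), a Gaussian roughness for
the interface to the preceding slab, and a solvent volume fraction. The
pellicle layers resolve their dry content into salivary material and
surfactant; the layer SLD is the incoherent volume mixture
`h·sld_solvent + (1−h)·(f_sal·sld_sal + f_surf·sld_surf)`. Reflectivity is
computed by the Abelès 2×2 characteristic-matrix recursion with Névot–Croce
damping `exp(−2 k_j k_{j+1} σ²)` per interface — standard and accurate while
roughness stays well below the adjacent thicknesses, which holds here
(σ ≤ ~10 Å against ≥ 35 Å layers). The neutron beam propagates through the
silicon substrate (solid–liquid cell geometry), so silicon is the
semi-infinite incident medium; total reflection appears below
Qc = √(16π ΔSLD) only when the solvent SLD exceeds silicon's.

**Resolution.** Constant relative resolution dq/q = 4% FWHM (typical of
time-of-flight instruments), applied as Gaussian quadrature re-evaluation of
the model on a 17-point ±3.5σ stencil per data point; configurable per
measurement. A known constant incoherent background may be attached to a
measurement and is added to the model rather than fitted.

**Solvent contrasts.** Buffer SLDs are computed from formula + density with
a bundled bound-coherent-scattering-length table (H −3.739 fm, D 6.671 fm,
O 5.803 fm, …): H₂O at 0.997 g/cm³ gives −0.56, D₂O at 1.105 g/cm³ gives
6.36, and the 0.38:0.62 D₂O:H₂O mixture 2.07 (all ×10⁻⁶ Å⁻²). PBS salts
(~150 mM) shift the SLD by well under the 0.01 tolerance used for contrast
validation and are neglected. The dry SLD of salivary material is not an
experimentally pinned quantity; the default 2.0×10⁻⁶ Å⁻² is typical of
hydrogenated protein/glycoprotein mixtures and is configurable. Labile-H
exchange with the solvent is off by default; because hydrations are high
(55–98%) and the salivary SLD is user-configurable, exchange mainly rescales
that one constant.

**Fitting.** Co-refinement shares all structural parameters across contrasts
and minimises Σ((R_model − R)/dR)². Parameters are optimised on transformed
scales (log for lengths, logit for fractions) by seeded differential
evolution (Sobol initialisation, deferred updating) followed by a
trust-region least-squares polish; this makes fits reproducible and start
insensitive. Pre-treatment fits hold surfactant content at zero; treated
fits free the per-layer surfactant fraction, starting from the pre-treatment
structure. The oxide is characterised first on bare-block data
(Si/SiO₂/solvent, thickness + two roughnesses) and then held fixed, and the
per-contrast solvent SLD is pinned at its nominal value. Uncertainties come
from an affine-invariant ensemble MCMC (emcee) around the optimum with
uniform priors on the fit bounds; intervals are medians ± half the 16–84th
percentile span, with a warning when the mean acceptance fraction leaves
[0.1, 0.9].

## QCM-D

The film is a single Voigt element of complex shear modulus G = μ + iωη and
fixed density 1080 kg/m³, between the resonator and a semi-infinite
Newtonian bulk (water at 25 °C: ρ = 1000 kg/m³, η = 0.89 mPa·s; the
measurement temperature is not modelled). The acoustic load impedance of the
film-on-liquid is the transmission-line solution
`Z_in = Z_f (Z_bulk + iZ_f tan kh)/(Z_f + iZ_bulk tan kh)` and the complex
frequency shift follows the small-load approximation relative to the
bare-liquid-loaded crystal, so a zero-thickness film gives exactly (0, 0).
η and μ are frequency independent (the simplest Voigt variant). Fits solve
(h, η, μ) in log space against all overtones' (Δf, ΔD) simultaneously with
five seeded multi-starts at the first point of each window (escaping the
known η/μ degeneracy; ties break toward thinner films) and warm starts
after; windows are decimated to at most 500 fits. A film is only accepted
where it improves on the no-film model by Δχ² > 6 — otherwise the
bulk-mimicking degeneracy (η → bulk, μ → 0, arbitrary h) would assign
spurious mass to pure-noise baselines. On disk, frequency columns are
overtone-normalised (Δf/n) as instrument exports are; internal shifts are
raw. Retention is defined as mass_after / mass_before (fraction remaining).

## Ellipsometry

Forward model: characteristic-matrix Fresnel solution for
ambient / film / SiO₂ / Si at 442.9 nm; ρ = r_p/r_s, Ψ = atan|ρ|,
Δ = arg ρ. Default angle of incidence 68° and substrate constants
(Si ñ = 4.62 − 0.14i, SiO₂ n = 1.466) are configurable — downstream mass is
insensitive to them once the inversion is self-consistent. Inversion of one
(Ψ, Δ) reading minimises |ρ_model − ρ_meas|² on a coarse (n_f, d_f) grid
plus Nelder–Mead polish; readings are flagged "ambiguous" above a residual
threshold (thickness-period ambiguity) and "index-unconstrained" along the
invisible-film degeneracy (d_f ≈ 0 or n_f ≈ n_o), where the de Feijter mass
is nevertheless well defined (≈ 0). The adsorbed amount uses
Γ[mg/m²] = (n_f − n_o)·d_f[nm]/(dn/dc)[ml/g] with dn/dc = 0.18 ml/g, and
depends only on the product (n_f − n_o)·d_f.

## Force volume

Pipeline per approach ramp: (1) deflection sensitivity = inverse slope of
the best-R² trailing linear segment (≥ 20% of samples, R² ≥ 0.99) of a
rigid-reference ramp; (2) Hertz sphere–plane fit F = B·(δ)^{3/2} with
δ = (piezo − z0) − deflection over the contact region (force above 5× the
baseline noise floor, window re-selected once), giving the contact point z0
— the probe radius is not separated from the reduced modulus, B is reported
as-is; (3) force = k·deflection and d_ts = (z0 − piezo) + deflection, which
keeps d_ts ≈ 0 throughout hard contact; (4) exponential fit
F = F₀·exp(−d_ts/λ) over d_ts > 5 nm, log-linear initialisation plus
nonlinear polish, with an upper window cutoff where the smoothed force
sinks below 1× the noise floor. Ramps with no resolvable contact or tail
are flagged and excluded (counted, never silently dropped) — this is how
the stiff, tail-less "aggregate" patches appearing after amphoteric
treatment are handled. The exponential steric pedestal biases z0 by
~(F₀/B)^{2/3} (≈ 1 nm at defaults); this shifts only the fitted amplitude,
not λ, because a distance offset factors out of an exponential.
Distributions use Freedman–Diaconis histograms plus a Gaussian KDE; the
central value is the median, condition comparisons use the ratio of medians
with a seeded 1000-resample bootstrap 95% interval.

## Synthetic study conditions

Generators are pure functions of (truth, noise spec, seed) — identical
calls are bit-identical. Defaults encode the study conditions:

* **NR** — q ∈ [0.01, 0.3] Å⁻¹ (120 log-spaced points), 2% relative
  counting noise, 10⁻⁷ background, dq/q 4%. Truth models are the published
  two-layer fits: pre-treatment inner 46 Å at 55.7–62.0% hydration, outer
  286–325 Å at 97.1–97.5%; amphoteric-treated outer collapses to 117 Å with
  8% surfactant in the dry outer content (two contrasts only, as measured);
  nonionic-treated outer is essentially unchanged (277 Å) with inner
  hydration up ~8 points.
* **QCM-D** — baseline/saliva/rinse/surfactant/rinse protocol,
  single-exponential kinetics per step (τ = 300 s; adsorption is not
  modelled mechanistically), noise 0.2 Hz / 0.1×10⁻⁶. Wet-mass plateaus:
  pellicle 15 mg/m²; 13 after the nonionic (retention 0.87), 8 after the
  amphoteric (0.53, a ~7 mg/m² removal), 0 after SDS. The reported
  representative Δmass and the replicate-averaged retentions are not
  mutually consistent for a single before-mass; the defaults honour the
  retentions and the amphoteric Δ ≈ 7 mg/m², making the nonionic removal
  ~2 mg/m².
* **Force volume** — 64×64 grids, ramp length 160 nm at 800 samples,
  contact at 120 nm with 2 nm per-ramp jitter (surface tilt/roughness over
  the 2×2 µm scan), F₀ = 1 nN, B = 1 nN/nm^{3/2}, detector noise 0.05 nm
  equivalent (0.0025 V at 20 nm/V); λ = 12 nm before treatment, 4 nm after
  the amphoteric, unchanged after the nonionic; optional ~5% stiff
  aggregate ramps.
* **Ellipsometry** — (n_f, d_f) series with σ(n_f) = 10⁻³,
  σ(d_f) = 0.2 nm; dry masses 2.5 → 2.25 / 2.12 / 0 mg/m².

What the generators deliberately omit: instrument drift and crosstalk,
mechanistic adsorption kinetics, multi-layer viscoelasticity, off-specular
scattering, retract-curve adhesion, and inter-pellicle variability (real
replicate pellicles differ enough that they cannot be co-refined jointly).
Passing recovery tests therefore demonstrates that the *analysis pipelines*
are correct and well-conditioned at realistic noise, not that the
instruments' systematic errors are under control.

## Problem sizes and verification

The test suite checks closed forms (Fresnel, critical edge, Sauerbrey,
de Feijter), cross-implementation identities (Abelès vs an independently
coded Parratt recursion to 10⁻⁸), round trips (ellipsometric inversion,
force-curve reconstruction) and full-pipeline parameter recovery. The
acceptance script re-runs the two headline recoveries at full scale: two
64×64 force-volume grids (λ 12 → 4 nm; fold-change target 3) and two NR
co-refinements of the amphoteric-scenario truths (outer thickness ratio
target 325/117 ≈ 2.78). The seeded demo (`pellifilm demo`) runs the whole
study; its `reduced` profile runs the identical pipeline at 16×16 grids and
smaller optimiser budgets, which is the configuration exercised inside the
test suite. Co-refinements use differential evolution with popsize 18 and
up to 150 generations (80 in the reduced profile); each NR fit takes about
one to two minutes on one CPU.

## Known limitations

* The NR likelihood assumes independent Gaussian errors with the quoted dR;
  correlated systematics (misalignment, normalisation) are not modelled.
* The Voigt fit's η/μ degeneracy is mitigated, not eliminated; at low
  dissipation only the areal mass is robust.
* The ellipsometric inversion is single-wavelength and can alias thick
  films (period ambiguity); such readings are flagged, not resolved.
* Hertz contact-point determination assumes the indentation response
  dominates over the steric pedestal at the fitted forces; extremely soft
  films would need a layered contact model.
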