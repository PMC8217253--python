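# pellifilm

Analysis toolkit for the structure of **reconstituted salivary pellicles** —
the thin, mostly proteinaceous films that adsorb from saliva onto
solid–liquid interfaces — and for how surfactants (the amphoteric CAPB, the
nonionic C₁₂E₅, the anionic SDS) modify them. It is aimed at biointerface
labs combining four surface techniques on the same films:

1. **Specular neutron reflectometry (NR)** — slab-model forward computation
   (Abelès transfer matrix, Névot–Croce roughness, Gaussian dq/q smearing)
   for a Si/SiO₂/inner-layer/outer-layer/solvent stack, with isotopic
   contrast co-refinement and ensemble-MCMC credible intervals. The pellicle
   is modelled as a dense inner layer plus a diffuse, highly hydrated outer
   layer; each layer's SLD is the volume-fraction mixture
   `sld = h·sld_solvent + (1−h)·(f_sal·sld_sal + f_surf·sld_surf)`.
2. **QCM-D** — single-layer Voigt (Voinova-type) viscoelastic film under
   Newtonian liquid loading via the small-load approximation
   `Δf* = (i f₀/π Z_q)·ΔZ_L`, fitted across overtones 3/5/7 to give the
   "wet" areal mass ρ·h (pellicle density fixed at 1.08 g/cm³).
3. **Ellipsometry** — multilayer Fresnel forward model, (Ψ, Δ) → (n_f, d_f)
   inversion, and the de Feijter "dry" mass Γ = (n_f − n_o)·d_f/(dn/dc)
   with dn/dc = 0.18 ml/g.
4. **AFM force volume** — deflection calibration, Hertz sphere–plane
   contact-point determination (F = B·δ^{3/2}), conversion to force vs
   tip–sample distance, and exponential steric fits
   F = F₀·exp(−d_ts/λ_exp) over d_ts > 5 nm, aggregated into decay-length
   distributions and before/after fold changes.

Because raw instrument data for such studies are rarely public, every
technique is paired with a seeded synthetic-data generator
(`pellifilm.synthetic`) so each pipeline is verifiable end to end by
parameter recovery.

## Worked example

Recover the steric decay length of a pellicle and its collapse after
exposure to an amphoteric surfactant from a synthetic 16×16 force-volume
grid:

```python
from pellifilm import synthetic as syn
from pellifilm.forcevolume import (Cantilever, analyze_volume,
                                   condition_ratio, deflection_sensitivity)

results = []
for lam, seed in [(12.0, 1), (4.0, 2)]:          # nm, before/after truth
    ramps, ref, _ = syn.gen_force_volume(lam, grid=(16, 16), seed=seed)
    cant = Cantilever(0.1, deflection_sensitivity(ref))
    results.append(analyze_volume(ramps, cant))

fold, ci = condition_ratio(results[0], results[1], seed=3)
print(f"median lambda before: {results[0].median_lambda:.2f} nm")
print(f"median lambda after:  {results[1].median_lambda:.2f} nm")
print(f"fold change: {fold:.2f}  (95% CI {ci[0]:.2f}-{ci[1]:.2f})")
```

Output:

```
median lambda before: 12.00 nm
median lambda after:  4.01 nm
fold change: 2.99  (95% CI 2.98-3.01)
```

The ~3-fold contraction of λ_exp mirrors the collapse of the diffuse mucin
outer layer that the NR co-refinement resolves independently (outer-layer
thickness 325 Å → 117 Å).

The same workflow is available from the shell:

```bash
pellifilm simulate --scenario capb --seed 1 --out capb/
pellifilm fv-analyze --data capb/fv_before --k 0.1 --out lambdas.json
pellifilm demo --seed 1            # full synthetic study, non-zero exit on breach
```

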