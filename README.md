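# coordflux

Tools for asking how a bacterium coordinates its catabolism with its
anabolism: given steady-state cultures in which either carbon uptake
(catabolic limitation) or glutamate synthesis (anabolic limitation) is
genetically titrated, the package estimates physiology from culture time
courses, infers genome-scale-style flux distributions from exchange rates
and ¹³C flux ratios, and decomposes each reaction's flux changes into the
part explained by protein concentration and the part explained by enzyme
saturation. A synthetic multi-omics generator with exact ground truth
stands in for experimental data, so every stage is testable end to end.

It is a library first — `import coordflux` — with a thin `coordflux` CLI
for shell use and narrative scripts under `examples/`.

## The quantities at the core

**Physiology.** Growth rate μ is the OLS slope of ln OD vs time. Specific
exchange rates come from C(t) = C₀ + (q/μ)·(X(t) − X₀) with biomass
X = OD·0.413 g CDW/l, so q = μ · slope(C on X) in mmol·gCDW⁻¹·h⁻¹
(secretion > 0). Exchanges are classed major / minor / trace, the trace
threshold being 10 µmol·gCDW⁻¹·h⁻¹.

**Flux inference.** With S the stoichiometric matrix, solve

1. max v_ATPM  s.t. S·v = 0, measured bands (±5% major/growth/O₂, ±10%
   minor), flux-ratio equalities (1−r)·v_a − r·v_b = 0;
2. min Σ|v|  s.t. the same constraints and v_ATPM ≥ optimum,

and report per-reaction uncertainty by flux variability analysis at
99.99% optimality.

**Regulation analysis.** Fluxes, proteins and substrates are normalized to
the wild-type reference and log-transformed. Per limitation, the protein
regulation coefficient ρ_P is the slope of log P on log J. Kinetic orders
α are fitted jointly on all conditions by bounded least squares,

    min_{0≤α≤4} Σ_i ( log J_i − log P_i − Σ_x α_x log M_{x,i} )²,

independently per flux–enzyme pair, excluding highly connected reactants
(H₂O, H⁺, CO₂, HCO₃⁻, sulfate, phosphate, ammonia); ρ_S is the slope of
the saturation term Σ α·log M on log J. Whenever log P + Σα log M = log J
holds per condition, ρ_P + ρ_S = 1 exactly. Coefficients in [0.5, 1.5]
count as consistent flux–protein changes; isoenzymes are averaged.

**Metabolome.** Ions are annotated by accurate mass as [M−H]⁻ within
0.001 Da, normalized to the wild type as log₂ fold changes, filtered at
CV < 30% across conditions, and clustered by seeded k-means++ (filtered
ions form the extra final cluster). Amounts convert to intracellular mM
via 0.413 mg CDW·ml⁻¹·OD⁻¹ and 2.7 µl cell volume per mg CDW.

## Worked example

```python
from coordflux import ScenarioConfig, analyze_regulation, simulate_condition_series

cfg = ScenarioConfig(seed=7)
cfg.noise = cfg.noise.zeroed()
ds = simulate_condition_series(cfg)
gt = ds.ground_truth
reg, excluded = analyze_regulation(
    ds.model, gt.fluxes, gt.proteins, gt.metabolites,
    {c.id: c.limitation for c in ds.conditions}, "ref",
)
print(reg[["reaction", "limitation", "rho_P", "rho_S", "combined"]].head(4))
```

prints

```
  reaction limitation  rho_P  rho_S  combined
0      UPT   anabolic   2.20  -1.20       1.0
1      UPT  catabolic   1.05  -0.05       1.0
2      EMP   anabolic   1.90  -0.90       1.0
3      EMP  catabolic   0.95   0.05       1.0
```

Read: under catabolic limitation the uptake and glycolysis proteins track
their fluxes (ρ_P ≈ 1 — hierarchical regulation), while under anabolic
limitation protein changes overshoot the flux changes (ρ_P ≈ 2) and
enzyme saturation compensates (ρ_S < 0); in every case the two layers sum
to 1 on noise-free data. `excluded` lists reactions dropped with reason
codes (e.g. the overflow acetate reaction has zero flux in some
conditions and is not log-transformable).

The same analysis from the shell:

```bash
coordflux simulate --seed 7 --out data/
coordflux pipeline --config scenario.yaml --out results/
```

See `examples/` for one short script per capability (simulation,
physiology, flux inference, regulation, metabolome clustering).

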