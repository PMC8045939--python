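"""Decompose flux changes into protein and enzyme-saturation contributions.

For every reaction with non-zero flux in all conditions, a measured
catalyst and fully measured substrates, the analysis fits bounded kinetic
orders α ∈ [0, 4] and reports, per limitation, the protein regulation
coefficient ρ_P (log-log response of protein to flux) and the saturation
coefficient ρ_S. On zero-noise data ρ_P + ρ_S = 1 exactly — the two layers
jointly account for each flux change.
"""

from coordflux import ScenarioConfig, analyze_regulation, simulate_condition_series

cfg = ScenarioConfig(seed=7)
cfg.noise = cfg.noise.zeroed()
dataset = simulate_condition_series(cfg)
gt = dataset.ground_truth

reg, excluded = analyze_regulation(
    dataset.model, gt.fluxes, gt.proteins, gt.metabolites,
    {c.id: c.limitation for c in dataset.conditions}, "ref",
)

print(f"{'reaction':<8} {'limitation':<10} {'rho_P':>7} {'rho_S':>7} {'sum':>6} {'in band':>8}")
for _, r in reg.iterrows():
    print(f"{r['reaction']:<8} {r['limitation']:<10} {r['rho_P']:>7.2f} "
          f"{r['rho_S']:>7.2f} {r['combined']:>6.2f} {str(r['in_band_P']):>8}")
print("\nexcluded reactions:", excluded)
print(
    "Under catabolic limitation protein expression tracks flux (ρ_P ≈ 1); "
    "under anabolic limitation the allocation reversal pushes ρ_P out of the "
    "[0.5, 1.5] band — the transaminases even turn negative, with saturation "
    "(ρ_S > 1) carrying the flux change instead."
)
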