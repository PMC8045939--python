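"""Infer the full flux distribution by two-step FBA with a ratio constraint.

Measured exchange rates band the exchange reactions (5% for major, 10% for
minor species), the growth rate bands biomass, and the ¹³C split ratio at
the G6P node enters as a linear equality. Step 1 maximizes ATP maintenance,
step 2 minimizes total absolute flux at that optimum; flux variability
analysis at 99.99% optimality gives the per-reaction uncertainty.
"""

from coordflux import ScenarioConfig, estimate_rate_panel, simulate_condition_series
from coordflux.pipeline import infer_fluxes

dataset = simulate_condition_series(ScenarioConfig(seed=7))
panel = estimate_rate_panel(dataset.od_timecourses, dataset.conc_timecourses)

cid = "ana_4"
fluxes, fva, residuals = infer_fluxes(
    dataset.model, panel, dataset.flux_ratios, [cid],
    zero_exchanges=("lac",),
)
truth = dataset.ground_truth.fluxes[cid]

print(f"{'reaction':<9} {'inferred':>9} {'truth':>9} {'fva_width':>10}")
widths = {r["reaction"]: r["v_max"] - r["v_min"] for _, r in fva.iterrows()}
for rid in fluxes.index:
    w = widths.get(rid)
    print(f"{rid:<9} {fluxes.loc[rid, cid]:>9.3f} {truth[rid]:>9.3f} "
          f"{'' if w is None else f'{w:>10.4f}'}")
print(f"\nmax |S·v| = {max(residuals.values()):.2e} (mass balance holds)")
print(
    "Inferred fluxes sit inside the measurement bands around the truth; the "
    "FVA widths show which fluxes the exchange data pin down tightly."
)
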