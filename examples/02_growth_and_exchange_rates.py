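"""Estimate growth and specific exchange rates from batch time courses.

The estimator regresses ln(OD) on time for μ and extracellular
concentration on biomass (OD · 0.413 g CDW/l) for each metabolite; the
specific rate is slope · μ. Here we recover the rates of one simulated
condition and compare them to the generator's ground truth.
"""

from coordflux import ScenarioConfig, estimate_rate_panel, simulate_condition_series

dataset = simulate_condition_series(ScenarioConfig(seed=7))
panel = estimate_rate_panel(dataset.od_timecourses, dataset.conc_timecourses)

cid = "cat_8"
truth = dataset.ground_truth.exchange_rates[cid]
mu_true = next(c.growth_rate for c in dataset.conditions if c.id == cid)

print(f"condition {cid}:  mu_hat = {panel.mu(cid):.4f} /h  (truth {mu_true:.4f})")
print(f"{'metabolite':<10} {'q_hat':>8} {'q_true':>8} {'class':>6}")
for _, row in panel.condition_rates(cid).iterrows():
    print(f"{row['metabolite']:<10} {row['q']:>8.3f} "
          f"{truth[row['metabolite']]:>8.3f} {row['class']:>6}")
print(
    "\nNegative q = uptake. With the default measurement noise the estimates "
    "sit within a few percent of truth; glucose/acetate/AKG are 'major' "
    "exchanges, species below 0.01 mmol/gCDW/h are 'trace' and never "
    "constrain flux inference."
)
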