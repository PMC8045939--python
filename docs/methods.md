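# Methods

This note documents the models, numerical choices and limitations behind
coordflux, in the order data flows through the package.

## Scope and data model

The package analyzes steady-state bacterial cultures arranged in two
limitation series — catabolic (titrated carbon-uptake capacity) and
anabolic (titrated GOGAT, restricting glutamate synthesis and hence
transamination) — plus one wild-type reference condition. A
`StoichiometricModel` (JSON-native; optional SBML ingestion through cobra)
holds metabolites, reactions with bounds and flat catalyst lists, and the
two distinguished reactions used downstream: ATP maintenance (the
flux-inference objective) and biomass. Gene–protein-reaction boolean logic
is deliberately out of scope: regulation analysis averages over measured
isoenzymes anyway, so catalysts are a flat list. Exchange fluxes are
signed with uptake negative, secretion positive; all fluxes are
mmol·gCDW⁻¹·h⁻¹ and the minor-exchange threshold of 10 µmol·gCDW⁻¹·h⁻¹ is
stored as 0.01 in those units.

## Synthetic data generator

The generator is first-class, tested code, not a fixture. It emulates the
statistical structure of a two-limitation titration study on a fixed
17-reaction toy network: glucose uptake, a G6P split node between a
high-ATP glycolytic lump and a bypass (the node carrying the ¹³C ratio
constraint), a TCA lump producing 2-oxoglutarate (AKG) and ATP, acetate
overflow, a GOGAT-like amination of AKG to glutamate, two transaminases
that return AKG, amino-acid drains into biomass, and secretion exchanges
for acetate, AKG and lactate. One reaction (TA1) carries two isoenzymes;
the transaminases have two non-currency substrates each. ATP and ammonia
are treated as highly connected species alongside the classical list
(H₂O, H⁺, CO₂, HCO₃⁻, sulfate, phosphate, ammonia) and are therefore
never fitted as kinetic substrates.

**Steady states.** Per condition the flux vector is solved analytically
from the balances, so S·v = 0 holds to machine precision. The condition
grid defaults to 8 induction levels per limitation plus the reference
(17 conditions). Growth rates run 0.30–0.90 h⁻¹ (catabolic), 0.30–0.85
(anabolic), 0.95 at reference — typical glucose batch values. Glucose
uptake is 9 mmol·gCDW⁻¹·h⁻¹ at reference and scales with μ under
catabolic limitation; under anabolic limitation carbon is in excess and
uptake stays comparatively high. Acetate secretion under catabolic
limitation switches on above a configurable overflow threshold
(default: 60% of the series' maximal μ — the threshold is a parameter
because its value cannot be stated more precisely than "read off a
figure"); under anabolic limitation both acetate and AKG are secreted at
every level, AKG the more strongly the lower μ.

**Omics with exact ground truth.** Every kinetic reaction obeys
v = k · P · Π_x M_x^α exactly, with fixed kinetic orders in (0, 4). The
construction inverts the power law: for each metabolite one "definer"
reaction is chosen whose enzyme follows a prescribed per-limitation
log-log response to flux, and the metabolite concentration is solved from
the rate law; enzymes of reactions that share a substrate absorb the
residual (P = J / Π M^α), which preserves the identity for every kinetic
reaction simultaneously. The prescribed protein responses encode the
study design: under catabolic limitation expression tracks flux (ρ_P
close to 1); under anabolic limitation the allocation reversal makes
catabolic enzymes over- or under-respond and the transaminases
anti-correlate with their flux (ρ_P < 0), with AKG accumulating at low μ
as a side effect of the titrated GOGAT — the generator's analog of the
2-oxoglutarate choke point. The overflow (acetate) and lactate dead-end
reactions have zero flux in part of the grid and are intentionally
outside the kinetic set; they exercise the "non-zero flux in all
conditions" exclusion path.

**Proteome sectors.** Sector mass fractions implement passive allocation
phenomenologically: the ribosomal fraction is linear in μ
(0.07 + 0.18·μ); the catabolic fraction follows a Crp-like signal —
0.32 − 0.22·μ under catabolic limitation (cAMP relieved at low μ),
0.10 + 0.10·μ under anabolic limitation (AKG suppresses cAMP); anabolic
and constitutive sectors split the remainder 45/55. The catabolic slope
under catabolic limitation is deliberately steeper than the ribosomal
slope so that the remainder — and with it the anabolic fraction — rises
with μ there and falls under anabolic limitation: the reversal pattern.
No mechanistic cAMP–Crp or transcription/translation competition model is
implied.

**Noise model.** Multiplicative lognormal noise on protein levels, ion
intensities and extracellular concentrations (σ = 0.1, 0.1, 0.02 by
default), additive Gaussian noise on OD readings (σ = 0.005) and on ratio
values (σ = 0.01, clipped to [0, 1] since ratios are bounded fractions).
All randomness flows from one integer seed; equal seeds give
byte-identical datasets. With all σ = 0 the observed tables equal the
ground-truth transforms exactly — the property the end-to-end tests rely
on. What the generator does *not* emulate: batch-effect structure,
missingness, ion suppression, adducts beyond [M−H]⁻, replicate
correlation, or any real kinetics; passing tests demonstrate correctness
of the estimators under the stated generative model, not performance on
real data.

**Batch time courses.** OD(t) = OD₀·e^{μt} sampled at 7 points between
OD 0.05 and 0.5 (within exponential phase); concentrations follow
C(t) = C₀ + (q/μ)(X − X₀) with X = OD·0.413 g/l and glucose starting at
11.1 mM (2 g/l medium).

## Physiology estimators

μ is the OLS slope of ln OD on time, either over the full series or — in
window mode — over the contiguous window (default 1.5 h, the
maximal-growth-phase convention used for promoter activities) maximizing
the fitted slope. Rates regress concentration (response) on biomass
(regressor) and multiply the slope by μ; the orientation was chosen over
per-interval finite differences because differences amplify noise.
Standard errors propagate from the slope. Promoter activity is the
OD-normalized GFP production rate via centered finite differences, and
steady-state GFP concentration is activity/μ. Rate regressions pool
whatever points the caller supplies; averaging replicates first is the
caller's choice since nothing structural dictates it.

## Flux inference

The FBA problem bands each measured exchange with a symmetric relative
band ±d·|q| (d = 0.05 for major exchanges, growth rate and O₂; 0.10 for
minor), so a measured zero pins the reaction to [0, 0]; trace-class
species are left free, and a configurable list of never-secreted species
is pinned to zero. Ratio constraints default to the split form
v_a/(v_a+v_b) = r, the natural reading of ¹³C split ratios at a branch
node, encoded as the linear equality (1−r)·v_a − r·v_b = 0; a pairwise
form v_a = r·v_b is available because the algebraic form of a published
ratio is not always stated. Step 1 maximizes the ATP-maintenance flux;
step 2 minimizes Σ|v| via auxiliary variables t ≥ |v| (an exact LP, not a
quadratic norm) with v_ATPM constrained ≥ the step-1 optimum minus a
1e-9-scale relaxation — an inequality rather than an equality to avoid
numerical infeasibility, which is also why variability analysis defaults
to 99.99% optimality rather than 100%. An optional L2 tie-breaker
(default weight 0, suggested 1e-6) selects the minimum-norm point of a
degenerate optimal face on small models. All LPs use scipy's HiGHS with
feasibility tolerances of 1e-10, giving ‖S·v‖∞ ≤ 1e-9 on returned
solutions. On infeasible problems an elastic relaxation minimizes total
slack on the measured bands and reports the bands needing positive slack
(no irreducibility claim). Loop handling beyond optimality relaxation is
out of scope: the toy network's only potential loop (lactate) is handled
by pinning its exchange.

## Regulation analysis

Reactions qualify if their flux is strictly positive in every condition
(log-transformable), at least one isoenzyme is measured, and all
non-highly-connected substrates are measured; every exclusion carries a
reason code so the "number of considered reactions" is auditable output,
never a hard-coded figure. The regression orientation puts log J on the
x-axis: ρ_P = slope(log P ~ log J), ρ_S = slope(Σα log M ~ log J), per
limitation with the reference condition included in both (it is the
origin of the normalized series). This orientation makes ρ the fraction
of flux change attributed to a layer and yields the exact identity
ρ_P + ρ_S = 1 under the generative law; the transposed orientation is a
config switch. Kinetic orders are fitted by `scipy.optimize.lsq_linear`
on the box [0, 4] jointly on all conditions of both limitations,
independently per flux–enzyme pair; rank-deficient designs are solved but
flagged non-identifiable. Growth-rate interpolation of protein profiles
(piecewise linear, extrapolation flagged rather than dropped, exclusion
configurable) is provided for datasets in which proteins were measured on
a different μ grid; the synthetic pipeline measures everything on the
same conditions and does not need it. The in-band classification interval
[0.5, 1.5] is a parameter.

## Metabolome processing

Annotation compares observed m/z to neutral monoisotopic mass minus
1.007276 Da (proton), boundary-inclusive within 0.001 Da (plus a 1e-12
guard for float roundoff); all matches within tolerance are reported and
flagged ambiguous when multiple. Fold changes divide replicate-mean
intensities by the reference mean on the linear scale before log₂. The CV
filter runs on linear-scale relative concentrations of condition means by
default; passing a replicate-level table gives the replicate-level
variant, since either reading of "CV across conditions" is defensible. K-means uses scikit-learn's k-means++ Lloyd
iteration with squared-Euclidean distance, best of 10 seeded restarts;
the filtered low-variance ions are appended as cluster k+1. On the
12-ion toy metabolome the pipeline defaults to k = 3; k = 11 (making the
filtered set cluster 12) is the appropriate setting for a
hundreds-of-ions dataset and is exposed on the CLI.

## Problem sizes and tolerances

Default test and acceptance problem sizes: 17 conditions, 17 reactions,
12 ions, 200 benchmark reactions for kinetic-order recovery, 100
replicates for noisy rate estimation — sizes at which every stage runs in
seconds while still exercising all code paths. Identity and recovery
checks on zero-noise data use 1e-6 (driven by LP and bounded-lsq
tolerances of 1e-10/1e-14); LP oracle comparisons use 1e-6; mass balance
1e-9. The noisy-recovery thresholds (median |α̂ − α| ≤ 0.3 at lognormal
σ = 0.1; median rate error ≤ 10% at 5% concentration noise) are package
acceptance choices under the stated generative conditions, not claims
about any particular real dataset.

## Known limitations

* The generator's induction-level → μ mapping is a design choice (linear
  grids); nothing calibrates it to a real titration curve.
* ρ coefficients ignore product inhibition and allosteric effectors;
  Eq.-style fitting uses substrates only.
* FVA reports ranges under the measured bands and near-optimal ATP
  production; it is not a loopless FVA.
* The toy network is not carbon-balanced in the literal atomic sense;
  it is a topological and statistical stand-in, which is sufficient for
  the estimators but not for yield predictions.
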