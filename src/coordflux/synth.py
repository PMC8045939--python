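"""Synthetic multi-omics generator with exact ground truth.

Emulates two genetic limitation series in *E. coli* — a catabolic one
(titrated carbon-uptake protein) and an anabolic one (titrated GOGAT,
restricting glutamate synthesis) — each at 8 induction levels, plus a
wild-type reference. For every condition the generator produces:

* a steady-state flux vector on a toy catabolism/anabolism network with
  S·v = 0 exactly,
* relative protein and metabolite concentrations obeying the power-law
  rate law v = k · P · Π_x M_x^α exactly for every kinetic reaction,
* proteome sector mass fractions (catabolic, anabolic, ribosomal,
  constitutive) reproducing the catabolic/anabolic allocation reversal
  between the two limitations,
* batch OD and extracellular-concentration time courses consistent with
  the exchange rates, and ¹³C-style flux-ratio values for the
  glycolysis/bypass split node.

Measurement noise is multiplicative lognormal for concentrations and ion
intensities, additive Gaussian for OD readings, and additive Gaussian
clipped to [0, 1] for ratio values. With all noise scales at zero the
observed tables equal the ground-truth transforms exactly, which is what
makes the generator usable as an end-to-end oracle for the downstream
flux-inference and regulation modules.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    Condition,
    Metabolite,
    Reaction,
    StoichiometricModel,
)
from .tables import MeasurementTable, from_wide, write_table

OD_TO_CDW = 0.413  # g CDW per litre per OD600 unit


class ConfigError(ValueError):
    pass


class SimulationError(ValueError):
    pass


@dataclass
class NoiseConfig:
    sigma_protein: float = 0.1   # lognormal scale on relative protein levels
    sigma_metabolite: float = 0.1  # lognormal scale on ion intensities
    sigma_od: float = 0.005      # additive Gaussian on OD600 readings
    sigma_conc: float = 0.02     # lognormal scale on extracellular conc
    sigma_ratio: float = 0.01    # additive Gaussian on flux-ratio values

    def validate(self) -> None:
        for name, val in asdict(self).items():
            if val < 0:
                raise ConfigError(f"{name} must be >= 0")

    def zeroed(self) -> "NoiseConfig":
        return NoiseConfig(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class ScenarioConfig:
    """Study-design parameters of the synthetic limitation series."""

    limitations: tuple[str, ...] = ("catabolic", "anabolic")
    levels_per_limitation: int = 8
    seed: int = 0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    alpha_range: tuple[float, float] = (0.0, 4.0)
    n_timepoints: int = 7
    n_replicates: int = 3
    # physiology of the series
    mu_reference: float = 0.95        # wild-type growth rate, h⁻¹
    mu_range_catabolic: tuple[float, float] = (0.30, 0.90)
    mu_range_anabolic: tuple[float, float] = (0.30, 0.85)
    glucose_uptake_reference: float = 9.0  # mmol·gCDW⁻¹·h⁻¹
    overflow_mu_fraction: float = 0.6  # acetate secretion starts above this
                                       # fraction of the catabolic series' max μ
    acetate_secretion_max: float = 4.0
    od_start: float = 0.05
    od_end: float = 0.5

    def validate(self) -> None:
        if self.levels_per_limitation < 2:
            raise ConfigError("levels_per_limitation must be >= 2")
        if not (0 <= self.alpha_range[0] <= self.alpha_range[1] <= 4):
            raise ConfigError("alpha_range must lie within [0, 4]")
        self.noise.validate()


@dataclass
class GroundTruth:
    fluxes: pd.DataFrame            # reaction × condition, mmol·gCDW⁻¹·h⁻¹
    proteins: pd.DataFrame          # protein × condition, relative to reference
    metabolites: pd.DataFrame       # metabolite × condition, relative to reference
    growth_rates: pd.Series         # condition → μ
    alpha: dict[str, dict[str, float]]  # reaction → substrate → kinetic order
    sector_fractions: pd.DataFrame  # sector × condition
    exchange_rates: pd.DataFrame    # metabolite × condition, signed q
    split_ratios: pd.Series         # condition → EMP split fraction at g6p


@dataclass
class SyntheticDataset:
    model: StoichiometricModel
    conditions: list[Condition]
    proteome: MeasurementTable          # relative protein concentrations
    protein_mass: MeasurementTable      # sector pseudo-protein mass fractions
    metabolome_ions: pd.DataFrame       # ion_id, mz, condition_id, replicate, intensity
    ion_annotation_truth: pd.DataFrame  # ion_id → metabolite_id (or none)
    od_timecourses: pd.DataFrame        # condition_id, time_h, od
    conc_timecourses: pd.DataFrame      # condition_id, metabolite, time_h, conc_mM
    flux_ratios: pd.DataFrame           # condition_id, reaction_a, reaction_b, form, value
    ground_truth: GroundTruth
    sector_assignment: dict[str, str]
    kinetic_reactions: tuple[str, ...]

    @property
    def reference_condition(self) -> str:
        return next(c.id for c in self.conditions if c.limitation == "reference")

    def write(self, outdir: str | Path) -> None:
        """Write model JSON, all observed CSV tables and ground-truth CSVs."""
        from .model import write_model

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_model(self.model, outdir / "model.json")
        pd.DataFrame(
            [
                {
                    "condition_id": c.id,
                    "limitation": c.limitation,
                    "induction_level": c.induction_level,
                    "growth_rate": c.growth_rate,
                }
                for c in self.conditions
            ]
        ).to_csv(outdir / "conditions.csv", index=False)
        write_table(self.proteome, outdir / "proteome.csv")
        write_table(self.protein_mass, outdir / "protein_mass.csv")
        self.metabolome_ions.to_csv(outdir / "metabolome_ions.csv", index=False)
        self.od_timecourses.to_csv(outdir / "od_timecourses.csv", index=False)
        self.conc_timecourses.to_csv(outdir / "conc_timecourses.csv", index=False)
        self.flux_ratios.to_csv(outdir / "flux_ratios.csv", index=False)
        gt = self.ground_truth
        gt.fluxes.to_csv(outdir / "truth_fluxes.csv")
        gt.proteins.to_csv(outdir / "truth_proteins.csv")
        gt.metabolites.to_csv(outdir / "truth_metabolites.csv")
        gt.sector_fractions.to_csv(outdir / "truth_sectors.csv")
        gt.exchange_rates.to_csv(outdir / "truth_exchange_rates.csv")
        (outdir / "truth_alpha.json").write_text(json.dumps(gt.alpha, indent=2))


# ---------------------------------------------------------------------------
# Toy network
# ---------------------------------------------------------------------------

#: neutral monoisotopic masses (Da) for the metabolome ion table
_MASSES = {
    "glc": 180.0634,
    "g6p": 260.0297,
    "pyr": 88.0160,
    "akg": 146.0215,
    "glu": 147.0532,
    "aa1": 89.0477,   # alanine-like
    "aa2": 133.0375,  # aspartate-like
    "ace": 60.0211,
    "lac": 90.0317,
}

#: kinetic orders of the power-law rate laws, fixed per reaction–substrate pair
TRUE_ALPHA: dict[str, dict[str, float]] = {
    "UPT": {"glc": 0.8},
    "EMP": {"g6p": 1.2},
    "PPP": {"g6p": 0.9},
    "TCA": {"pyr": 0.7},
    "AKGDH": {"akg": 0.6},
    "GOGAT": {"akg": 1.1},
    "TA1": {"glu": 0.9, "pyr": 0.5},
    "TA2": {"glu": 1.0, "pyr": 0.4},
}

#: reactions obeying the generative power law in every condition
KINETIC_REACTIONS = tuple(TRUE_ALPHA)

#: per-limitation protein log–log response targets for the "definer" enzymes.
#: Under catabolic limitation expression tracks flux (hierarchical regulation,
#: ρ ≈ 1); under anabolic limitation the sector reversal makes catabolic
#: enzymes over-/under-respond and the transaminases anti-correlate with flux.
_RHO_TARGETS = {
    "ptsG": {"catabolic": 1.05, "anabolic": 2.2},
    "pfkA": {"catabolic": 0.95, "anabolic": 1.9},
    "gltA": {"catabolic": 0.85, "anabolic": 0.4},
    "gltB": {"catabolic": 0.90, "anabolic": 1.8},
    "ilvE": {"catabolic": 1.02, "anabolic": -0.5},
}

CATALYSTS = {
    "UPT": ["ptsG"],
    "EMP": ["pfkA"],
    "PPP": ["zwf"],
    "TCA": ["gltA"],
    "AKGDH": ["sucA"],
    "ACK": ["ackA"],
    "LDH": ["ldhA"],
    "GOGAT": ["gltB"],
    "TA1": ["ilvE", "avtA"],  # isoenzyme pair
    "TA2": ["aspC"],
}

SECTOR_ASSIGNMENT = {
    "cat_sector_a": "catabolic",
    "cat_sector_b": "catabolic",
    "ana_sector_a": "anabolic",
    "ana_sector_b": "anabolic",
    "rib_sector": "ribosomal",
    "const_sector": "constitutive",
}


def build_toy_network() -> StoichiometricModel:
    """A fixed 17-reaction catabolism/anabolism network.

    Glucose is taken up and split at G6P between a high-ATP glycolytic lump
    (EMP) and a bypass (PPP) — the node carrying the ¹³C split-ratio
    constraint. Pyruvate feeds a TCA lump producing 2-oxoglutarate (AKG) and
    ATP, acetate overflow, and transamination. A GOGAT-like reaction
    aminates AKG to glutamate, two transaminases return AKG while making the
    amino acids drained by biomass. Acetate, AKG and lactate have secretion
    exchanges; ATP maintenance is the flux-inference objective.
    """
    mets = {}
    for mid, mass in _MASSES.items():
        mets[mid] = Metabolite(id=mid, name=mid, compartment="c", monoisotopic_mass=mass)
    # ATP is a lumped currency cofactor here and is treated like the other
    # highly connected species, i.e. excluded from kinetic-order fitting
    mets["atp"] = Metabolite(id="atp", name="ATP", compartment="c", highly_connected=True)
    mets["nh4"] = Metabolite(id="nh4", name="ammonia", compartment="c", highly_connected=True)

    def rxn(rid, stoich, lb, ub, exchange=False):
        return Reaction(
            id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
            is_exchange=exchange, catalysts=list(CATALYSTS.get(rid, [])),
        )

    reactions = {}
    for rid, mid, lb, ub in (
        ("EX_glc", "glc", -1000.0, 0.0),
        ("EX_ace", "ace", 0.0, 1000.0),
        ("EX_akg", "akg", 0.0, 1000.0),
        ("EX_lac", "lac", 0.0, 1000.0),
        ("EX_nh4", "nh4", -1000.0, 0.0),
    ):
        reactions[rid] = rxn(rid, {mid: -1.0}, lb, ub, exchange=True)
    reactions["UPT"] = rxn("UPT", {"glc": -1.0, "g6p": 1.0}, 0.0, 1000.0)
    reactions["EMP"] = rxn("EMP", {"g6p": -1.0, "pyr": 2.0, "atp": 2.0}, 0.0, 1000.0)
    reactions["PPP"] = rxn("PPP", {"g6p": -1.0, "pyr": 1.0}, 0.0, 1000.0)
    reactions["TCA"] = rxn("TCA", {"pyr": -1.0, "akg": 1.0, "atp": 2.0}, 0.0, 1000.0)
    reactions["AKGDH"] = rxn("AKGDH", {"akg": -1.0, "atp": 2.0}, 0.0, 1000.0)
    reactions["ACK"] = rxn("ACK", {"pyr": -1.0, "ace": 1.0, "atp": 1.0}, 0.0, 1000.0)
    reactions["LDH"] = rxn("LDH", {"pyr": -1.0, "lac": 1.0}, 0.0, 1000.0)
    reactions["GOGAT"] = rxn(
        "GOGAT", {"akg": -1.0, "nh4": -1.0, "atp": -1.0, "glu": 1.0}, 0.0, 1000.0
    )
    reactions["TA1"] = rxn(
        "TA1", {"glu": -1.0, "pyr": -1.0, "aa1": 1.0, "akg": 1.0}, 0.0, 1000.0
    )
    reactions["TA2"] = rxn(
        "TA2", {"glu": -1.0, "pyr": -1.0, "aa2": 1.0, "akg": 1.0}, 0.0, 1000.0
    )
    # biomass drains amino acids and ATP; stoichiometry scaled so that the
    # biomass flux equals μ numerically
    reactions["BIOMASS"] = rxn(
        "BIOMASS", {"aa1": -1.5, "aa2": -1.5, "atp": -3.0}, 0.0, 1000.0
    )
    reactions["ATPM"] = rxn("ATPM", {"atp": -1.0}, 0.0, 1000.0)

    return StoichiometricModel(
        metabolites=mets,
        reactions=reactions,
        atp_maintenance_id="ATPM",
        biomass_id="BIOMASS",
    )


# ---------------------------------------------------------------------------
# Steady-state ground truth
# ---------------------------------------------------------------------------


def _exchange_pattern(limitation: str, mu: float, cfg: ScenarioConfig):
    """Signed specific rates (secretion > 0) and the split ratio at G6P."""
    mu_ref = cfg.mu_reference
    if limitation in ("catabolic", "reference"):
        u = cfg.glucose_uptake_reference * mu / mu_ref
        mu_max = cfg.mu_range_catabolic[1]
        mu_thr = cfg.overflow_mu_fraction * mu_max
        q_ace = cfg.acetate_secretion_max * max(0.0, (mu - mu_thr) / (mu_max - mu_thr))
        q_akg = 0.0
    elif limitation == "anabolic":
        # carbon in excess: uptake stays comparatively high, overflow of both
        # acetate and AKG at every induction level
        u = cfg.glucose_uptake_reference * (0.55 + 0.45 * mu / mu_ref)
        q_ace = 2.0 + 1.5 * mu
        q_akg = 2.5 * (1.0 - mu / mu_ref)
    else:
        raise ConfigError(f"unknown limitation {limitation!r}")
    split = 0.70 + 0.08 * mu / mu_ref
    return {"glc": -u, "ace": q_ace, "akg": q_akg, "lac": 0.0}, split


def _flux_vector(limitation: str, mu: float, cfg: ScenarioConfig) -> dict[str, float]:
    """Solve the toy network's balances analytically for one condition."""
    q, r = _exchange_pattern(limitation, mu, cfg)
    u = -q["glc"]
    v = {}
    v["EX_glc"] = q["glc"]
    v["UPT"] = u
    v["EMP"] = r * u
    v["PPP"] = (1.0 - r) * u
    v["BIOMASS"] = mu
    v["TA1"] = 1.5 * mu
    v["TA2"] = 1.5 * mu
    v["GOGAT"] = 3.0 * mu
    v["EX_nh4"] = -3.0 * mu
    v["ACK"] = q["ace"]
    v["EX_ace"] = q["ace"]
    v["LDH"] = 0.0
    v["EX_lac"] = 0.0
    # pyruvate balance: 2·EMP + PPP = TCA + ACK + TA1 + TA2
    v["TCA"] = 2 * v["EMP"] + v["PPP"] - v["ACK"] - v["TA1"] - v["TA2"]
    # AKG balance: TCA + TA1 + TA2 = AKGDH + GOGAT + EX_akg
    v["EX_akg"] = q["akg"]
    v["AKGDH"] = v["TCA"] + v["TA1"] + v["TA2"] - v["GOGAT"] - v["EX_akg"]
    # ATP balance closes on maintenance
    v["ATPM"] = (
        2 * v["EMP"] + 2 * v["TCA"] + 2 * v["AKGDH"] + v["ACK"]
        - v["GOGAT"] - 3.0 * mu
    )
    if v["TCA"] <= 0 or v["AKGDH"] <= 0 or v["ATPM"] <= 0:
        raise SimulationError(
            f"infeasible toy steady state at limitation={limitation}, mu={mu}"
        )
    return v


def _condition_grid(cfg: ScenarioConfig) -> list[Condition]:
    conds = [Condition("ref", "reference", 0, cfg.mu_reference)]
    ranges = {"catabolic": cfg.mu_range_catabolic, "anabolic": cfg.mu_range_anabolic}
    for lim in cfg.limitations:
        lo, hi = ranges[lim]
        mus = np.linspace(lo, hi, cfg.levels_per_limitation)
        prefix = "cat" if lim == "catabolic" else "ana"
        for lvl, mu in enumerate(mus, start=1):
            conds.append(Condition(f"{prefix}_{lvl}", lim, lvl, float(mu)))
    return conds


def _sector_fractions(limitation: str, mu: float) -> dict[str, float]:
    """Phenomenological passive-allocation sectors (Crp-driven catabolic share).

    φ_rib grows linearly with μ; φ_cat follows a Crp-like signal — high at low
    μ under catabolic limitation (cAMP relieved), low at low μ under anabolic
    limitation (AKG inhibits cAMP synthesis); the anabolic and constitutive
    sectors share the remainder in fixed proportion.
    """
    phi_rib = 0.07 + 0.18 * mu
    if limitation in ("catabolic", "reference"):
        phi_cat = 0.32 - 0.22 * mu
    else:
        phi_cat = 0.10 + 0.10 * mu
    remainder = 1.0 - phi_rib - phi_cat
    return {
        "catabolic": phi_cat,
        "anabolic": 0.45 * remainder,
        "ribosomal": phi_rib,
        "constitutive": 0.55 * remainder,
    }


def _ground_truth(cfg: ScenarioConfig) -> tuple[list[Condition], GroundTruth]:
    conds = _condition_grid(cfg)
    cids = [c.id for c in conds]
    flux = pd.DataFrame(
        {c.id: _flux_vector(c.limitation, c.growth_rate, cfg) for c in conds}
    )
    ratios = pd.Series(
        {c.id: _exchange_pattern(c.limitation, c.growth_rate, cfg)[1] for c in conds}
    )
    qs = pd.DataFrame(
        {c.id: _exchange_pattern(c.limitation, c.growth_rate, cfg)[0] for c in conds}
    )
    mu = pd.Series({c.id: c.growth_rate for c in conds})
    # log-normalized fluxes for the rows that stay strictly positive
    pos = list(KINETIC_REACTIONS) + ["BIOMASS"]
    logJ = np.log(flux.loc[pos].divide(flux.loc[pos, "ref"], axis=0))

    lim_of = {c.id: ("catabolic" if c.limitation == "reference" else c.limitation)
              for c in conds}

    # definer enzymes: protein follows its ρ target; the metabolite
    # concentration of the designated free substrate is the power-law inverse
    logP = pd.DataFrame(0.0, index=sorted({p for ps in CATALYSTS.values() for p in ps}),
                        columns=cids)
    logM = pd.DataFrame(0.0, index=list(_MASSES), columns=cids)

    definer = [  # (reaction, enzyme, free substrate)
        ("UPT", "ptsG", "glc"),
        ("EMP", "pfkA", "g6p"),
        ("TCA", "gltA", "pyr"),
        ("GOGAT", "gltB", "akg"),
        ("TA1", "ilvE", "glu"),
    ]
    for rid, enz, free_met in definer:
        for cid in cids:
            rho = _RHO_TARGETS[enz][lim_of[cid]]
            lp = rho * logJ.loc[rid, cid]
            logP.loc[enz, cid] = lp
            other = sum(
                a * logM.loc[met, cid]
                for met, a in TRUE_ALPHA[rid].items()
                if met != free_met
            )
            logM.loc[free_met, cid] = (
                (logJ.loc[rid, cid] - lp - other) / TRUE_ALPHA[rid][free_met]
            )
    logP.loc["avtA"] = logP.loc["ilvE"]  # proportional isoenzymes

    # residual enzymes absorb what flux and substrates do not explain
    for rid, enz in (("PPP", "zwf"), ("AKGDH", "sucA"), ("TA2", "aspC")):
        sat = sum(a * logM.loc[met] for met, a in TRUE_ALPHA[rid].items())
        logP.loc[enz] = logJ.loc[rid] - sat

    # enzymes of the non-kinetic reactions follow their sector's trend
    logP.loc["ackA"] = np.log(mu / cfg.mu_reference).values * 0.8
    logP.loc["ldhA"] = 0.0

    # metabolites that are not substrates of kinetic reactions: amino acids
    # stay nearly constant (the "cluster 12" pattern), overflow products track
    # their secretion
    logM.loc["aa1"] = 0.1 * logJ.loc["BIOMASS"].values
    logM.loc["aa2"] = 0.12 * logJ.loc["BIOMASS"].values
    q_ace_ref = qs.loc["ace", "ref"]
    logM.loc["ace"] = np.log(np.maximum(qs.loc["ace"], 0.2) / q_ace_ref).values
    logM.loc["lac"] = 0.0

    sectors = pd.DataFrame(
        {c.id: _sector_fractions(c.limitation, c.growth_rate) for c in conds}
    )
    return conds, GroundTruth(
        fluxes=flux,
        proteins=np.exp(logP),
        metabolites=np.exp(logM),
        growth_rates=mu,
        alpha={r: dict(a) for r, a in TRUE_ALPHA.items()},
        sector_fractions=sectors,
        exchange_rates=qs,
        split_ratios=ratios,
    )


# ---------------------------------------------------------------------------
# Noise and observed tables
# ---------------------------------------------------------------------------


def corrupt_with_noise(
    values: np.ndarray | pd.Series | pd.DataFrame,
    sigma: float,
    kind: str = "lognormal",
    seed: int | np.random.Generator = 0,
):
    """Apply seeded measurement noise: ``lognormal`` v·exp(ε) or ``gaussian`` v+ε."""
    if sigma < 0:
        raise ConfigError("sigma must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.asarray(values, dtype=float)
    if sigma == 0:
        noisy = arr.copy()
    else:
        eps = rng.normal(0.0, sigma, size=arr.shape)
        if kind == "lognormal":
            noisy = arr * np.exp(eps)
        elif kind == "gaussian":
            noisy = arr + eps
        else:
            raise ConfigError(f"unknown noise kind {kind!r}")
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(noisy, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(noisy, index=values.index)
    return noisy


def simulate_batch_timecourses(
    condition: Condition,
    exchange_rates: dict[str, float],
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
    initial_conc: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exponential-growth OD and extracellular concentration time courses.

    OD(t) = OD₀·e^{μt}; for each exchanged metabolite with specific rate q
    (secretion positive): C(t) = C₀ + (q/μ)·(X(t) − X₀) with biomass
    X = OD·0.413 g/l. Sampled at 6–8 points during exponential phase.
    """
    mu = condition.growth_rate
    if mu <= 0:
        raise SimulationError(f"growth rate must be > 0 (got {mu})")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if initial_conc is None:
        initial_conc = {}
    t_end = math.log(cfg.od_end / cfg.od_start) / mu
    t = np.linspace(0.0, t_end, cfg.n_timepoints)
    od_true = cfg.od_start * np.exp(mu * t)
    od_obs = corrupt_with_noise(od_true, cfg.noise.sigma_od, "gaussian", rng)
    od_df = pd.DataFrame(
        {"condition_id": condition.id, "time_h": t, "od": od_obs}
    )
    X = od_true * OD_TO_CDW
    rows = []
    defaults = {"glc": 11.1}  # 2 g/l glucose in mM
    for met, q in exchange_rates.items():
        c0 = initial_conc.get(met, defaults.get(met, 0.0))
        conc = c0 + (q / mu) * (X - X[0])
        conc = corrupt_with_noise(conc, cfg.noise.sigma_conc, "lognormal", rng)
        for ti, ci in zip(t, conc):
            rows.append(
                {"condition_id": condition.id, "metabolite": met,
                 "time_h": ti, "conc_mM": ci}
            )
    return od_df, pd.DataFrame(rows)


def simulate_condition_series(cfg: ScenarioConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset for the configured scenario."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    model = build_toy_network()
    conds, truth = _ground_truth(cfg)

    # observed proteome (relative concentrations, one value per condition)
    prot_obs = corrupt_with_noise(
        truth.proteins, cfg.noise.sigma_protein, "lognormal", rng
    )
    proteome = from_wide(prot_obs, unit="relative", name="proteome")

    # sector pseudo-protein masses
    sector_rows = {}
    weights = {"cat_sector_a": ("catabolic", 0.6), "cat_sector_b": ("catabolic", 0.4),
               "ana_sector_a": ("anabolic", 0.7), "ana_sector_b": ("anabolic", 0.3),
               "rib_sector": ("ribosomal", 1.0), "const_sector": ("constitutive", 1.0)}
    for pid, (sector, w) in weights.items():
        sector_rows[pid] = truth.sector_fractions.loc[sector] * w
    mass_true = pd.DataFrame(sector_rows).T
    mass_obs = corrupt_with_noise(mass_true, cfg.noise.sigma_protein, "lognormal", rng)
    protein_mass = from_wide(mass_obs, unit="mass_fraction", name="protein_mass")

    # metabolome ion intensities: per-ion gain cancels in fold changes
    ion_rows = []
    annot_rows = []
    gains = {}
    for i, (mid, mass) in enumerate(_MASSES.items()):
        ion_id = f"ion_{i:03d}"
        gains[ion_id] = (mid, 1e5 * float(rng.lognormal(0.0, 0.5)))
        annot_rows.append({"ion_id": ion_id, "metabolite_id": mid,
                           "mz": mass - 1.007276})
    for j in range(3):  # unannotatable decoys
        ion_id = f"decoy_{j}"
        gains[ion_id] = (None, 1e4 * float(rng.lognormal(0.0, 0.5)))
        annot_rows.append({"ion_id": ion_id, "metabolite_id": None,
                           "mz": 300.0 + 17.1 * j})
    for ion_id, (mid, gain) in gains.items():
        for cid in truth.metabolites.columns:
            base = gain * (truth.metabolites.loc[mid, cid] if mid else 1.0)
            for rep in range(1, cfg.n_replicates + 1):
                val = float(
                    corrupt_with_noise(
                        np.array([base]), cfg.noise.sigma_metabolite, "lognormal", rng
                    )[0]
                )
                ion_rows.append(
                    {"ion_id": ion_id,
                     "mz": next(a["mz"] for a in annot_rows if a["ion_id"] == ion_id),
                     "condition_id": cid, "replicate": rep, "intensity": val}
                )
    metabolome_ions = pd.DataFrame(ion_rows)
    annotation_truth = pd.DataFrame(annot_rows)

    # time courses per condition
    od_frames, conc_frames = [], []
    for cond in conds:
        q, _ = _exchange_pattern(cond.limitation, cond.growth_rate, cfg)
        od_df, conc_df = simulate_batch_timecourses(cond, q, cfg, rng)
        od_frames.append(od_df)
        conc_frames.append(conc_df)

    # flux-ratio table: split fraction at the G6P node (EMP vs PPP)
    ratio_rows = []
    for cond in conds:
        r = float(truth.split_ratios[cond.id])
        if cfg.noise.sigma_ratio > 0:
            r = float(np.clip(r + rng.normal(0.0, cfg.noise.sigma_ratio), 0.0, 1.0))
        ratio_rows.append(
            {"condition_id": cond.id, "reaction_a": "EMP", "reaction_b": "PPP",
             "form": "split", "value": r}
        )

    return SyntheticDataset(
        model=model,
        conditions=conds,
        proteome=proteome,
        protein_mass=protein_mass,
        metabolome_ions=metabolome_ions,
        ion_annotation_truth=annotation_truth,
        od_timecourses=pd.concat(od_frames, ignore_index=True),
        conc_timecourses=pd.concat(conc_frames, ignore_index=True),
        flux_ratios=pd.DataFrame(ratio_rows),
        ground_truth=truth,
        sector_assignment=dict(SECTOR_ASSIGNMENT),
        kinetic_reactions=KINETIC_REACTIONS,
    )


# ---------------------------------------------------------------------------
# Stand-alone regulation benchmark
# ---------------------------------------------------------------------------


def simulate_regulation_benchmark(
    n_reactions: int = 200,
    seed: int = 0,
    sigma: float = 0.1,
    alpha_range: tuple[float, float] = (0.2, 3.8),
    levels_per_limitation: int = 8,
) -> pd.DataFrame:
    """Independent single-substrate reactions for kinetic-order recovery tests.

    Substrate log-concentrations are the primary varying quantity (severalfold
    changes across conditions, as metabolomes show); protein responses are
    drawn with modest slopes, and flux follows the power law exactly before
    lognormal measurement noise of scale ``sigma`` is applied to P and M.
    True ρ_P per limitation is computed from the realized noise-free series.

    Returns a tidy frame with one row per reaction × condition plus the true
    α and per-limitation true ρ_P as constant columns.
    """
    rng = np.random.default_rng(seed)
    x = np.linspace(-1.0, 1.0, levels_per_limitation)
    cond_ids = (
        [f"cat_{i+1}" for i in range(levels_per_limitation)]
        + [f"ana_{i+1}" for i in range(levels_per_limitation)]
        + ["ref"]
    )
    lims = (["catabolic"] * levels_per_limitation
            + ["anabolic"] * levels_per_limitation + ["reference"])
    xs = np.concatenate([x, x, [0.0]])

    rows = []
    for r in range(n_reactions):
        alpha = float(rng.uniform(*alpha_range))
        m = float(rng.choice([-1, 1]) * rng.uniform(0.5, 1.1))
        p = float(rng.uniform(-0.3, 0.6))
        jitter = rng.normal(0.0, 0.3, size=len(xs))
        jitter[-1] = 0.0  # reference stays at the origin
        logM = m * xs + jitter
        logP = p * xs
        logJ = logP + alpha * logM

        rho_true = {}
        for lim in ("catabolic", "anabolic"):
            sel = [i for i, l in enumerate(lims) if l in (lim, "reference")]
            jj, pp = logJ[sel], logP[sel]
            rho_true[lim] = float(
                np.cov(jj, pp, bias=True)[0, 1] / np.var(jj)
            )

        logP_obs = logP + rng.normal(0.0, sigma, len(xs))
        logM_obs = logM + rng.normal(0.0, sigma, len(xs))
        for i, cid in enumerate(cond_ids):
            rows.append(
                {"reaction": f"rxn_{r:03d}", "condition_id": cid,
                 "limitation": lims[i],
                 "logJ": logJ[i], "logP": logP_obs[i], "logM": logM_obs[i],
                 "alpha_true": alpha,
                 "rho_p_true_catabolic": rho_true["catabolic"],
                 "rho_p_true_anabolic": rho_true["anabolic"]}
            )
    return pd.DataFrame(rows)
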