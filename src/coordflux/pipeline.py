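"""End-to-end orchestration: simulate → physiology → FBA/FVA → regulation →
metabolome → report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import StoichiometricModel, Condition, load_model
from .tables import read_table
from .synth import ScenarioConfig, NoiseConfig, SyntheticDataset, simulate_condition_series
from .physiology import RatePanel, estimate_rate_panel
from .fluxes import (
    RatioConstraint,
    add_ratio_constraints,
    build_fba_problem,
    flux_variability,
    mass_balance_residual,
    solve_two_step,
)
from .regulation import analyze_regulation, fraction_in_band, sector_fraction
from .metabolome import annotate_ions, cv_filter, fold_change_matrix, kmeans_cluster

log = logging.getLogger("coordflux")


class PipelineConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of ``scenario`` (simulation mode) or ``data_dir`` (tables on
    disk, in the layout written by ``coordflux simulate``) must be given;
    the seed is mandatory in simulation mode.
    """

    scenario: ScenarioConfig | None = None
    data_dir: str | None = None
    outdir: str | None = None
    zero_exchanges: tuple[str, ...] = ("lac",)
    deviations: dict = field(default_factory=dict)
    optimality_fraction: float = 0.9999
    kmeans_k: int = 3
    kmeans_restarts: int = 10
    cv_threshold: float = 0.30
    band: tuple[float, float] = (0.5, 1.5)
    stages: tuple[str, ...] = ("physiology", "fba", "regulation", "metabolome")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        scenario = None
        if "scenario" in doc:
            sc = dict(doc["scenario"])
            if "seed" not in sc:
                raise PipelineConfigError("seed is mandatory in simulation mode")
            noise = NoiseConfig(**sc.pop("noise", {}))
            if "limitations" in sc:
                sc["limitations"] = tuple(sc["limitations"])
            scenario = ScenarioConfig(noise=noise, **sc)
        kwargs = {k: v for k, v in doc.items() if k in (
            "data_dir", "outdir", "optimality_fraction", "kmeans_k",
            "kmeans_restarts", "cv_threshold",
        )}
        if "zero_exchanges" in doc:
            kwargs["zero_exchanges"] = tuple(doc["zero_exchanges"])
        if "deviations" in doc:
            kwargs["deviations"] = dict(doc["deviations"])
        cfg = cls(scenario=scenario, **kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if (self.scenario is None) == (self.data_dir is None):
            raise PipelineConfigError(
                "exactly one of scenario (simulation mode) or data_dir must be set"
            )


# ---------------------------------------------------------------------------


def _load_data_dir(path: str) -> SyntheticDataset:
    """Read the on-disk table layout back into a dataset (no ground truth)."""
    d = Path(path)
    model = load_model(d / "model.json")
    conds_df = pd.read_csv(d / "conditions.csv")
    conditions = [
        Condition(r.condition_id, r.limitation, int(r.induction_level),
                  float(r.growth_rate))
        for r in conds_df.itertuples()
    ]
    return SyntheticDataset(
        model=model,
        conditions=conditions,
        proteome=read_table(d / "proteome.csv"),
        protein_mass=read_table(d / "protein_mass.csv"),
        metabolome_ions=pd.read_csv(d / "metabolome_ions.csv"),
        ion_annotation_truth=pd.DataFrame(),
        od_timecourses=pd.read_csv(d / "od_timecourses.csv"),
        conc_timecourses=pd.read_csv(d / "conc_timecourses.csv"),
        flux_ratios=pd.read_csv(d / "flux_ratios.csv"),
        ground_truth=None,
        sector_assignment={},
        kinetic_reactions=(),
    )


def infer_fluxes(
    model: StoichiometricModel,
    rate_panel: RatePanel,
    flux_ratios: pd.DataFrame,
    condition_ids: list[str],
    zero_exchanges: tuple[str, ...] = (),
    deviations: dict | None = None,
    optimality_fraction: float = 0.9999,
    run_fva: bool = True,
):
    """Two-step FBA (and FVA over its non-zero fluxes) for each condition."""
    flux_cols = {}
    fva_rows = []
    residuals = {}
    for cid in condition_ids:
        problem = build_fba_problem(
            model, rate_panel, cid,
            zero_exchanges=list(zero_exchanges),
            deviations=deviations,
        )
        ratios = [
            RatioConstraint(r.reaction_a, r.reaction_b, float(r.value), r.form)
            for r in flux_ratios[flux_ratios["condition_id"] == cid].itertuples()
        ]
        add_ratio_constraints(problem, ratios)
        sol = solve_two_step(problem)
        flux_cols[cid] = sol.fluxes
        residuals[cid] = mass_balance_residual(model, sol.fluxes)
        if run_fva:
            nonzero = [r for r in sol.fluxes.index if abs(sol.fluxes[r]) > 1e-9]
            fva = flux_variability(
                problem, sol.objective_value,
                optimality_fraction=optimality_fraction, reactions=nonzero,
            )
            for rid, row in fva.intervals.iterrows():
                fva_rows.append(
                    {"condition_id": cid, "reaction": rid,
                     "v_min": row["v_min"], "v_max": row["v_max"],
                     "flux": float(sol.fluxes[rid])}
                )
    flux_table = pd.DataFrame(flux_cols)
    return flux_table, pd.DataFrame(fva_rows), residuals


def relative_metabolites_from_ions(
    ions: pd.DataFrame,
    model: StoichiometricModel,
    reference_condition: str,
) -> pd.DataFrame:
    """Annotate ions on the model's metabolite masses and return a
    metabolite × condition table of wild-type-relative concentrations."""
    masses = {
        m.id: m.monoisotopic_mass
        for m in model.metabolites.values()
        if m.monoisotopic_mass
    }
    mz_per_ion = ions.groupby("ion_id")["mz"].first()
    ann = annotate_ions(mz_per_ion.values, masses)
    ann["ion_id"] = mz_per_ion.index
    fc = fold_change_matrix(ions, reference_condition)
    rows = {}
    for r in ann.dropna(subset=["metabolite_id"]).itertuples():
        if r.ion_id in fc.index and r.metabolite_id not in rows:
            rows[r.metabolite_id] = 2.0 ** fc.loc[r.ion_id]
    return pd.DataFrame(rows).T


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; return the JSON-able report.

    Per-stage CSV outputs are written under ``config.outdir`` when set.
    """
    config.validate()
    report: dict = {"version": __version__, "stages": {}}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    if config.scenario is not None:
        report["seed"] = config.scenario.seed
        log.info("simulating scenario (seed=%d)", config.scenario.seed)
        dataset = simulate_condition_series(config.scenario)
        if outdir:
            dataset.write(outdir / "dataset")
    else:
        dataset = _load_data_dir(config.data_dir)
    ref = dataset.reference_condition
    cond_lims = {c.id: c.limitation for c in dataset.conditions}
    cids = [c.id for c in dataset.conditions]

    # physiology ----------------------------------------------------------
    try:
        panel = estimate_rate_panel(dataset.od_timecourses, dataset.conc_timecourses)
    except Exception as exc:  # noqa: BLE001
        raise StageError("physiology", exc) from exc
    if outdir:
        panel.to_csv(outdir / "rates.csv")
    report["stages"]["physiology"] = {
        "n_conditions": len(panel.growth),
        "mu": dict(zip(panel.growth["condition_id"], panel.growth["mu"])),
        "classes": panel.rates.groupby("metabolite")["class"].first().to_dict(),
    }

    # flux inference ------------------------------------------------------
    try:
        flux_table, fva_table, residuals = infer_fluxes(
            dataset.model, panel, dataset.flux_ratios, cids,
            zero_exchanges=config.zero_exchanges,
            deviations=config.deviations,
            optimality_fraction=config.optimality_fraction,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("fba", exc) from exc
    if outdir:
        flux_table.to_csv(outdir / "fluxes.csv")
        fva_table.to_csv(outdir / "fva.csv", index=False)
    widths = (fva_table["v_max"] - fva_table["v_min"]) if len(fva_table) else pd.Series(dtype=float)
    report["stages"]["fba"] = {
        "max_mass_balance_residual": max(residuals.values()),
        "median_fva_width": float(widths.median()) if len(widths) else None,
        "max_fva_width": float(widths.max()) if len(widths) else None,
    }

    # regulation ----------------------------------------------------------
    try:
        protein_wide = dataset.proteome.wide()
        metab_rel = relative_metabolites_from_ions(
            dataset.metabolome_ions, dataset.model, ref
        )
        reg, excluded = analyze_regulation(
            dataset.model, flux_table, protein_wide, metab_rel,
            cond_lims, ref, band=config.band,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("regulation", exc) from exc
    if outdir:
        out = reg.copy()
        out["alpha"] = out["alpha"].map(json.dumps)
        out.to_csv(outdir / "regulation.csv", index=False)
    frac_band = {}
    for lim, grp in reg.groupby("limitation"):
        frac_band[lim] = {
            "rho_P": fraction_in_band(grp["rho_P"], config.band),
            "combined": fraction_in_band(grp["combined"], config.band),
        }
    sectors = sector_fraction(dataset.protein_mass.wide(), dataset.sector_assignment) \
        if dataset.sector_assignment else None
    report["stages"]["regulation"] = {
        "n_considered_reactions": int(reg["reaction"].nunique()),
        "excluded": excluded,
        "fraction_in_band": frac_band,
        "rho_P_summary": {
            lim: {"median": float(grp["rho_P"].median())}
            for lim, grp in reg.groupby("limitation")
        },
    }
    if sectors is not None and outdir:
        sectors.to_csv(outdir / "sectors.csv")

    # metabolome ----------------------------------------------------------
    try:
        fc = fold_change_matrix(dataset.metabolome_ions, ref)
        rel = 2.0 ** fc
        retained, filtered = cv_filter(rel, config.cv_threshold)
        k = min(config.kmeans_k, max(1, len(retained)))
        seed = config.scenario.seed if config.scenario else 0
        clusters = kmeans_cluster(
            fc.loc[retained], k=k, seed=seed,
            restarts=config.kmeans_restarts, filtered_ions=filtered,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("metabolome", exc) from exc
    if outdir:
        clusters.labels.to_csv(outdir / "clusters.csv")
    report["stages"]["metabolome"] = {
        "n_ions": int(dataset.metabolome_ions["ion_id"].nunique()),
        "n_retained": int(len(retained)),
        "n_filtered": int(len(filtered)),
        "k": clusters.k,
        "inertia": clusters.inertia,
    }

    if outdir:
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
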