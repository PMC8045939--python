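"""Hierarchical regulation analysis: protein (ρ_P) vs enzyme-saturation (ρ_S)
contributions to flux changes, with bounded power-law kinetic orders.

For each reaction, fluxes, catalyst proteins and substrate metabolites are
normalized to the reference (wild-type) condition and log-transformed. The
protein regulation coefficient ρ_P is, per limitation, the OLS slope of
log P on log J; kinetic orders α are fitted jointly on all conditions of
both limitations by bounded least squares

    min_{0 ≤ α ≤ 4}  Σ_i ( log J_i − log P_i − Σ_x α_x · log M_{x,i} )²,

independently for each flux–enzyme pair; the saturation coefficient ρ_S is
the per-limitation slope of the saturation term s_i = Σ_x α_x log M_{x,i}
on log J. With that shared orientation, log P + s = log J per condition
implies ρ_P + ρ_S = 1 exactly. Highly connected reactants (water, protons,
CO₂, bicarbonate, sulfate, phosphate, ammonia) are excluded from the
fitting; for reactions with several isoenzymes, coefficients are averaged
over all measured proteins. Coefficients in [0.5, 1.5] count as
"consistent" flux–protein (or flux–saturation) changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import lsq_linear

from .model import StoichiometricModel

ALPHA_BOUNDS = (0.0, 4.0)
BAND = (0.5, 1.5)

#: exclusion / status reason codes
REASON_ZERO_FLUX = "zero_flux_in_some_condition"
REASON_NO_PROTEIN = "no_measured_isoenzyme"
REASON_MISSING_SUBSTRATE = "unmeasured_substrate"
REASON_TOO_FEW = "too_few_conditions"
REASON_NO_VARIANCE = "no_flux_variance"


class RegulationError(ValueError):
    pass


@dataclass
class ReactionSeries:
    """Aligned per-condition series for one reaction (reference-normalized)."""

    reaction_id: str
    conditions: list[str]
    limitations: list[str]
    log_flux: np.ndarray                     # log(J), reference = 0
    log_protein: dict[str, np.ndarray]       # per measured isoenzyme
    log_metabolite: dict[str, np.ndarray]    # per (non-highly-connected) substrate
    growth_rates: np.ndarray | None = None


@dataclass
class RegulationCoefficients:
    reaction_id: str
    per_limitation: pd.DataFrame  # rows limitation; rho_P, rho_P_se, rho_S,
                                  # rho_S_se, combined, n_conditions
    alpha: dict[str, dict[str, float]]  # isoenzyme → substrate → α
    status: str = "ok"
    reason: str = ""
    alpha_identifiable: bool = True

    def in_band(self, limitation: str, which: str = "rho_P",
                band: tuple[float, float] = BAND) -> bool:
        val = self.per_limitation.loc[limitation, which]
        return bool(np.isfinite(val) and band[0] <= val <= band[1])


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def normalize_log_to_reference(
    values: pd.Series, reference_condition: str
) -> pd.Series:
    """ln(value / reference); the reference condition maps to 0.

    Non-positive values make the series unusable for log-linear analysis and
    raise; callers drop the offending reaction with a reason code.
    """
    ref = values[reference_condition]
    if ref <= 0:
        raise RegulationError("non-positive reference value")
    if (values <= 0).any():
        raise RegulationError("non-positive value in series")
    return np.log(values / ref)


def interpolate_to_growth_rate(
    profile: list[tuple[float, float]], target_mu: float
) -> tuple[float, bool]:
    """Piecewise-linear interpolation of (μ, value) pairs to a target μ.

    Targets outside the measured range are linearly extrapolated from the
    two nearest points and flagged. Matches the growth-rate alignment used
    when protein and flux measurements come from different μ grids.
    """
    if len(profile) < 2:
        raise RegulationError("need at least 2 profile points")
    pts = sorted(profile)
    mus = np.array([p[0] for p in pts], dtype=float)
    vals = np.array([p[1] for p in pts], dtype=float)
    if np.any(np.diff(mus) == 0):
        raise RegulationError("duplicate growth rates in profile")
    if target_mu < mus[0]:
        seg = (0, 1); flagged = True
    elif target_mu > mus[-1]:
        seg = (len(mus) - 2, len(mus) - 1); flagged = True
    else:
        return float(np.interp(target_mu, mus, vals)), False
    i, j = seg
    slope = (vals[j] - vals[i]) / (mus[j] - mus[i])
    return float(vals[i] + slope * (target_mu - mus[i])), flagged


def _slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.linregress(x, y)
    return float(res.slope), float(res.stderr)


def rho_protein(
    log_flux: np.ndarray, log_protein: np.ndarray, transpose: bool = False
) -> tuple[float, float]:
    """Protein regulation coefficient: OLS slope of log P on log J.

    Returns (slope, stderr); (nan, nan) when fewer than 3 conditions or the
    regressor does not vary. ``transpose=True`` regresses log J on log P
    instead (the other reading of "slope between fluxes and proteins").
    """
    x, y = (log_protein, log_flux) if transpose else (log_flux, log_protein)
    if len(x) < 3 or np.allclose(x, x[0]):
        return float("nan"), float("nan")
    return _slope(x, y)


def rho_saturation(
    log_flux: np.ndarray, saturation_term: np.ndarray, transpose: bool = False
) -> tuple[float, float]:
    """Saturation regulation coefficient: OLS slope of s = Σ α·log M on log J."""
    x, y = (saturation_term, log_flux) if transpose else (log_flux, saturation_term)
    if len(x) < 3 or np.allclose(x, x[0]):
        return float("nan"), float("nan")
    return _slope(x, y)


def fit_kinetic_orders(
    log_flux: np.ndarray,
    log_protein: np.ndarray,
    log_metabolites: np.ndarray,
    bounds: tuple[float, float] = ALPHA_BOUNDS,
) -> tuple[np.ndarray, bool]:
    """Bounded least squares for the kinetic orders of one flux–enzyme pair.

    ``log_metabolites`` has one column per substrate. Returns (α, identifiable);
    a rank-deficient design is still solved but flagged non-identifiable.
    """
    A = np.atleast_2d(np.asarray(log_metabolites, dtype=float))
    if A.shape[0] != len(log_flux):
        A = A.T
    y = np.asarray(log_flux, dtype=float) - np.asarray(log_protein, dtype=float)
    res = lsq_linear(A, y, bounds=bounds, tol=1e-14)
    identifiable = np.linalg.matrix_rank(A, tol=1e-10) == A.shape[1]
    return res.x, identifiable


def fraction_in_band(
    coefficients, band: tuple[float, float] = BAND
) -> float:
    """Fraction of finite coefficients inside the closed band.

    Non-estimable (NaN) entries are excluded from the denominator.
    """
    arr = np.asarray(list(coefficients), dtype=float)
    if arr.size == 0:
        raise RegulationError("empty coefficient list")
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise RegulationError("no estimable coefficients")
    return float(np.mean((finite >= band[0]) & (finite <= band[1])))


def sector_fraction(
    protein_mass: pd.DataFrame, sector_assignment: dict[str, str]
) -> pd.DataFrame:
    """Per-condition sector mass fractions (rows sectors, columns conditions).

    ``protein_mass`` is protein × condition; unassigned proteins fall into
    the "other" sector. Fractions are normalized by total measured mass, so
    each column sums to 1.
    """
    if protein_mass.empty:
        raise RegulationError("empty protein mass table")
    sectors = protein_mass.index.map(lambda p: sector_assignment.get(p, "other"))
    grouped = protein_mass.groupby(sectors).sum()
    return grouped / grouped.sum(axis=0)


# ---------------------------------------------------------------------------
# Reaction-level analysis
# ---------------------------------------------------------------------------


def build_reaction_series(
    model: StoichiometricModel,
    flux_table: pd.DataFrame,       # reaction × condition, absolute fluxes
    protein_table: pd.DataFrame,    # protein × condition, relative concentrations
    metabolite_table: pd.DataFrame, # metabolite × condition, relative concentrations
    condition_limitations: dict[str, str],
    reference_condition: str,
    reactions: list[str] | None = None,
) -> tuple[list[ReactionSeries], dict[str, str]]:
    """Join fluxes, proteins and substrates per reaction; log-normalize.

    Returns the usable series plus a reason code per excluded reaction:
    zero flux in some condition, no measured isoenzyme, or an unmeasured
    (non-highly-connected) substrate.
    """
    cids = [c for c in flux_table.columns if c in condition_limitations]
    if reference_condition not in cids:
        raise RegulationError("reference condition missing from flux table")
    targets = reactions if reactions is not None else [
        rid for rid, r in model.reactions.items() if r.catalysts
    ]
    series: list[ReactionSeries] = []
    excluded: dict[str, str] = {}
    for rid in targets:
        rxn = model.reactions[rid]
        flux = flux_table.loc[rid, cids]
        if (flux <= 0).any():
            excluded[rid] = REASON_ZERO_FLUX
            continue
        measured = [p for p in rxn.catalysts if p in protein_table.index]
        if not measured:
            excluded[rid] = REASON_NO_PROTEIN
            continue
        subs = model.reaction_substrates(rid, exclude_highly_connected=True)
        missing = [m for m in subs if m not in metabolite_table.index]
        if missing:
            excluded[rid] = REASON_MISSING_SUBSTRATE
            continue
        logJ = normalize_log_to_reference(flux, reference_condition)
        logP = {
            p: normalize_log_to_reference(
                protein_table.loc[p, cids], reference_condition
            ).values
            for p in measured
        }
        logM = {
            m: normalize_log_to_reference(
                metabolite_table.loc[m, cids], reference_condition
            ).values
            for m in subs
        }
        series.append(
            ReactionSeries(
                reaction_id=rid,
                conditions=list(cids),
                limitations=[condition_limitations[c] for c in cids],
                log_flux=logJ.values,
                log_protein=logP,
                log_metabolite=logM,
            )
        )
    return series, excluded


def analyze_reaction(
    series: ReactionSeries, band: tuple[float, float] = BAND,
    transpose: bool = False,
) -> RegulationCoefficients:
    """Per-limitation ρ_P and ρ_S with isoenzyme averaging for one reaction.

    Kinetic orders are fitted per isoenzyme on all conditions jointly; the
    reference condition participates in both limitations' regressions (it is
    the shared origin of the normalized series).
    """
    lims = sorted({l for l in series.limitations if l != "reference"})
    met_ids = list(series.log_metabolite)
    M = np.column_stack([series.log_metabolite[m] for m in met_ids]) if met_ids \
        else np.zeros((len(series.log_flux), 0))

    alpha: dict[str, dict[str, float]] = {}
    identifiable = True
    sat_terms: dict[str, np.ndarray] = {}
    for enz, logP in series.log_protein.items():
        if M.shape[1]:
            a, ok = fit_kinetic_orders(series.log_flux, logP, M)
            identifiable = identifiable and ok
        else:
            a = np.zeros(0)
        alpha[enz] = {m: float(ai) for m, ai in zip(met_ids, a)}
        sat_terms[enz] = M @ a if M.shape[1] else np.zeros(len(series.log_flux))

    rows = []
    for lim in lims:
        sel = np.array(
            [l in (lim, "reference") for l in series.limitations], dtype=bool
        )
        jj = series.log_flux[sel]
        rp, rps, rs, rss = [], [], [], []
        for enz, logP in series.log_protein.items():
            s_p, se_p = rho_protein(jj, logP[sel], transpose=transpose)
            s_s, se_s = rho_saturation(jj, sat_terms[enz][sel], transpose=transpose)
            rp.append(s_p); rps.append(se_p); rs.append(s_s); rss.append(se_s)
        rho_p = float(np.mean(rp))
        rho_s = float(np.mean(rs))
        rows.append(
            {"limitation": lim, "rho_P": rho_p, "rho_P_se": float(np.mean(rps)),
             "rho_S": rho_s, "rho_S_se": float(np.mean(rss)),
             "combined": rho_p + rho_s, "n_conditions": int(sel.sum())}
        )
    per_lim = pd.DataFrame(rows).set_index("limitation")
    status = "ok" if np.isfinite(per_lim[["rho_P", "rho_S"]].values).all() else "not_estimable"
    return RegulationCoefficients(
        reaction_id=series.reaction_id,
        per_limitation=per_lim,
        alpha=alpha,
        status=status,
        reason="" if status == "ok" else REASON_TOO_FEW,
        alpha_identifiable=identifiable,
    )


def analyze_regulation(
    model: StoichiometricModel,
    flux_table: pd.DataFrame,
    protein_table: pd.DataFrame,
    metabolite_table: pd.DataFrame,
    condition_limitations: dict[str, str],
    reference_condition: str,
    band: tuple[float, float] = BAND,
    transpose: bool = False,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Full regulation analysis over all catalyzed reactions.

    Returns a tidy result frame (one row per reaction × limitation) and the
    reason codes for excluded reactions — the auditable "number of considered
    reactions" bookkeeping.
    """
    series, excluded = build_reaction_series(
        model, flux_table, protein_table, metabolite_table,
        condition_limitations, reference_condition,
    )
    rows = []
    for s in series:
        coeffs = analyze_reaction(s, band=band, transpose=transpose)
        for lim, r in coeffs.per_limitation.iterrows():
            rows.append(
                {"reaction": s.reaction_id, "limitation": lim,
                 "rho_P": r["rho_P"], "rho_P_se": r["rho_P_se"],
                 "rho_S": r["rho_S"], "rho_S_se": r["rho_S_se"],
                 "combined": r["combined"], "n_conditions": r["n_conditions"],
                 "alpha": {e: a for e, a in coeffs.alpha.items()},
                 "in_band_P": coeffs.in_band(lim, "rho_P", band),
                 "in_band_combined": coeffs.in_band(lim, "combined", band),
                 "status": coeffs.status,
                 "alpha_identifiable": coeffs.alpha_identifiable}
            )
    return pd.DataFrame(rows), excluded
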