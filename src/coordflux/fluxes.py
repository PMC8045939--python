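"""Constraint-based flux inference: two-step FBA with flux-ratio constraints
plus flux variability analysis.

The inference mirrors ¹³C-constrained FBA practice: measured exchange rates,
the growth rate and (optionally) the O₂ consumption rate band the
corresponding reactions (5% deviation for major exchanges, growth and O₂;
10% for minor exchanges); ¹³C flux-ratio values enter as linear equalities;
step 1 maximizes the ATP-maintenance flux, step 2 fixes that optimum as a
lower bound and minimizes the total absolute flux Σ|v| to yield the reported
distribution. Flux uncertainty comes from variability analysis at a slightly
relaxed optimality (99.99% by default).

All linear programs are solved with scipy's HiGHS backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model import StoichiometricModel
from .physiology import RatePanel

FEASIBILITY_TOL = 1e-9
DEFAULT_DEVIATIONS = {"major": 0.05, "minor": 0.10, "growth": 0.05, "o2": 0.05}


class FluxInferenceError(RuntimeError):
    pass


class InfeasibleProblemError(FluxInferenceError):
    def __init__(self, violated_bands: dict[str, float]):
        self.violated_bands = violated_bands
        names = ", ".join(sorted(violated_bands)) or "unknown"
        super().__init__(f"infeasible problem; violated measured bands: {names}")


class UnboundedProblemError(FluxInferenceError):
    pass


@dataclass
class RatioConstraint:
    """A ¹³C flux-ratio constraint between two reactions.

    ``split`` form: v_a/(v_a+v_b) = r, encoded as (1−r)·v_a − r·v_b = 0,
    with 0 ≤ r ≤ 1. ``pairwise`` form: v_a = r·v_b, with r ≥ 0.
    """

    reaction_a: str
    reaction_b: str
    ratio: float
    form: str = "split"

    def __post_init__(self) -> None:
        if self.form == "split":
            if not 0.0 <= self.ratio <= 1.0:
                raise ValueError("split ratio must lie in [0, 1]")
        elif self.form == "pairwise":
            if self.ratio < 0:
                raise ValueError("pairwise ratio must be >= 0")
        else:
            raise ValueError(f"unknown ratio form {self.form!r}")

    def coefficients(self) -> dict[str, float]:
        if self.form == "split":
            return {self.reaction_a: 1.0 - self.ratio, self.reaction_b: -self.ratio}
        return {self.reaction_a: 1.0, self.reaction_b: -self.ratio}


@dataclass
class FBAProblem:
    model: StoichiometricModel
    bounds: dict[str, tuple[float, float]]       # effective reaction bounds
    banded: dict[str, tuple[float, float]]       # subset set from measurements
    ratio_constraints: list[RatioConstraint] = field(default_factory=list)

    def reaction_ids(self) -> list[str]:
        return list(self.model.reactions)


@dataclass
class FBASolution:
    fluxes: pd.Series
    objective_value: float       # step-1 ATP-maintenance optimum
    total_abs_flux: float
    status: str

    def __getitem__(self, rid: str) -> float:
        return float(self.fluxes[rid])


@dataclass
class FVAResult:
    intervals: pd.DataFrame      # index reaction, columns v_min, v_max
    optimality_fraction: float


# ---------------------------------------------------------------------------
# Problem construction
# ---------------------------------------------------------------------------


def _band(q: float, dev: float) -> tuple[float, float]:
    """Symmetric relative band around a signed rate; exact zero stays pinned."""
    half = dev * abs(q)
    return (q - half, q + half)


def build_fba_problem(
    model: StoichiometricModel,
    rate_panel: RatePanel,
    condition_id: str,
    exchange_mapping: dict[str, str] | None = None,
    o2_rate: float | None = None,
    zero_exchanges: list[str] | None = None,
    deviations: dict[str, float] | None = None,
) -> FBAProblem:
    """Band measured exchange rates, growth and O₂ onto model reactions.

    ``exchange_mapping`` maps measured metabolite names to exchange-reaction
    ids; when omitted, each metabolite is looked up via its exchange reaction
    in the model. Trace-class metabolites are left unconstrained;
    ``zero_exchanges`` (e.g. pyruvate/lactate/ethanol analogs) are pinned to
    zero.
    """
    dev = dict(DEFAULT_DEVIATIONS)
    if deviations:
        dev.update(deviations)
    bounds = {
        rid: (r.lower_bound, r.upper_bound) for rid, r in model.reactions.items()
    }
    banded: dict[str, tuple[float, float]] = {}

    def resolve(met: str) -> str:
        if exchange_mapping and met in exchange_mapping:
            rid = exchange_mapping[met]
            if rid not in model.reactions:
                raise FluxInferenceError(f"mapped exchange {rid!r} not in model")
            return rid
        rid = model.exchange_for(met)
        if rid is None:
            raise FluxInferenceError(
                f"measured metabolite {met!r} has no exchange reaction in the model"
            )
        return rid

    for _, row in rate_panel.condition_rates(condition_id).iterrows():
        met, q, cls = row["metabolite"], float(row["q"]), row["class"]
        if cls == "trace":
            continue
        rid = resolve(met)
        d = dev["major"] if cls == "major" else dev["minor"]
        band = _band(q, d)
        bounds[rid] = band
        banded[rid] = band

    mu = rate_panel.mu(condition_id)
    band = _band(mu, dev["growth"])
    bounds[model.biomass_id] = band
    banded[model.biomass_id] = band

    if o2_rate is not None:
        rid = resolve("o2")
        band = _band(o2_rate, dev["o2"])
        bounds[rid] = band
        banded[rid] = band

    for met in zero_exchanges or []:
        rid = resolve(met)
        bounds[rid] = (0.0, 0.0)
        banded[rid] = (0.0, 0.0)

    for rid, (lb, ub) in bounds.items():
        if lb > ub:
            raise FluxInferenceError(f"empty bound band on reaction {rid!r}")
    return FBAProblem(model=model, bounds=bounds, banded=banded)


def add_ratio_constraints(
    problem: FBAProblem, ratios: list[RatioConstraint]
) -> FBAProblem:
    """Append flux-ratio equalities to the problem (returns the same object)."""
    for rc in ratios:
        for rid in (rc.reaction_a, rc.reaction_b):
            if rid not in problem.model.reactions:
                raise FluxInferenceError(f"ratio constraint references unknown {rid!r}")
    problem.ratio_constraints.extend(ratios)
    return problem


# ---------------------------------------------------------------------------
# LP assembly and solving
# ---------------------------------------------------------------------------


def _equality_system(problem: FBAProblem):
    S, met_ids, rxn_ids = problem.model.stoichiometric_matrix()
    rows = [S]
    rhs = [np.zeros(S.shape[0])]
    idx = {rid: j for j, rid in enumerate(rxn_ids)}
    for rc in problem.ratio_constraints:
        row = np.zeros(len(rxn_ids))
        for rid, coef in rc.coefficients().items():
            row[idx[rid]] = coef
        rows.append(row[None, :])
        rhs.append(np.zeros(1))
    return np.vstack(rows), np.concatenate(rhs), rxn_ids


def _lp(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": 1e-10,
            "dual_feasibility_tolerance": 1e-10,
        },
    )
    return res


def _diagnose_infeasibility(problem: FBAProblem) -> dict[str, float]:
    """Elastic relaxation: minimal slack on each measured band that restores
    feasibility; returns the bands needing positive slack."""
    A_eq, b_eq, rxn_ids = _equality_system(problem)
    n = len(rxn_ids)
    banded_ids = [rid for rid in rxn_ids if rid in problem.banded]
    m = len(banded_ids)
    if m == 0:
        return {}
    # variables: v (n), s (m) >= 0
    bounds = []
    for rid in rxn_ids:
        if rid in problem.banded:
            bounds.append((None, None))
        else:
            bounds.append(problem.bounds[rid])
    bounds += [(0, None)] * m
    A_eq_full = np.hstack([A_eq, np.zeros((A_eq.shape[0], m))])
    rows, rhs = [], []
    for k, rid in enumerate(banded_ids):
        j = rxn_ids.index(rid)
        lb, ub = problem.banded[rid]
        r1 = np.zeros(n + m); r1[j] = 1.0; r1[n + k] = -1.0
        rows.append(r1); rhs.append(ub)           # v - s <= ub
        r2 = np.zeros(n + m); r2[j] = -1.0; r2[n + k] = -1.0
        rows.append(r2); rhs.append(-lb)          # -v - s <= -lb
    c = np.concatenate([np.zeros(n), np.ones(m)])
    res = _lp(c, A_eq_full, b_eq, bounds, np.array(rows), np.array(rhs))
    if not res.success:
        return {}
    slack = res.x[n:]
    return {rid: float(s) for rid, s in zip(banded_ids, slack) if s > 1e-7}


def solve_two_step(problem: FBAProblem, tie_break_l2: float = 0.0) -> FBASolution:
    """Maximize ATP maintenance, then minimize Σ|v| at that optimum.

    Step 2 enforces v_ATPM ≥ optimum (within a small numerical relaxation)
    and minimizes total absolute flux via auxiliary variables t ≥ |v|; an
    optional quadratic tie-breaker of weight ``tie_break_l2`` selects the
    minimum-norm point of a degenerate optimal face.
    """
    A_eq, b_eq, rxn_ids = _equality_system(problem)
    n = len(rxn_ids)
    v_bounds = [problem.bounds[rid] for rid in rxn_ids]
    obj_idx = rxn_ids.index(problem.model.atp_maintenance_id)

    # step 1: maximize ATP-maintenance flux
    c = np.zeros(n)
    c[obj_idx] = -1.0
    res1 = _lp(c, A_eq, b_eq, v_bounds)
    if res1.status == 3:
        raise UnboundedProblemError(
            f"objective {problem.model.atp_maintenance_id!r} is unbounded; "
            "check exchange and maintenance bounds"
        )
    if not res1.success:
        raise InfeasibleProblemError(_diagnose_infeasibility(problem))
    atp_opt = float(res1.x[obj_idx])

    v = _minimize_total_flux(problem, atp_opt)
    if tie_break_l2 > 0:
        v = _l2_tie_break(problem, atp_opt, v, tie_break_l2)
    fluxes = pd.Series(v, index=rxn_ids)
    return FBASolution(
        fluxes=fluxes,
        objective_value=atp_opt,
        total_abs_flux=float(np.abs(v).sum()),
        status="optimal",
    )


def _minimize_total_flux(problem: FBAProblem, atp_opt: float) -> np.ndarray:
    A_eq, b_eq, rxn_ids = _equality_system(problem)
    n = len(rxn_ids)
    obj_idx = rxn_ids.index(problem.model.atp_maintenance_id)
    # variables [v, t]; t_j >= |v_j|
    A_eq_full = np.hstack([A_eq, np.zeros((A_eq.shape[0], n))])
    rows, rhs = [], []
    for j in range(n):
        r1 = np.zeros(2 * n); r1[j] = 1.0; r1[n + j] = -1.0
        rows.append(r1); rhs.append(0.0)          # v - t <= 0
        r2 = np.zeros(2 * n); r2[j] = -1.0; r2[n + j] = -1.0
        rows.append(r2); rhs.append(0.0)          # -v - t <= 0
    r3 = np.zeros(2 * n); r3[obj_idx] = -1.0
    rows.append(r3)
    rhs.append(-(atp_opt - FEASIBILITY_TOL * max(1.0, abs(atp_opt))))
    bounds = [problem.bounds[rid] for rid in rxn_ids] + [(0, None)] * n
    c = np.concatenate([np.zeros(n), np.ones(n)])
    res = _lp(c, A_eq_full, b_eq, bounds, np.array(rows), np.array(rhs))
    if not res.success:
        raise InfeasibleProblemError(_diagnose_infeasibility(problem))
    return res.x[:n]


def _l2_tie_break(
    problem: FBAProblem, atp_opt: float, v0: np.ndarray, weight: float
) -> np.ndarray:
    """Pick the minimum-L2 point on the Σ|v|-optimal face (small models only)."""
    from scipy.optimize import minimize

    A_eq, b_eq, rxn_ids = _equality_system(problem)
    obj_idx = rxn_ids.index(problem.model.atp_maintenance_id)
    total0 = float(np.abs(v0).sum())
    cons = [
        {"type": "eq", "fun": lambda v, A=A_eq, b=b_eq: A @ v - b},
        {"type": "ineq", "fun": lambda v: v[obj_idx] - atp_opt + 1e-8},
        {"type": "ineq", "fun": lambda v: total0 + 1e-8 - np.abs(v).sum()},
    ]
    res = minimize(
        lambda v: weight * float(v @ v),
        v0,
        bounds=[problem.bounds[rid] for rid in rxn_ids],
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    return res.x if res.success else v0


def flux_variability(
    problem: FBAProblem,
    atp_optimum: float,
    optimality_fraction: float = 0.9999,
    reactions: list[str] | None = None,
    require_optimality: bool = True,
) -> FVAResult:
    """Per-reaction flux ranges subject to v_ATPM ≥ fraction · optimum.

    With ``require_optimality=False`` the objective constraint is dropped and
    the intervals are the plain feasible ranges under the measured bands.
    """
    A_eq, b_eq, rxn_ids = _equality_system(problem)
    n = len(rxn_ids)
    obj_idx = rxn_ids.index(problem.model.atp_maintenance_id)
    bounds = [problem.bounds[rid] for rid in rxn_ids]
    if require_optimality:
        A_ub = np.zeros((1, n)); A_ub[0, obj_idx] = -1.0
        b_ub = np.array([-(optimality_fraction * atp_optimum)])
    else:
        A_ub = b_ub = None
    targets = reactions if reactions is not None else rxn_ids
    recs = {}
    for rid in targets:
        j = rxn_ids.index(rid)
        c = np.zeros(n)
        c[j] = 1.0
        lo = _lp(c, A_eq, b_eq, bounds, A_ub, b_ub)
        hi = _lp(-c, A_eq, b_eq, bounds, A_ub, b_ub)
        if not (lo.success and hi.success):
            raise InfeasibleProblemError(_diagnose_infeasibility(problem))
        recs[rid] = (float(lo.x[j]), float(hi.x[j]))
    df = pd.DataFrame(recs, index=["v_min", "v_max"]).T
    return FVAResult(intervals=df, optimality_fraction=optimality_fraction
                     if require_optimality else 0.0)


def mass_balance_residual(model: StoichiometricModel, fluxes: pd.Series) -> float:
    """‖S·v‖∞ over internal metabolites."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    v = fluxes.reindex(rxn_ids).values
    return float(np.max(np.abs(S @ v)))
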