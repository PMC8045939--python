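import numpy as np
import pandas as pd
import pytest

from conftest import model_bounds
from oracles import vertex_enumeration_lp

from coordflux.fluxes import (
    FBAProblem,
    InfeasibleProblemError,
    RatioConstraint,
    UnboundedProblemError,
    add_ratio_constraints,
    build_fba_problem,
    flux_variability,
    mass_balance_residual,
    solve_two_step,
)
from coordflux.model import Metabolite, Reaction, StoichiometricModel
from coordflux.physiology import RatePanel, estimate_rate_panel
from coordflux.pipeline import infer_fluxes


def make_problem(model, ratios=()):
    problem = FBAProblem(model=model, bounds=model_bounds(model), banded={})
    return add_ratio_constraints(problem, list(ratios))


class TestRatioConstraints:
    def test_split_half_means_equal_branches(self):
        rc = RatioConstraint("A", "B", 0.5, "split")
        assert rc.coefficients() == {"A": 0.5, "B": -0.5}

    def test_split_one_pins_branch_b(self, branch_model):
        problem = make_problem(branch_model, [RatioConstraint("BR_A", "BR_B", 1.0)])
        # v_b must be 0, but the secretion band requires >= 1.8 -> infeasible
        with pytest.raises(InfeasibleProblemError):
            solve_two_step(problem)

    def test_split_bad_range_rejected(self):
        with pytest.raises(ValueError):
            RatioConstraint("A", "B", 1.2, "split")

    def test_split_eighty_twenty_partition(self, branch_model):
        problem = make_problem(branch_model, [RatioConstraint("BR_A", "BR_B", 0.8)])
        sol = solve_two_step(problem)
        total = sol["BR_A"] + sol["BR_B"]
        assert sol["BR_A"] == pytest.approx(0.8 * total, abs=1e-9)


class TestTwoStepFBA:
    def test_worked_branch_example_atp_optimum(self, branch_model):
        """Uptake banded [9.5, 10.5], 80/20 split, secretion banded [1.8, 2.2]:
        the ATP optimum is 0.8 · 10.5 = 8.4 by hand."""
        problem = make_problem(branch_model, [RatioConstraint("BR_A", "BR_B", 0.8)])
        sol = solve_two_step(problem)
        assert sol.objective_value == pytest.approx(8.4, abs=1e-9)
        assert mass_balance_residual(branch_model, sol.fluxes) <= 1e-9

    def test_matches_vertex_enumeration_oracle(self, branch_model):
        for r in (None, 0.8, 0.82):
            ratios = [] if r is None else [RatioConstraint("BR_A", "BR_B", r)]
            problem = make_problem(branch_model, ratios)
            sol = solve_two_step(problem)
            A_eq, b_eq, rxn_ids = _equalities(problem)
            lb = [problem.bounds[x][0] for x in rxn_ids]
            ub = [problem.bounds[x][1] for x in rxn_ids]
            c = np.zeros(len(rxn_ids))
            c[rxn_ids.index("ATPM")] = 1.0
            best, _ = vertex_enumeration_lp(c, A_eq, b_eq, lb, ub, maximize=True)
            assert sol.objective_value == pytest.approx(best, abs=1e-6)

    def test_step2_total_flux_not_larger_than_step1(self, branch_model):
        from coordflux.fluxes import _equality_system, _lp

        problem = make_problem(branch_model, [RatioConstraint("BR_A", "BR_B", 0.8)])
        sol = solve_two_step(problem)
        A_eq, b_eq, rxn_ids = _equality_system(problem)
        c = np.zeros(len(rxn_ids))
        c[rxn_ids.index("ATPM")] = -1.0
        res1 = _lp(c, A_eq, b_eq, [problem.bounds[r] for r in rxn_ids])
        assert sol.total_abs_flux <= np.abs(res1.x).sum() + 1e-9

    def test_agrees_with_cobra_oracle(self, branch_model):
        """Step-1 objective equals cobra's FBA optimum on the same network."""
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("branch")
        mets = {m: cobra.Metabolite(m) for m in branch_model.metabolites}
        for rid, r in branch_model.reactions.items():
            cr = cobra.Reaction(rid)
            cr.lower_bound, cr.upper_bound = r.lower_bound, r.upper_bound
            cm.add_reactions([cr])
            cr.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        cm.objective = "ATPM"
        expected = cm.optimize().objective_value
        sol = solve_two_step(make_problem(branch_model))
        assert sol.objective_value == pytest.approx(expected, abs=1e-6)

    def test_contradictory_bands_reported(self, branch_model):
        m = branch_model
        m.reactions["EX_b"].lower_bound = 8.9   # forces uptake >= 11.125
        m.reactions["EX_b"].upper_bound = 9.0
        problem = FBAProblem(
            model=m, bounds=model_bounds(m),
            banded={"EX_in": (-10.5, -9.5), "EX_b": (8.9, 9.0)},
        )
        add_ratio_constraints(problem, [RatioConstraint("BR_A", "BR_B", 0.8)])
        with pytest.raises(InfeasibleProblemError) as err:
            solve_two_step(problem)
        assert set(err.value.violated_bands) & {"EX_in", "EX_b"}

    def test_unbounded_objective_reported(self):
        mets = {"a": Metabolite("a"), "atp": Metabolite("atp")}
        rxns = {
            "EX_in": Reaction("EX_in", {"a": -1.0}, -np.inf, 0.0, is_exchange=True),
            "MK": Reaction("MK", {"a": -1.0, "atp": 1.0}, 0.0, np.inf),
            "ATPM": Reaction("ATPM", {"atp": -1.0}, 0.0, np.inf),
        }
        m = StoichiometricModel(mets, rxns, "ATPM", "MK")
        with pytest.raises(UnboundedProblemError):
            solve_two_step(make_problem(m))


class TestBuildProblem:
    def _panel(self):
        growth = pd.DataFrame([{"condition_id": "c1", "mu": 0.5, "mu_stderr": 0.0}])
        rates = pd.DataFrame(
            [
                {"condition_id": "c1", "metabolite": "glc", "q": -10.0,
                 "q_stderr": 0.0, "class": "major"},
                {"condition_id": "c1", "metabolite": "akg", "q": 0.02,
                 "q_stderr": 0.0, "class": "minor"},
                {"condition_id": "c1", "metabolite": "ace", "q": 0.001,
                 "q_stderr": 0.0, "class": "trace"},
            ]
        )
        return RatePanel(growth=growth, rates=rates)

    def test_deviation_bands(self, toy_model):
        problem = build_fba_problem(toy_model, self._panel(), "c1")
        assert problem.bounds["EX_glc"] == pytest.approx((-10.5, -9.5))
        assert problem.bounds["EX_akg"] == pytest.approx((0.018, 0.022))
        # trace metabolite left at model bounds
        assert problem.bounds["EX_ace"] == (0.0, 1000.0)
        assert problem.bounds["BIOMASS"] == pytest.approx((0.475, 0.525))

    def test_zero_exchanges_pinned(self, toy_model):
        problem = build_fba_problem(
            toy_model, self._panel(), "c1", zero_exchanges=["lac"]
        )
        assert problem.bounds["EX_lac"] == (0.0, 0.0)

    def test_unmapped_metabolite_is_an_error(self, toy_model):
        panel = self._panel()
        panel.rates.loc[0, "metabolite"] = "unknown_met"
        with pytest.raises(Exception, match="unknown_met"):
            build_fba_problem(toy_model, panel, "c1")


class TestFVA:
    def test_secretion_pinned_at_full_optimality(self, branch_model):
        problem = make_problem(branch_model, [RatioConstraint("BR_A", "BR_B", 0.8)])
        sol = solve_two_step(problem)
        fva = flux_variability(problem, sol.objective_value, optimality_fraction=1.0)
        lo, hi = fva.intervals.loc["BR_B"]
        assert lo == pytest.approx(2.1, abs=1e-7)
        assert hi == pytest.approx(2.1, abs=1e-7)

    def test_intervals_contain_solution_and_never_shrink(self, branch_model):
        problem = make_problem(branch_model, [RatioConstraint("BR_A", "BR_B", 0.8)])
        sol = solve_two_step(problem)
        tight = flux_variability(problem, sol.objective_value, 1.0)
        relaxed = flux_variability(problem, sol.objective_value, 0.9999)
        for rid in tight.intervals.index:
            lo_t, hi_t = tight.intervals.loc[rid]
            lo_r, hi_r = relaxed.intervals.loc[rid]
            assert lo_t - 1e-7 <= sol[rid] <= hi_t + 1e-7
            assert lo_r <= lo_t + 1e-9 and hi_r >= hi_t - 1e-9


class TestRecoveryOnSyntheticData:
    def test_exact_recovery_with_zero_deviation_bands(self, zero_noise_dataset):
        ds = zero_noise_dataset
        panel = estimate_rate_panel(ds.od_timecourses, ds.conc_timecourses)
        cids = [c.id for c in ds.conditions]
        flux, _, residuals = infer_fluxes(
            ds.model, panel, ds.flux_ratios, cids,
            zero_exchanges=("lac",),
            deviations={"major": 0.0, "minor": 0.0, "growth": 0.0},
            run_fva=False,
        )
        truth = ds.ground_truth.fluxes.reindex(flux.index)[flux.columns]
        assert (flux - truth).abs().max().max() < 1e-6
        assert max(residuals.values()) <= 1e-9

    def test_recovery_within_feasible_band_widths(self, zero_noise_dataset):
        """Under the default 5%/10% bands both the truth and the inferred flux
        lie in each reaction's feasible interval, so they agree to within the
        widths the measurement bands permit."""
        ds = zero_noise_dataset
        panel = estimate_rate_panel(ds.od_timecourses, ds.conc_timecourses)
        cids = [c.id for c in ds.conditions][:4]
        flux, _, _ = infer_fluxes(
            ds.model, panel, ds.flux_ratios, cids,
            zero_exchanges=("lac",), run_fva=False,
        )
        for cid in cids:
            problem = build_fba_problem(
                ds.model, panel, cid, zero_exchanges=["lac"]
            )
            sub = ds.flux_ratios[ds.flux_ratios["condition_id"] == cid]
            add_ratio_constraints(problem, [
                RatioConstraint(r.reaction_a, r.reaction_b, r.value, r.form)
                for r in sub.itertuples()
            ])
            iv = flux_variability(problem, 0.0, require_optimality=False)
            for rid in iv.intervals.index:
                lo, hi = iv.intervals.loc[rid]
                truth = ds.ground_truth.fluxes.loc[rid, cid]
                assert lo - 1e-6 <= truth <= hi + 1e-6
                assert abs(flux.loc[rid, cid] - truth) <= (hi - lo) + 1e-6


def _equalities(problem):
    from coordflux.fluxes import _equality_system

    return _equality_system(problem)
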