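import numpy as np
import pandas as pd
import pytest

from oracles import grid_search_bounded_fit, ols_slope

from coordflux.regulation import (
    RegulationError,
    analyze_regulation,
    fit_kinetic_orders,
    fraction_in_band,
    interpolate_to_growth_rate,
    normalize_log_to_reference,
    rho_protein,
    rho_saturation,
    sector_fraction,
)
from coordflux.synth import TRUE_ALPHA, simulate_regulation_benchmark


class TestNormalization:
    def test_reference_maps_to_zero_and_e_to_one(self):
        s = pd.Series({"ref": 2.0, "a": 2.0 * np.e})
        out = normalize_log_to_reference(s, "ref")
        assert out["ref"] == 0.0
        assert out["a"] == pytest.approx(1.0)

    def test_zero_flux_raises_for_exclusion(self):
        with pytest.raises(RegulationError):
            normalize_log_to_reference(pd.Series({"ref": 1.0, "a": 0.0}), "ref")


class TestInterpolation:
    PROFILE = [(0.2, 1.0), (0.4, 2.0), (0.6, 3.0)]

    def test_midpoint(self):
        val, flagged = interpolate_to_growth_rate(self.PROFILE, 0.3)
        assert val == pytest.approx(1.5) and not flagged

    def test_node_identity(self):
        val, flagged = interpolate_to_growth_rate(self.PROFILE, 0.4)
        assert val == pytest.approx(2.0) and not flagged

    def test_extrapolation_is_flagged(self):
        val, flagged = interpolate_to_growth_rate(self.PROFILE, 0.7)
        assert val == pytest.approx(3.5) and flagged

    def test_duplicate_mu_rejected(self):
        with pytest.raises(RegulationError):
            interpolate_to_growth_rate([(0.2, 1.0), (0.2, 2.0)], 0.3)


class TestRhoSlopes:
    def test_proportional_changes_give_one(self):
        logJ = np.log([1, 2, 4])
        assert rho_protein(logJ, np.log([1, 2, 4]))[0] == pytest.approx(1.0)

    def test_constant_protein_gives_zero(self):
        logJ = np.log([1, 2, 4])
        assert rho_protein(logJ, np.zeros(3))[0] == pytest.approx(0.0)

    def test_antiproportional_gives_minus_one(self):
        logJ = np.log([1, 2, 4])
        assert rho_protein(logJ, np.log([4, 2, 1]))[0] == pytest.approx(-1.0)

    def test_saturation_term_equal_to_flux_gives_one(self):
        logJ = np.log([1, 2, 4])
        assert rho_saturation(logJ, logJ.copy())[0] == pytest.approx(1.0)

    def test_constant_saturation_gives_zero(self):
        logJ = np.log([1, 2, 4])
        assert rho_saturation(logJ, np.zeros(3))[0] == pytest.approx(0.0)

    def test_slope_and_stderr_match_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 12)
        y = 0.7 * x + rng.normal(0, 0.2, 12)
        slope, se = rho_protein(x, y)
        s_o, se_o = ols_slope(x, y)
        assert slope == pytest.approx(s_o, abs=1e-12)
        assert se == pytest.approx(se_o, abs=1e-12)

    def test_decomposition_identity(self):
        """log P + s = log J per condition implies rho_P + rho_S = 1."""
        rng = np.random.default_rng(1)
        logJ = rng.normal(0, 0.5, 9)
        logP = 0.4 * logJ + rng.normal(0, 0.1, 9)
        s = logJ - logP
        assert rho_protein(logJ, logP)[0] + rho_saturation(logJ, s)[0] == \
            pytest.approx(1.0, abs=1e-9)


class TestKineticOrders:
    def test_exact_interior_solution(self):
        logM = np.linspace(-1, 1, 9)
        y = 2.0 * logM  # logJ - logP
        alpha, ok = fit_kinetic_orders(y, np.zeros(9), logM[:, None])
        assert ok and alpha[0] == pytest.approx(2.0, abs=1e-9)

    def test_bound_active_at_four(self):
        logM = np.linspace(-1, 1, 9)
        alpha, _ = fit_kinetic_orders(6.0 * logM, np.zeros(9), logM[:, None])
        assert alpha[0] == pytest.approx(4.0, abs=1e-12)

    def test_two_substrates_match_grid_oracle(self):
        rng = np.random.default_rng(4)
        M = np.column_stack([rng.normal(0, 0.8, 17), rng.normal(0, 0.8, 17)])
        y = M @ np.array([1.3, 0.4]) + rng.normal(0, 0.05, 17)
        alpha, ok = fit_kinetic_orders(y, np.zeros(17), M)
        a_grid, _ = grid_search_bounded_fit(y, M, step=0.01)
        assert ok
        assert np.allclose(alpha, a_grid, atol=0.011)

    def test_rank_deficiency_flagged(self):
        M = np.column_stack([np.ones(6), np.ones(6)]) * np.linspace(0, 1, 6)[:, None]
        _, ok = fit_kinetic_orders(np.linspace(0, 1, 6), np.zeros(6), M)
        assert not ok

    def test_recovery_benchmark_median_error(self):
        """200 reactions, 17 conditions, lognormal sigma=0.1 noise on P and M:
        median |alpha_hat - alpha| <= 0.3 and median rho_P error <= 0.15."""
        bench = simulate_regulation_benchmark(n_reactions=200, seed=7, sigma=0.1)
        a_err, r_err = [], []
        for rid, grp in bench.groupby("reaction"):
            alpha, _ = fit_kinetic_orders(
                grp["logJ"].values, grp["logP"].values, grp["logM"].values[:, None]
            )
            a_err.append(abs(alpha[0] - grp["alpha_true"].iloc[0]))
            for lim in ("catabolic", "anabolic"):
                sel = grp["limitation"].isin([lim, "reference"])
                slope, _ = rho_protein(grp.loc[sel, "logJ"].values,
                                       grp.loc[sel, "logP"].values)
                r_err.append(abs(slope - grp[f"rho_p_true_{lim}"].iloc[0]))
        assert np.median(a_err) <= 0.3
        assert np.median(r_err) <= 0.15

    def test_true_slope_above_four_clamps_to_bound(self):
        bench = simulate_regulation_benchmark(
            n_reactions=20, seed=9, sigma=0.1, alpha_range=(5.0, 7.0)
        )
        for rid, grp in bench.groupby("reaction"):
            alpha, _ = fit_kinetic_orders(
                grp["logJ"].values, grp["logP"].values, grp["logM"].values[:, None]
            )
            assert alpha[0] == pytest.approx(4.0, abs=1e-9)


class TestAggregationAndBand:
    def test_fraction_in_band_counts_closed_interval(self):
        assert fraction_in_band([0.4, 0.7, 1.2, 1.8]) == pytest.approx(0.5)
        assert fraction_in_band([0.5, 1.5, 1.0]) == 1.0

    def test_non_estimable_excluded_from_denominator(self):
        assert fraction_in_band([np.nan, 1.0]) == 1.0

    def test_empty_list_rejected(self):
        with pytest.raises(RegulationError):
            fraction_in_band([])

    def test_sector_fraction_even_split(self):
        mass = pd.DataFrame({"c1": [1.0, 1.0]}, index=["p1", "p2"])
        sf = sector_fraction(mass, {"p1": "catabolic", "p2": "anabolic"})
        assert sf.loc["catabolic", "c1"] == pytest.approx(0.5)
        assert sf.loc["anabolic", "c1"] == pytest.approx(0.5)

    def test_unassigned_goes_to_other(self):
        mass = pd.DataFrame({"c1": [3.0]}, index=["px"])
        sf = sector_fraction(mass, {})
        assert sf.loc["other", "c1"] == 1.0


class TestEndToEndOnGroundTruth:
    def test_zero_noise_identity_and_alpha_recovery(self, zero_noise_dataset):
        ds = zero_noise_dataset
        gt = ds.ground_truth
        lims = {c.id: c.limitation for c in ds.conditions}
        reg, excluded = analyze_regulation(
            ds.model, gt.fluxes, gt.proteins, gt.metabolites, lims, "ref"
        )
        assert np.abs(reg["combined"] - 1.0).max() < 1e-6
        # overflow/dead-end reactions are excluded via the zero-flux rule
        assert excluded["ACK"] == "zero_flux_in_some_condition"
        assert excluded["LDH"] == "zero_flux_in_some_condition"
        for row in reg.itertuples():
            for enz, alphas in row.alpha.items():
                for met, val in alphas.items():
                    assert val == pytest.approx(
                        TRUE_ALPHA[row.reaction][met], abs=1e-6
                    )

    def test_isoenzyme_average_equals_members(self, zero_noise_dataset):
        ds = zero_noise_dataset
        gt = ds.ground_truth
        lims = {c.id: c.limitation for c in ds.conditions}
        reg, _ = analyze_regulation(
            ds.model, gt.fluxes, gt.proteins, gt.metabolites, lims, "ref"
        )
        # TA1's two isoenzymes are proportional, so the average equals each
        ta1 = reg[reg["reaction"] == "TA1"].iloc[0]
        assert set(ta1["alpha"]) == {"ilvE", "avtA"}

    def test_directionality_and_band_ordering(self, zero_noise_dataset):
        """Anabolic limitation: transaminase protein rises while flux falls
        (rho_P < 0), and fewer reactions stay in the [0.5, 1.5] band than
        under catabolic limitation."""
        ds = zero_noise_dataset
        gt = ds.ground_truth
        lims = {c.id: c.limitation for c in ds.conditions}
        reg, _ = analyze_regulation(
            ds.model, gt.fluxes, gt.proteins, gt.metabolites, lims, "ref"
        )
        ta_ana = reg[(reg["reaction"] == "TA1") & (reg["limitation"] == "anabolic")]
        assert ta_ana["rho_P"].iloc[0] < 0
        frac = {
            lim: fraction_in_band(grp["rho_P"])
            for lim, grp in reg.groupby("limitation")
        }
        assert frac["catabolic"] > frac["anabolic"]

    def test_sector_trends_from_observed_masses(self, zero_noise_dataset):
        from scipy.stats import spearmanr

        ds = zero_noise_dataset
        sf = sector_fraction(ds.protein_mass.wide(), ds.sector_assignment)
        for lim, expected_sign in (("catabolic", -1), ("anabolic", 1)):
            conds = sorted((c for c in ds.conditions if c.limitation == lim),
                           key=lambda c: c.growth_rate)
            mus = [c.growth_rate for c in conds]
            fr = [sf.loc["catabolic", c.id] for c in conds]
            rho, _ = spearmanr(mus, fr)
            assert np.sign(rho) == expected_sign
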