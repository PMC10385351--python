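import numpy as np
import pandas as pd
import pytest

from augbreed.augmented_design import (
    adjust,
    anova_augmented,
    block_effects,
    check_anova,
    cv_percent,
    federer_weighted_mean,
)
from augbreed.synthetic_data import SimulationConfig, TraitSim, simulate_trial
from augbreed.traits_io import TrialValidationError

from conftest import build_trial
from oracles import ls_fit_augmented, rcbd_residual_ms


def random_trial(rng, n_blocks, n_checks, n_tests):
    checks = rng.normal(10, 3, size=(n_checks, n_blocks))
    tests = {f"g{i}": float(rng.normal(10, 3)) for i in range(n_tests)}
    blocks = {g: f"B{(i % n_blocks) + 1}" for i, g in enumerate(tests)}
    return build_trial(checks, tests, blocks)


class TestCheckAnova:
    def test_additive_data_has_zero_error(self):
        # values = check effect + block effect exactly -> residual 0
        check_eff = np.array([1.0, 4.0, 6.0])
        block_eff = np.array([0.0, 2.0])
        values = check_eff[:, None] + block_eff[None, :]
        table = build_trial(values, {"g1": 5.0}, {"g1": "B1"})
        assert check_anova(table, "y").error_ms == pytest.approx(0.0, abs=1e-12)

    def test_matches_least_squares_residual(self, toy_trial):
        ca = check_anova(toy_trial, "y")
        oracle = rcbd_residual_ms(np.array([[1.0, 2.0], [3.0, 5.0]]))
        assert ca.error_ms == pytest.approx(oracle, abs=1e-10)
        assert ca.error_df == 1

    def test_invariant_to_block_relabeling(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(3, 4))
        t1 = build_trial(values, {"g1": 0.0}, {"g1": "B1"})
        t2 = build_trial(values[:, ::-1], {"g1": 0.0}, {"g1": "B1"})
        assert check_anova(t1, "y").error_ms == pytest.approx(
            check_anova(t2, "y").error_ms)

    def test_missing_check_plot_aborts(self, toy_trial):
        data = toy_trial.data.copy()
        data.loc[(data.genotype_id == "check1") & (data.block == "B2"),
                 "y"] = np.nan
        # bypass construction-time completeness by rebuilding trait frame
        table = build_trial(np.array([[1.0, 2.0], [3.0, 5.0]]),
                            {"g1": 10.0}, {"g1": "B1"})
        table.data.loc[(table.data.genotype_id == "check1")
                       & (table.data.block == "B2"), "y"] = np.nan
        with pytest.raises(TrialValidationError, match="check1"):
            check_anova(table, "y")


class TestBlockEffects:
    def test_identical_blocks_zero_effects(self):
        values = np.tile(np.array([[1.0], [5.0]]), (1, 3))
        table = build_trial(values, {"g1": 2.0}, {"g1": "B2"})
        assert np.allclose(block_effects(table, "y"), 0.0)

    def test_uniform_offset_splits_evenly(self):
        # block 2 uniformly +10 over block 1 -> effects {-5, +5}
        values = np.array([[1.0, 11.0], [4.0, 14.0]])
        table = build_trial(values, {"g1": 0.0}, {"g1": "B1"})
        eff = block_effects(table, "y")
        assert eff["B1"] == pytest.approx(-5.0)
        assert eff["B2"] == pytest.approx(+5.0)

    def test_location_invariance_and_zero_sum(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=(4, 3))
        t1 = build_trial(values, {"g1": 0.0}, {"g1": "B1"})
        t2 = build_trial(values + 100.0, {"g1": 100.0}, {"g1": "B1"})
        e1, e2 = block_effects(t1, "y"), block_effects(t2, "y")
        assert np.allclose(e1, e2)
        assert e1.sum() == pytest.approx(0.0, abs=1e-10)


class TestAdjust:
    def test_zero_effects_leave_raw_values(self):
        values = np.tile(np.array([[1.0], [5.0]]), (1, 2))
        table = build_trial(values, {"g1": 7.0, "g2": 9.0},
                            {"g1": "B1", "g2": "B2"})
        adj = adjust(table, "y")
        assert adj.adjusted["g1"] == pytest.approx(7.0)
        assert adj.adjusted["g2"] == pytest.approx(9.0)

    def test_noiseless_simulation_recovers_genotype_effects(self):
        traits = [TraitSim("y", mean=50.0, sigma_g2=9.0, sigma_e2=0.0,
                           block_sd=3.0)]
        config = SimulationConfig(
            traits=traits, n_blocks=3, check_ids=("c1", "c2", "c3"),
            populations={"P": 12}, seed=5)
        table, truth = simulate_trial(config)
        adj = adjust(table, "y")
        expected = 50.0 + truth.genotype_effects.loc[adj.adjusted.index, "y"]
        assert np.allclose(adj.adjusted, expected, atol=1e-9)

    def test_block_shifts_summing_to_zero_leave_adjusted_values(self):
        from augbreed.traits_io import TraitSpec, TrialTable

        rng = np.random.default_rng(13)
        table = random_trial(rng, 3, 3, 6)
        adj1 = adjust(table, "y").adjusted
        shifts = {"B1": 42.0, "B2": -30.0, "B3": -12.0}  # sums to zero
        shifted = table.data.copy()
        for blk, c in shifts.items():
            shifted.loc[shifted.block == blk, "y"] += c
        table2 = TrialTable(shifted, [TraitSpec("y")])
        adj2 = adjust(table2, "y").adjusted
        assert np.allclose(adj1, adj2)

    def test_general_block_shift_moves_adjusted_by_mean_shift_only(self):
        """Only block contrasts are identifiable: an arbitrary per-block
        shift moves every adjusted value by the mean shift, so genotype
        contrasts stay put."""
        from augbreed.traits_io import TraitSpec, TrialTable

        rng = np.random.default_rng(14)
        table = random_trial(rng, 3, 3, 6)
        adj1 = adjust(table, "y").adjusted
        shifted = table.data.copy()
        shifted.loc[shifted.block == "B2", "y"] += 42.0
        table2 = TrialTable(shifted, [TraitSpec("y")])
        adj2 = adjust(table2, "y").adjusted
        assert np.allclose(adj2 - adj1, 42.0 / 3)

    @pytest.mark.parametrize("n_blocks, n_checks, n_tests", [
        (2, 2, 3), (3, 3, 6), (4, 3, 6),
    ])
    def test_least_squares_equivalence(self, n_blocks, n_checks, n_tests):
        """Check-mean adjustment equals the direct LS fit of the model:
        identical test-genotype contrasts and identical error MS."""
        rng = np.random.default_rng(100 + n_blocks)
        table = random_trial(rng, n_blocks, n_checks, n_tests)
        adj = adjust(table, "y")
        effects, error_ms, genotypes = ls_fit_augmented(table, "y")
        assert adj.error_ms == pytest.approx(error_ms, abs=1e-8)
        tests = list(adj.adjusted.index)
        ours = adj.adjusted
        for g1 in tests[1:]:
            assert (ours[g1] - ours[tests[0]]) == pytest.approx(
                effects[g1] - effects[tests[0]], abs=1e-8)
        # check-vs-test contrasts are identifiable too
        check_means = adj.check_means
        for chk in check_means.index:
            assert (check_means[chk] - ours[tests[0]]) == pytest.approx(
                effects[chk] - effects[tests[0]], abs=1e-8)


class TestAnova:
    def test_df_additivity(self):
        rng = np.random.default_rng(21)
        table = random_trial(rng, 4, 3, 10)
        frame = anova_augmented(table, "y").frame
        n = 4 * 3 + 10
        assert frame.at["total", "df"] == n - 1
        assert (frame.at["blocks", "df"] + frame.at["treatments_adj", "df"]
                + frame.at["error", "df"]) == n - 1
        assert (frame.at["checks", "df"] + frame.at["genotypes_adj", "df"]
                + frame.at["checks_vs_genotypes", "df"]
                ) == frame.at["treatments_adj", "df"]

    def test_identical_checks_zero_check_ss(self):
        values = np.full((3, 3), 5.0)
        tests = {f"g{i}": float(i) for i in range(6)}
        blocks = {g: f"B{(i % 3) + 1}" for i, g in enumerate(tests)}
        table = build_trial(values, tests, blocks)
        frame = anova_augmented(table, "y").frame
        assert frame.at["checks", "ss"] == pytest.approx(0.0, abs=1e-10)

    def test_null_genotype_f_centered_on_its_null_expectation(self):
        """With zero genotypic variance the adjusted-genotype mean square
        carries the block-estimation noise of the check-based adjustment:
        E[MS_gen] = sigma_e2 * (1 + (v - sum n_j^2 / v) / (c (v - 1))),
        and independently E[MS_err^-1] = (d2 / (d2 - 2)) / sigma_e2, so
        the null F ratio is centered slightly above 1 in small designs
        (and approaches 1 as c and d2 grow)."""
        b, c, v = 4, 5, 24
        traits = [TraitSim("y", mean=10.0, sigma_g2=0.0, sigma_e2=4.0,
                           block_sd=1.0)]
        config = SimulationConfig(
            traits=traits, n_blocks=b,
            check_ids=tuple(f"c{i}" for i in range(c)),
            populations={"P": v}, seed=0)
        d2 = (b - 1) * (c - 1)
        fs = []
        master = np.random.SeedSequence(2024)
        for stream in master.spawn(500):
            table, _ = simulate_trial(config, seed=stream)
            fs.append(anova_augmented(table, "y").frame.at[
                "genotypes_adj", "F"])
        fs = np.asarray(fs)
        n_j = v / b  # round-robin: equal tests per block
        ms_factor = 1 + (v - b * n_j**2 / v) / (c * (v - 1))
        expected = ms_factor * d2 / (d2 - 2)
        se = fs.std(ddof=1) / np.sqrt(len(fs))
        assert abs(fs.mean() - expected) < 4 * se

    def test_p_values_within_unit_interval(self):
        rng = np.random.default_rng(23)
        table = random_trial(rng, 3, 4, 8)
        frame = anova_augmented(table, "y").frame
        p = frame["p"].dropna()
        assert ((p >= 0) & (p <= 1)).all()


class TestFedererMean:
    def test_all_checks_equals_grand_mean(self):
        # a trial with no test entries: every genotype equally replicated,
        # so the weighted mean reduces to the arithmetic grand mean
        rng = np.random.default_rng(31)
        values = rng.normal(size=(4, 3))
        table = build_trial(values, {}, {})
        assert federer_weighted_mean(table, "y") == pytest.approx(
            values.mean(), abs=1e-9)

    def test_hand_computed_toy(self, toy_trial):
        # checks: means {1.5, 4.0} each replicated twice; block effects
        # from check means: B1 = 2 - 2.75 = -0.75, B2 = +0.75
        # adjusted tests: g1 = 10 + 0.75 = 10.75, g2 = 20 - 0.75 = 19.25
        expected = (2 * 1.5 + 2 * 4.0 + 10.75 + 19.25) / 6
        assert federer_weighted_mean(toy_trial, "y") == pytest.approx(expected)

    def test_close_to_grand_mean_on_balanced_simulation(self, small_config):
        table, _ = simulate_trial(small_config)
        adj = adjust(table, "yield")
        check_range = adj.check_means.max() - adj.check_means.min()
        assert abs(adj.federer_mean - adj.grand_mean) < check_range


class TestCv:
    def test_algebraic_identity(self):
        assert cv_percent(25.0, 50.0) == pytest.approx(10.0)

    def test_published_error_variance_and_mean(self):
        # error MS and test mean of the study's total-fruit-mass column
        assert cv_percent(12997.73, 976.67) == pytest.approx(11.67, abs=0.005)

    def test_scale_invariance(self):
        assert cv_percent(25.0, 50.0) == pytest.approx(
            cv_percent(25.0 * 4, 100.0))

    def test_requires_positive_mean(self):
        with pytest.raises(ValueError):
            cv_percent(1.0, 0.0)
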