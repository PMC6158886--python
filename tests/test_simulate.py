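"""Synthetic competition generator: dynamics, determinism, ground truth, I/O."""

import numpy as np
import pandas as pd
import pytest

import galdose as gd
from galdose.events import CHANNELS


class TestGroundTruth:
    def test_gal80_halving_raises_expression(self):
        truth = gd.default_ground_truth("A")
        for g in gd.enumerate_genotypes():
            if g.copy_of("GAL80") == 2:
                partner = g.with_copy("GAL80", 1)
                assert (
                    truth.mean_log_expression[partner]
                    > truth.mean_log_expression[g]
                )

    def test_gal2_halving_costs_fitness_only_at_low_galactose(self):
        for env, sign in [("B", -1), ("C", -1), ("D", +1)]:
            truth = gd.default_ground_truth(env)
            wt = gd.WILD_TYPE
            gal2 = gd.Genotype.from_reduced(["GAL2"])
            diff = (
                truth.selection_coefficient[gal2]
                - truth.selection_coefficient[wt]
            )
            assert np.sign(diff) == sign, env

    def test_pure_galactose_slope_positive_at_high_concentration(self):
        truth = gd.default_ground_truth("D")
        mus, ss = [], []
        for g in gd.enumerate_genotypes():
            if g.copy_of("GAL2") == 2:  # exclude the permease-specific term
                mus.append(truth.mean_log_expression[g])
                ss.append(truth.selection_coefficient[g])
        slope = np.polyfit(np.exp(mus), ss, 1)[0]
        assert slope > 0

    def test_neutral_configuration_equalizes_selection(self):
        truth = gd.default_ground_truth("D", neutral=True)
        values = set(truth.selection_coefficient.values())
        assert values == {0.0}

    def test_invalid_contamination_rejected(self, truth_d):
        with pytest.raises(ValueError):
            gd.GroundTruth(
                environment=truth_d.environment,
                mean_log_expression=truth_d.mean_log_expression,
                selection_coefficient=truth_d.selection_coefficient,
                contamination_fraction=0.5,
            )


class TestCompetitionDynamics:
    def test_neutral_competition_holds_fraction(self, neutral_truth_d):
        exp = gd.simulate_competition(
            gd.WILD_TYPE, "D", neutral_truth_d, init_fraction=0.5,
            n_events=25_000, seed=3,
        )
        quant = gd.classify_events(exp.tables[48.0])
        se = np.sqrt(0.25 / 25_000)
        # contamination is classified as query; bound against the clean fraction
        clean = 1.0 - neutral_truth_d.contamination_fraction
        expected = 0.5 * clean + neutral_truth_d.contamination_fraction
        assert abs(quant.query_fraction - expected) < 4 * se

    def test_known_selection_gives_fourfold_odds_at_48h(self):
        # ds = ln(2)/24 per hour doubles the odds per 24 h: R(48)/R(0) = 4
        truth = gd.default_ground_truth("D", neutral=True, contamination_fraction=0.0)
        g = gd.WILD_TYPE
        truth.selection_coefficient[g] = np.log(2) / 24
        ratios = []
        for seed in range(8):
            exp = gd.simulate_competition(
                g, "D", truth, init_fraction=0.5, n_events=25_000, seed=seed
            )
            r = [
                gd.population_ratio(gd.classify_events(exp.tables[t]))
                for t in (0.0, 48.0)
            ]
            ratios.append(r[1] / r[0])
        assert abs(np.mean(ratios) - 4.0) < 0.15

    def test_log_odds_linear_in_time(self):
        # contamination-free so the raw (ungated) ratio follows the dynamics
        truth = gd.default_ground_truth("D", contamination_fraction=0.0)
        g = gd.Genotype.from_reduced(["GAL80"])
        ds = truth.selection_coefficient[g]
        slopes = []
        for seed in range(6):
            exp = gd.simulate_competition(g, "D", truth, seed=seed, n_events=25_000)
            logodds = [
                np.log(gd.population_ratio(gd.classify_events(exp.tables[t])))
                for t in (0.0, 24.0, 48.0)
            ]
            slopes.append(np.polyfit([0, 24, 48], logodds, 1)[0])
        sem = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - ds) < 3 * sem

    def test_same_seed_reproduces_event_tables(self, truth_d):
        g = gd.Genotype.from_reduced(["GAL3"])
        a = gd.simulate_competition(g, "D", truth_d, seed=9, n_events=2000)
        b = gd.simulate_competition(g, "D", truth_d, seed=9, n_events=2000)
        for t in a.tables:
            assert a.tables[t].equals(b.tables[t])

    def test_sample_seed_is_stable_and_distinct(self):
        g1, g2 = gd.enumerate_genotypes()[:2]
        s1 = gd.sample_seed(1, g1, "A", 0)
        s2 = gd.sample_seed(1, g1, "A", 0)
        s3 = gd.sample_seed(1, g2, "A", 0)
        assert s1.entropy == s2.entropy
        assert s1.entropy != s3.entropy

    @pytest.mark.parametrize("kwargs", [
        {"init_fraction": 0.0}, {"init_fraction": 1.0}, {"n_events": 10},
    ])
    def test_invalid_arguments_rejected(self, truth_d, kwargs):
        with pytest.raises(ValueError):
            gd.simulate_competition(gd.WILD_TYPE, "D", truth_d, seed=0, **kwargs)

    def test_nonfinite_selection_rejected(self, truth_d):
        truth_d.selection_coefficient[gd.WILD_TYPE] = np.nan
        with pytest.raises(ValueError):
            gd.simulate_competition(gd.WILD_TYPE, "D", truth_d, seed=0)


class TestEventIO:
    def test_round_trip_small_table(self, tmp_path):
        data = pd.DataFrame(
            {"FSC": [1.5, 2.25, 3e4], "SSC": [0.1, 0.2, 0.3],
             "YFP": [10.0, 1e-3, 7.125], "mCherry": [5.0, 6.0, 1e6]}
        )
        table = gd.EventTable(
            data, genotype=gd.WILD_TYPE, environment="A", replicate=2, timepoint=24.0
        )
        path = tmp_path / "events.csv"
        gd.write_events(path, table)
        back = gd.read_events(path)
        assert back.equals(table)

    def test_round_trip_full_size_sample(self, tmp_path, truth_d):
        exp = gd.simulate_competition(
            gd.WILD_TYPE, "D", truth_d, seed=4, n_events=25_000
        )
        table = exp.tables[0.0]
        path = tmp_path / "big.csv"
        gd.write_events(path, table)
        back = gd.read_events(path)
        assert back.equals(table)
        assert back.genotype == gd.WILD_TYPE
        assert back.timepoint == 0.0

    def test_negative_channel_value_raises_with_line_context(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "# genotype=2222\n# environment=A\n# replicate=0\n# timepoint=0.0\n"
            "FSC,SSC,YFP,mCherry\n1,1,1,1\n2,2,-3,2\n"
        )
        with pytest.raises(gd.EventTableParseError) as exc:
            gd.read_events(path)
        assert exc.value.line == 7

    def test_negative_values_rejected_at_construction(self):
        data = pd.DataFrame({c: [1.0, -1.0] for c in CHANNELS})
        with pytest.raises(ValueError):
            gd.EventTable(data)
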