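"""Raw fitness, wild-type normalization and mixing-ratio invariance."""

import numpy as np
import pandas as pd
import pytest

import galdose as gd


class TestRawFitness:
    def test_neutral_competition_is_one(self):
        assert gd.raw_fitness(2.3, 2.3, 48.0) == pytest.approx(1.0)

    def test_closed_form_fold_change(self):
        # (4/1)^(24/48) = 2
        assert gd.raw_fitness(1.0, 4.0, 48.0) == pytest.approx(2.0)

    def test_log_convention_recovers_selection_coefficient(self):
        s = 0.01
        r0, r1 = 1.5, 1.5 * np.exp(s * 48)
        assert gd.selection_coefficient(r0, r1, 48.0) == pytest.approx(s)
        assert gd.raw_fitness(r0, r1, 48.0) == pytest.approx(np.exp(24 * s))

    def test_simulated_dynamics_recover_fold_change(self):
        truth = gd.default_ground_truth("D", contamination_fraction=0.0)
        g = gd.Genotype.from_reduced(["GAL80"])
        ds = truth.selection_coefficient[g]
        values = []
        for seed in range(6):
            exp = gd.simulate_competition(g, "D", truth, seed=seed, n_events=25_000)
            r = {
                t: gd.population_ratio(gd.classify_events(exp.tables[t]))
                for t in (0.0, 48.0)
            }
            values.append(gd.raw_fitness(r[0.0], r[48.0], 48.0))
        sem = np.std(values, ddof=1) / np.sqrt(len(values))
        assert abs(np.mean(values) - np.exp(24 * ds)) < 3 * sem

    def test_initial_fraction_invariance(self):
        truth = gd.default_ground_truth("D", contamination_fraction=0.0)
        g = gd.Genotype.from_reduced(["GAL2"])
        estimates = {}
        for frac in (0.3, 0.7):
            vals = []
            for seed in range(6):
                exp = gd.simulate_competition(
                    g, "D", truth, init_fraction=frac, seed=100 + seed,
                    n_events=25_000,
                )
                r = {
                    t: gd.population_ratio(gd.classify_events(exp.tables[t]))
                    for t in (0.0, 48.0)
                }
                vals.append(gd.raw_fitness(r[0.0], r[48.0], 48.0))
            estimates[frac] = (np.mean(vals), np.std(vals, ddof=1) / np.sqrt(len(vals)))
        diff = abs(estimates[0.3][0] - estimates[0.7][0])
        combined = np.hypot(estimates[0.3][1], estimates[0.7][1])
        assert diff < 3 * combined

    @pytest.mark.parametrize("r0,r1,dur", [(0.0, 1.0, 48), (1.0, -1.0, 48), (1.0, 1.0, 0)])
    def test_invalid_inputs_rejected(self, r0, r1, dur):
        with pytest.raises(ValueError):
            gd.raw_fitness(r0, r1, dur)


class TestNormalization:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["genotype", "replicate", "raw_fitness"])

    def test_uniform_table_normalizes_to_one(self):
        rows = [(g.code, r, 1.7) for g in gd.enumerate_genotypes() for r in range(3)]
        out = gd.normalize_fitness(self._table(rows))
        assert np.allclose(out["fitness"], 1.0)

    def test_hand_arithmetic(self):
        rows = [("2222", 0, 1.0), ("2222", 1, 1.2), ("2222", 2, 1.4), ("1222", 0, 1.8)]
        out = gd.normalize_fitness(self._table(rows))
        query = out.loc[out["genotype"] == "1222", "fitness"].iloc[0]
        assert query == pytest.approx(1.8 / 1.2)

    def test_wild_type_mean_exactly_one_per_environment(self, rng):
        rows = []
        for env in ("C", "D"):
            for g in gd.enumerate_genotypes():
                for r in range(3):
                    rows.append(
                        {"environment": env, "genotype": g.code, "replicate": r,
                         "raw_fitness": float(rng.uniform(0.5, 1.5))}
                    )
        out = gd.normalize_fitness(pd.DataFrame(rows))
        for env, df in out.groupby("environment"):
            wt = df.loc[df["genotype"] == "2222", "fitness"]
            assert wt.mean() == pytest.approx(1.0, abs=1e-12)

    def test_normalization_is_idempotent(self, rng):
        rows = [
            {"genotype": g.code, "replicate": r, "raw_fitness": float(rng.uniform(0.5, 1.5))}
            for g in gd.enumerate_genotypes() for r in range(3)
        ]
        once = gd.normalize_fitness(pd.DataFrame(rows))
        twice = gd.normalize_fitness(once.assign(raw_fitness=once["fitness"]))
        assert np.allclose(once["fitness"], twice["fitness"])

    def test_missing_wild_type_rejected(self):
        rows = [("1222", 0, 1.0), ("1222", 1, 1.1)]
        with pytest.raises(gd.MissingWildTypeError):
            gd.normalize_fitness(self._table(rows))


class TestMixingInvariance:
    def test_bh_step_up_hand_example(self):
        # p = {0.01, 0.02, 0.04, 0.8}, m = 4, alpha = 0.05:
        # 0.04 > 3*0.05/4 = 0.0375 and 0.8 > 0.05, while 0.02 <= 2*0.05/4,
        # so the step-up rule rejects exactly the first two.
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(
            [0.01, 0.02, 0.04, 0.8], alpha=0.05, method="fdr_bh"
        )
        assert reject.tolist() == [True, True, False, False]

    def test_identical_distributions_no_discoveries(self, rng):
        rows = []
        for g in gd.enumerate_genotypes():
            base = rng.uniform(0.9, 1.1)
            for cond in (0.27, 0.54, 0.67):
                for r in range(9):
                    rows.append(
                        {"genotype": g.code, "condition": cond,
                         "fitness": base + rng.normal(0, 0.01)}
                    )
        tests = gd.mixing_ratio_invariance_test(pd.DataFrame(rows))
        assert tests["discovery"].sum() == 0
        assert len(tests) == 16 * 3

    def test_shifted_condition_is_discovered(self, rng):
        rows = []
        for g in gd.enumerate_genotypes():
            for cond in (0.3, 0.7):
                shift = 0.2 if (cond == 0.7 and g.code == "1111") else 0.0
                for r in range(9):
                    rows.append(
                        {"genotype": g.code, "condition": cond,
                         "fitness": 1.0 + shift + rng.normal(0, 0.01)}
                    )
        tests = gd.mixing_ratio_invariance_test(pd.DataFrame(rows))
        flagged = tests.loc[tests["discovery"], "genotype"].tolist()
        assert flagged == ["1111"]

    def test_single_replicate_condition_rejected(self):
        rows = [
            {"genotype": "2222", "condition": 0.3, "fitness": 1.0},
            {"genotype": "2222", "condition": 0.3, "fitness": 1.1},
            {"genotype": "2222", "condition": 0.7, "fitness": 1.0},
        ]
        with pytest.raises(ValueError):
            gd.mixing_ratio_invariance_test(pd.DataFrame(rows))
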