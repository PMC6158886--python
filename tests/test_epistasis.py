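"""Overall and net epistatic deviations, error propagation and Holm testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import galdose as gd
from galdose.genotypes import GENES

A, B, C, D = GENES  # GAL2, GAL3, GAL4, GAL80


def lattice_maps(summary):
    mean = {
        gd.Genotype.from_code(c): m
        for c, m in zip(summary["genotype"], summary["fitness_mean"])
    }
    sem = {
        gd.Genotype.from_code(c): s
        for c, s in zip(summary["genotype"], summary["fitness_sem"])
    }
    return mean, sem


def multiplicative_summary(factors, sem=0.0):
    rows = []
    for g in gd.enumerate_genotypes():
        rows.append(
            {"genotype": g.code,
             "fitness_mean": float(np.prod([factors[x] for x in g.reduced])),
             "fitness_sem": sem}
        )
    return pd.DataFrame(rows)


class TestOverallDeviation:
    def test_multiplicative_null_is_zero(self):
        summary = multiplicative_summary({A: 0.9, B: 1.1, C: 0.8, D: 1.05})
        mean, _ = lattice_maps(summary)
        for genes in gd.gene_subsets(min_size=2):
            eps, _ = gd.overall_deviation(genes, mean)
            assert eps == pytest.approx(0.0, abs=1e-12)

    def test_pairwise_hand_arithmetic(self):
        mean = {g: 1.0 for g in gd.enumerate_genotypes()}
        mean[gd.Genotype.from_reduced([A, B])] = 0.9
        eps, _ = gd.overall_deviation(frozenset([A, B]), mean)
        assert eps == pytest.approx(-0.1)

    @pytest.mark.parametrize("size", [2, 3, 4])
    def test_unit_fitness_se_is_sqrt_one_plus_m(self, size):
        # at w = 1 every partial product is 1: SE = s * sqrt(1 + |M|)
        s = 0.02
        mean = {g: 1.0 for g in gd.enumerate_genotypes()}
        sem = {g: s for g in gd.enumerate_genotypes()}
        genes = frozenset(list(GENES)[:size])
        eps, se = gd.overall_deviation(genes, mean, sem)
        assert eps == 0.0
        assert se == pytest.approx(s * np.sqrt(1 + size))

    def test_single_gene_set_rejected(self):
        mean = {g: 1.0 for g in gd.enumerate_genotypes()}
        with pytest.raises(ValueError):
            gd.overall_deviation(frozenset([A]), mean)

    def test_missing_strain_rejected(self):
        mean = {gd.WILD_TYPE: 1.0}
        with pytest.raises(KeyError):
            gd.overall_deviation(frozenset([A, B]), mean)


class TestNetDeviation:
    def test_pairwise_net_equals_overall(self, fitness_lattice):
        mean, sem = lattice_maps(fitness_lattice)
        for genes in gd.gene_subsets(min_size=2, max_size=2):
            eps, _ = gd.overall_deviation(genes, mean, sem)
            eps_net, _ = gd.net_deviation(genes, mean, sem)
            assert eps_net == pytest.approx(eps, abs=1e-14)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_fourth_order_matches_printed_expansion(self, seed):
        """eps'_ABCD term-by-term: inclusion-exclusion over the lattice."""
        rng = np.random.default_rng(seed)
        mean = {g: float(rng.uniform(0.5, 1.5)) for g in gd.enumerate_genotypes()}

        def eps(*genes):
            return gd.overall_deviation(frozenset(genes), mean)[0]

        expansion = (
            eps(A, B, C, D)
            - eps(A, B, C) - eps(A, B, D) - eps(A, C, D) - eps(B, C, D)
            + eps(A, B) + eps(B, C) + eps(A, C)
            + eps(A, D) + eps(B, D) + eps(C, D)
        )
        recursion, _ = gd.net_deviation(frozenset([A, B, C, D]), mean)
        assert recursion == pytest.approx(expansion, abs=1e-12)

    def test_third_order_matches_printed_expansion(self, fitness_lattice):
        mean, _ = lattice_maps(fitness_lattice)

        def eps(*genes):
            return gd.overall_deviation(frozenset(genes), mean)[0]

        expected = eps(A, B, C) - eps(A, B) - eps(B, C) - eps(A, C)
        got, _ = gd.net_deviation(frozenset([A, B, C]), mean)
        assert got == pytest.approx(expected, abs=1e-14)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_reconstruction_identity(self, seed):
        """sum of eps'_S over S subset M (|S| >= 2) equals eps_M exactly."""
        rng = np.random.default_rng(seed)
        mean = {g: float(rng.uniform(0.5, 1.5)) for g in gd.enumerate_genotypes()}
        for genes in gd.gene_subsets(min_size=2):
            total = sum(
                gd.net_deviation(s, mean)[0]
                for s in gd.gene_subsets(min_size=2)
                if s <= genes
            )
            eps, _ = gd.overall_deviation(genes, mean)
            assert total == pytest.approx(eps, abs=1e-12)

    def test_multiplicative_lattice_all_net_zero(self):
        summary = multiplicative_summary({A: 0.93, B: 1.04, C: 0.88, D: 0.9})
        mean, _ = lattice_maps(summary)
        for genes in gd.gene_subsets(min_size=2):
            eps_net, _ = gd.net_deviation(genes, mean)
            assert eps_net == pytest.approx(0.0, abs=1e-12)

    def test_net_se_quadrature_over_expansion(self, fitness_lattice):
        mean, sem = lattice_maps(fitness_lattice)
        genes = frozenset([A, B, C])
        var = sum(
            gd.overall_deviation(s, mean, sem)[1] ** 2
            for s in gd.expansion_coefficients(genes)
        )
        _, se = gd.net_deviation(genes, mean, sem)
        assert se == pytest.approx(np.sqrt(var))

    def test_delta_mode_accounts_for_shared_terms(self, fitness_lattice):
        mean, sem = lattice_maps(fitness_lattice)
        genes = frozenset([A, B, C, D])
        _, se_q = gd.net_deviation(genes, mean, sem, se_mode="quadrature")
        _, se_d = gd.net_deviation(genes, mean, sem, se_mode="delta")
        assert se_d > 0
        # shared single-gene terms partially cancel in the expansion, so the
        # covariance-aware SE cannot exceed the naive quadrature SE here
        assert se_d <= se_q + 1e-12

    def test_seven_strains_enter_third_order_net(self):
        strains = gd.strains_in_net_deviation(frozenset([A, B, C]))
        assert len(strains) == 7


class TestSignificance:
    def test_zero_deviation_p_one(self):
        z, p = gd.z_test(0.0, 0.01)
        assert z == 0.0
        assert p == 1.0

    def test_normal_quantile(self):
        _, p = gd.z_test(1.959964 * 0.01, 0.01)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_zero_se_untestable(self):
        with pytest.raises(ValueError):
            gd.z_test(0.1, 0.0)

    def test_holm_hand_applied_step_down(self):
        # {0.001, 0.02, 0.03}: 0.001 < 0.05/3, 0.02 < 0.05/2, 0.03 < 0.05/1
        adjusted = gd.holm_adjust([0.001, 0.02, 0.03])
        assert (adjusted < 0.05).all()
        # and the adjusted values follow max(k * p_(k)) cumulatively
        assert adjusted == pytest.approx([0.003, 0.04, 0.04])

    def test_star_thresholds(self):
        assert gd.stars(0.2) == ""
        assert gd.stars(0.03) == "*"
        assert gd.stars(0.009) == "**"
        assert gd.stars(0.0009) == "***"
        assert gd.stars(0.00009) == "****"

    def test_decisions_monotone_in_alpha(self, fitness_lattice):
        table = gd.epistasis_table(fitness_lattice)
        for _, row in table.iterrows():
            flags = [row["p_holm"] < a for a in sorted(gd.ALPHA_LEVELS)]
            # once significant at a stringent level, significant at looser ones
            assert flags == sorted(flags)

    def test_table_counts(self, fitness_lattice):
        table = gd.epistasis_table(fitness_lattice)
        assert (table["kind"] == "overall").sum() == 11
        assert (table["kind"] == "net").sum() == 5
        assert set(table.loc[table["kind"] == "net", "order"]) == {3, 4}

    def test_injected_epistasis_detected_with_monotone_power(self):
        sems = 0.008
        detections = []
        for effect in (0.02, 0.05, 0.10):
            hits = 0
            n_sims = 60
            rng = np.random.default_rng(2024)
            for _ in range(n_sims):
                summary = multiplicative_summary(
                    {A: 0.95, B: 1.0, C: 0.98, D: 0.96}
                )
                idx = summary.index[summary["genotype"] == gd.Genotype.from_reduced([A, D]).code]
                summary.loc[idx, "fitness_mean"] += effect
                summary["fitness_mean"] += rng.normal(0, sems, len(summary))
                summary["fitness_sem"] = sems
                table = gd.epistasis_table(summary)
                row = table[(table["kind"] == "overall") & (table["genes"] == "GAL2+GAL80")]
                hits += int(row["p_holm"].iloc[0] < 0.05)
            detections.append(hits / n_sims)
        assert detections[0] <= detections[1] <= detections[2]
        assert detections[2] > 0.9
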