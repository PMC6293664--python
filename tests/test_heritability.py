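"""Nested-ANOVA sums of squares, heritability estimates and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

import heritsim as hs
from heritsim.errors import DegenerateVarianceError, InvalidInputError

from _oracles import brute_force_ss


small_tables = st.tuples(
    st.integers(1, 4), st.integers(1, 4), st.integers(1, 4)).flatmap(
    lambda abc: arrays(np.float64, abc,
                       elements=st.floats(-10, 10, allow_nan=False)))


class TestNestedSS:
    def test_hand_computed_toy(self, toy_table):
        ss = hs.nested_ss(toy_table)
        assert ss.ssa == pytest.approx(16.0)
        assert ss.ss_b_a == pytest.approx(0.0)
        assert ss.ss_c_b == pytest.approx(4.0)
        assert ss.sst == pytest.approx(20.0)

    def test_constant_table_has_no_variation(self):
        ss = hs.nested_ss(hs.NestedPhenotypeTable(np.full((3, 2, 4), 7.0)))
        assert ss.ssa == ss.ss_b_a == ss.ss_c_b == 0.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(y=small_tables)
    def test_matches_brute_force_oracle(self, y):
        ss = hs.nested_ss(hs.NestedPhenotypeTable(y))
        ssa, ss_ba, ss_cb, sst = brute_force_ss(y)
        assert ss.ssa == pytest.approx(ssa, rel=1e-9, abs=1e-8)
        assert ss.ss_b_a == pytest.approx(ss_ba, rel=1e-9, abs=1e-8)
        assert ss.ss_c_b == pytest.approx(ss_cb, rel=1e-9, abs=1e-8)
        # additivity: SST equals the naive total deviation sum
        assert ss.sst == pytest.approx(sst, rel=1e-9, abs=1e-8)

    def test_rejects_bad_shapes(self):
        with pytest.raises(InvalidInputError):
            hs.NestedPhenotypeTable(np.zeros((2, 2)))
        with pytest.raises(InvalidInputError):
            hs.NestedPhenotypeTable(np.empty((0, 1, 1)))


class TestCollectiveSS:
    def test_toy_collective_means(self, toy_table):
        zss = hs.collective_ss(toy_table.collective_means())
        assert zss.ss_alpha == pytest.approx(8.0)
        assert zss.ss_beta_alpha == pytest.approx(0.0)
        assert zss.sst_z == pytest.approx(8.0)

    def test_identical_z_has_no_variation(self):
        zss = hs.collective_ss(np.full((4, 3), 2.5))
        assert zss.ss_alpha == zss.ss_beta_alpha == 0.0

    def test_mean_trait_scaling_identity(self, rng):
        """With z = within-collective mean: SSa = c SSA, SS(b/a) = c SS(B/A)."""
        table = hs.simulate_nested_table(5, 4, 6, 1.0, 0.5, 0.8, rng=rng)
        ss = hs.nested_ss(table)
        zss = hs.collective_ss(table.collective_means())
        c = table.c
        assert c * zss.ss_alpha == pytest.approx(ss.ssa, rel=1e-10)
        assert c * zss.ss_beta_alpha == pytest.approx(ss.ss_b_a, rel=1e-10)

    def test_rejects_unbalanced(self):
        with pytest.raises(InvalidInputError):
            hs.collective_ss(np.empty((0, 2)))


class TestHeritabilityEstimates:
    def test_toy_values(self, toy_table):
        ss = hs.nested_ss(toy_table)
        zss = hs.collective_ss(toy_table.collective_means())
        assert hs.particle_H2(ss).h2 == pytest.approx(0.8)
        assert hs.collective_H2(zss).h2 == pytest.approx(1.0)
        assert hs.heritability_ratio(ss) == pytest.approx(1.25)

    def test_pure_genetic_and_zero_genetic_cases(self):
        assert hs.particle_H2(hs.SSComponents(
            ssa=1.0, ss_b_a=0.0, ss_c_b=0.0, sst=1.0)).h2 == 1.0
        assert hs.particle_H2(hs.SSComponents(
            ssa=0.0, ss_b_a=1.0, ss_c_b=1.0, sst=2.0)).h2 == 0.0
        assert hs.collective_H2(hs.SSComponents(
            ss_alpha=0.0, ss_beta_alpha=1.0, sst_z=1.0)).h2 == 0.0

    def test_degenerate_tables_raise(self):
        flat = hs.SSComponents(ssa=0.0, ss_b_a=0.0, ss_c_b=0.0, sst=0.0)
        with pytest.raises(DegenerateVarianceError):
            hs.particle_H2(flat)
        with pytest.raises(DegenerateVarianceError):
            hs.heritability_ratio(hs.SSComponents(
                ssa=0.0, ss_b_a=0.0, ss_c_b=1.0, sst=1.0))

    def test_equivalence_of_mean_trait_routes(self, rng):
        """Collective H2 from z-means equals SSA / (SSA + SS(B/A))."""
        table = hs.simulate_nested_table(6, 5, 4, 2.0, 1.0, 3.0, rng=rng)
        ss = hs.nested_ss(table)
        zss = hs.collective_ss(table.collective_means())
        assert hs.collective_H2(zss).h2 == pytest.approx(
            ss.ssa / (ss.ssa + ss.ss_b_a), rel=1e-10)

    def test_ratio_equals_quotient_of_heritabilities(self, rng):
        table = hs.simulate_nested_table(6, 5, 4, 2.0, 1.0, 3.0, rng=rng)
        ss = hs.nested_ss(table)
        zss = hs.collective_ss(table.collective_means())
        quotient = hs.collective_H2(zss).h2 / hs.particle_H2(ss).h2
        assert hs.heritability_ratio(ss) == pytest.approx(quotient, rel=1e-10)

    def test_ratio_never_below_one(self, rng):
        for _ in range(100):
            a, b, c = rng.integers(2, 8), rng.integers(1, 6), rng.integers(2, 10)
            table = hs.simulate_nested_table(
                int(a), int(b), int(c),
                *rng.uniform(0.05, 3.0, size=3), rng=rng)
            assert hs.heritability_ratio(hs.nested_ss(table)) >= 1.0

    def test_scale_invariance(self, rng):
        table = hs.simulate_nested_table(5, 4, 3, 1.0, 0.7, 0.4, rng=rng)
        scaled = hs.NestedPhenotypeTable(table.values * 3.7)
        for fn in (lambda t: hs.particle_H2(hs.nested_ss(t)).h2,
                   lambda t: hs.heritability_ratio(hs.nested_ss(t))):
            assert fn(scaled) == pytest.approx(fn(table), rel=1e-10)

    def test_any_linear_collective_trait_gives_same_h2(self, rng):
        """z = p * sum + q leaves collective H2 and the ratio unchanged."""
        table = hs.simulate_nested_table(5, 4, 3, 1.0, 0.7, 0.4, rng=rng)
        z_mean = table.collective_means()
        z_affine = 2.5 * table.values.sum(axis=2) - 1.3
        h2_mean = hs.collective_H2(hs.collective_ss(z_mean)).h2
        h2_affine = hs.collective_H2(hs.collective_ss(z_affine)).h2
        assert h2_affine == pytest.approx(h2_mean, rel=1e-10)


class TestPOSlope:
    @pytest.mark.parametrize("pairs, expected", [
        ([(1, 1), (2, 2), (3, 3)], 1.0),
        ([(1, 5), (2, 5), (3, 5)], 0.0),
        ([(1, 2), (2, 2.5), (3, 4)], 1.0),  # Sxy = 2, Sxx = 2
    ])
    def test_hand_computed_slopes(self, pairs, expected):
        assert hs.po_slope(pairs) == pytest.approx(expected)

    def test_scale_invariance(self, rng):
        pairs = rng.normal(size=(50, 2))
        assert hs.po_slope(pairs * 11.0) == pytest.approx(
            hs.po_slope(pairs), rel=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(InvalidInputError):
            hs.po_slope([(1.0, 1.0)])
        with pytest.raises(DegenerateVarianceError):
            hs.po_slope([(2.0, 1.0), (2.0, 3.0)])


class TestRelativeHeritability:
    def test_linear_trait_fixed_n_no_instability_gives_ratio_one(self):
        # sigma = 0: collective volume is N x cell value, and an OLS slope
        # is invariant to a common scaling of both variables
        params = hs.SimulationParams(sigma=0.0, sigma_env=0.25, n_bar=32,
                                     generations=4, seed=21)
        _, ped = hs.grow_population(params)
        s_cell, s_coll, ratio = hs.relative_heritability(ped, "volume")
        assert ratio == pytest.approx(1.0, abs=1e-9)
        assert s_cell == pytest.approx(s_coll, rel=1e-9)

    def test_fully_degenerate_population_is_undefined(self):
        # one genotype, no noise: every phenotype is the same constant
        params = hs.SimulationParams(sigma=0.0, sigma_env=0.0,
                                     n_genotypes=1, generations=3, seed=2)
        _, ped = hs.grow_population(params)
        with pytest.raises(DegenerateVarianceError):
            hs.relative_heritability(ped, "volume")

    def test_developmental_noise_favors_collectives(self):
        ratios = []
        for rep in range(10):
            params = hs.SimulationParams(sigma=0.25, sigma_env=1e-4,
                                         n_bar=32, generations=7,
                                         seed=300 + rep)
            _, ped = hs.grow_population(params)
            ratios.append(hs.relative_heritability(ped, "volume")[2])
        assert np.mean(ratios) > 1.0


class TestVarianceComponentRecovery:
    def test_mean_squares_recover_simulated_components(self, rng):
        a, b, c = 200, 20, 5
        truth = dict(var_a=2.0, var_b=1.0, var_c=0.5)
        table = hs.simulate_nested_table(a, b, c, **truth, mean=10.0, rng=rng)
        ss = hs.nested_ss(table)
        ms_a = ss.ssa / (a - 1)
        ms_b = ss.ss_b_a / (a * (b - 1))
        ms_c = ss.ss_c_b / (a * b * (c - 1))
        assert (ms_a - ms_b) / (b * c) == pytest.approx(truth["var_a"],
                                                        rel=0.25)
        assert (ms_b - ms_c) / c == pytest.approx(truth["var_b"], rel=0.1)
        assert ms_c == pytest.approx(truth["var_c"], rel=0.05)


class TestSSVsVarianceError:
    def test_zero_within_clone_variance_gives_zero_error(self):
        assert hs.ss_vs_variance_error(1.0, 0.0, 0.0, 10, 10, 32) == 0.0

    def test_error_vanishes_as_design_grows(self):
        errors = [hs.ss_vs_variance_error(1.0, 0.5, 2.0, n, n, 32)
                  for n in (2, 10, 100, 1000)]
        assert all(e1 > e2 for e1, e2 in zip(errors, errors[1:]))
        assert errors[-1] < 0.05

    def test_monotone_along_each_axis(self):
        for a in (2, 10, 100):
            assert (hs.ss_vs_variance_error(1.0, 0.5, 2.0, a, 50, 8)
                    < hs.ss_vs_variance_error(1.0, 0.5, 2.0, a, 5, 8))
        for b in (2, 10, 100):
            assert (hs.ss_vs_variance_error(1.0, 0.5, 2.0, 50, b, 8)
                    < hs.ss_vs_variance_error(1.0, 0.5, 2.0, 5, b, 8))

    def test_degenerate_variances_raise(self):
        with pytest.raises(DegenerateVarianceError):
            hs.ss_vs_variance_error(0.0, 0.0, 0.0, 10, 10, 32)


class TestLongFormatIO:
    def test_round_trip(self, rng):
        table = hs.simulate_nested_table(3, 2, 4, 1.0, 0.5, 0.2, rng=rng)
        rebuilt = hs.NestedPhenotypeTable.from_long(table.to_long_frame())
        np.testing.assert_allclose(rebuilt.values, table.values)

    def test_unbalanced_long_input_rejected(self, rng):
        frame = hs.simulate_nested_table(
            3, 2, 4, 1.0, 0.5, 0.2, rng=rng).to_long_frame()
        with pytest.raises(InvalidInputError):
            hs.NestedPhenotypeTable.from_long(frame.iloc[:-1])

    def test_population_to_nested_table_balanced(self):
        params = hs.SimulationParams(sigma=0.2, sigma_env=0.1, n_bar=8,
                                     generations=3, n_genotypes=4, seed=6)
        pops, _ = hs.grow_population(params)
        table = hs.population_to_nested_table(pops)
        assert (table.a, table.b, table.c) == (4, 8, 8)

    def test_population_to_nested_table_rejects_variable_n(self):
        params = hs.SimulationParams(sigma=0.2, sigma_env=0.1, cv_n=0.25,
                                     n_bar=8, generations=3, n_genotypes=4,
                                     seed=6)
        pops, _ = hs.grow_population(params)
        with pytest.raises(InvalidInputError):
            hs.population_to_nested_table(pops)
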