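"""Mixture algebra and the synthetic applicant-population generators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rrmice import (
    FactorDraw,
    InfeasibleFactorsError,
    UndefinedCorrelationError,
    d_from_pb,
    draw_factors,
    gen_artificial,
    gen_natural,
    mixture_sd,
    pb_from_mixture,
    read_dataset,
    solve_within_corr,
    true_params,
    write_dataset,
)


class TestMixtureAlgebra:
    @pytest.mark.parametrize(
        "d, br, expected",
        [
            (1.5, 0.5, 1.25),  # worked example
            (0.0, 0.3, 1.0),  # identical groups give a standard normal
            (2.0, 0.2, np.sqrt(1.64)),
        ],
    )
    def test_mixture_sd_values(self, d, br, expected):
        assert mixture_sd(d, br) == pytest.approx(expected, abs=1e-12)

    def test_mixture_sd_of_simulated_mixture(self, rng):
        y = rng.random(2_000_000) < 0.2
        x = 2.0 * y + rng.standard_normal(2_000_000)
        assert x.std() == pytest.approx(mixture_sd(2.0, 0.2), abs=0.005)

    @given(st.floats(0, 10), st.floats(0.01, 0.99))
    @settings(max_examples=200, deadline=None)
    def test_mixture_sd_at_least_one(self, d, br):
        sd = mixture_sd(d, br)
        assert sd >= 1.0
        if d == 0.0:
            assert sd == 1.0

    @pytest.mark.parametrize(
        "d, br, expected",
        [(1.5, 0.5, 0.60), (0.0, 0.3, 0.0), (3.0, 0.5, 1.5 / np.sqrt(3.25))],
    )
    def test_pb_from_mixture_values(self, d, br, expected):
        assert pb_from_mixture(d, br) == pytest.approx(expected, abs=1e-10)

    def test_d_from_pb_inverts_worked_example(self):
        assert d_from_pb(0.60, 0.5) == pytest.approx(1.5, abs=1e-12)

    @given(st.floats(0.01, 0.95), st.floats(0.05, 0.95))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_and_monotonicity(self, rho, br):
        d = d_from_pb(rho, br)
        assert pb_from_mixture(d, br) == pytest.approx(rho, abs=1e-10)
        assert pb_from_mixture(d + 0.1, br) > pb_from_mixture(d, br)

    @pytest.mark.parametrize("br", [0.0, 1.0, -0.1])
    def test_domain_errors(self, br):
        with pytest.raises(ValueError):
            mixture_sd(1.0, br)
        with pytest.raises(ValueError):
            d_from_pb(0.5, br)

    def test_no_finite_mean_difference_at_unit_correlation(self):
        with pytest.raises(ValueError):
            d_from_pb(1.0, 0.5)


class TestSolveWithinCorr:
    def test_inverse_of_marginal_identity(self):
        # marginal corr(Z,X) = (rho_w + pq d_x d_z) / (sigma_x sigma_z)
        assert solve_within_corr(0.36, 1.5, 1.5, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_no_group_shift_in_z(self):
        rho_w = solve_within_corr(0.3, 1.5, 0.0, 0.5)
        assert rho_w == pytest.approx(0.3 * mixture_sd(1.5, 0.5), abs=1e-12)

    def test_infeasible_target_raises(self):
        with pytest.raises(InfeasibleFactorsError):
            solve_within_corr(-0.9, 3.0, 3.0, 0.5)


class TestGenArtificial:
    def test_exact_row_count_and_completeness(self, drr_artificial_dataset):
        ds = drr_artificial_dataset
        assert ds.n == 500
        assert np.isfinite(ds.x).all()
        assert set(np.unique(ds.y)) <= {0, 1}

    def test_base_rate_within_binomial_bound(self, rng):
        n = 1_000_000
        ds = gen_artificial(n, FactorDraw(rho_xy=0.3, br=0.9), "drr", rng)
        assert abs(ds.y.mean() - 0.9) < 3 * np.sqrt(0.9 * 0.1 / n)

    def test_large_sample_calibration_drr(self, rng):
        # median split: half successful, sample r near the attenuated value
        ds = gen_artificial(1_000_000, FactorDraw(rho_xy=0.6, br=0.5), "drr", rng)
        assert ds.y.mean() == pytest.approx(0.5, abs=0.005)
        tp = true_params(ds)
        assert tp.rho_b == pytest.approx(0.6, abs=0.01)

    def test_large_sample_calibration_irr(self, rng):
        f = FactorDraw(rho_xy=0.5, br=0.3, rho_zx=0.6, rho_zy=0.4)
        ds = gen_artificial(1_000_000, f, "irr", rng)
        tp = true_params(ds)
        assert tp.r_zx == pytest.approx(0.6, abs=0.01)
        assert tp.rho_b == pytest.approx(0.5, abs=0.01)
        assert tp.br == pytest.approx(0.3, abs=0.005)

    def test_non_positive_definite_matrix_rejected(self, rng):
        f = FactorDraw(rho_xy=0.9, br=0.5, rho_zx=0.9, rho_zy=0.1)
        with pytest.raises(InfeasibleFactorsError):
            gen_artificial(100, f, "irr", rng)


class TestGenNatural:
    def test_worked_example_point_biserial(self, rng):
        ds = gen_natural(1_000_000, FactorDraw(rho_xy=0.6, br=0.5), "drr", rng)
        assert true_params(ds).rho_pb == pytest.approx(0.60, abs=0.005)

    def test_marginal_zx_correlation_matches_target(self, rng):
        f = FactorDraw(rho_xy=0.6, br=0.5, rho_zx=0.36, rho_zy=0.6)
        ds = gen_natural(1_000_000, f, "irr", rng)
        assert np.corrcoef(ds.z, ds.x)[0, 1] == pytest.approx(0.36, abs=0.01)

    def test_fixed_counts_mode_pins_base_rate(self, rng):
        ds = gen_natural(
            500, FactorDraw(rho_xy=0.5, br=0.3), "drr", rng, fixed_counts=True
        )
        assert int(ds.y.sum()) == 150


class TestTrueParams:
    def test_constant_criterion_raises(self, drr_natural_dataset):
        ds = drr_natural_dataset
        ds.y = np.ones(ds.n, dtype=np.int64)
        with pytest.raises(UndefinedCorrelationError):
            true_params(ds)

    def test_base_rate_is_exact_count(self, drr_natural_dataset):
        tp = true_params(drr_natural_dataset)
        assert tp.br == drr_natural_dataset.y.sum() / 500


class TestFactorDrawAndIO:
    def test_uniform_draws_respect_bounds(self, rng):
        for _ in range(50):
            f, _ = draw_factors("irr", "natural", rng)
            assert 0.1 <= f.rho_xy <= 0.9
            assert 0.1 <= f.br <= 0.9
            # accepted draws must be feasible
            gen_natural(50, f, "irr", rng)

    def test_csv_round_trip(self, tmp_path, irr_natural_dataset):
        path = tmp_path / "pool.csv"
        write_dataset(irr_natural_dataset, path, seed=1)
        back = read_dataset(path)
        np.testing.assert_allclose(back.x, irr_natural_dataset.x)
        np.testing.assert_array_equal(back.y, irr_natural_dataset.y)
        np.testing.assert_allclose(back.z, irr_natural_dataset.z)
        assert back.scenario == "irr"
        assert back.factors == irr_natural_dataset.factors
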