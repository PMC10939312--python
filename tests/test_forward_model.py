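"""Response banks, modulation models and plausibility criteria."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from expsup.forward_model import (
    MODEL_FAMILIES,
    FeatureSpace,
    ModulationModel,
    build_bank,
    build_grid,
    clip_space,
    modulate,
    modulated_stimulus_response,
    plausibility_check,
    rejection_table,
    suppression_factor,
)


class TestSuppressionFactor:
    @pytest.mark.parametrize("d", [0.0, 0.3, 1.5])
    def test_global_is_constant(self, d):
        m = ModulationModel("gain", "global", a=0.3)
        assert suppression_factor(m, d) == pytest.approx(0.3)

    def test_formula_endpoints(self):
        local = ModulationModel("gain", "local", a=0.4, b=1.0)
        remote = ModulationModel("gain", "remote", a=0.4, b=1.0)
        assert suppression_factor(local, 0.0) == pytest.approx(0.4)
        assert suppression_factor(remote, 0.0) == pytest.approx(1.0)

    def test_no_suppression_beyond_b_for_local(self):
        # b = 0.1 rad: populations tuned ~5.7 degrees away escape suppression
        m = ModulationModel("gain", "local", a=0.5, b=0.1)
        assert suppression_factor(m, 0.1) == pytest.approx(1.0)
        assert suppression_factor(m, 0.2) == pytest.approx(1.0)
        assert suppression_factor(m, 0.05) < 1.0

    @given(
        a=st.floats(0.05, 1.0),
        b=st.floats(0.1, 2.3),
        frac=st.floats(0.0, 1.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_local_remote_mirror_identity(self, a, b, frac):
        # within d <= b the two ramps are mirror images: c_loc + c_rem = 1 + a
        d = frac * b
        local = suppression_factor(ModulationModel("gain", "local", a=a, b=b), d)
        remote = suppression_factor(ModulationModel("gain", "remote", a=a, b=b), d)
        assert local + remote == pytest.approx(1.0 + a, abs=1e-12)

    @pytest.mark.parametrize("a", [0.05, 0.5, 0.95])
    def test_local_approaches_global_as_b_grows(self, a):
        big_b = 1e6
        m = ModulationModel("gain", "local", a=a, b=big_b)
        d = np.linspace(0, np.pi / 2, 500)
        gap = np.abs(suppression_factor(m, d) - a)
        assert gap.max() <= (np.pi / 2) / big_b * (1 - a) + 1e-15

    def test_factor_bounded_between_a_and_one(self):
        d = np.linspace(0, np.pi / 2, 100)
        for op, dist in MODEL_FAMILIES:
            m = ModulationModel(op, dist, a=0.3, b=0.7 if dist != "global" else None)
            c = suppression_factor(m, d)
            assert np.all(c >= 0.3 - 1e-12) and np.all(c <= 1.0 + 1e-12)


class TestResponseBank:
    @pytest.mark.parametrize("kind", ["circular", "linear"])
    @pytest.mark.parametrize("sigma", [0.1, 0.5, 2.0, 5.0])
    def test_population_peaks_normalized_to_one(self, kind, sigma):
        from expsup.forward_model import population_curves

        bank = build_bank(FeatureSpace(kind), sigma)
        # exact peak of 1 at each population's mean ...
        at_means = population_curves(bank.space, bank.mus, sigma, bank.mus)
        assert np.diag(at_means) == pytest.approx(np.ones(8), abs=1e-12)
        # ... and the discretized grid comes within its sampling error of it
        assert bank.curves.max(axis=1) == pytest.approx(np.ones(8), abs=5e-4)

    def test_circular_summed_response_uniform_for_wide_tuning(self, circular_space):
        bank = build_bank(circular_space, sigma=50.0)
        s = bank.summed
        assert s.max() - s.min() < 1e-6 * s.max()

    def test_linear_summed_response_lower_at_range_ends(self, linear_bank):
        s = linear_bank.summed
        assert s[0] < s[len(s) // 2]
        assert s[-1] < s[len(s) // 2]

    def test_invalid_sigma_rejected(self, circular_space):
        with pytest.raises(ValueError):
            build_bank(circular_space, sigma=0.0)


class TestClipSpace:
    def test_bounds_match_brute_force_scan(self, linear_space):
        bank = build_bank(linear_space, sigma=0.5)
        lo, hi = clip_space(bank, threshold=0.95)
        grid = linear_space.grid
        ok = bank.summed >= 0.95 * bank.summed.max()
        idx = np.flatnonzero(ok)
        assert lo == pytest.approx(grid[idx[0]])
        assert hi == pytest.approx(grid[idx[-1]])

    def test_bounds_symmetric_about_center(self, linear_space):
        bank = build_bank(linear_space, sigma=0.5)
        center = (linear_space.lo + linear_space.hi) / 2
        assert (center - bank.clip_lo) == pytest.approx(bank.clip_hi - center, abs=1e-6)

    def test_wide_tuning_clips_to_nearly_full_range(self, linear_space):
        bank = build_bank(linear_space, sigma=30.0)
        assert bank.clip_hi - bank.clip_lo > 0.97 * linear_space.width

    def test_circular_space_is_noop(self, circular_bank):
        lo, hi = clip_space(circular_bank)
        assert (lo, hi) == (circular_bank.space.lo, circular_bank.space.hi)


class TestModulate:
    @pytest.mark.parametrize("op,dist", MODEL_FAMILIES)
    def test_a_equal_one_leaves_bank_unmodulated(self, circular_bank, op, dist):
        m = ModulationModel(op, dist, a=1.0, b=0.5 if dist != "global" else None)
        mod = modulate(circular_bank, m, expected_position=0.7)
        np.testing.assert_allclose(mod, circular_bank.curves, atol=1e-12)

    def test_global_gain_scales_summed_response(self, circular_bank):
        m = ModulationModel("gain", "global", a=0.05)
        mod = modulate(circular_bank, m, expected_position=1.0)
        np.testing.assert_allclose(
            mod.sum(axis=0), 0.05 * circular_bank.summed, rtol=1e-12
        )

    @pytest.mark.parametrize("dist", ["local", "remote", "global"])
    def test_tuning_models_preserve_population_peaks(self, circular_bank, dist):
        m = ModulationModel("tuning", dist, a=0.3, b=0.5 if dist != "global" else None)
        # a width-only change: the response at each population's own mean
        # stays exactly at the normalized peak of 1
        peaks = np.diag(
            modulated_stimulus_response(circular_bank, m, circular_bank.mus)
        )
        assert peaks == pytest.approx(np.ones(8), abs=1e-12)
        mod = modulate(circular_bank, m, expected_position=0.0)
        assert mod.max(axis=1) == pytest.approx(np.ones(8), abs=5e-4)

    def test_gain_modulation_never_exceeds_unmodulated(self, circular_bank):
        m = ModulationModel("gain", "local", a=0.3, b=1.0)
        mod = modulate(circular_bank, m, expected_position=1.2)
        assert np.all(mod <= circular_bank.curves + 1e-12)

    def test_expected_position_outside_clip_rejected(self, linear_bank):
        with pytest.raises(ValueError):
            modulate(linear_bank, ModulationModel("gain", "global", a=0.5), -10.0)

    def test_stimulus_response_matches_curve_evaluation(self, circular_bank):
        m = ModulationModel("gain", "local", a=0.4, b=0.6)
        pos = np.array([0.9])
        resp = modulated_stimulus_response(circular_bank, m, pos)
        curves = modulate(circular_bank, m, 0.9)
        gi = np.argmin(np.abs(circular_bank.space.grid - 0.9))
        np.testing.assert_allclose(resp[:, 0], curves[:, gi], atol=1e-3)


class TestPlausibility:
    def test_deep_global_gain_fails_minimum_response(self, circular_bank):
        res = plausibility_check(
            circular_bank, ModulationModel("gain", "global", a=0.05)
        )
        assert not res and res.fail_criterion == 2

    def test_unmodulated_midwidth_circular_bank_passes(self, circular_bank):
        res = plausibility_check(circular_bank, ModulationModel("gain", "global", a=1.0))
        assert res and res.fail_criterion is None

    def test_untuned_gaussian_fails_selectivity(self, linear_space):
        # sigma = 6: response half pi from the mean is exp(-(pi/2)^2/72) ~ 0.966
        bank = build_bank(linear_space, sigma=6.0)
        res = plausibility_check(bank, ModulationModel("gain", "global", a=1.0))
        assert not res and res.fail_criterion == 3

    def test_spiky_linear_bank_fails_coverage(self, linear_space):
        bank = build_bank(linear_space, sigma=0.1)
        res = plausibility_check(bank, ModulationModel("gain", "global", a=1.0))
        assert not res and res.fail_criterion == 1


class TestParameterGrid:
    def test_default_grid_size(self):
        grid = build_grid()
        assert grid.size == 7820
        assert grid.family_size("local") == 7820
        assert grid.family_size("global") == len(grid.sigmas) * len(grid.a_values)

    def test_top_two_percent_size(self):
        assert build_grid().top_k(0.02) == 156

    def test_empty_value_lists_rejected(self):
        with pytest.raises(ValueError):
            build_grid({"sigmas": []})


class TestRejectionTable:
    def test_bulk_path_matches_per_point_oracle(self):
        """The bisection fast path must agree with exhaustive checks."""
        space = FeatureSpace("linear")
        grid = build_grid(
            {"sigmas": (0.1, 0.5, 3.0), "a_values": (0.05, 0.1, 0.5, 1.0),
             "b_values": (0.1, 1.0)}
        )
        table = rejection_table(space, grid, detail=True)
        detail = table.attrs["detail"]
        banks = {s: build_bank(space, s) for s in grid.sigmas}
        for row in detail.itertuples():
            m = ModulationModel(
                row.op_class, row.distance, a=row.a,
                b=None if np.isnan(row.b) else row.b,
            )
            res = plausibility_check(banks[row.sigma], m)
            assert res.passed == row.plausible, row
            if not res.passed:
                assert res.fail_criterion == row.fail_criterion, row

    def test_rates_independent_of_b_for_global_families(self):
        space = FeatureSpace("circular")
        grid = build_grid({"sigmas": (0.3, 0.5), "a_values": (0.05, 0.5),
                           "b_values": (0.1,)})
        t = rejection_table(space, grid, families=[("gain", "global")])
        assert t.loc[0, "n_total"] == 4  # sigmas x a only
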