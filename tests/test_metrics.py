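"""The seven outcome metrics on hand-constructed datasets."""

import numpy as np
import pytest

from expsup.forward_model import FeatureSpace, ModulationModel
from expsup.metrics import METRIC_NAMES, compute_metrics, raw_slopes
from expsup.synthetic_data import (
    DESIGN_6x6,
    GroundTruthSpec,
    generate_ground_truth_dataset,
)
from expsup.voxel_sim import TrialDataset


def make_dataset(task, trailing, expected, localizer, n_stimuli):
    task = np.asarray(task, dtype=float)
    return TrialDataset(
        responses=task,
        leading=np.asarray(trailing),
        trailing=np.asarray(trailing),
        expected=np.asarray(expected, dtype=bool),
        localizer=np.asarray(localizer, dtype=float),
        n_stimuli=n_stimuli,
    )


def two_stim_dataset(exp_scale=1.0, n_vox=12):
    """Two stimuli with anti-correlated patterns; localizer noise-free."""
    p0 = np.arange(1.0, n_vox + 1.0)
    p1 = p0[::-1].copy()
    pats = [p0, p1]
    trailing = [0, 1, 0, 1]
    expected = [False, False, True, True]
    task = np.array(
        [pats[0], pats[1], exp_scale * pats[0], exp_scale * pats[1]]
    )
    localizer = np.stack([p0, p1])[:, None, :]
    return make_dataset(task, trailing, expected, localizer, 2)


class TestMeanAmplitudeModulation:
    def test_equal_conditions_give_zero(self):
        ds = two_stim_dataset(exp_scale=1.0)
        assert compute_metrics(ds).mam == 0.0

    def test_unit_offset_gives_one(self):
        ds = two_stim_dataset()
        ds.responses[~ds.expected] += 1.0
        assert compute_metrics(ds).mam == pytest.approx(1.0)

    def test_missing_condition_rejected(self):
        ds = two_stim_dataset()
        with pytest.raises(ValueError, match="condition"):
            make = compute_metrics(
                make_dataset(
                    ds.responses[:2], ds.trailing[:2], [False, False],
                    ds.localizer, 2,
                )
            )


class TestClassCorrelations:
    def test_anticorrelated_patterns(self):
        mr = compute_metrics(two_stim_dataset())
        assert mr.wc["expected"] == pytest.approx(1.0)
        assert mr.wc["unexpected"] == pytest.approx(1.0)
        assert mr.bc["expected"] == pytest.approx(-1.0)
        assert mr.cp["expected"] == pytest.approx(-2.0)

    def test_z_scoring_makes_correlations_affine_invariant(self):
        ds = two_stim_dataset()
        mr0 = compute_metrics(ds)
        ds.responses[:] = 5.0 * ds.responses + 3.0
        mr1 = compute_metrics(ds)
        for cond in ("expected", "unexpected"):
            assert mr1.wc[cond] == pytest.approx(mr0.wc[cond])
            assert mr1.bc[cond] == pytest.approx(mr0.bc[cond])

    def test_cp_slope_antisymmetric_under_condition_swap(self):
        ds = two_stim_dataset(exp_scale=0.5)
        sl = raw_slopes(compute_metrics(ds))
        ds_sw = make_dataset(
            ds.responses, ds.trailing, ~ds.expected, ds.localizer, 2
        )
        sl_sw = raw_slopes(compute_metrics(ds_sw))
        assert sl["CP"] == pytest.approx(-sl_sw["CP"])


def binned_dataset(n_vox=20):
    """3 stimuli x 2 conditions; voxel suppression proportional to localizer
    amplitude, with amplitude increasing along the voxel index."""
    rng = np.random.default_rng(0)
    amp = np.linspace(1.0, 2.0, n_vox)
    loc_pat = np.outer(np.array([1.0, 1.1, 0.9]), amp)  # (S, V)
    localizer = loc_pat[:, None, :] + 0.001 * rng.standard_normal((3, 1, n_vox))
    trailing = [0, 1, 2, 0, 1, 2]
    expected = [False] * 3 + [True] * 3
    un = loc_pat
    ex = loc_pat - 0.5 * amp[None, :]  # suppression = amp/2 per voxel
    task = np.vstack([un, ex])
    return make_dataset(task, trailing, expected, localizer, 3)


class TestBinnedMetrics:
    def test_uniform_suppression_has_flat_slopes(self):
        ds = two_stim_dataset(n_vox=20)
        ds.responses[ds.expected] -= 1.0  # same suppression everywhere
        mr = compute_metrics(ds)
        assert mr.ama_slope == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(mr.ama_bins, 1.0)

    def test_amplitude_proportional_suppression_gives_positive_slope(self):
        mr = compute_metrics(binned_dataset())
        assert mr.ama_slope > 0

    def test_bin_means_match_hand_binning(self):
        ds = binned_dataset(20)
        mr = compute_metrics(ds)
        supp = ds.responses[:3].mean(axis=0) - ds.responses[3:].mean(axis=0)
        order = np.argsort(ds.localizer.mean(axis=(0, 1)))
        hand = supp[order].reshape(10, 2).mean(axis=1)
        np.testing.assert_allclose(mr.ama_bins, hand)

    def test_too_few_voxels_rejected(self):
        ds = two_stim_dataset(n_vox=4)
        with pytest.raises(ValueError, match="voxels"):
            compute_metrics(ds)


class TestSelectivity:
    def test_unit_rank_step_selectivity(self):
        # a voxel responding (1, 2, 3) to rank-ordered images has slope 1
        loc = np.zeros((3, 1, 10))
        loc[:, 0, :] = np.array([1.0, 2.0, 3.0])[:, None]
        loc[:, 0, :] += 0.001 * np.arange(10)  # break voxel degeneracy
        from expsup.metrics import MetricEngine

        eng = MetricEngine([0, 1, 2, 0, 1, 2], [False] * 3 + [True] * 3, 3)
        sel = eng.localizer_summary(loc)["sel"]
        np.testing.assert_allclose(sel, 1.0)

    def test_flat_voxels_have_zero_selectivity_and_flat_slope(self):
        # flat across stimuli within each voxel, but patterned across voxels
        loc = np.tile(1.0 + 0.1 * np.arange(10), (3, 1, 1))
        task = np.tile(1.0 + 0.1 * np.arange(10), (6, 1))
        task[:3] += 0.5
        ds = make_dataset(task, [0, 1, 2, 0, 1, 2],
                          [False] * 3 + [True] * 3, loc, 3)
        mr = compute_metrics(ds)
        assert mr.ams_slope == pytest.approx(0.0, abs=1e-12)


class TestImagePreference:
    def test_preference_independent_suppression_is_flat(self):
        mr = compute_metrics(two_stim_dataset(exp_scale=1.0))
        assert mr.ip_slope == pytest.approx(0.0, abs=1e-12)

    def test_more_preferred_more_suppressed_is_positive(self):
        # voxel prefers stimulus 0; suppression largest for stimulus 0
        loc = np.zeros((3, 1, 10))
        loc[:, 0, :] = np.array([3.0, 2.0, 1.0])[:, None]
        loc += 0.01 * np.arange(10)
        un = np.tile(np.array([3.0, 2.0, 1.0])[:, None], (1, 10))
        un = un + 0.01 * np.arange(10)  # break within-pattern degeneracy
        ex = un - np.array([1.5, 1.0, 0.5])[:, None]
        ds = make_dataset(np.vstack([un, ex]), [0, 1, 2, 0, 1, 2],
                          [False] * 3 + [True] * 3, loc, 3)
        mr = compute_metrics(ds)
        assert mr.ip_slope > 0
        np.testing.assert_allclose(mr.ip_values, [1.5, 1.0, 0.5])


class TestInvariances:
    def test_metrics_invariant_to_voxel_and_trial_order(self):
        ds = binned_dataset(20)
        mr0 = compute_metrics(ds)
        rng = np.random.default_rng(1)
        vperm = rng.permutation(20)
        tperm = rng.permutation(6)
        ds2 = make_dataset(
            ds.responses[tperm][:, vperm],
            ds.trailing[tperm],
            ds.expected[tperm],
            ds.localizer[:, :, vperm],
            3,
        )
        mr1 = compute_metrics(ds2)
        assert mr1.mam == pytest.approx(mr0.mam)
        assert mr1.ama_slope == pytest.approx(mr0.ama_slope)
        assert mr1.ams_slope == pytest.approx(mr0.ams_slope)
        assert mr1.ip_slope == pytest.approx(mr0.ip_slope)
        for cond in ("expected", "unexpected"):
            assert mr1.wc[cond] == pytest.approx(mr0.wc[cond])
            assert mr1.bc[cond] == pytest.approx(mr0.bc[cond])

    def test_null_simulation_zeroes_every_suppression_metric(self):
        """a = 1 with zero noise: no metric may register any effect."""
        spec = GroundTruthSpec(
            model=ModulationModel("gain", "local", a=1.0, b=0.5),
            sigma=0.5, noise_sd=0.0, n_participants=1, n_repetitions=1,
            master_seed=4, n_voxels=40,
        )
        ds = generate_ground_truth_dataset(
            spec, DESIGN_6x6, FeatureSpace("circular")
        )[0][0]
        mr = compute_metrics(ds)
        sl = raw_slopes(mr)
        for m in METRIC_NAMES:
            assert sl[m] == pytest.approx(0.0, abs=1e-12), m


class TestCpConvention:
    def test_sign_flag_flips_classification_performance(self):
        ds = two_stim_dataset(exp_scale=0.5)
        printed = compute_metrics(ds, cp_sign=1)
        haxby = compute_metrics(ds, cp_sign=-1)
        for cond in ("expected", "unexpected"):
            assert haxby.cp[cond] == pytest.approx(-printed.cp[cond])
        with pytest.raises(ValueError, match="cp_sign"):
            compute_metrics(ds, cp_sign=2)
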