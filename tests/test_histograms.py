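import numpy as np
import pytest
from scipy import stats

from swapmix import (
    MixtureParams,
    corrected_nontarget_histogram,
    generate_dataset,
    heuristic_proportions,
    mean_abs_error_by_position,
    nontarget_deviation_histogram,
    shuffle_expected_histogram,
    target_error_histogram,
    wrap_diff,
)
from swapmix.exceptions import ConfigurationError, EmptyInputError
from swapmix.histograms import make_bin_edges, shuffle_deviations

from conftest import build_trialset, single_condition_config


class TestBinEdges:
    def test_orientation_default(self, orientation):
        edges = make_bin_edges(orientation, 15.0)
        assert len(edges) == 13
        assert edges[0] == -90.0 and edges[-1] == 90.0

    def test_bad_width_rejected(self, orientation):
        with pytest.raises(ConfigurationError):
            make_bin_edges(orientation, 17.0)


class TestTargetHistogram:
    def test_perfect_responses_center_bin(self, orientation):
        feats = np.array([[0.0, 30.0, 60.0, 90.0]] * 50) + np.arange(50)[:, None]
        trials = build_trialset(orientation, feats, 0, feats[:, 0])
        h = target_error_histogram(trials, 15.0)
        assert h.observed[6] == 50  # first bin right of zero gets exact hits
        assert h.observed.sum() == 50

    def test_uniform_responses_flat(self, rng):
        cfg = single_condition_config(MixtureParams(0.0, 0.0, 1.0, 8.0), n_trials=6000, seed=2)
        h = target_error_histogram(generate_dataset(cfg), 15.0)
        assert stats.chisquare(h.observed).pvalue > 1e-4

    def test_central_mass_matches_vonmises_cdf(self):
        # p_T = 0.7, kappa = 10 (analysis circle): mass in the two central bins
        # follows the von Mises CDF over +/- 15 deg raw (30 deg doubled)
        kappa, p_t = 10.0, 0.7
        cfg = single_condition_config(MixtureParams(p_t, 0.0, 0.3, kappa), n_trials=20000, seed=8)
        trials = generate_dataset(cfg)
        h = target_error_histogram(trials, 15.0)
        central = (h.observed[5] + h.observed[6]) / h.observed.sum()
        grid = np.linspace(-np.deg2rad(30), np.deg2rad(30), 2001)
        vm_mass = np.trapezoid(stats.vonmises.pdf(grid, kappa), grid)
        expected = p_t * vm_mass + 0.3 * (30.0 / 180.0)
        assert central == pytest.approx(expected, abs=0.015)


class TestNontargetHistogram:
    def test_three_deviations_per_trial(self):
        cfg = single_condition_config(MixtureParams(0.6, 0.3, 0.1, 8.0), n_trials=100, seed=1)
        counts = nontarget_deviation_histogram(generate_dataset(cfg), 15.0)
        assert counts.sum() == 300

    def test_swap_free_data_still_structured(self):
        # the minimum-separation constraint alone makes this histogram non-uniform
        cfg = single_condition_config(MixtureParams(0.75, 0.0, 0.25, 8.0), n_trials=996, seed=3)
        counts = nontarget_deviation_histogram(generate_dataset(cfg), 15.0)
        assert stats.chisquare(counts).pvalue < 1e-3


class TestShuffleCorrection:
    def test_pair_count(self):
        cfg = single_condition_config(MixtureParams(0.6, 0.3, 0.1, 8.0), n_trials=24, seed=4)
        trials = generate_dataset(cfg)
        devs = shuffle_deviations(trials)
        assert devs.size == 24 * 23 * 3

    def test_expected_mass_matches_observed(self):
        cfg = single_condition_config(MixtureParams(0.6, 0.3, 0.1, 8.0), n_trials=48, seed=5)
        trials = generate_dataset(cfg)
        expected = shuffle_expected_histogram(trials, 15.0)
        assert expected.sum() == pytest.approx(48 * 3, abs=1e-9)

    def test_pseudo_nontargets_respect_min_separation(self, orientation):
        cfg = single_condition_config(MixtureParams(0.6, 0.3, 0.1, 8.0), n_trials=60, seed=6)
        trials = generate_dataset(cfg)
        d0 = wrap_diff(trials.response, trials.target_feature, orientation)
        offsets = wrap_diff(
            trials.nontarget_features, trials.target_feature[:, None], orientation
        )
        # pseudo non-targets for trial B from offsets of trial A keep their
        # separation from B's target and from each other
        for b in range(0, 60, 7):
            for a in range(0, 60, 11):
                if a == b:
                    continue
                pseudo = trials.target_feature[b] + offsets[a]
                sep_t = np.abs(wrap_diff(pseudo, trials.target_feature[b], orientation))
                assert np.all(sep_t >= orientation.min_separation - 1e-9)
                pair = np.abs(wrap_diff(pseudo[:, None], pseudo[None, :], orientation))
                iu = np.triu_indices(3, k=1)
                assert np.all(pair[iu] >= orientation.min_separation - 1e-9)

    def test_order_invariant(self):
        cfg = single_condition_config(MixtureParams(0.6, 0.3, 0.1, 8.0), n_trials=36, seed=7)
        trials = generate_dataset(cfg)
        shuffled_rows = trials.table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        from swapmix import TrialSet

        reordered = TrialSet(trials.space, shuffled_rows)
        np.testing.assert_allclose(
            shuffle_expected_histogram(trials, 15.0),
            shuffle_expected_histogram(reordered, 15.0),
        )

    def test_requires_two_trials(self, orientation):
        trials = build_trialset(orientation, [[0.0, 30.0, 60.0, 90.0]], 0, 5.0)
        with pytest.raises(EmptyInputError):
            shuffle_deviations(trials)

    def test_corrected_sums_to_zero(self):
        cfg = single_condition_config(MixtureParams(0.6, 0.3, 0.1, 8.0), n_trials=120, seed=8)
        h = corrected_nontarget_histogram(generate_dataset(cfg), 15.0)
        assert h.corrected.sum() == pytest.approx(0.0, abs=1e-6)
        assert h.expected.sum() == pytest.approx(h.observed.sum(), abs=1e-6)

    def test_nulls_out_on_swap_free_data(self):
        """Without swaps the corrected histogram is flat at zero (within
        binomial error per bin) even though the raw histogram is structured."""
        cfg = single_condition_config(MixtureParams(0.75, 0.0, 0.25, 8.0), n_trials=996, seed=9)
        h = corrected_nontarget_histogram(generate_dataset(cfg), 15.0)
        total = h.observed.sum()
        p = h.expected / total
        se = np.sqrt(total * p * (1 - p))
        assert np.all(np.abs(h.corrected) <= 3 * se)

    def test_reveals_swaps_when_present(self):
        cfg = single_condition_config(MixtureParams(0.55, 0.35, 0.10, 8.0), n_trials=996, seed=10)
        h = corrected_nontarget_histogram(generate_dataset(cfg), 15.0)
        # swaps produce a clear central excess; the shuffle baseline absorbs
        # part of the swap structure (it is exact only under the no-swap null),
        # so the excess is a conservative, not exhaustive, swap count
        central = h.corrected[5] + h.corrected[6]
        assert central > 0.04 * h.observed.sum()
        assert central > 5 * np.sqrt(h.observed.sum() / 6)  # far beyond noise


class TestHeuristics:
    def test_uniform_level(self):
        cfg = single_condition_config(MixtureParams(0.0, 0.0, 1.0, 8.0), n_trials=6000, seed=11)
        p_t, _ = heuristic_proportions(generate_dataset(cfg), 15.0)
        assert p_t == pytest.approx(1 / 6, abs=0.02)

    def test_exact_target_responses(self, orientation):
        feats = np.array([[0.0, 30.0, 60.0, 90.0]] * 40) + np.arange(40)[:, None]
        trials = build_trialset(orientation, feats, 2, feats[:, 2])
        p_t, p_nt = heuristic_proportions(trials, 15.0)
        assert p_t == 1.0
        assert p_nt == 0.0  # non-targets all at least 30 degrees away

    def test_swaps_raise_pnt_above_chance(self):
        low = single_condition_config(MixtureParams(0.75, 0.05, 0.20, 8.0), n_trials=996, seed=12)
        high = single_condition_config(MixtureParams(0.55, 0.30, 0.15, 8.0), n_trials=996, seed=12)
        _, p_nt_low = heuristic_proportions(generate_dataset(low), 15.0)
        _, p_nt_high = heuristic_proportions(generate_dataset(high), 15.0)
        assert p_nt_high > p_nt_low + 0.1

    def test_consistency_with_central_bins(self):
        # with bin_width = window, p_t equals the mass of the two central bins
        cfg = single_condition_config(MixtureParams(0.6, 0.3, 0.1, 8.0), n_trials=480, seed=13)
        trials = generate_dataset(cfg)
        h = target_error_histogram(trials, 15.0)
        p_t, _ = heuristic_proportions(trials, 15.0)
        assert p_t == pytest.approx((h.observed[5] + h.observed[6]) / h.observed.sum(), abs=1e-9)


class TestMeanAbsErrorByPosition:
    def test_perfect_responses(self, orientation):
        feats = np.array([[0.0, 30.0, 60.0, 90.0]] * 40) + np.arange(40)[:, None]
        ti = np.tile([0, 1, 2, 3], 10)
        trials = build_trialset(orientation, feats, ti, feats[np.arange(40), ti])
        out = mean_abs_error_by_position(trials)
        assert (out["mae"] == 0).all()
        assert set(out["target_index"]) == {0, 1, 2, 3}

    def test_uniform_responses_at_chance(self):
        cfg = single_condition_config(MixtureParams(0.0, 0.0, 1.0, 8.0), n_trials=12000, seed=14)
        out = mean_abs_error_by_position(generate_dataset(cfg))
        assert out["mae"].to_numpy() == pytest.approx([45.0] * 4, abs=1.5)

    def test_recency_gradient(self):
        # increasing precision across ordinal positions shows up as falling error
        cfg = single_condition_config(
            MixtureParams(0.95, 0.0, 0.05, 8.0),
            n_trials=12000,
            seed=15,
            kappa_by_position=(1.0, 3.0, 9.0, 27.0),
        )
        out = mean_abs_error_by_position(generate_dataset(cfg)).sort_values("target_index")
        mae = out["mae"].to_numpy()
        assert np.all(np.diff(mae) < 0)
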