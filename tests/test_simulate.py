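import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from swapmix import (
    CircularSpace,
    GeneratorConfig,
    MixtureParams,
    circ_mad,
    generate_dataset,
    generate_responses,
    sample_features,
    sample_locations,
    wrap_diff,
)
from swapmix.exceptions import ConfigurationError
from swapmix.simulate import min_location_separation_deg

from conftest import single_condition_config


def min_pairwise(angles, space):
    angles = np.atleast_2d(angles)
    d = np.abs(wrap_diff(angles[:, :, None], angles[:, None, :], space))
    iu = np.triu_indices(angles.shape[1], k=1)
    return d[:, iu[0], iu[1]].min()


class TestSampleFeatures:
    def test_min_separation_enforced(self, orientation, rng):
        draws = sample_features(orientation, 4, rng, size=500)
        assert min_pairwise(draws, orientation) >= 10.0

    def test_single_item_unconstrained(self, orientation, rng):
        draws = sample_features(orientation, 1, rng, size=2000).ravel()
        # marginal stays uniform: chi-square over 12 bins
        counts, _ = np.histogram(draws, bins=12, range=(0, 180))
        assert stats.chisquare(counts).pvalue > 1e-4

    def test_tight_constraint_keeps_marginal_uniform(self, rng):
        # 4 items with 40-degree minimum separation on a 180-degree circle:
        # only near-equally-spaced tuples survive, yet each marginal is uniform
        space = CircularSpace(180.0, 40.0)
        draws = sample_features(space, 4, rng, size=3000)
        assert min_pairwise(draws, space) >= 40.0
        counts, _ = np.histogram(draws[:, 2], bins=10, range=(0, 180))
        assert stats.chisquare(counts).pvalue > 1e-4

    def test_infeasible_constraint_rejected(self, rng):
        space = CircularSpace(180.0, 40.0)
        with pytest.raises(ConfigurationError):
            sample_features(space, 5, rng)


class TestSampleLocations:
    def test_same_location_identical(self, rng):
        locs = sample_locations("same", 4, 6.0, 3.0, rng, size=200)
        assert np.all(locs == locs[:, :1])

    def test_chord_constraint_implies_angle(self, rng):
        # chord >= 3 dva at radius 6 translates to about 29 degrees of arc
        min_angle = min_location_separation_deg(6.0, 3.0)
        assert min_angle == pytest.approx(28.955, abs=0.01)
        locs = sample_locations("different", 4, 6.0, 3.0, rng, size=500)
        assert min_pairwise(locs, CircularSpace(360.0, 0.0)) >= min_angle - 1e-9

    def test_same_locations_uniform_over_trials(self, rng):
        locs = sample_locations("same", 4, 6.0, 3.0, rng, size=5000)[:, 0]
        # Rayleigh-style check: resultant of uniform angles is near zero
        resultant = np.abs(np.mean(np.exp(1j * np.deg2rad(locs))))
        assert resultant < 3.0 / np.sqrt(5000)


class TestGenerateResponses:
    def test_deterministic_target_reproduction(self, orientation, rng):
        feats = sample_features(orientation, 4, rng, size=200)
        ti = rng.integers(0, 4, 200)
        resp = generate_responses(feats, ti, MixtureParams(1.0, 0.0, 0.0, 700.0), orientation, rng)
        devs = wrap_diff(resp, feats[np.arange(200), ti], orientation)
        assert np.max(np.abs(devs)) < 3.0  # kappa ceiling leaves tiny jitter

    def test_uniform_guessing_mad(self, orientation, rng):
        feats = sample_features(orientation, 4, rng, size=20000)
        ti = rng.integers(0, 4, 20000)
        resp = generate_responses(feats, ti, MixtureParams(0.0, 0.0, 1.0, 8.0), orientation, rng)
        devs = wrap_diff(resp, feats[np.arange(20000), ti], orientation)
        assert circ_mad(devs, orientation) == pytest.approx(45.0, abs=1.0)

    def test_swap_destination_weights(self, orientation, rng):
        # all swap mass on the item immediately after the target
        n = 100_000
        feats = sample_features(orientation, 4, rng, size=n)
        ti = rng.integers(0, 3, n)  # keep +1 available
        resp = generate_responses(
            feats,
            ti,
            MixtureParams(0.0, 1.0, 0.0, 700.0),
            orientation,
            rng,
            swap_weights={1: 1.0},
        )
        devs = np.abs(wrap_diff(resp[:, None], feats, orientation))
        dest = devs.argmin(axis=1)
        assert np.mean(dest == ti + 1) > 0.999

    def test_mixture_proportions_recovered_empirically(self, orientation, rng):
        n = 20000
        p = MixtureParams(0.6, 0.3, 0.1, 700.0)
        feats = sample_features(orientation, 4, rng, size=n)
        ti = rng.integers(0, 4, n)
        resp = generate_responses(feats, ti, p, orientation, rng)
        # attribute each response to the closest item; a 6-degree window catches
        # essentially all kappa-at-ceiling draws, and uniform guesses land inside
        # some window with probability 4 * 12 / 180
        devs = np.abs(wrap_diff(resp[:, None], feats, orientation))
        close = devs.min(axis=1) < 6.0
        is_target = close & (devs.argmin(axis=1) == ti)
        is_swap = close & (devs.argmin(axis=1) != ti)
        capture = 4 * 12.0 / 180.0
        for observed, expected in [
            (np.mean(is_target), 0.6 + 0.1 * capture / 4),
            (np.mean(is_swap), 0.3 + 0.1 * 3 * capture / 4),
            (np.mean(~close), 0.1 * (1 - capture)),
        ]:
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < 3 * se


class TestGenerateDataset:
    def test_default_trial_count(self):
        ts = generate_dataset(GeneratorConfig(n_participants=1, seed=0))
        assert ts.n_trials == 480  # 4 conditions x 120 trials

    def test_reproducible(self):
        a = generate_dataset(GeneratorConfig(n_participants=2, seed=42))
        b = generate_dataset(GeneratorConfig(n_participants=2, seed=42))
        assert a.table.equals(b.table)

    def test_target_positions_balanced_per_block(self):
        cfg = GeneratorConfig(n_participants=1, seed=1)
        ts = generate_dataset(cfg)
        for (_, _), sub in ts.table.groupby(["location_condition", "isi_condition"]):
            for block in range(3):
                chunk = sub.iloc[block * 40 : (block + 1) * 40]
                counts = chunk["target_index"].value_counts()
                assert set(counts.index) == {0, 1, 2, 3}
                assert (counts == 10).all()

    def test_emitted_trials_satisfy_invariants(self):
        ts = generate_dataset(GeneratorConfig(n_participants=2, seed=5))
        ts.validate(placement_radius=6.0, min_center_distance=3.0)

    def test_unbalanced_trial_count_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(trials_per_condition=100)

    @settings(max_examples=10)
    @given(
        seed=st.integers(0, 10_000),
        n_items=st.sampled_from([2, 3, 4]),
        space=st.sampled_from([CircularSpace.orientation(), CircularSpace.color()]),
    )
    def test_invariants_over_random_configs(self, seed, n_items, space):
        params = MixtureParams(0.6, 0.25, 0.15, 6.0)
        cfg = GeneratorConfig(
            space=space,
            n_participants=1,
            trials_per_condition=n_items * 3,
            n_blocks=1,
            n_items=n_items,
            conditions=(("same", "short"), ("different", "long")),
            mixture_by_condition={
                ("same", "short"): params,
                ("different", "long"): params,
            },
            seed=seed,
        )
        ts = generate_dataset(cfg)
        assert ts.n_trials == 2 * n_items * 3
        ts.validate(placement_radius=6.0, min_center_distance=3.0)


def test_mixture_proportion_match_at_scale():
    """Empirical component frequencies over 10^4+ trials stay within three
    binomial standard errors of the configured mixture."""
    truth = MixtureParams(0.67, 0.25, 0.08, 700.0)
    cfg = single_condition_config(truth, n_trials=12000, seed=77)
    ts = generate_dataset(cfg)
    devs = np.abs(wrap_diff(ts.response[:, None], ts.features, ts.space))
    close = devs.min(axis=1) < 6.0
    hit = devs.argmin(axis=1)
    p_t_emp = np.mean(close & (hit == ts.target_index))
    expected = 0.67 + 0.08 * 12.0 / 180.0  # plus uniform mass caught in the window
    se = np.sqrt(expected * (1 - expected) / 12000)
    assert abs(p_t_emp - expected) < 3 * se
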