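import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from swapmix import CircularSpace, MixtureParams, TrialSet
from swapmix.data import trial_columns

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def orientation():
    return CircularSpace.orientation()


@pytest.fixture
def color():
    return CircularSpace.color()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_trialset(
    space,
    features,
    target_index,
    response,
    locations=None,
    participant="p01",
    location_condition="same",
    isi_condition="short",
) -> TrialSet:
    """Assemble a TrialSet from raw arrays (no invariant checks)."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    n, m = features.shape
    target_index = np.broadcast_to(np.asarray(target_index, dtype=int), (n,))
    response = np.broadcast_to(np.asarray(response, dtype=float), (n,))
    if locations is None:
        locations = np.zeros((n, m))
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    df = pd.DataFrame(
        {
            "participant": participant,
            "location_condition": location_condition,
            "isi_condition": isi_condition,
            "trial_index": np.arange(n),
            "target_index": target_index,
            "response": response,
        }
    )
    for i in range(m):
        df[f"feature_{i}"] = features[:, i]
        df[f"location_{i}"] = locations[:, i]
    return TrialSet(space, df[trial_columns(m)])


@pytest.fixture
def tiny_orientation_trials(orientation):
    """Five hand-built four-item orientation trials for brute-force oracles."""
    features = [
        [10.0, 40.0, 90.0, 130.0],
        [0.0, 20.0, 60.0, 170.0],
        [15.0, 55.0, 95.0, 135.0],
        [5.0, 30.0, 80.0, 120.0],
        [45.0, 70.0, 110.0, 160.0],
    ]
    target_index = [0, 2, 1, 3, 0]
    response = [12.0, 65.0, 50.0, 119.0, 160.0]
    return build_trialset(orientation, features, target_index, response)


def single_condition_config(
    params: MixtureParams,
    n_trials: int = 120,
    seed: int = 0,
    space=None,
    **kwargs,
):
    """GeneratorConfig for one participant in one condition."""
    from swapmix import GeneratorConfig

    return GeneratorConfig(
        space=space or CircularSpace.orientation(),
        n_participants=1,
        trials_per_condition=n_trials,
        n_blocks=kwargs.pop("n_blocks", 1),
        conditions=(("same", "short"),),
        mixture_by_condition={("same", "short"): params},
        seed=seed,
        **kwargs,
    )
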