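"""Synthetic trial generator for sequential cued-recall experiments.

Emulates the structure of a four-item delayed-reproduction study: on each
trial four items are presented sequentially, each with a feature value on a
circular space (orientations differing by at least 10 degrees, or colors by
at least 20) and a location on an invisible placement circle (radius 6 dva;
in *different-location* trials the bar centres are at least 3 dva apart, in
*same-location* trials all items share one random location).  One item is
cued and its feature reported; responses are drawn from the three-component
mixture (target / swap / guess) with condition-dependent parameters.

Feature tuples and location tuples are sampled by whole-tuple rejection —
on any constraint violation the entire tuple is redrawn — which keeps the
joint distribution exchangeable and every marginal uniform.

Each participant in a condition completes 120 trials in three blocks of 40,
with every ordinal position cued ten times per block in random order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .circular import KAPPA_CEILING, CircularSpace, wrap_diff
from .data import ISI_CONDITIONS, LOCATION_CONDITIONS, TrialSet, trial_columns
from .exceptions import ConfigurationError, InvalidArgumentError
from .mixture import MixtureParams

Condition = tuple[str, str]

DEFAULT_CONDITIONS: tuple[Condition, ...] = (
    ("same", "short"),
    ("different", "short"),
    ("same", "long"),
    ("different", "long"),
)

#: Default generating mixtures: swap proportions elevated in the same-location
#: short-ISI condition relative to the other three, with target proportion
#: around two thirds and concentration 8 on the analysis circle — the effect
#: pattern and magnitudes characteristic of four-item sequential orientation
#: recall.
DEFAULT_MIXTURES: dict[Condition, MixtureParams] = {
    ("same", "short"): MixtureParams(0.67, 0.25, 0.08, 8.0),
    ("different", "short"): MixtureParams(0.67, 0.12, 0.21, 8.0),
    ("same", "long"): MixtureParams(0.70, 0.14, 0.16, 8.0),
    ("different", "long"): MixtureParams(0.70, 0.15, 0.15, 8.0),
}

_DEFAULT_MAX_ATTEMPTS = 10**5


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic dataset.

    ``swap_weights`` maps the relative ordinal position of a non-target
    (-3..-1, +1..+3 for four items) to an unnormalised probability weight;
    ``None`` means swaps are equally likely to land on any non-target, the
    exchangeable-non-target assumption of the mixture model.  Weights are
    renormalised per trial over the positions that exist for its target; a
    target position left with zero total weight falls back to a uniform swap
    destination.

    ``kappa_by_position`` optionally gives a per-ordinal-position
    concentration (to emulate recency); when set it overrides the mixture's
    ``kappa`` for responses centred on an item at that position.
    """

    space: CircularSpace = field(default_factory=CircularSpace.orientation)
    n_participants: int = 12
    trials_per_condition: int = 120
    n_items: int = 4
    n_blocks: int = 3
    conditions: tuple[Condition, ...] = DEFAULT_CONDITIONS
    mixture_by_condition: Mapping[Condition, MixtureParams] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURES)
    )
    swap_weights: Mapping[int, float] | None = None
    kappa_by_position: Sequence[float] | None = None
    placement_radius: float = 6.0
    min_center_distance: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ConfigurationError("n_items must be >= 1")
        if self.trials_per_condition % (self.n_items * self.n_blocks) != 0:
            raise ConfigurationError(
                "trials_per_condition must divide evenly into blocks with each "
                f"ordinal position cued equally often (got {self.trials_per_condition} "
                f"trials, {self.n_blocks} blocks, {self.n_items} items)"
            )
        for cond in self.conditions:
            loc, isi = cond
            if loc not in LOCATION_CONDITIONS or isi not in ISI_CONDITIONS:
                raise ConfigurationError(f"unknown condition {cond}")
            if cond not in self.mixture_by_condition:
                raise ConfigurationError(f"no mixture parameters for condition {cond}")
        if self.swap_weights is not None:
            valid = set(range(-(self.n_items - 1), self.n_items)) - {0}
            for pos, w in self.swap_weights.items():
                if pos not in valid:
                    raise ConfigurationError(f"swap weight for impossible position {pos}")
                if w < 0:
                    raise ConfigurationError("swap weights must be non-negative")
        if self.kappa_by_position is not None and len(self.kappa_by_position) != self.n_items:
            raise ConfigurationError("kappa_by_position must have one entry per item")
        if self.min_center_distance > 2 * self.placement_radius:
            raise ConfigurationError("min_center_distance exceeds the placement diameter")


def _min_pairwise_sep(angles: np.ndarray, period: float) -> np.ndarray:
    """Minimum absolute wrapped pairwise distance per row of ``(n, m)`` angles."""
    space = CircularSpace(period, 0.0)
    d = np.abs(wrap_diff(angles[:, :, None], angles[:, None, :], space))
    m = angles.shape[1]
    iu = np.triu_indices(m, k=1)
    return d[:, iu[0], iu[1]].min(axis=1)


def _rejection_sample(
    n: int,
    n_items: int,
    period: float,
    min_sep: float,
    rng: np.random.Generator,
    max_attempts: int,
) -> np.ndarray:
    """Draw ``n`` uniform ``n_items``-tuples with all pairwise wrapped
    distances >= ``min_sep``, redrawing whole tuples on violation."""
    out = np.empty((n, n_items))
    pending = np.arange(n)
    draws = 0
    while pending.size:
        cand = rng.uniform(0.0, period, size=(pending.size, n_items))
        draws += pending.size
        if n_items > 1 and min_sep > 0:
            ok = _min_pairwise_sep(cand, period) >= min_sep
        else:
            ok = np.ones(pending.size, dtype=bool)
        out[pending[ok]] = cand[ok]
        pending = pending[~ok]
        if draws > max_attempts * max(n, 1):
            raise RuntimeError(
                f"rejection sampling exceeded {draws} draws for {n} tuples "
                f"(min_sep={min_sep}, period={period}, n_items={n_items}); "
                "the constraint is too tight to sample efficiently"
            )
    return out


def sample_features(
    space: CircularSpace,
    n_items: int,
    rng: np.random.Generator,
    *,
    size: int | None = None,
    max_attempts: int = _DEFAULT_MAX_ATTEMPTS,
) -> np.ndarray:
    """Uniform feature tuples respecting the minimum pairwise separation.

    Returns shape ``(n_items,)`` or, with ``size``, ``(size, n_items)``.
    """
    if n_items * space.min_separation >= space.period:
        raise ConfigurationError(
            f"{n_items} items with min separation {space.min_separation} cannot fit "
            f"on a {space.period}-degree circle"
        )
    n = 1 if size is None else size
    out = _rejection_sample(n, n_items, space.period, space.min_separation, rng, max_attempts)
    return out[0] if size is None else out


def min_location_separation_deg(placement_radius: float, min_center_distance: float) -> float:
    """Angular separation implied by a chord-distance constraint on a circle."""
    return float(np.rad2deg(2.0 * np.arcsin(min_center_distance / (2.0 * placement_radius))))


def sample_locations(
    condition: str,
    n_items: int,
    placement_radius: float,
    min_center_distance: float,
    rng: np.random.Generator,
    *,
    size: int | None = None,
    max_attempts: int = _DEFAULT_MAX_ATTEMPTS,
) -> np.ndarray:
    """Item location angles (degrees on the placement circle) for one trial.

    ``same``: one uniform angle repeated for all items.  ``different``:
    whole-tuple rejection until every pairwise chord distance at the given
    radius is at least ``min_center_distance``.
    """
    if condition not in LOCATION_CONDITIONS:
        raise InvalidArgumentError(f"unknown location condition {condition!r}")
    n = 1 if size is None else size
    if condition == "same":
        angle = rng.uniform(0.0, 360.0, size=n)
        out = np.repeat(angle[:, None], n_items, axis=1)
    else:
        min_angle = min_location_separation_deg(placement_radius, min_center_distance)
        if n_items * min_angle >= 360.0:
            raise ConfigurationError(
                f"{n_items} locations with minimum angular separation {min_angle:.1f} "
                "degrees cannot fit on the placement circle"
            )
        out = _rejection_sample(n, n_items, 360.0, min_angle, rng, max_attempts)
    return out[0] if size is None else out


def _normalized_swap_matrix(
    target_index: np.ndarray,
    n_items: int,
    swap_weights: Mapping[int, float] | None,
) -> np.ndarray:
    """Per-trial probability of each item position being the swap destination."""
    n = len(target_index)
    pos = np.arange(n_items)[None, :]
    rel = pos - target_index[:, None]
    if swap_weights is None:
        w = np.ones((n, n_items))
    else:
        w = np.zeros((n, n_items))
        for d, weight in swap_weights.items():
            w[rel == d] = weight
    w[rel == 0] = 0.0
    totals = w.sum(axis=1, keepdims=True)
    # a target position for which no weighted non-target exists (e.g. all mass
    # on +1 with the last item cued) falls back to a uniform swap destination
    starved = totals[:, 0] == 0
    if np.any(starved):
        w[starved] = 1.0
        w[rel == 0] = 0.0
        totals = w.sum(axis=1, keepdims=True)
    return w / totals


def generate_responses(
    features: np.ndarray,
    target_index: np.ndarray,
    params: MixtureParams,
    space: CircularSpace,
    rng: np.random.Generator,
    *,
    swap_weights: Mapping[int, float] | None = None,
    kappa_by_position: Sequence[float] | None = None,
) -> np.ndarray:
    """Draw responses from the generative mixture for a batch of trials.

    Von Mises noise is applied on the analysis circle (doubled for
    orientation) and mapped back to the raw scale, so the generating
    ``kappa`` is directly comparable to a fitted one.
    """
    n, n_items = features.shape
    comp = rng.choice(3, size=n, p=[params.p_t, params.p_nt, params.p_u])

    center_idx = target_index.astype(int).copy()
    swap_rows = np.flatnonzero(comp == 1)
    if swap_rows.size and n_items > 1:
        probs = _normalized_swap_matrix(target_index[swap_rows], n_items, swap_weights)
        u = rng.random(swap_rows.size)
        center_idx[swap_rows] = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)

    if kappa_by_position is not None:
        kappa = np.asarray(kappa_by_position, dtype=float)[center_idx]
    else:
        kappa = np.full(n, params.kappa)
    kappa = np.minimum(kappa, KAPPA_CEILING)

    noise_rad = rng.vonmises(0.0, np.maximum(kappa, 1e-12))
    noise_deg_raw = np.rad2deg(noise_rad) / space.analysis_scale
    centers = features[np.arange(n), center_idx]
    response = np.mod(centers + noise_deg_raw, space.period)

    guess_rows = comp == 2
    response[guess_rows] = rng.uniform(0.0, space.period, size=int(guess_rows.sum()))
    return response


def generate_response(
    features: np.ndarray,
    target_index: int,
    params: MixtureParams,
    space: CircularSpace,
    rng: np.random.Generator,
    **kwargs,
) -> float:
    """Single-trial convenience wrapper around :func:`generate_responses`."""
    resp = generate_responses(
        np.asarray(features, dtype=float)[None, :],
        np.array([target_index]),
        params,
        space,
        rng,
        **kwargs,
    )
    return float(resp[0])


def _balanced_targets(
    trials_per_condition: int, n_items: int, n_blocks: int, rng: np.random.Generator
) -> np.ndarray:
    """Target positions, each cued equally often within each block, shuffled
    within block."""
    per_block = trials_per_condition // n_blocks
    reps = per_block // n_items
    blocks = [rng.permutation(np.repeat(np.arange(n_items), reps)) for _ in range(n_blocks)]
    return np.concatenate(blocks)


def _participant_rng(seed: int, participant_index: int) -> np.random.Generator:
    # Fixed per-participant substream: reproducible regardless of how many
    # participants are generated.
    return np.random.default_rng([seed, participant_index])


def generate_participant(config: GeneratorConfig, participant_index: int) -> pd.DataFrame:
    """Generate every condition for one participant (deterministic in
    ``config.seed`` and the participant index)."""
    rng = _participant_rng(config.seed, participant_index)
    frames = []
    for loc_cond, isi_cond in config.conditions:
        n = config.trials_per_condition
        feats = sample_features(config.space, config.n_items, rng, size=n)
        locs = sample_locations(
            loc_cond,
            config.n_items,
            config.placement_radius,
            config.min_center_distance,
            rng,
            size=n,
        )
        targets = _balanced_targets(n, config.n_items, config.n_blocks, rng)
        params = config.mixture_by_condition[(loc_cond, isi_cond)]
        resp = generate_responses(
            feats,
            targets,
            params,
            config.space,
            rng,
            swap_weights=config.swap_weights,
            kappa_by_position=config.kappa_by_position,
        )
        df = pd.DataFrame(
            {
                "participant": f"p{participant_index + 1:02d}",
                "location_condition": loc_cond,
                "isi_condition": isi_cond,
                "trial_index": np.arange(n),
                "target_index": targets,
                "response": resp,
            }
        )
        for i in range(config.n_items):
            df[f"feature_{i}"] = feats[:, i]
            df[f"location_{i}"] = locs[:, i]
        frames.append(df[trial_columns(config.n_items)])
    return pd.concat(frames, ignore_index=True)


def generate_dataset(config: GeneratorConfig) -> TrialSet:
    """Generate the full dataset: all conditions for all participants.

    Identical configs (including seed) yield identical datasets.
    """
    frames = [generate_participant(config, p) for p in range(config.n_participants)]
    return TrialSet(config.space, pd.concat(frames, ignore_index=True))
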