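"""Swap gradients: response–non-target MAD by temporal and spatial distance.

If swap errors occur preferentially for non-targets at a particular
temporal separation (ordinal-position difference) or spatial distance from
the target, the mean absolute deviation (MAD) of responses from those
non-targets falls below the chance level; the minimum feature separation
within trials then pushes MADs at other separations slightly above it.  The
chance level is obtained with the same exhaustive trial-shuffling used for
the histogram correction: the MAD of each response from all shuffled
non-target features, averaged across participant × condition slices.

Note the MAD measure does not by itself discriminate swap errors from
response biases toward non-target features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import CircularSpace, circ_mad, wrap_diff
from .data import TrialSet
from .exceptions import EmptyInputError
from .histograms import shuffle_deviations

logger = logging.getLogger(__name__)

#: Spatial distance bins on the placement circle, degrees; right-closed:
#: (0, 67.5], (67.5, 105], (105, 142.5], (142.5, 180].  With a ~30-degree
#: minimum angular separation between items these bins receive nearly equal
#: numbers of non-targets.
SPATIAL_BIN_EDGES = np.array([0.0, 67.5, 105.0, 142.5, 180.0])

_LOCATION_CIRCLE = CircularSpace(360.0, 0.0)


@dataclass
class DistanceProfile:
    """MAD of responses from non-targets per distance group.

    Groups with no observations carry ``n = 0`` and ``mad = nan`` (absent,
    not zero).  ``expected_mad`` is the shuffle-derived chance level.
    """

    grouping: str
    group_labels: np.ndarray
    mad: np.ndarray
    n: np.ndarray
    expected_mad: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grouping": self.grouping,
                "group_label": self.group_labels,
                "mad": self.mad,
                "n": self.n,
                "expected_mad": self.expected_mad,
            }
        )


def _profile_from_pools(
    grouping: str, labels, pools: list[np.ndarray], space: CircularSpace, expected: float
) -> DistanceProfile:
    mads = np.array([circ_mad(p, space) if p.size else np.nan for p in pools])
    ns = np.array([p.size for p in pools])
    return DistanceProfile(grouping, np.asarray(labels), mads, ns, expected)


def mad_by_temporal_separation(
    trials: TrialSet, expected_mad: float = np.nan
) -> DistanceProfile:
    """MAD of responses from non-targets grouped by relative ordinal position.

    For four items the groups run from three positions before the target
    (-3) to three after (+3), excluding 0; a group only receives deviations
    from trials where that relative position exists.
    """
    if trials.n_trials == 0:
        raise EmptyInputError("mad_by_temporal_separation requires trials")
    m = trials.n_items
    feats = trials.features
    resp = trials.response
    ti = trials.target_index
    labels = [d for d in range(-(m - 1), m) if d != 0]
    pools = []
    for d in labels:
        pos = ti + d
        rows = (pos >= 0) & (pos < m)
        devs = wrap_diff(resp[rows], feats[rows, pos[rows]], trials.space)
        pools.append(np.atleast_1d(devs))
    return _profile_from_pools("temporal", labels, pools, trials.space, expected_mad)


def spatial_bin_index(distances: np.ndarray) -> np.ndarray:
    """Assign angular distances in (0, 180] to the four right-closed bins."""
    return np.searchsorted(SPATIAL_BIN_EDGES[1:-1], distances, side="left")


def mad_by_spatial_bin(trials: TrialSet, expected_mad: float = np.nan) -> DistanceProfile:
    """MAD of responses from non-targets grouped by target-to-non-target
    angular distance on the placement circle (different-location trials only;
    same-location trials are excluded with a logged count)."""
    keep = trials.table["location_condition"] == "different"
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("mad_by_spatial_bin: excluded %d same-location trials", n_excluded)
    sub = TrialSet(trials.space, trials.table.loc[keep].reset_index(drop=True))
    if sub.n_trials == 0:
        raise EmptyInputError("mad_by_spatial_bin requires different-location trials")

    dist = np.abs(
        wrap_diff(sub.nontarget_locations, sub.target_location[:, None], _LOCATION_CIRCLE)
    )
    devs = wrap_diff(sub.response[:, None], sub.nontarget_features, sub.space)
    bins = spatial_bin_index(dist.ravel())
    flat = devs.ravel()
    pools = [flat[bins == b] for b in range(4)]
    labels = [
        f"({SPATIAL_BIN_EDGES[i]:g}, {SPATIAL_BIN_EDGES[i + 1]:g}]" for i in range(4)
    ]
    return _profile_from_pools("spatial", labels, pools, sub.space, expected_mad)


def expected_mad_shuffled(trials: TrialSet) -> float:
    """Chance-level MAD for one participant × condition slice.

    The MAD of each response from all shuffled non-target features
    (exhaustive over ordered trial pairs), reflecting the minimum-separation
    constraint; with unconstrained features and uniform responses this tends
    to period/4.
    """
    return circ_mad(shuffle_deviations(trials), trials.space)


def chance_mad_line(trials: TrialSet) -> float:
    """The single chance level used as reference line: per-slice shuffled
    MADs averaged across participants and conditions."""
    values = [expected_mad_shuffled(sub) for _, sub in trials.slices()]
    if not values:
        raise EmptyInputError("chance_mad_line requires trials")
    return float(np.mean(values))


def distance_profiles_table(trials: TrialSet) -> pd.DataFrame:
    """Tidy per-slice temporal and spatial profiles with the shuffle baseline."""
    rows = []
    for (participant, loc, isi), sub in trials.slices():
        expected = expected_mad_shuffled(sub)
        profiles = [mad_by_temporal_separation(sub, expected)]
        if loc == "different":
            profiles.append(mad_by_spatial_bin(sub, expected))
        for prof in profiles:
            df = prof.to_frame()
            df["participant"] = participant
            df["location_condition"] = loc
            df["isi_condition"] = isi
            rows.append(df)
    return pd.concat(rows, ignore_index=True)
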