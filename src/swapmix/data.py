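"""Trial-level data container.

A :class:`TrialSet` wraps a pandas DataFrame with one row per trial and the
:class:`~swapmix.circular.CircularSpace` its features live on.  Columns:

- ``participant`` — participant identifier
- ``location_condition`` — ``same`` or ``different``
- ``isi_condition`` — ``short`` or ``long``
- ``trial_index`` — running index within participant × condition
- ``target_index`` — 0-based ordinal position of the cued item
- ``feature_0 .. feature_{m-1}`` — item feature values in presentation order,
  degrees on the raw feature circle
- ``location_0 .. location_{m-1}`` — item location angles on the placement
  circle, degrees on a 360-degree circle
- ``response`` — reported feature value, degrees

All angles are stored on the raw feature scale; the factor-two analysis
scaling for orientation never appears at rest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .circular import CircularSpace, wrap_diff
from .exceptions import ValidationError

LOCATION_CONDITIONS = ("same", "different")
ISI_CONDITIONS = ("short", "long")

_FIXED_COLUMNS = (
    "participant",
    "location_condition",
    "isi_condition",
    "trial_index",
    "target_index",
    "response",
)


def feature_columns(n_items: int) -> list[str]:
    return [f"feature_{i}" for i in range(n_items)]


def location_columns(n_items: int) -> list[str]:
    return [f"location_{i}" for i in range(n_items)]


def trial_columns(n_items: int) -> list[str]:
    """Canonical column order for a trial table with ``n_items`` items."""
    return [
        "participant",
        "location_condition",
        "isi_condition",
        "trial_index",
        "target_index",
        *feature_columns(n_items),
        *location_columns(n_items),
        "response",
    ]


@dataclass
class TrialSet:
    """A set of cued-recall trials on one circular feature space."""

    space: CircularSpace
    table: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return len(self.table)

    @property
    def n_items(self) -> int:
        return sum(1 for c in self.table.columns if c.startswith("feature_"))

    @property
    def features(self) -> np.ndarray:
        """Item features in presentation order, shape ``(n_trials, n_items)``."""
        return self.table[feature_columns(self.n_items)].to_numpy(dtype=float)

    @property
    def locations(self) -> np.ndarray:
        return self.table[location_columns(self.n_items)].to_numpy(dtype=float)

    @property
    def response(self) -> np.ndarray:
        return self.table["response"].to_numpy(dtype=float)

    @property
    def target_index(self) -> np.ndarray:
        return self.table["target_index"].to_numpy(dtype=int)

    @property
    def target_feature(self) -> np.ndarray:
        f = self.features
        return f[np.arange(len(f)), self.target_index]

    @property
    def target_location(self) -> np.ndarray:
        loc = self.locations
        return loc[np.arange(len(loc)), self.target_index]

    def nontarget_mask(self) -> np.ndarray:
        """Boolean ``(n_trials, n_items)``; True where the item is a non-target."""
        n, m = self.n_trials, self.n_items
        mask = np.ones((n, m), dtype=bool)
        mask[np.arange(n), self.target_index] = False
        return mask

    @property
    def nontarget_features(self) -> np.ndarray:
        """Non-target features, shape ``(n_trials, n_items - 1)``, presentation order."""
        mask = self.nontarget_mask()
        return self.features[mask].reshape(self.n_trials, self.n_items - 1)

    @property
    def nontarget_locations(self) -> np.ndarray:
        mask = self.nontarget_mask()
        return self.locations[mask].reshape(self.n_trials, self.n_items - 1)

    def select(
        self,
        participant=None,
        location: str | None = None,
        isi: str | None = None,
    ) -> "TrialSet":
        """Subset by participant and/or condition labels."""
        keep = pd.Series(True, index=self.table.index)
        if participant is not None:
            keep &= self.table["participant"] == participant
        if location is not None:
            keep &= self.table["location_condition"] == location
        if isi is not None:
            keep &= self.table["isi_condition"] == isi
        return TrialSet(self.space, self.table.loc[keep].reset_index(drop=True))

    def slices(self) -> Iterator[tuple[tuple, "TrialSet"]]:
        """Iterate participant × condition slices in a deterministic order.

        Analyses that involve trial shuffling must operate on these slices
        before any pooling.
        """
        keys = ["participant", "location_condition", "isi_condition"]
        for key, sub in self.table.groupby(keys, sort=True):
            yield key, TrialSet(self.space, sub.reset_index(drop=True))

    def participants(self) -> list:
        return sorted(self.table["participant"].unique().tolist())

    def conditions(self) -> list[tuple[str, str]]:
        pairs = self.table[["location_condition", "isi_condition"]].drop_duplicates()
        return sorted(map(tuple, pairs.to_numpy().tolist()))

    def validate(self, placement_radius=None, min_center_distance=None) -> None:
        """Raise :class:`ValidationError` naming every trial that violates an
        invariant (target index range, feature separation, same-location
        geometry, and — when the placement geometry is supplied — minimum
        chord distance in different-location trials)."""
        problems: list[str] = []
        n, m = self.n_trials, self.n_items
        if n == 0:
            return
        ti = self.table["target_index"].to_numpy()
        bad_ti = np.flatnonzero((ti < 0) | (ti >= m))
        problems += [f"trial {i}: target_index {ti[i]} out of range" for i in bad_ti]

        feats = self.features
        sep = np.abs(wrap_diff(feats[:, :, None], feats[:, None, :], self.space))
        iu = np.triu_indices(m, k=1)
        min_sep = sep[:, iu[0], iu[1]].min(axis=1)
        bad_sep = np.flatnonzero(min_sep < self.space.min_separation - 1e-9)
        problems += [
            f"trial {i}: feature separation {min_sep[i]:.3f} < {self.space.min_separation}"
            for i in bad_sep
        ]

        locs = self.locations
        loc_cond = self.table["location_condition"].to_numpy()
        ldiff = np.abs(wrap_diff(locs[:, :, None], locs[:, None, :], CircularSpace(360.0, 0.0)))
        pair_ldiff = ldiff[:, iu[0], iu[1]]
        same_rows = loc_cond == "same"
        bad_same = np.flatnonzero(same_rows & (pair_ldiff.max(axis=1) > 1e-6))
        problems += [f"trial {i}: same-location trial with unequal locations" for i in bad_same]
        if placement_radius is not None and min_center_distance is not None:
            chord = 2.0 * placement_radius * np.sin(np.deg2rad(pair_ldiff) / 2.0)
            bad_diff = np.flatnonzero(
                (loc_cond == "different") & (chord.min(axis=1) < min_center_distance - 1e-9)
            )
            problems += [
                f"trial {i}: different-location chord distance below {min_center_distance}"
                for i in bad_diff
            ]
        if problems:
            raise ValidationError(
                f"{len(problems)} invalid trial(s):\n" + "\n".join(problems[:50])
            )
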