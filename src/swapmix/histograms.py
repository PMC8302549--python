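"""Deviation histograms, the trial-shuffling correction, and heuristic measures.

The central diagnostic for swap errors is the histogram of response
deviations from the non-target features of the same trial.  Because items
within a trial are constrained to differ by a minimum feature distance, this
histogram is non-uniform even in the complete absence of swaps.  The
correction transplants the target-to-non-target offsets of one trial, A,
onto the target of another trial, B — yielding pseudo-non-targets that obey
the separation constraints but are unrelated to B's response — and does so
for every ordered pair of trials within a participant × condition slice.
The resulting expected histogram, rescaled to the observed mass, is
subtracted from the observed one; any remaining central peak indicates
genuine swaps.

Heuristic proportions count responses falling within a fixed window of the
target (or of any non-target) and deliberately use the *uncorrected*
deviations.  The default bin width (15 degrees for orientation, 30 for
color) makes the two central histogram bins coincide exactly with the
heuristic window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import CircularSpace, wrap_diff
from .data import TrialSet
from .exceptions import ConfigurationError, EmptyInputError, InvalidArgumentError


@dataclass
class DeviationHistogram:
    """Observed, shuffle-expected, and corrected deviation counts.

    Bins are uniform, symmetric about zero, on the raw feature scale.
    ``expected`` is rescaled so its total mass equals the observed mass,
    hence ``corrected`` sums to zero by construction.
    """

    bin_edges: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    corrected: np.ndarray
    normalization: float

    @classmethod
    def build(cls, bin_edges, observed, expected) -> "DeviationHistogram":
        observed = np.asarray(observed, dtype=float)
        total = float(observed.sum())
        expected = np.asarray(expected, dtype=float)
        if expected.sum() > 0:
            expected = expected * (total / expected.sum())
        return cls(
            bin_edges=np.asarray(bin_edges, dtype=float),
            observed=observed,
            expected=expected,
            corrected=observed - expected,
            normalization=total,
        )

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "observed": self.observed,
                "expected": self.expected,
                "corrected": self.corrected,
            }
        )


def make_bin_edges(space: CircularSpace, bin_width: float) -> np.ndarray:
    """Uniform bin edges covering ``(-period/2, period/2]`` symmetrically."""
    n_bins = space.period / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9 or round(n_bins) % 2 != 0:
        raise ConfigurationError(
            f"bin width {bin_width} must divide the {space.period}-degree deviation "
            "range into an even number of bins"
        )
    n_bins = int(round(n_bins))
    return -space.period / 2 + bin_width * np.arange(n_bins + 1)


def _histogram(devs: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # np.histogram closes the last bin on the right, which together with the
    # wrap convention (+period/2, never -period/2) makes binning deterministic.
    counts, _ = np.histogram(devs, bins=edges)
    return counts.astype(float)


def target_error_histogram(trials: TrialSet, bin_width: float) -> DeviationHistogram:
    """Histogram of response errors (deviations from the target feature).

    The ``expected`` reference is flat — uniform guessing — which is the
    natural plotting baseline for target errors.
    """
    if trials.n_trials == 0:
        raise EmptyInputError("target_error_histogram requires trials")
    edges = make_bin_edges(trials.space, bin_width)
    devs = wrap_diff(trials.response, trials.target_feature, trials.space)
    observed = _histogram(devs, edges)
    expected = np.full(len(edges) - 1, observed.sum() / (len(edges) - 1))
    return DeviationHistogram.build(edges, observed, expected)


def nontarget_deviations(trials: TrialSet) -> np.ndarray:
    """Wrapped deviations of each response from every non-target, flattened
    (``n_trials * (n_items - 1)`` values)."""
    devs = wrap_diff(trials.response[:, None], trials.nontarget_features, trials.space)
    return devs.ravel()


def nontarget_deviation_histogram(trials: TrialSet, bin_width: float) -> np.ndarray:
    """Observed counts of response deviations from non-target features."""
    if trials.n_trials == 0:
        raise EmptyInputError("nontarget_deviation_histogram requires trials")
    edges = make_bin_edges(trials.space, bin_width)
    return _histogram(nontarget_deviations(trials), edges)


def shuffle_deviations(trials: TrialSet, chunk: int = 512) -> np.ndarray:
    """Deviations of each response from all *shuffled* non-target features.

    For every ordered pair of distinct trials (A, B) within the slice, the
    non-target offsets of A are transplanted onto B's target and B's response
    deviation from each pseudo-non-target recorded.  N trials with m
    non-targets yield ``N*(N-1)*m`` deviations.  Exhaustive (no subsampling),
    so the result is deterministic given the data.
    """
    n = trials.n_trials
    if n < 2:
        raise EmptyInputError("the shuffling correction requires at least 2 trials")
    space = trials.space
    d0 = wrap_diff(trials.response, trials.target_feature, space)  # (n,)
    offsets = wrap_diff(trials.nontarget_features, trials.target_feature[:, None], space)

    out = []
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        # wrap(d0_B - offset_A): (chunk_B, n_A, m)
        block = wrap_diff(d0[start:stop, None, None], offsets[None, :, :], space)
        mask = np.ones((stop - start, n), dtype=bool)
        mask[np.arange(stop - start), np.arange(start, stop)] = False
        out.append(block[mask].ravel())
    return np.concatenate(out)


def shuffle_expected_histogram(trials: TrialSet, bin_width: float) -> np.ndarray:
    """Expected non-target deviation counts in the absence of swaps,
    rescaled so the total mass matches the observed histogram's
    (``n_trials * (n_items - 1)``)."""
    edges = make_bin_edges(trials.space, bin_width)
    counts = _histogram(shuffle_deviations(trials), edges)
    return counts / (trials.n_trials - 1)


def corrected_nontarget_histogram(trials: TrialSet, bin_width: float) -> DeviationHistogram:
    """Shuffle-corrected non-target deviation histogram.

    Shuffling is performed separately within each participant × condition
    slice (trials are only exchangeable within a slice); observed and
    expected counts are then summed over slices.
    """
    edges = make_bin_edges(trials.space, bin_width)
    observed = np.zeros(len(edges) - 1)
    expected = np.zeros(len(edges) - 1)
    for _, sub in trials.slices():
        observed += nontarget_deviation_histogram(sub, bin_width)
        expected += shuffle_expected_histogram(sub, bin_width)
    return DeviationHistogram.build(edges, observed, expected)


def heuristic_proportions(trials: TrialSet, window: float) -> tuple[float, float]:
    """Model-free proportions of target-like and swap-like responses.

    ``p_t`` is the fraction of responses within ``window`` degrees of the
    target feature; ``p_nt`` the fraction within the same window of *any*
    non-target.  A response can count toward both.  Uses uncorrected
    deviations by design.
    """
    if window <= 0 or window > trials.space.period / 4:
        raise InvalidArgumentError(
            f"heuristic window must lie in (0, period/4], got {window}"
        )
    if trials.n_trials == 0:
        raise EmptyInputError("heuristic_proportions requires trials")
    t_dev = np.abs(wrap_diff(trials.response, trials.target_feature, trials.space))
    nt_dev = np.abs(
        wrap_diff(trials.response[:, None], trials.nontarget_features, trials.space)
    )
    p_t = float(np.mean(t_dev <= window))
    p_nt = float(np.mean((nt_dev <= window).any(axis=1)))
    return p_t, p_nt


def heuristic_table(trials: TrialSet, window: float) -> pd.DataFrame:
    """Tidy per-slice heuristic proportions."""
    rows = []
    for (participant, loc, isi), sub in trials.slices():
        p_t, p_nt = heuristic_proportions(sub, window)
        rows.append(
            {
                "participant": participant,
                "location_condition": loc,
                "isi_condition": isi,
                "p_t_heuristic": p_t,
                "p_nt_heuristic": p_nt,
                "n_trials": sub.n_trials,
            }
        )
    return pd.DataFrame(rows)


def mean_abs_error_by_position(trials: TrialSet) -> pd.DataFrame:
    """Mean absolute response error per ordinal position of the cued item,
    per participant × condition (the model-free recency measure)."""
    devs = wrap_diff(trials.response, trials.target_feature, trials.space)
    df = trials.table[
        ["participant", "location_condition", "isi_condition", "target_index"]
    ].copy()
    df["abs_error"] = np.abs(devs)
    out = (
        df.groupby(
            ["participant", "location_condition", "isi_condition", "target_index"],
            sort=True,
        )["abs_error"]
        .agg(mae="mean", n="count")
        .reset_index()
    )
    return out
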