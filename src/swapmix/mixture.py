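"""Three-component mixture model of continuous-report errors.

Each response is modelled as drawn from a von Mises distribution centred on
the target feature (probability ``p_T``), a von Mises centred on one of the
non-target features in the same trial — a swap error — (total probability
``p_NT``, split equally over the non-targets), or a circular-uniform guess
(``p_U``).  All von Mises components share one concentration ``kappa``.  On
the analysis circle (orientation data doubled to cover 360 degrees) the
density of a response ``x`` given target ``t`` and non-targets ``f_i`` is::

    p(x) = p_T * vm(x; t, kappa)
         + p_NT * (1/m) * sum_i vm(x; f_i, kappa)
         + p_U / (2*pi)

with ``m`` the number of non-targets (3 for four-item trials).

Fitting is by expectation–maximisation over per-trial component
responsibilities, with closed-form M-steps: mixing proportions are mean
responsibilities, and ``kappa`` is the Bessel-ratio inverse of the
responsibility-weighted resultant of component-centred deviations.  The
likelihood is multimodal when the target and swap clusters overlap, so the
fit is multistarted and the best final likelihood wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .circular import KAPPA_CEILING, CircularSpace, kappa_from_resultant, wrap_diff
from .data import TrialSet
from .exceptions import EmptyInputError, InvalidArgumentError

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class MixtureParams:
    """Mixing proportions and shared concentration of the response mixture.

    ``kappa`` is expressed on the analysis circle (i.e. after the factor-two
    scaling for orientation data), which is the scale on which concentration
    estimates are conventionally reported.
    """

    p_t: float
    p_nt: float
    p_u: float
    kappa: float

    def __post_init__(self) -> None:
        for name, p in (("p_t", self.p_t), ("p_nt", self.p_nt), ("p_u", self.p_u)):
            if not np.isfinite(p) or p < -1e-12 or p > 1 + 1e-12:
                raise InvalidArgumentError(f"{name} must lie in [0, 1], got {p}")
        if abs(self.p_t + self.p_nt + self.p_u - 1.0) > 1e-9:
            raise InvalidArgumentError(
                f"proportions must sum to 1, got {self.p_t + self.p_nt + self.p_u}"
            )
        if not np.isfinite(self.kappa) or self.kappa < 0 or self.kappa > KAPPA_CEILING:
            raise InvalidArgumentError(
                f"kappa must lie in [0, {KAPPA_CEILING}], got {self.kappa}"
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p_t, self.p_nt, self.p_u, self.kappa)


@dataclass
class MixtureFit:
    """Result of a maximum-likelihood mixture fit.

    ``responsibilities`` holds, per trial, the posterior weight of each
    component in the order ``[target, non-target 1 .. m, uniform]`` (rows sum
    to one).  ``ll_trace`` is the EM log-likelihood trajectory of the winning
    start, non-decreasing by construction.
    """

    params: MixtureParams
    log_likelihood: float
    n_trials: int
    n_restarts_used: int
    converged: bool
    responsibilities: np.ndarray
    ll_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def to_analysis_scale(values, space: CircularSpace):
    """Map raw feature degrees onto the 360-degree analysis circle.

    Period-180 spaces are scaled by a factor of two; full-circle spaces pass
    through unchanged (the general rule is multiplication by ``360/period``).
    """
    return np.asarray(values, dtype=float) * space.analysis_scale


def from_analysis_scale(values, space: CircularSpace):
    """Inverse of :func:`to_analysis_scale`."""
    return np.asarray(values, dtype=float) / space.analysis_scale


def _deviation_matrix(trials: TrialSet) -> np.ndarray:
    """Wrapped response deviations on the analysis circle, in radians.

    Column 0 is the deviation from the target; columns 1..m are deviations
    from the non-targets in presentation order.  Shape ``(n_trials, m + 1)``.
    """
    centers = np.column_stack([trials.target_feature, trials.nontarget_features])
    dev_deg = wrap_diff(trials.response[:, None], centers, trials.space)
    return np.deg2rad(dev_deg * trials.space.analysis_scale)


def _component_densities(cos_d: np.ndarray, kappa) -> np.ndarray:
    """Von Mises density per radian at precomputed cos(deviation)."""
    kappa = np.asarray(kappa, dtype=float)
    return np.exp(kappa * (cos_d - 1.0)) / (_TWO_PI * special.i0e(kappa))


def _trial_likelihood(d_cos: np.ndarray, params: MixtureParams) -> np.ndarray:
    f = _component_densities(d_cos, params.kappa)
    lik = params.p_t * f[:, 0] + params.p_u / _TWO_PI
    if d_cos.shape[1] > 1:
        lik = lik + params.p_nt * f[:, 1:].mean(axis=1)
    return lik


def mixture_loglik(trials: TrialSet, params: MixtureParams) -> float:
    """Summed log-likelihood (nats) of the mixture over a slice of trials."""
    if trials.n_trials == 0:
        raise EmptyInputError("mixture_loglik requires at least one trial")
    d = _deviation_matrix(trials)
    lik = _trial_likelihood(np.cos(d), params)
    return float(np.sum(np.log(np.maximum(lik, 1e-300))))


# Multistart lattice: (p_t, p_nt) coarse grid crossed with kappa levels.
_LATTICE_PROPS = ((0.8, 0.1), (0.5, 0.3), (0.3, 0.3))
_LATTICE_KAPPAS = (2.0, 8.0, 32.0)


def _initial_starts(d0_rad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Starting values: one moment-based start plus a 3x3 lattice."""
    props = [(0.6, 0.3, 0.1)]
    mean_cos = float(np.clip(np.mean(np.cos(d0_rad)), 0.0, 1.0))
    kappa0 = float(np.clip(kappa_from_resultant(mean_cos), 0.5, KAPPA_CEILING))
    kappas = [kappa0]
    for p_t, p_nt in _LATTICE_PROPS:
        for k in _LATTICE_KAPPAS:
            props.append((p_t, p_nt, 1.0 - p_t - p_nt))
            kappas.append(k)
    return np.array(props), np.array(kappas)


def fit_mixture(
    trials: TrialSet,
    *,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> MixtureFit:
    """Maximum-likelihood fit of the mixture to one participant × condition slice.

    Runs EM from 10 starting points (one moment-based, nine on a coarse
    lattice), batched so all starts iterate in lockstep; the start with the
    best final likelihood wins, ties broken in favour of the lower
    concentration.  Convergence is declared when the log-likelihood changes
    by less than ``tol`` nats or after ``max_iter`` iterations.

    Proportions may converge to exact zeros; such boundary estimates are
    returned as-is.
    """
    n = trials.n_trials
    if n == 0:
        raise EmptyInputError("fit_mixture requires trials")
    if n == 1:
        raise InvalidArgumentError("cannot fit a mixture to a single trial")
    if n < 10:
        warnings.warn(
            f"fitting a 4-parameter mixture to only {n} trials; estimates will be unstable",
            stacklevel=2,
        )

    d = _deviation_matrix(trials)  # (n, m+1) radians
    cos_d = np.cos(d)
    m = d.shape[1] - 1

    props, kappas = _initial_starts(d[:, 0])
    n_starts = len(kappas)
    # Component weights per start: [p_t, p_nt/m * m, p_u]  -> (S, m+2)
    weights = np.column_stack(
        [props[:, 0], *(props[:, 1:2] / m,) * m, props[:, 2]]
    )
    kappa = kappas.copy()

    ll_prev = np.full(n_starts, -np.inf)
    traces: list[list[float]] = [[] for _ in range(n_starts)]
    active = np.ones(n_starts, dtype=bool)
    converged = np.zeros(n_starts, dtype=bool)

    def _e_step(w, k):
        """Joint component probabilities and per-trial likelihood."""
        dens = np.empty((len(k), n, m + 2))
        dens[:, :, : m + 1] = _component_densities(cos_d[None, :, :], k[:, None, None])
        dens[:, :, m + 1] = 1.0 / _TWO_PI
        joint = w[:, None, :] * dens
        lik = joint.sum(axis=2)
        return joint, lik

    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        joint, lik = _e_step(weights[idx], kappa[idx])
        ll = np.log(np.maximum(lik, 1e-300)).sum(axis=1)
        gamma = joint / np.maximum(lik, 1e-300)[:, :, None]

        new_w = gamma.mean(axis=1)
        # non-targets share one proportion p_nt split equally (1/m each)
        new_w[:, 1 : m + 1] = new_w[:, 1 : m + 1].sum(axis=1, keepdims=True) / m
        # kappa M-step: component means are fixed at the item features, so the
        # sufficient statistic is the responsibility-weighted mean cosine of
        # the centred deviations (not the resultant length, which re-estimates
        # a free mean direction)
        g_vm = gamma[:, :, : m + 1]
        w_tot = g_vm.sum(axis=(1, 2))
        c = (g_vm * cos_d[None]).sum(axis=(1, 2))
        mean_cos = np.where(w_tot > 0, c / np.maximum(w_tot, 1e-300), 0.0)
        new_kappa = kappa_from_resultant(np.clip(mean_cos, 0.0, 1.0))

        weights[idx] = new_w
        kappa[idx] = np.atleast_1d(new_kappa)
        for j, i in enumerate(idx):
            traces[i].append(float(ll[j]))
        done = np.abs(ll - ll_prev[idx]) < tol
        converged[idx[done]] = True
        active[idx[done]] = False
        ll_prev[idx] = ll

    best_ll = np.max(ll_prev)
    contenders = np.flatnonzero(ll_prev >= best_ll - 1e-9)
    best = contenders[np.argmin(kappa[contenders])]

    joint, lik = _e_step(weights[[best]], kappa[[best]])
    resp = (joint / np.maximum(lik, 1e-300)[:, :, None])[0]
    final_ll = float(np.log(np.maximum(lik, 1e-300)).sum())

    p_nt = float(weights[best, 1 : m + 1].sum())
    params = MixtureParams(
        p_t=float(np.clip(weights[best, 0], 0.0, 1.0)),
        p_nt=float(np.clip(p_nt, 0.0, 1.0)),
        p_u=float(np.clip(1.0 - weights[best, 0] - p_nt, 0.0, 1.0)),
        kappa=float(kappa[best]),
    )
    return MixtureFit(
        params=params,
        log_likelihood=final_ll,
        n_trials=n,
        n_restarts_used=n_starts,
        converged=bool(converged[best]),
        responsibilities=resp,
        ll_trace=np.asarray(traces[best]),
    )


def fit_all_slices(trials: TrialSet, **kwargs) -> dict[tuple, MixtureFit]:
    """Fit every participant × condition slice; keys are (participant, location, isi)."""
    return {key: fit_mixture(sub, **kwargs) for key, sub in trials.slices()}
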