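"""JZS Bayes factors, the swap-interaction statistic, and sequential stopping.

The default Bayesian t test places a Cauchy prior with scale ``r`` on the
standardized effect size under the alternative (equivalently, a
Jeffreys–Zellner–Siow g-prior with ``g ~ InverseGamma(1/2, r^2/2)``) and a
point mass at zero under the null.  The Bayes factor is the ratio of
marginal likelihoods of the observed t statistic,

    BF10 = ∫ (1+Ng)^(-1/2) (1 + t²/((1+Ng)ν))^(-(ν+1)/2) p(g) dg
           ───────────────────────────────────────────────────────
                         (1 + t²/ν)^(-(ν+1)/2)

with ``ν = N - 1`` degrees of freedom, evaluated by adaptive quadrature.
The default scale ``r = sqrt(2)/2`` matches the conventional "medium" prior
of standard Bayesian analysis software.

The interaction of location and ISI conditions on the swap proportion is
summarised per participant by the difference of differences

    Δp_NT = (p_NT(different, short) - p_NT(same, short))
          - (p_NT(different, long)  - p_NT(same, long))

and a one-sample Bayesian t test on Δp_NT drives the sequential stopping
rule: stop once BF10 > threshold (evidence for an effect) or BF01 >
threshold (evidence against), or at the participant cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate, stats

from .exceptions import EmptyInputError, InvalidArgumentError
from .mixture import MixtureParams

#: Default Cauchy prior scale on effect size ("medium").
DEFAULT_PRIOR_SCALE = math.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class BFResult:
    """A Bayes factor with the t statistic it was computed from."""

    t: float
    df: int
    r: float
    bf10: float

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def jzs_bf_one_sample(t: float, n: int, r: float = DEFAULT_PRIOR_SCALE) -> BFResult:
    """Two-sided JZS Bayes factor for a one-sample t test.

    ``n`` is the number of observations (``df = n - 1``).  The g-integral is
    evaluated with adaptive quadrature to a relative tolerance well below
    1e-6.
    """
    if n < 2:
        raise InvalidArgumentError("a Bayes factor needs at least 2 observations")
    if r <= 0:
        raise InvalidArgumentError("prior scale must be positive")
    if not np.isfinite(t):
        raise InvalidArgumentError("t must be finite")
    nu = n - 1

    def integrand(g: float) -> float:
        shrink = 1.0 + n * g
        like = shrink**-0.5 * (1.0 + t * t / (shrink * nu)) ** (-(nu + 1) / 2.0)
        prior = stats.invgamma.pdf(g, 0.5, scale=r * r / 2.0)
        return like * prior

    # compactify [0, inf) onto (0, 1) via g = u/(1-u); the transformed
    # integrand is bounded at both endpoints, which keeps the quadrature
    # well-behaved even for the slowly decaying small-df tail
    def transformed(u: float) -> float:
        g = u / (1.0 - u)
        return integrand(g) / (1.0 - u) ** 2

    u_mode = (r * r) / (1.0 + r * r)  # prior scale mapped into u-space
    num, _ = integrate.quad(
        transformed, 0.0, 1.0, epsabs=1e-14, epsrel=1e-9, limit=300, points=[u_mode]
    )
    den = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    return BFResult(t=float(t), df=nu, r=float(r), bf10=float(num / den))


def one_sample_bf(values: Sequence[float], r: float = DEFAULT_PRIOR_SCALE) -> BFResult:
    """JZS Bayes factor testing whether the mean of ``values`` differs from zero."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InvalidArgumentError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise InvalidArgumentError(
            "t statistic undefined: all values are identical (zero variance)"
        )
    t = x.mean() / (sd / math.sqrt(x.size))
    return jzs_bf_one_sample(t, x.size, r)


def paired_bf(x: Sequence[float], y: Sequence[float], r: float = DEFAULT_PRIOR_SCALE) -> BFResult:
    """Paired-sample Bayes factor: the one-sample test on per-subject differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidArgumentError("paired samples must have equal length")
    if x.size < 2:
        raise InvalidArgumentError("need at least 2 pairs")
    return one_sample_bf(x - y, r)


def delta_pnt(fits_by_condition: Mapping[tuple[str, str], MixtureParams]) -> float:
    """Difference-of-differences in the swap proportion for one participant.

    Requires all four (location, ISI) condition fits; raises otherwise.
    """
    required = [("different", "short"), ("same", "short"), ("different", "long"), ("same", "long")]
    missing = [c for c in required if c not in fits_by_condition]
    if missing:
        raise InvalidArgumentError(f"missing condition fits: {missing}")
    p = {c: fits_by_condition[c].p_nt for c in required}
    return (p[("different", "short")] - p[("same", "short")]) - (
        p[("different", "long")] - p[("same", "long")]
    )


def delta_pnt_table(fits: Mapping[tuple, MixtureParams]) -> dict:
    """Per-participant Δp_NT from a {(participant, location, isi): params} map.

    Participants missing any of the four conditions are excluded (with a
    warning via the return value's absence).
    """
    by_participant: dict = {}
    for (participant, loc, isi), params in fits.items():
        by_participant.setdefault(participant, {})[(loc, isi)] = params
    out = {}
    for participant, conds in sorted(by_participant.items()):
        try:
            out[participant] = delta_pnt(conds)
        except InvalidArgumentError:
            continue
    return out


@dataclass
class StoppingTrace:
    """Trajectory of a sequentially monitored Bayes factor.

    ``decision`` is ``"H1"`` (BF10 exceeded the threshold), ``"H0"`` (BF01
    exceeded it), or ``"max-n"``.  ``bf10`` holds one entry per evaluated
    sample size (``nan`` where the t statistic was undefined).
    """

    ns: np.ndarray
    bf10: np.ndarray
    decision: str
    n_final: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"n": self.ns, "bf10": self.bf10, "decision": self.decision})


def stopping_rule(
    deltas: Sequence[float],
    threshold: float = 10.0,
    n_max: int = 20,
    n_min: int = 2,
    r: float = DEFAULT_PRIOR_SCALE,
) -> StoppingTrace:
    """Apply the sequential Bayesian stopping rule to per-participant values.

    After each participant from ``n_min`` on, a one-sample Bayes factor
    tests whether the mean differs from zero; the run stops at strong
    evidence in either direction (``threshold``, conventionally 10) or at
    ``n_max`` participants.  ``deltas`` beyond the stopping point are
    ignored (in a live experiment they would never be collected).
    """
    deltas = np.asarray(deltas, dtype=float)
    if n_min < 2:
        raise InvalidArgumentError("n_min must be at least 2")
    ns, bfs = [], []
    decision = "max-n"
    n_final = min(len(deltas), n_max)
    for k in range(n_min, min(len(deltas), n_max) + 1):
        sample = deltas[:k]
        try:
            bf = one_sample_bf(sample, r).bf10
        except InvalidArgumentError:
            bf = np.nan
        ns.append(k)
        bfs.append(bf)
        if np.isfinite(bf):
            if bf > threshold:
                decision, n_final = "H1", k
                break
            if 1.0 / bf > threshold:
                decision, n_final = "H0", k
                break
    return StoppingTrace(np.asarray(ns), np.asarray(bfs), decision, n_final)
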