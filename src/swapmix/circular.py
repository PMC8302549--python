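"""Circular arithmetic and von Mises primitives shared by all analyses.

Angles are degrees at every public interface (the convention in which
continuous-report data are recorded); trigonometry is done in radians
internally.  Two feature spaces matter in practice: bar orientation, which
lives on a 180-degree circle, and hue on a color wheel, which lives on a
360-degree circle.  Orientation data are mapped onto the full 360-degree
"analysis circle" (a factor-two scaling) before any von Mises density is
evaluated, so the distribution can be used in its standard formulation.

Bessel functions are used in their exponentially scaled forms (``i0e``,
``i1e``) throughout, which keeps likelihoods finite up to the concentration
ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

from .exceptions import EmptyInputError, InvalidArgumentError

#: Concentration values above this are numerically indistinguishable from a
#: point mass (the Bessel-ratio inversion degenerates); estimates are capped.
KAPPA_CEILING = 700.0

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class CircularSpace:
    """A circular report dimension.

    Parameters
    ----------
    period:
        Length of the circle in degrees: 180 for bar orientation, 360 for
        color angle.  Arbitrary positive periods are accepted.
    min_separation:
        Minimum pairwise wrapped distance, in degrees, enforced between the
        feature values of items within a trial (10 for orientation, 20 for
        color).  Zero disables the constraint.
    """

    period: float
    min_separation: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.period) or self.period <= 0:
            raise InvalidArgumentError(f"period must be positive, got {self.period}")
        if not np.isfinite(self.min_separation) or self.min_separation < 0:
            raise InvalidArgumentError(
                f"min_separation must be non-negative, got {self.min_separation}"
            )
        if self.min_separation >= self.period / 4:
            raise InvalidArgumentError(
                "min_separation must be < period/4 so that four items are placeable "
                f"(got {self.min_separation} on a {self.period}-degree circle)"
            )

    @classmethod
    def orientation(cls) -> "CircularSpace":
        """Bar orientation: 180-degree period, 10-degree minimum separation."""
        return cls(period=180.0, min_separation=10.0)

    @classmethod
    def color(cls) -> "CircularSpace":
        """Color-wheel angle: 360-degree period, 20-degree minimum separation."""
        return cls(period=360.0, min_separation=20.0)

    @property
    def analysis_scale(self) -> float:
        """Factor mapping the raw feature circle onto the 360-degree analysis circle."""
        return 360.0 / self.period


@dataclass(frozen=True)
class VonMisesParams:
    """Mean direction (degrees on the analysis circle) and concentration."""

    mu: float
    kappa: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise InvalidArgumentError(f"mu must be finite, got {self.mu}")
        if not np.isfinite(self.kappa) or self.kappa < 0:
            raise InvalidArgumentError(f"kappa must be >= 0, got {self.kappa}")
        if self.kappa > KAPPA_CEILING:
            raise InvalidArgumentError(
                f"kappa exceeds the implementation ceiling {KAPPA_CEILING}"
            )


def wrap_diff(a, b, space: CircularSpace):
    """Signed circular difference ``a - b`` in ``(-period/2, period/2]``.

    A deviation of exactly half the period maps to ``+period/2`` (the
    deterministic tie-break that keeps histogram bins bit-exact).
    Accepts scalars or arrays and broadcasts.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidArgumentError("wrap_diff requires finite inputs")
    period = space.period
    d = np.mod(a - b, period)
    d = np.where(d > period / 2, d - period, d)
    if d.ndim == 0:
        return float(d)
    return d


def wrap_angle(a, period: float):
    """Reduce angles to ``[0, period)``."""
    return np.mod(np.asarray(a, dtype=float), period)


def vm_pdf(x, params: VonMisesParams, analysis_period: float = 360.0):
    """Von Mises density (per radian) at ``x`` degrees on the analysis circle.

    With ``kappa = 0`` this is the circular-uniform density ``1/(2*pi)``.
    The density is evaluated through exponentially scaled Bessel functions so
    it stays finite up to the concentration ceiling.
    """
    if params.kappa < 0:
        raise InvalidArgumentError("kappa must be >= 0")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("vm_pdf requires finite inputs")
    phi = (x - params.mu) * (_TWO_PI / analysis_period)
    out = np.exp(params.kappa * (np.cos(phi) - 1.0)) / (_TWO_PI * special.i0e(params.kappa))
    if out.ndim == 0:
        return float(out)
    return out


def bessel_ratio(kappa):
    """``I1(kappa)/I0(kappa)``, the mean resultant length of a von Mises."""
    kappa = np.asarray(kappa, dtype=float)
    out = special.i1e(kappa) / special.i0e(kappa)
    if out.ndim == 0:
        return float(out)
    return out


def kappa_from_resultant(r, tol: float = 1e-10, max_iter: int = 12):
    """Invert the Bessel ratio: the ``kappa >= 0`` with ``I1(k)/I0(k) = r``.

    Seeded with the Best–Fisher piecewise approximation and polished by
    Newton iterations on the (monotone) Bessel ratio.  ``r = 0`` maps to 0;
    values of ``r`` at or beyond the ratio attained at the concentration
    ceiling map to the ceiling.
    """
    r_arr = np.asarray(r, dtype=float)
    scalar = r_arr.ndim == 0
    r_arr = np.atleast_1d(r_arr)
    if np.any(~np.isfinite(r_arr)) or np.any(r_arr < 0) or np.any(r_arr > 1):
        raise InvalidArgumentError("resultant length must lie in [0, 1]")

    k = np.empty_like(r_arr)
    small = r_arr < 0.53
    mid = (r_arr >= 0.53) & (r_arr < 0.85)
    high = r_arr >= 0.85
    rs = r_arr[small]
    k[small] = 2.0 * rs + rs**3 + 5.0 * rs**5 / 6.0
    rm = r_arr[mid]
    k[mid] = -0.4 + 1.39 * rm + 0.43 / (1.0 - rm)
    rh = r_arr[high]
    with np.errstate(divide="ignore", over="ignore"):
        k[high] = 1.0 / (rh**3 - 4.0 * rh**2 + 3.0 * rh)
    k = np.clip(k, 1e-8, KAPPA_CEILING)

    # Newton refinement; A'(k) = 1 - A/k - A^2.
    for _ in range(max_iter):
        a = special.i1e(k) / special.i0e(k)
        f = a - r_arr
        fp = 1.0 - a / k - a * a
        step = np.where(fp > 0, f / np.maximum(fp, 1e-300), 0.0)
        k_new = np.clip(k - step, 1e-12, KAPPA_CEILING)
        if np.max(np.abs(k_new - k)) < tol:
            k = k_new
            break
        k = k_new

    r_ceiling = special.i1e(KAPPA_CEILING) / special.i0e(KAPPA_CEILING)
    k = np.where(r_arr <= 1e-12, 0.0, k)
    k = np.where(r_arr >= r_ceiling, KAPPA_CEILING, k)
    if scalar:
        return float(k[0])
    return k


def circ_mad(deviations, space: CircularSpace) -> float:
    """Mean absolute wrapped deviation, in degrees, in ``[0, period/2]``.

    Inputs are re-wrapped defensively (a no-op for already-wrapped values).
    """
    d = np.asarray(deviations, dtype=float)
    if d.size == 0:
        raise EmptyInputError("circ_mad requires at least one deviation")
    return float(np.mean(np.abs(wrap_diff(d, 0.0, space))))


def uniform_chance_mad(space: CircularSpace) -> float:
    """Expected MAD of responses uniform on the circle (period/4 by quadrature).

    This is the chance level against which swap-gradient MADs are compared
    when features are unconstrained: 45 degrees for orientation, 90 for color.
    """
    half = space.period / 2
    value, _ = integrate.quad(lambda x: abs(x) / space.period, -half, half, points=[0.0])
    return value
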