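"""Renal time-dose-rate (or time-activity) curve model.

The retention of :sup:`177`Lu-dotatate in a kidney, sampled at a handful of
imaging time points, is represented by the simplest shape that respects the
data: an initial straight line between the first two samples (equivalent to a
trapezoid over the poorly resolved early redistribution phase) followed by a
trailing mono-exponential fitted to the last three samples.  The area under
this curve -- the absorbed dose when the ordinate is a dose rate in Gy/h, or
the cumulated activity when it is an activity in MBq -- has a closed form.

The first sample (nominally 1 h post administration) is deliberately excluded
from the exponential fit: at that time the fast initial washout through the
kidneys dominates and would otherwise corrupt the effective half-time of the
slow retention phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ACTIVITY",
    "DOSE_RATE",
    "WEIGHT_SCHEMES",
    "TimeSample",
    "EffectiveHalfTime",
    "PiecewiseDoseRateCurve",
    "NonDecayingTailError",
    "fit_monoexp_tail",
    "build_curve",
    "integrate_curve",
    "effective_half_time",
]

ACTIVITY = "activity"
DOSE_RATE = "dose_rate"

#: Supported weightings for the tail fit.  ``inverse_square`` (weights
#: proportional to 1/value**2, i.e. constant relative error) is the default.
WEIGHT_SCHEMES = ("uniform", "inverse", "inverse_square")

_FIT_XTOL = 1e-10
_FIT_MAX_ITER = 200


class NonDecayingTailError(ValueError):
    """Raised when the fitted tail does not decay (lambda <= 0)."""


@dataclass(frozen=True)
class TimeSample:
    """A single measurement: time post administration and a non-negative value.

    Parameters
    ----------
    t : float
        Time post administration, hours.
    value : float
        Activity (MBq) or absorbed-dose rate (Gy/h) depending on ``kind``.
    kind : str
        Either ``"activity"`` or ``"dose_rate"``.
    """

    t: float
    value: float
    kind: str = ACTIVITY

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"sample time must be >= 0, got {self.t}")
        if self.value < 0:
            raise ValueError(f"sample value must be >= 0, got {self.value}")
        if self.kind not in (ACTIVITY, DOSE_RATE):
            raise ValueError(f"unknown sample kind {self.kind!r}")


@dataclass(frozen=True)
class EffectiveHalfTime:
    """Effective (physical + biological) half-time of renal retention, hours."""

    t_half: float

    def __post_init__(self) -> None:
        if not self.t_half > 0:
            raise ValueError(f"half-time must be > 0, got {self.t_half}")

    @property
    def lam(self) -> float:
        """Effective decay constant, h^-1."""
        return math.log(2.0) / self.t_half


def effective_half_time(lam: float) -> EffectiveHalfTime:
    """Convert a decay constant (h^-1) into an effective half-time (h)."""
    if not lam > 0:
        raise ValueError(f"decay constant must be > 0, got {lam}")
    return EffectiveHalfTime(math.log(2.0) / lam)


@dataclass(frozen=True)
class PiecewiseDoseRateCurve:
    """Initial straight line followed by a mono-exponential tail.

    The line passes through ``(t1, v1)`` and ``(t2, amplitude)``; for
    ``t >= t2`` the curve is ``amplitude * exp(-lam * (t - t2))``, so it is
    continuous at ``t2`` by construction.  Before ``t1`` the line is, by
    default, extended backward to ``t = 0`` and clamped at zero wherever the
    extension would become negative.  Setting ``extend_to_zero=False`` makes
    the region ``[0, t1)`` contribute no area instead.

    The units of ``v1``/``amplitude`` are Gy/h for dose-rate curves or MBq
    for activity curves; the integral is then Gy or MBq*h respectively.
    """

    t1: float
    v1: float
    t2: float
    amplitude: float
    lam: float
    extend_to_zero: bool = True
    clamp_at_zero: bool = True

    def __post_init__(self) -> None:
        if self.t1 < 0:
            raise ValueError(f"t1 must be >= 0, got {self.t1}")
        if self.t2 < self.t1:
            raise ValueError(f"need t1 <= t2, got t1={self.t1}, t2={self.t2}")
        if not self.lam > 0:
            raise ValueError(f"decay constant must be > 0, got {self.lam}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.v1 < 0:
            raise ValueError(f"v1 must be >= 0, got {self.v1}")
        if self.t1 == self.t2 and not math.isclose(
            self.v1, self.amplitude, rel_tol=1e-9, abs_tol=1e-300
        ):
            raise ValueError("zero-length line requires v1 == amplitude")

    # -- construction helpers ------------------------------------------------

    @classmethod
    def monoexp(cls, amplitude: float, lam: float, t0: float = 0.0) -> "PiecewiseDoseRateCurve":
        """A pure mono-exponential from ``t0`` (degenerate line of zero length)."""
        return cls(t1=t0, v1=amplitude, t2=t0, amplitude=amplitude, lam=lam,
                   extend_to_zero=False)

    # -- evaluation ----------------------------------------------------------

    @property
    def slope(self) -> float:
        if self.t2 == self.t1:
            return 0.0
        return (self.amplitude - self.v1) / (self.t2 - self.t1)

    def line_value(self, t):
        """Raw (unclamped) value of the straight-line segment at ``t``."""
        return self.v1 + self.slope * (np.asarray(t, dtype=float) - self.t1)

    def value(self, t):
        """Curve value at time(s) ``t`` (array-aware)."""
        t = np.asarray(t, dtype=float)
        tail = self.amplitude * np.exp(-self.lam * np.maximum(t - self.t2, 0.0))
        line = self.line_value(t)
        if self.clamp_at_zero:
            line = np.maximum(line, 0.0)
        if not self.extend_to_zero:
            line = np.where(t < self.t1, 0.0, line)
        out = np.where(t >= self.t2, tail, line)
        return out if out.ndim else float(out)

    # -- integration ---------------------------------------------------------

    @property
    def _line_start(self) -> float:
        return 0.0 if self.extend_to_zero else self.t1

    def line_area(self) -> float:
        """Area of the (possibly clamped) line segment on ``[start, t2]``."""
        a, b = self._line_start, self.t2
        if b <= a:
            return 0.0
        la, lb = float(self.line_value(a)), float(self.line_value(b))
        if self.clamp_at_zero and la < 0.0:
            # slope must be positive for la < 0 <= lb; keep the positive wedge
            t0 = a + (0.0 - la) / self.slope
            return 0.5 * lb * (b - t0)
        return 0.5 * (la + lb) * (b - a)

    def tail_area(self) -> float:
        return self.amplitude / self.lam

    def integral(self) -> float:
        """Closed-form area under the curve on ``[0, inf)``."""
        return self.line_area() + self.tail_area()

    def scaled(self, k: float) -> "PiecewiseDoseRateCurve":
        """The curve with all ordinate values multiplied by ``k`` (k > 0)."""
        if not k > 0:
            raise ValueError("scale factor must be > 0")
        return replace(self, v1=self.v1 * k, amplitude=self.amplitude * k)


def _weights(values: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "uniform":
        return np.ones_like(values)
    if scheme == "inverse":
        return 1.0 / values
    if scheme == "inverse_square":
        return 1.0 / values**2
    raise ValueError(f"unknown weight scheme {scheme!r}; choose from {WEIGHT_SCHEMES}")


def fit_monoexp_tail(
    samples: Sequence[TimeSample],
    weight_scheme: str = "inverse_square",
) -> tuple[float, float]:
    """Fit ``C * exp(-lam * (t - t0))`` to the last three samples.

    ``t0`` is the time of the first of the three samples (the second imaging
    time point of the full series), so the returned amplitude ``C`` is the
    curve value there.  A log-domain ordinary-least-squares fit provides the
    starting point; the reported parameters minimise the *linear-scale*
    weighted squared residuals under the requested scheme.

    Returns
    -------
    (amplitude, lam)

    Raises
    ------
    ValueError
        If there are not exactly three samples, times are not strictly
        increasing, or any value is non-positive.
    NonDecayingTailError
        If the fitted tail does not decay (lam <= 0), e.g. all values equal.
    """
    if len(samples) != 3:
        raise ValueError(f"tail fit requires exactly 3 samples, got {len(samples)}")
    t = np.array([s.t for s in samples], dtype=float)
    y = np.array([s.value for s in samples], dtype=float)
    if not np.all(np.diff(t) > 0):
        raise ValueError("sample times must be strictly increasing")
    if np.any(y <= 0):
        raise ValueError("tail fit requires strictly positive values")

    t0 = t[0]
    # log-domain OLS initialiser
    coef = np.polyfit(t - t0, np.log(y), 1)
    lam0, logc0 = -coef[0], coef[1]
    if lam0 <= 0:
        raise NonDecayingTailError(
            f"non-decaying tail: log-linear slope gives lambda = {lam0:.4g} h^-1"
        )
    sw = np.sqrt(_weights(y, weight_scheme))

    def resid(p):
        c, lam = p
        return sw * (c * np.exp(-lam * (t - t0)) - y)

    sol = least_squares(
        resid,
        x0=[math.exp(logc0), lam0],
        xtol=_FIT_XTOL,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=_FIT_MAX_ITER * 3,
        method="lm",
    )
    c, lam = float(sol.x[0]), float(sol.x[1])
    if lam <= 0 or c <= 0:
        raise NonDecayingTailError(
            f"non-decaying tail after refinement: C={c:.4g}, lambda={lam:.4g}"
        )
    return c, lam


def fit_amplitude_fixed_lam(
    samples: Sequence[TimeSample],
    lam: float,
    weight_scheme: str = "inverse_square",
) -> float:
    """Weighted least-squares amplitude for a tail with a prescribed lambda.

    Used when a kidney's own half-time is unreliable (severe planar overlap)
    and the contralateral kidney's decay constant is substituted: only the
    scale ``C`` of ``C * exp(-lam * (t - t0))`` is then estimated.
    """
    if not lam > 0:
        raise ValueError("lam must be > 0")
    t = np.array([s.t for s in samples], dtype=float)
    y = np.array([s.value for s in samples], dtype=float)
    if np.any(y <= 0):
        raise ValueError("amplitude fit requires strictly positive values")
    w = _weights(y, weight_scheme)
    e = np.exp(-lam * (t - t[0]))
    return float(np.sum(w * y * e) / np.sum(w * e * e))


def build_curve(
    first_sample: TimeSample,
    amplitude: float,
    lam: float,
    t2: float,
    extend_to_zero: bool = True,
    clamp_at_zero: bool = True,
) -> PiecewiseDoseRateCurve:
    """Attach the initial line to a fitted tail.

    The line is determined analytically from the curve values at the first
    data point ``(t1, v1)`` and at the second data point ``(t2, amplitude)``,
    where the tail starts.
    """
    if first_sample.t >= t2:
        raise ValueError(
            f"first sample time {first_sample.t} must precede tail start {t2}"
        )
    return PiecewiseDoseRateCurve(
        t1=first_sample.t,
        v1=first_sample.value,
        t2=t2,
        amplitude=amplitude,
        lam=lam,
        extend_to_zero=extend_to_zero,
        clamp_at_zero=clamp_at_zero,
    )


def integrate_curve(curve: PiecewiseDoseRateCurve) -> float:
    """Closed-form area under the curve: absorbed dose (Gy) or cumulated
    activity (MBq*h) depending on the ordinate units."""
    return curve.integral()
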