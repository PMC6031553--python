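"""Per-cycle kidney absorbed-dose estimation: reference method and simplifications.

The reference ("protocol", id ``P``) method is hybrid planar/SPECT dosimetry in
every treatment cycle: the shape of the renal time-activity curve comes from
four serial planar acquisitions, rescaled into absolute dose-rate units by a
single quantitative SPECT/CT, fitted with the piecewise line + mono-exponential
model, and integrated analytically.

The simplified strategies trade imaging burden against accuracy:

========  ==============================================================
``A``     four cycles to everyone; cumulative dose is the sum of the
          first four reference-method cycles (cycle 4 := cycle 3 when
          only three were given)
``B``     planar-only dosimetry in cycle 1; later cycles scaled by the
          ratio of administered activities
``C``     planar-only dosimetry in every cycle
``D``     hybrid dosimetry in cycle 1 only; administered-activity scaling
``E``     hybrid cycle 1, then one SPECT per cycle: cycle-1 dose scaled
          by the ratio of SPECT dose rates (decay-corrected for
          acquisition-time differences with the cycle-1 half-time)
``F``     one SPECT per cycle at 24 h; a single population effective
          half-time (51.6 h) assumed for everyone
``G``     one SPECT per cycle at 96 h (the single-time-point
          approximation, dose = 2 t_ref / ln 2 * R(t_ref)); when the
          SPECT is acquired at another time, the dose rate is
          extrapolated to t_ref with the individual per-kidney half-time
``H``     method G in cycle 1 only; administered-activity scaling after
``I``     method G with the dose rate surrogate taken from a planar
          acquisition at 96 h instead of SPECT
========  ==============================================================

All per-cycle results are reported as the left/right-kidney mean absorbed
dose, which is the quantity treatment decisions are based on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .curves import (
    ACTIVITY,
    DOSE_RATE,
    PiecewiseDoseRateCurve,
    TimeSample,
    build_curve,
    fit_amplitude_fixed_lam,
    fit_monoexp_tail,
    integrate_curve,
)

__all__ = [
    "METHOD_IDS",
    "SIDES",
    "KidneyCycleRecord",
    "DoseEstimate",
    "DoseFactorConfig",
    "DosimetryConfig",
    "ProtocolViolationError",
    "apply_recovery",
    "planar_background_correct",
    "hybrid_rescale",
    "fit_hybrid_curve",
    "protocol_curves",
    "method_P",
    "method_A",
    "planar_ad",
    "scale_by_injected_activity",
    "method_E_scale",
    "method_F",
    "method_G",
    "dispatch_method",
    "imaging_burden_reduction",
]

METHOD_IDS = ("P", "A", "B", "C", "D", "E", "F", "G", "H", "I")
SIDES = ("left", "right")

#: Imaging burden of the reference protocol vs a single SPECT session:
#: four whole-body planar sessions (~120 min total patient time per cycle)
#: against one SPECT/CT session (~40 min).
PLANAR_SESSIONS_PER_CYCLE = 4
SPECT_SESSIONS_PER_CYCLE = 1
PLANAR_MINUTES_PER_CYCLE = 120.0
SPECT_MINUTES_PER_CYCLE = 40.0


class ProtocolViolationError(ValueError):
    """A method was asked to run on a cycle lacking the acquisitions it needs."""

    def __init__(self, method_id: str, patient_id: str, cycle_index: int, why: str):
        self.method_id = method_id
        self.patient_id = patient_id
        self.cycle_index = cycle_index
        super().__init__(
            f"protocol violation for method {method_id}, patient {patient_id}, "
            f"cycle {cycle_index}: {why}"
        )


@dataclass(frozen=True)
class KidneyCycleRecord:
    """All measurements for one kidney in one treatment cycle."""

    patient_id: str
    cycle_index: int
    side: str
    planar_series: tuple[TimeSample, ...]
    spect_sample: TimeSample | None
    injected_activity: float
    kidney_mass: float | None = None
    lambda_borrowed: bool = False

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.cycle_index < 1:
            raise ValueError("cycle_index is 1-based")
        if not self.injected_activity > 0:
            raise ValueError("injected activity must be > 0")
        times = [s.t for s in self.planar_series]
        if len(times) > 4:
            raise ValueError("at most 4 planar samples per cycle")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("planar sample times must be strictly increasing")
        if self.spect_sample is not None and not self.spect_sample.t > 0:
            raise ValueError("SPECT acquisition time must be > 0")
        if self.kidney_mass is not None and not self.kidney_mass > 0:
            raise ValueError("kidney mass must be > 0")


@dataclass(frozen=True)
class DoseEstimate:
    """Per-cycle absorbed-dose estimate (Gy) for both kidneys, tagged with the
    method that produced it."""

    patient_id: str
    cycle_index: int
    method_id: str
    ad_left: float
    ad_right: float
    lam_left: float | None = None
    lam_right: float | None = None

    def __post_init__(self) -> None:
        if self.method_id not in METHOD_IDS:
            raise ValueError(f"unknown method id {self.method_id!r}")
        if self.ad_left < 0 or self.ad_right < 0:
            raise ValueError("absorbed doses must be >= 0")

    @property
    def ad_mean(self) -> float:
        """Left/right mean renal absorbed dose, Gy."""
        return 0.5 * (self.ad_left + self.ad_right)

    def ad(self, side: str) -> float:
        return self.ad_left if side == "left" else self.ad_right


@dataclass(frozen=True)
class DoseFactorConfig:
    """Mass-scaled kidney self-dose factor (OLINDA-style S value).

    ``df(m) = df_ref * (m / mass_ref) ** exponent`` in Gy per MBq*h.  The
    default exponent -1 reflects local electron deposition (dose factor
    inversely proportional to mass); photon cross-dose is not modelled in the
    planar pathway.  The default ``df_ref`` corresponds to the mean
    electron/photon energy of the 177Lu decay absorbed locally in a 150-g
    kidney.
    """

    df_ref: float = 5.6e-4
    mass_ref: float = 150.0
    exponent: float = -1.0

    def __post_init__(self) -> None:
        if not self.df_ref > 0:
            raise ValueError("df_ref must be > 0")
        if not self.mass_ref > 0:
            raise ValueError("mass_ref must be > 0")

    def factor(self, mass: float) -> float:
        """Dose factor (Gy per MBq*h) for a kidney of the given mass (g)."""
        if not mass > 0:
            raise ValueError("kidney mass must be > 0")
        return self.df_ref * (mass / self.mass_ref) ** self.exponent


@dataclass(frozen=True)
class DosimetryConfig:
    """Constants of the dosimetry protocol and its simplifications."""

    recovery: float = 0.85            # SPECT partial-volume recovery factor
    half_time_ref: float = 51.6       # population effective half-time, h (method F)
    t_ref: float = 96.0               # single-time-point imaging time, h (methods G/H/I)
    dose_factor: DoseFactorConfig = field(default_factory=DoseFactorConfig)
    weight_scheme: str = "inverse_square"
    extend_to_zero: bool = True
    clamp_at_zero: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.recovery <= 1:
            raise ValueError("recovery factor must be in (0, 1]")
        if not self.half_time_ref > 0:
            raise ValueError("reference half-time must be > 0")
        if not self.t_ref > 0:
            raise ValueError("t_ref must be > 0")

    @property
    def lam_ref(self) -> float:
        """Population effective decay constant, h^-1."""
        return math.log(2.0) / self.half_time_ref


DEFAULT_DOSIMETRY = DosimetryConfig()


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def apply_recovery(median_dose_rate: float, recovery: float) -> float:
    """Correct a VOI-median SPECT dose rate for partial-volume losses."""
    if not 0 < recovery <= 1:
        raise ValueError(f"recovery factor must be in (0, 1], got {recovery}")
    return median_dose_rate / recovery


def planar_background_correct(
    a_roi: float, bg_per_pixel: float, n_pixels: float, thickness_factor: float
) -> float:
    """Subtract the scaled background-compartment contribution from a kidney
    ROI activity; clamps at zero (with a warning) if the correction exceeds
    the ROI value."""
    if min(a_roi, bg_per_pixel, n_pixels, thickness_factor) < 0:
        raise ValueError("background-correction inputs must be >= 0")
    corrected = a_roi - bg_per_pixel * n_pixels * thickness_factor
    if corrected < 0:
        warnings.warn(
            "background correction exceeds ROI activity; clamping at 0",
            stacklevel=2,
        )
        return 0.0
    return corrected


def _interp_loglinear(series: Sequence[TimeSample], t: float) -> float:
    """Value of a sampled series at ``t``: exact sample if present, otherwise
    log-linear interpolation between the bracketing samples."""
    for s in series:
        if math.isclose(s.t, t, rel_tol=1e-9, abs_tol=1e-9):
            return s.value
    times = [s.t for s in series]
    if not times or t < times[0] or t > times[-1]:
        raise ValueError(f"time {t} h outside the sampled range {times}")
    for lo, hi in zip(series, series[1:]):
        if lo.t <= t <= hi.t:
            if lo.value <= 0 or hi.value <= 0:
                raise ValueError("log-linear interpolation requires positive values")
            f = (t - lo.t) / (hi.t - lo.t)
            return math.exp((1 - f) * math.log(lo.value) + f * math.log(hi.value))
    raise AssertionError("unreachable")


def hybrid_rescale(
    planar_series: Sequence[TimeSample], spect_sample: TimeSample
) -> list[TimeSample]:
    """Rescale a planar activity series into absolute dose rates.

    ``R(t) = A_P(t) / A_P(t_S) * R(t_S)``: the planar series supplies the
    curve shape, the SPECT sample the absolute dose-rate calibration at its
    acquisition time ``t_S``.
    """
    ap_ts = _interp_loglinear(planar_series, spect_sample.t)
    if ap_ts <= 0:
        raise ValueError("planar activity at the SPECT time must be > 0")
    scale = spect_sample.value / ap_ts
    return [TimeSample(s.t, s.value * scale, DOSE_RATE) for s in planar_series]


def _fit_series_curve(
    series: Sequence[TimeSample],
    config: DosimetryConfig,
    fixed_lam: float | None = None,
) -> PiecewiseDoseRateCurve:
    """Fit the piecewise model to a 4-point series (tail on the last three)."""
    tail = list(series[-3:])
    if fixed_lam is None:
        amplitude, lam = fit_monoexp_tail(tail, config.weight_scheme)
    else:
        lam = fixed_lam
        amplitude = fit_amplitude_fixed_lam(tail, lam, config.weight_scheme)
    return build_curve(
        series[0], amplitude, lam, t2=tail[0].t,
        extend_to_zero=config.extend_to_zero, clamp_at_zero=config.clamp_at_zero,
    )


def fit_hybrid_curve(
    record: KidneyCycleRecord,
    config: DosimetryConfig = DEFAULT_DOSIMETRY,
    fixed_lam: float | None = None,
) -> PiecewiseDoseRateCurve:
    """Reference-method dose-rate curve for one kidney: rescale the planar
    series by the SPECT sample, fit the tail, attach the initial line."""
    if len(record.planar_series) != 4:
        raise ProtocolViolationError(
            "P", record.patient_id, record.cycle_index,
            f"hybrid dosimetry needs 4 planar samples, got {len(record.planar_series)}",
        )
    if record.spect_sample is None:
        raise ProtocolViolationError(
            "P", record.patient_id, record.cycle_index, "hybrid dosimetry needs a SPECT sample"
        )
    rescaled = hybrid_rescale(record.planar_series, record.spect_sample)
    return _fit_series_curve(rescaled, config, fixed_lam=fixed_lam)


def _check_pair(left: KidneyCycleRecord, right: KidneyCycleRecord) -> None:
    if left.patient_id != right.patient_id or left.cycle_index != right.cycle_index:
        raise ValueError("left/right records must share patient and cycle")
    if {left.side, right.side} != {"left", "right"}:
        raise ValueError("need one left and one right record")


def protocol_curves(
    left: KidneyCycleRecord,
    right: KidneyCycleRecord,
    config: DosimetryConfig = DEFAULT_DOSIMETRY,
) -> dict[str, PiecewiseDoseRateCurve]:
    """Reference-method curves for both kidneys of one cycle.

    If a record is flagged ``lambda_borrowed`` (kidney severely overlapped by
    extra-renal uptake on the planar images), the contralateral kidney's
    fitted decay constant is substituted and only the tail amplitude is
    estimated for the flagged side.
    """
    _check_pair(left, right)
    records = {r.side: r for r in (left, right)}
    curves: dict[str, PiecewiseDoseRateCurve] = {}
    borrowed = [s for s in SIDES if records[s].lambda_borrowed]
    if len(borrowed) == 2:
        raise ValueError("cannot borrow the decay constant for both kidneys")
    for side in SIDES:
        if side not in borrowed:
            curves[side] = fit_hybrid_curve(records[side], config)
    for side in borrowed:
        other = "right" if side == "left" else "left"
        curves[side] = fit_hybrid_curve(records[side], config, fixed_lam=curves[other].lam)
    return curves


def method_P(
    left: KidneyCycleRecord,
    right: KidneyCycleRecord,
    config: DosimetryConfig = DEFAULT_DOSIMETRY,
) -> DoseEstimate:
    """Hybrid planar/SPECT dosimetry for one cycle (the reference method)."""
    curves = protocol_curves(left, right, config)
    return DoseEstimate(
        patient_id=left.patient_id,
        cycle_index=left.cycle_index,
        method_id="P",
        ad_left=integrate_curve(curves["left"]),
        ad_right=integrate_curve(curves["right"]),
        lam_left=curves["left"].lam,
        lam_right=curves["right"].lam,
    )


def method_A(per_cycle_P: Sequence[DoseEstimate]) -> float:
    """Cumulative dose of the fixed four-cycle regimen, Gy.

    Sums the reference-method left/right-mean doses of cycles 1-4; when only
    three cycles exist, the fourth is set equal to the third.  Cycles beyond
    the fourth are ignored.
    """
    est = sorted(per_cycle_P, key=lambda e: e.cycle_index)
    if len(est) < 3:
        raise ValueError("four-cycle regimen needs at least 3 reference cycles")
    ads = [e.ad_mean for e in est[:4]]
    if len(ads) == 3:
        ads.append(ads[2])
    return float(sum(ads))


def planar_ad(
    record: KidneyCycleRecord,
    df: DoseFactorConfig,
    config: DosimetryConfig = DEFAULT_DOSIMETRY,
) -> tuple[float, float]:
    """Planar-only absorbed dose for one kidney.

    The activity series is fitted with the same piecewise model, integrated
    to the cumulated activity (MBq*h), and converted with the mass-scaled
    dose factor.  Returns ``(ad, lam)``.
    """
    if len(record.planar_series) != 4:
        raise ProtocolViolationError(
            "C", record.patient_id, record.cycle_index,
            f"planar dosimetry needs 4 planar samples, got {len(record.planar_series)}",
        )
    if record.kidney_mass is None:
        raise ProtocolViolationError(
            "C", record.patient_id, record.cycle_index, "planar dosimetry needs a kidney mass"
        )
    curve = _fit_series_curve(record.planar_series, config)
    a_tilde = integrate_curve(curve)
    return a_tilde * df.factor(record.kidney_mass), curve.lam


def scale_by_injected_activity(d1: float, a1: float, an: float) -> float:
    """Assume constant dose per administered activity: ``D_n = D_1 * A_n / A_1``."""
    if not a1 > 0:
        raise ValueError("cycle-1 injected activity must be > 0")
    if an < 0:
        raise ValueError("injected activity must be >= 0")
    return d1 * an / a1


def method_E_scale(
    d1: float, r1: float, rn: float, ts1: float, tsn: float, lam1: float
) -> float:
    """Scale a cycle-1 dose by the ratio of SPECT dose rates.

    ``D_n = D_1 * (R_n(t_S,n) / R_1(t_S,1)) * exp(lam_1 * (t_S,n - t_S,1))``;
    the exponential corrects for different SPECT acquisition times using the
    cycle-1 effective decay constant.
    """
    if not r1 > 0:
        raise ValueError("cycle-1 dose rate must be > 0")
    if rn < 0:
        raise ValueError("dose rate must be >= 0")
    return d1 * (rn / r1) * math.exp(lam1 * (tsn - ts1))


def method_F(rn: float, tsn: float, lam_ref: float) -> float:
    """Absorbed dose from one SPECT sample assuming a population half-time:
    ``D = R(t_S) / lam_ref * exp(lam_ref * t_S)`` (mono-exponential from t=0)."""
    if not lam_ref > 0:
        raise ValueError("reference decay constant must be > 0")
    if rn < 0:
        raise ValueError("dose rate must be >= 0")
    return rn / lam_ref * math.exp(lam_ref * tsn)


def method_G(
    rn: float, tsn: float, lam_n: float | None = None, t_ref: float = 96.0
) -> float:
    """Single-time-point absorbed dose: ``D = 2 t_ref / ln 2 * R(t_ref)``.

    When the acquisition time differs from ``t_ref`` the dose rate is first
    extrapolated with the individual effective decay constant ``lam_n``:
    ``D = 2 t_ref / ln 2 * R(t_S) * exp(lam_n * (t_S - t_ref))``.
    """
    if rn < 0:
        raise ValueError("dose rate must be >= 0")
    if math.isclose(tsn, t_ref, rel_tol=1e-12, abs_tol=1e-9):
        decay = 1.0
    else:
        if lam_n is None:
            raise ValueError(
                "an effective decay constant is required when the acquisition "
                f"time ({tsn} h) differs from t_ref ({t_ref} h)"
            )
        decay = math.exp(lam_n * (tsn - t_ref))
    return 2.0 * t_ref / math.log(2.0) * rn * decay


def imaging_burden_reduction(
    sessions_before: int = PLANAR_SESSIONS_PER_CYCLE,
    sessions_after: int = SPECT_SESSIONS_PER_CYCLE,
    minutes_before: float = PLANAR_MINUTES_PER_CYCLE,
    minutes_after: float = SPECT_MINUTES_PER_CYCLE,
) -> dict[str, float]:
    """Relative reduction (%) in imaging sessions and imaging time per cycle
    when the four-time-point protocol is replaced by a single session."""
    return {
        "time_points_pct": 100.0 * (1.0 - sessions_after / sessions_before),
        "imaging_time_pct": 100.0 * (1.0 - minutes_after / minutes_before),
    }


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def _pairs_by_patient(
    records: Iterable[KidneyCycleRecord],
) -> dict[str, list[tuple[int, KidneyCycleRecord, KidneyCycleRecord]]]:
    grouped: dict[tuple[str, int], dict[str, KidneyCycleRecord]] = {}
    for r in records:
        grouped.setdefault((r.patient_id, r.cycle_index), {})[r.side] = r
    out: dict[str, list[tuple[int, KidneyCycleRecord, KidneyCycleRecord]]] = {}
    for (pid, cyc), sides in sorted(grouped.items()):
        if set(sides) != {"left", "right"}:
            raise ValueError(f"patient {pid} cycle {cyc}: need both kidneys")
        out.setdefault(pid, []).append((cyc, sides["left"], sides["right"]))
    for pid in out:
        out[pid].sort(key=lambda x: x[0])
    return out


def _spect_or_violate(
    r: KidneyCycleRecord, method_id: str
) -> TimeSample:
    if r.spect_sample is None:
        raise ProtocolViolationError(
            method_id, r.patient_id, r.cycle_index, "a SPECT acquisition is required"
        )
    return r.spect_sample


def _estimate_G(
    left: KidneyCycleRecord,
    right: KidneyCycleRecord,
    config: DosimetryConfig,
    method_id: str = "G",
) -> DoseEstimate:
    """Single-time-point estimate for one cycle; fits the per-kidney decay
    constant from the hybrid curve only when extrapolation is needed."""
    ads: dict[str, float] = {}
    lams: dict[str, float | None] = {"left": None, "right": None}
    records = {"left": left, "right": right}
    need_lam = any(
        not math.isclose(
            _spect_or_violate(r, method_id).t, config.t_ref, rel_tol=1e-12, abs_tol=1e-9
        )
        for r in records.values()
    )
    if need_lam:
        try:
            curves = protocol_curves(left, right, config)
        except ProtocolViolationError as err:
            raise ProtocolViolationError(
                method_id, left.patient_id, left.cycle_index,
                "extrapolation to t_ref needs the planar-derived half-time "
                f"({err})",
            ) from err
        lams = {s: curves[s].lam for s in SIDES}
    for side, r in records.items():
        spect = _spect_or_violate(r, method_id)
        ads[side] = method_G(spect.value, spect.t, lams[side], config.t_ref)
    return DoseEstimate(
        patient_id=left.patient_id, cycle_index=left.cycle_index, method_id=method_id,
        ad_left=ads["left"], ad_right=ads["right"],
        lam_left=lams["left"], lam_right=lams["right"],
    )


def _planar_estimate(
    left: KidneyCycleRecord,
    right: KidneyCycleRecord,
    config: DosimetryConfig,
    method_id: str,
) -> DoseEstimate:
    try:
        ad_l, lam_l = planar_ad(left, config.dose_factor, config)
        ad_r, lam_r = planar_ad(right, config.dose_factor, config)
    except ProtocolViolationError as err:
        raise ProtocolViolationError(
            method_id, left.patient_id, left.cycle_index, str(err)
        ) from err
    return DoseEstimate(
        patient_id=left.patient_id, cycle_index=left.cycle_index, method_id=method_id,
        ad_left=ad_l, ad_right=ad_r, lam_left=lam_l, lam_right=lam_r,
    )


def _retag(est: DoseEstimate, method_id: str, cycle_index: int | None = None) -> DoseEstimate:
    return DoseEstimate(
        patient_id=est.patient_id,
        cycle_index=est.cycle_index if cycle_index is None else cycle_index,
        method_id=method_id,
        ad_left=est.ad_left, ad_right=est.ad_right,
        lam_left=est.lam_left, lam_right=est.lam_right,
    )


def _scale_sides(
    base: DoseEstimate, method_id: str, cycle_index: int, f_left: float, f_right: float
) -> DoseEstimate:
    return DoseEstimate(
        patient_id=base.patient_id, cycle_index=cycle_index, method_id=method_id,
        ad_left=base.ad_left * f_left, ad_right=base.ad_right * f_right,
        lam_left=base.lam_left, lam_right=base.lam_right,
    )


def dispatch_method(
    method_id: str,
    records: Iterable[KidneyCycleRecord],
    config: DosimetryConfig = DEFAULT_DOSIMETRY,
    strict: bool = True,
) -> list[DoseEstimate]:
    """Run one treatment-planning strategy over a full measurement dataset.

    Returns one :class:`DoseEstimate` per patient and cycle (for strategy
    ``A``: per padded cycle 1-4).  A cycle lacking the acquisitions the
    strategy requires raises :class:`ProtocolViolationError`; with
    ``strict=False`` the violation is reported as a warning and the affected
    patient is skipped instead.
    """
    if method_id not in METHOD_IDS:
        raise ValueError(f"unknown method id {method_id!r}; choose from {METHOD_IDS}")
    pairs = _pairs_by_patient(records)
    out: list[DoseEstimate] = []
    for pid, cycles in pairs.items():
        try:
            out.extend(_dispatch_patient(method_id, pid, cycles, config))
        except ProtocolViolationError:
            if strict:
                raise
            warnings.warn(
                f"skipping patient {pid} for method {method_id}: "
                "required acquisitions missing",
                stacklevel=2,
            )
    return out


def _dispatch_patient(
    method_id: str,
    pid: str,
    cycles: list[tuple[int, KidneyCycleRecord, KidneyCycleRecord]],
    config: DosimetryConfig,
) -> list[DoseEstimate]:
    out: list[DoseEstimate] = []
    if method_id == "P":
        out.extend(method_P(l, r, config) for _, l, r in cycles)

    elif method_id == "A":
        if len(cycles) < 3:
            raise ProtocolViolationError(
                "A", pid, len(cycles),
                "the four-cycle regimen needs at least 3 reference cycles",
            )
        p_est = [method_P(l, r, config) for _, l, r in cycles[:4]]
        padded = p_est + [p_est[-1]] * (4 - len(p_est))
        out.extend(
            _retag(e, "A", cycle_index=i + 1) for i, e in enumerate(padded)
        )

    elif method_id in ("B", "C"):
        first = _planar_estimate(cycles[0][1], cycles[0][2], config, method_id)
        if method_id == "C":
            out.append(first)
            out.extend(
                _planar_estimate(l, r, config, "C") for _, l, r in cycles[1:]
            )
        else:
            a1 = cycles[0][1].injected_activity
            for cyc, l, r, in cycles:
                f = scale_by_injected_activity(1.0, a1, l.injected_activity)
                out.append(_scale_sides(first, "B", cyc, f, f))

    elif method_id == "D":
        first = _retag(method_P(cycles[0][1], cycles[0][2], config), "D")
        a1 = cycles[0][1].injected_activity
        for cyc, l, r in cycles:
            f = scale_by_injected_activity(1.0, a1, l.injected_activity)
            out.append(_scale_sides(first, "D", cyc, f, f))

    elif method_id == "E":
        first_p = method_P(cycles[0][1], cycles[0][2], config)
        spect1 = {
            "left": _spect_or_violate(cycles[0][1], "E"),
            "right": _spect_or_violate(cycles[0][2], "E"),
        }
        out.append(_retag(first_p, "E"))
        for cyc, l, r in cycles[1:]:
            ads = {}
            for side, rec in (("left", l), ("right", r)):
                sp = _spect_or_violate(rec, "E")
                ads[side] = method_E_scale(
                    first_p.ad(side),
                    spect1[side].value, sp.value,
                    spect1[side].t, sp.t,
                    first_p.lam_left if side == "left" else first_p.lam_right,
                )
            out.append(DoseEstimate(
                patient_id=pid, cycle_index=cyc, method_id="E",
                ad_left=ads["left"], ad_right=ads["right"],
                lam_left=first_p.lam_left, lam_right=first_p.lam_right,
            ))

    elif method_id == "F":
        for cyc, l, r in cycles:
            sp_l, sp_r = _spect_or_violate(l, "F"), _spect_or_violate(r, "F")
            out.append(DoseEstimate(
                patient_id=pid, cycle_index=cyc, method_id="F",
                ad_left=method_F(sp_l.value, sp_l.t, config.lam_ref),
                ad_right=method_F(sp_r.value, sp_r.t, config.lam_ref),
            ))

    elif method_id == "G":
        out.extend(_estimate_G(l, r, config) for _, l, r in cycles)

    elif method_id == "H":
        first = _retag(_estimate_G(cycles[0][1], cycles[0][2], config, "H"), "H")
        a1 = cycles[0][1].injected_activity
        for cyc, l, r in cycles:
            f = scale_by_injected_activity(1.0, a1, l.injected_activity)
            out.append(_scale_sides(first, "H", cyc, f, f))

    elif method_id == "I":
        for cyc, l, r in cycles:
            ads = {}
            for side, rec in (("left", l), ("right", r)):
                if rec.kidney_mass is None:
                    raise ProtocolViolationError(
                        "I", pid, cyc, "planar dosimetry needs a kidney mass"
                    )
                if not rec.planar_series:
                    raise ProtocolViolationError(
                        "I", pid, cyc, "a planar acquisition is required"
                    )
                try:
                    a96 = _interp_loglinear(rec.planar_series, 96.0)
                except ValueError as err:
                    raise ProtocolViolationError("I", pid, cyc, str(err)) from err
                r_surrogate = a96 * config.dose_factor.factor(rec.kidney_mass)
                ads[side] = method_G(r_surrogate, 96.0, None, config.t_ref) \
                    if math.isclose(config.t_ref, 96.0) else method_G(
                        r_surrogate, 96.0,
                        _fit_series_curve(rec.planar_series, config).lam,
                        config.t_ref,
                    )
            out.append(DoseEstimate(
                patient_id=pid, cycle_index=cyc, method_id="I",
                ad_left=ads["left"], ad_right=ads["right"],
            ))

    return out
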