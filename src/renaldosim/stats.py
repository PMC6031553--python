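"""Method-comparison statistics.

Three pieces of machinery:

* Bland-Altman analysis of per-cycle relative dose differences, with the
  standard deviation estimated through one-way random-effects ANOVA (patient
  as the grouping factor) so that repeated cycles within a patient do not
  masquerade as independent observations.  Limits of agreement are the mean
  difference +/- 2 SD_total with SD_total^2 = sigma^2_between + sigma^2_within.

* Cumulative-dose uncertainty: each per-cycle reference dose carries an
  estimated fractional uncertainty (10 %, 1 SD by default); cycle
  uncertainties are propagated in quadrature (no covariance between cycles)
  and an alternative method is called consistent when its cumulative dose
  falls inside the reference cumulative dose +/- 2 SD.

* Single-time-point error theory: the dose estimate 2 t_ref/ln2 * R(t_ref)
  for a mono-exponential washout has exact fractional error
  E1(f) = 2 f 2^(-f) - 1 with f = t_ref / T_half (zero at f = 1 and f = 2).
  The patient-based counterpart E2 = (D_G - D_P)/D_P is swept over a grid of
  t_ref values and summarised by its mean, SD and RMSD over all kidneys and
  cycles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .methods import (
    DEFAULT_DOSIMETRY,
    DoseEstimate,
    DosimetryConfig,
    KidneyCycleRecord,
    _pairs_by_patient,
    _spect_or_violate,
    method_G,
    protocol_curves,
)
from .curves import integrate_curve

__all__ = [
    "PairedCycleDiff",
    "MethodComparison",
    "CumulativeDose",
    "SweepResult",
    "paired_cycle_diffs",
    "bland_altman",
    "cumulative_with_uncertainty",
    "classify_consistency",
    "consistency_analysis",
    "e1_theoretical",
    "e2_per_cycle",
    "tref_sweep",
]


@dataclass(frozen=True)
class PairedCycleDiff:
    """Relative per-cycle dose difference between an alternative method and
    the reference, in percent of the mean of the two methods."""

    patient_id: str
    cycle_index: int
    rel_diff: float


@dataclass(frozen=True)
class MethodComparison:
    """Bland-Altman summary for one method against the reference (percent)."""

    method_id: str
    mean_diff: float
    sd_between: float
    sd_within: float
    sd_total: float
    loa_low: float
    loa_high: float
    n_patients: int
    n_obs: int


@dataclass(frozen=True)
class CumulativeDose:
    """Cumulative absorbed dose (Gy) over a patient's cycles with the
    propagated 2-SD confidence interval."""

    patient_id: str
    method_id: str
    n_cycles: int
    d_cum: float
    sd_cum: float
    ci_low: float
    ci_high: float
    consistent_with_ref: bool | None = None


@dataclass(frozen=True)
class SweepResult:
    """Single-time-point error sweep over the imaging time t_ref (all in %)."""

    t_ref: np.ndarray
    e1: np.ndarray
    e2_mean: np.ndarray
    e2_sd: np.ndarray
    e2_rmsd: np.ndarray
    n_obs: int

    @property
    def argmin_rmsd_h(self) -> float:
        """Imaging time (h) minimising the RMSD of the patient-based error."""
        return float(self.t_ref[int(np.argmin(self.e2_rmsd))])


def paired_cycle_diffs(
    alt: Sequence[DoseEstimate], ref: Sequence[DoseEstimate]
) -> list[PairedCycleDiff]:
    """Pair per-cycle left/right-mean doses of two methods by patient and
    cycle; the difference is normalised to the mean of the two methods."""
    ref_map = {(e.patient_id, e.cycle_index): e for e in ref}
    out = []
    for e in alt:
        r = ref_map.get((e.patient_id, e.cycle_index))
        if r is None:
            continue
        m = 0.5 * (e.ad_mean + r.ad_mean)
        if not m > 0:
            raise ValueError(
                f"relative difference undefined for zero mean dose "
                f"({e.patient_id}, cycle {e.cycle_index})"
            )
        out.append(
            PairedCycleDiff(e.patient_id, e.cycle_index, 100.0 * (e.ad_mean - r.ad_mean) / m)
        )
    return out


def _anova_components(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """One-way random-effects variance components (between, within) and the
    grand mean for possibly unbalanced groups.

    sigma^2_within = MS_within; sigma^2_between = max(0, (MS_b - MS_w)/n0)
    with n0 the Searle average group size ``(N - sum n_i^2 / N) / (a - 1)``.
    """
    a = len(groups)
    n_i = np.array([len(g) for g in groups], dtype=float)
    n = float(n_i.sum())
    grand = float(np.concatenate(groups).mean())
    means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(n_i * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    ms_between = ss_between / (a - 1)
    df_within = n - a
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    n0 = (n - float(np.sum(n_i**2)) / n) / (a - 1)
    var_between = max(0.0, (ms_between - ms_within) / n0)
    return var_between, ms_within, grand


def bland_altman(
    diffs: Sequence[PairedCycleDiff],
    method_id: str = "",
    loa_multiplier: float = 2.0,
) -> MethodComparison:
    """Bland-Altman limits of agreement with ANOVA variance components.

    With a single patient the variance cannot be decomposed; the plain sample
    SD is used instead (with a warning) and attributed to the within
    component.
    """
    if not diffs:
        raise ValueError("no paired differences given")
    by_patient: dict[str, list[float]] = {}
    for d in diffs:
        by_patient.setdefault(d.patient_id, []).append(d.rel_diff)
    groups = [np.asarray(v, dtype=float) for v in by_patient.values()]
    values = np.concatenate(groups)

    if len(groups) < 2:
        warnings.warn(
            "only one patient: falling back to the plain sample SD",
            stacklevel=2,
        )
        mean = float(values.mean())
        sd_within = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        var_between = 0.0
    else:
        var_between, var_within, mean = _anova_components(groups)
        sd_within = math.sqrt(var_within)
    sd_between = math.sqrt(var_between)
    sd_total = math.sqrt(sd_between**2 + sd_within**2)
    return MethodComparison(
        method_id=method_id,
        mean_diff=mean,
        sd_between=sd_between,
        sd_within=sd_within,
        sd_total=sd_total,
        loa_low=mean - loa_multiplier * sd_total,
        loa_high=mean + loa_multiplier * sd_total,
        n_patients=len(groups),
        n_obs=len(values),
    )


def cumulative_with_uncertainty(
    per_cycle: Sequence[float],
    u: float = 0.10,
    patient_id: str = "",
    method_id: str = "",
) -> CumulativeDose:
    """Sum per-cycle doses and propagate a fractional per-cycle uncertainty.

    ``sd_cum = sqrt(sum (u * D_i)^2)`` (cycles treated as uncorrelated);
    the confidence interval is ``d_cum +/- 2 sd_cum``.
    """
    doses = np.asarray(per_cycle, dtype=float)
    if np.any(doses < 0):
        raise ValueError("per-cycle doses must be >= 0")
    if u < 0:
        raise ValueError("fractional uncertainty must be >= 0")
    d_cum = float(doses.sum())
    sd_cum = float(math.sqrt(float(np.sum((u * doses) ** 2))))
    return CumulativeDose(
        patient_id=patient_id,
        method_id=method_id,
        n_cycles=len(doses),
        d_cum=d_cum,
        sd_cum=sd_cum,
        ci_low=d_cum - 2.0 * sd_cum,
        ci_high=d_cum + 2.0 * sd_cum,
    )


def classify_consistency(alt: CumulativeDose, ref: CumulativeDose) -> bool:
    """True iff the alternative cumulative dose lies inside the reference
    confidence interval (closed at both ends)."""
    if alt.patient_id != ref.patient_id:
        raise ValueError(
            f"patient mismatch: {alt.patient_id!r} vs {ref.patient_id!r}"
        )
    return ref.ci_low <= alt.d_cum <= ref.ci_high


def consistency_analysis(
    estimates_by_method: Mapping[str, Sequence[DoseEstimate]],
    u: float = 0.10,
    reference: str = "P",
) -> list[CumulativeDose]:
    """Cumulative-dose consistency of every method against the reference.

    For each patient, every method's per-cycle doses are summed over the
    cycles actually given (strategy ``A`` over its own padded four cycles);
    the uncertainty band is attached to the reference sum only, and each
    alternative is classified against it.
    """
    if reference not in estimates_by_method:
        raise ValueError(f"reference method {reference!r} missing from estimates")

    def per_patient(estimates: Sequence[DoseEstimate]) -> dict[str, list[DoseEstimate]]:
        by: dict[str, list[DoseEstimate]] = {}
        for e in estimates:
            by.setdefault(e.patient_id, []).append(e)
        for v in by.values():
            v.sort(key=lambda e: e.cycle_index)
        return by

    ref_by = per_patient(estimates_by_method[reference])
    out: list[CumulativeDose] = []
    ref_cum: dict[str, CumulativeDose] = {}
    for pid, ests in ref_by.items():
        ref_cum[pid] = cumulative_with_uncertainty(
            [e.ad_mean for e in ests], u=u, patient_id=pid, method_id=reference
        )
        out.append(ref_cum[pid])
    for mid, ests in estimates_by_method.items():
        if mid == reference:
            continue
        for pid, pe in per_patient(ests).items():
            if pid not in ref_cum:
                continue
            cum = cumulative_with_uncertainty(
                [e.ad_mean for e in pe], u=0.0, patient_id=pid, method_id=mid
            )
            out.append(
                CumulativeDose(
                    patient_id=pid, method_id=mid, n_cycles=cum.n_cycles,
                    d_cum=cum.d_cum, sd_cum=cum.sd_cum,
                    ci_low=cum.ci_low, ci_high=cum.ci_high,
                    consistent_with_ref=classify_consistency(cum, ref_cum[pid]),
                )
            )
    return out


def e1_theoretical(f: float) -> float:
    """Theoretical fractional error of the single-time-point estimate for a
    mono-exponential washout: ``E1 = 2 f 2^(-f) - 1``, ``f = t_ref/T_half``.

    Exact zero at f = 1 and f = 2 (imaging at one or two half-times).
    """
    if not f > 0:
        raise ValueError(f"f must be > 0, got {f}")
    return 2.0 * f * 2.0 ** (-f) - 1.0


def e2_per_cycle(d_g: float, d_p: float) -> float:
    """Patient-based fractional error of the single-time-point estimate:
    ``E2 = (D_G - D_P) / D_P`` (reference-based, not symmetric)."""
    if not d_p > 0:
        raise ValueError("reference dose must be > 0")
    return (d_g - d_p) / d_p


def tref_sweep(
    records: Iterable[KidneyCycleRecord],
    config: DosimetryConfig = DEFAULT_DOSIMETRY,
    grid: Sequence[float] | None = None,
    half_time_theory: float | None = None,
) -> SweepResult:
    """Sweep the single-time-point imaging time and compare against theory.

    For every kidney and cycle the reference dose, the fitted per-kidney
    decay constant and the SPECT dose-rate sample are computed once; for each
    candidate ``t_ref`` the single-time-point dose is formed by extrapolation
    and the patient-based error E2 is summarised by its mean, SD (ddof=1) and
    RMSD (population convention, divide by n) over all kidneys and cycles.
    ``e1`` is the theoretical error for ``half_time_theory`` (default: the
    configured population half-time).
    """
    grid = np.asarray(
        grid if grid is not None else np.arange(24.0, 148.0, 4.0), dtype=float
    )
    t_half = half_time_theory if half_time_theory is not None else config.half_time_ref

    d_p, lam, r_s, t_s = [], [], [], []
    pairs = _pairs_by_patient(records)
    if not pairs:
        raise ValueError("empty cohort")
    for pid, cycles in pairs.items():
        for _, left, right in cycles:
            curves = protocol_curves(left, right, config)
            for side, rec in (("left", left), ("right", right)):
                spect = _spect_or_violate(rec, "G")
                d_p.append(integrate_curve(curves[side]))
                lam.append(curves[side].lam)
                r_s.append(spect.value)
                t_s.append(spect.t)
    d_p = np.asarray(d_p)
    lam = np.asarray(lam)
    r_s = np.asarray(r_s)
    t_s = np.asarray(t_s)

    e2_mean = np.empty_like(grid)
    e2_sd = np.empty_like(grid)
    e2_rmsd = np.empty_like(grid)
    for i, tr in enumerate(grid):
        d_g = 2.0 * tr / math.log(2.0) * r_s * np.exp(lam * (t_s - tr))
        e2 = (d_g - d_p) / d_p
        e2_mean[i] = 100.0 * e2.mean()
        e2_sd[i] = 100.0 * e2.std(ddof=1)
        e2_rmsd[i] = 100.0 * math.sqrt(float(np.mean(e2**2)))
    e1 = np.array([100.0 * e1_theoretical(tr / t_half) for tr in grid])
    return SweepResult(
        t_ref=grid, e1=e1, e2_mean=e2_mean, e2_sd=e2_sd, e2_rmsd=e2_rmsd,
        n_obs=len(d_p),
    )
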