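"""CSV schemas and run configuration.

All data travel as long-format CSV tables with fixed headers; times are hours
as decimals, activities MBq, dose rates Gy/h, doses Gy, masses g.  The run
configuration round-trips losslessly through YAML or JSON and is hashed into
every output manifest for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .bed import RadiobiologyParams
from .cohort import CohortConfig, PatientTruth
from .curves import ACTIVITY, DOSE_RATE, TimeSample
from .methods import (
    DoseEstimate,
    DoseFactorConfig,
    DosimetryConfig,
    KidneyCycleRecord,
)
from .stats import CumulativeDose, MethodComparison, SweepResult

__all__ = [
    "SchemaError",
    "MEASUREMENT_COLUMNS",
    "ESTIMATE_COLUMNS",
    "StatsConfig",
    "RunConfig",
    "records_to_frame",
    "frame_to_records",
    "estimates_to_frame",
    "frame_to_estimates",
    "truths_to_frame",
    "comparisons_to_frame",
    "cumulatives_to_frame",
    "sweep_to_frame",
    "load_config",
    "save_config",
    "config_hash",
    "write_manifest",
]


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


MEASUREMENT_COLUMNS = [
    "patient_id", "cycle", "side", "sample_kind", "t_h", "value",
    "is_t_s", "a_inj_mbq", "kidney_mass_g", "lambda_borrowed",
]
_PLANAR_KIND = "planar_activity"
_SPECT_KIND = "spect_dose_rate"

ESTIMATE_COLUMNS = [
    "patient_id", "cycle", "method_id", "ad_left_gy", "ad_right_gy",
    "ad_mean_gy", "lam_left", "lam_right",
]

TRUTH_COLUMNS = [
    "patient_id", "cycle", "side", "centre", "target_bed_gy", "kidney_mass_g",
    "a_inj_mbq", "lam_true", "half_time_true_h", "first_ratio_true",
    "ad_true_gy", "r24_true_gy_h", "planar_bias", "events",
]


def _check_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing columns {missing}")


def records_to_frame(records: Iterable[KidneyCycleRecord]) -> pd.DataFrame:
    """One row per measurement sample."""
    rows = []
    for r in records:
        base = dict(
            patient_id=r.patient_id, cycle=r.cycle_index, side=r.side,
            a_inj_mbq=r.injected_activity,
            kidney_mass_g=np.nan if r.kidney_mass is None else r.kidney_mass,
            lambda_borrowed=r.lambda_borrowed,
        )
        for s in r.planar_series:
            rows.append({**base, "sample_kind": _PLANAR_KIND, "t_h": s.t,
                         "value": s.value, "is_t_s": False})
        if r.spect_sample is not None:
            rows.append({**base, "sample_kind": _SPECT_KIND,
                         "t_h": r.spect_sample.t, "value": r.spect_sample.value,
                         "is_t_s": True})
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    return df


def frame_to_records(df: pd.DataFrame) -> list[KidneyCycleRecord]:
    _check_columns(df, MEASUREMENT_COLUMNS, "measurement")
    records = []
    for (pid, cyc, side), g in df.groupby(
        ["patient_id", "cycle", "side"], sort=True
    ):
        planar = g[g["sample_kind"] == _PLANAR_KIND].sort_values("t_h")
        spect = g[g["sample_kind"] == _SPECT_KIND]
        if len(spect) > 1:
            raise SchemaError(
                f"{pid} cycle {cyc} {side}: more than one SPECT sample"
            )
        spect_sample = None
        if len(spect) == 1:
            row = spect.iloc[0]
            spect_sample = TimeSample(float(row.t_h), float(row.value), DOSE_RATE)
        mass = g["kidney_mass_g"].iloc[0]
        records.append(
            KidneyCycleRecord(
                patient_id=str(pid), cycle_index=int(cyc), side=str(side),
                planar_series=tuple(
                    TimeSample(float(t), float(v), ACTIVITY)
                    for t, v in zip(planar["t_h"], planar["value"])
                ),
                spect_sample=spect_sample,
                injected_activity=float(g["a_inj_mbq"].iloc[0]),
                kidney_mass=None if pd.isna(mass) else float(mass),
                lambda_borrowed=bool(g["lambda_borrowed"].iloc[0]),
            )
        )
    return records


def estimates_to_frame(estimates: Iterable[DoseEstimate]) -> pd.DataFrame:
    rows = [
        dict(
            patient_id=e.patient_id, cycle=e.cycle_index, method_id=e.method_id,
            ad_left_gy=e.ad_left, ad_right_gy=e.ad_right, ad_mean_gy=e.ad_mean,
            lam_left=np.nan if e.lam_left is None else e.lam_left,
            lam_right=np.nan if e.lam_right is None else e.lam_right,
        )
        for e in estimates
    ]
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)


def frame_to_estimates(df: pd.DataFrame) -> list[DoseEstimate]:
    _check_columns(df, ESTIMATE_COLUMNS, "estimate")
    return [
        DoseEstimate(
            patient_id=str(r.patient_id), cycle_index=int(r.cycle),
            method_id=str(r.method_id),
            ad_left=float(r.ad_left_gy), ad_right=float(r.ad_right_gy),
            lam_left=None if pd.isna(r.lam_left) else float(r.lam_left),
            lam_right=None if pd.isna(r.lam_right) else float(r.lam_right),
        )
        for r in df.itertuples()
    ]


def truths_to_frame(truths: Iterable[PatientTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        for (cyc, side), kc in sorted(t.cycles.items()):
            rows.append(dict(
                patient_id=t.patient_id, cycle=cyc, side=side, centre=t.centre,
                target_bed_gy=t.target_bed_gy,
                kidney_mass_g=t.kidney_mass[side],
                a_inj_mbq=t.a_inj[cyc - 1],
                lam_true=kc.lam,
                half_time_true_h=np.log(2.0) / kc.lam,
                first_ratio_true=kc.first_ratio,
                ad_true_gy=kc.ad_gy,
                r24_true_gy_h=kc.r24_gy_h,
                planar_bias=t.planar_bias[(cyc, side)],
                events=";".join(t.events),
            ))
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def comparisons_to_frame(comparisons: Iterable[MethodComparison]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in comparisons])


def cumulatives_to_frame(cumulatives: Iterable[CumulativeDose]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in cumulatives])


def sweep_to_frame(sweep: SweepResult) -> pd.DataFrame:
    return pd.DataFrame({
        "t_ref_h": sweep.t_ref,
        "e1_pct": sweep.e1,
        "e2_mean_pct": sweep.e2_mean,
        "e2_sd_pct": sweep.e2_sd,
        "e2_rmsd_pct": sweep.e2_rmsd,
    })


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatsConfig:
    """Parameters of the comparison statistics."""

    u: float = 0.10                  # per-cycle fractional uncertainty (1 SD)
    loa_multiplier: float = 2.0
    sweep_start_h: float = 24.0
    sweep_stop_h: float = 144.0
    sweep_step_h: float = 4.0

    def grid(self) -> np.ndarray:
        return np.arange(self.sweep_start_h, self.sweep_stop_h + 1e-9, self.sweep_step_h)


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration for a pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    dosimetry: DosimetryConfig = field(default_factory=DosimetryConfig)
    radiobiology: RadiobiologyParams = field(default_factory=RadiobiologyParams)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        df_cfg = d.get("dosimetry", {}).copy()
        if "dose_factor" in df_cfg:
            df_cfg["dose_factor"] = DoseFactorConfig(**df_cfg["dose_factor"])
        cohort = d.get("cohort", {}).copy()
        for key in ("planar_times_a", "planar_times_b"):
            if key in cohort:
                cohort[key] = tuple(cohort[key])
        return cls(
            cohort=CohortConfig(**cohort),
            dosimetry=DosimetryConfig(**df_cfg),
            radiobiology=RadiobiologyParams(**d.get("radiobiology", {})),
            stats=StatsConfig(**d.get("stats", {})),
        )


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.from_dict(data or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    d = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir: str | Path, config: RunConfig, extra: dict | None = None) -> Path:
    """Log the verbatim configuration, its hash and the seed next to outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.cohort.seed,
        "config_hash": config_hash(config),
        "config": config.to_dict(),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
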