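"""End-to-end orchestration: per-case fitting and cohort comparison.

A case runs through the sequential phases of the inverse analysis: the
end-diastolic point is taken as the maximum-volume sample of the (resampled)
waveforms, a Klotz single-beat EDPVR is built from it, the passive wall is
calibrated (unloading inside), and the contractility waveform is estimated
per time point.  Cohort runs fit every case and modality, skip-and-report
failures, and emit the concordance table over EDV/ESV/SV/EF, peak Tmax and
time-to-peak Tmax.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .concordance import cohort_report
from .constitutive import ActiveParams, PassiveParams
from .cohort import CaseRecord
from .estimation import (
    FitSummary,
    MASKING_FLOOR_KPA,
    TmaxWaveform,
    Waveform,
    estimate_tmax_waveform,
    resample_to_common_grid,
)
from .mechanics import PVPoint, PassiveFit, fit_passive, klotz_single_beat, kpa_to_mmhg

__all__ = ["RunConfig", "CaseResult", "CohortOutcome", "run_case", "run_cohort", "ConfigError"]

log = logging.getLogger("lvmech")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration serialized verbatim into every output."""

    klotz_an_mmhg: float = 28.2
    klotz_bn: float = 2.79
    passive_template: PassiveParams = field(default_factory=PassiveParams)
    active: ActiveParams = field(default_factory=ActiveParams)
    masking_floor_kpa: float = MASKING_FLOOR_KPA
    tmax_upper_kpa: float = 200.0
    fit_tol_c_rel: float = 1e-4
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.klotz_an_mmhg <= 0 or self.klotz_bn <= 0:
            raise ConfigError("Klotz constants must be positive")
        if self.masking_floor_kpa < 0:
            raise ConfigError("masking floor must be >= 0")
        if self.tmax_upper_kpa <= 0:
            raise ConfigError("Tmax upper bound must be positive")

    def to_dict(self) -> dict:
        return {
            "klotz_An_mmHg": self.klotz_an_mmhg,
            "klotz_Bn": self.klotz_bn,
            "passive_template": self.passive_template.to_dict(),
            "active": self.active.to_dict(),
            "masking_floor_kPa": self.masking_floor_kpa,
            "tmax_upper_kPa": self.tmax_upper_kpa,
            "fit_tol_C_rel": self.fit_tol_c_rel,
            "master_seed": self.master_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        try:
            kwargs: dict = {}
            mapping = {
                "klotz_An_mmHg": "klotz_an_mmhg",
                "klotz_Bn": "klotz_bn",
                "masking_floor_kPa": "masking_floor_kpa",
                "tmax_upper_kPa": "tmax_upper_kpa",
                "fit_tol_C_rel": "fit_tol_c_rel",
                "master_seed": "master_seed",
            }
            for key, attr in mapping.items():
                if key in d:
                    kwargs[attr] = d[key]
            if "passive_template" in d:
                p = d["passive_template"]
                kwargs["passive_template"] = PassiveParams(
                    C=p.get("C_kPa", 0.1), bff=p.get("bff", 29.9),
                    bxx=p.get("bxx", 13.5), bfx=p.get("bfx", 26.6),
                )
            if "active" in d:
                a = d["active"]
                kwargs["active"] = ActiveParams(
                    ca0=a.get("Ca0_umol_per_L", 4.35),
                    ca0max=a.get("Ca0max_umol_per_L", 4.35),
                    b=a.get("B_per_um", 4.75),
                    l0=a.get("l0_um", 1.58),
                    ls0=a.get("ls0_um", 1.85),
                )
            return cls(**kwargs)
        except (TypeError, ValueError, KeyError) as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset also parses JSON
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping")
        return cls.from_dict(data)


@dataclass(frozen=True)
class CaseResult:
    """One fitted case x modality with volume metrics and full provenance."""

    case_id: str
    modality: str
    passive_fit: PassiveFit
    tmax_waveform: TmaxWaveform
    summary: FitSummary
    edv_ml: float
    esv_ml: float
    config: RunConfig
    stage_seconds: dict = field(default_factory=dict)

    @property
    def sv_ml(self) -> float:
        return self.edv_ml - self.esv_ml

    @property
    def ef(self) -> float:
        return self.sv_ml / self.edv_ml

    def metrics(self) -> dict:
        return {
            "EDV": self.edv_ml,
            "ESV": self.esv_ml,
            "SV": self.sv_ml,
            "EF": self.ef,
            "peak_tmax": self.summary.peak_tmax_kpa,
            "time_to_peak": self.summary.time_to_peak_s,
        }

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "modality": self.modality,
            "passive_fit": self.passive_fit.to_dict(),
            "summary": self.summary.to_dict(),
            "metrics": self.metrics(),
            "config": self.config.to_dict(),
            "stage_seconds": self.stage_seconds,
        }


def run_case(
    pressure: Waveform,
    volume: Waveform,
    wall_volume_ml: float,
    config: RunConfig | None = None,
    case_id: str = "case",
    modality: str = "",
) -> CaseResult:
    """Fit one case: Klotz calibration, unloading, per-point Tmax estimation."""
    config = config if config is not None else RunConfig()
    stage_seconds: dict = {}

    t0 = time.perf_counter()
    t, p, v = resample_to_common_grid(pressure, volume)
    i_ed = int(np.argmax(v))  # ED = maximum-volume sample (earliest tie)
    vm, pm_kpa = float(v[i_ed]), float(p[i_ed])
    klotz = klotz_single_beat(
        float(kpa_to_mmhg(pm_kpa)), vm, config.klotz_an_mmhg, config.klotz_bn
    )
    stage_seconds["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fit = fit_passive(
        PVPoint(pm_kpa, vm),
        wall_volume_ml,
        klotz,
        config.passive_template,
        tol_c_rel=config.fit_tol_c_rel,
    )
    stage_seconds["passive"] = time.perf_counter() - t0
    log.info(
        "%s/%s passive: C=%.4f kPa Rin=%.3f cm (%d outer iterations)",
        case_id, modality, fit.passive.C, fit.wall.rin_cm, len(fit.trace),
    )

    t0 = time.perf_counter()
    tw, summary = estimate_tmax_waveform(
        fit.wall, fit.passive, config.active, t, p, v,
        masking_floor_kpa=config.masking_floor_kpa,
        upper_kpa=config.tmax_upper_kpa,
    )
    stage_seconds["active"] = time.perf_counter() - t0
    log.info(
        "%s/%s active: peak Tmax=%.2f kPa at t=%.3f s, max rel err=%.2e, converged=%s",
        case_id, modality, summary.peak_tmax_kpa, summary.time_to_peak_s,
        summary.max_rel_error, summary.converged,
    )

    return CaseResult(
        case_id=case_id,
        modality=modality,
        passive_fit=fit,
        tmax_waveform=tw,
        summary=summary,
        edv_ml=float(v.max()),
        esv_ml=float(v.min()),
        config=config,
        stage_seconds=stage_seconds,
    )


@dataclass(frozen=True)
class CohortOutcome:
    """All per-case results, structured failures, and the concordance table."""

    results: tuple[CaseResult, ...]
    failures: tuple[dict, ...]
    report: pd.DataFrame

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            for metric, value in r.metrics().items():
                rows.append(
                    {"case_id": r.case_id, "modality": r.modality, "metric": metric, "value": value}
                )
        return pd.DataFrame(rows)


def run_cohort(
    records: list[CaseRecord],
    config: RunConfig | None = None,
    out_dir=None,
) -> CohortOutcome:
    """Fit every case x modality and compare modalities across the cohort.

    Failed cases are skipped and reported as structured diagnostics; the
    concordance table uses only cases where both modalities fitted.
    """
    if not records:
        raise ValueError("empty cohort")
    config = config if config is not None else RunConfig()
    results: list[CaseResult] = []
    failures: list[dict] = []
    for rec in records:
        try:
            results.append(
                run_case(
                    rec.pressure, rec.volume, rec.wall_volume_ml, config,
                    case_id=rec.case_id, modality=rec.modality,
                )
            )
        except Exception as exc:  # noqa: BLE001 - skip-and-report policy
            log.warning("case %s/%s failed: %s", rec.case_id, rec.modality, exc)
            failures.append(
                {"case_id": rec.case_id, "modality": rec.modality,
                 "error": type(exc).__name__, "message": str(exc)}
            )
    if not results:
        raise RuntimeError("all cases failed")

    rows = []
    fitted = {(r.case_id, r.modality) for r in results}
    for r in results:
        other = "echo" if r.modality == "mri" else "mri"
        if (r.case_id, other) in fitted:
            for metric, value in r.metrics().items():
                rows.append(
                    {"case_id": r.case_id, "modality": r.modality, "metric": metric, "value": value}
                )
    metrics = pd.DataFrame(rows)
    n_complete = metrics["case_id"].nunique() if not metrics.empty else 0
    # the concordance screen needs >= 4 complete cases; smaller cohorts still
    # return per-case results with an empty table
    report = cohort_report(metrics) if n_complete >= 4 else pd.DataFrame()

    outcome = CohortOutcome(results=tuple(results), failures=tuple(failures), report=report)
    if out_dir is not None:
        _write_cohort_artifacts(outcome, config, Path(out_dir))
    return outcome


def _write_cohort_artifacts(outcome: CohortOutcome, config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for r in outcome.results:
        case_dir = out / r.case_id
        case_dir.mkdir(exist_ok=True)
        stem = r.modality or "case"
        r.tmax_waveform.to_frame().to_csv(case_dir / f"{stem}_tmax.csv", index=False)
        (case_dir / f"{stem}_fit.json").write_text(json.dumps(r.to_dict(), indent=2))
    if not outcome.report.empty:
        outcome.report.to_csv(out / "concordance.csv", index=False)
        (out / "concordance.json").write_text(
            json.dumps(
                {
                    "axes": "regression: y = ECHO-derived, x = MRI-derived",
                    "rows": outcome.report.to_dict(orient="records"),
                },
                indent=2,
            )
        )
    (out / "run_config.json").write_text(json.dumps(config.to_dict(), indent=2))
    if outcome.failures:
        (out / "failures.json").write_text(json.dumps(list(outcome.failures), indent=2))
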