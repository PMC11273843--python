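"""Paired-modality agreement statistics.

Linear regression (gradient, intercept, R^2), Bland-Altman analysis in
absolute and percent modes (bias, 1.96-SD limits of agreement, rms
difference), and a Tukey 1.5-IQR outlier screen on paired differences.

Axis convention, stated in every report: y = ECHO-derived value regressed on
x = MRI-derived value.  Percent differences use the pairwise mean as
denominator.  Outliers are excluded from the regression but Bland-Altman
statistics are computed on all pairs, with both counts reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PairedMetric",
    "RegressionResult",
    "BlandAltmanResult",
    "ols_gradient",
    "bland_altman",
    "quartile_outliers",
    "cohort_report",
    "CONCORDANCE_METRICS",
    "MODALITY_A",
    "MODALITY_B",
]

MODALITY_A = "echo"  # regression y-axis
MODALITY_B = "mri"  # regression x-axis
LOA_MULTIPLIER = 1.96
IQR_FENCE = 1.5

CONCORDANCE_METRICS = ("EDV", "ESV", "SV", "EF", "peak_tmax", "time_to_peak")


@dataclass(frozen=True)
class PairedMetric:
    """One metric measured for the same cases by both modalities."""

    case_ids: tuple
    value_a: np.ndarray  # ECHO-derived
    value_b: np.ndarray  # MRI-derived
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.value_a, dtype=float)
        b = np.asarray(self.value_b, dtype=float)
        if a.shape != b.shape or a.ndim != 1 or len(a) != len(self.case_ids):
            raise ValueError("case ids and both value arrays must align")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("paired values must be finite")
        object.__setattr__(self, "value_a", a)
        object.__setattr__(self, "value_b", b)
        object.__setattr__(self, "case_ids", tuple(self.case_ids))

    def __len__(self) -> int:
        return len(self.case_ids)

    def subset(self, keep: np.ndarray) -> "PairedMetric":
        keep = np.asarray(keep)
        return PairedMetric(
            tuple(np.asarray(self.case_ids, dtype=object)[keep]),
            self.value_a[keep],
            self.value_b[keep],
            self.name,
            self.units,
        )


@dataclass(frozen=True)
class RegressionResult:
    gradient: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    rms: float
    mode: str  # "absolute" | "percent"
    n: int


def ols_gradient(pairs: PairedMetric) -> RegressionResult:
    """Ordinary least squares of the ECHO value (y) on the MRI value (x)."""
    if len(pairs) < 3:
        raise ValueError("regression requires at least 3 pairs")
    x, y = pairs.value_b, pairs.value_a
    if np.ptp(x) == 0:
        raise ValueError("regression undefined: x values are constant")
    design = np.column_stack([x, np.ones_like(x)])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RegressionResult(gradient=float(coef[0]), intercept=float(coef[1]), r_squared=r2)


def bland_altman(pairs: PairedMetric, mode: str = "absolute") -> BlandAltmanResult:
    """Bland-Altman agreement of ECHO vs MRI values.

    absolute mode: d_i = a_i - b_i;
    percent mode: d_i = 100 (a_i - b_i) / ((a_i + b_i)/2).
    bias = mean difference, LOA = bias +/- 1.96 sample SD, rms = sqrt(mean d^2).
    """
    if len(pairs) < 2:
        raise ValueError("Bland-Altman requires at least 2 pairs")
    a, b = pairs.value_a, pairs.value_b
    if mode == "absolute":
        d = a - b
    elif mode == "percent":
        mean = 0.5 * (a + b)
        if np.any(mean == 0):
            raise ValueError("percent mode undefined for a pair with a + b = 0")
        d = 100.0 * (a - b) / mean
    else:
        raise ValueError("mode must be 'absolute' or 'percent'")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        rms=float(np.sqrt(np.mean(d**2))),
        mode=mode,
        n=len(pairs),
    )


def quartile_outliers(differences: np.ndarray) -> np.ndarray:
    """Indices of values outside the Tukey fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation.
    """
    d = np.asarray(differences, dtype=float)
    if len(d) < 4:
        raise ValueError("outlier screen requires at least 4 values")
    q1, q3 = np.percentile(d, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - IQR_FENCE * iqr, q3 + IQR_FENCE * iqr
    return np.flatnonzero((d < lo) | (d > hi))


def cohort_report(metrics: pd.DataFrame) -> pd.DataFrame:
    """Concordance table across the cohort, one row per metric.

    ``metrics`` has columns case_id, modality ('echo'|'mri'), metric, value.
    Per metric: Tukey outlier screen on paired absolute differences, OLS
    regression (y = ECHO, x = MRI) on the retained pairs, Bland-Altman in
    absolute and percent modes on all pairs.
    """
    required = {"case_id", "modality", "metric", "value"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics frame needs columns {sorted(required)}")
    rows = []
    for name, sub in metrics.groupby("metric", sort=False):
        wide = sub.pivot_table(index="case_id", columns="modality", values="value")
        if not {MODALITY_A, MODALITY_B}.issubset(wide.columns):
            raise ValueError(f"metric {name}: both modalities required")
        wide = wide.dropna(subset=[MODALITY_A, MODALITY_B])
        if len(wide) < 4:
            raise ValueError(f"metric {name}: need >= 4 complete cases, got {len(wide)}")
        pairs = PairedMetric(
            tuple(wide.index), wide[MODALITY_A].to_numpy(), wide[MODALITY_B].to_numpy(), name
        )
        diffs = pairs.value_a - pairs.value_b
        out_idx = quartile_outliers(diffs)
        keep = np.setdiff1d(np.arange(len(pairs)), out_idx)
        retained = pairs.subset(keep)
        reg = ols_gradient(retained)
        ba_abs = bland_altman(pairs, "absolute")
        ba_pct = bland_altman(pairs, "percent")
        rows.append(
            {
                "metric": name,
                "n_total": len(pairs),
                "n_retained": len(retained),
                "outlier_cases": ",".join(str(pairs.case_ids[i]) for i in out_idx),
                "gradient": reg.gradient,
                "intercept": reg.intercept,
                "r_squared": reg.r_squared,
                "bias_abs": ba_abs.bias,
                "loa_low_abs": ba_abs.loa_low,
                "loa_high_abs": ba_abs.loa_high,
                "rms_abs": ba_abs.rms,
                "bias_pct": ba_pct.bias,
                "loa_low_pct": ba_pct.loa_low,
                "loa_high_pct": ba_pct.loa_high,
                "rms_pct": ba_pct.rms,
            }
        )
    report = pd.DataFrame(rows)
    report.attrs["axes"] = "regression: y = ECHO-derived, x = MRI-derived"
    return report
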