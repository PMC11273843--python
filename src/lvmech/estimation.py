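"""Per-timepoint contractility estimation.

Given a calibrated passive wall and synchronized pressure/volume samples over
one cardiac cycle, the contractility parameter Tmax is estimated independently
at each time point by minimizing the squared relative pressure mismatch
``((P - Ptilde)/P)^2``.  In the reduced model the simulated pressure is a
strictly increasing function of Tmax at fixed volume, so the minimizer is
found exactly by bracketed root finding; zero contractility is the natural
floor (points where the passive pressure already meets or exceeds the
measurement return Tmax = 0 with the residual reported).

Points with measured pressure below a masking floor (default 0.25 kPa,
about 1.9 mmHg) are excluded: the relative cost is ill-conditioned near zero
pressure.  A fit is declared converged when the maximum relative error over
unmasked points is below 5%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .constitutive import ActiveParams, PassiveParams
from .mechanics import ReducedWall, cavity_pressure, mmhg_to_kpa

__all__ = [
    "Waveform",
    "TmaxWaveform",
    "FitSummary",
    "resample_to_common_grid",
    "estimate_tmax_at_point",
    "estimate_tmax_waveform",
    "summarize_fit",
    "waveform_to_csv",
    "waveform_from_csv",
    "synchronized_from_csv",
    "MASKING_FLOOR_KPA",
    "CONVERGENCE_REL_ERROR",
    "TmaxEstimationError",
]

MASKING_FLOOR_KPA = 0.25
CONVERGENCE_REL_ERROR = 0.05
DEFAULT_TMAX_UPPER_KPA = 200.0
MAX_BRACKET_EXPANSIONS = 8


class TmaxEstimationError(RuntimeError):
    """Estimation failed; carries the residual at the best bracket endpoint."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class Waveform:
    """Time-stamped pressure (kPa) or volume (mL) series over one cycle."""

    times_s: np.ndarray
    values: np.ndarray
    kind: str  # "pressure" | "volume"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if len(t) < 8:
            raise ValueError("a waveform needs at least 8 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if self.kind not in ("pressure", "volume"):
            raise ValueError("kind must be 'pressure' or 'volume'")
        if self.kind == "volume" and np.any(v < 0):
            raise ValueError("volumes must be non-negative")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass(frozen=True)
class TmaxWaveform:
    """Estimated Tmax(t): values (kPa), per-point relative error, mask."""

    times_s: np.ndarray
    tmax_kpa: np.ndarray
    rel_error: np.ndarray  # NaN on masked points
    masked: np.ndarray  # True where the point was skipped

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.tmax_kpa) < 0):
            raise ValueError("Tmax must be non-negative everywhere")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "tmax_kPa": self.tmax_kpa,
                "rel_error": self.rel_error,
                "masked": self.masked.astype(int),
            }
        )


@dataclass(frozen=True)
class FitSummary:
    """Peak contractility, its timing, worst relative error, convergence flag."""

    peak_tmax_kpa: float
    time_to_peak_s: float
    max_rel_error: float
    converged: bool

    def to_dict(self) -> dict:
        return {
            "peak_tmax_kPa": self.peak_tmax_kpa,
            "time_to_peak_s": self.time_to_peak_s,
            "max_rel_error": self.max_rel_error,
            "converged": self.converged,
        }


def resample_to_common_grid(
    pressure: Waveform, volume: Waveform
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synchronize pressure onto the volume sampling grid.

    The volume grid (the modality's native acquisition grid) is kept;
    pressure is linearly interpolated onto it.  Returns (t, P, V) with one
    entry per volume sample.
    """
    if pressure.kind != "pressure" or volume.kind != "volume":
        raise ValueError("expected a pressure and a volume waveform, in that order")
    if volume.times_s[-1] < pressure.times_s[0] or volume.times_s[0] > pressure.times_s[-1]:
        raise ValueError("pressure and volume waveforms do not overlap in time")
    p = np.interp(volume.times_s, pressure.times_s, pressure.values)
    return volume.times_s.copy(), p, volume.values.copy()


def estimate_tmax_at_point(
    wall: ReducedWall,
    passive: PassiveParams,
    active: ActiveParams,
    volume_ml: float,
    pressure_kpa: float,
    upper_kpa: float = DEFAULT_TMAX_UPPER_KPA,
) -> tuple[float, float]:
    """Tmax (kPa) matching one measured (V, P) sample, and its relative error.

    Exploits strict monotonicity of the simulated pressure in Tmax: solves
    ``Ptilde(Tmax) = P`` by Brent's method with automatic upward bracket
    expansion (doubling, at most 8 times).  If the passive pressure already
    meets or exceeds the measurement, the non-negativity floor Tmax = 0 is
    returned with the resulting residual.
    """
    if pressure_kpa <= 0:
        raise ValueError("measured pressure must be positive (mask near-zero points)")
    p_passive = cavity_pressure(wall, volume_ml, passive, 0.0, active)
    if p_passive >= pressure_kpa:
        return 0.0, abs(p_passive - pressure_kpa) / pressure_kpa

    def f(t: float) -> float:
        return cavity_pressure(wall, volume_ml, passive, t, active) - pressure_kpa

    hi = upper_kpa
    f_hi = f(hi)
    expansions = 0
    while f_hi < 0.0:
        if expansions >= MAX_BRACKET_EXPANSIONS:
            raise TmaxEstimationError(
                "Tmax bracket expansion exhausted (active stress saturated below target)",
                residual=abs(f_hi) / pressure_kpa,
            )
        hi *= 2.0
        expansions += 1
        f_hi = f(hi)
    tmax = float(optimize.brentq(f, 0.0, hi, xtol=1e-10, rtol=4.0 * np.finfo(float).eps))
    resid = abs(cavity_pressure(wall, volume_ml, passive, tmax, active) - pressure_kpa)
    return tmax, resid / pressure_kpa


def estimate_tmax_waveform(
    wall: ReducedWall,
    passive: PassiveParams,
    active: ActiveParams,
    times_s: np.ndarray,
    pressure_kpa: np.ndarray,
    volume_ml: np.ndarray,
    masking_floor_kpa: float = MASKING_FLOOR_KPA,
    upper_kpa: float = DEFAULT_TMAX_UPPER_KPA,
) -> tuple[TmaxWaveform, FitSummary]:
    """Independent per-point Tmax estimation over a synchronized cycle.

    Points with measured pressure below the masking floor are skipped (at
    most half the cycle may be masked).  The summary's convergence flag is
    true when the worst unmasked relative error is below 5%.
    """
    t = np.asarray(times_s, dtype=float)
    p = np.asarray(pressure_kpa, dtype=float)
    v = np.asarray(volume_ml, dtype=float)
    if not (t.shape == p.shape == v.shape):
        raise ValueError("times, pressures and volumes must align")
    masked = p < masking_floor_kpa
    if masked.mean() > 0.5:
        raise TmaxEstimationError(
            f"{masked.sum()}/{len(p)} points below the {masking_floor_kpa} kPa floor: "
            "waveform not estimable"
        )
    tmax = np.zeros_like(p)
    rel = np.full_like(p, np.nan)
    for i in np.flatnonzero(~masked):
        tmax[i], rel[i] = estimate_tmax_at_point(wall, passive, active, v[i], p[i], upper_kpa)
    wf = TmaxWaveform(times_s=t.copy(), tmax_kpa=tmax, rel_error=rel, masked=masked)
    return wf, summarize_fit(wf)


def summarize_fit(w: TmaxWaveform) -> FitSummary:
    """Peak Tmax, time-to-peak (earliest sample on ties, no interpolation),
    and worst relative error over unmasked points."""
    keep = ~np.asarray(w.masked, dtype=bool)
    if not np.any(keep):
        raise ValueError("no unmasked points to summarize")
    tmax = np.asarray(w.tmax_kpa)[keep]
    times = np.asarray(w.times_s)[keep]
    rel = np.asarray(w.rel_error)[keep]
    i_peak = int(np.argmax(tmax))  # argmax returns the earliest tie
    max_rel = float(np.nanmax(rel))
    return FitSummary(
        peak_tmax_kpa=float(tmax[i_peak]),
        time_to_peak_s=float(times[i_peak]),
        max_rel_error=max_rel,
        converged=bool(max_rel < CONVERGENCE_REL_ERROR),
    )


# ---------------------------------------------------------------------------
# waveform CSV interface (time_s, pressure_kPa | pressure_mmHg | volume_mL)
# ---------------------------------------------------------------------------

def waveform_to_csv(w: Waveform, path) -> None:
    col = "pressure_kPa" if w.kind == "pressure" else "volume_mL"
    pd.DataFrame({"time_s": w.times_s, col: w.values}).to_csv(path, index=False)


def synchronized_from_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read an already-synchronized cycle CSV: one row per time point with
    columns time_s, pressure_kPa (or pressure_mmHg, converted on load) and
    volume_mL.  Returns (t, P_kPa, V_mL)."""
    df = pd.read_csv(path)
    missing = {"time_s", "volume_mL"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    v = df["volume_mL"].to_numpy(dtype=float)
    if "pressure_kPa" in df.columns:
        p = df["pressure_kPa"].to_numpy(dtype=float)
    elif "pressure_mmHg" in df.columns:
        p = np.asarray(mmhg_to_kpa(df["pressure_mmHg"].to_numpy(dtype=float)))
    else:
        raise ValueError(f"{path}: expected a pressure_kPa or pressure_mmHg column")
    return t, p, v


def waveform_from_csv(path) -> Waveform:
    """Read a waveform CSV; the value column header declares kind and unit.

    Accepted value columns: pressure_kPa, pressure_mmHg (converted to kPa on
    load), volume_mL.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing time_s column")
    t = df["time_s"].to_numpy(dtype=float)
    if "pressure_kPa" in df.columns:
        return Waveform(t, df["pressure_kPa"].to_numpy(dtype=float), "pressure")
    if "pressure_mmHg" in df.columns:
        return Waveform(t, mmhg_to_kpa(df["pressure_mmHg"].to_numpy(dtype=float)), "pressure")
    if "volume_mL" in df.columns:
        return Waveform(t, df["volume_mL"].to_numpy(dtype=float), "volume")
    raise ValueError(f"{path}: expected pressure_kPa, pressure_mmHg or volume_mL column")
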