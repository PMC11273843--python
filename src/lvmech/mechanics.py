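"""Reduced left-ventricular mechanics: incompressible thick-walled inflation.

The 3D finite-element problem is replaced by a spherically symmetric,
exactly incompressible thick wall with circumferential fibers (f = theta,
s = phi, n = r).  The radial map ``r(R) = (R^3 - Rin^3 + a^3)^(1/3)`` satisfies
J = 1 identically, so the hydrostatic Lagrange multiplier drops out of the
tangential-minus-radial Cauchy stress differences and the cavity pressure
follows from one radial equilibrium integral

    P = int_a^b (sigma_tt + sigma_pp - 2 sigma_rr) / r dr,

evaluated by Gauss-Legendre quadrature over the reference wall.  This
preserves the estimation contract of the full model — cavity pressure as a
monotone function of cavity volume and material state — at desk scale.

This module is also the single place where pressures cross the mmHg/kPa unit
boundary (measurements and the Klotz curve are mmHg; everything internal is
kPa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numpy.polynomial import legendre
from scipy import optimize

from .constitutive import ActiveParams, FiberStrain, PassiveParams, active_pk2, passive_pk2

__all__ = [
    "MMHG_TO_KPA",
    "mmhg_to_kpa",
    "kpa_to_mmhg",
    "ReducedWall",
    "PVPoint",
    "KlotzCurve",
    "cavity_pressure",
    "passive_pv_curve",
    "klotz_single_beat",
    "edpvr_to_csv",
    "inflate_to_pressure",
    "unload",
    "fit_passive",
    "PassiveFit",
    "sphere_volume_ml",
    "sphere_radius_cm",
    "NonphysicalStateError",
    "ConvergenceError",
    "InfeasibleParametersError",
]

#: 1 mmHg in kPa.  Applied in exactly this module.
MMHG_TO_KPA = 0.1333224


def mmhg_to_kpa(p: float | np.ndarray) -> float | np.ndarray:
    return p * MMHG_TO_KPA


def kpa_to_mmhg(p: float | np.ndarray) -> float | np.ndarray:
    return p / MMHG_TO_KPA


class NonphysicalStateError(ValueError):
    """Deformed state outside the admissible range (e.g. collapsed cavity)."""


class ConvergenceError(RuntimeError):
    """An iterative solve failed to meet its tolerance; carries a trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


class InfeasibleParametersError(RuntimeError):
    """No bracket could be established for a root solve."""


def sphere_volume_ml(r_cm: float) -> float:
    """Volume (mL = cm^3) of a sphere of radius r (cm)."""
    return 4.0 * math.pi / 3.0 * r_cm**3


def sphere_radius_cm(v_ml: float) -> float:
    """Radius (cm) of the sphere with volume v (mL)."""
    return (3.0 * v_ml / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class ReducedWall:
    """Unloaded reference wall: inner/outer radii (cm), circumferential fibers."""

    rin_cm: float
    rout_cm: float

    def __post_init__(self) -> None:
        if not 0.0 < self.rin_cm < self.rout_cm:
            raise ValueError(f"require 0 < Rin < Rout, got ({self.rin_cm}, {self.rout_cm})")

    @property
    def cavity_volume_ml(self) -> float:
        return sphere_volume_ml(self.rin_cm)

    @property
    def wall_volume_ml(self) -> float:
        return sphere_volume_ml(self.rout_cm) - sphere_volume_ml(self.rin_cm)

    def to_dict(self) -> dict:
        return {"Rin_cm": self.rin_cm, "Rout_cm": self.rout_cm, "wall_volume_mL": self.wall_volume_ml}


@dataclass(frozen=True)
class PVPoint:
    """One cavity pressure-volume state (kPa, mL)."""

    pressure_kpa: float
    volume_ml: float

    def __post_init__(self) -> None:
        if not self.volume_ml > 0:
            raise ValueError("volume must be > 0")


def _gauss_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    return legendre.leggauss(n)


def cavity_pressure(
    wall: ReducedWall,
    volume_ml: float,
    passive: PassiveParams,
    tmax_kpa: float = 0.0,
    active: ActiveParams | None = None,
    n_quad: int = 32,
    check_quadrature: bool = False,
) -> float:
    """Cavity pressure (kPa) of the inflated/compressed reduced wall.

    Kinematics: deformed inner radius a = (3V/4pi)^(1/3); the incompressible
    radial map gives tangential stretch lam_t = r/R and radial stretch
    lam_r = (R/r)^2 at every reference radius R.  Fiber and sheet strains both
    equal the tangential Green-Lagrange strain; the passive Fung law plus the
    active fiber stress enter the equilibrium integral through the Cauchy
    stress differences (hydrostatic part cancels exactly).

    P = 0 at the unloaded volume with Tmax = 0; strictly increasing in both
    volume and Tmax over physiological states.
    """
    if volume_ml <= 0:
        raise NonphysicalStateError("cavity volume must be > 0")
    if tmax_kpa > 0 and active is None:
        raise ValueError("active parameters required when Tmax > 0")

    a3 = 3.0 * volume_ml / (4.0 * math.pi)

    def integral(n: int) -> float:
        x, w = _gauss_nodes(n)
        half = 0.5 * (wall.rout_cm - wall.rin_cm)
        mid = 0.5 * (wall.rout_cm + wall.rin_cm)
        R = half * x + mid
        wq = half * w
        r3 = R**3 - wall.rin_cm**3 + a3
        if np.any(r3 <= 0.0):
            raise NonphysicalStateError("wall collapse: deformed radius not positive")
        r = np.cbrt(r3)
        lam_t = r / R
        lam_t2 = lam_t**2
        lam_r2 = lam_t2**-2
        e_t = 0.5 * (lam_t2 - 1.0)
        e_r = 0.5 * (lam_r2 - 1.0)
        s = passive_pk2(FiberStrain(eff=e_t, ess=e_t, enn=e_r), passive)
        s_ff = np.asarray(s.ff, dtype=float)
        if tmax_kpa > 0:
            s_ff = s_ff + active_pk2(e_t, tmax_kpa, active)
        # sigma_tt - sigma_rr and sigma_pp - sigma_rr (hydrostatic part cancels)
        d_tt = lam_t2 * s_ff - lam_r2 * np.asarray(s.nn)
        d_pp = lam_t2 * np.asarray(s.ss) - lam_r2 * np.asarray(s.nn)
        integrand = (d_tt + d_pp) / r * (R**2 / r**2)
        return float(np.sum(wq * integrand))

    p = integral(n_quad)
    if check_quadrature:
        p_ref = integral(2 * n_quad)
        scale = max(abs(p_ref), 1e-12)
        if abs(p - p_ref) / scale > 1e-4:
            import warnings

            warnings.warn(
                f"quadrature not converged: {n_quad}- vs {2*n_quad}-point differ by "
                f"{abs(p - p_ref) / scale:.2e} relative",
                RuntimeWarning,
                stacklevel=2,
            )
    return p


def passive_pv_curve(
    wall: ReducedWall,
    volumes_ml: np.ndarray,
    passive: PassiveParams,
    n_quad: int = 32,
) -> list[PVPoint]:
    """Passive (Tmax = 0) pressure at each grid volume: the model EDPVR."""
    volumes_ml = np.asarray(volumes_ml, dtype=float)
    return [
        PVPoint(pressure_kpa=cavity_pressure(wall, v, passive, n_quad=n_quad), volume_ml=float(v))
        for v in volumes_ml
    ]


def edpvr_to_csv(model_points: list[PVPoint], klotz: "KlotzCurve", path) -> None:
    """Export model and Klotz EDPVRs as CSV (volume_mL, pressure_kPa, source).

    The Klotz curve is evaluated on the same volume grid as the model points.
    """
    import pandas as pd

    vols = [p.volume_ml for p in model_points]
    rows = [
        {"volume_mL": p.volume_ml, "pressure_kPa": p.pressure_kpa, "source": "model"}
        for p in model_points
    ] + [
        {"volume_mL": v, "pressure_kPa": float(klotz.pressure_kpa(v)), "source": "klotz"}
        for v in vols
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class KlotzCurve:
    """Single-beat empirical EDPVR, normalized between V0 and V30.

    P(V) = An * ((V - V0)/(V30 - V0))^Bn in mmHg; V0 is the zero-pressure
    volume, V30 the volume at 30 mmHg.  The measured end-diastolic point used
    to build the curve lies on it by construction.
    """

    v0_ml: float
    v30_ml: float
    an_mmhg: float = 28.2
    bn: float = 2.79
    vm_ml: float | None = None
    pm_mmhg: float | None = None

    def __post_init__(self) -> None:
        if not self.v0_ml < self.v30_ml:
            raise ValueError("require V0 < V30")
        if not (self.an_mmhg > 0 and self.bn > 0):
            raise ValueError("An and Bn must be > 0")

    def pressure_mmhg(self, v_ml: float | np.ndarray) -> float | np.ndarray:
        v = np.asarray(v_ml, dtype=float)
        xi = np.clip((v - self.v0_ml) / (self.v30_ml - self.v0_ml), 0.0, None)
        out = self.an_mmhg * xi**self.bn
        if np.ndim(v_ml) == 0:
            return float(out)
        return out

    def pressure_kpa(self, v_ml: float | np.ndarray) -> float | np.ndarray:
        return mmhg_to_kpa(self.pressure_mmhg(v_ml))

    def to_dict(self) -> dict:
        return {
            "V0_mL": self.v0_ml,
            "V30_mL": self.v30_ml,
            "An_mmHg": self.an_mmhg,
            "Bn": self.bn,
            "Vm_mL": self.vm_ml,
            "Pm_mmHg": self.pm_mmhg,
        }


def klotz_single_beat(
    pm_mmhg: float, vm_ml: float, an_mmhg: float = 28.2, bn: float = 2.79
) -> KlotzCurve:
    """Single-beat EDPVR from one measured end-diastolic point (Pm in mmHg).

    V0 = Vm (0.6 - 0.006 Pm); V30 = V0 + (Vm - V0) / (Pm/An)^(1/Bn).
    Rejects non-diastolic pressures (Pm >= 100 mmHg would put V0 <= 0).
    """
    if not pm_mmhg > 0:
        raise ValueError("ED pressure must be > 0 mmHg")
    if pm_mmhg >= 100.0:
        raise ValueError("ED pressure >= 100 mmHg: not a diastolic state (V0 <= 0)")
    if not vm_ml > 0:
        raise ValueError("ED volume must be > 0 mL")
    v0 = vm_ml * (0.6 - 0.006 * pm_mmhg)
    v30 = v0 + (vm_ml - v0) / (pm_mmhg / an_mmhg) ** (1.0 / bn)
    return KlotzCurve(v0_ml=v0, v30_ml=v30, an_mmhg=an_mmhg, bn=bn, vm_ml=vm_ml, pm_mmhg=pm_mmhg)


def inflate_to_pressure(
    wall: ReducedWall,
    pressure_kpa: float,
    passive: PassiveParams,
    n_quad: int = 32,
    xtol_ml: float = 1e-10,
) -> float:
    """Cavity volume (mL) at which the passive wall carries a given pressure.

    Uses the strict monotonicity of the passive pressure-volume relation;
    bracket expanded geometrically from the unloaded volume.
    """
    if pressure_kpa == 0.0:
        return wall.cavity_volume_ml
    v_lo = wall.cavity_volume_ml

    def f(v: float) -> float:
        return cavity_pressure(wall, v, passive, n_quad=n_quad) - pressure_kpa

    if pressure_kpa > 0:
        v_hi = v_lo
        for _ in range(60):
            v_hi *= 1.3
            if f(v_hi) >= 0.0:
                break
        else:
            raise InfeasibleParametersError("could not bracket inflation volume")
        lo, hi = v_lo, v_hi
    else:
        v_hi = v_lo
        for _ in range(60):
            v_hi *= 0.7
            if f(v_hi) <= 0.0:
                break
        else:
            raise InfeasibleParametersError("could not bracket compression volume")
        lo, hi = v_hi, v_lo
    return float(optimize.brentq(f, lo, hi, xtol=xtol_ml))


def unload(
    measured_ed: PVPoint,
    wall_volume_ml: float,
    passive: PassiveParams,
    omega: float = 0.5,
    tol_cm: float = 1e-5,
    max_iter: int = 200,
) -> ReducedWall:
    """Recover the unloaded wall by the backward displacement fixed point.

    Finds the unloaded inner radius Rin such that inflating the wall (outer
    radius from exact wall-volume conservation) to the measured ED pressure
    reproduces the measured ED volume.  Relaxed fixed-point iteration
    ``Rin <- Rin + omega (a_target - a_model)``; falls back to a bracketed
    root solve on the same residual if the fixed point stalls.
    """
    if measured_ed.pressure_kpa < 0:
        raise ValueError("ED pressure must be >= 0")
    if not wall_volume_ml > 0:
        raise ValueError("wall volume must be > 0")
    a_target = sphere_radius_cm(measured_ed.volume_ml)
    if measured_ed.pressure_kpa == 0.0:
        return ReducedWall(a_target, sphere_radius_cm(measured_ed.volume_ml + wall_volume_ml))

    def wall_for(rin: float) -> ReducedWall:
        return ReducedWall(rin, (rin**3 + 3.0 * wall_volume_ml / (4.0 * math.pi)) ** (1.0 / 3.0))

    def a_model(rin: float) -> float:
        v = inflate_to_pressure(wall_for(rin), measured_ed.pressure_kpa, passive)
        return sphere_radius_cm(v)

    rin = a_target
    for _ in range(max_iter):
        resid = a_model(rin) - a_target
        if abs(resid) < tol_cm:
            return wall_for(rin)
        rin_new = rin - omega * resid
        if rin_new <= 0.0:
            rin_new = 0.5 * rin
        rin = rin_new

    # fixed point stalled: bracketed root solve on the same residual
    def g(rin_: float) -> float:
        return a_model(rin_) - a_target

    lo, hi = 0.05 * a_target, a_target
    g_hi = g(hi)
    g_lo = g(lo)
    for _ in range(20):
        if g_lo * g_hi <= 0.0:
            break
        lo *= 0.5
        g_lo = g(lo)
    else:
        raise InfeasibleParametersError("unload: no sign change in bracket after expansion")
    rin = float(optimize.brentq(g, lo, hi, xtol=0.1 * tol_cm))
    return wall_for(rin)


@dataclass(frozen=True)
class PassiveFit:
    """Converged passive calibration: fitted parameters, wall, iteration trace."""

    passive: PassiveParams
    wall: ReducedWall
    trace: tuple[dict, ...]
    converged: bool

    def to_dict(self) -> dict:
        return {
            "passive": self.passive.to_dict(),
            "wall": self.wall.to_dict(),
            "converged": self.converged,
            "trace": list(self.trace),
        }


def fit_passive(
    measured_ed: PVPoint,
    wall_volume_ml: float,
    klotz: KlotzCurve,
    template: PassiveParams | None = None,
    n_grid: int = 20,
    tol_c_rel: float = 1e-4,
    max_evals: int = 120,
    c_bounds_kpa: tuple[float, float] = (1e-3, 200.0),
) -> PassiveFit:
    """Calibrate the passive stress scale C against a Klotz EDPVR.

    Bounded 1-D search on log C of the nested least-squares objective

        F(C) = sum_j (P_model(V_j; C, unload(C)) - P_target(V_j))^2

    over ``n_grid`` volumes uniformly spanning [target V0, EDV]; the wall is
    re-unloaded (anchored through the measured ED point) inside every
    objective evaluation, so the returned wall and C are jointly consistent.
    The fit grid is anchored at the target curve's zero-pressure volume
    rather than the model's unloaded volume: a grid tied to the moving
    unloaded state collapses toward EDV as C stiffens, where any C matches
    trivially.

    ``klotz`` may be any object exposing ``pressure_kpa(volume_mL)`` and
    ``v0_ml``, which is how self-consistency tests substitute a
    model-generated target curve.  Coarse log-grid bracketing precedes the
    bounded Brent refinement; a minimizer pinned at the C bounds raises
    :class:`ConvergenceError`.
    """
    passive = template if template is not None else PassiveParams()
    edv = measured_ed.volume_ml
    v_lo = float(klotz.v0_ml)
    if not v_lo < edv:
        raise ValueError("target curve V0 must lie below the measured EDV")
    v_grid = np.linspace(v_lo, edv, n_grid)
    target = np.asarray(klotz.pressure_kpa(v_grid), dtype=float)
    trace: list[dict] = []
    wall_cache: dict[float, ReducedWall] = {}
    log_bounds = (math.log(c_bounds_kpa[0]), math.log(c_bounds_kpa[1]))

    def objective(log_c: float) -> float:
        if len(trace) >= max_evals:
            raise ConvergenceError(
                f"passive calibration not converged in {max_evals} evaluations", trace
            )
        c = math.exp(log_c)
        wall_ = unload(measured_ed, wall_volume_ml, replace(passive, C=c))
        p_mod = np.array([cavity_pressure(wall_, v, replace(passive, C=c)) for v in v_grid])
        f = float(np.sum((p_mod - target) ** 2))
        trace.append({"eval": len(trace), "C_kPa": c, "Rin_cm": wall_.rin_cm, "objective": f})
        wall_cache[log_c] = wall_
        return f

    # coarse bracket on a log grid, then bounded Brent refinement
    coarse = np.linspace(log_bounds[0], log_bounds[1], 13)
    f_coarse = [objective(lc) for lc in coarse]
    i_best = int(np.argmin(f_coarse))
    if i_best in (0, len(coarse) - 1):
        raise ConvergenceError(
            "passive calibration minimizer pinned at the C bounds", trace
        )
    res = optimize.minimize_scalar(
        objective,
        bounds=(coarse[i_best - 1], coarse[i_best + 1]),
        method="bounded",
        options={"xatol": tol_c_rel},
    )
    c_fit = float(math.exp(res.x))
    passive = replace(passive, C=c_fit)
    wall = wall_cache.get(float(res.x)) or unload(measured_ed, wall_volume_ml, passive)
    return PassiveFit(passive=passive, wall=wall, trace=tuple(trace), converged=True)
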