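"""Myocardial constitutive laws at a material point.

Passive behaviour follows the Fung-type transversely isotropic hyperelastic
law ``W = (C/2)(exp(Q) - 1)`` with a quadratic form ``Q`` in the Green-Lagrange
strain components expressed in the local fiber (f), sheet (s) and sheet-normal
(n) frame.  Active behaviour follows the Guccione-style active-stress law: a
Hill-type calcium fraction scales the contractility parameter ``Tmax`` along
the fiber direction, with a length-dependent calcium sensitivity ``ECa50``.

All stresses are second Piola-Kirchhoff components in the fiber frame, in kPa.
Strain components may be scalars or broadcastable numpy arrays, which is how
the reduced thick-wall solver evaluates whole quadrature grids in one call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PassiveParams",
    "ActiveParams",
    "FiberStrain",
    "FiberStress",
    "strain_energy",
    "passive_pk2",
    "eca50",
    "active_pk2",
    "NonphysicalStrainError",
]

#: Largest admissible Fung exponent; beyond this exp(Q) overflows float64 and
#: the strain state is far outside any physiological regime anyway.
Q_OVERFLOW = 700.0


class NonphysicalStrainError(ValueError):
    """Raised when a strain state is outside the admissible range."""


@dataclass(frozen=True)
class PassiveParams:
    """Passive Fung-law constants.

    C is the stress scale in kPa; bff, bxx, bfx are the dimensionless
    exponents weighting fiber, transverse and fiber-shear strains.  Only C is
    identifiable from a single end-diastolic pressure-volume curve, so the
    exponents default to literature values for ventricular myocardium and are
    held fixed during fitting (configurable).
    """

    C: float = 0.1
    bff: float = 29.9
    bxx: float = 13.5
    bfx: float = 26.6

    def __post_init__(self) -> None:
        for name in ("C", "bff", "bxx", "bfx"):
            if not getattr(self, name) > 0:
                raise ValueError(f"PassiveParams.{name} must be > 0")

    def to_dict(self) -> dict:
        return {"C_kPa": self.C, "bff": self.bff, "bxx": self.bxx, "bfx": self.bfx}


@dataclass(frozen=True)
class ActiveParams:
    """Active-stress constants of the Guccione-type law.

    ca0 / ca0max: peak and prescribed-maximum intracellular calcium (umol/L);
    b: length-sensitivity constant (1/um); l0: sarcomere length below which no
    active force develops (um); ls0: unloaded (reference) sarcomere length (um).
    Defaults follow the canonical active-stress parameterisation for
    ventricular myocardium.
    """

    ca0: float = 4.35
    ca0max: float = 4.35
    b: float = 4.75
    l0: float = 1.58
    ls0: float = 1.85

    def __post_init__(self) -> None:
        for name in ("ca0", "ca0max", "b", "l0", "ls0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ActiveParams.{name} must be > 0")

    def to_dict(self) -> dict:
        return {
            "Ca0_umol_per_L": self.ca0,
            "Ca0max_umol_per_L": self.ca0max,
            "B_per_um": self.b,
            "l0_um": self.l0,
            "ls0_um": self.ls0,
        }


def params_to_json(passive: PassiveParams, active: ActiveParams) -> str:
    """Serialize a parameter set with explicit units (fit provenance block)."""
    return json.dumps({"passive": passive.to_dict(), "active": active.to_dict()}, indent=2)


def params_from_json(text: str) -> tuple[PassiveParams, ActiveParams]:
    d = json.loads(text)
    p = d["passive"]
    a = d["active"]
    return (
        PassiveParams(C=p["C_kPa"], bff=p["bff"], bxx=p["bxx"], bfx=p["bfx"]),
        ActiveParams(
            ca0=a["Ca0_umol_per_L"],
            ca0max=a["Ca0max_umol_per_L"],
            b=a["B_per_um"],
            l0=a["l0_um"],
            ls0=a["ls0_um"],
        ),
    )


@dataclass(frozen=True)
class FiberStrain:
    """Green-Lagrange strain components in the fiber/sheet/normal frame.

    Components may be scalars or broadcastable arrays.  Normal components must
    exceed -0.5 so that the right Cauchy-Green tensor stays positive along the
    frame axes.
    """

    eff: float | np.ndarray = 0.0
    ess: float | np.ndarray = 0.0
    enn: float | np.ndarray = 0.0
    efs: float | np.ndarray = 0.0
    esf: float | np.ndarray = 0.0
    efn: float | np.ndarray = 0.0
    enf: float | np.ndarray = 0.0
    esn: float | np.ndarray = 0.0
    ens: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        for name in ("eff", "ess", "enn"):
            if np.any(np.asarray(getattr(self, name)) <= -0.5):
                raise NonphysicalStrainError(
                    f"FiberStrain.{name} <= -0.5: right Cauchy-Green not positive"
                )


@dataclass(frozen=True)
class FiberStress:
    """Second Piola-Kirchhoff stress components in the fiber frame (kPa)."""

    ff: float | np.ndarray = 0.0
    ss: float | np.ndarray = 0.0
    nn: float | np.ndarray = 0.0
    fs: float | np.ndarray = 0.0
    sf: float | np.ndarray = 0.0
    fn: float | np.ndarray = 0.0
    nf: float | np.ndarray = 0.0
    sn: float | np.ndarray = 0.0
    ns: float | np.ndarray = 0.0


def _fung_exponent(e: FiberStrain, p: PassiveParams) -> np.ndarray:
    q = (
        p.bff * np.square(e.eff)
        + p.bxx * (np.square(e.ess) + np.square(e.enn) + np.square(e.esn) + np.square(e.ens))
        + p.bfx * (np.square(e.efn) + np.square(e.enf) + np.square(e.efs) + np.square(e.esf))
    )
    if np.any(q > Q_OVERFLOW):
        raise NonphysicalStrainError(f"Fung exponent Q > {Q_OVERFLOW}: nonphysical strain state")
    return q


def strain_energy(e: FiberStrain, p: PassiveParams) -> float | np.ndarray:
    """Strain-energy density W = (C/2)(exp(Q) - 1), in kPa.

    W >= 0 with equality only at zero strain.
    """
    return 0.5 * p.C * np.expm1(_fung_exponent(e, p))


def passive_pk2(e: FiberStrain, p: PassiveParams) -> FiberStress:
    """Passive second Piola-Kirchhoff stress S = dW/dE in the fiber frame.

    Each component is ``C * exp(Q) * b_ij * E_ij`` with the exponent weight of
    its strain component; this is the exact gradient of :func:`strain_energy`
    when the nine components are treated as independent.
    """
    scale = p.C * np.exp(_fung_exponent(e, p))
    return FiberStress(
        ff=scale * p.bff * e.eff,
        ss=scale * p.bxx * e.ess,
        nn=scale * p.bxx * e.enn,
        sn=scale * p.bxx * e.esn,
        ns=scale * p.bxx * e.ens,
        fn=scale * p.bfx * e.efn,
        nf=scale * p.bfx * e.enf,
        fs=scale * p.bfx * e.efs,
        sf=scale * p.bfx * e.esf,
    )


def eca50(l_um: float | np.ndarray, a: ActiveParams) -> float | np.ndarray:
    """Length-dependent calcium sensitivity ECa50(l) in umol/L.

    ``ECa50 = Ca0max / sqrt(exp(B (l - l0)) - 1)``, strictly decreasing in
    sarcomere length l.  At or below the slack length l0 no active force can
    develop; the sensitivity is returned as +inf (a signalling value which the
    Hill fraction maps to zero stress).
    """
    l_arr = np.asarray(l_um, dtype=float)
    denom_sq = np.expm1(a.b * (l_arr - a.l0))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom_sq > 0.0, a.ca0max / np.sqrt(np.where(denom_sq > 0, denom_sq, 1.0)), np.inf)
    if np.isscalar(l_um) or np.ndim(l_um) == 0:
        return float(out)
    return out


def active_pk2(
    eff: float | np.ndarray, tmax_kpa: float, a: ActiveParams
) -> float | np.ndarray:
    """Active fiber-direction PK2 stress (kPa) of the Hill-type law.

    Sarcomere length l = ls0 * sqrt(2 Eff + 1); the stress is
    ``Tmax * Ca0^2 / (Ca0^2 + ECa50(l)^2)``, bounded by [0, Tmax], zero at or
    below slack length, saturating to Tmax for long sarcomeres.
    """
    if tmax_kpa < 0:
        raise ValueError("Tmax must be >= 0")
    lam_sq = 2.0 * np.asarray(eff, dtype=float) + 1.0
    if np.any(lam_sq <= 0.0):
        raise NonphysicalStrainError("2*Eff + 1 <= 0: nonphysical fiber strain")
    l_um = a.ls0 * np.sqrt(lam_sq)
    sens = np.asarray(eca50(l_um, a))
    with np.errstate(over="ignore"):
        frac = np.where(np.isinf(sens), 0.0, a.ca0**2 / (a.ca0**2 + np.square(np.where(np.isinf(sens), 1.0, sens))))
    out = tmax_kpa * frac
    if np.isscalar(eff) or np.ndim(eff) == 0:
        return float(out)
    return out
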