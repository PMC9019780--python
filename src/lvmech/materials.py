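"""Myocardial constitutive laws.

Passive response: Holzapfel-Ogden anisotropic hyperelasticity with an
isotropic exponential term, transversely anisotropic fiber/sheet terms and a
fiber-sheet coupling term, formulated on the isochoric right Cauchy-Green
tensor, plus a volumetric penalty enforcing near-incompressibility.  The
printed parameter set for this patient keeps only the isotropic pair (a, b)
and the fiber modulus af; a vanishing fiber exponent is handled by its exact
quadratic limit (af/2)(I4f-1)^2.  Anisotropic I4 terms engage only in fiber
tension (I4 > 1), the standard convention for muscle tissue.

Active response: time-varying elastance fiber tension - a cosine twitch whose
amplitude carries calcium and sarcomere-length dependence (ECa50) and whose
relaxation time scales linearly with instantaneous sarcomere length.  Active
stress acts along the deformed fiber direction only.

All stresses in kPa, lengths in mm, sarcomere lengths in um, time in s.
Functions are vectorized over arbitrary leading axes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PassiveParams", "ActiveParams", "DeformationState",
    "kinematics", "passive_energy", "passive_stress", "pk2_passive",
    "eca50", "active_fiber_stress", "pk2_total", "total_stress",
]

_EYE = np.eye(3)


class KinematicsError(ValueError):
    """Raised for non-physical deformation input (det F <= 0 etc.)."""


@dataclass(frozen=True)
class PassiveParams:
    """Holzapfel-Ogden constants (kPa / dimensionless) and volumetric penalty.

    ``bulk_modulus`` (kPa) sets the penalty through D = 2/K unless ``d_direct``
    overrides the raw D.  Defaults are the printed patient values: only a, b
    and af are nonzero.
    """

    a: float = 3.354
    b: float = 7.08
    af: float = 2.501
    bf: float = 0.0
    a_s: float = 0.0
    b_s: float = 0.0
    afs: float = 0.0
    bfs: float = 0.0
    bulk_modulus: float = 1000.0
    d_direct: float | None = None

    @property
    def D(self) -> float:
        return self.d_direct if self.d_direct is not None else 2.0 / self.bulk_modulus

    def validate(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be > 0")
        for n in ("af", "bf", "a_s", "b_s", "afs", "bfs"):
            if getattr(self, n) < 0:
                raise ValueError(f"{n} must be >= 0")
        if self.D <= 0:
            raise ValueError("volumetric penalty D must be > 0")

    def scaled(self, a_scale: float) -> "PassiveParams":
        """Uniform scaling of the ground-matrix stiffness a (calibration knob)."""
        return replace(self, a=self.a * a_scale)


@dataclass(frozen=True)
class ActiveParams:
    """Time-varying elastance twitch constants.

    tmax kPa, ca0/ca0max umol/l, m s/um, b_tr s, big_b 1/um, l0 um.  t0 (time
    to peak tension) and the cycle period are not part of the printed set;
    defaults 0.25 s and 0.8 s (75 bpm) are physiologic and config-exposed.
    ``eps_clamp`` keeps ECa50 finite as the sarcomere approaches l0.
    """

    tmax: float = 135.7
    ca0: float = 4.35
    ca0max: float = 4.35
    m: float = 1.0489
    b_tr: float = -1.429
    big_b: float = 4.750
    l0: float = 1.58
    t0: float = 0.25
    period: float = 0.8
    eps_clamp: float = 0.01

    def validate(self) -> None:
        if self.tmax <= 0 or self.l0 <= 0:
            raise ValueError("tmax and l0 must be > 0")
        if not 0 < self.t0 < self.period:
            raise ValueError("t0 must lie inside the cycle period")


@dataclass
class DeformationState:
    """Kinematic quantities at a material point (vectorized)."""

    F: np.ndarray
    J: np.ndarray
    Cbar: np.ndarray
    I1: np.ndarray
    I4f: np.ndarray
    I4s: np.ndarray
    I8fs: np.ndarray
    Eff: np.ndarray


# --------------------------------------------------------------------------
# kinematics
# --------------------------------------------------------------------------

def kinematics(F: np.ndarray, f0: np.ndarray, s0: np.ndarray) -> DeformationState:
    """Invariants of the isochoric right Cauchy-Green tensor plus fiber strain.

    ``F`` (..., 3, 3); ``f0``/``s0`` unit vectors (..., 3).  Raises
    :class:`KinematicsError` if det F <= 0.
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise KinematicsError("deformation gradient has non-positive determinant")
    C = np.einsum("...ki,...kj->...ij", F, F)
    Cbar = C * (J ** (-2.0 / 3.0))[..., None, None]
    I1 = np.trace(Cbar, axis1=-2, axis2=-1)
    I4f = np.einsum("...i,...ij,...j->...", f0, Cbar, f0)
    I4s = np.einsum("...i,...ij,...j->...", s0, Cbar, s0)
    I8fs = np.einsum("...i,...ij,...j->...", f0, Cbar, s0)
    Eff = 0.5 * (np.einsum("...i,...ij,...j->...", f0, C, f0) - 1.0)
    return DeformationState(F=F, J=J, Cbar=Cbar, I1=I1, I4f=I4f, I4s=I4s,
                            I8fs=I8fs, Eff=Eff)


# --------------------------------------------------------------------------
# passive energy and stress
# --------------------------------------------------------------------------

_TENSION_DELTA = 1e-4   # C1 smoothing width of the fiber tension-only switch


def _tension_part(x: np.ndarray):
    """Smoothed positive part of I4 - 1 and its derivative.

    The hard switch max(x, 0) puts every reference-state quadrature point
    exactly on a stiffness discontinuity; the one-sided quadratic blend
    s = x^2/(2 delta) on (0, delta), x - delta/2 beyond (delta = 1e-4, fiber
    strains of a few 1e-5) keeps the stress C1 while the reference state
    remains exactly stress-free.
    """
    d = _TENSION_DELTA
    s = np.where(x <= 0.0, 0.0, np.where(x >= d, x - 0.5 * d, x ** 2 / (2 * d)))
    ds = np.where(x <= 0.0, 0.0, np.where(x >= d, 1.0, x / d))
    return s, ds


def _aniso_energy(a_i: float, b_i: float, x: np.ndarray) -> np.ndarray:
    """(a/2b)(exp(b x^2) - 1), with the exact quadratic limit at b -> 0."""
    if a_i == 0.0:
        return np.zeros_like(x)
    if b_i > 1e-12:
        return a_i / (2.0 * b_i) * (np.exp(b_i * x ** 2) - 1.0)
    return 0.5 * a_i * x ** 2


def passive_energy(state: DeformationState, p: PassiveParams) -> np.ndarray:
    """Strain-energy density (kPa), normalized to zero in the reference state."""
    dev = p.a / (2.0 * p.b) * (np.exp(p.b * (state.I1 - 3.0)) - 1.0)
    dev = dev + _aniso_energy(p.af, p.bf, _tension_part(state.I4f - 1.0)[0])
    dev = dev + _aniso_energy(p.a_s, p.b_s, _tension_part(state.I4s - 1.0)[0])
    dev = dev + _aniso_energy(p.afs, p.bfs, state.I8fs)
    J = state.J
    vol = (1.0 / p.D) * (0.5 * (J ** 2 - 1.0) - np.log(J))
    return dev + vol


def pk2_passive(C: np.ndarray, f0: np.ndarray, s0: np.ndarray,
                p: PassiveParams) -> np.ndarray:
    """Second Piola-Kirchhoff passive stress from the right Cauchy-Green tensor.

    Analytic derivative of the energy: isochoric projection of the fictitious
    stress plus the volumetric term J U'(J) C^{-1}.  Exactly zero at C = I.
    """
    C = np.asarray(C, dtype=float)
    detC = np.linalg.det(C)
    if np.any(detC <= 0):
        raise KinematicsError("right Cauchy-Green tensor is not positive definite")
    J = np.sqrt(detC)
    Jm23 = detC ** (-1.0 / 3.0)
    Cbar = C * Jm23[..., None, None]
    Cinv = np.linalg.inv(C)

    I1 = np.trace(Cbar, axis1=-2, axis2=-1)
    I4f = np.einsum("...i,...ij,...j->...", f0, Cbar, f0)
    I4s = np.einsum("...i,...ij,...j->...", s0, Cbar, s0)
    I8 = np.einsum("...i,...ij,...j->...", f0, Cbar, s0)

    psi1 = 0.5 * p.a * np.exp(np.minimum(p.b * (I1 - 3.0), 100.0))
    x4f, dx4f = _tension_part(I4f - 1.0)
    psi4f = p.af * x4f * dx4f * np.exp(np.minimum(p.bf * x4f ** 2, 100.0))
    x4s, dx4s = _tension_part(I4s - 1.0)
    psi4s = p.a_s * x4s * dx4s * np.exp(np.minimum(p.b_s * x4s ** 2, 100.0))
    psi8 = p.afs * I8 * np.exp(np.minimum(p.bfs * I8 ** 2, 100.0))

    ff = np.einsum("...i,...j->...ij", f0, f0)
    ss = np.einsum("...i,...j->...ij", s0, s0)
    fs = np.einsum("...i,...j->...ij", f0, s0)
    sym_fs = 0.5 * (fs + np.swapaxes(fs, -1, -2))

    Sbar = 2.0 * (psi1[..., None, None] * _EYE
                  + psi4f[..., None, None] * ff
                  + psi4s[..., None, None] * ss
                  + psi8[..., None, None] * sym_fs)
    trSC = np.einsum("...ij,...ij->...", Sbar, C)
    S_iso = Jm23[..., None, None] * (Sbar - (trSC / 3.0)[..., None, None] * Cinv)

    Uprime = (1.0 / p.D) * (J - 1.0 / J)
    S_vol = (J * Uprime)[..., None, None] * Cinv
    return S_iso + S_vol


def passive_stress(F: np.ndarray, f0: np.ndarray, s0: np.ndarray,
                   p: PassiveParams) -> np.ndarray:
    """Passive Cauchy stress sigma = F S F^T / J (kPa), symmetric, zero at F=I."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise KinematicsError("deformation gradient has non-positive determinant")
    C = np.einsum("...ki,...kj->...ij", F, F)
    S = pk2_passive(C, f0, s0, p)
    return np.einsum("...iI,...IJ,...jJ->...ij", F, S, F) / J[..., None, None]


# --------------------------------------------------------------------------
# active law
# --------------------------------------------------------------------------

def eca50(l: np.ndarray, ap: ActiveParams) -> np.ndarray:
    """Length-dependent calcium sensitivity ECa50 (umol/l).

    ECa50 = Ca0max / sqrt(exp(B (l - l0)) - 1); strictly decreasing in l.
    Sarcomere lengths at or below l0 are clamped to l0 + eps so the activation
    factor tends to zero there instead of raising a domain error.
    """
    l = np.asarray(l, dtype=float)
    lc = np.maximum(l, ap.l0 + ap.eps_clamp)
    return ap.ca0max / np.sqrt(np.exp(np.minimum(ap.big_b * (lc - ap.l0), 100.0)) - 1.0)


def _omega(t: np.ndarray, tr: np.ndarray, ap: ActiveParams) -> np.ndarray:
    """Twitch phase: rising 0<=t<t0, relaxing t0<=t<=t0+tr, zero after."""
    t = np.asarray(t, dtype=float)
    rising = np.pi * t / ap.t0
    relaxing = np.pi * (t - ap.t0 + tr) / tr
    w = np.where(t < ap.t0, rising, np.where(t <= ap.t0 + tr, relaxing, 0.0))
    return np.where(t < 0, 0.0, w)


def active_fiber_stress(t: float, Eff: np.ndarray, lr: np.ndarray,
                        ap: ActiveParams) -> np.ndarray:
    """Active fiber tension sigma_af(t, Eff) in kPa; non-negative by construction.

    l = lr sqrt(2 Eff + 1); tr = m l + b_tr; amplitude Tmax/2 times the calcium
    activation factor Ca0^2/(Ca0^2+ECa50^2) times (1 - cos omega).
    """
    Eff = np.asarray(Eff, dtype=float)
    stretch_sq = 2.0 * Eff + 1.0
    if np.any(stretch_sq <= 0.0):
        raise KinematicsError("non-physical fiber state: 2*Eff + 1 <= 0")
    l = np.asarray(lr, dtype=float) * np.sqrt(stretch_sq)
    tr = np.maximum(ap.m * l + ap.b_tr, 1e-3)
    tmod = np.mod(t, ap.period)
    ec = eca50(l, ap)
    gain = ap.ca0 ** 2 / (ap.ca0 ** 2 + ec ** 2)
    w = _omega(tmod, tr, ap)
    return 0.5 * ap.tmax * gain * (1.0 - np.cos(w))


# --------------------------------------------------------------------------
# combined stress
# --------------------------------------------------------------------------

def pk2_total(C: np.ndarray, f0: np.ndarray, s0: np.ndarray, lr: np.ndarray,
              t: float, p: PassiveParams, ap: ActiveParams,
              active_scale: float = 1.0) -> np.ndarray:
    """Total second Piola-Kirchhoff stress (passive + active fiber tension).

    The active Cauchy stress sigma_af f^ (x) f^ pulls back to
    J sigma_af (f0 (x) f0)/I4f with I4f = f0.C f0.
    """
    S = pk2_passive(C, f0, s0, p)
    if active_scale != 0.0:
        I4 = np.einsum("...i,...ij,...j->...", f0, C, f0)
        Eff = 0.5 * (I4 - 1.0)
        saf = active_scale * active_fiber_stress(t, Eff, lr, ap)
        J = np.sqrt(np.linalg.det(C))
        ff = np.einsum("...i,...j->...ij", f0, f0)
        S = S + (J * saf / I4)[..., None, None] * ff
    return S


def total_stress(F: np.ndarray, f0: np.ndarray, s0: np.ndarray, lr: np.ndarray,
                 t: float, p: PassiveParams, ap: ActiveParams,
                 active_scale: float = 1.0) -> np.ndarray:
    """Total Cauchy stress (kPa): passive plus sigma_af along the deformed fiber."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise KinematicsError("deformation gradient has non-positive determinant")
    C = np.einsum("...ki,...kj->...ij", F, F)
    S = pk2_total(C, f0, s0, lr, t, p, ap, active_scale)
    return np.einsum("...iI,...IJ,...jJ->...ij", F, S, F) / J[..., None, None]
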