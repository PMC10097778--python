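"""Pointwise kinematics and constitutive model.

The tissue is modelled as two incompressible hyperelastic continua: the
intracellular space carries a Holzapfel–Ogden-type energy with an isotropic
exponential term in I1 and a one-sided exponential fiber term in I4f; the
extracellular matrix carries the isotropic term only.  Contraction enters
through an active-strain split F = F_p F_a with a transversely isotropic,
volume-preserving active factor F_a = diag(1-g, (1-g)^-1/2, (1-g)^-1/2)
in the fiber/sheet/normal frame, driven by a scalar activation g(t) that is
nonzero only inside the cells.

All stresses are in kPa, lengths in um, times in ms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np

__all__ = [
    "MaterialParams",
    "ActiveTransient",
    "TensorState",
    "active_deformation",
    "invariants",
    "strain_energy",
    "stresses",
]

PARAM_NAMES = ("a_i", "b_i", "a_if", "b_if", "a_e", "b_e")


@dataclass(frozen=True)
class MaterialParams:
    """The six constitutive scalars.

    a_i, a_if, a_e are stress-like (kPa); b_i, b_if, b_e are dimensionless
    exponential rates.  b -> 0 limits are handled analytically.
    """

    a_i: float = 5.70
    b_i: float = 11.67
    a_if: float = 19.83
    b_if: float = 24.72
    a_e: float = 1.52
    b_e: float = 16.31

    def __post_init__(self):
        for name in PARAM_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "MaterialParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, arr))))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MaterialParams":
        with open(path) as fh:
            return cls(**json.load(fh))


class ActiveTransient:
    """Scalar activation g(t) driving the active-strain factor.

    Either parametric — a smooth sin^2 rise to ``gamma_max`` at ``t_peak``
    followed by a cos^2 relaxation reaching zero at ``t_end`` — or tabulated
    from ``samples`` (two columns: time ms, gamma), linearly interpolated.
    """

    def __init__(self, gamma_max: float = 0.2, t_peak: float = 138.0,
                 t_end: float = 500.0, samples: np.ndarray | None = None):
        if samples is not None:
            samples = np.asarray(samples, dtype=float)
            if samples.ndim != 2 or samples.shape[1] != 2:
                raise ValueError("samples must be an (n, 2) array")
            t, g = samples[:, 0], samples[:, 1]
            if np.any(np.diff(t) <= 0):
                raise ValueError("sample times must be strictly increasing")
            if np.any((g < 0) | (g >= 1)):
                raise ValueError("gamma must satisfy 0 <= gamma < 1")
            if abs(g[0]) > 1e-12:
                raise ValueError("gamma(0) must be 0")
            self.t_peak = float(t[np.argmax(g)])
            self.t_end = float(t[-1])
            self.gamma_max = float(g.max())
        else:
            if not 0 <= gamma_max < 1:
                raise ValueError("gamma_max must be in [0, 1)")
            if not 0 < t_peak < t_end:
                raise ValueError("need 0 < t_peak < t_end")
            self.gamma_max, self.t_peak, self.t_end = gamma_max, t_peak, t_end
        self._samples = samples

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self._samples is not None:
            return np.interp(t, self._samples[:, 0], self._samples[:, 1])
        g = np.where(
            t <= self.t_peak,
            np.sin(0.5 * np.pi * np.clip(t, 0, None) / self.t_peak) ** 2,
            np.cos(0.5 * np.pi * np.clip(t - self.t_peak, 0, None)
                   / (self.t_end - self.t_peak)) ** 2)
        g = np.where(t >= self.t_end, 0.0, g)
        return self.gamma_max * g

    @classmethod
    def from_csv(cls, path) -> "ActiveTransient":
        import pandas as pd
        df = pd.read_csv(path)
        return cls(samples=df.iloc[:, :2].to_numpy())

    def to_csv(self, path, n: int = 101) -> None:
        import pandas as pd
        t = np.linspace(0, self.t_end, n)
        pd.DataFrame({"time_ms": t, "gamma": self(t)}).to_csv(path,
                                                              index=False)


@dataclass
class TensorState:
    """Pointwise kinematic/stress bundle at one material point."""

    F: np.ndarray
    F_a: np.ndarray
    F_p: np.ndarray
    J: float
    C_bar: np.ndarray
    I1: float
    I4f: float
    p: float = 0.0
    P: np.ndarray | None = None
    sigma: np.ndarray | None = None
    E: np.ndarray | None = None


def active_deformation(gamma: float) -> np.ndarray:
    """Active factor diag(1-g, (1-g)^-1/2, (1-g)^-1/2); det == 1 exactly."""
    if not 0 <= gamma < 1:
        raise ValueError("gamma must satisfy 0 <= gamma < 1 "
                         "(gamma >= 1 makes the active factor singular)")
    s = (1.0 - gamma) ** -0.5
    return np.diag([1.0 - gamma, s, s])


def invariants(F: np.ndarray, F_a: np.ndarray,
               f0: np.ndarray = np.array([1.0, 0.0, 0.0])):
    """(J, I1, I4f) of the modified isochoric elastic Cauchy–Green tensor.

    The elastic factor is F_p = F F_a^{-1}; the isochoric modification uses
    the total J = det F.
    """
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0:
        raise ValueError(f"det(F) = {J:.3g} <= 0 (inverted state)")
    det_a = np.linalg.det(F_a)
    if abs(det_a) < 1e-14:
        raise ValueError("active factor is singular")
    Fp = F @ np.linalg.inv(F_a)
    Cbar = J ** (-2 / 3) * (Fp.T @ Fp)
    I1 = float(np.trace(Cbar))
    I4f = float(f0 @ (Cbar @ f0))
    return J, I1, I4f


def _state(F, gamma, p=0.0, f0=np.array([1.0, 0.0, 0.0])) -> TensorState:
    Fa = active_deformation(gamma)
    J, I1, I4f = invariants(F, Fa, f0)
    Fp = F @ np.linalg.inv(Fa)
    return TensorState(F=np.asarray(F, float), F_a=Fa, F_p=Fp, J=J,
                       C_bar=J ** (-2 / 3) * (Fp.T @ Fp), I1=I1, I4f=I4f,
                       p=p)


def _exp_term(a: float, b: float, x: float) -> float:
    # a/(2b) (e^{bx} - 1); analytic b->0 limit a x / 2
    if b < 1e-12:
        return 0.5 * a * x
    return 0.5 * a / b * math.expm1(b * x)


def strain_energy(state: TensorState, params: MaterialParams,
                  subdomain: str) -> float:
    """Strain-energy density (kPa) for 'intracellular' or 'extracellular'."""
    if subdomain == "intracellular":
        q = max(state.I4f - 1.0, 0.0)
        w = _exp_term(params.a_i, params.b_i, state.I1 - 3.0)
        if params.b_if < 1e-12:
            w += 0.5 * params.a_if * q * q
        else:
            w += 0.5 * params.a_if / params.b_if * math.expm1(
                params.b_if * q * q)
        return w
    if subdomain == "extracellular":
        return _exp_term(params.a_e, params.b_e, state.I1 - 3.0)
    raise ValueError(f"unknown subdomain {subdomain!r}")


def _piola(F, gamma, p, a, b, af, bf, f0=None):
    """First Piola–Kirchhoff stress of the augmented energy psi + p(J-1).

    Works for real or complex F (complex-step differentiation); the fiber
    direction is the first frame axis.
    """
    one_m = 1.0 - gamma
    ai0 = 1.0 / one_m            # (F_a^{-1})_ff
    ai1 = math.sqrt(one_m)       # transverse entries
    Fp0 = F[:, 0] * ai0
    Fp1 = F[:, 1] * ai1
    Fp2 = F[:, 2] * ai1
    J = (F[0, 0] * (F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1])
         - F[0, 1] * (F[1, 0] * F[2, 2] - F[1, 2] * F[2, 0])
         + F[0, 2] * (F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0]))
    Jm23 = J ** (-2.0 / 3.0)
    trC = (Fp0 @ Fp0) + (Fp1 @ Fp1) + (Fp2 @ Fp2)
    I1 = Jm23 * trC
    I4 = Jm23 * (Fp0 @ Fp0)
    # cofactor matrix: J F^{-T}
    cof = np.empty_like(F)
    cof[0, 0] = F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1]
    cof[0, 1] = F[1, 2] * F[2, 0] - F[1, 0] * F[2, 2]
    cof[0, 2] = F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0]
    cof[1, 0] = F[0, 2] * F[2, 1] - F[0, 1] * F[2, 2]
    cof[1, 1] = F[0, 0] * F[2, 2] - F[0, 2] * F[2, 0]
    cof[1, 2] = F[0, 1] * F[2, 0] - F[0, 0] * F[2, 1]
    cof[2, 0] = F[0, 1] * F[1, 2] - F[0, 2] * F[1, 1]
    cof[2, 1] = F[0, 2] * F[1, 0] - F[0, 0] * F[1, 2]
    cof[2, 2] = F[0, 0] * F[1, 1] - F[0, 1] * F[1, 0]
    FinvT = cof / J

    dpsi1 = 0.5 * a * np.exp(b * (I1 - 3.0))
    # one-sided fiber term (branch on the real part for complex-step)
    active = (I4.real if np.iscomplexobj(F) else I4) > 1.0
    if active:
        q = I4 - 1.0
        dpsi4 = af * q * np.exp(bf * q * q)
    else:
        dpsi4 = 0.0 * I4

    # dI1/dF = Jm23 * 2 F Fa^{-1}Fa^{-T} - (2/3) I1 F^{-T}
    dI1 = np.empty_like(F)
    dI1[:, 0] = 2.0 * Jm23 * F[:, 0] * (ai0 * ai0)
    dI1[:, 1] = 2.0 * Jm23 * F[:, 1] * (ai1 * ai1)
    dI1[:, 2] = 2.0 * Jm23 * F[:, 2] * (ai1 * ai1)
    dI1 -= (2.0 / 3.0) * I1 * FinvT
    P = dpsi1 * dI1 + p * cof
    if active:
        dI4 = -(2.0 / 3.0) * I4 * FinvT
        dI4[:, 0] = dI4[:, 0] + 2.0 * Jm23 * (ai0 * ai0) * F[:, 0]
        P = P + dpsi4 * dI4
    return P


def stresses(state: TensorState, params: MaterialParams, subdomain: str,
             p: float = 0.0):
    """(P, sigma, E) at a material point of the augmented energy psi + p(J-1).

    P is the first Piola–Kirchhoff stress, sigma = J^{-1} P F^T the Cauchy
    stress, E = (F^T F - I)/2 the Green–Lagrange strain.
    """
    if state.J <= 0:
        raise ValueError("J <= 0: inverted state")
    gamma = 1.0 - float(state.F_a[0, 0])
    if subdomain == "intracellular":
        P = _piola(state.F, gamma, p, params.a_i, params.b_i,
                   params.a_if, params.b_if)
    elif subdomain == "extracellular":
        P = _piola(state.F, gamma, p, params.a_e, params.b_e, 0.0, 0.0)
    else:
        raise ValueError(f"unknown subdomain {subdomain!r}")
    F = state.F
    sigma = (P @ F.T) / state.J
    E = 0.5 * (F.T @ F - np.eye(3))
    state.P, state.sigma, state.E, state.p = P, sigma, E, p
    return P, sigma, E


def make_state(F, gamma: float = 0.0, p: float = 0.0) -> TensorState:
    """Convenience constructor for a :class:`TensorState` from F and gamma."""
    return _state(F, gamma, p)
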