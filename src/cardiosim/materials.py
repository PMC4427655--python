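"""Constitutive laws for myocardium, mitral leaflets and chordae tendineae.

Passive myocardium follows an orthotropic exponential (Holzapfel–Ogden-type)
strain-energy density expressed in the local fiber/sheet/normal frame, using
full (non-isochoric) invariants plus a ``(k/2) (ln J)^2`` volumetric penalty;
near-incompressibility is enforced by choosing the bulk penalty ``k`` much
larger than the shear-scale parameters.  The default parameter set is the
transversely isotropic one used throughout the package (only the isotropic and
fiber terms are nonzero).

Leaflet and chordae behaviour is represented by decoupled one-dimensional
two-parameter exponential laws relating true (Cauchy) stress to true
(logarithmic) strain; chordae are tension-only.  Active contraction is a
prescribed squared-sine tension pulse along the fiber direction with a linear
length dependence.

Units are fixed package-wide: kPa, mL, mm, s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SHEAR_MODES",
    "CURVE_MODES",
    "MaterialParamsHO",
    "DeformationState",
    "StressStrainCurve",
    "ExpLaw1D",
    "ActiveLaw",
    "strain_energy",
    "cauchy_stress",
    "shear_test",
    "stress_1d",
    "active_tension",
]

#: The six ordered simple-shear modes in the fiber (F), sheet (S), normal (N)
#: frame.  Mode "XY" shears the XY-plane such that material lines along axis
#: X are rotated and stretched (displacement along Y with gradient along X):
#: F = I + gamma * (e_Y ⊗ e_X).  FN and FS are therefore the fiber-stretching
#: (stiff) modes.
SHEAR_MODES = ("FS", "FN", "SF", "SN", "NF", "NS")

#: All labels a StressStrainCurve may carry: the shear rigs plus the 1-D
#: leaflet (circumferential / radial) and chordae (basal / marginal) tests.
CURVE_MODES = SHEAR_MODES + ("circumferential", "radial", "basal", "marginal")

_AXIS_INDEX = {"F": 0, "S": 1, "N": 2}


@dataclass(frozen=True)
class MaterialParamsHO:
    """Passive myocardium parameters (kPa for scales, dimensionless exponents).

    The defaults are the transversely isotropic set for normal human
    myocardium: ``k=1000, a=0.33, b=7.08, a_ff=0.25, b_ff=5.34`` with all
    sheet and fiber–sheet terms zero.
    """

    k: float = 1000.0
    a: float = 0.33
    b: float = 7.08
    a_ff: float = 0.25
    b_ff: float = 5.34
    a_ss: float = 0.0
    b_ss: float = 0.0
    a_fs: float = 0.0
    b_fs: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k", "a", "b", "a_ff", "b_ff", "a_ss", "b_ss", "a_fs", "b_fs"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {value}")

    def replace(self, **kwargs: float) -> "MaterialParamsHO":
        fields = {n: getattr(self, n) for n in ("k", "a", "b", "a_ff", "b_ff", "a_ss", "b_ss", "a_fs", "b_fs")}
        fields.update(kwargs)
        return MaterialParamsHO(**fields)


@dataclass(frozen=True)
class DeformationState:
    """A deformation gradient together with the reference material frame.

    ``f0, s0, n0`` are the unit fiber, sheet and sheet-normal directions in
    the reference configuration; they must be mutually orthonormal and
    ``det F`` must be positive.
    """

    F: np.ndarray
    f0: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    s0: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    n0: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        if F.shape != (3, 3):
            raise ValueError("F must be a 3x3 matrix")
        object.__setattr__(self, "F", F)
        if np.linalg.det(F) <= 0:
            raise ValueError("det F must be positive (non-invertible or inverted state)")
        frame = np.column_stack([self.f0, self.s0, self.n0]).astype(float)
        if not np.allclose(frame.T @ frame, np.eye(3), atol=1e-8):
            raise ValueError("f0, s0, n0 must be mutually orthonormal unit vectors")
        object.__setattr__(self, "f0", frame[:, 0])
        object.__setattr__(self, "s0", frame[:, 1])
        object.__setattr__(self, "n0", frame[:, 2])


@dataclass(frozen=True)
class StressStrainCurve:
    """True-strain / true-stress samples from one mechanical test.

    ``mode`` identifies the test: one of the six shear rigs or a 1-D tissue
    direction.  Strain is logarithmic (for the shear rigs the abscissa is the
    engineering shear amount gamma itself, recorded in ``meta``), stress is
    Cauchy stress in kPa.
    """

    mode: str
    strain: np.ndarray
    stress: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in CURVE_MODES:
            raise ValueError(f"unknown curve mode {self.mode!r}; expected one of {CURVE_MODES}")
        strain = np.asarray(self.strain, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        if strain.ndim != 1 or strain.shape != stress.shape or strain.size < 1:
            raise ValueError("strain and stress must be 1-D arrays of equal length")
        if strain.size >= 2 and not np.all(np.diff(strain) > 0):
            raise ValueError("strain must be strictly increasing")
        object.__setattr__(self, "strain", strain)
        object.__setattr__(self, "stress", stress)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mode": self.mode, "strain": self.strain, "stress_kPa": self.stress})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> list["StressStrainCurve"]:
        df = pd.read_csv(path)
        curves = []
        for mode, grp in df.groupby("mode", sort=False):
            curves.append(cls(mode=str(mode), strain=grp["strain"].to_numpy(), stress=grp["stress_kPa"].to_numpy()))
        return curves


@dataclass(frozen=True)
class ExpLaw1D:
    """Two-parameter exponential true-stress/true-strain law.

    sigma(eps) = A (exp(B eps) - 1) for eps >= 0.  With ``tension_only``
    (chordae) negative strain yields zero stress; otherwise the same formula
    extends to compression (where it is negative).
    """

    A: float
    B: float
    tension_only: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.A) and self.A >= 0):
            raise ValueError(f"A must be finite and >= 0, got {self.A}")
        if not (np.isfinite(self.B) and self.B > 0):
            raise ValueError(f"B must be finite and > 0, got {self.B}")


@dataclass(frozen=True)
class ActiveLaw:
    """Prescribed active fiber-tension waveform.

    A squared-sine pulse of peak ``T_max`` (kPa) on the window
    ``[t_act, t_act + t_dur]`` within the cycle, scaled by a linear length
    dependence ``g(lambda) = max(0, 1 + length_dep (lambda - 1))``.
    """

    T_max: float = 120.0
    t_act: float = 0.0
    t_dur: float = 0.55
    length_dep: float = 4.0

    def __post_init__(self) -> None:
        if self.T_max < 0:
            raise ValueError("T_max must be >= 0")
        if self.t_dur <= 0:
            raise ValueError("t_dur must be > 0")


# ---------------------------------------------------------------------------
# passive myocardium law
# ---------------------------------------------------------------------------

def _exp_term(scale: float, expo: float, x: float) -> float:
    """Energy contribution scale/(2 expo) (exp(expo x) - 1), with the
    zero-scale term exactly 0 and the expo -> 0 limit scale * x / 2."""
    if scale == 0.0:
        return 0.0
    if expo == 0.0:
        return 0.5 * scale * x
    return scale / (2.0 * expo) * np.expm1(expo * x)


def strain_energy(params: MaterialParamsHO, state: DeformationState) -> float:
    """Strain-energy density (kPa) of the passive myocardium law.

    Psi = a/(2b) (e^{b(I1-3)} - 1) - a ln J
        + sum_{i in ff,ss} a_i/(2 b_i) (e^{b_i <I4i-1>^2} - 1)
        + a_fs/(2 b_fs) (e^{b_fs I8fs^2} - 1)
        + k/2 (ln J)^2

    with <x> = max(x, 0) so fiber and sheet terms act in tension only, and
    any term with zero scale contributing exactly 0.  The ``-a ln J`` term is
    the standard compensation that renders the reference configuration
    stress-free when full (non-isochoric) invariants are used; it vanishes on
    every isochoric deformation.
    """
    F = state.F
    C = F.T @ F
    J = np.linalg.det(F)
    I1 = np.trace(C)
    I4f = float(state.f0 @ C @ state.f0)
    I4s = float(state.s0 @ C @ state.s0)
    I8fs = float(state.f0 @ C @ state.s0)

    psi = _exp_term(params.a, params.b, I1 - 3.0) - params.a * np.log(J)
    psi += _exp_term(params.a_ff, params.b_ff, max(I4f - 1.0, 0.0) ** 2)
    psi += _exp_term(params.a_ss, params.b_ss, max(I4s - 1.0, 0.0) ** 2)
    psi += _exp_term(params.a_fs, params.b_fs, I8fs**2)
    psi += 0.5 * params.k * np.log(J) ** 2
    return float(psi)


def _first_pk_stress(params: MaterialParamsHO, state: DeformationState) -> np.ndarray:
    """Analytic first Piola–Kirchhoff stress dPsi/dF."""
    F = state.F
    C = F.T @ F
    J = np.linalg.det(F)
    I1 = np.trace(C)
    I4f = float(state.f0 @ C @ state.f0)
    I4s = float(state.s0 @ C @ state.s0)
    I8fs = float(state.f0 @ C @ state.s0)
    f0, s0 = state.f0, state.s0

    P = np.zeros((3, 3))
    if params.a > 0:
        # dPsi/dI1 = a/2 e^{b(I1-3)} ; dI1/dF = 2F ; reference compensation
        P += params.a * (np.exp(params.b * (I1 - 3.0)) * F - np.linalg.inv(F).T)
    for scale, expo, I4, d0 in (
        (params.a_ff, params.b_ff, I4f, f0),
        (params.a_ss, params.b_ss, I4s, s0),
    ):
        e4 = I4 - 1.0
        if scale > 0 and e4 > 0:
            # dPsi/dI4 = scale e4 e^{expo e4^2} ; dI4/dF = 2 (F d0) ⊗ d0
            coeff = 2.0 * scale * e4 * np.exp(expo * e4 * e4)
            P += coeff * np.outer(F @ d0, d0)
    if params.a_fs > 0 and I8fs != 0.0:
        coeff = params.a_fs * I8fs * np.exp(params.b_fs * I8fs**2)
        P += coeff * (np.outer(F @ s0, f0) + np.outer(F @ f0, s0))
    if params.k > 0:
        P += params.k * np.log(J) * np.linalg.inv(F).T
    return P


def cauchy_stress(params: MaterialParamsHO, state: DeformationState) -> np.ndarray:
    """True (Cauchy) stress tensor sigma = J^{-1} (dPsi/dF) F^T in kPa."""
    J = np.linalg.det(state.F)
    sigma = _first_pk_stress(params, state) @ state.F.T / J
    # symmetrize away floating-point asymmetry
    return 0.5 * (sigma + sigma.T)


def shear_test(
    params: MaterialParamsHO,
    mode: str,
    gammas: np.ndarray,
) -> StressStrainCurve:
    """Virtual simple-shear rig in the fiber frame.

    For mode "XY" the deformation is F = I + gamma (e_Y ⊗ e_X) in the
    (f0, s0, n0) frame — material lines along X are sheared, so I4_X grows as
    1 + gamma^2 and the X-direction exponential term engages.  The recorded
    curve is the shear component sigma_XY of Cauchy stress versus the shear
    amount gamma (reported as the true-strain abscissa of the rig, noted in
    the curve metadata).
    """
    if mode not in SHEAR_MODES:
        raise ValueError(f"unknown shear mode {mode!r}; expected one of {SHEAR_MODES}")
    gammas = np.asarray(gammas, dtype=float)
    if np.any(gammas < 0):
        raise ValueError("shear amounts must be >= 0")
    i, j = _AXIS_INDEX[mode[0]], _AXIS_INDEX[mode[1]]
    stresses = np.empty_like(gammas)
    for idx, g in enumerate(gammas):
        F = np.eye(3)
        F[j, i] += g
        sigma = cauchy_stress(params, DeformationState(F=F))
        stresses[idx] = sigma[i, j]
    return StressStrainCurve(
        mode=mode,
        strain=gammas,
        stress=stresses,
        meta={"abscissa": "engineering shear amount gamma"},
    )


# ---------------------------------------------------------------------------
# 1-D laws
# ---------------------------------------------------------------------------

def stress_1d(law: ExpLaw1D, strain) -> np.ndarray | float:
    """True stress (kPa) of the 1-D exponential law at true strain ``strain``.

    Vectorized over ``strain``.  Tension-only laws (chordae) return 0 for
    negative strain.
    """
    eps = np.asarray(strain, dtype=float)
    sigma = law.A * np.expm1(law.B * eps)
    if law.tension_only:
        sigma = np.where(eps > 0.0, sigma, 0.0)
    if np.isscalar(strain) or eps.ndim == 0:
        return float(sigma)
    return sigma


def active_tension(law: ActiveLaw, t: float, fiber_stretch: float = 1.0) -> float:
    """Active fiber Cauchy stress (kPa) at time ``t`` within the cycle.

    T = T_max * sin^2(pi (t - t_act)/t_dur) on the activation window, zero
    outside, scaled by the clamped linear length dependence g(lambda).
    """
    tau = t - law.t_act
    if tau < 0.0 or tau > law.t_dur:
        return 0.0
    w = np.sin(np.pi * tau / law.t_dur) ** 2
    g = max(0.0, 1.0 + law.length_dep * (fiber_stretch - 1.0))
    return float(law.T_max * w * g)
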