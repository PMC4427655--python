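"""Reduced-order left ventricle.

The ventricle is a truncated-ellipsoid cavity described by its wall volume,
unloaded cavity volume and long-axis aspect ratio.  Kinematics are lumped
into a single representative fiber stretch that grows with cavity volume;
total fiber Cauchy stress (passive myocardium law + prescribed active
tension) maps to cavity pressure through a thick-wall logarithmic (one-fiber)
relation

    P = (sigma_f / 3) * ln(1 + V_wall / V_cav).

An infarct is a wall-volume fraction ``phi`` in which no active stress is
generated at any time during the cycle; its only other effect is the
papillary-muscle displacement handed to the valve model.  The module also
provides the infarct-sizing bisection (find ``phi`` that lowers the ejection
fraction to a prescribed target) and the healthy-baseline calibration
protocol (tune peak active tension and aspect ratio so the converged cycle
matches target ejection fraction and long-axis shortening).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .materials import ActiveLaw, MaterialParamsHO, active_tension

__all__ = [
    "VentricleGeometry",
    "InfarctRegion",
    "VentricleState",
    "fiber_stretch",
    "passive_fiber_stress",
    "cavity_pressure",
    "long_axis_length",
    "size_infarct",
    "calibrate_baseline",
    "CalibrationResult",
]


@dataclass(frozen=True)
class VentricleGeometry:
    """Truncated-ellipsoid LV geometry (volumes in mL, aspect dimensionless).

    ``aspect`` is the ratio of the long semi-axis to the short semi-axis of
    the equivalent prolate spheroid; it only affects the long-axis length
    readout, not the pressure–volume behaviour.
    """

    V_wall: float = 150.0
    V_cav_ref: float = 20.0
    aspect: float = 1.0

    def __post_init__(self) -> None:
        if self.V_wall <= 0:
            raise ValueError("V_wall must be > 0")
        if self.V_cav_ref <= 0:
            raise ValueError("V_cav_ref must be > 0")
        if self.aspect < 1.0:
            raise ValueError("aspect must be >= 1 (long axis at least as long as short axis)")


@dataclass(frozen=True)
class InfarctRegion:
    """Infarcted wall-volume fraction and papillary-displacement coupling.

    ``phi`` is the fraction of the wall generating no active stress;
    ``pap_disp_scale`` converts ``phi`` into a papillary-tip displacement
    magnitude (mm per unit phi) used by the valve model.
    """

    phi: float = 0.0
    pap_disp_scale: float = 40.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"phi must lie in [0, 1], got {self.phi}")
        if self.pap_disp_scale < 0:
            raise ValueError("pap_disp_scale must be >= 0")


@dataclass(frozen=True)
class VentricleState:
    """Snapshot of the lumped ventricle at one time point."""

    t: float
    V_cav: float
    lambda_f: float
    sigma_f: float
    P: float
    L: float


def fiber_stretch(geom: VentricleGeometry, V_cav: float) -> float:
    """Representative fiber stretch at cavity volume ``V_cav`` (mL).

    lambda_f = ((V_cav + V_wall/3) / (V_cav_ref + V_wall/3))^(1/3); equals 1
    at the unloaded volume and grows monotonically with filling (mid-wall
    radius scaling of the thick-wall sphere).
    """
    if V_cav <= 0:
        raise ValueError("V_cav must be > 0")
    third = geom.V_wall / 3.0
    return ((V_cav + third) / (geom.V_cav_ref + third)) ** (1.0 / 3.0)


def passive_fiber_stress(params: MaterialParamsHO, lam: float) -> float:
    """Fiber-direction passive Cauchy stress under isochoric uniaxial stretch.

    The deformation is F = diag(lam, lam^-1/2, lam^-1/2) with the fiber along
    the stretched axis; the hydrostatic pressure is eliminated by requiring
    zero transverse (sheet-direction) Cauchy stress, so the returned value is
    sigma_ff - sigma_ss of the incompressible law.
    """
    if lam <= 0:
        raise ValueError("fiber stretch must be > 0")
    lam2 = lam * lam
    inv = 1.0 / lam
    I1 = lam2 + 2.0 * inv
    # isotropic matrix term: sigma_iso = a e^{b(I1-3)} B, B = F F^T
    sigma = params.a * math.exp(params.b * (I1 - 3.0)) * (lam2 - inv)
    # fiber term, tension-only: adds to sigma_ff
    e4f = lam2 - 1.0
    if params.a_ff > 0.0 and e4f > 0.0:
        sigma += 2.0 * params.a_ff * e4f * math.exp(params.b_ff * e4f * e4f) * lam2
    # sheet term, tension-only: transverse I4s = 1/lam > 1 in fiber
    # compression; subtracts from the transverse-stress elimination
    e4s = inv - 1.0
    if params.a_ss > 0.0 and e4s > 0.0:
        sigma -= 2.0 * params.a_ss * e4s * math.exp(params.b_ss * e4s * e4s) * inv
    return sigma


def cavity_pressure(
    geom: VentricleGeometry,
    params: MaterialParamsHO,
    act: ActiveLaw,
    inf: InfarctRegion,
    t: float,
    V_cav: float,
) -> float:
    """Cavity pressure (kPa) at time ``t`` in the cycle and volume ``V_cav``.

    Total fiber stress is the passive uniaxial fiber stress plus the active
    tension scaled by the non-infarcted wall fraction (1 - phi); the
    thick-wall relation P = sigma_f/3 * ln(1 + V_wall/V_cav) closes the model.
    """
    lam = fiber_stretch(geom, V_cav)
    sigma_f = passive_fiber_stress(params, lam)
    if act.T_max > 0.0 and inf.phi < 1.0:
        sigma_f += (1.0 - inf.phi) * active_tension(act, t, lam)
    return sigma_f / 3.0 * math.log(1.0 + geom.V_wall / V_cav)


def long_axis_length(geom: VentricleGeometry, V_cav: float) -> float:
    """Long-axis length (mm) of the equivalent prolate spheroid.

    L = 2 c with semi-axes (c, r, r), c = aspect * r and cavity volume
    V = 4/3 pi r^2 c, i.e. L = 2 aspect^(2/3) (3 V / 4 pi)^(1/3) with V in
    mL (cm^3) converted to mm.
    """
    if V_cav <= 0:
        raise ValueError("V_cav must be > 0")
    return 20.0 * geom.aspect ** (2.0 / 3.0) * (3.0 * V_cav / (4.0 * math.pi)) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# infarct sizing and baseline calibration
# ---------------------------------------------------------------------------

def size_infarct(model, ef_target: float, tol: float = 0.0025) -> InfarctRegion:
    """Find the infarct fraction that lowers the ejection fraction to target.

    Bisects ``phi`` on [0, 0.6] using full limit-cycle runs of the coupled
    ventricle–circulation model (EF is monotone non-increasing in ``phi``).
    Raises ``ValueError`` naming the achievable EF range when the target lies
    outside it.  Deterministic.
    """
    from .circulation import run_cycle  # deferred: circulation imports this module

    def ef_at(phi: float) -> float:
        m = model.with_infarct(replace(model.infarct, phi=phi))
        return run_cycle(m).EF

    lo, hi = 0.0, 0.6
    ef_lo, ef_hi = ef_at(lo), ef_at(hi)
    if ef_target > ef_lo + tol or ef_target < ef_hi - tol:
        raise ValueError(
            f"EF target {ef_target:.3f} unreachable: achievable EF range is "
            f"[{ef_hi:.3f}, {ef_lo:.3f}] for phi in [0, 0.6]"
        )
    if abs(ef_lo - ef_target) <= tol:
        return replace(model.infarct, phi=lo)
    if abs(ef_hi - ef_target) <= tol:
        return replace(model.infarct, phi=hi)
    phi_mid, ef_mid = lo, ef_lo
    for _ in range(60):
        phi_mid = 0.5 * (lo + hi)
        ef_mid = ef_at(phi_mid)
        if abs(ef_mid - ef_target) <= tol and (hi - lo) < 0.02:
            break
        if ef_mid > ef_target:
            lo = phi_mid
        else:
            hi = phi_mid
        if hi - lo < 1e-5:
            break
    if abs(ef_mid - ef_target) > tol:
        raise ValueError(
            f"infarct sizing did not reach |EF - {ef_target:.3f}| <= {tol:.4f}; "
            f"closest EF {ef_mid:.4f} at phi = {phi_mid:.4f}"
        )
    return replace(model.infarct, phi=phi_mid)


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the healthy-baseline calibration protocol."""

    T_max: float
    aspect: float
    EF: float
    shortening: float
    EDV: float
    ESV: float
    n_evals: int

    def summary(self) -> str:
        return (
            "Healthy-baseline calibration\n"
            f"  T_max   = {self.T_max:8.3f} kPa\n"
            f"  aspect  = {self.aspect:8.4f}\n"
            f"  EF      = {100 * self.EF:8.2f} %\n"
            f"  short.  = {self.shortening:8.3f} mm\n"
            f"  EDV/ESV = {self.EDV:6.1f} / {self.ESV:6.1f} mL\n"
        )


def calibrate_baseline(
    model,
    ef_target: float = 0.55,
    shortening_target: float = 12.1,
    tol_ef: float = 0.005,
    tol_shortening: float = 0.2,
    T_max_bracket: tuple[float, float] = (5.0, 400.0),
) -> CalibrationResult:
    """Two-parameter calibration of the healthy baseline.

    Solves the two-target root-finding problem (EF, shortening) over
    (T_max, aspect).  The system is triangular — the aspect ratio scales the
    long-axis readout but does not feed back into the pressure–volume
    dynamics — so T_max is found by bracketed root finding on the EF residual
    and the aspect then follows in closed form from the converged volumes:

        shortening = 20 aspect^(2/3) (3/4pi)^(1/3) (EDV^(1/3) - Vmin^(1/3)).

    Raises if the implied aspect falls below 1 or EF cannot be bracketed.
    """
    from scipy.optimize import brentq

    from .circulation import run_cycle

    n_evals = 0

    def ef_residual(T_max: float) -> float:
        nonlocal n_evals
        n_evals += 1
        m = model.with_active(replace(model.active, T_max=T_max))
        return run_cycle(m).EF - ef_target

    lo, hi = T_max_bracket
    r_lo, r_hi = ef_residual(lo), ef_residual(hi)
    if r_lo * r_hi > 0:
        raise ValueError(
            f"EF target {ef_target:.3f} not bracketed by T_max in {T_max_bracket}: "
            f"EF({lo}) = {r_lo + ef_target:.3f}, EF({hi}) = {r_hi + ef_target:.3f}"
        )
    T_max = brentq(ef_residual, lo, hi, xtol=1e-3, rtol=1e-6)
    m = model.with_active(replace(model.active, T_max=T_max))
    cyc = run_cycle(m)

    v_min = min(cyc.V_lv)
    per_aspect = 20.0 * (3.0 / (4.0 * math.pi)) ** (1.0 / 3.0) * (
        cyc.EDV ** (1.0 / 3.0) - v_min ** (1.0 / 3.0)
    )
    if per_aspect <= 0:
        raise ValueError("no volume excursion in the converged cycle; cannot calibrate aspect")
    aspect = (shortening_target / per_aspect) ** 1.5
    if aspect < 1.0:
        raise ValueError(
            f"shortening target {shortening_target} mm implies aspect {aspect:.3f} < 1; "
            "reduce preload (end-diastolic volume) or the target"
        )
    geom = replace(model.geom, aspect=aspect)
    m2 = m.with_geometry(geom)
    cyc2 = run_cycle(m2)
    if abs(cyc2.EF - ef_target) > tol_ef:
        raise ValueError(f"calibrated EF {cyc2.EF:.4f} misses target {ef_target} beyond tol {tol_ef}")
    if abs(cyc2.shortening - shortening_target) > tol_shortening:
        raise ValueError(
            f"calibrated shortening {cyc2.shortening:.3f} mm misses target "
            f"{shortening_target} beyond tol {tol_shortening}"
        )
    return CalibrationResult(
        T_max=float(T_max),
        aspect=float(aspect),
        EF=float(cyc2.EF),
        shortening=float(cyc2.shortening),
        EDV=float(cyc2.EDV),
        ESV=float(cyc2.ESV),
        n_evals=n_evals,
    )
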