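"""Lumped-compartment circulation coupled to the reduced-order ventricle.

Two dynamic states — LV cavity volume and arterial pressure — with diode
(one-way) mitral and aortic valves, a single Windkessel (arterial compliance
discharging through a peripheral resistance) and constant venous filling
pressure.  A mitral regurgitant leak is a square-root orifice law driven by
the transvalvular pressure and a time-dependent gap area supplied by the
valve model (zero for a competent valve).

`run_cycle` integrates repeated cardiac cycles until a periodic limit cycle
is reached and summarizes the final cycle (PV loop, EDV/ESV/EF, long-axis
shortening, regurgitant volume per beat).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .materials import ActiveLaw, MaterialParamsHO
from .ventricle import (
    InfarctRegion,
    VentricleGeometry,
    cavity_pressure,
    fiber_stretch,
    long_axis_length,
)

__all__ = [
    "CirculationParams",
    "HeartModel",
    "CycleResult",
    "step",
    "run_cycle",
    "compare_cycles",
]


@dataclass(frozen=True)
class CirculationParams:
    """Windkessel and valve parameters (kPa, mL, s units).

    Defaults are physiological stand-ins: venous filling pressure ~4 mmHg,
    systolic arterial pressure ~120 mmHg, one beat per second.
    ``k_orifice`` is the regurgitant orifice coefficient of the square-root
    leak law Q = k A sqrt(dP) (mL/s per mm^2 per sqrt(kPa)); the default
    follows from the Bernoulli orifice equation for blood with a discharge
    coefficient of 0.62.
    """

    P_ven: float = 0.55
    R_mv: float = 0.003
    R_av: float = 0.005
    C_art: float = 8.0
    R_per: float = 0.32
    P_art_init: float = 11.0
    k_orifice: float = 0.85

    def __post_init__(self) -> None:
        for name in ("R_mv", "R_av", "C_art", "R_per"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.k_orifice < 0:
            raise ValueError("k_orifice must be >= 0")


@dataclass(frozen=True)
class HeartModel:
    """Full configuration of the coupled ventricle–circulation model.

    ``A_gap`` is an optional callable mapping time-in-cycle (s) to a mitral
    regurgitant gap area (mm^2); ``None`` means a competent valve.
    """

    geom: VentricleGeometry = field(default_factory=VentricleGeometry)
    materials: MaterialParamsHO = field(default_factory=MaterialParamsHO)
    active: ActiveLaw = field(default_factory=ActiveLaw)
    infarct: InfarctRegion = field(default_factory=InfarctRegion)
    circ: CirculationParams = field(default_factory=CirculationParams)
    period: float = 1.0
    dt: float = 0.001
    A_gap: Callable[[float], float] | None = None

    def with_geometry(self, geom: VentricleGeometry) -> "HeartModel":
        return replace(self, geom=geom)

    def with_active(self, active: ActiveLaw) -> "HeartModel":
        return replace(self, active=active)

    def with_infarct(self, infarct: InfarctRegion) -> "HeartModel":
        return replace(self, infarct=infarct)

    def with_gap(self, A_gap: Callable[[float], float] | None) -> "HeartModel":
        return replace(self, A_gap=A_gap)

    def pressure(self, t: float, V: float) -> float:
        return cavity_pressure(self.geom, self.materials, self.active, self.infarct, t, V)


@dataclass
class State:
    """Integrator state: time in cycle, LV volume, arterial pressure."""

    t: float
    V_lv: float
    P_art: float


@dataclass(frozen=True)
class CycleResult:
    """Time series and summary scalars of one (final) cardiac cycle."""

    t: np.ndarray
    V_lv: np.ndarray
    P_lv: np.ndarray
    P_art: np.ndarray
    L: np.ndarray
    Q_reg: np.ndarray
    EDV: float
    ESV: float
    EF: float
    shortening: float
    regurgitant_volume: float
    converged: bool
    n_cycles: int = 0

    @staticmethod
    def ef_from_volumes(EDV: float, ESV: float) -> float:
        """Ejection fraction (EDV - ESV)/EDV from end-diastolic and
        end-systolic volumes."""
        if EDV <= 0:
            raise ValueError("EDV must be > 0")
        return (EDV - ESV) / EDV

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "V_ml": self.V_lv,
                "P_lv_kPa": self.P_lv,
                "P_art_kPa": self.P_art,
                "L_mm": self.L,
                "Q_reg_ml_s": self.Q_reg,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "EDV_ml": self.EDV,
            "ESV_ml": self.ESV,
            "EF": self.EF,
            "shortening_mm": self.shortening,
            "regurgitant_volume_ml": self.regurgitant_volume,
            "peak_P_lv_kPa": float(np.max(self.P_lv)),
            "converged": self.converged,
            "n_cycles": self.n_cycles,
        }


def _flows(model: HeartModel, t: float, V: float, P_lv: float, P_art: float) -> tuple[float, float, float]:
    c = model.circ
    q_in = max(0.0, (c.P_ven - P_lv) / c.R_mv)
    q_out = max(0.0, (P_lv - P_art) / c.R_av)
    q_reg = 0.0
    if model.A_gap is not None and c.k_orifice > 0.0:
        area = model.A_gap(t)
        if area > 0.0 and P_lv > c.P_ven:
            q_reg = c.k_orifice * area * math.sqrt(P_lv - c.P_ven)
    return q_in, q_out, q_reg


def step(state: State, model: HeartModel, dt: float) -> State:
    """Advance the circulation by ``dt`` with explicit sub-stepped Euler.

    The sub-step count is chosen from the local stiffness estimate
    (dP_lv/dV times the open-valve conductance) so the explicit update stays
    stable; NaN or non-positive volumes abort with a diagnostic.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    c = model.circ
    t, V, P_art = state.t, state.V_lv, state.P_art
    g = 1.0 / c.R_mv + 1.0 / c.R_av
    lam_art = 1.0 / (c.R_per * c.C_art) + 1.0 / (c.R_av * c.C_art)
    t_end = state.t + dt
    guard = 0
    while t < t_end - 1e-12:
        P_lv = model.pressure(t, V)
        # local stiffness: dP_lv/dV times the open-path conductances
        dPdV = abs(model.pressure(t, V * 1.001) - P_lv) / (0.001 * V)
        lam = dPdV * g + lam_art
        h = min(t_end - t, 0.5 / lam if lam > 0 else dt)
        q_in, q_out, q_reg = _flows(model, t, V, P_lv, P_art)
        V_new = V + (q_in - q_out - q_reg) * h
        # cavity-obliteration floor: the thick-wall closure admits no
        # vanishing volume; scale the outflows (keeping the arterial charge
        # consistent, so volume stays conserved) instead of integrating past
        # collapse
        if V_new < 0.25:
            total_out = q_out + q_reg
            if total_out > 0.0:
                deficit = (0.25 - V_new) / h
                factor = max(0.0, 1.0 - deficit / total_out)
                q_out *= factor
                q_reg *= factor
            V_new = 0.25
        V = V_new
        P_art += (q_out - P_art / c.R_per) / c.C_art * h
        t += h
        guard += 1
        if guard > 100000 or not (math.isfinite(V) and math.isfinite(P_art)) or V <= 0:
            raise FloatingPointError(
                f"circulation integration diverged at t={t:.4f}s: V={V}, P_art={P_art}"
            )
    return State(t=t_end, V_lv=V, P_art=P_art)


def _initial_volume(model: HeartModel) -> float:
    """Passive equilibrium volume at the venous pressure (bisection)."""
    lo, hi = model.geom.V_cav_ref, model.geom.V_cav_ref
    p_ven = model.circ.P_ven
    act_off = replace(model, active=replace(model.active, T_max=0.0))
    while act_off.pressure(0.0, hi) < p_ven and hi < 1000.0:
        hi *= 1.5
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if act_off.pressure(0.0, mid) < p_ven:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def run_cycle(
    model: HeartModel,
    max_cycles: int = 50,
    volume_tol: float = 0.1,
) -> CycleResult:
    """Integrate repeated cardiac cycles to a periodic limit cycle.

    Convergence: the maximum absolute difference between the sampled LV
    volume traces of two consecutive cycles falls below ``volume_tol`` (mL).
    The final cycle is summarized; ``converged=False`` (result still
    returned) if ``max_cycles`` is exhausted.
    """
    n_steps = max(2, int(round(model.period / model.dt)))
    dt = model.period / n_steps
    state = State(t=0.0, V_lv=_initial_volume(model), P_art=model.circ.P_art_init)

    prev_trace: np.ndarray | None = None
    converged = False
    n_cycles = 0
    t_arr = np.empty(n_steps + 1)
    v_arr = np.empty(n_steps + 1)
    p_arr = np.empty(n_steps + 1)
    pa_arr = np.empty(n_steps + 1)
    qr_arr = np.empty(n_steps + 1)

    for cycle in range(max_cycles):
        n_cycles = cycle + 1
        state.t = 0.0
        for i in range(n_steps + 1):
            t_arr[i] = state.t
            v_arr[i] = state.V_lv
            pa_arr[i] = state.P_art
            p_lv = model.pressure(state.t, state.V_lv)
            p_arr[i] = p_lv
            qr_arr[i] = _flows(model, state.t, state.V_lv, p_lv, state.P_art)[2]
            if i < n_steps:
                state = step(state, model, dt)
        # limit cycle: volume trace periodic; the arterial pressure must be
        # periodic too, else a flat-volume transient (closed aortic valve
        # while the Windkessel still discharges) converges spuriously
        if (
            prev_trace is not None
            and np.max(np.abs(v_arr - prev_trace)) < volume_tol
            and abs(pa_arr[-1] - pa_arr[0]) < 0.02
        ):
            converged = True
            break
        prev_trace = v_arr.copy()

    L = np.array([long_axis_length(model.geom, v) for v in v_arr])
    EDV = float(np.max(v_arr))
    ESV = float(np.min(v_arr))
    EF = CycleResult.ef_from_volumes(EDV, ESV)
    shortening = float(L[int(np.argmax(v_arr))] - np.min(L))
    reg_vol = float(np.trapezoid(qr_arr, t_arr))
    return CycleResult(
        t=t_arr.copy(),
        V_lv=v_arr.copy(),
        P_lv=p_arr.copy(),
        P_art=pa_arr.copy(),
        L=L,
        Q_reg=qr_arr.copy(),
        EDV=EDV,
        ESV=ESV,
        EF=EF,
        shortening=shortening,
        regurgitant_volume=reg_vol,
        converged=converged,
        n_cycles=n_cycles,
    )


def compare_cycles(baseline: CycleResult, variant: CycleResult) -> dict:
    """Tabulate scalar deltas (variant - baseline) and overlay PV-loop data."""
    if not (baseline.converged and variant.converged):
        raise ValueError("both cycles must be converged limit cycles")
    deltas = {
        "dEDV_ml": variant.EDV - baseline.EDV,
        "dESV_ml": variant.ESV - baseline.ESV,
        "dEF": variant.EF - baseline.EF,
        "dPeak_P_lv_kPa": float(np.max(variant.P_lv) - np.max(baseline.P_lv)),
        "dRegurgitant_volume_ml": variant.regurgitant_volume - baseline.regurgitant_volume,
        "dShortening_mm": variant.shortening - baseline.shortening,
    }
    overlay = {
        "baseline": {"V_ml": baseline.V_lv.tolist(), "P_kPa": baseline.P_lv.tolist()},
        "variant": {"V_ml": variant.V_lv.tolist(), "P_kPa": variant.P_lv.tolist()},
    }
    return {"deltas": deltas, "pv_overlay": overlay}
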