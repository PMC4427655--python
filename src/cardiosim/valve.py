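"""Quasi-static mitral-apparatus model.

The valve is discretized into independent radial strips around the annulus.
Each strip carries a 2-D mechanical problem in its own cutting plane
(x: anterior -> posterior across the annulus, y: apical, positive toward the
apex): two elastic leaflet cables (anterior and posterior) hinged at the
annulus, loaded by the transvalvular pressure acting normal to their
segments, tethered by tension-only exponential chordae to a papillary tip,
with penalty contact (i) between the opposing leaflets (coaptation) and
(ii) against the rigid sub-valvular element of the annuloplasty device when
present.  Equilibrium is found by damped Newton iteration on the assembled
nodal force residual (the distributed pressure load on an open, free-edged
cable is follower-like and has no global potential); an independent
root-solver route over the same residual serves as a cross-check in the
test suite.

Annulus kinematics follow cavity volume, D(t) ∝ V(t)^(1/3) relative to a
reference volume; the rigid annuloplasty ring overrides the diameter with a
time-invariant undersized value.  An infarct displaces the papillary tips of
the posterior (infarct-sector) strips apically and laterally in a 2:1 ratio,
scaled by phi * pap_disp_scale.  Strip gap widths integrate to the
regurgitant orifice area handed back to the circulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .circulation import CycleResult
from .materials import ExpLaw1D, stress_1d
from .ventricle import InfarctRegion

__all__ = [
    "ChordaSpec",
    "ValveGeometry",
    "DeviceGeometry",
    "ContactParams",
    "StripSolution",
    "ValveSolution",
    "ValveTrace",
    "ValveConvergenceError",
    "default_valve_geometry",
    "attach_device",
    "solve_strip",
    "solve_valve",
    "chordae_force_trace",
]


class ValveConvergenceError(RuntimeError):
    """Newton iteration failed; carries the last residual norm."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class ChordaSpec:
    """One chorda of a strip: which cable it inserts on, where, and its
    material.  ``rest_length`` (mm) is the slack length; ``area`` (mm^2) the
    reference cross-section."""

    kind: str  # "basal" | "marginal"
    cable: str  # "anterior" | "posterior"
    insertion_frac: float
    rest_length: float
    law: ExpLaw1D
    area: float

    def __post_init__(self) -> None:
        if self.kind not in ("basal", "marginal"):
            raise ValueError("chorda kind must be 'basal' or 'marginal'")
        if self.cable not in ("anterior", "posterior"):
            raise ValueError("chorda cable must be 'anterior' or 'posterior'")
        if not 0.0 < self.insertion_frac <= 1.0:
            raise ValueError("insertion_frac must lie in (0, 1]")
        if self.rest_length <= 0 or self.area <= 0:
            raise ValueError("rest_length and area must be > 0")


@dataclass(frozen=True)
class DeviceGeometry:
    """Rigid annuloplasty ring with optional sub-valvular element.

    The ring undersizes (and freezes) the annulus diameter by
    ``undersize_factor``; the sub-valvular element is a rigid cylinder of
    radius ``subvalvular_radius`` whose section sits ``subvalvular_depth`` mm
    below and ``subvalvular_reach`` mm anterior of the posterior annulus
    point, engaging the posterior chordae (string wrap) and leaflet (contact)
    of the strips it covers.
    """

    undersize_factor: float = 0.92
    ring_plane_offset: float = 0.0
    subvalvular_depth: float = 11.0
    subvalvular_reach: float = 6.0
    subvalvular_radius: float = 4.0
    enabled_subvalvular: bool = True
    covered_strips: tuple[int, ...] = (6, 7, 8, 9, 10, 11)

    def __post_init__(self) -> None:
        if not 0.5 <= self.undersize_factor <= 1.0:
            raise ValueError(
                f"undersize_factor must lie in [0.5, 1], got {self.undersize_factor}"
            )
        if self.subvalvular_radius <= 0:
            raise ValueError("subvalvular_radius must be > 0")


@dataclass(frozen=True)
class ContactParams:
    """Penalty-contact and Newton-solver settings."""

    penalty_stiffness: float = 1000.0  # kPa/mm
    gap_tol: float = 0.05  # mm
    max_newton_iters: int = 80
    residual_tol: float = 1e-8  # relative to the pressure-load force scale
    #: absolute convergence floor (kPa mm^2 = µN-scale): below this the
    #: force imbalance is mechanically meaningless and the floppy unloaded
    #: modes of a slack strip cannot be driven further
    residual_abs: float = 5e-3

    def __post_init__(self) -> None:
        if self.penalty_stiffness <= 0:
            raise ValueError("penalty_stiffness must be > 0")


@dataclass(frozen=True)
class ValveGeometry:
    """Strip-discretized mitral apparatus.

    ``pap_tips`` holds the healthy papillary tip (x, y) per strip in the
    strip plane; ``chordae`` the per-strip chordae (same set each strip);
    ``infarct_strips`` the posterior-papillary sector displaced by an
    infarct.  ``annulus_diameter`` is the reference diameter at cavity
    volume ``annulus_ref_volume``.
    """

    n_strips: int = 12
    annulus_diameter: float = 30.0
    anterior_len: float = 24.0
    posterior_len: float = 16.0
    pap_tips: np.ndarray = field(default_factory=lambda: np.tile([4.0, 22.0], (12, 1)))
    chordae: tuple[ChordaSpec, ...] = ()
    leaflet_law: ExpLaw1D = field(default_factory=lambda: ExpLaw1D(A=15.0, B=15.0))
    thickness: float = 1.0
    n_seg_anterior: int = 8
    n_seg_posterior: int = 6
    coapt_point: tuple[float, float] = (5.0, 7.0)
    annulus_ref_volume: float = 71.0
    infarct_strips: tuple[int, ...] = (6, 7, 8, 9, 10, 11)
    #: fractional regional annular dilation per unit infarct fraction,
    #: applied to the infarct-sector strips (ischemic remodeling dilates the
    #: posterior annulus; the rigid ring removes it)
    annular_dilation_coeff: float = 0.5
    #: systolic apical excursion of a healthy, actively contracting papillary
    #: tip (mm at peak load); an infarcted papillary muscle generates no
    #: active stress and loses this excursion entirely
    pap_systolic_shortening: float = 3.5
    device: DeviceGeometry | None = None

    def __post_init__(self) -> None:
        if self.n_strips < 6:
            raise ValueError("n_strips must be >= 6")
        if self.anterior_len <= 0 or self.posterior_len <= 0:
            raise ValueError("leaflet lengths must be > 0")
        tips = np.asarray(self.pap_tips, dtype=float)
        if tips.shape != (self.n_strips, 2):
            raise ValueError(f"pap_tips must have shape ({self.n_strips}, 2)")
        object.__setattr__(self, "pap_tips", tips)

    def scallop_label(self, strip: int) -> str:
        labels = ("A1-P1", "A2-P2", "A3-P3")
        per = max(1, self.n_strips // 3)
        return labels[min(strip // per, 2)]

    def strip_width(self, diameter: float) -> float:
        return math.pi * diameter / self.n_strips


def default_valve_geometry(
    leaflet_laws: dict[str, ExpLaw1D] | None = None,
    chordae_laws: dict[str, ExpLaw1D] | None = None,
    slack: float = 1.0,
    slack_anterior: float = 1.08,
    **overrides,
) -> ValveGeometry:
    """Build the default apparatus with chordae rest lengths derived from a
    nominal closed (systolic) configuration.

    The nominal configuration routes each leaflet straight from its annulus
    hinge to the coaptation point, with the leftover leaflet length hanging
    as a vertical coaptation tail.  Chordae rest lengths are the nominal
    pap-tip-to-insertion distances scaled by ``slack`` (posterior) and
    ``slack_anterior`` (anterior marginal): anterior marginal chordae are
    relatively longer, reflecting the anterior leaflet's greater excursion —
    in systole it leans on the coapted posterior leaflet rather than hanging
    on its chordae, and ischemic posterior tethering can therefore uncouple
    the free edges.  Each strip carries one basal and one marginal posterior
    chorda and a marginal anterior chorda.
    """
    from .calibration import DEFAULT_CHORDAE_LAWS, DEFAULT_LEAFLET_LAWS

    leaflet_laws = leaflet_laws or DEFAULT_LEAFLET_LAWS
    chordae_laws = chordae_laws or DEFAULT_CHORDAE_LAWS
    geom = ValveGeometry(leaflet_law=leaflet_laws["radial"], **overrides)
    pap = geom.pap_tips[0]

    def nominal_point(cable: str, frac: float) -> np.ndarray:
        nodes = _nominal_cable(geom, cable, geom.annulus_diameter)
        # walk the polyline to the requested arc length
        remaining = frac * (geom.anterior_len if cable == "anterior" else geom.posterior_len)
        for i in range(nodes.shape[0] - 1):
            d = float(np.linalg.norm(nodes[i + 1] - nodes[i]))
            if remaining <= d or i == nodes.shape[0] - 2:
                return nodes[i] + (nodes[i + 1] - nodes[i]) * (remaining / d)
            remaining -= d
        return nodes[-1]

    chordae = []
    for kind, cable, frac, area in (
        ("basal", "posterior", 0.55, 0.7),
        ("marginal", "posterior", 1.0, 0.4),
        ("marginal", "anterior", 1.0, 0.4),
    ):
        pt = nominal_point(cable, frac)
        s = slack_anterior if cable == "anterior" else slack
        rest = s * float(np.linalg.norm(pt - pap))
        chordae.append(
            ChordaSpec(
                kind=kind,
                cable=cable,
                insertion_frac=frac,
                rest_length=rest,
                law=chordae_laws[kind],
                area=area,
            )
        )
    return replace(geom, chordae=tuple(chordae))


def attach_device(geom: ValveGeometry, device: DeviceGeometry) -> ValveGeometry:
    """Pin the annulus to the undersized rigid ring (suture points, no
    separation) and register the sub-valvular element contact surface.

    The returned geometry has a frozen annulus diameter
    ``undersize_factor * annulus_diameter``; with the sub-valvular element
    disabled only the ring constraint remains.
    """
    if device.undersize_factor == 1.0 and not device.enabled_subvalvular:
        return replace(geom, device=device)
    return replace(geom, device=device)


# ---------------------------------------------------------------------------
# strip mechanics
# ---------------------------------------------------------------------------

def _nominal_cable(geom: ValveGeometry, cable: str, diameter: float) -> np.ndarray:
    """Nominal closed-configuration polyline for one cable (used for chordae
    rest lengths and as the solver's cold-start guess)."""
    cx, cy = geom.coapt_point
    half_t = 0.5 * geom.thickness
    if cable == "anterior":
        n = geom.n_seg_anterior
        hinge = np.array([-0.5 * diameter, 0.0])
        length = geom.anterior_len
        x_tail = cx - half_t
    else:
        n = geom.n_seg_posterior
        hinge = np.array([0.5 * diameter, 0.0])
        length = geom.posterior_len
        x_tail = cx + half_t
    target = np.array([x_tail, cy])
    reach = float(np.linalg.norm(target - hinge))
    reach = min(reach, length - 1e-6)
    tail = length - reach
    # sample n+1 nodes along hinge->target then vertical tail downward
    pts = []
    for k in range(n + 1):
        s = length * k / n
        if s <= reach:
            pts.append(hinge + (target - hinge) * (s / reach))
        else:
            pts.append(target + np.array([0.0, s - reach]))
    return np.array(pts)


@dataclass
class _StripProblem:
    """Assembled per-strip mechanical problem (internal)."""

    geom: ValveGeometry
    diameter: float
    width: float
    dP: float
    pap: np.ndarray
    element: tuple[float, float, float] | None  # (cx, cy, r) or None
    contact: ContactParams
    k_bend: float = 2.0  # kPa mm^2, numerical regularization
    k_comp: float = 5.0  # kPa, compressive regularization of leaflet cables

    def __post_init__(self) -> None:
        g = self.geom
        self.n_a = g.n_seg_anterior
        self.n_p = g.n_seg_posterior
        self.l0_a = g.anterior_len / self.n_a
        self.l0_p = g.posterior_len / self.n_p
        self.area_leaflet = self.width * g.thickness
        self.hinge_a = np.array([-0.5 * self.diameter, 0.0])
        self.hinge_p = np.array([0.5 * self.diameter, 0.0])
        # chordae insertion node indices
        self.chordae = []
        for ch in g.chordae:
            n = self.n_a if ch.cable == "anterior" else self.n_p
            idx = max(1, min(n, int(round(ch.insertion_frac * n))))
            self.chordae.append((ch, idx))
        self.f_scale = max(1.0, abs(self.dP) * self.width * (g.anterior_len + g.posterior_len))

    # -- vector layout: q = [a_1..a_na, p_1..p_np] flattened (x, y) --------
    def split(self, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        na, npp = self.n_a, self.n_p
        a = np.vstack([self.hinge_a, q[: 2 * na].reshape(na, 2)])
        p = np.vstack([self.hinge_p, q[2 * na :].reshape(npp, 2)])
        return a, p

    def initial_guess(self) -> np.ndarray:
        # nominal closed configuration, slightly stretched from the hinges
        # and with the tails nudged apart: keeps the start off the exact
        # rest-length / contact-clearance kinks where finite-difference
        # Jacobians are ill-defined
        a = _nominal_cable(self.geom, "anterior", self.diameter)
        p = _nominal_cable(self.geom, "posterior", self.diameter)
        a = a[0] + 1.005 * (a - a[0]) + np.array([-0.15, 0.0])
        p = p[0] + 1.005 * (p - p[0]) + np.array([0.15, 0.0])
        a[0] = self.hinge_a
        p[0] = self.hinge_p
        if self.element is not None:
            # start the posterior cable clear of the sub-valvular element
            cx, cy, r = self.element
            C = np.array([cx, cy])
            clearance = r + 0.6 * self.geom.thickness
            for j in range(1, p.shape[0]):
                d = p[j] - C
                dist = float(np.hypot(d[0], d[1]))
                if dist < clearance:
                    p[j] = C + d / max(dist, 1e-6) * clearance
        return np.concatenate([a[1:].ravel(), p[1:].ravel()])

    # -- energy and analytic gradient --------------------------------------
    def energy_grad(self, q: np.ndarray, want_grad: bool = True):
        a, p = self.split(q)
        E = 0.0
        ga = np.zeros_like(a)
        gp = np.zeros_like(p)
        law = self.geom.leaflet_law
        for X, g_out, l0, side in ((a, ga, self.l0_a, 1.0), (p, gp, self.l0_p, -1.0)):
            E += self._cable_elastic(X, g_out, l0, law)
            E += self._bending(X, g_out)
            E += self._pressure(X, g_out, side)
        E += self._chordae(a, p, ga, gp)
        E += self._coaptation_contact(a, p, ga, gp)
        if self.element is not None:
            E += self._element_contact(p, gp)
        if not want_grad:
            return E, None
        grad = np.concatenate([ga[1:].ravel(), gp[1:].ravel()])
        return E, grad

    def _cable_elastic(self, X, g_out, l0, law: ExpLaw1D) -> float:
        area = self.area_leaflet
        d = X[1:] - X[:-1]
        ln = np.sqrt(np.einsum("ij,ij->i", d, d))
        eps = np.log(ln / l0)
        tens = eps > 0.0
        be = np.minimum(law.B * eps, 500.0)
        b1e = np.minimum((law.B + 1.0) * eps, 500.0)
        E_t = area * l0 * law.A * ((np.exp(b1e) - 1.0) / (law.B + 1.0) - np.expm1(eps))
        T_t = area * law.A * np.expm1(be)
        E_c = 0.5 * area * l0 * self.k_comp * eps * eps
        T_c = area * self.k_comp * eps * l0 / ln
        E = float(np.sum(np.where(tens, E_t, E_c)))
        T = np.where(tens, T_t, T_c)
        f = (T / ln)[:, None] * d
        g_out[:-1] -= f
        g_out[1:] += f
        return E

    def _bending(self, X, g_out) -> float:
        kb = self.k_bend
        v = X[:-2] - 2.0 * X[1:-1] + X[2:]
        g_out[:-2] += kb * v
        g_out[1:-1] -= 2.0 * kb * v
        g_out[2:] += kb * v
        return 0.5 * kb * float(np.sum(v * v))

    def _pressure(self, X, g_out, side: float) -> float:
        # consistent nodal loads: each segment carries dP * w * length normal
        # to itself, split between its end nodes (free-edge consistent, no
        # phantom closing edge); the returned shoelace value is the work-like
        # potential of the interior load, used for diagnostics only
        c = -side * self.dP * self.width
        d = X[1:] - X[:-1]
        half = (c * 0.5) * np.column_stack([d[:, 1], -d[:, 0]])
        g_out[:-1] += half
        g_out[1:] += half
        A = 0.5 * float(np.sum(X[:-1, 0] * X[1:, 1] - X[1:, 0] * X[:-1, 1]))
        return c * A

    def _chorda_path(self, ins: np.ndarray) -> tuple[float, np.ndarray]:
        """Path length pap->insertion and the unit pull direction at the
        insertion (taut-string wrap around the sub-valvular element)."""
        pap = self.pap
        if self.element is None:
            d = ins - pap
            ln = float(np.hypot(d[0], d[1]))
            return ln, d / ln
        cx, cy, r = self.element
        C = np.array([cx, cy])
        return _wrap_length(pap, ins, C, r)

    def _chordae(self, a, p, ga, gp) -> float:
        E = 0.0
        for ch, idx in self.chordae:
            X, g_out = (a, ga) if ch.cable == "anterior" else (p, gp)
            wrap = ch.cable == "posterior" and self.element is not None
            if wrap:
                ln, pull = self._chorda_path(X[idx])
            else:
                d = X[idx] - self.pap
                ln = float(np.hypot(d[0], d[1]))
                pull = d / ln
            eps = math.log(ln / ch.rest_length)
            if eps <= 0.0:
                continue
            E += ch.area * ch.rest_length * _phi(ch.law, eps)
            T = ch.area * ch.law.A * math.expm1(min(ch.law.B * eps, 500.0))
            g_out[idx] += T * pull
        return E

    def _coaptation_contact(self, a, p, ga, gp) -> float:
        """Unsigned repulsive-shell contact between the posterior nodes and
        the anterior polyline: penalty once the surfaces come closer than the
        shared thickness."""
        kpen = self.contact.penalty_stiffness * self.width * self.l0_p
        delta = self.contact.gap_tol
        clearance = self.geom.thickness
        dist, iseg, s, cpt = _closest_matrix(p[1:], a)
        pen = clearance - dist
        active = np.nonzero((pen > -delta) & (dist > 1e-12))[0]
        E = 0.0
        for jj in active:
            j = jj + 1
            e, fmag = _smooth_penalty(kpen, pen[jj], delta)
            f = fmag * (p[j] - cpt[jj]) / dist[jj]
            E += e
            gp[j] -= f
            ga[iseg[jj]] += (1.0 - s[jj]) * f
            ga[iseg[jj] + 1] += s[jj] * f
        return E

    def _element_contact(self, p, gp) -> float:
        cx, cy, r = self.element
        C = np.array([cx, cy])
        clearance = r + 0.5 * self.geom.thickness
        kpen = self.contact.penalty_stiffness * self.width * self.l0_p
        delta = self.contact.gap_tol
        d = p[1:] - C
        dist = np.sqrt(np.einsum("ij,ij->i", d, d))
        pen = clearance - dist
        active = np.nonzero((pen > -delta) & (dist > 1e-12))[0]
        E = 0.0
        for jj in active:
            e, fmag = _smooth_penalty(kpen, pen[jj], delta)
            E += e
            gp[jj + 1] -= fmag * (d[jj] / dist[jj])
        return E

    # -- post-processing ----------------------------------------------------
    def metrics(self, q: np.ndarray) -> dict:
        a, p = self.split(q)
        clearance = self.geom.thickness
        tol = self.contact.gap_tol
        coapt = 0.0
        dmin_all = math.inf
        pen_max = 0.0
        for j in range(1, p.shape[0]):
            dmin, _, _, _ = _closest_on_polyline(p[j], a)
            dmin_all = min(dmin_all, dmin)
            if dmin <= clearance + tol:
                coapt += self.l0_p
            pen_max = max(pen_max, clearance - dmin)
        if self.element is not None:
            cx, cy, r = self.element
            C = np.array([cx, cy])
            for j in range(1, p.shape[0]):
                pen_max = max(pen_max, r + 0.5 * clearance - float(np.linalg.norm(p[j] - C)))
        gap = 0.0 if coapt > 0.0 else max(0.0, dmin_all - clearance)
        forces = {}
        contact_active = coapt > 0.0
        for ch, idx in self.chordae:
            X = a if ch.cable == "anterior" else p
            wrap = ch.cable == "posterior" and self.element is not None
            if wrap:
                ln, _ = self._chorda_path(X[idx])
            else:
                ln = float(np.linalg.norm(X[idx] - self.pap))
            eps = math.log(ln / ch.rest_length)
            T = ch.area * ch.law.A * math.expm1(ch.law.B * eps) if eps > 0 else 0.0
            forces[(ch.cable, ch.kind)] = T / 1000.0  # kPa mm^2 -> N
        return {
            "coaptation_len": coapt,
            "gap_width": gap,
            "forces_N": forces,
            "contact_active": contact_active,
            "penetration_max": max(0.0, pen_max),
        }


def _smooth_penalty(k: float, pen: float, delta: float) -> tuple[float, float]:
    """C1-smooth one-sided penalty: zero below -delta, quadratic force blend
    on [-delta, delta], linear force k*pen beyond. Returns (energy, force)."""
    if pen <= -delta:
        return 0.0, 0.0
    if pen < delta:
        z = pen + delta
        return k * z**3 / (12.0 * delta), k * z * z / (4.0 * delta)
    return 0.5 * k * pen * pen + k * delta * delta / 6.0, k * pen


def _phi(law: ExpLaw1D, eps: float) -> float:
    """Closed-form energy density integral of the exponential law such that
    d/d(length) of area*l0*phi(ln(l/l0)) equals area*sigma(eps)."""
    b1 = law.B + 1.0
    return law.A * ((math.exp(min(b1 * eps, 500.0)) - 1.0) / b1 - math.expm1(min(eps, 500.0)))


def _closest_matrix(pts: np.ndarray, X: np.ndarray):
    """Vectorized closest point on polyline X for each row of pts:
    (distances, segment indices, barycentric coords, closest points)."""
    a0 = X[:-1]
    d = X[1:] - X[:-1]
    dd = np.einsum("ij,ij->i", d, d)
    dd = np.where(dd == 0.0, 1.0, dd)
    # s[m, k] for point m, segment k
    s = np.clip(np.einsum("mkj,kj->mk", pts[:, None, :] - a0[None, :, :], d) / dd, 0.0, 1.0)
    c = a0[None, :, :] + s[:, :, None] * d[None, :, :]
    diff = pts[:, None, :] - c
    dist = np.sqrt(np.einsum("mkj,mkj->mk", diff, diff))
    kmin = np.argmin(dist, axis=1)
    m = np.arange(pts.shape[0])
    return dist[m, kmin], kmin, s[m, kmin], c[m, kmin]


def _closest_on_polyline(pt: np.ndarray, X: np.ndarray):
    """Closest point on polyline X to pt: (distance, segment index,
    barycentric coordinate, closest point)."""
    best = (math.inf, 0, 0.0, X[0])
    for i in range(X.shape[0] - 1):
        d = X[i + 1] - X[i]
        dd = float(d @ d)
        s = 0.0 if dd == 0.0 else float(np.clip((pt - X[i]) @ d / dd, 0.0, 1.0))
        c = X[i] + s * d
        dist = float(np.linalg.norm(pt - c))
        if dist < best[0]:
            best = (dist, i, s, c)
    return best


def _wrap_length(P1: np.ndarray, P2: np.ndarray, C: np.ndarray, r: float):
    """Taut-string length from P1 to P2 around circle (C, r) and the unit
    pull direction at P2 (pointing from P2 along the taut string)."""
    v1, v2 = P1 - C, P2 - C
    d1, d2 = float(np.linalg.norm(v1)), float(np.linalg.norm(v2))
    chord = P2 - P1
    ln_straight = float(np.linalg.norm(chord))
    if d1 <= r + 1e-9 or d2 <= r + 1e-9:
        # endpoint at/inside the cylinder: fall back to the straight chord
        return ln_straight, chord / ln_straight
    alpha = math.acos(float(np.clip(v1 @ v2 / (d1 * d2), -1.0, 1.0)))
    b1 = math.acos(min(1.0, r / d1))
    b2 = math.acos(min(1.0, r / d2))
    theta = alpha - b1 - b2
    if theta <= 0.0:
        return ln_straight, chord / ln_straight
    # wrap side: the string bends around the side of the circle away from
    # the chord; rotate the tangent point accordingly
    s = 1.0 if (v2[0] * v1[1] - v2[1] * v1[0]) > 0 else -1.0
    length = math.sqrt(d1 * d1 - r * r) + math.sqrt(d2 * d2 - r * r) + r * theta
    # tangent point seen from P2: rotate v2/d2 by +s*b2 (toward P1 side)
    ca, sa = math.cos(s * b2), math.sin(s * b2)
    u2 = v2 / d2
    t2 = C + r * np.array([ca * u2[0] - sa * u2[1], sa * u2[0] + ca * u2[1]])
    pull = P2 - t2
    pull_n = float(np.linalg.norm(pull))
    if pull_n <= 1e-12:
        return length, chord / ln_straight
    return length, pull / pull_n


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

def _relax(prob: _StripProblem, q: np.ndarray, target: float, max_iter: int = 30000) -> np.ndarray:
    """Dynamic relaxation (adaptive explicit pseudo-time stepping on the
    force residual): robust far-from-equilibrium transport of floppy cable
    systems into the Newton basin."""
    _, g = prob.energy_grad(q)
    r = float(np.max(np.abs(g)))
    tau = 1e-4
    for _ in range(max_iter):
        if r <= target:
            break
        q_new = q - tau * g
        _, g_new = prob.energy_grad(q_new)
        r_new = float(np.max(np.abs(g_new)))
        if r_new < r * 1.02:  # accept mild increases to traverse kinks
            q, g, r = q_new, g_new, r_new
            tau = min(tau * 1.2, 2e-3)
        else:
            tau = max(tau * 0.4, 1e-7)
    return q


def _newton_solve(prob: _StripProblem, q0: np.ndarray) -> tuple[np.ndarray, float]:
    """Damped Newton on the nodal force residual with backtracking on the
    residual norm (the pressure load on the open free edge is follower-like,
    so the residual is not an exact energy gradient)."""
    q = q0.copy()
    tol = max(prob.contact.residual_tol * prob.f_scale, prob.contact.residual_abs)
    _, g = prob.energy_grad(q)
    n = q.size
    for _ in range(prob.contact.max_newton_iters):
        res = float(np.max(np.abs(g)))
        if res <= tol:
            return q, res
        # FD Jacobian of the residual
        J = np.empty((n, n))
        h = 1e-6 * max(1.0, float(np.max(np.abs(q))))
        for k in range(n):
            qk = q.copy()
            qk[k] += h
            _, gk = prob.energy_grad(qk)
            J[:, k] = (gk - g) / h
        try:
            delta = np.linalg.solve(J + 1e-10 * prob.f_scale * np.eye(n), -g)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(J, -g, rcond=None)[0]
        # cap the per-node step
        step_max = float(np.max(np.abs(delta)))
        if step_max > 5.0:
            delta *= 5.0 / step_max
        norm0 = float(np.linalg.norm(g))
        alpha = 1.0
        accepted = False
        for _ls in range(40):
            _, g_new = prob.energy_grad(q + alpha * delta)
            if float(np.linalg.norm(g_new)) < (1.0 - 1e-4 * alpha) * norm0:
                q = q + alpha * delta
                g = g_new
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
    res = float(np.max(np.abs(g)))
    if res > tol:
        raise ValveConvergenceError(
            f"strip equilibrium did not converge: residual {res:.3e} > tol {tol:.3e}", res
        )
    return q, res


@dataclass(frozen=True)
class StripSolution:
    """Equilibrium of one strip at one instant."""

    q: np.ndarray
    coaptation_len: float
    gap_width: float
    forces_N: dict
    contact_active: bool
    penetration_max: float
    residual: float


def solve_strip(
    geom: ValveGeometry,
    dP: float,
    pap_tip: np.ndarray,
    diameter: float | None = None,
    device_element: tuple[float, float, float] | None = None,
    contact: ContactParams | None = None,
    q0: np.ndarray | None = None,
) -> StripSolution:
    """Solve the static equilibrium of one strip under transvalvular
    pressure ``dP`` (kPa) with papillary tip at ``pap_tip``.

    Cold starts are continued from the nominal configuration by ramping the
    pressure; a warm start ``q0`` (typically the previous time sample) is
    used directly.  Raises :class:`ValveConvergenceError` on Newton failure
    and ``RuntimeError`` if converged penetration exceeds 10x the contact
    ``gap_tol`` (penalty too soft).
    """
    if dP < 0:
        raise ValueError("transvalvular pressure must be >= 0")
    contact = contact or ContactParams()
    diameter = geom.annulus_diameter if diameter is None else diameter

    def make(dp: float) -> _StripProblem:
        return _StripProblem(
            geom=geom,
            diameter=diameter,
            width=geom.strip_width(diameter),
            dP=dp,
            pap=np.asarray(pap_tip, dtype=float),
            element=device_element,
            contact=contact,
        )

    def robust(p: _StripProblem, q: np.ndarray, cold: bool) -> tuple[np.ndarray, float]:
        if cold:
            q = _relax(p, q, 0.3)
        last: ValveConvergenceError | None = None
        target = 0.1
        for _ in range(4):
            try:
                return _newton_solve(p, q)
            except ValveConvergenceError as err:
                last = err
                q = _relax(p, q, target)
                target *= 0.2
        raise last

    def cold_path() -> tuple[np.ndarray, float]:
        q = prob.initial_guess()
        res = math.inf
        for frac in (0.25, 0.5, 0.75, 1.0):
            q, res = robust(make(frac * dP), q, cold=True)
        return q, res

    prob = make(dP)
    if q0 is not None:
        try:
            q, res = robust(prob, q0, cold=False)
        except ValveConvergenceError:
            q, res = cold_path()
    else:
        q, res = cold_path()
    m = prob.metrics(q)
    if m["penetration_max"] > 10.0 * contact.gap_tol:
        raise RuntimeError(
            f"contact penetration {m['penetration_max']:.3f} mm exceeds "
            f"10x gap_tol; penalty stiffness too soft"
        )
    return StripSolution(
        q=q,
        coaptation_len=m["coaptation_len"],
        gap_width=m["gap_width"],
        forces_N=m["forces_N"],
        contact_active=m["contact_active"],
        penetration_max=m["penetration_max"],
        residual=res,
    )


@dataclass(frozen=True)
class ValveSolution:
    """All strips at one sampled instant."""

    t: float
    dP: float
    diameter: float
    strips: tuple[StripSolution, ...]
    A_gap: float
    avg_posterior_chordae_force: float


@dataclass(frozen=True)
class ValveTrace:
    """Valve solutions over the sampled systolic window."""

    times: np.ndarray
    solutions: tuple[ValveSolution, ...]

    @property
    def A_gap(self) -> np.ndarray:
        return np.array([s.A_gap for s in self.solutions])

    @property
    def posterior_force(self) -> np.ndarray:
        return np.array([s.avg_posterior_chordae_force for s in self.solutions])

    def a_gap_callable(self):
        """Piecewise-linear A_gap(t) in mm^2, zero outside the window."""
        t, a = self.times, self.A_gap
        return lambda tt: float(np.interp(tt, t, a, left=0.0, right=0.0))


def _systolic_times(cycle: CycleResult, p_ven: float, n_times: int) -> np.ndarray:
    """Sampled instants uniformly over the loaded systolic window: where the
    transvalvular pressure exceeds 10% of its peak (covers isovolumic
    contraction, ejection and early relaxation — the phases in which the
    closed mitral valve carries load)."""
    dp = cycle.P_lv - p_ven
    peak = float(np.max(dp))
    if peak <= 0:
        raise ValueError("cycle has no positive transvalvular pressure")
    mask = dp > 0.1 * peak
    t_lo, t_hi = float(cycle.t[mask][0]), float(cycle.t[mask][-1])
    return np.linspace(t_lo, t_hi, n_times)


def solve_valve(
    geom: ValveGeometry,
    cycle: CycleResult,
    infarct: InfarctRegion,
    device: DeviceGeometry | None = None,
    contact: ContactParams | None = None,
    n_times: int = 20,
    p_ven: float = 0.55,
) -> ValveTrace:
    """Quasi-statically solve the apparatus at sampled systolic instants.

    Annulus diameter follows D ∝ V_cav^(1/3) relative to the geometry's
    reference volume (overridden, time-invariant, by the rigid ring);
    papillary tips of the infarct-sector strips displace apically and
    laterally (2:1) by ``phi * pap_disp_scale``.  Identical strips are
    solved once and shared; solutions are warm-started across time samples.
    """
    if device is not None:
        geom = attach_device(geom, device)
    device = geom.device
    contact = contact or ContactParams()
    times = _systolic_times(cycle, p_ven, n_times)
    disp = np.zeros(2)
    if infarct.phi > 0:
        mag = infarct.phi * infarct.pap_disp_scale
        disp = mag * np.array([1.0, 2.0]) / math.sqrt(5.0)

    # group strips with identical configuration (pap tip, element, dilation)
    groups: dict[tuple, list[int]] = {}
    for s in range(geom.n_strips):
        in_sector = s in geom.infarct_strips
        pap = geom.pap_tips[s] + (disp if in_sector else 0.0)
        # a healthy papillary muscle contracts with the ventricle; the
        # infarcted posterior papillary muscle (in-sector, phi > 0) does not
        contracting = not (in_sector and infarct.phi > 0)
        has_elem = (
            device is not None
            and device.enabled_subvalvular
            and s in device.covered_strips
        )
        dil = 1.0
        if in_sector and device is None:
            dil = 1.0 + geom.annular_dilation_coeff * infarct.phi
        key = (round(pap[0], 9), round(pap[1], 9), has_elem, dil, contracting)
        groups.setdefault(key, []).append(s)

    dps = np.array(
        [max(0.0, float(np.interp(t, cycle.t, cycle.P_lv)) - p_ven) for t in times]
    )
    # march from the best-conditioned (peak-pressure) instant outward,
    # warm-starting each solve from the nearest already-solved time
    order = [int(np.argmax(dps))]
    lo = hi = order[0]
    while lo > 0 or hi < len(times) - 1:
        if hi < len(times) - 1:
            hi += 1
            order.append(hi)
        if lo > 0:
            lo -= 1
            order.append(lo)

    solutions: list[ValveSolution | None] = [None] * len(times)
    warm: dict[tuple, dict[int, np.ndarray]] = {k: {} for k in groups}
    for it in order:
        t = times[it]
        V = float(np.interp(t, cycle.t, cycle.V_lv))
        if device is not None:
            D = device.undersize_factor * geom.annulus_diameter
        else:
            # volume-driven annular kinematics; the fibrous annulus has a
            # limited excursion, so the factor is clamped to +-15/25%
            factor = min(1.15, max(0.75, (V / geom.annulus_ref_volume) ** (1.0 / 3.0)))
            D = geom.annulus_diameter * factor
        dP = dps[it]
        dp_peak = float(np.max(dps))
        strip_solutions: list[StripSolution | None] = [None] * geom.n_strips
        strip_D: list[float] = [D] * geom.n_strips
        for key, members in groups.items():
            pap = np.array([key[0], key[1]])
            if key[4] and dp_peak > 0:
                # active papillary shortening tracks the load waveform
                pap = pap + np.array(
                    [0.0, geom.pap_systolic_shortening * dP / dp_peak]
                )
            D_s = D * key[3]
            if key[2]:
                elem_geom = (
                    0.5 * D_s - device.subvalvular_reach,
                    device.subvalvular_depth + device.ring_plane_offset,
                    device.subvalvular_radius,
                )
            else:
                elem_geom = None
            q0 = None
            if warm[key]:
                nearest = min(warm[key], key=lambda j: abs(j - it))
                q0 = warm[key][nearest]
            sol = solve_strip(
                geom,
                dP,
                pap,
                diameter=D_s,
                device_element=elem_geom,
                contact=contact,
                q0=q0,
            )
            warm[key][it] = sol.q
            for s in members:
                strip_solutions[s] = sol
                strip_D[s] = D_s
        a_gap = sum(
            sol.gap_width * geom.strip_width(d)
            for sol, d in zip(strip_solutions, strip_D)
        )
        post_forces = [
            f
            for s in geom.infarct_strips
            for (cable, kind), f in strip_solutions[s].forces_N.items()
            if cable == "posterior"
        ]
        avg_f = float(np.mean(post_forces)) if post_forces else 0.0
        solutions[it] = ValveSolution(
            t=float(t),
            dP=dP,
            diameter=D,
            strips=tuple(strip_solutions),
            A_gap=float(a_gap),
            avg_posterior_chordae_force=avg_f,
        )
    return ValveTrace(times=times, solutions=tuple(solutions))


def chordae_force_trace(trace: ValveTrace, normalize_by: float | None = None) -> np.ndarray:
    """Average posterior-papillary chordae force per sampled time, divided
    by ``normalize_by`` (the healthy peak); the healthy trace normalized by
    its own peak has maximum exactly 1.0."""
    f = trace.posterior_force
    if f.size == 0:
        raise ValueError("empty chordae force trace")
    if normalize_by is None:
        normalize_by = float(np.max(f))
    if normalize_by <= 0:
        raise ValueError("normalization peak must be > 0")
    return f / normalize_by


# the papillary-displacement calibration runs on the leak-coupled system and
# therefore lives in cardiosim.study (calibrate_pap_disp_scale)
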