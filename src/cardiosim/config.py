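"""Study configuration: YAML schema, validation and model factories.

All physical quantities use the package-wide unit convention (kPa, mL, mm,
s).  Unknown keys are rejected; validation reports the complete list of
violations, not just the first.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .circulation import CirculationParams, HeartModel
from .materials import ActiveLaw, ExpLaw1D, MaterialParamsHO
from .valve import ContactParams, DeviceGeometry, ValveGeometry, default_valve_geometry
from .ventricle import VentricleGeometry

__all__ = ["StudyConfig", "ConfigError", "validate_config"]


class ConfigError(ValueError):
    """Raised with the full list of schema violations."""

    def __init__(self, errors: list[str]):
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))
        self.errors = errors


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class MaterialsSection(_Section):
    k: float = Field(1000.0, ge=0)
    a: float = Field(0.33, ge=0)
    b: float = Field(7.08, ge=0)
    a_ff: float = Field(0.25, ge=0)
    b_ff: float = Field(5.34, ge=0)
    a_ss: float = Field(0.0, ge=0)
    b_ss: float = Field(0.0, ge=0)
    a_fs: float = Field(0.0, ge=0)
    b_fs: float = Field(0.0, ge=0)


class VentricleSection(_Section):
    v_wall_ml: float = Field(150.0, gt=0)
    v_cav_ref_ml: float = Field(20.0, gt=0)
    aspect: float = Field(1.0, ge=1.0)


class ActivationSection(_Section):
    T_max_kPa: float = Field(120.0, ge=0)
    t_act_s: float = Field(0.0, ge=0)
    t_dur_s: float = Field(0.55, gt=0)
    length_dep: float = Field(4.0, ge=0)


class CirculationSection(_Section):
    p_ven_kPa: float = Field(0.55, gt=0)
    r_mv: float = Field(0.003, gt=0)
    r_av: float = Field(0.005, gt=0)
    c_art: float = Field(8.0, gt=0)
    r_per: float = Field(0.32, gt=0)
    p_art_init_kPa: float = Field(11.0, gt=0)
    k_orifice: float = Field(0.85, ge=0)
    period_s: float = Field(1.0, gt=0)
    dt_s: float = Field(0.001, gt=0)


class InfarctSection(_Section):
    phi: float | None = Field(None, ge=0.0, le=1.0)
    pap_disp_scale: float | None = Field(None, ge=0.0)


class Law1DSection(_Section):
    A_kPa: float = Field(..., ge=0)
    B: float = Field(..., gt=0)


class ValveSection(_Section):
    n_strips: int = Field(12, ge=6)
    annulus_diameter_mm: float = Field(30.0, gt=0)
    anterior_len_mm: float = Field(24.0, gt=0)
    posterior_len_mm: float = Field(16.0, gt=0)
    thickness_mm: float = Field(1.0, gt=0)
    n_seg_anterior: int = Field(8, ge=3)
    n_seg_posterior: int = Field(6, ge=3)
    pap_tip_mm: tuple[float, float] = (4.0, 22.0)
    coapt_point_mm: tuple[float, float] = (5.0, 7.0)
    slack: float = Field(1.0, gt=0)
    slack_anterior: float = Field(1.08, gt=0)
    annular_dilation_coeff: float = Field(0.5, ge=0)
    pap_systolic_shortening_mm: float = Field(3.5, ge=0)
    n_times: int = Field(20, ge=3)
    leaflet_radial: Law1DSection = Law1DSection(A_kPa=15.0, B=15.0)
    leaflet_circumferential: Law1DSection = Law1DSection(A_kPa=20.0, B=25.0)
    chordae_basal: Law1DSection = Law1DSection(A_kPa=40.0, B=45.0)
    chordae_marginal: Law1DSection = Law1DSection(A_kPa=25.0, B=60.0)


class DeviceSection(_Section):
    undersize_factor: float = Field(0.92, ge=0.5, le=1.0)
    ring_plane_offset_mm: float = 0.0
    subvalvular_depth_mm: float = Field(11.0, gt=0)
    subvalvular_reach_mm: float = 6.0
    subvalvular_radius_mm: float = Field(4.0, gt=0)
    enabled_subvalvular: bool = True


class ContactSection(_Section):
    penalty_stiffness: float = Field(1000.0, gt=0)
    gap_tol_mm: float = Field(0.05, gt=0)
    max_newton_iters: int = Field(80, ge=1)
    residual_tol: float = Field(1e-8, gt=0)


class CalibrationSection(_Section):
    ef_healthy: float = Field(0.55, gt=0, lt=1)
    shortening_mm: float = Field(12.1, gt=0)
    ef_infarcted: float = Field(0.45, gt=0, lt=1)
    chordae_force_infarcted: float = Field(0.78, gt=0)
    tol_ef: float = Field(0.005, gt=0)
    tol_shortening_mm: float = Field(0.2, gt=0)
    tol_ef_sizing: float = Field(0.0025, gt=0)
    tol_chordae_force: float = Field(0.005, gt=0)


class StudyConfig(_Section):
    """Complete, schema-validated study configuration."""

    materials: MaterialsSection = MaterialsSection()
    ventricle: VentricleSection = VentricleSection()
    activation: ActivationSection = ActivationSection()
    circulation: CirculationSection = CirculationSection()
    infarct: InfarctSection = InfarctSection()
    valve: ValveSection = ValveSection()
    device: DeviceSection = DeviceSection()
    contact: ContactSection = ContactSection()
    calibration: CalibrationSection = CalibrationSection()
    seed: int = 0
    out_dir: str | None = None

    # -- factories ----------------------------------------------------------
    def heart_model(self) -> HeartModel:
        from .ventricle import InfarctRegion

        return HeartModel(
            geom=VentricleGeometry(
                V_wall=self.ventricle.v_wall_ml,
                V_cav_ref=self.ventricle.v_cav_ref_ml,
                aspect=self.ventricle.aspect,
            ),
            materials=MaterialParamsHO(**self.materials.model_dump()),
            active=ActiveLaw(
                T_max=self.activation.T_max_kPa,
                t_act=self.activation.t_act_s,
                t_dur=self.activation.t_dur_s,
                length_dep=self.activation.length_dep,
            ),
            infarct=InfarctRegion(),
            circ=CirculationParams(
                P_ven=self.circulation.p_ven_kPa,
                R_mv=self.circulation.r_mv,
                R_av=self.circulation.r_av,
                C_art=self.circulation.c_art,
                R_per=self.circulation.r_per,
                P_art_init=self.circulation.p_art_init_kPa,
                k_orifice=self.circulation.k_orifice,
            ),
            period=self.circulation.period_s,
            dt=self.circulation.dt_s,
        )

    def valve_geometry(self, annulus_ref_volume: float) -> ValveGeometry:
        import numpy as np

        v = self.valve
        return default_valve_geometry(
            leaflet_laws={
                "radial": ExpLaw1D(v.leaflet_radial.A_kPa, v.leaflet_radial.B),
                "circumferential": ExpLaw1D(
                    v.leaflet_circumferential.A_kPa, v.leaflet_circumferential.B
                ),
            },
            chordae_laws={
                "basal": ExpLaw1D(v.chordae_basal.A_kPa, v.chordae_basal.B, tension_only=True),
                "marginal": ExpLaw1D(
                    v.chordae_marginal.A_kPa, v.chordae_marginal.B, tension_only=True
                ),
            },
            slack=v.slack,
            slack_anterior=v.slack_anterior,
            n_strips=v.n_strips,
            annulus_diameter=v.annulus_diameter_mm,
            anterior_len=v.anterior_len_mm,
            posterior_len=v.posterior_len_mm,
            thickness=v.thickness_mm,
            n_seg_anterior=v.n_seg_anterior,
            n_seg_posterior=v.n_seg_posterior,
            pap_tips=np.tile(list(v.pap_tip_mm), (v.n_strips, 1)),
            coapt_point=tuple(v.coapt_point_mm),
            annular_dilation_coeff=v.annular_dilation_coeff,
            pap_systolic_shortening=v.pap_systolic_shortening_mm,
            annulus_ref_volume=annulus_ref_volume,
        )

    def device_geometry(self) -> DeviceGeometry:
        d = self.device
        return DeviceGeometry(
            undersize_factor=d.undersize_factor,
            ring_plane_offset=d.ring_plane_offset_mm,
            subvalvular_depth=d.subvalvular_depth_mm,
            subvalvular_reach=d.subvalvular_reach_mm,
            subvalvular_radius=d.subvalvular_radius_mm,
            enabled_subvalvular=d.enabled_subvalvular,
        )

    def contact_params(self) -> ContactParams:
        c = self.contact
        return ContactParams(
            penalty_stiffness=c.penalty_stiffness,
            gap_tol=c.gap_tol_mm,
            max_newton_iters=c.max_newton_iters,
            residual_tol=c.residual_tol,
        )


def validate_config(path: str | Path) -> StudyConfig:
    """Parse and validate a YAML study configuration.

    Raises :class:`ConfigError` carrying every schema violation, or
    ``OSError`` if the file cannot be read.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(["top level of the configuration must be a mapping"])
    try:
        return StudyConfig(**data)
    except ValidationError as err:
        msgs = [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        ]
        raise ConfigError(msgs) from err
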