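# Example study configuration. Every key is optional; an empty file runs
# the default three-arm study. Units: kPa, mL, mm, s.

materials:
  k: 1000.0      # bulk penalty (kPa)
  a: 0.33        # isotropic scale (kPa)
  b: 7.08
  a_ff: 0.25     # fiber scale (kPa)
  b_ff: 5.34
  a_ss: 0.0
  b_ss: 0.0
  a_fs: 0.0
  b_fs: 0.0

ventricle:
  v_wall_ml: 150.0
  v_cav_ref_ml: 20.0
  aspect: 1.0          # overwritten by the healthy-baseline calibration

circulation:
  p_ven_kPa: 0.55
  r_per: 0.32
  c_art: 8.0
  period_s: 1.0
  dt_s: 0.001

calibration:
  ef_healthy: 0.55
  shortening_mm: 12.1
  ef_infarcted: 0.45
  chordae_force_infarcted: 0.78

device:
  undersize_factor: 0.92
  subvalvular_depth_mm: 11.0
  subvalvular_reach_mm: 6.0
  subvalvular_radius_mm: 4.0
  enabled_subvalvular: true

# infarct:
#   phi: 0.18            # set to bypass the automatic sizing
#   pap_disp_scale: 12.0 # set to bypass the chordae-force calibration
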