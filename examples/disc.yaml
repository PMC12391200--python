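# Idealized three-region cervical disc, biphasic-swelling model.
geometry:
  ap_depth: 15.0        # anterior-posterior depth, mm
  lat_width: 20.0       # lateral width, mm
  disc_height: 6.0      # mm
  cep_thickness: 0.9    # endplate layer thickness, mm
  np_area_fraction: 0.4
  bean_concavity: 0.3
materials:
  NP:  {HA_MPa: 0.44, nu: 0.2, k0_e-4mm4Ns: 2.96, phi_s0: 0.127, fcd_mM: 182.2}
  AF:  {HA_MPa: 0.57, nu: 0.2, k0_e-4mm4Ns: 2.75, phi_s0: 0.183, fcd_mM: 135.5}
  CEP: {HA_MPa: 1.19, nu: 0.2, k0_e-4mm4Ns: 1.93, phi_s0: 0.307, fcd_mM: 286.7}
protocol:
  axial_strain: 0.10
  ramp_duration: 10000.0   # s
  hold_until: 400000.0     # s
swelling: true
c_star_mM: 150.0
temperature_K: 298.0
resolution: 8
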