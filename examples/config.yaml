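# Default run configuration: 0.14 ml saliva film on a lower central
# incisor with a 2.4 mm bracket, 0.25 s swallow peaking at 0.172 m/s.
domain:
  length_md: 10.0      # mesio-distal extent, mm
  length_og: 10.0      # occluso-gingival extent, mm
  depth: 1.4           # film thickness, mm (volume = 140 mm^3 = 0.14 ml)
  cell_size: 0.2       # mm
appliance:
  bracket_width: 2.4   # mm, mesio-distal
  bracket_height: 3.0  # mm, occluso-gingival
  bracket_thickness: 1.0  # mm, labial protrusion
  wire_diameter: 0.3556   # mm (0.014 inch)
  bracket_center: [5.0, 5.0]
  wire_height: 1.2     # mm above the tooth plane
fluid:
  density: 1000.0             # kg/m^3
  dynamic_viscosity: 1.0e-3   # Pa s
cycle:
  duration: 0.25       # s
  peak_speed: 0.172    # m/s
slip: free             # "frictionless" tooth/bracket; "no" for sensitivity
band_width: 2.0        # peri-bracket metric band, mm
n_outputs: 11          # field snapshots per swallow
cohort:
  n_patients: 27
  rho_w: 0.5           # within-patient correlation
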