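# 50 nm gold core with a 5 nm polystyrene coating, water/glass, TM -20 deg
modality: iscat
layers:
  - {material: water}
  - {material: glass}
illumination: {wavelength_nm: 520, theta_deg: -20, polarization: TM, direction: up}
optics: {NA: 1.3, n: 1.5, magnification: 133.33}
image: {fov_um: 3.0, pixels: 128}
scatterer:
  type: coated_sphere
  core_diameter_nm: 50
  coating_nm: 5
  material: polystyrene      # shell
  core_material: gold
  frequency: 4
  gap_nm: 5
focal_planes_um: [0.0]
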