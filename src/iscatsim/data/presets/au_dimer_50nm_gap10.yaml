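# coupled 50 nm gold spheres, 10 nm gap along x, 5 nm above glass in water
modality: iscat
layers:
  - {material: water}
  - {material: glass}
illumination: {wavelength_nm: 520, theta_deg: -20, polarization: TM, direction: up}
optics: {NA: 1.3, n: 1.5, magnification: 133.33}
image: {fov_um: 3.0, pixels: 128}
scatterer:
  type: dimer
  diameter_nm: 50
  gap_nm: 10
  material: gold
  frequency: 6
  surface_gap_nm: 5
focal_planes_um: [0.0]
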