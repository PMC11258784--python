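# 40 nm gold sphere at a glass-water interface; TM sweep around the
# Brewster angle (~41.6 deg) tunes the reference beam continuously
modality: iscat
layers:
  - {material: water}
  - {material: glass}
illumination: {wavelength_nm: 520, theta_deg: 40, polarization: TM, direction: up}
optics: {NA: 1.3, n: 1.5, magnification: 133.33}
image: {fov_um: 3.0, pixels: 96}
scatterer: {type: sphere, diameter_nm: 40, material: gold, position_nm: [0, 0, 25]}
focal_planes_um: [-0.5, 0.0, 0.5]
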