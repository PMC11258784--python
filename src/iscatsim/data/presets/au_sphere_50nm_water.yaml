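# 50 nm gold nanosphere in water, 5 nm above a glass substrate,
# TM plane wave at -20 deg, 520 nm (canonical single-particle scene)
modality: iscat
layers:
  - {material: water}
  - {material: glass}
illumination: {wavelength_nm: 520, theta_deg: -20, polarization: TM, direction: up}
optics: {NA: 1.3, n: 1.5, n_prime: 1.0, magnification: 133.33}
image: {fov_um: 3.0, pixels: 128}
scatterer: {type: sphere, diameter_nm: 50, material: gold, position_nm: [0, 0, 30]}
focal_planes_um: [0.0]
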