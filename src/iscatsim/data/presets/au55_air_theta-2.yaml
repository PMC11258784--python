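# as au55_air_theta14 but near-normal incidence (theta = -2 deg): the
# focus correlation map shows the characteristic two-ridge crossing
modality: iscat
layers:
  - {material: air}
  - {material: glass}
illumination: {wavelength_nm: 517, theta_deg: -2, polarization: [0.70710678, 0.70710678j], direction: up}
optics: {NA: 1.3, n: 1.5, magnification: 133.33}
image: {fov_um: 3.9, pixels: 128}
scatterer: {type: sphere, diameter_nm: 55, material: gold, position_nm: [0, 0, 32.5]}
focal_planes_um: [-1.0, -0.5, 0.0, 0.5, 1.0]
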