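# 100 nm silver nanocube on a glass-air interface; 450 nm, normal incidence,
# linear polarization (rotating the polarization rotates the image)
modality: iscat
layers:
  - {material: air}
  - {material: glass}
illumination: {wavelength_nm: 450, theta_deg: 0, polarization: TM, direction: up}
optics: {NA: 1.42, n: 1.5, magnification: 160}
image: {fov_um: 4.4, pixels: 128}
scatterer: {type: cube, edge_nm: 100, material: silver, n_per_edge: 5, gap_nm: 0.5}
focal_planes_um: [-0.4]
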