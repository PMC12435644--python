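# Staged pipeline config: local electrode pair around a dry craniotomy on a
# mouse-like layered-sphere phantom. Run with:
#   mousefield all --config examples/run_sphere.yaml --run runs/sphere
#   mousefield report --run runs/sphere
name: sphere-1x1
phantom:
  kind: layered_sphere
  subdiv: 3
  layers:
    - {name: gray_matter, sigma_S_per_m: 0.275, extent_mm: 4.0}
    - {name: csf, sigma_S_per_m: 1.654, extent_mm: 4.4}
    - {name: bone, sigma_S_per_m: 0.01, extent_mm: 4.8}
    - {name: soft_tissue, sigma_S_per_m: 0.465, extent_mm: 5.2}
montage:
  preset: 1x1_cran
  target_mm: [0.0, 0.0, 5.2]
  params:
    pair_offset_mm: 2.0
    fill_conductivity_S_per_m: 2.5e-14   # dry window; 1.654 for saline fill
solver:
  tol: 1.0e-10
  method: auto
  n_layers: 8
analysis:
  regions:
    - {name: brain, type: tissue, tissues: [gray_matter]}
    - {name: roi, type: box, center_mm: [0.0, 0.0, 3.5], size_mm: [2.0, 2.0, 1.0], tissues: [gray_matter]}
  focality: {P: 0.4, target: roi, reference: brain}
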