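# Coarse-step variant of example1.yaml: same biology and seeding, with
# the diffusion/mechanics clocks coarsened to 0.5 min (the implicit
# diffusion solver is unconditionally stable) so the 5-day run fits in a
# routine test session.
domain: {xmin: -1000.0, xmax: 1000.0, ymin: -1000.0, ymax: 1000.0, voxel_size: 20.0}
time:
  duration: 7200.0
  dt_diffusion: 0.5
  dt_mechanics: 0.5
  dt_phenotype: 6.0
  save_interval: 360.0
seed: 0
death:
  necrotic_persistence: 7200.0  # necrotic remnants persist through the run
substrates:
  oxygen:
    diffusion: 100000.0
    decay: 0.1
    initial: 38.0
    boundary: dirichlet
    boundary_value: 38.0
    dt: 0.05              # sub-step: cell uptake makes oxygen stiff
    secretion_saturation: 38.0
cell_types:
  tumor:
    volume: 2494.0
    behaviors:
      cycle entry: 1.7e-5
      apoptosis: 5.3e-5
      necrosis: 0.0028
      oxygen uptake: 10.0
  motile tumor:
    volume: 2494.0
    behaviors:
      cycle entry: 1.7e-5
      apoptosis: 5.3e-5
      necrosis: 0.0028
      oxygen uptake: 10.0
      migration speed: 1.0
      migration bias: 0.5
      migration persistence time: 5.0
      chemotactic response to oxygen: 1.0
rules: ../rules/example1.txt
placements:
  - {kind: disk, type: tumor, count: 2000, radius: 400.0, center: [0.0, 0.0]}
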