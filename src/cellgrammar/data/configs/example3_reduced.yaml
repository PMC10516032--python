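# Coarse-step variant of example3.yaml: identical biology and seeding
# with 0.5 min diffusion/mechanics clocks for routine test runs.
domain: {xmin: -1000.0, xmax: 1000.0, ymin: -1000.0, ymax: 1000.0, voxel_size: 20.0}
time:
  duration: 7200.0
  dt_diffusion: 0.5
  dt_mechanics: 0.5
  dt_phenotype: 6.0
  save_interval: 360.0
seed: 0
substrates:
  oxygen:
    diffusion: 100000.0   # um^2/min
    decay: 0.1            # 1/min background tissue consumption
    initial: 38.0
    boundary: dirichlet
    boundary_value: 38.0
    dt: 0.05              # sub-step: cell uptake makes oxygen stiff
    secretion_saturation: 38.0
  pro-inflammatory factor:
    diffusion: 1000.0     # assumed immuno-factor transport (see docs)
    decay: 0.01
    initial: 0.0
    boundary: no-flux
    secretion_saturation: 1.0
  anti-inflammatory factor:
    diffusion: 1000.0
    decay: 0.01
    initial: 0.0
    boundary: no-flux
    secretion_saturation: 1.0
  debris:
    diffusion: 100.0      # particulate cell remnants: slow transport
    decay: 0.01
    initial: 0.0
    boundary: no-flux
    secretion_saturation: 1.0
death:
  apoptotic_volume_halflife: 120.0  # corpses persist ~8.6 h, reference scale
cell_types:
  tumor:
    volume: 2494.0
    behaviors:
      cycle entry: 0.0          # rule base: growth only under oxygen
      apoptosis: 7.2e-5
      necrosis: 0.0028
      oxygen uptake: 10.0
  macrophage:
    volume: 2494.0
    behaviors:
      migration speed: 1.0
      migration bias: 0.5
      migration persistence time: 5.0
      chemotactic response to debris: 1.0
      oxygen uptake: 1.0
      phagocytose dead cell: 0.05
      pro-inflammatory factor secretion: 0.0   # rule base
      anti-inflammatory factor secretion: 10.0 # rule base
  CD8 T cell:
    volume: 2494.0
    behaviors:
      migration speed: 1.0
      migration bias: 0.5
      migration persistence time: 10.0
      chemotactic response to pro-inflammatory factor: 1.0
      oxygen uptake: 1.0
      attack tumor: 0.1         # rule base, 1/min
      damage rate: 1.8          # damage units/min while attacking
rules: ../rules/example3.txt
placements:
  - {kind: disk, type: tumor, count: 1000, radius: 280.0, center: [0.0, 0.0]}
  - {kind: ring, types: [CD8 T cell, macrophage], count_per_type: 50,
     inner_radius: 300.0, width: 40.0}
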