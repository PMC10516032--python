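# Hypoxia-driven 2-D tumor growth at physioxia (38 mmHg), full scale:
# 2000 viable cells seeded uniformly in a 400 um disk, 5 simulated days.
# Reference-framework clock hierarchy (diffusion 0.01 / mechanics 0.1 /
# phenotype 6 min). See example1_reduced.yaml for the coarse-step variant
# used in the test suite.
domain: {xmin: -1000.0, xmax: 1000.0, ymin: -1000.0, ymax: 1000.0, voxel_size: 20.0}
time:
  duration: 7200.0        # 5 days, minutes
  dt_diffusion: 0.01
  dt_mechanics: 0.1
  dt_phenotype: 6.0
  save_interval: 360.0
seed: 0
death:
  necrotic_persistence: 7200.0  # necrotic remnants persist through the run
substrates:
  oxygen:
    diffusion: 100000.0   # um^2/min
    decay: 0.1            # 1/min
    initial: 38.0         # mmHg, physioxic far field
    boundary: dirichlet
    boundary_value: 38.0
    secretion_saturation: 38.0
cell_types:
  tumor:
    volume: 2494.0
    behaviors:
      cycle entry: 1.7e-5       # 1/min, base division rate (rule base)
      apoptosis: 5.3e-5         # 1/min, background turnover
      necrosis: 0.0028          # 1/min, fully expressed only at anoxia
      oxygen uptake: 10.0       # 1/min
  motile tumor:
    volume: 2494.0
    behaviors:
      cycle entry: 1.7e-5
      apoptosis: 5.3e-5
      necrosis: 0.0028
      oxygen uptake: 10.0
      migration speed: 1.0      # um/min, post-hypoxic migratory phenotype
      migration bias: 0.5
      migration persistence time: 5.0
      chemotactic response to oxygen: 1.0
rules: ../rules/example1.txt
placements:
  - {kind: disk, type: tumor, count: 2000, radius: 400.0, center: [0.0, 0.0]}
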