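# cellgrammar

A hypothesis grammar for cell behavior — human-readable rule statements
mapped one-to-one onto Hill-response mathematics — together with a
desk-scale, lattice-free agent-based simulator that executes rule sets
against a diffusive microenvironment, and a coordinate transform for
initializing virtual tissues from annotated spatial-transcriptomics
spot tables.

It is written for systems biologists and modelers who want to state
cell-level hypotheses as plain sentences,

```
In tumor cells:
oxygen increases cycle entry from 1.7e-05 towards 0.0007 with a Hill
response, with half-max 21.5 and Hill power 4.
```

validate them against controlled vocabularies of signals and behaviors,
and run them as multicellular simulations without writing solver code.

## The model

Each rule modulates one behavioral parameter `b` (a division rate, a
migration speed, an attack rate, ...) as a function of one signal `s`
(a substrate concentration, mechanical pressure, contact counts,
accumulated damage, ...). A single rule is a Hill response

    b(s) = b0 + (bM − b0) · R(s),        R(s) = (s/s*)^p / (1 + (s/s*)^p)

with base value `b0`, saturation `bM`, half-max `s*` and Hill power `p`.
When several rules target the same behavior, the up-regulating signals
`u` and down-regulating signals `d` pool into multivariate Hill
responses

    U = Σ(u_i/u_i*)^p_i / (1 + Σ(u_i/u_i*)^p_i)     (D analogously)

and combine bilinearly,

    b(u, d) = (1 − D) · ((1 − U) · b0 + U · bM) + D · bm ,

so with no signal the behavior sits at `b0`, full up-regulation drives
it to `bM`, and full down-regulation overrides everything toward `bm`.
Adding or removing a rule never requires touching the others.

Rules execute on off-lattice 2-D cell agents with volume, live/dead
state, pairwise adhesion/repulsion mechanics, biased-random-walk
motility with chemotaxis, stochastic division/death/transformation
events (probability `1 − exp(−rate·dt)` per step), phagocytosis, and
effector attack with damage accumulation. Substrates diffuse and decay
on a voxel mesh with cell-coupled secretion and uptake (implicit
operator-split solver: unconditionally stable, mass-conserving,
non-negativity-preserving).

Spot tables with Visium geometry (triangular lattice, 71.000 µm pitch)
are mapped to cell-scale coordinates by recentering on a selected spot
subset and rescaling by `bias · cell_diameter / lattice_spacing` with
defaults `bias = 0.97` and `cell_diameter = 16.825 µm`.

## Worked example

Parse a bundled rule listing, aggregate the tumor "cycle entry" rules,
and evaluate the response at physioxic oxygen with no pressure:

```python
import cellgrammar as cg
from cellgrammar import grammar
from cellgrammar.response import SignalVector, evaluate_behavior

rules = grammar.parse_statements_text(open(cg.example_path("example1.txt")).read())
group = grammar.aggregate(rules, "tumor", "cycle entry", base_value=1.7e-5)
rv = evaluate_behavior(group, SignalVector({"oxygen": 21.5, "pressure": 0.0}))
print(rv)
```

prints

```
ResponseValue(U=0.5, D=0.0, b=0.0003585)
```

oxygen at its 21.5 mmHg half-max gives a half response (`U = 0.5`), no
pressure gives `D = 0`, and the cycle-entry rate lands midway between
its base 1.7e-05/min and its 7e-04/min maximum.

Run a bundled tissue simulation from the shell and watch the census:

```sh
cellgrammar simulate --config src/cellgrammar/data/configs/example3_reduced.yaml --seed 1
```

prints (5 simulated days, about two minutes of wall time)

```
t = 7200 min
  tumor (live): 452
  tumor (dead): 14
  macrophage (live): 50
  macrophage (dead): 0
  CD8 T cell (live): 50
  CD8 T cell (dead): 0
  births: 456
  removed: 133
  phagocytosed: 857
```

— the 1000-cell tumor declines under combined immune attack and
hypoxia, as in the corresponding figure experiment. Other subcommands:
`validate` (rules against a config's vocabularies), `annotate` (text or
HTML rule descriptions), `respond` (tabulate response curves),
`init-from-spots` and `make-fixture` (spatial initialization).

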