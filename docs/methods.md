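# Methods

## Rule grammar and response mathematics

A rule is one sentence tying a signal to a behavior of one cell type.
Two serialized dialects are accepted: the detailed statement form
(`In <type> cells:` block headers, one statement per line, scientific
notation exactly as printed) and an 8-column CSV dialect
(`cell_type, signal, direction, behavior, saturation, half_max,
hill_power, applies_to_dead`). The CSV dialect is this package's own
serialization, modeled on the detailed statements; the detailed form is
the interchange format. Terse statements without parameters
("S increases B.") are accepted only in validation mode — simulation
requires full parameters. The grammar deliberately has no negation
tokens ("low oxygen", "lack of X"): inhibitory hypotheses are stated as
`decreases` rules, and the parser rejects unparseable phrasings with
the offending line and token.

Rules for the same (cell type, behavior) pair aggregate into one group
holding `b0` (owned by the cell definition, not the rule file — a
`from X` clause that disagrees is a recorded warning and the definition
wins), `bM` (maximum over up-rule saturations; warning when they
differ), `bm` (minimum over down-rule saturations), and the pooled
signal terms. A base value outside `[bm, bM]` is an aggregation error,
not a silent clamp.

Responses: Hill terms `(s/s*)^p` are computed in log space once
`s/s* > 1`, and each term is capped at 1e15, so printed powers of 10
(and far beyond) cannot overflow; the pooled response is then exact to
double precision. The capped-linear shape is anchored so the response
is 0.5 at the half-max — `clamp(s/(2·s*), 0, 1)` — and contributes the
term `r/(1−r)` to the pooled sum so that a single linear rule
reproduces the capped-linear curve exactly. Mixed Hill/linear groups
are supported but all bundled examples are all-Hill.

## Signals and behaviors

The controlled vocabularies are parameterized by the simulation's
substrates and cell types, so `contact with fibroblast`,
`debris secretion`, `transform to motile tumor`, `attack tumor`
resolve by suffix. Units: minutes, microns, mmHg for oxygen, arbitrary
concentration units for immuno-factors; all rates per minute.

Mechanical pressure is the crowding scalar
`Σ (1 − d_ij/(R_i+R_j))² / 0.027288820670331` over overlapping
neighbors. The divisor is the reference framework's simple-pressure
scale: it makes confluent packing read as order-one pressure, which is
the scale the bundled rule half-maxes (0.25–1) are written against —
without it the raw sum plateaus near 0.01–0.06 in mechanically relaxed
tissue and pressure rules would never engage.

Basement-membrane contact is registered in the dictionary but raises
"unsupported in this build" when evaluated; accumulated attack time is
exposed as a monotone counter that is never reset. Multi-phase cycle
exits are registered but unused by every bundled example (the cycle
model is the single-rate "cycle entry → immediate division" reduction).

## Microenvironment

Substrates obey `∂ρ/∂t = D∇²ρ − λρ` plus cell-coupled sources/sinks on
a 2-D voxel mesh (20 µm default, z collapsed to one voxel). Transport
uses operator splitting: implicit backward-Euler tridiagonal solves
along each axis, then an exact decay factor `e^(−λ·dt)`. The scheme is
unconditionally stable, conserves mass exactly under no-flux boundaries
(verified to 1e-8 relative over 1000 steps), and preserves
non-negativity (M-matrix solves, positive decay). Secretion/uptake per
voxel is the pooled implicit update

    ρ ← (ρ + dt·f·Σ S_k ρ*_k) / (1 + dt·f·Σ (S_k + U_k)),   f = V_cell/V_voxel

which is monotone and can never produce negative concentrations, at any
step size.

Stiffness: oxygen uptake by packed tumor tissue gives an effective
reaction rate of several per minute; splitting that reaction against
near-instant diffusion (D = 1e5 µm²/min) at a coarse step badly
overestimates interior oxygen. Configs therefore may declare a
per-substrate sub-step (`dt:` under the substrate); the engine advances
that substrate in sub-iterations of the coarse diffusion step. The
bundled coarse-step configs sub-step oxygen at 0.05 min, which
reproduces the fine-step (0.01 min) interior oxygen to within ~25%
while keeping 5-day runs at desk scale; the full-scale configs use the
reference clock hierarchy (0.01/0.1/6 min) throughout.

Default oxygen parameters follow the reference convention: D = 1e5
µm²/min, background decay λ = 0.1/min, far-field Dirichlet value
38 mmHg (physioxia). The immuno-factors use the documented assumption
D = 1e3 µm²/min, λ = 0.01/min. Debris — particulate cell remnants
rather than a cytokine — is given D = 100 µm²/min so that corpse
fields produce a spatially informative cue for phagocyte homing.

## Agents

Cells are off-lattice 2-D agents with volume (radius `(3V/4π)^{1/3}`),
live/apoptotic/necrotic state, accumulated damage and attack time, and
a working phenotype that the rules overwrite every phenotype step.
Storage is struct-of-arrays with per-cell proxy objects, so mechanics
and rule evaluation vectorize over the population while the per-agent
API stays available; a dedicated test pins the vectorized engine path
to the per-agent reference path on a mixed live/dead fixture.

Mechanics: pairwise polynomial potentials — repulsion
`√(c_i c_j)(1 − d/s)²` inside membrane overlap (`s = R_i+R_j`),
adhesion `√(a_i a_j)·√(aff_ij)·(1 − d/r_A)²` inside
`r_A = 1.25·s` — integrated with overdamped Euler (drag 1). Forces are
equal and opposite by construction; neighbor search is an exact
KD-tree range query, so force sums are order-independent.

Motility: with probability `dt/τ` the direction re-draws as
`normalize(bias · chemo + (1 − bias) · random unit vector)` where
`chemo` is the normalized sensitivity-weighted gradient sum;
displacement is `speed · direction · dt`.

Stochastic events (division, apoptosis, necrosis, transformation,
phagocytosis, attack initiation) fire with probability
`1 − exp(−rate·dt)` per phenotype step — exact for a Poisson process,
and necessary because printed rates up to 1/min at a 6-min step would
exceed probability one linearly. When several same-class events fire in
one step, the first in a seeded shuffled order wins. Attack initiation
couples `attack_rate × target immunogenicity` (the two printed
parameters, combined multiplicatively); while an attack holds, the
target accumulates `damage_rate · dt` and attack time per mechanics
step, and the attack ends on contact loss or target death.

Death: apoptotic cells shrink exponentially (volume half-life
configurable, library default 8.6 min; the bundled immune config uses
120 min so corpses persist ~8.6 h as in the reference framework) and
are removed below 5% of their volume at death; necrotic cells persist
a fixed duration (default 1440 min; the hypoxia config keeps remnants
for the whole run) — a substitute for unmodeled swelling/lysis
dynamics. Dead cells keep repulsion (they remain obstacles) but lose
adhesion (junction loss), do not divide, migrate, or attack, and at
each phenotype step their rate-like parameters are zeroed before only
`applies_to_dead` rules are applied — so a dead cell secretes debris
via its flagged rule but a dead macrophage does not keep secreting
cytokines at its base rate.

Two volume conventions are additions of this package: live cells relax
toward their type's target volume at 0.0045/min (without regrowth,
repeated halving at division would shrink radii without bound and break
contact mechanics), and phagocytosis transfers the prey's volume to the
predator, which then digests it through the same relaxation.

## Simulation loop and configuration

Three nested clocks (defaults 0.01 / 0.1 / 6 min, config-overridable,
validated `dt_diffusion ≤ dt_mechanics ≤ dt_phenotype`): per phenotype
step, rules are evaluated per (cell type, behavior) group over signal
arrays and events are sampled; per mechanics step, motility, forces,
attack continuation, and dead-cell dynamics advance; per diffusion
step, sources/sinks and transport advance. Identical seed and config
give identical outputs (single RNG stream, deterministic iteration
order). The census (live/dead per type plus birth/removal/phagocytosis
counters) reconciles exactly at every save time.

## Spatial-transcriptomics initialization

The spot transform recenters on the arithmetic mean of a selected
subset H (default: spots annotated `other_cells`, the configuration
used for tissue profiles carrying that annotation; the selector is a
parameter because other tissues lack it) and rescales isotropically by
`bias · cell_diameter / lattice_spacing` with defaults 0.97, 16.825 µm,
71.000 µm. It is a pure similarity transform — pairwise distance
ratios are preserved to 1e-12 — so dividing transformed distances by
the scale recovers the originals exactly. No collision resolution is
applied after scaling; overlaps relax through mechanics in the first
simulated minutes.

The synthetic fixture generator emulates the Visium capture geometry:
a triangular lattice (alternate rows offset by half the pitch, row
pitch `√3/2` times the pitch) in which every nearest-neighbor distance
equals the 71.000 µm spacing and interior spots have six equidistant
neighbors. Annotation schemes place a central tumor disk with a
fibroblast annulus ("disk", emulating a dense uniform fibroblast rim)
or seeded scattered foci with thin collars ("patchy"). The fixture
reproduces geometry and annotation layout only — it carries no
expression data, no spot-level noise, and no tissue irregularity, so
tests passing on it certify the coordinate pipeline, not annotation
quality on real arrays.

## Bundled tissue experiments and their calibration

Two rule sets ship as runnable configs at two step policies each (the
reference clock hierarchy, and a coarse 0.5-min variant with oxygen
sub-stepping for routine test runs).

The hypoxia experiment seeds 2000 viable tumor cells uniformly in a
400 µm disk at 38 mmHg far-field physioxia. With reference oxygen
parameters the tissue interior falls below the 3.75 mmHg necrosis
half-max once the domain is large enough (±1000 µm) that the Dirichlet
boundary acts as a genuine far field; a necrotic core then forms and
is detected as necrotic cells lying closer to the tumor centroid than
live cells.

The immune experiment seeds 1000 tumor cells in a 280 µm disk (the
same areal density as the hypoxia experiment) ringed by 50 CD8 T cells
and 50 macrophages. The paper-stated quantities are the rule
parameters, the cell counts, and the 38 mmHg environment; every other
constant was chosen once from reference-framework conventions and the
target phenomenology (a tumor that declines under immune attack):
domain ±1000 µm (interior oxygen 18–25 mmHg, throttling cycling),
macrophage debris chemotaxis with phagocytosis base 0.05/min, CD8
persistence 10 min and bias 0.5 with pro-inflammatory-factor
chemotaxis, damage rate 1.8/min, apoptotic corpse half-life 120 min.
Under these conditions the live tumor count falls well below its
initial value across seeds within 5 simulated days. These
configurations are the package's study conditions; the acceptance
tests run them unmodified.

## Known limitations

2-D only; single-process; no advection or adaptive meshing. No elastic
spring attachments, no fusion dynamics (the rate is registered but
inert), no intracellular ODE/SBML submodels, no multi-phase cell
cycles. The Dirichlet boundary pins the boundary voxel centers rather
than the domain faces (first-order boundary placement). Attack-time
semantics are monotone-accumulate, never reset. Agent phenotypes are
re-evaluated only at phenotype steps, so signals changing faster than
6 min are aliased — consistent with the reference framework's clock
hierarchy.
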