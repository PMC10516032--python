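"""cellgrammar: a hypothesis grammar for cell behavior, and the agent-based
simulator that executes it.

Human-readable rule statements ("oxygen increases cycle entry ...") map
one-to-one onto Hill-response mathematics and drive off-lattice cell
agents coupled to a diffusive microenvironment. Annotated spatial-
transcriptomics spot tables can initialize the virtual tissue.
"""

from . import agents, dictionaries, engine, grammar, microenv, response, spatial
from .agents import CellAgent, CellDefinition, Population
from .engine import SimulationConfig, SimulationOutput, load_config, run_simulation
from .grammar import (
    BehaviorRuleGroup,
    Rule,
    RuleSet,
    aggregate,
    parse_rules_table,
    parse_statement,
    parse_statements_text,
    render_annotation,
    validate_rules,
)
from .microenv import Microenvironment, Substrate
from .response import (
    SignalVector,
    combined_behavior,
    evaluate_behavior,
    hill,
    linear_response,
    multivariate_hill,
)
from .spatial import TransformParams, synth_visium_fixture, transform_spots

__version__ = "0.1.0"

def example_path(name: str) -> str:
    """Absolute path to a bundled example rules file or config."""
    import os

    base = os.path.join(os.path.dirname(__file__), "data")
    for sub in ("rules", "configs"):
        p = os.path.join(base, sub, name)
        if os.path.exists(p):
            return p
    raise FileNotFoundError(f"no bundled file named {name!r}")
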