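"""Parsing, validation, aggregation, and rendering of cell-behavior rules.

A rule is one hypothesis statement tying a microenvironmental signal to a
cell behavior, e.g.::

    In tumor cells:
    oxygen increases cycle entry from 1.7e-05 towards 0.0007 with a Hill
    response, with half-max 21.5 and Hill power 4.

Two serialized dialects are supported: the detailed statement form above
(block headers ``In <type> cells:``, one statement per line) and a
tabular CSV dialect with columns ``cell_type, signal, direction,
behavior, saturation, half_max, hill_power, applies_to_dead``.

Rules for the same (cell type, behavior) pair are aggregated into a
:class:`BehaviorRuleGroup` — the (b0, bM, bm, up-signals, down-signals)
object that the response mathematics evaluates.
"""

from __future__ import annotations

import csv
import html as _html
import io
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "Rule",
    "RuleSet",
    "SignalTerm",
    "BehaviorRuleGroup",
    "AnnotationDocument",
    "RuleParseError",
    "AggregationError",
    "ValidationIssue",
    "ValidationReport",
    "parse_statement",
    "parse_statements_text",
    "parse_rules_table",
    "validate_rules",
    "aggregate",
    "render_annotation",
]

DIRECTIONS = ("increases", "decreases")
SHAPES = ("hill", "linear")


class RuleParseError(ValueError):
    """Raised for malformed rule statements or table rows."""


class AggregationError(ValueError):
    """Raised when a rule group is internally inconsistent (b0 outside [bm, bM])."""


@dataclass(frozen=True)
class Rule:
    """One hypothesis statement: in `cell_type`, `signal` `direction` `behavior`.

    ``saturation`` is the behavior value approached at full response — a
    maximum (bM) for "increases", a minimum (bm) for "decreases".
    ``base_override`` carries the statement's "from X" clause; the cell
    definition's base value remains authoritative.
    """

    cell_type: str
    signal: str
    direction: str
    behavior: str
    saturation: float
    half_max: float
    hill_power: float
    response_shape: str = "hill"
    applies_to_dead: bool = False
    base_override: Optional[float] = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if self.response_shape not in SHAPES:
            raise ValueError(f"response_shape must be one of {SHAPES}, got {self.response_shape!r}")
        if self.half_max is not None and self.half_max <= 0:
            raise ValueError(f"half_max must be > 0, got {self.half_max}")
        if self.hill_power is not None and self.hill_power <= 0:
            raise ValueError(f"hill_power must be > 0, got {self.hill_power}")

    @property
    def key(self) -> tuple:
        return (self.cell_type, self.signal, self.direction, self.behavior)


class RuleSet:
    """Ordered collection of rules with per-rule source provenance.

    No two rules may share the same (cell_type, signal, direction,
    behavior) key.
    """

    def __init__(self) -> None:
        self.rules: list[Rule] = []
        self.provenance: list[str] = []
        self._keys: dict[tuple, str] = {}

    def add(self, rule: Rule, provenance: str = "<memory>") -> None:
        if rule.key in self._keys:
            raise RuleParseError(
                f"duplicate rule {rule.key} at {provenance}; "
                f"first defined at {self._keys[rule.key]}"
            )
        self.rules.append(rule)
        self.provenance.append(provenance)
        self._keys[rule.key] = provenance

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def __eq__(self, other) -> bool:
        return isinstance(other, RuleSet) and self.rules == other.rules

    def cell_types(self) -> list[str]:
        """Cell types in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.rules:
            seen.setdefault(r.cell_type, None)
        return list(seen)

    def behaviors_for(self, cell_type: str) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rules:
            if r.cell_type == cell_type:
                seen.setdefault(r.behavior, None)
        return list(seen)

    def rules_for(self, cell_type: str, behavior: Optional[str] = None) -> list[Rule]:
        return [
            r for r in self.rules
            if r.cell_type == cell_type and (behavior is None or r.behavior == behavior)
        ]


@dataclass(frozen=True)
class SignalTerm:
    """One signal's contribution to a pooled up- or down-response."""

    signal: str
    half_max: float
    hill_power: float
    response_shape: str = "hill"
    applies_to_dead: bool = False


@dataclass
class BehaviorRuleGroup:
    """Aggregated rules for one (cell type, behavior) pair.

    Holds the base value b0 (owned by the cell definition), the maximum
    bM reached under full up-regulation, the minimum bm under full
    down-regulation, and the pooled signal terms for each direction.
    """

    cell_type: str
    behavior: str
    base_value: float
    max_value: float
    min_value: float
    up_signals: list[SignalTerm] = field(default_factory=list)
    down_signals: list[SignalTerm] = field(default_factory=list)
    applies_to_dead: bool = False
    warnings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class AnnotationDocument:
    """A rendered human-readable description of a rule set."""

    format: str  # "text" or "html"
    body: str


# ---------------------------------------------------------------------------
# statement parsing

_HEADER_RE = re.compile(r"^In\s+(?P<cell_type>.+?)\s+cells:$")
_NUM = r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?"
_DETAILED_RE = re.compile(
    rf"^(?:In\s+(?P<cell_type>.+?)\s+cells?,\s+)?"
    rf"(?P<signal>.+?)\s+(?P<direction>increases|decreases)\s+(?P<behavior>.+?)"
    rf"\s+from\s+(?P<base>{_NUM})\s+towards\s+(?P<saturation>{_NUM})"
    rf"\s+with\s+a\s+(?P<shape>Hill|hill|linear)\s+response,"
    rf"\s+with\s+half-max\s+(?P<half_max>{_NUM})\s+and\s+Hill\s+power\s+(?P<power>{_NUM})\."
    rf"(?P<dead>\s+Rule applies to dead cells\.)?$"
)
_TERSE_RE = re.compile(
    r"^(?:In\s+(?P<cell_type>.+?)\s+cells?,\s+)?"
    r"(?P<signal>.+?)\s+(?P<direction>increases|decreases)\s+(?P<behavior>[^.]+?)\.?$"
)


def _parse_number(token: str, line: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise RuleParseError(f"unparseable numeric literal {token!r} in line: {line!r}") from None


def parse_statement(line: str, defaults: Optional[dict] = None,
                    allow_terse: bool = False) -> Optional[Rule]:
    """Parse one detailed statement into a :class:`Rule`.

    ``defaults`` is the block context (currently the ``cell_type`` set by
    an ``In <type> cells:`` header). Empty lines and comments yield None.
    Terse statements without parameters ("S increases B.") are accepted
    only with ``allow_terse`` (validation mode); simulation requires the
    detailed form.
    """
    if defaults is None:
        defaults = {}
    line = line.strip()
    if not line or line.startswith("#"):
        return None
    if line == "Cell Hypothesis Rules (detailed)":  # annotation title line
        return None
    header = _HEADER_RE.match(line)
    if header:
        defaults["cell_type"] = header.group("cell_type")
        return None

    m = _DETAILED_RE.match(line)
    if m:
        cell_type = m.group("cell_type") or defaults.get("cell_type")
        if not cell_type:
            raise RuleParseError(f"no cell type in context for statement: {line!r}")
        return Rule(
            cell_type=cell_type,
            signal=m.group("signal"),
            direction=m.group("direction"),
            behavior=m.group("behavior"),
            saturation=_parse_number(m.group("saturation"), line),
            half_max=_parse_number(m.group("half_max"), line),
            hill_power=_parse_number(m.group("power"), line),
            response_shape=m.group("shape").lower(),
            applies_to_dead=m.group("dead") is not None,
            base_override=_parse_number(m.group("base"), line),
        )

    t = _TERSE_RE.match(line)
    if t and re.search(r"\bfrom\b|\btowards\b|half-max|Hill power|\bresponse\b",
                       t.group("behavior")):
        # A detailed statement with a malformed/missing clause, not a terse rule.
        raise RuleParseError(
            f"malformed detailed statement (missing or broken 'from X towards Y "
            f"with a Hill response, with half-max H and Hill power P' clause): {line!r}"
        )
    if t:
        if not allow_terse:
            raise RuleParseError(
                f"statement lacks the detailed 'from X towards Y ... half-max H and "
                f"Hill power P' clause (required outside validation mode): {line!r}"
            )
        cell_type = t.group("cell_type") or defaults.get("cell_type")
        if not cell_type:
            raise RuleParseError(f"no cell type in context for statement: {line!r}")
        return Rule(
            cell_type=cell_type,
            signal=t.group("signal"),
            direction=t.group("direction"),
            behavior=t.group("behavior").strip(),
            saturation=None, half_max=None, hill_power=None,
        )

    if not re.search(r"\b(increases|decreases)\b", line):
        raise RuleParseError(
            f"no direction word ('increases'/'decreases') in line: {line!r}"
        )
    if re.search(r"\bfrom\b|\btowards\b|half-max|Hill power|\bresponse\b", line):
        raise RuleParseError(
            f"malformed detailed statement (expected 'from X towards Y with a "
            f"Hill response, with half-max H and Hill power P'): {line!r}"
        )
    raise RuleParseError(f"unparseable statement: {line!r}")


def parse_statements_text(stream, source: str = "<stream>",
                          allow_terse: bool = False) -> RuleSet:
    """Parse a detailed-statement file (block headers + one statement per line)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    ruleset = RuleSet()
    context: dict = {}
    for lineno, raw in enumerate(stream, start=1):
        rule = parse_statement(raw, context, allow_terse=allow_terse)
        if rule is not None:
            ruleset.add(rule, provenance=f"{source}:{lineno}")
    return ruleset


# ---------------------------------------------------------------------------
# tabular parsing

_TABLE_COLUMNS = ("cell_type", "signal", "direction", "behavior",
                  "saturation", "half_max", "hill_power", "applies_to_dead")


def parse_rules_table(stream, source: str = "<stream>") -> RuleSet:
    """Parse the 8-column CSV rules dialect into a :class:`RuleSet`.

    '#'-prefixed lines are comments; an optional header row naming the
    columns is recognized and skipped. Duplicate (cell_type, signal,
    direction, behavior) rows are rejected.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    ruleset = RuleSet()
    reader = csv.reader(stream)
    for rowno, row in enumerate(reader, start=1):
        if not row or (row[0].lstrip().startswith("#")):
            continue
        cells = [c.strip() for c in row]
        if not any(cells):
            continue
        if cells[0] == "cell_type":  # header row
            continue
        if len(cells) != len(_TABLE_COLUMNS):
            raise RuleParseError(
                f"{source}:{rowno}: expected {len(_TABLE_COLUMNS)} columns "
                f"{_TABLE_COLUMNS}, got {len(cells)}"
            )
        ct, signal, direction, behavior, sat, hmax, power, dead = cells
        if direction not in DIRECTIONS:
            raise RuleParseError(
                f"{source}:{rowno}: unknown direction {direction!r}"
            )
        try:
            rule = Rule(
                cell_type=ct, signal=signal, direction=direction, behavior=behavior,
                saturation=float(sat), half_max=float(hmax), hill_power=float(power),
                applies_to_dead=dead.lower() in ("1", "true", "yes"),
            )
        except ValueError as exc:
            raise RuleParseError(f"{source}:{rowno}: {exc}") from None
        ruleset.add(rule, provenance=f"{source}:{rowno}")
    return ruleset


# ---------------------------------------------------------------------------
# validation

@dataclass(frozen=True)
class ValidationIssue:
    rule_index: int
    kind: str  # unknown_cell_type | unknown_signal | unknown_behavior | base_mismatch
    message: str


class ValidationReport:
    """Collection of per-rule validation findings; empty iff all rules resolve."""

    def __init__(self) -> None:
        self.issues: list[ValidationIssue] = []

    def add(self, rule_index: int, kind: str, message: str) -> None:
        self.issues.append(ValidationIssue(rule_index, kind, message))

    def __len__(self) -> int:
        return len(self.issues)

    def __iter__(self):
        return iter(self.issues)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        if self.ok:
            return "all rules resolve"
        return "\n".join(f"rule {i.rule_index}: [{i.kind}] {i.message}" for i in self.issues)


def validate_rules(rules: RuleSet, signals, behaviors,
                   cell_types: Sequence[str]) -> ValidationReport:
    """Check every rule against the signal/behavior dictionaries and cell types.

    ``signals`` and ``behaviors`` are the dictionaries from
    :mod:`cellgrammar.dictionaries`. Failures are report entries, never
    exceptions.
    """
    report = ValidationReport()
    known_types = set(cell_types)
    for i, rule in enumerate(rules):
        if rule.cell_type not in known_types:
            report.add(i, "unknown_cell_type",
                       f"cell type {rule.cell_type!r} not declared in the configuration")
        try:
            signals.resolve(rule.signal)
        except KeyError as exc:
            report.add(i, "unknown_signal", str(exc.args[0]))
        try:
            behaviors.resolve(rule.behavior)
        except KeyError as exc:
            report.add(i, "unknown_behavior", str(exc.args[0]))
    return report


# ---------------------------------------------------------------------------
# aggregation

def aggregate(rules: RuleSet, cell_type: str, behavior: str,
              base_value: float) -> BehaviorRuleGroup:
    """Pool all rules for (cell_type, behavior) into one rule group.

    The base value b0 comes from the cell definition, not the rule file;
    a "from X" clause disagreeing with it is recorded as a warning (the
    configuration wins). bM is the maximum saturation over up rules (b0
    if none), bm the minimum over down rules (b0 if none); differing
    same-direction saturations are taken at the extreme with a warning.
    """
    matching = rules.rules_for(cell_type, behavior)
    group = BehaviorRuleGroup(
        cell_type=cell_type, behavior=behavior,
        base_value=base_value, max_value=base_value, min_value=base_value,
    )
    up_sats: list[float] = []
    down_sats: list[float] = []
    for rule in matching:
        if rule.base_override is not None and rule.base_override != base_value:
            group.warnings.append(
                f"rule '{rule.signal} {rule.direction} {rule.behavior}' declares base "
                f"{rule.base_override} but the cell definition sets {base_value}; "
                f"the cell definition wins"
            )
        term = SignalTerm(rule.signal, rule.half_max, rule.hill_power,
                          rule.response_shape, rule.applies_to_dead)
        if rule.direction == "increases":
            group.up_signals.append(term)
            up_sats.append(rule.saturation)
        else:
            group.down_signals.append(term)
            down_sats.append(rule.saturation)
        if rule.applies_to_dead:
            group.applies_to_dead = True
    if up_sats:
        group.max_value = max(up_sats)
        if len(set(up_sats)) > 1:
            group.warnings.append(
                f"{cell_type}/{behavior}: up rules carry different saturations "
                f"{sorted(set(up_sats))}; using the maximum {group.max_value}"
            )
    if down_sats:
        group.min_value = min(down_sats)
        if len(set(down_sats)) > 1:
            group.warnings.append(
                f"{cell_type}/{behavior}: down rules carry different saturations "
                f"{sorted(set(down_sats))}; using the minimum {group.min_value}"
            )
    if up_sats and group.max_value < base_value:
        raise AggregationError(
            f"{cell_type}/{behavior}: base value {base_value} exceeds the "
            f"up-regulated maximum {group.max_value}"
        )
    if down_sats and group.min_value > base_value:
        raise AggregationError(
            f"{cell_type}/{behavior}: base value {base_value} is below the "
            f"down-regulated minimum {group.min_value}"
        )
    return group


def aggregate_all(rules: RuleSet, cell_type: str,
                  base_values) -> dict[str, BehaviorRuleGroup]:
    """Aggregate every behavior this cell type has rules for.

    ``base_values`` maps behavior name -> base value (missing entries
    default to the first rule's "from" clause, else 0).
    """
    groups: dict[str, BehaviorRuleGroup] = {}
    for behavior in rules.behaviors_for(cell_type):
        base = base_values.get(behavior)
        if base is None:
            overrides = [r.base_override for r in rules.rules_for(cell_type, behavior)
                         if r.base_override is not None]
            base = overrides[0] if overrides else 0.0
        groups[behavior] = aggregate(rules, cell_type, behavior, base)
    return groups


# ---------------------------------------------------------------------------
# annotation rendering

def _fmt_number(x: float) -> str:
    if x is None:
        return ""
    if float(x).is_integer() and abs(x) < 1e16:
        return str(int(x))
    return repr(float(x))


def render_statement(rule: Rule) -> str:
    """Render one rule in the detailed-statement phrasing.

    Round-trips: ``parse_statement(render_statement(r)) == r`` for rules
    carrying a base override (statement-parsed rules always do).
    """
    base = rule.base_override if rule.base_override is not None else 0.0
    shape = "Hill" if rule.response_shape == "hill" else "linear"
    text = (
        f"{rule.signal} {rule.direction} {rule.behavior} "
        f"from {_fmt_number(base)} towards {_fmt_number(rule.saturation)} "
        f"with a {shape} response, with half-max {_fmt_number(rule.half_max)} "
        f"and Hill power {_fmt_number(rule.hill_power)}."
    )
    if rule.applies_to_dead:
        text += " Rule applies to dead cells."
    return text


def render_annotation(rules: RuleSet, format: str = "text") -> AnnotationDocument:
    """Render the full rule set as a text or HTML annotation document."""
    if format not in ("text", "html"):
        raise ValueError(f"unsupported annotation format {format!r}")
    if format == "text":
        lines = ["Cell Hypothesis Rules (detailed)", ""]
        for cell_type in rules.cell_types():
            lines.append(f"In {cell_type} cells:")
            for rule in rules.rules_for(cell_type):
                lines.append(render_statement(rule))
            lines.append("")
        return AnnotationDocument("text", "\n".join(lines).rstrip() + "\n")

    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>"
        "<title>Cell Hypothesis Rules</title></head><body>",
        "<h1>Cell Hypothesis Rules (detailed)</h1>",
    ]
    for cell_type in rules.cell_types():
        parts.append(f"<h2>In {_html.escape(cell_type)} cells:</h2>")
        parts.append("<ul>")
        for rule in rules.rules_for(cell_type):
            parts.append(f"<li>{_html.escape(render_statement(rule))}</li>")
        parts.append("</ul>")
    parts.append("</body></html>")
    return AnnotationDocument("html", "\n".join(parts) + "\n")
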