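"""Rule parsing, validation, aggregation, and annotation rendering."""

import io

import pytest

import cellgrammar as cg
from cellgrammar import grammar
from cellgrammar.dictionaries import build_dictionaries
from cellgrammar.grammar import (
    AggregationError,
    Rule,
    RuleParseError,
    aggregate,
    parse_rules_table,
    parse_statement,
    parse_statements_text,
    render_annotation,
    render_statement,
    validate_rules,
)
from cellgrammar.response import SignalVector, evaluate_behavior


class TestParseStatement:
    def test_detailed_statement_with_header_context(self):
        ctx = {}
        assert parse_statement("In tumor cells:", ctx) is None
        rule = parse_statement(
            "oxygen increases cycle entry from 1.7e-05 towards 0.0007 with a "
            "Hill response, with half-max 21.5 and Hill power 4.", ctx)
        assert rule == Rule("tumor", "oxygen", "increases", "cycle entry",
                            saturation=7.0e-4, half_max=21.5, hill_power=4.0,
                            response_shape="hill", applies_to_dead=False,
                            base_override=1.7e-5)

    def test_dead_cell_suffix(self):
        ctx = {"cell_type": "tumor"}
        rule = parse_statement(
            "dead increases debris secretion from 0 towards 0.017 with a Hill "
            "response, with half-max 0.1 and Hill power 10. "
            "Rule applies to dead cells.", ctx)
        assert rule.applies_to_dead is True
        assert rule.saturation == 0.017 and rule.hill_power == 10.0

    def test_inline_cell_type_clause(self):
        rule = parse_statement(
            "In MCF-7 cells, doxorubicin increases apoptosis from 0 towards "
            "0.01 with a Hill response, with half-max 0.5 and Hill power 2.")
        assert rule.cell_type == "MCF-7" and rule.signal == "doxorubicin"

    def test_empty_and_comment_lines_skipped(self):
        assert parse_statement("", {}) is None
        assert parse_statement("   ", {}) is None
        assert parse_statement("# a comment", {}) is None

    def test_missing_parameters_rejected_outside_validation_mode(self):
        with pytest.raises(RuleParseError, match="detailed"):
            parse_statement("oxygen increases cycle entry.",
                            {"cell_type": "tumor"})

    def test_terse_accepted_in_validation_mode(self):
        rule = parse_statement("oxygen increases cycle entry.",
                               {"cell_type": "tumor"}, allow_terse=True)
        assert rule.behavior == "cycle entry" and rule.saturation is None

    def test_unknown_direction_word(self):
        with pytest.raises(RuleParseError, match="direction"):
            parse_statement("oxygen modulates cycle entry.", {"cell_type": "t"},
                            allow_terse=True)

    def test_malformed_detailed_clause(self):
        with pytest.raises(RuleParseError, match="malformed|half-max"):
            parse_statement(
                "oxygen increases cycle entry from 1.7e-05 towards 0.0007 "
                "with a Hill response.", {"cell_type": "tumor"}, allow_terse=True)

    def test_unparseable_numeric_literal(self):
        with pytest.raises(RuleParseError):
            parse_statement(
                "oxygen increases cycle entry from abc towards 0.0007 with a "
                "Hill response, with half-max 21.5 and Hill power 4.",
                {"cell_type": "tumor"}, allow_terse=True)

    def test_no_negation_phrasing(self):
        # the grammar has no symbols for "no"/"lack of"/"low"
        with pytest.raises(RuleParseError):
            parse_statement("low oxygen increases necrosis.", {"cell_type": "t"})


class TestParseRulesTable:
    HEADER = "cell_type,signal,direction,behavior,saturation,half_max,hill_power,applies_to_dead\n"

    def test_row_matches_statement_form(self):
        rs = parse_rules_table(self.HEADER +
                               "tumor,oxygen,increases,cycle entry,0.0007,21.5,4,0\n")
        assert len(rs) == 1
        r = rs.rules[0]
        assert (r.cell_type, r.signal, r.direction, r.behavior) == \
            ("tumor", "oxygen", "increases", "cycle entry")
        assert (r.saturation, r.half_max, r.hill_power) == (7e-4, 21.5, 4.0)
        assert r.applies_to_dead is False

    def test_empty_stream(self):
        assert len(parse_rules_table("")) == 0
        assert len(parse_rules_table("# only a comment\n")) == 0

    def test_duplicate_rows_rejected(self):
        row = "tumor,oxygen,increases,cycle entry,0.0007,21.5,4,0\n"
        with pytest.raises(RuleParseError, match="duplicate"):
            parse_rules_table(self.HEADER + row + row)

    def test_malformed_row_names_row_number(self):
        with pytest.raises(RuleParseError, match=":3"):
            parse_rules_table(self.HEADER +
                              "tumor,oxygen,increases,cycle entry,0.0007,21.5,4,0\n"
                              "tumor,pressure,decreases\n", source="rules.csv")

    def test_bad_direction(self):
        with pytest.raises(RuleParseError, match="direction"):
            parse_rules_table("tumor,oxygen,promotes,cycle entry,1,1,1,0\n")


class TestValidateRules:
    def _dicts(self):
        return build_dictionaries(["oxygen"], ["tumor", "motile tumor"])

    def test_example1_rules_all_resolve(self, example_rules):
        sig, beh = self._dicts()
        report = validate_rules(example_rules[1], sig, beh, ["tumor", "motile tumor"])
        assert report.ok
        assert len(report) == 0

    def test_misspelled_signal_reported(self):
        rs = parse_rules_table(
            "tumor,oxgen,increases,cycle entry,0.0007,21.5,4,0\n")
        sig, beh = self._dicts()
        report = validate_rules(rs, sig, beh, ["tumor"])
        assert [i.kind for i in report] == ["unknown_signal"]

    def test_undeclared_cell_type_reported(self):
        rs = parse_rules_table(
            "stroma,oxygen,increases,cycle entry,0.0007,21.5,4,0\n")
        sig, beh = self._dicts()
        report = validate_rules(rs, sig, beh, ["tumor"])
        assert [i.kind for i in report] == ["unknown_cell_type"]


class TestAggregate:
    def test_example3_cd8_migration_speed(self, example_rules):
        """Two down rules saturating at 0: bm=0, bM=b0=1."""
        group = aggregate(example_rules[3], "CD8 T cell", "migration speed", 1.0)
        assert group.min_value == 0.0
        assert group.max_value == 1.0 == group.base_value
        assert len(group.down_signals) == 2 and len(group.up_signals) == 0
        assert {t.signal for t in group.down_signals} == \
            {"anti-inflammatory factor", "contact with tumor"}

    def test_no_matching_rules_is_identity(self, rng):
        group = aggregate(grammar.RuleSet(), "tumor", "cycle entry", 0.42)
        assert group.max_value == group.min_value == group.base_value == 0.42
        assert not group.up_signals and not group.down_signals
        for _ in range(10):
            sig = SignalVector({"oxygen": rng.uniform(0, 50)})
            assert evaluate_behavior(group, sig).b == pytest.approx(0.42)

    def test_conflicting_up_saturations_take_maximum_with_warning(self):
        rs = grammar.RuleSet()
        rs.add(Rule("t", "a", "increases", "b", 0.5, 1.0, 2.0))
        rs.add(Rule("t", "c", "increases", "b", 1.0, 1.0, 2.0))
        group = aggregate(rs, "t", "b", 0.1)
        assert group.max_value == 1.0
        assert len(group.warnings) == 1

    def test_base_outside_saturation_range_is_an_error(self):
        rs = grammar.RuleSet()
        rs.add(Rule("t", "a", "increases", "b", 0.5, 1.0, 2.0))
        with pytest.raises(AggregationError):
            aggregate(rs, "t", "b", 2.0)  # base above the up-regulated max

    def test_base_override_mismatch_warns_and_config_wins(self):
        rs = grammar.RuleSet()
        rs.add(Rule("t", "a", "increases", "b", 1.0, 1.0, 2.0, base_override=0.3))
        group = aggregate(rs, "t", "b", 0.2)
        assert group.base_value == 0.2
        assert any("cell definition wins" in w for w in group.warnings)


class TestRenderAnnotation:
    def test_example1_statement_rendered_verbatim_compatible(self, example_rules):
        rule = example_rules[1].rules[0]
        assert render_statement(rule) == (
            "oxygen increases cycle entry from 1.7e-05 towards 0.0007 with a "
            "Hill response, with half-max 21.5 and Hill power 4.")

    @pytest.mark.parametrize("example", [1, 2, 3, 4, 5])
    def test_round_trip_all_listings(self, example_rules, example):
        doc = render_annotation(example_rules[example], "text")
        reparsed = parse_statements_text(doc.body)
        assert reparsed == example_rules[example]

    def test_html_contains_every_rule_once(self, example_rules):
        doc = render_annotation(example_rules[3], "html")
        assert doc.format == "html"
        for rule in example_rules[3]:
            # html-escaped statements appear exactly once
            import html as _html
            assert doc.body.count(_html.escape(render_statement(rule))) == 1

    def test_empty_ruleset_renders_header_only(self):
        doc = render_annotation(grammar.RuleSet(), "text")
        assert "Cell Hypothesis Rules" in doc.body
        assert "increases" not in doc.body

    def test_unsupported_format(self, example_rules):
        with pytest.raises(ValueError):
            render_annotation(example_rules[1], "docx")


def test_parser_determinism(example_rules):
    path = cg.example_path("example4.txt")
    with open(path) as fh:
        text = fh.read()
    assert parse_statements_text(text) == parse_statements_text(text)


def test_duplicate_statement_rejected():
    line = ("oxygen increases cycle entry from 0 towards 0.0007 with a Hill "
            "response, with half-max 21.5 and Hill power 4.")
    text = f"In tumor cells:\n{line}\n{line}\n"
    with pytest.raises(RuleParseError, match="duplicate"):
        parse_statements_text(text)
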