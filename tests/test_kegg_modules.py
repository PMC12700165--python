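import itertools

import numpy as np
import pandas as pd
import pytest

from rumenaux import kegg_modules as km
from rumenaux.errors import DefinitionParseError

K1, K2, K3 = "K00001", "K00002", "K00003"


# ---------------------------------------------------------------------------
# independent oracle: evaluate a definition by string splitting (different
# mechanics from the package's token-stream parser)

def _split_depth0(s, sep):
    parts, depth, cur = [], 0, ""
    for ch in s:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == sep and depth == 0:
            parts.append(cur)
            cur = ""
        else:
            cur += ch
    parts.append(cur)
    return parts


def _strip_parens(s):
    while s.startswith("(") and s.endswith(")"):
        depth = 0
        for i, ch in enumerate(s):
            depth += ch == "("
            depth -= ch == ")"
            if depth == 0 and i < len(s) - 1:
                return s
        s = s[1:-1]
    return s


def oracle_eval(expr, kos):
    """None means 'only optional content here'."""
    expr = _strip_parens(expr.strip())
    space_parts = _split_depth0(expr, " ")
    if len(space_parts) > 1:
        vals = [oracle_eval(p, kos) for p in space_parts]
        vals = [v for v in vals if v is not None]
        return all(vals) if vals else None
    comma_parts = _split_depth0(expr, ",")
    if len(comma_parts) > 1:
        vals = [oracle_eval(p, kos) for p in comma_parts]
        vals = [v for v in vals if v is not None]
        return any(vals) if vals else None
    if expr == "--":
        return False
    if expr.startswith("(") or "+" in _strip_all_leaf(expr) \
            or "-" in _strip_all_leaf(expr):
        return _oracle_chain(expr, kos)
    return expr in kos


def _strip_all_leaf(expr):
    # a bare leaf has no operators outside parentheses
    out, depth = "", 0
    for ch in expr:
        depth += ch == "("
        depth -= ch == ")"
        if depth == 0 and ch in "+-":
            out += ch
    return out


def _oracle_chain(expr, kos):
    parts, ops = [], []
    depth, cur = 0, ""
    for ch in expr:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if depth == 0 and ch in "+-" and cur:
            parts.append(cur)
            ops.append(ch)
            cur = ""
        elif depth == 0 and ch == "-" and not cur and not parts:
            ops.append("-lead")
            cur = ""
        else:
            cur += ch
    parts.append(cur)
    vals = []
    if ops and ops[0] == "-lead":
        ops = ops[1:]
        ops.insert(0, "-")
        parts = [None] + parts[:]  # leading optional has no left operand
        parts = [p for p in parts if p is not None]
        required = []
    required = []
    idx_ops = [""] + ops
    for op, part in zip(idx_ops, parts):
        if op == "-":
            continue  # optional, ignored
        required.append(part)
    if not required:
        return None
    vals = [oracle_eval(p, kos) for p in required]
    vals = [v for v in vals if v is not None]
    return all(vals) if vals else None


def oracle_completeness(defn, kos):
    steps = _split_depth0(defn.strip(), " ")
    vals = [oracle_eval(s, kos) for s in steps]
    return sum(1 for v in vals if v is None or v) / len(steps)


# ---------------------------------------------------------------------------
# grammar enumeration: every valid definition of <= N tokens over 3 KOs

def enumerate_definitions(max_tokens):
    """Grow all DEFINITION strings with at most ``max_tokens`` tokens
    (KOs, operators and parentheses each count one token)."""
    kos = [K1, K2, K3]
    atoms = [(k, 1) for k in kos] + [("--", 1)]
    exprs = dict(atoms)

    def add(expr, cost):
        if cost <= max_tokens and expr not in exprs:
            exprs[expr] = cost
            return True
        return False

    changed = True
    while changed:
        changed = False
        current = list(exprs.items())
        for (a, ca) in current:
            for (b, cb) in current:
                for sep, extra in ((" ", 1), (",", 1), ("+", 1), ("-", 1)):
                    if sep in "+-" and (a == "--" or b == "--"
                                        or " " in a or "," in a
                                        or " " in b or "," in b):
                        # chain operands must be atoms or parenthesized
                        if not (a.startswith("(") or a in kos):
                            continue
                        if not (b.startswith("(") or b in kos):
                            continue
                    changed |= add(a + sep + b, ca + cb + 1)
            if not (a.startswith("(") and a.endswith(")")):
                changed |= add("(" + a + ")", ca + 2)
    return sorted(exprs)


class TestParserGrammar:
    def test_two_plain_steps(self):
        steps = km.parse_definition(f"{K1} {K2}")
        assert steps == [km.Ko(K1), km.Ko(K2)]

    def test_or_group_then_step(self):
        steps = km.parse_definition(f"({K1},{K2}) {K3}")
        assert steps == [km.Or((km.Ko(K1), km.Ko(K2))), km.Ko(K3)]

    def test_complex_with_optional(self):
        steps = km.parse_definition(f"{K1}+{K2}-{K3}")
        assert steps == [km.And((km.Ko(K1), km.Ko(K2),
                                 km.Optional_(km.Ko(K3))), complex=True)]

    @pytest.mark.parametrize("bad", ["", "(K00001", "K00001+", ",K00001",
                                     "K00001,,K00002", "K00001)("])
    def test_malformed_definitions_rejected(self, bad):
        with pytest.raises(DefinitionParseError):
            km.parse_definition(bad)

    def test_error_carries_offset(self):
        with pytest.raises(DefinitionParseError) as err:
            km.parse_definition("K00001+")
        assert err.value.offset == 7

    def test_round_trip_canonical(self):
        for defn in (f"{K1} {K2}", f"({K1},{K2}) {K3}",
                     f"{K1}+{K2}-{K3}", f"({K1} {K2}),{K3}",
                     f"-- {K1}"):
            steps = km.parse_definition(defn)
            text = km.serialize_steps(steps)
            assert km.parse_definition(text) == steps


class TestStepwiseCompleteness:
    @pytest.mark.parametrize("defn,kos,expected", [
        (f"{K1} {K2}", {K1}, 0.5),
        (f"({K1},{K2}) {K3}", {K2, K3}, 1.0),
        (f"{K1}+{K2} {K3}", {K1, K3}, 0.5),
    ])
    def test_hand_worked_examples(self, defn, kos, expected):
        steps = km.parse_definition(defn)
        assert km.stepwise_completeness(steps, kos) == expected

    def test_optional_component_ignored(self):
        steps = km.parse_definition(f"{K1}-{K2}")
        assert km.stepwise_completeness(steps, {K1}) == 1.0
        assert km.stepwise_completeness(steps, {K1, K2}) == 1.0

    def test_gap_step_never_satisfied(self):
        steps = km.parse_definition(f"-- {K1}")
        assert km.stepwise_completeness(steps, {K1, K2, K3}) == 0.5

    def test_nested_module_resolved_one_level(self):
        defs = {"M00002": km.ModuleDefinition("M00002", "inner",
                                              km.parse_definition(K2))}
        steps = km.parse_definition(f"{K1} M00002")
        assert km.stepwise_completeness(steps, {K1, K2}, defs) == 1.0
        assert km.stepwise_completeness(steps, {K1}, defs) == 0.5

    def test_unresolved_module_warns_unsatisfied(self):
        steps = km.parse_definition(f"{K1} M00099")
        with pytest.warns(UserWarning, match="M00099"):
            assert km.stepwise_completeness(steps, {K1, K2}) == 0.5

    def test_monotone_under_ko_growth(self):
        """Adding KOs never decreases completeness (random triples)."""
        rng = np.random.default_rng(17)
        defs = enumerate_definitions(5)
        universe = [K1, K2, K3]
        for _ in range(1000):
            defn = defs[int(rng.integers(len(defs)))]
            steps = km.parse_definition(defn)
            base = {k for k in universe if rng.random() < 0.5}
            extra = base | {k for k in universe if rng.random() < 0.5}
            assert km.stepwise_completeness(steps, extra) \
                >= km.stepwise_completeness(steps, base)

    def test_full_universe_completes_gap_free_modules(self):
        for defn in enumerate_definitions(5):
            steps = km.parse_definition(defn)
            c = km.stepwise_completeness(steps, {K1, K2, K3})
            if "--" not in defn:
                assert c == 1.0
            # a gap-containing step keeps completeness below 1 unless the
            # gap sits inside a satisfied OR
            elif defn == "--":
                assert c == 0.0

    def test_parser_matches_string_splitting_oracle(self):
        """Token-stream parser vs independent string-splitting evaluator
        on every valid small definition and every KO subset."""
        universe = [K1, K2, K3]
        subsets = [set(c) for r in range(4)
                   for c in itertools.combinations(universe, r)]
        for defn in enumerate_definitions(6):
            steps = km.parse_definition(defn)
            for kos in subsets:
                assert km.stepwise_completeness(steps, kos) \
                    == oracle_completeness(defn, kos), (defn, kos)


class TestCompletenessMatrix:
    def _table(self):
        return pd.DataFrame(
            [("M00001", "a", f"{K1} {K2}"), ("M00002", "b", f"{K1},{K3}")],
            columns=["module_id", "name", "definition"])

    def test_full_ko_set_all_ones(self):
        defs = km.parse_module_table(self._table())
        comp, complete = km.completeness_matrix(defs,
                                                {"g": {K1, K2, K3}})
        assert (comp.loc["g"] == 1.0).all()
        assert complete.loc["g"].all()

    def test_empty_ko_set_all_zero(self):
        defs = km.parse_module_table(self._table())
        comp, _ = km.completeness_matrix(defs, {"g": set()})
        assert (comp.loc["g"] == 0.0).all()

    def test_duplicate_module_ids_rejected(self):
        table = pd.concat([self._table(), self._table()])
        with pytest.raises(ValueError, match="duplicate"):
            km.parse_module_table(table)

    def test_planted_half_complete(self):
        defs = km.parse_module_table(self._table())
        comp, complete = km.completeness_matrix(defs, {"g": {K1}})
        assert comp.loc["g", "M00001"] == 0.5
        assert not complete.loc["g", "M00001"]
        assert comp.loc["g", "M00002"] == 1.0
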