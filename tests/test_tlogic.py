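import itertools
import math

import numpy as np
import pytest

from protoforge.errors import ContractError, FormulaSyntaxError
from protoforge.reactorsim import Trace
from protoforge.tlogic import (And, Atom, Or, Temporal, domain_margin,
                               eval_boolean, formula, parse_formula,
                               satisfaction_degree, unparse, validity_domain)


def naive_eval(node, trace, i):
    """Independent position-by-position evaluator (semantics oracle)."""
    times = trace.times
    if isinstance(node, Atom):
        series = times if node.observable == "Time" \
            else trace.concentrations[node.observable]
        x = series[i]
        return x >= node.rhs if node.comparator == ">=" else x <= node.rhs
    if isinstance(node, And):
        return naive_eval(node.left, trace, i) and \
            naive_eval(node.right, trace, i)
    if isinstance(node, Or):
        return naive_eval(node.left, trace, i) or \
            naive_eval(node.right, trace, i)
    if node.t1 is None:
        window = range(i, len(times))
    else:
        window = [j for j in range(len(times))
                  if times[i] + node.t1 <= times[j] <= times[i] + node.t2]
    results = [naive_eval(node.child, trace, j) for j in window]
    return any(results) if node.op == "F" else all(results)


class TestParser:
    def test_plain_atom(self):
        f = parse_formula("Time >= 0")
        assert isinstance(f.root, Atom)
        assert f.free_variables == ()

    def test_free_variable_under_eventually(self):
        f = parse_formula("F(X >= $y)")
        assert isinstance(f.root, Temporal) and f.root.op == "F"
        assert f.root.t1 is None
        assert f.free_variables == ("y",)

    def test_negated_atom_desugars_by_comparator_flip(self):
        f = parse_formula("!(X >= 2)")
        assert f.root == Atom("X", "<=", 2.0)

    CORPUS = [
        "X >= 1.5", "X <= $r", "F(X >= $y)", "G(Y <= 2)",
        "F[0,600](Out2 >= $N)", "G[0,3600](Out4 <= $R)",
        "F[0,600](Out2 >= $N) & G[0,3600](Out4 <= $R)",
        "(X >= 1 | Y <= 2) & F(X >= 3)",
        "F(G(X >= 1))", "G[10,20](F[0,5](X >= $a))",
        "X >= 1 & Y <= 2 & Time >= 0",
        "X >= 1 | Y <= 2 | X <= 0",
        "F(X >= $a & Y <= $b)", "G(X >= $a | X <= $b)",
        "F[0.5,2.5](X >= 0.25)", "G(NAD+ >= 0)",
        "F(NADH >= $N_NADH)", "!(X <= $low)",
        "F[0,60](X >= 1e-6)", "G[0,3.6e3](Y <= 2E-5)",
    ]

    @pytest.mark.parametrize("text", CORPUS)
    def test_unparse_round_trip(self, text):
        f = parse_formula(text)
        again = parse_formula(unparse(f))
        assert again.root == f.root
        assert again.free_variables == f.free_variables

    @pytest.mark.parametrize("text", ["X >", "F[1](X >= 0)", "X >= ",
                                      "&& Y <= 1", "F(X >= $)",
                                      "!(F(X >= 1))", "F[5,1](X >= 0)"])
    def test_syntax_errors(self, text):
        with pytest.raises(FormulaSyntaxError):
            parse_formula(text)


class TestEvalBoolean:
    def test_globally_nonnegative_trace(self, step_trace):
        assert eval_boolean(step_trace, parse_formula("G(X >= 0)"))

    def test_unreachable_level_is_false(self, step_trace):
        assert not eval_boolean(step_trace, parse_formula("F(X >= 4.2)"))

    def test_window_clipped_to_horizon(self, step_trace):
        # window [3, 10] clips to samples at t = 3, 4 where X <= 2
        assert eval_boolean(step_trace, parse_formula("G[3,10](X <= 2)"))

    def test_free_variables_rejected(self, step_trace):
        with pytest.raises(ContractError):
            eval_boolean(step_trace, parse_formula("F(X >= $y)"))

    def test_random_formulas_match_position_oracle(self, step_trace):
        rng = np.random.default_rng(42)
        obs = ["X", "Y"]

        def random_node(depth):
            kind = rng.integers(0, 4 if depth > 0 else 1)
            if kind == 0:
                return Atom(obs[rng.integers(0, 2)],
                            [">=", "<="][rng.integers(0, 2)],
                            float(np.round(rng.uniform(0, 5), 2)))
            if kind == 1:
                return And(random_node(depth - 1), random_node(depth - 1))
            if kind == 2:
                return Or(random_node(depth - 1), random_node(depth - 1))
            if rng.integers(0, 2):
                return Temporal("FG"[rng.integers(0, 2)],
                                random_node(depth - 1))
            t1 = float(rng.integers(0, 4))
            return Temporal("FG"[rng.integers(0, 2)],
                            random_node(depth - 1), t1,
                            t1 + float(rng.integers(0, 4)))

        for _ in range(200):
            node = random_node(2)
            assert eval_boolean(step_trace, formula(node)) == \
                naive_eval(node, step_trace, 0)


class TestValidityDomain:
    def test_eventually_upper_bounds_variable(self, step_trace):
        dom = validity_domain(step_trace, parse_formula("F(X >= $y)"))
        (box,) = dom.boxes
        assert box.interval("y") == (-math.inf, 3.7)

    def test_globally_intersects_positions(self, step_trace):
        dom = validity_domain(step_trace, parse_formula("G(X >= $y)"))
        (box,) = dom.boxes
        assert box.interval("y") == (-math.inf, 0.0)

    def test_pinch_to_point_on_constant_trace(self):
        tr = Trace(times=np.arange(4.0),
                   concentrations={"X": np.full(4, 2.5)})
        dom = validity_domain(tr, parse_formula("F(X >= $y) & F(X <= $y)"))
        (box,) = dom.boxes
        assert box.interval("y") == (2.5, 2.5)

    def test_variable_free_formula_rejected(self, step_trace):
        with pytest.raises(ContractError):
            validity_domain(step_trace, parse_formula("F(X >= 1)"))

    def test_grid_equivalence_with_boolean_semantics(self, step_trace):
        """v in domain(phi) iff eval_boolean(phi[v]) — exhaustively on a grid."""
        texts = ["F(X >= $a)", "G(Y <= $a)", "F(X >= $a & Y <= $b)",
                 "G(X >= $a | Y <= $b)", "F[1,3](X >= $a) & G[0,2](Y <= $b)",
                 "F(X >= $a) & F(X <= $a)"]
        grid = np.arange(-0.5, 5.6, 0.5)
        for text in texts:
            f = parse_formula(text)
            dom = validity_domain(step_trace, f)
            for point in itertools.product(grid,
                                           repeat=len(f.free_variables)):
                values = dict(zip(f.free_variables, map(float, point)))
                assert dom.contains(values) == \
                    eval_boolean(step_trace, f.substitute(values)), \
                    (text, values)

    def test_enlarging_trace_never_shrinks_ge_domain(self, step_trace):
        f = parse_formula("F[0,2](X >= $y) & G(X >= $z)")
        small = validity_domain(step_trace, f)
        bigger = Trace(times=step_trace.times,
                       concentrations={"X":
                                       step_trace.concentrations["X"] + 1.0})
        big = validity_domain(bigger, f)
        for box in small.boxes:
            corners = {v: box.interval(v)[1] for v in f.free_variables}
            assert big.contains(corners)


class TestSatisfactionDegree:
    def test_true_formula_scores_one(self, step_trace):
        res = satisfaction_degree(step_trace, parse_formula("F(X >= $y)"),
                                  {"y": 2.0})
        assert res.satisfaction_degree == 1.0
        assert res.boolean_value and res.violation_degree == 0.0

    def test_normalized_distance_two_thirds(self):
        # domain y <= 1; objective 2 -> vd = (2-1)/2 = 0.5, sd = 2/3
        tr = Trace(times=np.arange(3.0),
                   concentrations={"X": np.array([0.0, 1.0, 0.5])})
        res = satisfaction_degree(tr, parse_formula("F(X >= $y)"), {"y": 2.0})
        assert res.violation_degree == pytest.approx(0.5)
        assert res.satisfaction_degree == pytest.approx(2.0 / 3.0)
        assert res.witness == {"y": 1.0}

    def test_interior_objective_witness_is_objective(self, step_trace):
        f = parse_formula("F(X >= $a) & G(Y <= $b)")
        res = satisfaction_degree(step_trace, f, {"a": 1.0, "b": 6.0})
        assert res.witness == {"a": 1.0, "b": 6.0}

    def test_unsatisfiable_domain_scores_zero(self, step_trace):
        f = parse_formula("G(X >= $y) & G(X <= $y)")  # non-constant trace
        res = satisfaction_degree(step_trace, f, {"y": 1.0})
        assert res.satisfaction_degree == 0.0
        assert math.isinf(res.violation_degree)

    def test_sd_non_increasing_away_from_domain(self, step_trace):
        f = parse_formula("F(X >= $y)")
        sds = [satisfaction_degree(step_trace, f, {"y": 3.7 + d}
                                   ).satisfaction_degree
               for d in np.linspace(0, 10, 25)]
        assert all(a >= b - 1e-15 for a, b in zip(sds, sds[1:]))

    def test_margin_is_distance_to_boundary(self, step_trace):
        f = parse_formula("F(X >= $y)")
        dom = validity_domain(step_trace, f)
        assert domain_margin(dom, {"y": 2.0}) == pytest.approx((3.7 - 2) / 2)
        assert domain_margin(dom, {"y": 4.0}) == 0.0
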