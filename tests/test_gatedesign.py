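import itertools

import pytest

from protoforge.errors import CapabilityError, InvariantError
from protoforge.gatedesign import (TruthTable, boolean_reachability,
                                   build_circuits, crosstalk_report,
                                   mine_gates, synthesize_expression)
from protoforge.netio import NetworkModel, Reaction, Species
from protoforge.synthetic import (PlantedNetworkConfig, gate_table,
                                  generate_planted_network)


def brute_force_mine(network, table, max_reactions):
    """Independent exhaustive enumerator over all subsets and bindings.

    Returns the set of (reaction id set, ordered bound inputs, output
    species) realizing the table under reachability semantics.
    """
    n_in = len(table.input_ids)
    want = table.column(table.output_ids[0])
    # symmetric input slots: report one representative binding per orbit
    autos = [p for p in itertools.permutations(range(n_in))
             if all(want[tuple(bits[i] for i in p)] == want[bits]
                    for bits in want)]
    found = set()
    for size in range(1, max_reactions + 1):
        for subset in itertools.combinations(network.reactions, size):
            ids = frozenset(r.id for r in subset)
            subs = {s for r in subset for s, _ in r.substrates}
            inhs = {i for r in subset for i in r.inhibitors}
            prods = {p for r in subset for p, _ in r.products}
            enzymes = {r.enzyme for r in subset if r.enzyme}
            for out in prods:
                for bound in itertools.permutations(
                        sorted((subs | inhs) - {out}), n_in):
                    internals = enzymes | {s for s in subs
                                           if s not in bound
                                           and s not in prods}
                    if out in internals:
                        continue
                    ok = True
                    for bits in itertools.product((0, 1), repeat=n_in):
                        present = {sp for sp, b in zip(bound, bits) if b}
                        reach = boolean_reachability(
                            network, present | internals, ids)
                        if (out in reach) != bool(want[bits]):
                            ok = False
                            break
                    if ok:
                        canon = min(tuple(bound[i] for i in p)
                                    for p in autos)
                        found.add((ids, canon, out))
    return found


class TestReachability:
    def test_empty_closure(self):
        net = NetworkModel()
        assert boolean_reachability(net, set()) == set()

    def test_two_step_chain(self):
        net = NetworkModel(
            species=[Species(id=x) for x in "SIP"] +
                    [Species(id=e, role="enzyme") for e in ("E1", "E2")],
            reactions=[
                Reaction(id="r1", substrates=[("S", 1)], products=[("I", 1)],
                         enzyme="E1"),
                Reaction(id="r2", substrates=[("I", 1)], products=[("P", 1)],
                         enzyme="E2")])
        # hand fixed point: S -> I -> P in two rounds
        assert boolean_reachability(net, {"S", "E1", "E2"}) == \
            {"S", "E1", "E2", "I", "P"}
        assert "P" not in boolean_reachability(net, {"S", "E1"})

    def test_inhibitor_blocks_production(self):
        net = NetworkModel(
            species=[Species(id="S"), Species(id="P"), Species(id="X"),
                     Species(id="E", role="enzyme")],
            reactions=[Reaction(id="r", substrates=[("S", 1)],
                                products=[("P", 1)], enzyme="E",
                                inhibitors=["X"])])
        assert "P" in boolean_reachability(net, {"S", "E"})
        assert "P" not in boolean_reachability(net, {"S", "E", "X"})

    def test_unknown_active_reaction_rejected(self):
        net = NetworkModel()
        with pytest.raises(InvariantError):
            boolean_reachability(net, set(), {"ghost"})


class TestMineGates:
    def test_single_bisubstrate_and_motif(self):
        net = NetworkModel(
            species=[Species(id="A"), Species(id="B"), Species(id="P"),
                     Species(id="E", role="enzyme")],
            reactions=[Reaction(id="r", substrates=[("A", 1), ("B", 1)],
                                products=[("P", 1)], enzyme="E")])
        motifs = mine_gates(net, gate_table("AND"), max_reactions=2)
        assert len(motifs) == 1
        (m,) = motifs
        assert m.reactions == ("r",)
        assert dict(m.input_binding) == {"A": "A", "B": "B"}
        assert m.output_species == "P"
        assert m.required_internals == ("E",)

    def test_no_producer_gives_empty_list(self, tiny_network):
        # BUF demands a produced output; a table over an unproduced species
        net = NetworkModel(species=[Species(id="A")], reactions=[
            Reaction(id="r", substrates=[("A", 1)], products=[("A", 1)])])
        assert mine_gates(net, gate_table("AND"), 2) == []

    def test_more_than_three_inputs_is_capability_error(self):
        rows = {bits: (int(all(bits)),)
                for bits in itertools.product((0, 1), repeat=4)}
        table = TruthTable.from_dict(("a", "b", "c", "d"), ("y",), rows)
        with pytest.raises(CapabilityError):
            mine_gates(NetworkModel(), table, 1)

    def test_constant_table_rejected_by_invariant(self):
        with pytest.raises(InvariantError):
            TruthTable.from_dict(("a",), ("y",), {(0,): (1,), (1,): (1,)})

    @pytest.mark.parametrize("gate", ["BUF", "AND", "OR", "ANDN"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_equals_brute_force_on_planted_networks(self, gate, seed):
        """Completeness at small scale: mining == exhaustive enumeration."""
        inputs = ("M00",) if gate == "BUF" else ("M00", "M01")
        net, _ = generate_planted_network(PlantedNetworkConfig(
            n_species=8, n_reactions=12,
            planted_motifs=[(gate, inputs, "M05")], seed=seed))
        assert len(net.reactions) <= 12
        table = gate_table(gate)
        mined = {(frozenset(m.reactions), tuple(sp for _, sp
                                                in m.input_binding),
                  m.output_species)
                 for m in mine_gates(net, table, 2)}
        assert mined == brute_force_mine(net, table, 2)

    def test_soundness_of_every_mined_motif(self):
        net, _ = generate_planted_network(PlantedNetworkConfig(
            n_species=10, n_reactions=14,
            planted_motifs=[("AND", ("M00", "M01"), "M05"),
                            ("OR", ("M02", "M03"), "M06")], seed=3))
        for gate in ("AND", "OR", "ANDN"):
            table = gate_table(gate)
            want = table.column(table.output_ids[0])
            for m in mine_gates(net, table, 2):
                internals = set(m.required_internals)
                for bits in table.sorted_rows():
                    present = {sp for sp, b
                               in zip(m.input_species, bits) if b}
                    reach = boolean_reachability(
                        net, present | internals, set(m.reactions))
                    assert (m.output_species in reach) == bool(want[bits])

    def test_deterministic_ranking(self):
        net, _ = generate_planted_network(PlantedNetworkConfig(
            n_species=8, n_reactions=12,
            planted_motifs=[("AND", ("M00", "M01"), "M05")], seed=5))
        a = mine_gates(net, gate_table("AND"), 2)
        b = mine_gates(net, gate_table("AND"), 2)
        assert a == b
        assert all(len(x.reactions) <= len(y.reactions)
                   for x, y in zip(a, a[1:]))


class TestSynthesizeExpression:
    def or_table(self):
        return gate_table("OR")

    def test_or_is_sum_of_literals(self):
        expr = synthesize_expression(gate_table("OR"), "Y")
        assert str(expr) == "A + B"

    def test_single_minterm(self):
        table = TruthTable.from_dict(
            ("A", "B"), ("Y",),
            {(0, 0): (0,), (0, 1): (0,), (1, 0): (1,), (1, 1): (0,)})
        expr = synthesize_expression(table, "Y")
        assert str(expr) == "A·¬B"

    def test_xor_two_terms_and_equivalence(self):
        table = TruthTable.from_dict(
            ("A", "B"), ("Y",),
            {(0, 0): (0,), (0, 1): (1,), (1, 0): (1,), (1, 1): (0,)})
        expr = synthesize_expression(table, "Y")
        col = table.column("Y")
        for bits in table.sorted_rows():
            assert expr.evaluate(dict(zip(("A", "B"), bits))) == col[bits]
        assert len(expr.terms) == 2

    @pytest.mark.parametrize("gate", ["BUF", "AND", "OR", "ANDN"])
    def test_equivalence_on_canonical_gates(self, gate):
        table = gate_table(gate)
        expr = synthesize_expression(table, "Y")
        col = table.column("Y")
        for bits in table.sorted_rows():
            assert expr.evaluate(dict(zip(table.input_ids, bits))) \
                == col[bits]


class TestBuildCircuits:
    def buf_library(self):
        net = NetworkModel(
            species=[Species(id="in"), Species(id="out"),
                     Species(id="E", role="enzyme")],
            reactions=[Reaction(id="r", substrates=[("in", 1)],
                                products=[("out", 1)], enzyme="E")])
        return mine_gates(net, gate_table("BUF"), 1)

    def test_single_buf_spec_returns_sole_motif(self):
        library = self.buf_library()
        spec = TruthTable.from_dict(("in",), ("out",),
                                    {(0,): (0,), (1,): (1,)})
        circuits = build_circuits(library, spec)
        assert len(circuits) >= 1
        top = circuits[0]
        assert len(top.gates) == 1
        assert top.gates[0].reactions == ("r",)
        assert top.species_set == {"E"}

    def test_unproducible_output_yields_diagnostic(self):
        library = self.buf_library()
        spec = TruthTable.from_dict(("in",), ("absent",),
                                    {(0,): (0,), (1,): (1,)})
        circuits = build_circuits(library, spec)
        assert circuits == []
        assert "absent" in circuits.diagnostic

    def test_circuits_satisfy_spec_symbolically(self):
        net, _ = generate_planted_network(PlantedNetworkConfig(
            n_species=10, n_reactions=10,
            planted_motifs=[("AND", ("M00", "M01"), "M05"),
                            ("BUF", ("M02",), "M06")], seed=7))
        library = mine_gates(net, gate_table("AND"), 2) + \
            mine_gates(net, gate_table("BUF"), 2)
        spec = TruthTable.from_function(
            ("M00", "M01", "M02"), ("M05", "M06"),
            lambda bits: (bits[0] & bits[1], bits[2]))
        circuits = build_circuits(library, spec)
        assert circuits, circuits.diagnostic
        for c in circuits:
            # independent re-evaluation: gate tables composed over wiring
            for bits, expected in spec.rows.items():
                level = dict(zip(spec.input_ids, bits))
                for _ in range(len(c.gates) + 1):
                    for g in c.gates:
                        in_bits = tuple(level.get(sp, 0)
                                        for sp in g.input_species)
                        out = g.table.rows[in_bits][0]
                        level[g.output_species] = max(
                            level.get(g.output_species, 0), out)
                assert tuple(level.get(o, 0)
                             for o in spec.output_ids) == expected


class TestCrosstalk:
    _n = 0

    def make_circuit(self, species, enzymes, inputs):
        from protoforge.gatedesign import CircuitImplementation
        TestCrosstalk._n += 1
        out = f"y{TestCrosstalk._n}"  # outputs distinct between circuits
        spec = TruthTable.from_dict((inputs[0],), (out,),
                                    {(0,): (0,), (1,): (1,)})
        return CircuitImplementation(
            spec=spec, gates=(), wiring={},
            input_species={inputs[0]: inputs[0]}, output_species={out: out},
            species_set=frozenset(species), enzyme_set=frozenset(enzymes))

    def test_disjoint_circuits_not_flagged(self):
        a = self.make_circuit({"E1", "C1"}, {"E1"}, ["inA"])
        b = self.make_circuit({"E2", "C2"}, {"E2"}, ["inB"])
        rep = crosstalk_report([a, b])
        assert rep.flagged() == []

    def test_shared_cofactors_flagged(self):
        a = self.make_circuit({"E1", "NAD+", "NADH"}, {"E1"}, ["inA"])
        b = self.make_circuit({"E2", "NAD+", "NADH"}, {"E2"}, ["inB"])
        (pair,) = crosstalk_report([a, b]).flagged()
        assert set(pair[2]) >= {"NAD+", "NADH"}

    def test_declared_common_input_never_flagged(self):
        a = self.make_circuit({"E1"}, {"E1"}, ["glucose"])
        b = self.make_circuit({"E2"}, {"E2"}, ["glucose"])
        rep = crosstalk_report([a, b], shared_inputs={"glucose"})
        assert rep.flagged() == []
        # but undeclared sharing of the same input is a flag
        assert crosstalk_report([a, b]).flagged()

    def test_requires_two_circuits(self):
        with pytest.raises(ValueError):
            crosstalk_report([self.make_circuit({"E"}, {"E"}, ["x"])])
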