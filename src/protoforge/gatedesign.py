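"""Mine reaction networks for Boolean logic gates and assemble circuits.

A gate is a small reaction subset whose input/output behaviour under discrete
reachability semantics reproduces a truth table; circuits are compositions of
gates wired by species identity and verified symbolically against a
multi-output specification.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from sympy import And as SymAnd, Not as SymNot, Or as SymOr, SOPform, symbols

from .errors import CapabilityError, InvariantError
from .netio import NetworkModel

MAX_LOGICAL_INPUTS = 3


# ---------------------------------------------------------------------------
# Truth tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthTable:
    """Exhaustive mapping from input bit-vectors to output bit-vectors."""

    input_ids: tuple[str, ...]
    output_ids: tuple[str, ...]
    rows: dict[tuple[int, ...], tuple[int, ...]] = field(hash=False)

    def __post_init__(self):
        n = len(self.input_ids)
        expected = {bits for bits in itertools.product((0, 1), repeat=n)}
        if set(self.rows) != expected:
            raise InvariantError(
                f"truth table must contain exactly the 2^{n} input rows")
        for col, out_id in enumerate(self.output_ids):
            vals = {out[col] for out in self.rows.values()}
            if vals != {0, 1}:
                raise InvariantError(
                    f"output column {out_id!r} is constant (non-constant required)")

    @classmethod
    def from_dict(cls, input_ids, output_ids, rows: dict) -> "TruthTable":
        return cls(tuple(input_ids), tuple(output_ids),
                   {tuple(k): tuple(v) for k, v in rows.items()})

    @classmethod
    def from_function(cls, input_ids, output_ids, fn) -> "TruthTable":
        """Build from fn(bits) -> output bit tuple."""
        rows = {bits: tuple(fn(bits))
                for bits in itertools.product((0, 1), repeat=len(input_ids))}
        return cls(tuple(input_ids), tuple(output_ids), rows)

    @property
    def single_output(self) -> bool:
        return len(self.output_ids) == 1

    def column(self, output_id: str) -> dict[tuple[int, ...], int]:
        col = self.output_ids.index(output_id)
        return {bits: out[col] for bits, out in self.rows.items()}

    def sorted_rows(self) -> list[tuple[int, ...]]:
        return sorted(self.rows)


# ---------------------------------------------------------------------------
# Discrete semantics
# ---------------------------------------------------------------------------

def boolean_reachability(network: NetworkModel, present: set[str],
                         active_reactions: set[str] | None = None,
                         preloaded: set[str] = frozenset()) -> set[str]:
    """Producible species under discrete reachability semantics.

    A species is producible iff it is present, or it is a product of an active
    reaction whose substrates are all producible, whose enzyme (if any) is
    producible or pre-loaded, and none of whose inhibitors is producible.
    The closure is computed in deterministic simultaneous rounds, testing
    inhibitors against the current set.
    """
    rxns = network.reactions
    if active_reactions is not None:
        known = {r.id for r in rxns}
        if not set(active_reactions) <= known:
            raise InvariantError(
                f"unknown reactions: {sorted(set(active_reactions) - known)}")
        rxns = [r for r in rxns if r.id in active_reactions]

    producible = set(present)
    while True:
        added = set()
        for r in rxns:
            if not all(s in producible for s, _ in r.substrates):
                continue
            if r.enzyme is not None and r.enzyme not in producible \
                    and r.enzyme not in preloaded:
                continue
            if any(i in producible for i in r.inhibitors):
                continue
            added.update(p for p, _ in r.products if p not in producible)
        if not added:
            return producible
        producible |= added


# ---------------------------------------------------------------------------
# Gate motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateMotif:
    """A reaction subset realizing a single-output truth table."""

    table: TruthTable
    reactions: tuple[str, ...]
    input_binding: tuple[tuple[str, str], ...]  # (logical input, species id)
    output_id: str
    output_species: str
    enzymes: tuple[str, ...]
    required_internals: tuple[str, ...]  # pre-loaded cofactors incl. enzymes
    context_score: float = 0.0

    @property
    def input_species(self) -> tuple[str, ...]:
        return tuple(sp for _, sp in self.input_binding)

    def used_species(self) -> set[str]:
        return (set(self.input_species) | {self.output_species}
                | set(self.required_internals))

    def key(self):
        return (frozenset(self.reactions), self.input_binding,
                self.output_species)


def _context_score(network: NetworkModel, species_ids: set[str]) -> float:
    """Count of involved species sharing the most common context tag."""
    by_id = network.species_by_id()
    tags = [by_id[s].context_tag for s in species_ids
            if s in by_id and by_id[s].context_tag is not None]
    return float(max((tags.count(t) for t in set(tags)), default=0))


def _motif_behaviour(network, rxn_ids, bound_species, out_sp, internals):
    """Output bit per input row under reachability semantics."""
    out = {}
    for bits in itertools.product((0, 1), repeat=len(bound_species)):
        present = {sp for sp, b in zip(bound_species, bits) if b}
        present |= set(internals)
        reach = boolean_reachability(network, present, set(rxn_ids))
        out[bits] = 1 if out_sp in reach else 0
    return out


def mine_gates(network: NetworkModel, table: TruthTable,
               max_reactions: int = 2) -> list[GateMotif]:
    """Enumerate every reaction subset + binding realizing ``table``.

    Pre-loaded internals of a candidate subset are all enzymes of its
    reactions plus any substrate that is neither a logical input nor a
    product of an included reaction.
    """
    if not table.single_output:
        raise InvariantError("mine_gates requires a single-output table")
    if len(table.input_ids) > MAX_LOGICAL_INPUTS:
        raise CapabilityError(
            f"search bound: at most {MAX_LOGICAL_INPUTS} logical inputs")
    if max_reactions < 1:
        raise ValueError("max_reactions must be >= 1")

    n_in = len(table.input_ids)
    want = table.column(table.output_ids[0])
    out_id = table.output_ids[0]

    # input permutations leaving the table invariant (symmetric slots);
    # used to canonicalize bindings so e.g. an AND motif is reported once
    autos = [perm for perm in itertools.permutations(range(n_in))
             if all(want[tuple(bits[i] for i in perm)] == want[bits]
                    for bits in want)]

    def canonical_binding(bound):
        return min(tuple(bound[i] for i in perm) for perm in autos)

    motifs = {}
    rxn_list = network.reactions
    for size in range(1, max_reactions + 1):
        for subset in itertools.combinations(rxn_list, size):
            rxn_ids = tuple(sorted(r.id for r in subset))
            substrate_sp = {s for r in subset for s, _ in r.substrates}
            inhibitor_sp = {i for r in subset for i in r.inhibitors}
            product_sp = {p for r in subset for p, _ in r.products}
            enzymes = tuple(sorted({r.enzyme for r in subset
                                    if r.enzyme is not None}))
            for out_sp in sorted(product_sp):
                # inhibitors are bindable inputs: NOT-logic needs them
                candidates = sorted((substrate_sp | inhibitor_sp) - {out_sp})
                if len(candidates) < n_in:
                    continue
                for bound in itertools.permutations(candidates, n_in):
                    if canonical_binding(bound) != tuple(bound):
                        continue
                    internals = set(enzymes) | {
                        s for s in substrate_sp
                        if s not in bound and s not in product_sp}
                    if out_sp in internals:
                        continue
                    got = _motif_behaviour(network, rxn_ids, bound, out_sp,
                                           internals)
                    if got != want:
                        continue
                    motif = GateMotif(
                        table=table, reactions=rxn_ids,
                        input_binding=tuple(zip(table.input_ids, bound)),
                        output_id=out_id, output_species=out_sp,
                        enzymes=enzymes,
                        required_internals=tuple(sorted(internals)),
                        context_score=_context_score(
                            network, set(bound) | {out_sp} | internals))
                    motifs.setdefault(motif.key(), motif)

    return sorted(motifs.values(),
                  key=lambda m: (len(m.reactions), -m.context_score,
                                 m.reactions, m.input_binding))


# ---------------------------------------------------------------------------
# Two-level logic synthesis (diagnostics / minimal SOP)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BooleanExpression:
    """Minimal sum-of-products: terms are tuples of (input id, positive?)."""

    inputs: tuple[str, ...]
    terms: tuple[tuple[tuple[str, bool], ...], ...]

    def evaluate(self, assignment: dict[str, int]) -> int:
        for term in self.terms:
            if all(bool(assignment[v]) == pos for v, pos in term):
                return 1
        return 0

    def __str__(self):
        def lit(v, pos):
            return v if pos else f"¬{v}"
        return " + ".join("·".join(lit(v, p) for v, p in term)
                          for term in self.terms)


def synthesize_expression(table: TruthTable, output_id: str) -> BooleanExpression:
    """Minimal two-level SOP (Quine-McCluskey) for one output column."""
    col = table.column(output_id)
    if len(set(col.values())) == 1:
        raise InvariantError(f"output column {output_id!r} is constant")
    syms = symbols(" ".join(table.input_ids)) if len(table.input_ids) > 1 \
        else (symbols(table.input_ids[0]),)
    minterms = [list(bits) for bits, v in sorted(col.items()) if v == 1]
    expr = SOPform(list(syms), minterms)

    def as_terms(e):
        parts = e.args if isinstance(e, SymOr) else (e,)
        terms = []
        for part in parts:
            lits = part.args if isinstance(part, SymAnd) else (part,)
            term = []
            for l in lits:
                if isinstance(l, SymNot):
                    term.append((str(l.args[0]), False))
                else:
                    term.append((str(l), True))
            term.sort(key=lambda t: table.input_ids.index(t[0]))
            terms.append(tuple(term))
        return tuple(sorted(terms))

    return BooleanExpression(inputs=table.input_ids, terms=as_terms(expr))


# ---------------------------------------------------------------------------
# Circuit assembly (NetBuild-style)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircuitImplementation:
    """A wired multi-gate circuit satisfying a multi-output specification.

    ``species_set`` holds the encapsulated entities: enzymes plus pre-loaded
    cofactor/reporter substrates.  Logical inputs and wire intermediates are
    not counted as entities (they arrive from outside or start at zero).
    """

    spec: TruthTable
    gates: tuple[GateMotif, ...]
    wiring: dict[str, str] = field(hash=False)
    input_species: dict[str, str] = field(hash=False)
    output_species: dict[str, str] = field(hash=False)
    species_set: frozenset[str] = frozenset()
    enzyme_set: frozenset[str] = frozenset()
    score: tuple = ()

    @property
    def n_entities(self) -> int:
        return len(self.species_set)

    @property
    def n_enzymes(self) -> int:
        return len(self.enzyme_set)

    def footprint(self) -> set[str]:
        """All reactive species ids touched by the circuit."""
        sp = set(self.species_set) | set(self.input_species.values())
        sp |= set(self.output_species.values()) | set(self.wiring)
        for g in self.gates:
            sp |= g.used_species()
        return sp


class CircuitList(list):
    """Ranked circuits; ``diagnostic`` explains an empty result."""

    diagnostic: str | None = None


def _gate_key(g: GateMotif):
    return (g.reactions, g.input_binding, g.output_species)


def _real_key(real):
    gates, vec = real
    return (len(gates), tuple(sorted(_gate_key(g) for g in gates)), vec)


def _realizations(target_sp, depth, producers_of, input_cols, memo,
                  cap=40):
    """Ways to produce target_sp as a Boolean function of circuit inputs.

    Returns a deterministic list of (frozenset of gate motifs, output-bit
    tuple over spec rows).  Several gates producing the same species realize
    logical OR (width <= 2).  The search is breadth-bounded: per species and
    depth, only the ``cap`` smallest realizations (by gate count) are kept,
    which preserves the minimal circuits assembly ranks first.
    """
    key = (target_sp, depth)
    if key in memo:
        return memo[key]
    memo[key] = []  # guard while recursing
    results: dict = {}
    if target_sp in input_cols:
        results[(frozenset(), input_cols[target_sp])] = None
    if depth > 0:
        producers = sorted(producers_of.get(target_sp, []), key=_gate_key)
        per_gate = {}
        for g in producers:
            child_lists = []
            for child_sp in g.input_species:
                opts = _realizations(child_sp, depth - 1, producers_of,
                                     input_cols, memo, cap)
                opts = sorted(opts, key=_real_key)[:cap]
                child_lists.append(opts)
            gate_opts = []
            if all(child_lists):
                seen = set()
                for choice in itertools.product(*child_lists):
                    gates = frozenset({g}).union(*(c[0] for c in choice))
                    vecs = [c[1] for c in choice]
                    outvec = tuple(
                        g.table.rows[tuple(v[i] for v in vecs)][0]
                        for i in range(len(vecs[0])))
                    if (gates, outvec) in seen:
                        continue
                    seen.add((gates, outvec))
                    gate_opts.append((gates, outvec))
                    results.setdefault((gates, outvec), None)
                    if len(gate_opts) >= cap:
                        break
            per_gate[_gate_key(g)] = sorted(gate_opts, key=_real_key)
        for g1, g2 in itertools.combinations(producers, 2):
            count = 0
            for ga, va in per_gate[_gate_key(g1)]:
                for gb, vb in per_gate[_gate_key(g2)]:
                    vec = tuple(max(a, b) for a, b in zip(va, vb))
                    results.setdefault((ga | gb, vec), None)
                    count += 1
                    if count >= cap:
                        break
                if count >= cap:
                    break
    out = sorted(results, key=_real_key)[:3 * cap]
    memo[key] = out
    return out


def _collisions(gates, input_sp, shared_cofactors):
    """Species used by >= 2 gates that are not inputs, wires or declared cofactors."""
    outputs = {g.output_species for g in gates}
    consumed = {sp for g in gates for sp in g.input_species}
    wires = outputs & consumed
    usage = {}
    for g in gates:
        for sp in g.used_species():
            usage.setdefault(sp, set()).add(g)
    bad = set()
    for sp, users in usage.items():
        if len(users) < 2:
            continue
        if sp in input_sp or sp in wires or sp in shared_cofactors:
            continue
        bad.add(sp)
    return bad, wires


def build_circuits(library: list[GateMotif], spec: TruthTable,
                   max_results: int = 10, input_species: dict | None = None,
                   output_species: dict | None = None,
                   shared_cofactors: set[str] = frozenset(),
                   max_depth: int = 3) -> CircuitList:
    """Assemble gate motifs into circuits satisfying a multi-output spec.

    Gates are wired by species identity (a gate's output species feeding a
    downstream gate's input species); several gates producing the same wire
    species realize logical OR.  A species used by two gates that is neither
    a circuit input, a wire, nor a declared shared cofactor is an unintended
    collision and the combination is rejected.  Every returned circuit is
    re-verified symbolically on all rows.
    """
    if not library:
        raise ValueError("library must be non-empty")
    input_species = input_species or {i: i for i in spec.input_ids}
    output_species = output_species or {o: o for o in spec.output_ids}

    rows = spec.sorted_rows()
    input_cols = {input_species[i]: tuple(bits[k] for bits in rows)
                  for k, i in enumerate(spec.input_ids)}
    producers_of = {}
    for g in library:
        producers_of.setdefault(g.output_species, []).append(g)

    memo = {}
    per_output = []
    result = CircuitList()
    for o in spec.output_ids:
        sp = output_species[o]
        target = tuple(spec.rows[bits][spec.output_ids.index(o)]
                       for bits in rows)
        opts = [(g, v) for g, v in
                _realizations(sp, max_depth, producers_of, input_cols, memo)
                if v == target and g]
        if not opts:
            try:
                sop = str(synthesize_expression(spec, o))
            except InvariantError:
                sop = "constant"
            result.diagnostic = (f"no feasible implementation for output "
                                 f"{o!r} (species {sp!r}, required logic: {sop})")
            return result
        per_output.append(opts)

    input_sp = set(input_cols)
    seen = set()
    candidates = []
    for combo in itertools.product(*per_output):
        gates = frozenset().union(*(c[0] for c in combo))
        if gates in seen:
            continue
        seen.add(gates)
        bad, wires = _collisions(gates, input_sp, shared_cofactors)
        if bad:
            continue
        if not _verify_circuit(gates, spec, input_species, output_species):
            continue
        enzymes = frozenset(e for g in gates for e in g.enzymes)
        entities = frozenset(s for g in gates for s in g.required_internals)
        score = (len(enzymes), len(entities),
                 -sum(g.context_score for g in gates))
        ordered = tuple(sorted(gates, key=lambda g: (g.reactions,
                                                     g.input_binding)))
        candidates.append(CircuitImplementation(
            spec=spec, gates=ordered, wiring={w: w for w in sorted(wires)},
            input_species=dict(input_species),
            output_species=dict(output_species),
            species_set=entities, enzyme_set=enzymes, score=score))

    candidates.sort(key=lambda c: (c.score, tuple(g.reactions for g in c.gates)))
    result.extend(candidates[:max_results])
    if not result:
        result.diagnostic = ("all gate combinations rejected "
                             "(species collisions or failed verification)")
    return result


def _verify_circuit(gates, spec, input_species, output_species) -> bool:
    """Independent symbolic check: iterate species bits to a fixed point."""
    for bits, expected in spec.rows.items():
        level = {input_species[i]: b for i, b in zip(spec.input_ids, bits)}
        for _ in range(len(gates) + 1):
            new = dict(level)
            for g in gates:
                in_bits = tuple(level.get(sp, 0) for sp in g.input_species)
                val = g.table.rows[in_bits][0]
                new[g.output_species] = max(new.get(g.output_species, 0), val)
            if new == level:
                break
            level = new
        got = tuple(level.get(output_species[o], 0) for o in spec.output_ids)
        if got != expected:
            return False
    return True


# ---------------------------------------------------------------------------
# Cross-talk
# ---------------------------------------------------------------------------

@dataclass
class CrosstalkReport:
    """Pairwise shared-species analysis between circuits."""

    pairs: list[tuple[int, int, tuple[str, ...], bool]]

    def flagged(self):
        return [p for p in self.pairs if p[3]]


def crosstalk_report(circuits: list[CircuitImplementation],
                     shared_inputs: set[str] = frozenset()) -> CrosstalkReport:
    """Flag circuit pairs sharing reactive species beyond declared inputs."""
    if len(circuits) < 2:
        raise ValueError("crosstalk_report requires >= 2 circuits")
    pairs = []
    for i, j in itertools.combinations(range(len(circuits)), 2):
        shared = circuits[i].footprint() & circuits[j].footprint()
        severity = bool(shared - set(shared_inputs))
        pairs.append((i, j, tuple(sorted(shared)), severity))
    return CrosstalkReport(pairs=pairs)
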