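"""Temporal logic over finite traces: parsing, evaluation, validity domains
and the normalized satisfaction degree.

The fragment covers atoms ``obs >= rhs`` / ``obs <= rhs`` (rhs a constant or
a ``$``-prefixed free threshold variable), conjunction ``&``, disjunction
``|``, and the temporal operators ``F``/``G`` with optional time windows
``F[t1,t2](...)``.  Negation is accepted on atoms only and desugared by
flipping the comparator.  Semantics are piecewise-constant over the trace
samples; windows are clipped to the trace horizon.

For a formula with free threshold variables, the validity domain — the set of
variable values making the formula true — is an exact finite union of
axis-aligned boxes, because every atom constrains a single variable by a
half-line at each trace position.  The satisfaction degree of an objective
point v is sd = 1/(1+vd), where vd is the Euclidean distance from v to the
domain with each coordinate normalized by max(|v_k|, eps); sd = 1 iff the
formula is true at v, and sd -> 0 as the system moves far from the
specification (sd = 0 exactly for an empty, unsatisfiable domain).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, FormulaSyntaxError, ObservableError

EPS_NORM = 1e-9
TIME_OBSERVABLE = "Time"


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    observable: str
    comparator: str          # ">=" or "<="
    rhs: float | str         # constant, or free-variable name (str)

    @property
    def free_variable(self) -> str | None:
        return self.rhs if isinstance(self.rhs, str) else None

    def __str__(self):
        rhs = f"${self.rhs}" if isinstance(self.rhs, str) else repr(self.rhs)
        return f"{self.observable} {self.comparator} {rhs}"


@dataclass(frozen=True)
class And:
    left: "Node"
    right: "Node"

    def __str__(self):
        return f"({self.left} & {self.right})"


@dataclass(frozen=True)
class Or:
    left: "Node"
    right: "Node"

    def __str__(self):
        return f"({self.left} | {self.right})"


@dataclass(frozen=True)
class Temporal:
    op: str                  # "F" or "G"
    child: "Node"
    t1: float | None = None  # None => untimed (whole remaining horizon)
    t2: float | None = None

    def __post_init__(self):
        if (self.t1 is None) != (self.t2 is None):
            raise FormulaSyntaxError("time window needs both bounds")
        if self.t1 is not None and not (0 <= self.t1 <= self.t2):
            raise FormulaSyntaxError(
                f"window must satisfy 0 <= t1 <= t2, got [{self.t1},{self.t2}]")

    def __str__(self):
        win = "" if self.t1 is None else f"[{_fmt(self.t1)},{_fmt(self.t2)}]"
        return f"{self.op}{win}({self.child})"


Node = Atom | And | Or | Temporal


def _fmt(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() else repr(x)


@dataclass(frozen=True)
class Formula:
    """Root node plus the ordered list of free threshold variables."""

    root: Node
    free_variables: tuple[str, ...] = ()

    def __str__(self):
        return str(self.root)

    def substitute(self, values: dict[str, float]) -> "Formula":
        """Instantiate free variables with constants."""

        def sub(node):
            if isinstance(node, Atom):
                if isinstance(node.rhs, str) and node.rhs in values:
                    return Atom(node.observable, node.comparator,
                                float(values[node.rhs]))
                return node
            if isinstance(node, (And, Or)):
                return type(node)(sub(node.left), sub(node.right))
            return Temporal(node.op, sub(node.child), node.t1, node.t2)

        root = sub(self.root)
        remaining = tuple(v for v in self.free_variables if v not in values)
        return Formula(root, remaining)


def formula(root: Node) -> Formula:
    """Wrap an AST node, collecting free variables in appearance order."""
    seen = []

    def walk(node):
        if isinstance(node, Atom):
            v = node.free_variable
            if v is not None and v not in seen:
                seen.append(v)
        elif isinstance(node, (And, Or)):
            walk(node.left)
            walk(node.right)
        else:
            walk(node.child)

    walk(root)
    return Formula(root, tuple(seen))


# ---------------------------------------------------------------------------
# Parser (recursive descent)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"""
    (?P<ws>\s+)
  | (?P<num>(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)
  | (?P<cmp>>=|<=)
  | (?P<var>\$[A-Za-z_][A-Za-z_0-9]*)
  | (?P<id>[A-Za-z_][A-Za-z_0-9+'-]*)
  | (?P<sym>[()\[\],&|!])
""", re.VERBOSE)


def _tokenize(text: str):
    pos, out = 0, []
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise FormulaSyntaxError(f"unexpected character {text[pos]!r}",
                                     pos + 1)
        if m.lastgroup != "ws":
            out.append((m.lastgroup, m.group(), pos + 1))
        pos = m.end()
    out.append(("eof", "", len(text) + 1))
    return out


class _Parser:
    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def take(self, kind=None, value=None):
        tok = self.tokens[self.i]
        if (kind and tok[0] != kind) or (value and tok[1] != value):
            raise FormulaSyntaxError(
                f"expected {value or kind}, got {tok[1]!r}", tok[2])
        self.i += 1
        return tok

    def parse(self) -> Node:
        node = self.expr()
        tok = self.peek()
        if tok[0] != "eof":
            raise FormulaSyntaxError(f"trailing input {tok[1]!r}", tok[2])
        return node

    def expr(self) -> Node:
        node = self.term()
        while self.peek()[1] == "|":
            self.take()
            node = Or(node, self.term())
        return node

    def term(self) -> Node:
        node = self.factor()
        while self.peek()[1] == "&":
            self.take()
            node = And(node, self.factor())
        return node

    def factor(self) -> Node:
        kind, value, pos = self.peek()
        if value == "(":
            self.take()
            node = self.expr()
            self.take(value=")")
            return node
        if value == "!":
            self.take()
            atom = self.factor()
            if not isinstance(atom, Atom):
                raise FormulaSyntaxError(
                    "negation is only allowed on atoms", pos)
            flipped = ">=" if atom.comparator == "<=" else "<="
            return Atom(atom.observable, flipped, atom.rhs)
        if kind == "id" and value in ("F", "G") and \
                self.tokens[self.i + 1][1] in ("(", "["):
            self.take()
            t1 = t2 = None
            if self.peek()[1] == "[":
                self.take()
                t1 = float(self.take("num")[1])
                self.take(value=",")
                t2 = float(self.take("num")[1])
                self.take(value="]")
            self.take(value="(")
            child = self.expr()
            self.take(value=")")
            return Temporal(value, child, t1, t2)
        if kind == "id":
            return self.atom()
        raise FormulaSyntaxError(f"unexpected token {value!r}", pos)

    def atom(self) -> Atom:
        obs = self.take("id")[1]
        cmp_tok = self.take("cmp")[1]
        kind, value, pos = self.peek()
        if kind == "num":
            self.take()
            return Atom(obs, cmp_tok, float(value))
        if kind == "var":
            self.take()
            return Atom(obs, cmp_tok, value[1:])
        raise FormulaSyntaxError("expected a number or $variable", pos)


def parse_formula(text: str) -> Formula:
    """Parse formula text, e.g. ``F[0,600](Out2 >= $N) & G[0,3600](Out4 <= $R)``."""
    return formula(_Parser(text).parse())


def unparse(f: Formula) -> str:
    """Canonical text form; ``parse_formula(unparse(f))`` round-trips."""
    return str(f)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _observable(trace, name):
    if name == TIME_OBSERVABLE:
        return np.asarray(trace.times, dtype=float)
    try:
        return np.asarray(trace.concentrations[name], dtype=float)
    except KeyError:
        raise ObservableError(
            f"observable {name!r} not in trace (have "
            f"{sorted(trace.concentrations)} and {TIME_OBSERVABLE!r})")


def _window_indices(times, i, t1, t2):
    if t1 is None:
        return range(i, len(times))
    lo = times[i] + t1
    hi = times[i] + t2
    idx = np.nonzero((times >= lo - 1e-12) & (times <= hi + 1e-12))[0]
    return [j for j in idx if j >= 0]


def eval_boolean(trace, f: Formula) -> bool:
    """Finite-trace Boolean semantics at position 0 (no free variables)."""
    if f.free_variables:
        raise ContractError(
            f"formula has free variables {f.free_variables}; instantiate "
            "them or use validity_domain")
    times = np.asarray(trace.times, dtype=float)

    def ev(node, i) -> bool:
        if isinstance(node, Atom):
            x = _observable(trace, node.observable)[i]
            return bool(x >= node.rhs if node.comparator == ">=" else
                        x <= node.rhs)
        if isinstance(node, And):
            return ev(node.left, i) and ev(node.right, i)
        if isinstance(node, Or):
            return ev(node.left, i) or ev(node.right, i)
        idx = _window_indices(times, i, node.t1, node.t2)
        if node.op == "F":
            return any(ev(node.child, j) for j in idx)
        return all(ev(node.child, j) for j in idx)

    return ev(f.root, 0)


# ---------------------------------------------------------------------------
# Validity domains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    """Axis-aligned closed box: var -> (lo, hi); missing vars unconstrained."""

    bounds: tuple[tuple[str, tuple[float, float]], ...] = ()

    def as_dict(self):
        return dict(self.bounds)

    def interval(self, var):
        return self.as_dict().get(var, (-math.inf, math.inf))

    def is_empty(self):
        return any(lo > hi for _, (lo, hi) in self.bounds)

    def intersect(self, other: "Box") -> "Box | None":
        merged = self.as_dict()
        for var, (lo, hi) in other.bounds:
            plo, phi = merged.get(var, (-math.inf, math.inf))
            nlo, nhi = max(plo, lo), min(phi, hi)
            if nlo > nhi:
                return None
            merged[var] = (nlo, nhi)
        return Box(tuple(sorted(merged.items())))

    def contains(self, point: dict[str, float]) -> bool:
        return all(lo <= point[v] <= hi for v, (lo, hi) in self.bounds)


_FULL = Box()


@dataclass
class ValidityDomain:
    """Finite union of boxes over an ordered variable list; empty = unsat."""

    variables: tuple[str, ...]
    boxes: list[Box] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.boxes

    def contains(self, point: dict[str, float]) -> bool:
        return any(b.contains(point) for b in self.boxes)

    def to_jsonable(self):
        return {"variables": list(self.variables),
                "boxes": [{v: list(iv) for v, iv in b.bounds}
                          for b in self.boxes]}


def _canonicalize(boxes: list[Box]) -> list[Box]:
    unique = list({b.bounds: b for b in boxes if not b.is_empty()}.values())
    # drop boxes strictly contained in another box
    kept = [b for b in unique
            if not any(o.bounds != b.bounds and _box_covers(o, b)
                       for o in unique)]
    # merge pairs that differ in exactly one variable with touching intervals
    changed = True
    while changed:
        changed = False
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                m = _try_merge(kept[i], kept[j])
                if m is not None:
                    kept[i] = m
                    del kept[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(kept, key=lambda b: b.bounds)


def _box_covers(a: Box, b: Box) -> bool:
    vars_ = {v for v, _ in a.bounds} | {v for v, _ in b.bounds}
    for v in vars_:
        alo, ahi = a.interval(v)
        blo, bhi = b.interval(v)
        if not (alo <= blo and bhi <= ahi):
            return False
    return True


def _try_merge(a: Box, b: Box) -> Box | None:
    vars_ = sorted({v for v, _ in a.bounds} | {v for v, _ in b.bounds})
    diff = [v for v in vars_ if a.interval(v) != b.interval(v)]
    if len(diff) > 1:
        return None
    if not diff:
        return a
    v = diff[0]
    alo, ahi = a.interval(v)
    blo, bhi = b.interval(v)
    if max(alo, blo) > min(ahi, bhi):  # disjoint, cannot coalesce
        return None
    merged = a.as_dict()
    merged[v] = (min(alo, blo), max(ahi, bhi))
    return Box(tuple(sorted(merged.items())))


def validity_domain(trace, f: Formula) -> ValidityDomain:
    """Exact validity domain of ``f`` over its free threshold variables."""
    if not f.free_variables:
        raise ContractError("formula has no free variables; use eval_boolean")
    times = np.asarray(trace.times, dtype=float)
    memo: dict[tuple[int, int], list[Box]] = {}

    def dom(node, i) -> list[Box]:
        key = (id(node), i)
        if key in memo:
            return memo[key]
        if isinstance(node, Atom):
            x = float(_observable(trace, node.observable)[i])
            if isinstance(node.rhs, str):
                iv = (-math.inf, x) if node.comparator == ">=" else (x, math.inf)
                out = [Box(((node.rhs, iv),))]
            else:
                sat = (x >= node.rhs if node.comparator == ">=" else
                       x <= node.rhs)
                out = [_FULL] if sat else []
        elif isinstance(node, And):
            out = []
            for a in dom(node.left, i):
                for b in dom(node.right, i):
                    m = a.intersect(b)
                    if m is not None:
                        out.append(m)
            out = _canonicalize(out)
        elif isinstance(node, Or):
            out = _canonicalize(dom(node.left, i) + dom(node.right, i))
        else:
            idx = _window_indices(times, i, node.t1, node.t2)
            if node.op == "F":
                out = []
                for j in idx:
                    out.extend(dom(node.child, j))
                out = _canonicalize(out)
            else:  # G: intersection over all window positions
                out = [_FULL]
                for j in idx:
                    nxt = []
                    for a in out:
                        for b in dom(node.child, j):
                            m = a.intersect(b)
                            if m is not None:
                                nxt.append(m)
                    out = _canonicalize(nxt)
                    if not out:
                        break
        memo[key] = out
        return out

    return ValidityDomain(variables=f.free_variables,
                          boxes=dom(f.root, 0))


# ---------------------------------------------------------------------------
# Satisfaction degree
# ---------------------------------------------------------------------------

@dataclass
class SatisfactionResult:
    """Violation/satisfaction degree of an objective against a domain."""

    violation_degree: float
    satisfaction_degree: float
    witness: dict[str, float] | None
    boolean_value: bool
    domain: ValidityDomain | None = None


def _distance_to_box(box: Box, objective: dict[str, float]):
    d2 = 0.0
    witness = dict(objective)
    for var, v in objective.items():
        lo, hi = box.interval(var)
        if v < lo:
            gap, witness[var] = lo - v, lo
        elif v > hi:
            gap, witness[var] = v - hi, hi
        else:
            continue
        d2 += (gap / max(abs(v), EPS_NORM)) ** 2
    return math.sqrt(d2), witness


def satisfaction_degree(trace, f: Formula,
                        objective: dict[str, float]) -> SatisfactionResult:
    """Normalized distance-based degree: sd = 1/(1+vd), sd=1 iff true."""
    missing = [v for v in f.free_variables if v not in objective]
    if missing:
        raise ContractError(f"objective missing variables {missing}")
    domain = validity_domain(trace, f)
    if domain.empty:
        return SatisfactionResult(math.inf, 0.0, None, False, domain)
    best = (math.inf, None)
    for box in domain.boxes:
        d, w = _distance_to_box(box, objective)
        if d < best[0]:
            best = (d, w)
    vd, witness = best
    return SatisfactionResult(vd, 1.0 / (1.0 + vd), witness, vd == 0.0, domain)


def domain_margin(domain: ValidityDomain, objective: dict[str, float]) -> float:
    """Normalized distance from an interior objective to the domain boundary.

    Zero when the objective is outside every box; finite-bound coordinates
    only (an unbounded direction imposes no boundary).  Used as the
    robustness score once a specification is satisfied.
    """
    best = 0.0
    for box in domain.boxes:
        if not box.contains(objective):
            continue
        slack = math.inf
        for var, v in objective.items():
            lo, hi = box.interval(var)
            norm = max(abs(v), EPS_NORM)
            if lo > -math.inf:
                slack = min(slack, (v - lo) / norm)
            if hi < math.inf:
                slack = min(slack, (hi - v) / norm)
        best = max(best, 1.0 if math.isinf(slack) else slack)
    return best
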