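"""Enzymatic rate laws and stochastic/deterministic parameter conversion.

Irreversible forms only: the circuits of interest are driven far from
equilibrium by reporter sinks, and reverse constants are never available for
the mined parts.  Bi-bi expressions follow Cleland's standard irreversible
forms; substrate slot order (A, B) is the insertion order of ``Km_map``.

Mechanisms
----------
mm_uni          v = kcat*E*S / (Km + S)
ordered_bibi    v = kcat*E*A*B / (Kia*KmB + KmB*A + KmA*B + A*B)
pingpong_bibi   v = kcat*E*A*B / (KmB*A + KmA*B + A*B)
random_bibi     v = kcat*E*A*B / (alpha*KmA*KmB + KmB*A + KmA*B + A*B)
mass_action     v = k * prod(substrates)   (enzyme-free elementary step)
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .errors import (DivergentRateError, KineticsConfigError,
                     UnsupportedOrderError)

AVOGADRO = 6.02214076e23  # 1/mol

MECHANISMS = ("mass_action", "mm_uni", "ordered_bibi", "pingpong_bibi",
              "random_bibi")
_BIBI = ("ordered_bibi", "pingpong_bibi", "random_bibi")


@dataclass
class RateLaw:
    """Kinetic constants for one reaction.

    Km_map maps substrate id -> Km (mol/L) and must cover exactly the
    mechanism's substrate slots: one for mm_uni, two for the bi-bi forms.
    """

    mechanism: str
    kcat: float | None = None           # 1/s
    Km_map: dict[str, float] = field(default_factory=dict)
    Kia: float | None = None            # mol/L, ordered/random only
    alpha: float = 1.0                  # random bi-bi interaction factor
    k: float | None = None              # mass-action constant

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise KineticsConfigError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "mass_action":
            if self.k is None or self.k <= 0:
                raise KineticsConfigError("mass_action requires k > 0")
            return
        if self.kcat is None or self.kcat <= 0:
            raise KineticsConfigError(f"{self.mechanism} requires kcat > 0")
        need = 1 if self.mechanism == "mm_uni" else 2
        if len(self.Km_map) != need:
            raise KineticsConfigError(
                f"{self.mechanism} requires exactly {need} Km slot(s), "
                f"got {sorted(self.Km_map)}")
        if any(km <= 0 for km in self.Km_map.values()):
            raise KineticsConfigError("all Km must be > 0")
        if self.mechanism in ("ordered_bibi",):
            if self.Kia is None or self.Kia <= 0:
                raise KineticsConfigError("ordered_bibi requires Kia > 0")
        if self.mechanism == "random_bibi" and self.alpha <= 0:
            raise KineticsConfigError("random_bibi requires alpha > 0")

    @property
    def slots(self) -> tuple[str, ...]:
        """Substrate slot ids in (A, B) order."""
        return tuple(self.Km_map)


def reaction_rate(law: RateLaw, enzyme_conc: float,
                  substrate_concs: dict[str, float]) -> float:
    """Instantaneous rate in mol/L/s; zero when any required substrate is zero."""
    if law.mechanism == "mass_action":
        v = law.k
        for c in substrate_concs.values():
            v *= max(c, 0.0)
        return v

    E = max(enzyme_conc, 0.0)
    try:
        concs = [max(substrate_concs[s], 0.0) for s in law.slots]
    except KeyError as exc:
        raise KineticsConfigError(
            f"missing substrate slot {exc.args[0]!r} for {law.mechanism}") from exc

    if law.mechanism == "mm_uni":
        (S,) = concs
        Km = law.Km_map[law.slots[0]]
        return law.kcat * E * S / (Km + S) if S > 0 else 0.0

    A, B = concs
    if A <= 0 or B <= 0:
        return 0.0
    KmA, KmB = (law.Km_map[s] for s in law.slots)
    if law.mechanism == "ordered_bibi":
        denom = law.Kia * KmB + KmB * A + KmA * B + A * B
    elif law.mechanism == "pingpong_bibi":
        denom = KmB * A + KmA * B + A * B
    else:  # random_bibi
        denom = law.alpha * KmA * KmB + KmB * A + KmA * B + A * B
    return law.kcat * E * A * B / denom


def det_to_stoch(k: float, order: int, volume: float) -> float:
    """Deterministic constant -> stochastic per-combination constant.

    c = k * (N_A*V)^(1-order); order 1 is volume-independent.
    """
    if volume <= 0:
        raise ValueError("volume must be > 0")
    if order not in (0, 1, 2):
        raise UnsupportedOrderError(f"order {order} not supported (0, 1, 2)")
    return k * (AVOGADRO * volume) ** (1 - order)


def stoch_to_det(c: float, order: int, volume: float) -> float:
    """Inverse of :func:`det_to_stoch` (round-trip identity)."""
    if volume <= 0:
        raise ValueError("volume must be > 0")
    if order not in (0, 1, 2):
        raise UnsupportedOrderError(f"order {order} not supported (0, 1, 2)")
    return c * (AVOGADRO * volume) ** (order - 1)


def prob_to_rate(p: float, dt: float) -> float:
    """Per-step firing probability -> exponential-waiting-time rate (1/s)."""
    if not 0.0 <= p < 1.0:
        raise DivergentRateError(f"probability must be in [0, 1), got {p}")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return -math.log1p(-p) / dt


def rate_to_prob(rate: float, dt: float) -> float:
    """Inverse of :func:`prob_to_rate`: p = 1 - exp(-rate*dt)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return -math.expm1(-rate * dt)


@dataclass
class KineticParameters:
    """Per-reaction rate-law assignment plus a source annotation."""

    laws: dict[str, RateLaw] = field(default_factory=dict)
    source: str = "fixture"

    def law_for(self, reaction_id: str) -> RateLaw:
        try:
            return self.laws[reaction_id]
        except KeyError:
            raise KineticsConfigError(
                f"no rate law assigned to reaction {reaction_id!r}")

    def validate_against(self, network) -> None:
        """Every simulated reaction has exactly one law with matching slots."""
        for r in network.reactions:
            law = self.law_for(r.id)
            if law.mechanism == "mass_action":
                continue
            sub_ids = {sid for sid, _ in r.substrates}
            if not set(law.slots) <= sub_ids:
                raise KineticsConfigError(
                    f"reaction {r.id!r}: Km slots {law.slots} not a subset of "
                    f"substrates {sorted(sub_ids)}")

    @classmethod
    def from_json(cls, path: str | Path) -> "KineticParameters":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        laws = {}
        for rid, d in obj.get("laws", {}).items():
            laws[rid] = RateLaw(mechanism=d["mechanism"], kcat=d.get("kcat"),
                                Km_map=dict(d.get("Km_map", {})),
                                Kia=d.get("Kia"), alpha=d.get("alpha", 1.0),
                                k=d.get("k"))
        return cls(laws=laws, source=obj.get("source", str(path)))

    def to_json(self, path: str | Path) -> None:
        obj = {"source": self.source, "laws": {
            rid: {"mechanism": law.mechanism, "kcat": law.kcat,
                  "Km_map": law.Km_map, "Kia": law.Kia, "alpha": law.alpha,
                  "k": law.k}
            for rid, law in self.laws.items()}}
        Path(path).write_text(json.dumps(obj, indent=1), encoding="utf-8")
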