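"""End-to-end pipeline: mine -> build -> sensitivity -> landscape ->
optimize -> truthtable -> report.

Each stage writes machine-readable artifacts (JSON/CSV/PNG) into the output
directory; ``manifest.json`` records per-artifact SHA-256 checksums so a
rerun with identical configuration and seeds is verifiably identical
(timestamps live only in the manifest's excluded field).
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np

from . import designopt, gatedesign
from .errors import ProtoforgeError
from .fixtures import load_fixture
from .netio import read_network
from .synthetic import gate_table

STAGES = ("mine", "build", "sensitivity", "landscape", "optimize",
          "truthtable", "report")


def motif_to_jsonable(m: gatedesign.GateMotif) -> dict:
    return {"reactions": list(m.reactions),
            "input_binding": {k: v for k, v in m.input_binding},
            "output": {m.output_id: m.output_species},
            "enzymes": list(m.enzymes),
            "required_internals": list(m.required_internals),
            "context_score": m.context_score}


def circuit_to_jsonable(c: gatedesign.CircuitImplementation) -> dict:
    return {"gates": [motif_to_jsonable(g) for g in c.gates],
            "wiring": dict(c.wiring),
            "input_species": dict(c.input_species),
            "output_species": dict(c.output_species),
            "entities": sorted(c.species_set),
            "enzymes": sorted(c.enzyme_set),
            "n_entities": c.n_entities, "n_enzymes": c.n_enzymes}


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True),
                    encoding="utf-8")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Pipeline:
    """Stage runner over either a named fixture or a network file."""

    def __init__(self, config: dict, out_dir: str | Path):
        self.config = dict(config)
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.seed = int(config.get("seed", 0))
        self.fixture = None
        self.network = None
        if "fixture" in config:
            self.fixture = load_fixture(config["fixture"])
            self.network = self.fixture.network
        elif "network" in config:
            self.network = read_network(config["network"],
                                        config.get("dialect", "json"))
        else:
            raise ProtoforgeError("config must name a 'fixture' or 'network'")
        self.library: list[gatedesign.GateMotif] = []
        self.circuit = None
        self.params = None

    # -- stages --------------------------------------------------------------

    def stage_mine(self):
        max_rxn = int(self.config.get("max_reactions", 2))
        self.library = []
        for gate in self.config.get("gate_tables", ("BUF", "AND")):
            self.library.extend(
                gatedesign.mine_gates(self.network, gate_table(gate),
                                      max_rxn))
        path = self.out / "motifs.json"
        _write_json(path, {"count": len(self.library),
                           "motifs": [motif_to_jsonable(m)
                                      for m in self.library]})
        return [path]

    def stage_build(self):
        if not self.library:
            self.stage_mine()
        if self.fixture is not None:
            spec = self.fixture.design.table
            shared = self.fixture.shared_cofactors
        else:
            raise ProtoforgeError(
                "build stage requires a fixture (or spec) configuration")
        circuits = gatedesign.build_circuits(self.library, spec,
                                             shared_cofactors=shared)
        path = self.out / "circuits.json"
        _write_json(path, {"diagnostic": circuits.diagnostic,
                           "circuits": [circuit_to_jsonable(c)
                                        for c in circuits]})
        if circuits:
            self.circuit = circuits[0]
        return [path]

    def _require_fixture(self, stage):
        if self.fixture is None:
            raise ProtoforgeError(f"stage {stage!r} requires a fixture")
        return self.fixture

    def stage_sensitivity(self):
        fx = self._require_fixture("sensitivity")
        ranking = designopt.sensitivity_rank(fx)
        path = self.out / "sensitivity.json"
        _write_json(path, [{"name": e.name, "score": e.score,
                            "grid": list(e.grid), "sds": list(e.sds)}
                           for e in ranking.ranked()])
        self._top2 = ranking.top(2)
        return [path]

    def stage_landscape(self):
        fx = self._require_fixture("landscape")
        p1, p2 = getattr(self, "_top2", None) or fx.tunables[:2]
        pts = int(self.config.get("landscape_points", 7))
        g1 = fx.nominal[p1] * np.logspace(-2, 1, pts)
        g2 = fx.nominal[p2] * np.logspace(-2, 1, pts)
        lmap = designopt.landscape_map(fx, p1, p2, g1, g2)
        csv = self.out / "landscape.csv"
        lmap.to_frame().to_csv(csv, index=False)
        png = self.out / "landscape.png"
        lmap.plot(png)
        return [csv, png]

    def stage_optimize(self):
        fx = self._require_fixture("optimize")
        res = designopt.optimize_parameters(
            fx, seed=self.seed,
            budget=int(self.config.get("budget", 15)))
        self.params = res.best_params
        path = self.out / "optimization.json"
        _write_json(path, {"best_params": res.best_params,
                           "best_sd": res.best_sd,
                           "best_margin": res.best_margin,
                           "evaluations": res.evaluations,
                           "seed": res.seed, "history": res.history,
                           "warning": res.warning})
        return [path]

    def stage_truthtable(self):
        fx = self._require_fixture("truthtable")
        obs = fx.observed_table(params=self.params)
        path = self.out / "truthtable.json"
        _write_json(path, {
            "inputs": list(obs.input_ids), "outputs": list(obs.output_ids),
            "t_read_s": obs.t_read,
            "rows": [{"inputs": list(bits), "outputs": list(out),
                      "margins": obs.margins[bits],
                      "readouts": obs.readouts[bits]}
                     for bits, out in sorted(obs.rows.items())],
            "matches_spec": obs.matches(fx.design.table.rows)})
        return [path]

    def stage_report(self):
        return []

    # -- driver --------------------------------------------------------------

    def run(self, stages=None) -> Path:
        stages = list(stages or self.config.get("stages", STAGES))
        artifacts = []
        log = []
        for stage in stages:
            if stage not in STAGES:
                raise ProtoforgeError(f"unknown stage {stage!r}; "
                                      f"valid: {STAGES}")
            produced = getattr(self, f"stage_{stage}")()
            artifacts.extend(produced)
            log.append({"stage": stage,
                        "artifacts": [p.name for p in produced]})
        manifest = {
            "config": {k: v for k, v in self.config.items()},
            "stages": log,
            "checksums": {p.name: _sha256(p) for p in artifacts},
            "timestamp": datetime.datetime.now().isoformat(),  # excluded
        }
        _write_json(self.out / "manifest.json", manifest)
        return self.out


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Execute the configured stages; returns the report directory."""
    return Pipeline(config, out_dir).run()
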