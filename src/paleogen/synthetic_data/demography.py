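"""Declarative demography: a population tree with drift edges and
admixture nodes, plus per-leaf sampling specs.

Config files are plain YAML::

    seed: 7
    sites: 5000
    genome: {"1": 100000000, "2": 100000000}
    ts_tv_ratio: 2.0
    root: {name: R, freq: [0.05, 0.95]}
    edges:
      - {child: A, parent: R, F: 0.1}
      - {child: B, parent: R, F: 0.1}
    admixtures:
      - {child: X, parents: [A, B], alpha: 0.5}
    samples:
      - {population: A, n: 10, ploidy: 2, class: modern}
      - {population: X, n: 1, ploidy: 1, class: ancient}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ..errors import ValidationError

__all__ = ["DriftEdge", "AdmixtureEdge", "SampleSpec", "DemographyGraph"]


@dataclass(frozen=True)
class DriftEdge:
    child: str
    parent: str
    f: float  # Balding-Nichols drift, in [0, 1)

    def __post_init__(self):
        if not 0.0 <= self.f < 1.0:
            raise ValidationError(f"edge {self.parent}->{self.child}: F must be in [0,1)")


@dataclass(frozen=True)
class AdmixtureEdge:
    child: str
    parent1: str
    parent2: str
    alpha: float  # proportion from parent1

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"admixture node {self.child}: alpha must be in [0,1]")


@dataclass(frozen=True)
class SampleSpec:
    population: str
    n: int
    ploidy: int = 2
    sample_class: str = "modern"

    def __post_init__(self):
        if self.n < 0:
            raise ValidationError("sample count must be >= 0")
        if self.ploidy not in (1, 2):
            raise ValidationError("ploidy must be 1 or 2")


@dataclass
class DemographyGraph:
    root: str
    drift_edges: list[DriftEdge] = field(default_factory=list)
    admixture_edges: list[AdmixtureEdge] = field(default_factory=list)
    samples: list[SampleSpec] = field(default_factory=list)
    root_freq: tuple[float, float] = (0.05, 0.95)
    genome: dict[str, int] = field(default_factory=lambda: {"1": 100_000_000})
    ts_tv_ratio: float = 2.0

    def __post_init__(self):
        self._parents: dict[str, list[str]] = {}
        for e in self.drift_edges:
            if e.child in self._parents or e.child == self.root:
                raise ValidationError(f"node {e.child} has more than one incoming edge")
            self._parents[e.child] = [e.parent]
        for e in self.admixture_edges:
            if e.child in self._parents or e.child == self.root:
                raise ValidationError(f"node {e.child} has more than one incoming edge")
            self._parents[e.child] = [e.parent1, e.parent2]
        lo, hi = self.root_freq
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValidationError("root frequency bounds must satisfy 0 <= lo <= hi <= 1")
        for name, length in self.genome.items():
            if length < 1:
                raise ValidationError(f"chromosome {name}: length must be >= 1")
        if self.ts_tv_ratio < 0:
            raise ValidationError("ts_tv_ratio must be >= 0")
        self.topological_order()  # raises on cycles / unknown parents
        known = set(self.nodes)
        for s in self.samples:
            if s.population not in known:
                raise ValidationError(f"sample population {s.population!r} not in graph")

    @property
    def nodes(self) -> list[str]:
        out = [self.root]
        for e in self.drift_edges:
            out.append(e.child)
        for e in self.admixture_edges:
            out.append(e.child)
        return out

    def topological_order(self) -> list[str]:
        """Nodes ordered so every parent precedes its children."""
        order: list[str] = []
        done: set[str] = set()
        visiting: set[str] = set()

        def visit(node: str):
            if node in done:
                return
            if node in visiting:
                raise ValidationError(f"demography graph has a cycle through {node!r}")
            visiting.add(node)
            for p in self._parents.get(node, []):
                if p != self.root and p not in self._parents:
                    raise ValidationError(f"unknown parent node {p!r}")
                visit(p)
            visiting.discard(node)
            done.add(node)
            order.append(node)

        visit(self.root)
        for child in self._parents:
            visit(child)
        return order

    def parents_of(self, node: str) -> list[str]:
        return self._parents.get(node, [])

    # -- construction from config --------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "DemographyGraph":
        root_spec = d.get("root", {})
        if isinstance(root_spec, str):
            root_spec = {"name": root_spec}
        genome = {str(k): int(v) for k, v in d.get("genome", {"1": 100_000_000}).items()}
        return cls(
            root=root_spec.get("name", "root"),
            drift_edges=[
                DriftEdge(e["child"], e["parent"], float(e.get("F", e.get("f", 0.0))))
                for e in d.get("edges", [])
            ],
            admixture_edges=[
                AdmixtureEdge(e["child"], e["parents"][0], e["parents"][1],
                              float(e["alpha"]))
                for e in d.get("admixtures", [])
            ],
            samples=[
                SampleSpec(s["population"], int(s["n"]), int(s.get("ploidy", 2)),
                           s.get("class", "modern"))
                for s in d.get("samples", [])
            ],
            root_freq=tuple(root_spec.get("freq", (0.05, 0.95))),
            genome=genome,
            ts_tv_ratio=float(d.get("ts_tv_ratio", 2.0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> tuple["DemographyGraph", dict]:
        """Load graph from YAML; returns (graph, full config dict)."""
        with open(path) as fh:
            config = yaml.safe_load(fh) or {}
        return cls.from_dict(config), config
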