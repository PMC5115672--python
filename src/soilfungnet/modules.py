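"""Module extraction from positive co-occurrence networks.

A *module* is operationally defined as a connected sub-community of the
positive association network carrying two or more positive co-occurrence
links (i.e., a connected component whose induced edge count is at least
2).  Components consisting of a single linked pair, and isolated nodes,
are reported separately as non-module residue.  No statistical modularity
optimisation is attempted: these networks are typically too fragmented
for that, and the component rule matches how the clusters are read off
the drawn networks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .cooccur import AssociationGraph
from .io import OtuAnnotation

__all__ = ["Module", "ModuleSet", "extract_modules", "summarize_modules"]


@dataclass
class Module:
    """One module: its member OTUs and induced positive-edge count."""

    module_id: int
    members: frozenset[str]
    n_edges: int

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ModuleSet:
    """Partition of a positive network into modules and residue."""

    modules: list[Module]
    residual_pairs: list[tuple[str, str]] = field(default_factory=list)
    isolated_nodes: list[str] = field(default_factory=list)
    method: str | None = None
    depth_class: str | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.modules:
            if m.n_edges < 2:
                raise ValueError(f"module {m.module_id} has fewer than 2 edges")
            if seen & m.members:
                raise ValueError("modules are not disjoint")
            seen |= m.members

    def all_nodes(self) -> set[str]:
        nodes = set(self.isolated_nodes)
        for m in self.modules:
            nodes |= m.members
        for a, b in self.residual_pairs:
            nodes |= {a, b}
        return nodes


def extract_modules(graph: AssociationGraph) -> ModuleSet:
    """Connected components of a positive network, filtered by edge count.

    Components with >= 2 induced edges become modules (largest first,
    ties broken lexicographically by membership); single-edge pairs and
    isolated nodes are residue.  Raises if the graph carries negative
    edges - filter with ``graph.filter_sign('+')`` first.
    """
    negatives = [e for e in graph.edges if e[3] == "-"]
    if negatives:
        raise ValueError(
            f"{len(negatives)} negative edge(s) present; module extraction is "
            "defined on positive networks only (filter_sign('+') first)"
        )
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from((a, b) for a, b, _, _ in graph.edges)
    modules = []
    residual_pairs = []
    isolated = []
    components = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        components.append((set(comp), sub.number_of_edges()))
    components.sort(key=lambda c: (-len(c[0]), tuple(sorted(c[0]))))
    for members, n_edges in components:
        if n_edges >= 2:
            modules.append(Module(module_id=len(modules) + 1, members=frozenset(members), n_edges=n_edges))
        elif n_edges == 1:
            a, b = sorted(members)
            residual_pairs.append((a, b))
        else:
            isolated.extend(sorted(members))
    return ModuleSet(
        modules=modules,
        residual_pairs=sorted(residual_pairs),
        isolated_nodes=sorted(isolated),
        method=graph.method,
        depth_class=graph.depth_class,
    )


def summarize_modules(
    mods: ModuleSet, annotations: list[OtuAnnotation] | None = None
) -> pd.DataFrame:
    """Per-module summary: size, edge count, guild and taxonomy makeup.

    Missing annotations count as ``unassigned`` / ``unidentified``.
    Rows are ordered by module size (descending) then module id.
    """
    by_id = {a.otu_id: a for a in annotations or []}
    rows = []
    ordered = sorted(mods.modules, key=lambda m: (-m.size, m.module_id))
    for m in ordered:
        guilds = Counter(
            by_id[o].guild if o in by_id else "unassigned" for o in sorted(m.members)
        )
        taxa = Counter(
            by_id[o].lowest_rank() if o in by_id else "unidentified" for o in sorted(m.members)
        )
        rows.append(
            {
                "module_id": m.module_id,
                "size": m.size,
                "n_edges": m.n_edges,
                "members": ";".join(sorted(m.members)),
                "guilds": ";".join(f"{g}:{c}" for g, c in sorted(guilds.items())),
                "taxa": ";".join(f"{t}:{c}" for t, c in sorted(taxa.items())),
            }
        )
    columns = ["module_id", "size", "n_edges", "members", "guilds", "taxa"]
    return pd.DataFrame(rows, columns=columns)
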