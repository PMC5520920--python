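"""Turn per-layer differential records into a seed-plus-neighbors network."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from omicnet.io import Interactome, canonical_symbol

log = logging.getLogger(__name__)


class SeedError(ValueError):
    pass


@dataclass(frozen=True)
class LayerRecord:
    """One feature's differential evidence in one omic layer."""

    symbol: str
    layer: str
    p_value: float | None
    direction: int


@dataclass
class SeedSet:
    """Symbols selected as network seeds, with per-layer provenance."""

    records: dict[str, list[LayerRecord]]

    def __post_init__(self) -> None:
        if not self.records:
            raise SeedError("empty seed set")
        if any(not v for v in self.records.values()):
            raise SeedError("seed without a layer record")

    @property
    def symbols(self) -> set[str]:
        return set(self.records)


@dataclass
class SeedNetwork:
    """Seeds plus their immediate interactome neighbors."""

    graph: nx.Graph
    roles: dict[str, str]  # node -> "seed" | "neighbor"
    annotations: dict[str, list[LayerRecord]]
    n_seeds_missing: int = 0

    @property
    def seeds(self) -> set[str]:
        return {n for n, r in self.roles.items() if r == "seed"}

    @property
    def neighbors(self) -> set[str]:
        return {n for n, r in self.roles.items() if r == "neighbor"}


def select_seeds(
    layers: list[LayerRecord] | list, thresholds: dict[str, float | None]
) -> SeedSet:
    """Union across layers of features passing their layer threshold.

    A numeric threshold keeps records with ``p < threshold``; ``None`` means
    "reported as changed" — mere presence in the layer's differential table
    qualifies. Records from layers absent in ``thresholds`` are ignored.
    """
    records: dict[str, list[LayerRecord]] = {}
    for rec in layers:
        if not isinstance(rec, LayerRecord):  # e.g. diffexpr.DEResult
            rec = LayerRecord(
                symbol=rec.symbol,
                layer=rec.layer,
                p_value=getattr(rec, "p_value", None),
                direction=getattr(rec, "direction", 0),
            )
        if rec.layer not in thresholds:
            continue
        thr = thresholds[rec.layer]
        if thr is not None:
            if thr <= 0:
                continue
            if rec.p_value is None or rec.p_value >= thr:
                continue
        sym = canonical_symbol(rec.symbol)
        records.setdefault(sym, []).append(rec)
    if not records:
        raise SeedError("no feature passes any layer threshold")
    return SeedSet(records)


def build_seed_network(
    interactome: Interactome, seeds: SeedSet, edges: str = "induced"
) -> SeedNetwork:
    """Subgraph on seeds and their immediate neighbors.

    ``edges="induced"`` keeps every interactome edge among the selected nodes
    (including neighbor–neighbor edges, which module detection needs);
    ``edges="star"`` keeps only seed-incident edges. Seeds absent from the
    interactome are counted and logged; seeds present but isolated are
    retained as isolated nodes.
    """
    if edges not in ("induced", "star"):
        raise SeedError(f"unknown edge rule {edges!r}")
    g = interactome.graph
    present = seeds.symbols & set(g.nodes)
    missing = seeds.symbols - present
    if missing:
        log.info("%d seed(s) absent from the interactome", len(missing))
    if not present:
        raise SeedError("no seed maps to the interactome")
    nodes = set(present)
    for s in present:
        nodes.update(g.neighbors(s))
    if edges == "induced":
        sub = g.subgraph(nodes).copy()
    else:
        sub = nx.Graph()
        sub.add_nodes_from(nodes)
        sub.add_edges_from(
            (s, v, g[s][v]) for s in present for v in g.neighbors(s)
        )
    roles = {n: ("seed" if n in present else "neighbor") for n in nodes}
    annotations = {n: seeds.records.get(n, []) for n in nodes}
    return SeedNetwork(
        graph=sub, roles=roles, annotations=annotations, n_seeds_missing=len(missing)
    )
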