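"""Overlapping community detection via an influence landscape.

Each link injects influence proportional to the neighborhood similarity of
its endpoints; the influence spreads over a bounded number of steps with
per-step attenuation, degree-normalized, and each node's height is the
influence it received per unit strength. Module cores are the local maxima
of the height landscape (plateaus resolved lexicographically); overlapping
membership is solved as a diffusion from the cores through non-descending
height neighborhoods. Everything is deterministic — no RNG in this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_STEPS = 3
DEFAULT_ATTENUATION = 0.5

#: heights are quantized before comparison so symmetric nodes land on exact
#: plateaus despite float summation order
_QUANT = 1e-9

#: equal-height local maxima are merged into one plateau only when the edge
#: joining them is non-negligible next to their strongest incident edges
_PLATEAU_EDGE_FRACTION = 0.05


class ModuleError(ValueError):
    pass


@dataclass
class ModuleSet:
    """Overlapping modules: membership matrix, cores, centrality, hierarchy."""

    membership: pd.DataFrame  # nodes x modules; columns labeled by core symbol
    heights: pd.Series
    graph: nx.Graph
    parent: dict[str, str] = field(default_factory=dict)  # label -> next-level label

    @property
    def cores(self) -> list[str]:
        return list(self.membership.columns)

    @property
    def centrality(self) -> pd.Series:
        """Summed membership mass per module."""
        return self.membership.sum(axis=0)

    @property
    def n_modules(self) -> int:
        return self.membership.shape[1]

    def ranked(self) -> list[str]:
        """Module labels by descending centrality, alphabetical tie-break."""
        cent = self.centrality
        return sorted(cent.index, key=lambda c: (-cent[c], c))

    def hard_members(self, rel_threshold: float = 0.1) -> dict[str, set[str]]:
        """Member sets: nodes whose relative membership reaches the threshold."""
        totals = self.membership.sum(axis=1)
        rel = self.membership.div(totals.where(totals > 0, 1.0), axis=0)
        return {
            c: set(rel.index[rel[c] >= rel_threshold]) for c in self.membership.columns
        }


def _as_graph(network) -> nx.Graph:
    g = network if isinstance(network, nx.Graph) else network.graph
    if g.number_of_nodes() == 0:
        raise ModuleError("empty graph")
    return g


def community_landscape(
    network, steps: int = DEFAULT_STEPS, attenuation: float = DEFAULT_ATTENUATION
) -> pd.Series:
    """Per-node height of the influence landscape.

    Invariant under node relabeling and under uniform edge-weight scaling.
    Isolated nodes get height 0.
    """
    g = _as_graph(network)
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        wt = float(data.get("weight", 1.0))
        i, j = index[u], index[v]
        w[i, j] = w[j, i] = wt
    # closed-neighborhood weight vectors: self-weight = max incident weight,
    # so the weighted Jaccard reduces to the set Jaccard on unweighted graphs
    closed = w.copy()
    np.fill_diagonal(closed, w.max(axis=1))
    inject = np.zeros(n)
    for u, v in g.edges():
        i, j = index[u], index[v]
        denom = np.maximum(closed[i], closed[j]).sum()
        jac = np.minimum(closed[i], closed[j]).sum() / denom if denom > 0 else 0.0
        inject[i] += w[i, j] * jac
        inject[j] += w[i, j] * jac
    strength = w.sum(axis=1)
    safe = np.where(strength > 0, strength, 1.0)
    received = inject.copy()
    x = inject
    for _ in range(steps):
        x = attenuation * (w @ (x / safe))
        received = received + x
    h = np.where(strength > 0, received / safe, 0.0)
    return pd.Series(h, index=nodes)


def _plateau_cores(g: nx.Graph, hq: dict) -> tuple[list[str], dict[str, str]]:
    """Local maxima of the quantized landscape; one core per plateau component.

    Returns (core labels, candidate -> its plateau core).
    """
    candidates = [
        n for n in sorted(g.nodes) if all(hq[n] >= hq[m] for m in g.neighbors(n))
    ]
    max_w = {
        n: max((float(g[n][m].get("weight", 1.0)) for m in g.neighbors(n)), default=0.0)
        for n in g.nodes
    }
    plateau = nx.Graph()
    plateau.add_nodes_from(candidates)
    cset = set(candidates)
    for n in candidates:
        for m in g.neighbors(n):
            if m not in cset or hq[m] != hq[n]:
                continue
            wt = float(g[n][m].get("weight", 1.0))
            if wt >= _PLATEAU_EDGE_FRACTION * max(max_w[n], max_w[m]):
                plateau.add_edge(n, m)
    cores, core_of = [], {}
    for comp in nx.connected_components(plateau):
        core = min(comp)
        cores.append(core)
        for n in comp:
            core_of[n] = core
    return sorted(cores), core_of


def detect_modules(
    network, steps: int = DEFAULT_STEPS, attenuation: float = DEFAULT_ATTENUATION
) -> ModuleSet:
    """Overlapping modules of the landscape: cores plus diffused membership.

    Cores carry unit membership in their own module. Every other node's
    membership vector is the edge-weight-weighted average of the membership
    vectors of its non-descending-height neighbors (the linear system is
    solved exactly), so every node ends with total membership 1.
    """
    g = _as_graph(network)
    h = community_landscape(g, steps=steps, attenuation=attenuation)
    hq = {n: round(v / _QUANT) * _QUANT for n, v in h.items()}
    cores, _ = _plateau_cores(g, hq)

    nodes = sorted(g.nodes)
    k = len(cores)
    core_idx = {c: j for j, c in enumerate(cores)}
    noncore = [n for n in nodes if n not in core_idx]
    nc_idx = {n: i for i, n in enumerate(noncore)}

    m = np.zeros((len(nodes), k))
    node_pos = {n: i for i, n in enumerate(nodes)}
    for c, j in core_idx.items():
        m[node_pos[c], j] = 1.0

    if noncore:
        a = np.zeros((len(noncore), len(noncore)))
        b = np.zeros((len(noncore), k))
        for n in noncore:
            i = nc_idx[n]
            up = [
                (v, float(g[n][v].get("weight", 1.0)))
                for v in g.neighbors(n)
                if hq[v] >= hq[n]
            ]
            total = sum(wt for _, wt in up)
            if not up or total <= 0:
                raise ModuleError(f"node {n!r} has no non-descending neighbor")
            for v, wt in up:
                if v in core_idx:
                    b[i, core_idx[v]] += wt / total
                else:
                    a[i, nc_idx[v]] += wt / total
        sol = np.linalg.solve(np.eye(len(noncore)) - a, b)
        for n in noncore:
            m[node_pos[n]] = sol[nc_idx[n]]

    membership = pd.DataFrame(m, index=nodes, columns=cores)
    return ModuleSet(membership=membership, heights=h, graph=g)


def rank_modules(ms: ModuleSet, top_k: int | None = None) -> list[dict]:
    """Modules ordered by descending centrality (alphabetical tie-break).

    Labels are core symbols. Requesting more modules than exist returns all
    of them with a log message.
    """
    if ms.n_modules == 0:
        raise ModuleError("module set is empty")
    order = ms.ranked()
    if top_k is not None and top_k > len(order):
        log.info("top_k=%d exceeds module count %d; returning all", top_k, len(order))
    if top_k is not None:
        order = order[:top_k]
    cent = ms.centrality
    sizes = {c: len(v) for c, v in ms.hard_members().items()}
    return [
        {"rank": r + 1, "module": c, "core": c,
         "centrality": float(cent[c]), "size": sizes[c]}
        for r, c in enumerate(order)
    ]


def build_hierarchy(
    ms: ModuleSet,
    levels: int = 5,
    steps: int = DEFAULT_STEPS,
    attenuation: float = DEFAULT_ATTENUATION,
) -> list[ModuleSet]:
    """Coarsen modules level by level.

    The meta-network has one node per module; the meta-edge weight between
    two modules is their shared membership mass plus the weight of any edge
    joining their cores. Detection is re-applied per level until one module
    remains, the module count stops shrinking, or ``levels`` is reached.
    """
    out = [ms]
    current = ms
    for _ in range(max(0, levels - 1)):
        if current.n_modules <= 1:
            break
        meta = nx.Graph()
        meta.add_nodes_from(current.cores)
        memb = current.membership
        for i, c in enumerate(current.cores):
            for d in current.cores[i + 1 :]:
                wt = float((memb[c] * memb[d]).sum())
                if current.graph.has_edge(c, d):
                    wt += float(current.graph[c][d].get("weight", 1.0))
                if wt > 0:
                    meta.add_edge(c, d, weight=wt)
        nxt = detect_modules(meta, steps=steps, attenuation=attenuation)
        # link each module to the meta-module holding most of its mass
        current.parent = {
            c: nxt.membership.loc[c].idxmax() for c in current.cores
        }
        if nxt.n_modules >= current.n_modules:
            break
        out.append(nxt)
        current = nxt
    return out
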