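"""Synthetic inputs: planted-module interactomes, correlated omic layers,
and toy multi-exon gene models.

All randomness flows through one explicit seed per generator call; identical
specs and seeds give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from omicnet.io import Interactome
from omicnet.splice import Exon, GeneModel, STOP_CODONS

log = logging.getLogger(__name__)

_LAYERS = ("transcript", "protein", "phosphosite")


class SpecError(ValueError):
    """Infeasible generator specification."""


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """An interactome with planted overlapping modules.

    Adjacent planted modules share ``overlap_fraction`` of the later module's
    nodes; within-module pairs connect with ``p_in``, all other pairs with
    ``p_out``.
    """

    n_nodes: int
    module_sizes: tuple[int, ...]
    overlap_fraction: float = 0.0
    p_in: float = 0.9
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.module_sizes or any(s < 1 for s in self.module_sizes):
            raise SpecError("module sizes must be positive")
        if not 0 <= self.overlap_fraction < 1:
            raise SpecError("overlap_fraction must lie in [0, 1)")
        if not self.p_in > self.p_out:
            raise SpecError("p_in must exceed p_out")
        if not (0 <= self.p_out and self.p_in <= 1):
            raise SpecError("edge probabilities must lie in [0, 1]")
        overlaps = sum(
            int(round(self.overlap_fraction * s)) for s in self.module_sizes[1:]
        )
        if sum(self.module_sizes) - overlaps > self.n_nodes:
            raise SpecError("module sizes minus overlaps exceed n_nodes")


@dataclass(frozen=True)
class PlantedOmicsSpec:
    """Two-condition omic layers with effects planted in chosen modules."""

    n_samples_per_group: int
    effect_size: float
    noise_sd: float = 1.0
    layers: tuple[str, ...] = _LAYERS
    perturbed_modules: tuple[int, ...] = ()
    concordance: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 2:
            raise SpecError("need at least two samples per group")
        if self.effect_size < 0:
            raise SpecError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise SpecError("noise_sd must be positive")
        if set(self.layers) - set(_LAYERS):
            raise SpecError(f"layers must be a subset of {_LAYERS}")
        if not 0 <= self.concordance <= 1:
            raise SpecError("concordance must lie in [0, 1]")


def generate_interactome(
    spec: PlantedNetworkSpec,
) -> tuple[Interactome, pd.DataFrame]:
    """Planted-partition interactome with overlapping modules.

    Returns the graph plus a truth table mapping each node symbol to its
    planted module indices (comma-joined, empty for background nodes).
    """
    rng = np.random.default_rng(spec.seed)
    symbols = [f"G{i:04d}" for i in range(spec.n_nodes)]

    assignment: dict[str, list[int]] = {s: [] for s in symbols}
    cursor = 0
    prev_members: list[str] = []
    for mi, size in enumerate(spec.module_sizes):
        n_shared = int(round(spec.overlap_fraction * size)) if mi > 0 else 0
        members = prev_members[-n_shared:] if n_shared else []
        fresh = symbols[cursor : cursor + size - len(members)]
        if len(fresh) < size - len(members):
            raise SpecError("module sizes minus overlaps exceed n_nodes")
        cursor += len(fresh)
        members = members + fresh
        for s in members:
            assignment[s].append(mi)
        prev_members = members

    g = nx.Graph()
    g.add_nodes_from(symbols)
    n = len(symbols)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = symbols[i], symbols[j]
            within = bool(set(assignment[a]) & set(assignment[b]))
            p = spec.p_in if within else spec.p_out
            if rng.random() < p:
                g.add_edge(a, b, provenance="planted" if within else "background")

    truth = pd.DataFrame(
        {
            "symbol": symbols,
            "modules": [",".join(map(str, assignment[s])) for s in symbols],
        }
    )
    itx = Interactome(g, name=f"planted(seed={spec.seed})")
    return itx, truth


def planted_module_members(truth: pd.DataFrame) -> dict[int, set[str]]:
    """Invert a truth table into module-index -> member-symbol sets."""
    out: dict[int, set[str]] = {}
    for _, row in truth.iterrows():
        if not row["modules"]:
            continue
        for mi in str(row["modules"]).split(","):
            out.setdefault(int(mi), set()).add(row["symbol"])
    return out


def generate_omics(
    truth: pd.DataFrame, spec: PlantedOmicsSpec
) -> tuple[dict[str, pd.DataFrame], list[str], pd.DataFrame]:
    """Layered feature-by-sample tables with effects planted per module.

    Features in perturbed modules get a group-mean difference of
    ``effect_size`` (in expectation) with a random sign on the transcript
    layer; the other layers copy that sign for a ``concordance`` fraction of
    features and flip it otherwise. Returns (layer tables, per-sample group
    labels, per-feature truth).
    """
    members = planted_module_members(truth)
    unknown = set(spec.perturbed_modules) - set(members)
    if unknown:
        raise SpecError(f"unknown module index(es): {sorted(unknown)}")
    perturbed = set()
    for mi in spec.perturbed_modules:
        perturbed |= members[mi]

    symbols = list(truth["symbol"])
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples_per_group
    samples = [f"A{i + 1}" for i in range(n)] + [f"B{i + 1}" for i in range(n)]
    groups = ["A"] * n + ["B"] * n

    base_dir = pd.Series(
        rng.choice([-1, 1], size=len(symbols)), index=symbols
    )
    tables: dict[str, pd.DataFrame] = {}
    truth_rows = []
    for layer in spec.layers:
        if layer == "transcript":
            direction = base_dir.copy()
        else:
            flip = rng.random(len(symbols)) >= spec.concordance
            direction = base_dir * np.where(flip, -1, 1)
        x = rng.normal(0.0, spec.noise_sd, size=(len(symbols), 2 * n))
        for i, s in enumerate(symbols):
            if s in perturbed:
                x[i, n:] += spec.effect_size * direction[s]
        tables[layer] = pd.DataFrame(x, index=symbols, columns=samples)
        for s in symbols:
            truth_rows.append(
                {
                    "symbol": s,
                    "layer": layer,
                    "perturbed": s in perturbed,
                    "direction": int(direction[s]) if s in perturbed else 0,
                }
            )
    return tables, groups, pd.DataFrame(truth_rows)


def generate_gene_model(
    exon_lengths,
    cds_span: tuple[int, int] | None = None,
    seed: int = 0,
    symbol: str = "SYNGENE",
    exon_ids=None,
) -> GeneModel:
    """Random-sequence gene model with the given exon lengths.

    ``cds_span`` is a 0-based half-open transcript interval (defaults to the
    whole transcript trimmed to a codon multiple); the generated CDS starts
    with ATG, ends with a stop codon, and has no internal stop.
    """
    lengths = [int(x) for x in exon_lengths]
    if not lengths or any(x <= 0 for x in lengths):
        raise SpecError("exon lengths must be positive")
    total = sum(lengths)
    if cds_span is None:
        cds_span = (0, total - total % 3)
    start, end = cds_span
    if not (0 <= start < end <= total):
        raise SpecError("CDS span exceeds transcript length")
    if (end - start) % 3 != 0:
        raise SpecError("CDS length must be a codon multiple")
    if end - start < 6:
        raise SpecError("CDS too short for start and stop codons")

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    non_stop = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in STOP_CODONS
    ]
    seq = list(rng.choice(bases, size=total))
    seq[start : start + 3] = list("ATG")
    for pos in range(start + 3, end - 3, 3):
        seq[pos : pos + 3] = list(non_stop[rng.integers(len(non_stop))])
    seq[end - 3 : end] = list("TAA")
    transcript = "".join(seq)

    if exon_ids is None:
        exon_ids = [str(i + 1) for i in range(len(lengths))]
    if len(exon_ids) != len(lengths):
        raise SpecError("one exon id per exon length required")
    exons, g_pos, t_pos = [], 1, 0
    intron = 100  # fixed cosmetic gap between exons on the synthetic locus
    for eid, ln in zip(exon_ids, lengths):
        exons.append(
            Exon(str(eid), g_pos, g_pos + ln - 1, transcript[t_pos : t_pos + ln])
        )
        g_pos += ln + intron
        t_pos += ln
    return GeneModel(symbol=symbol, exons=exons, cds_start=start, cds_end=end)
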