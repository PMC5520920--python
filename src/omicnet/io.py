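"""Readers/writers for the formats the pipeline touches.

BioGRID TAB3-style interaction TSVs (plus a plain edge-list fallback), GMT
gene signatures, TSV feature-by-sample matrices with an optional ``#group``
header line, GFF3+FASTA gene models, and a JSON results bundle.

Symbols are canonicalized to uppercase throughout; every discarded record
(self-loop, duplicate, constant row, …) is counted and logged, never silently
dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from omicnet.splice import Exon, GeneModel, SpliceError

log = logging.getLogger(__name__)

#: BioGRID TAB3 column names consumed by the reader.
_TAB3_A = "Official Symbol Interactor A"
_TAB3_B = "Official Symbol Interactor B"
_TAB3_SYSTEM = "Experimental System"


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


def canonical_symbol(symbol: str) -> str:
    """Uppercase official-symbol canonicalization."""
    s = str(symbol).strip().upper()
    if not s:
        raise FormatError("empty symbol")
    return s


@dataclass
class Interactome:
    """Undirected, deduplicated interaction graph over canonical symbols."""

    graph: nx.Graph
    name: str = "interactome"
    n_self_loops_dropped: int = 0
    n_duplicates_dropped: int = 0

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, str]], name: str = "interactome"
    ) -> "Interactome":
        """Build from (symbol A, symbol B, provenance) triples."""
        g = nx.Graph()
        loops = dups = 0
        for a, b, prov in edges:
            a, b = canonical_symbol(a), canonical_symbol(b)
            if a == b:
                loops += 1
                continue
            if g.has_edge(a, b):
                dups += 1
                continue
            g.add_edge(a, b, provenance=prov)
        if loops:
            log.info("%s: dropped %d self-loop(s)", name, loops)
        if dups:
            log.info("%s: dropped %d duplicate edge(s)", name, dups)
        return cls(g, name, loops, dups)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class Signature:
    """A named gene set (GMT line)."""

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"signature {self.name!r} has no members")


def read_interactome(path: str | Path, format: str = "biogrid_tab3") -> Interactome:
    """Read an interactome from ``biogrid_tab3`` or 2/3-column ``edge_tsv``."""
    path = Path(path)
    if format == "biogrid_tab3":
        try:
            df = pd.read_csv(path, sep="\t", dtype=str)
        except pd.errors.EmptyDataError as e:
            raise FormatError(f"{path}: empty file") from e
        if df.empty:
            raise FormatError(f"{path}: no interactions")
        missing = {_TAB3_A, _TAB3_B} - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
        system = df[_TAB3_SYSTEM] if _TAB3_SYSTEM in df.columns else "unknown"
        df = df.assign(_system=system)
        triples = df[[_TAB3_A, _TAB3_B, "_system"]].itertuples(index=False)
    elif format == "edge_tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype=str, comment="#", header=None)
        except pd.errors.EmptyDataError as e:
            raise FormatError(f"{path}: empty file") from e
        if df.empty:
            raise FormatError(f"{path}: no interactions")
        if df.shape[1] < 2:
            raise FormatError(f"{path}: need at least two columns")
        prov = df[2] if df.shape[1] > 2 else "unknown"
        triples = df.assign(_p=prov)[[0, 1, "_p"]].itertuples(index=False)
    else:
        raise FormatError(f"unknown interactome format {format!r}")
    return Interactome.from_edges(triples, name=path.name)


def write_interactome(itx: Interactome, path: str | Path) -> None:
    """Write a BioGRID TAB3-like TSV (symbols, experimental system, source)."""
    rows = [
        {
            _TAB3_A: a,
            _TAB3_B: b,
            _TAB3_SYSTEM: d.get("provenance", "unknown"),
            "Source Database": itx.name,
        }
        for a, b, d in itx.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=[_TAB3_A, _TAB3_B, _TAB3_SYSTEM, "Source Database"]).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path: str | Path) -> list[Signature]:
    """Read a GMT file (name, description, tab-separated members)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT line needs name, description, members")
            members, seen = [], set()
            for m in parts[2:]:
                if not m.strip():
                    continue
                m = canonical_symbol(m)
                if m in seen:
                    log.warning("%s:%d: duplicate member %s dropped", path, ln, m)
                    continue
                seen.add(m)
                members.append(m)
            out.append(Signature(parts[0], parts[1], tuple(members)))
    return out


def write_gmt(signatures: Iterable[Signature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in signatures:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def read_matrix(path: str | Path) -> tuple[pd.DataFrame, list[str] | None]:
    """Read a features-by-samples TSV; returns (matrix, per-sample groups).

    A leading ``#group`` line, when present, carries one group label per
    sample column.
    """
    path = Path(path)
    groups = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#group"):
            groups = first.rstrip("\n").split("\t")[1:]
            df = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged rows or missing values")
    if groups is not None and len(groups) != df.shape[1]:
        raise FormatError(f"{path}: group line has {len(groups)} labels for {df.shape[1]} samples")
    return df, groups


def write_matrix(
    matrix: pd.DataFrame, path: str | Path, groups: list[str] | None = None
) -> None:
    with open(path, "w") as fh:
        if groups is not None:
            if len(groups) != matrix.shape[1]:
                raise FormatError("one group label per sample column required")
            fh.write("#group\t" + "\t".join(map(str, groups)) + "\n")
        matrix.to_csv(fh, sep="\t")


def read_gene_model(gff3_path: str | Path, fasta_path: str | Path) -> GeneModel:
    """Assemble a :class:`GeneModel` from a GFF3 + FASTA pair.

    GFF3 coordinates are 1-based inclusive; exon/CDS features must lie within
    the FASTA record for their seqid. The CDS span is converted to 0-based
    half-open transcript coordinates internally.
    """
    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise FormatError(f"{fasta_path}: no FASTA records")
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    exons, cds_spans, symbol = [], [], None
    for f in db.all_features(order_by=("seqid", "start")):
        if f.seqid not in seqs:
            raise FormatError(f"{gff3_path}: seqid {f.seqid!r} absent from FASTA")
        ref = seqs[f.seqid]
        if f.start < 1 or f.end > len(ref):
            raise FormatError(
                f"{gff3_path}: {f.featuretype} {f.start}..{f.end} outside "
                f"{f.seqid} (length {len(ref)})"
            )
        if f.featuretype == "gene":
            symbol = f.attributes.get("Name", [f.id])[0]
        elif f.featuretype == "exon":
            eid = f.attributes.get("ID", [f"exon{len(exons) + 1}"])[0]
            exons.append(Exon(eid.removeprefix("exon:"), f.start, f.end,
                              ref[f.start - 1 : f.end]))
        elif f.featuretype == "CDS":
            cds_spans.append((f.start, f.end))
    if not exons:
        raise FormatError(f"{gff3_path}: no exon features")
    if not cds_spans:
        raise FormatError(f"{gff3_path}: no CDS feature")
    exons.sort(key=lambda e: e.start)
    g_start = min(a for a, _ in cds_spans)
    g_end = max(b for _, b in cds_spans)
    # genomic (1-based) -> transcript (0-based half-open)
    off, t_start, t_end = 0, None, None
    for e in exons:
        if e.start <= g_start <= e.end:
            t_start = off + (g_start - e.start)
        if e.start <= g_end <= e.end:
            t_end = off + (g_end - e.start) + 1
        off += e.length
    if t_start is None or t_end is None:
        raise FormatError(f"{gff3_path}: CDS span not contained in exons")
    sym = canonical_symbol(symbol) if symbol else "GENE"
    return GeneModel(symbol=sym, exons=exons, cds_start=t_start, cds_end=t_end)


def write_gene_model(gm: GeneModel, gff3_path: str | Path, fasta_path: str | Path) -> None:
    """Write the GFF3 + FASTA pair read back by :func:`read_gene_model`."""
    seqid = f"{gm.symbol}_locus"
    span = gm.exons[-1].end
    seq = ["N"] * span
    for e in gm.exons:
        seq[e.start - 1 : e.end] = list(e.sequence)
    SeqIO.write(
        [SeqRecord(Seq("".join(seq)), id=seqid, description="synthetic locus")],
        str(fasta_path),
        "fasta",
    )
    # transcript (0-based half-open) -> genomic (1-based inclusive)
    off = 0
    g_start = g_end = None
    for e in gm.exons:
        if off <= gm.cds_start < off + e.length:
            g_start = e.start + (gm.cds_start - off)
        if off < gm.cds_end <= off + e.length:
            g_end = e.start + (gm.cds_end - off) - 1
        off += e.length
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            f"{seqid}\tomicnet\tgene\t{gm.exons[0].start}\t{span}\t.\t+\t.\t"
            f"ID=gene:{gm.symbol};Name={gm.symbol}\n"
        )
        for e in gm.exons:
            fh.write(
                f"{seqid}\tomicnet\texon\t{e.start}\t{e.end}\t.\t+\t.\t"
                f"ID=exon:{e.id};Parent=gene:{gm.symbol}\n"
            )
        fh.write(
            f"{seqid}\tomicnet\tCDS\t{g_start}\t{g_end}\t.\t+\t0\t"
            f"ID=cds:{gm.symbol};Parent=gene:{gm.symbol}\n"
        )


def write_results(path: str | Path, bundle: dict) -> None:
    """Write a JSON results bundle (dataframes become records)."""

    def default(o):
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        if hasattr(o, "__dict__"):
            return o.__dict__
        if hasattr(o, "item"):
            return o.item()
        return str(o)

    with open(path, "w") as fh:
        json.dump(bundle, fh, indent=2, default=default, sort_keys=True)
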