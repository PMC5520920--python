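"""Exon-skip transcript construction and proteoform prediction.

Builds exon-skipped transcript variants from a gene model, classifies the
reading frame, translates the predicted protein (recomputing residues whose
codons span novel exon junctions or sit in locally shifted frame segments),
runs in-silico PCR, and designs variant-specific tryptic peptides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

log = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


class SpliceError(ValueError):
    """Invalid gene model or skip request."""


@dataclass(frozen=True)
class Exon:
    """One exon: 1-based inclusive genomic span plus its sequence."""

    id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise SpliceError(
                f"exon {self.id}: span {self.start}..{self.end} does not match "
                f"sequence length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """Ordered exon structure of one gene with a CDS in transcript coordinates.

    ``cds_start``/``cds_end`` are 0-based half-open offsets into the spliced
    transcript (concatenation of exon sequences in order).
    """

    symbol: str
    exons: list[Exon]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not self.exons:
            raise SpliceError("gene model needs at least one exon")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise SpliceError(f"exons {a.id} and {b.id} overlap or are unordered")
        ids = [e.id for e in self.exons]
        if len(set(ids)) != len(ids):
            raise SpliceError("duplicate exon ids")
        t = self.transcript
        if not (0 <= self.cds_start < self.cds_end <= len(t)):
            raise SpliceError("CDS span exceeds transcript length")
        cds = t[self.cds_start : self.cds_end]
        if len(cds) % 3 != 0:
            raise SpliceError("reference CDS length not divisible by 3")
        if cds[:3] != "ATG":
            raise SpliceError("CDS does not begin with ATG")
        if cds[-3:] not in STOP_CODONS:
            raise SpliceError("CDS does not end with a stop codon")
        aa = translate_cdna(cds)
        if "*" in aa[:-1]:  # terminal stop is required above
            raise SpliceError("reference CDS contains an internal stop codon")

    @property
    def transcript(self) -> str:
        return "".join(e.sequence for e in self.exons)

    @property
    def exon_offsets(self) -> dict[str, int]:
        """Transcript offset (0-based) of each exon's first base."""
        off, out = 0, {}
        for e in self.exons:
            out[e.id] = off
            off += e.length
        return out

    @property
    def reference_protein(self) -> str:
        aa = translate_cdna(self.transcript[self.cds_start : self.cds_end])
        return aa.rstrip("*")

    def exon(self, exon_id: str) -> Exon:
        for e in self.exons:
            if e.id == str(exon_id):
                return e
        raise SpliceError(f"unknown exon id {exon_id!r}")


@dataclass
class TranscriptVariant:
    """An exon-skipped transcript and (after translation) its predicted protein."""

    gene_symbol: str
    skipped_exon_ids: tuple[str, ...]
    cdna: str
    deletion_length: int
    coding_deletion: int
    frame_class: str  # "in-frame" | "frameshift"
    novel_junctions: tuple[int, ...]  # variant-transcript offsets of new junctions
    protein: str | None = None
    protein_length: int | None = None
    deleted_aa: int | None = None
    ptc_position: int | None = None  # 1-based aa index of a premature stop
    novel_protein_intervals: tuple[tuple[int, int], ...] = ()


@dataclass
class PeptideRecord:
    sequence: str
    start: int  # 0-based protein offset
    end: int  # half-open
    missed_cleavages: int
    spans_novel_junction: bool | None = None
    unique_vs_reference: bool | None = None


@dataclass(frozen=True)
class PcrProduct:
    length: int
    sequence: str
    start: int  # 0-based template offset of forward primer 5' end
    end: int  # half-open, far end of reverse primer binding site


def translate_cdna(cdna: str) -> str:
    """Translate a cDNA string codon by codon (standard table, '*' for stop)."""
    usable = len(cdna) - len(cdna) % 3
    return str(Seq(cdna[:usable]).translate())


def skip_exons(
    gm: GeneModel,
    exon_ids: Iterable[str],
    *,
    guard_terminal_coding: bool = True,
) -> TranscriptVariant:
    """Remove the named exons from the spliced transcript.

    Raises :class:`SpliceError` for unknown ids, for removal of every coding
    exon, and (unless ``guard_terminal_coding=False``) for removal of the
    exons holding the CDS start or end.
    """
    skipped = tuple(str(x) for x in exon_ids)
    for x in skipped:
        gm.exon(x)  # raises on unknown id
    skipset = set(skipped)
    offsets = gm.exon_offsets

    coding_exons = [
        e
        for e in gm.exons
        if offsets[e.id] < gm.cds_end and offsets[e.id] + e.length > gm.cds_start
    ]
    if all(e.id in skipset for e in coding_exons):
        raise SpliceError("skip removes every coding exon")
    if guard_terminal_coding:
        first, last = coding_exons[0].id, coding_exons[-1].id
        if first in skipset or last in skipset:
            raise SpliceError(
                f"skip would remove a terminal coding exon ({first}/{last}); "
                "pass guard_terminal_coding=False to allow"
            )

    retained = [e for e in gm.exons if e.id not in skipset]
    cdna = "".join(e.sequence for e in retained)
    deletion = sum(gm.exon(x).length for x in skipped)

    # coding nt removed: overlap of each skipped exon with the CDS interval
    coding_del = 0
    for x in skipped:
        a = offsets[x]
        b = a + gm.exon(x).length
        coding_del += max(0, min(b, gm.cds_end) - max(a, gm.cds_start))

    # novel junctions: variant offsets where a retained exon follows a
    # non-successor of the reference order
    order = {e.id: i for i, e in enumerate(gm.exons)}
    junctions = []
    pos = 0
    for prev, nxt in zip(retained, retained[1:]):
        pos += prev.length
        if order[nxt.id] != order[prev.id] + 1:
            junctions.append(pos)

    return TranscriptVariant(
        gene_symbol=gm.symbol,
        skipped_exon_ids=skipped,
        cdna=cdna,
        deletion_length=deletion,
        coding_deletion=coding_del,
        frame_class="in-frame" if coding_del % 3 == 0 else "frameshift",
        novel_junctions=tuple(junctions),
    )


def classify_and_translate(tv: TranscriptVariant, gm: GeneModel) -> TranscriptVariant:
    """Complete a variant with its predicted protein.

    Translation starts at the reference CDS start (an error if that start was
    removed) and runs to the first stop codon. Residues whose codons span a
    novel junction, or that lie in a segment read in a locally shifted frame
    between junctions, are recorded as novel protein intervals.
    """
    offsets = gm.exon_offsets
    skipset = set(tv.skipped_exon_ids)

    # CDS start in variant coordinates; error if it fell inside a skipped exon
    removed_before_start = 0
    for x in skipset:
        a = offsets[x]
        b = a + gm.exon(x).length
        if a <= gm.cds_start < b:
            raise SpliceError("CDS start removed by the skip")
        if b <= gm.cds_start:
            removed_before_start += b - a
    s = gm.cds_start - removed_before_start

    aa = translate_cdna(tv.cdna[s:])
    stop = aa.find("*")
    protein = aa if stop < 0 else aa[:stop]

    ref_len = len(gm.reference_protein)
    expected_len = ref_len - tv.coding_deletion // 3 if tv.frame_class == "in-frame" else None
    ptc = None
    if stop >= 0 and (expected_len is None or stop < expected_len):
        ptc = stop + 1  # 1-based residue index of the premature stop

    # novel residues: junction-spanning codons plus shifted-frame segments
    intervals: list[tuple[int, int]] = []
    nlen = len(protein)

    def codon(pos: int) -> int:
        return (pos - s) // 3

    # walk retained exons tracking cumulative skipped-coding nt (frame shift)
    cum = 0
    pos = 0
    shift_runs: list[tuple[int, int]] = []  # variant spans read in shifted frame
    for e in gm.exons:
        a = offsets[e.id]
        b = a + e.length
        cov = max(0, min(b, gm.cds_end) - max(a, gm.cds_start))
        if e.id in skipset:
            cum += cov
            continue
        if cum % 3 != 0 and cov > 0:
            lo = max(pos, s)
            shift_runs.append((lo, pos + e.length))
        pos += e.length
    if tv.frame_class == "frameshift":
        # downstream of the last unbalanced junction everything is novel
        if tv.novel_junctions:
            first = min(tv.novel_junctions)
            intervals.append((max(0, codon(first - 1)), nlen))
    for j in tv.novel_junctions:
        if j - 1 >= s:
            intervals.append((codon(j - 1), codon(j) + 1))
    for lo, hi in shift_runs:
        intervals.append((codon(lo), codon(hi - 1) + 1))

    merged: list[tuple[int, int]] = []
    for lo, hi in sorted((max(0, lo), min(nlen, hi)) for lo, hi in intervals):
        if hi <= lo:
            continue
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))

    tv.protein = protein
    tv.protein_length = len(protein)
    tv.deleted_aa = ref_len - len(protein)
    tv.ptc_position = ptc
    tv.novel_protein_intervals = tuple(merged)
    return tv


def _matches(text: str, pattern: str, max_mismatches: int) -> list[int]:
    if max_mismatches == 0:
        out, i = [], text.find(pattern)
        while i >= 0:
            out.append(i)
            i = text.find(pattern, i + 1)
        return out
    out = []
    m = len(pattern)
    for i in range(len(text) - m + 1):
        mm = sum(1 for x, y in zip(text[i : i + m], pattern) if x != y)
        if mm <= max_mismatches:
            out.append(i)
    return out


def insilico_pcr(
    cdna: str,
    forward_primer: str,
    reverse_primer: str,
    max_mismatches: int = 0,
) -> list[PcrProduct]:
    """Predict PCR products on a template.

    A product is a forward-primer match followed downstream by the reverse
    complement of the reverse primer; the length includes both primer sites.
    """
    cdna = cdna.upper()
    fwd = forward_primer.upper()
    rev = reverse_primer.upper()
    for p, name in ((fwd, "forward"), (rev, "reverse")):
        if not p:
            raise SpliceError(f"{name} primer is empty")
        if set(p) - set("ACGT"):
            raise SpliceError(f"{name} primer has non-ACGT characters")
    rc = str(Seq(rev).reverse_complement())
    products = []
    for i in _matches(cdna, fwd, max_mismatches):
        for j in _matches(cdna, rc, max_mismatches):
            if j >= i + len(fwd):
                end = j + len(rc)
                products.append(
                    PcrProduct(length=end - i, sequence=cdna[i:end], start=i, end=end)
                )
    return products


def tryptic_digest(protein: str, missed_cleavages: int = 0) -> list[PeptideRecord]:
    """Cleave C-terminal to K/R except before P (Keil rule).

    With ``missed_cleavages=m`` every concatenation of up to ``m+1`` adjacent
    fragments is emitted; the 0-missed fragments tile the protein exactly.
    """
    bad = set(protein) - _AA_ALPHABET
    if bad:
        raise SpliceError(f"invalid residue(s): {sorted(bad)}")
    if not protein:
        return []
    cuts = [0]
    for i in range(len(protein) - 1):
        if protein[i] in "KR" and protein[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(protein))
    out = []
    nfrag = len(cuts) - 1
    for i in range(nfrag):
        for m in range(missed_cleavages + 1):
            if i + 1 + m > nfrag:
                break
            a, b = cuts[i], cuts[i + 1 + m]
            out.append(PeptideRecord(protein[a:b], a, b, m))
    return out


def variant_specific_peptides(
    tv: TranscriptVariant,
    reference_proteins: Mapping[str, str] | Sequence[str],
    missed_cleavages: int = 0,
) -> list[PeptideRecord]:
    """Tryptic peptides of the variant protein flagged for uniqueness/junction.

    A peptide is unique when it is absent as a substring of every reference
    protein; the junction flag marks peptides whose span intersects a novel
    protein interval. Sorted junction-spanning first, longer first.
    """
    if tv.protein is None:
        raise SpliceError("run classify_and_translate before peptide design")
    refs = (
        list(reference_proteins.values())
        if isinstance(reference_proteins, Mapping)
        else list(reference_proteins)
    )
    peptides = tryptic_digest(tv.protein, missed_cleavages)
    have_refs = len(refs) > 0
    if not have_refs:
        log.warning("empty reference set: uniqueness is indeterminate")
    for p in peptides:
        p.spans_novel_junction = any(
            p.start < hi and p.end > lo for lo, hi in tv.novel_protein_intervals
        )
        p.unique_vs_reference = (
            None if not have_refs else all(p.sequence not in r for r in refs)
        )
    peptides.sort(
        key=lambda p: (not p.spans_novel_junction, -len(p.sequence), p.start)
    )
    return peptides
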