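"""Fragment extension, genome placement and candidate-gene windows.

Significant k-mers frequently originate from the same reads and overlap
in sequence, so they are merged into longer *fragments* before mapping:
an overlap graph with directed edges for exact (k−1) suffix/prefix
overlaps is built, treating each k-mer and its reverse complement as a
single node, and maximal unambiguous paths (unitigs: in-degree ≤ 1 and
out-degree ≤ 1 along the walk) are merged.  Branching or isolated
k-mers are emitted as singleton fragments.  Fragments are then located
by exact substring search (both strands) in the reference; each hit is
widened to a linkage-disequilibrium window of ±50 kb, and genes whose
annotated interval intersects the window by at least one base are
reported as candidates.

Coordinates are 1-based inclusive throughout (GFF3 convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .kmers import canonicalize, reverse_complement

log = logging.getLogger(__name__)

DEFAULT_HALF_WIDTH = 50_000


@dataclass
class Hit:
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str


@dataclass
class Fragment:
    sequence: str
    member_kmers: list[str]
    hits: list[Hit] = field(default_factory=list)


@dataclass
class LDWindow:
    contig: str
    start: int
    end: int


@dataclass
class CandidateGene:
    gene_id: str
    contig: str
    start: int
    end: int
    overlap_bp: int


def _oriented_seq(node: str, forward: bool) -> str:
    return node if forward else reverse_complement(node)


def extend_fragments(kmers: Sequence[str]) -> list[Fragment]:
    """Merge k-mers overlapping by exactly k−1 bases into unitig fragments.

    A k-mer and its reverse complement collapse onto one node, so the
    output is strand-agnostic; each fragment is reported in canonical
    orientation (lexicographic minimum of sequence and its reverse
    complement) and the list is sorted by sequence for determinism.
    """
    kmers = list(kmers)
    if not kmers:
        return []
    lengths = {len(s) for s in kmers}
    if len(lengths) != 1:
        raise ValueError("mixed k-mer lengths")
    k = lengths.pop()

    members: dict[str, list[str]] = {}
    for km in kmers:
        members.setdefault(canonicalize(km), []).append(km)
    nodes = sorted(members)

    prefix_index: dict[str, list[tuple[str, bool]]] = {}
    for node in nodes:
        for fwd in (True, False):
            prefix_index.setdefault(_oriented_seq(node, fwd)[: k - 1], []).append((node, fwd))

    def successors(node: str, fwd: bool) -> list[tuple[str, bool]]:
        suffix = _oriented_seq(node, fwd)[1:]
        return [(v, vf) for v, vf in prefix_index.get(suffix, []) if v != node]

    def predecessors(node: str, fwd: bool) -> list[tuple[str, bool]]:
        # in-edges of (node, fwd) are the mirrors of out-edges of (node, !fwd)
        return [(u, not uf) for u, uf in successors(node, not fwd)]

    used: set[str] = set()
    fragments: list[Fragment] = []

    def walk(start_node: str, start_fwd: bool) -> None:
        chain = [(start_node, start_fwd)]
        used.add(start_node)
        while True:
            nxt = successors(*chain[-1])
            if len(nxt) != 1:
                break
            v, vf = nxt[0]
            if v in used or len(predecessors(v, vf)) != 1:
                break
            chain.append((v, vf))
            used.add(v)
        seq = _oriented_seq(*chain[0])
        for node, fwd in chain[1:]:
            seq += _oriented_seq(node, fwd)[-1]
        rc = reverse_complement(seq)
        member = sorted({m for node, _ in chain for m in members[node]})
        fragments.append(Fragment(min(seq, rc), member))

    # linear chains first: start at oriented nodes without a unique predecessor
    for node in nodes:
        if node in used:
            continue
        for fwd in (True, False):
            preds = predecessors(node, fwd)
            is_start = len(preds) != 1
            if not is_start:
                u, uf = preds[0]
                is_start = len(successors(u, uf)) != 1 or u in used
            if is_start and node not in used:
                walk(node, fwd)
                break
    # anything left sits on a cycle; break it deterministically
    for node in nodes:
        if node not in used:
            walk(node, True)

    fragments.sort(key=lambda f: f.sequence)
    return fragments


def _contig_items(ref) -> list[tuple[str, str]]:
    if hasattr(ref, "contigs"):
        return list(ref.contigs)
    if isinstance(ref, Mapping):
        return list(ref.items())
    from .io import read_fasta

    return list(read_fasta(ref).items())


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def map_fragments(fragments: Sequence[Fragment], ref) -> list[Fragment]:
    """Exact substring search of each fragment (both strands) in a reference.

    ``ref`` may be a :class:`~peff.simdata.ReferenceGenome`, a mapping
    of contig name to sequence, or a FASTA path.  All hits are
    reported; fragments with no hit keep an empty hit list (logged), as
    presence/absence alleles genuinely absent from the assembly do.
    """
    contigs = _contig_items(ref)
    out: list[Fragment] = []
    n_unplaced = 0
    for frag in fragments:
        hits: list[Hit] = []
        rc = reverse_complement(frag.sequence)
        for name, seq in contigs:
            for pos in _find_all(seq, frag.sequence):
                hits.append(Hit(name, pos + 1, pos + len(frag.sequence), "+"))
            if rc != frag.sequence:
                for pos in _find_all(seq, rc):
                    hits.append(Hit(name, pos + 1, pos + len(frag.sequence), "-"))
        hits.sort(key=lambda h: (h.contig, h.start, h.strand))
        if not hits:
            n_unplaced += 1
        out.append(Fragment(frag.sequence, list(frag.member_kmers), hits))
    if n_unplaced:
        log.info("%d fragment(s) had no exact placement in the reference", n_unplaced)
    return out


def ld_window(
    hit: Hit,
    contig_lengths: Mapping[str, int],
    half_width: int = DEFAULT_HALF_WIDTH,
) -> LDWindow:
    """±half_width window around a hit, clipped to the contig bounds."""
    if hit.contig not in contig_lengths:
        raise ValueError(f"unknown contig {hit.contig!r}")
    start = max(1, hit.start - half_width)
    end = min(int(contig_lengths[hit.contig]), hit.end + half_width)
    return LDWindow(hit.contig, start, end)


def candidate_genes(window: LDWindow, annotation: pd.DataFrame) -> list[CandidateGene]:
    """Genes intersecting the window by ≥ 1 bp, sorted by start (strand-agnostic)."""
    out = []
    sub = annotation[annotation["contig"] == window.contig]
    for row in sub.itertuples(index=False):
        lo = max(int(row.start), window.start)
        hi = min(int(row.end), window.end)
        if hi >= lo:
            out.append(CandidateGene(row.gene_id, window.contig, int(row.start),
                                     int(row.end), hi - lo + 1))
    out.sort(key=lambda g: g.start)
    return out


def annotate_fragments(
    fragments: Sequence[Fragment],
    contig_lengths: Mapping[str, int],
    annotation: pd.DataFrame,
    half_width: int = DEFAULT_HALF_WIDTH,
    unique_only: bool = False,
) -> pd.DataFrame:
    """Fragment → window → candidate gene table for all mapped fragments.

    Multi-hit fragments contribute one window per hit and are flagged;
    ``unique_only`` keeps only single-placement fragments.
    """
    rows = []
    for fi, frag in enumerate(fragments):
        if unique_only and len(frag.hits) != 1:
            continue
        multi = len(frag.hits) > 1
        for hit in frag.hits:
            window = ld_window(hit, contig_lengths, half_width)
            genes = candidate_genes(window, annotation)
            if not genes:
                rows.append((f"frag{fi + 1:03d}", frag.sequence, hit.contig, hit.start,
                             hit.end, hit.strand, window.start, window.end, multi,
                             None, None, None, 0))
            for g in genes:
                rows.append((f"frag{fi + 1:03d}", frag.sequence, hit.contig, hit.start,
                             hit.end, hit.strand, window.start, window.end, multi,
                             g.gene_id, g.start, g.end, g.overlap_bp))
    return pd.DataFrame(rows, columns=[
        "fragment_id", "sequence", "contig", "start", "end", "strand",
        "window_start", "window_end", "multi_hit",
        "gene_id", "gene_start", "gene_end", "overlap_bp",
    ])


def fragments_to_frame(fragments: Sequence[Fragment], tier: str | None = None) -> pd.DataFrame:
    rows = []
    for fi, frag in enumerate(fragments):
        if frag.hits:
            for hit in frag.hits:
                rows.append((f"frag{fi + 1:03d}", frag.sequence, len(frag.member_kmers),
                             hit.contig, hit.start, hit.end, hit.strand))
        else:
            rows.append((f"frag{fi + 1:03d}", frag.sequence, len(frag.member_kmers),
                         None, None, None, None))
    frame = pd.DataFrame(rows, columns=[
        "fragment_id", "sequence", "n_kmers", "contig", "start", "end", "strand",
    ])
    if tier is not None:
        frame["tier"] = tier
    return frame
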