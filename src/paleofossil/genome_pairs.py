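"""Reduce pairwise genome alignments to confident orthologous context.

Three steps defeat the classic trap where one TE family inserts
independently at homologous loci of two genomes (the inserts are homologs,
the insertions are not): keep only most-similar one-to-one blocks, prune
blocks touching protein-coding annotation, and discard isolated blocks —
an alignment is trusted only if it is linked, directly or indirectly, to
at least two others that are nearby in *both* genomes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

from .intervals import IntervalSet, gap as interval_gap
from .io_formats import AnnotationRecord

log = logging.getLogger(__name__)


@dataclass
class PairwiseBlock:
    """A gapped one-to-one aligned segment between two genomes.

    ``strand`` is the orientation of the genome-2 interval relative to
    genome 1.  Side lengths may differ.
    """

    g1_seq: str
    g1_start: int
    g1_end: int
    g2_seq: str
    g2_start: int
    g2_end: int
    strand: str = "+"
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.g1_end <= self.g1_start or self.g2_end <= self.g2_start:
            raise ValueError("block with empty side")

    @property
    def g1_interval(self) -> Tuple[int, int]:
        return (self.g1_start, self.g1_end)

    @property
    def g2_interval(self) -> Tuple[int, int]:
        return (self.g2_start, self.g2_end)


@dataclass
class LinkGraph:
    """Undirected link graph over block indices."""

    graph: nx.Graph

    def components(self) -> List[set]:
        return [set(c) for c in nx.connected_components(self.graph)]


def make_one_to_one(blocks: Sequence[PairwiseBlock]) -> List[PairwiseBlock]:
    """Greedy most-similar one-to-one reduction.

    Blocks are taken by descending score; one is kept iff it overlaps no
    kept block on either genome, so every base of each genome ends up
    covered at most once.
    """
    order = sorted(
        range(len(blocks)),
        key=lambda i: (
            -blocks[i].score,
            blocks[i].g1_seq, blocks[i].g1_start,
            blocks[i].g2_seq, blocks[i].g2_start,
        ),
    )
    kept1: Dict[str, IntervalSet] = {}
    kept2: Dict[str, IntervalSet] = {}
    out = []
    for i in order:
        b = blocks[i]
        s1 = kept1.setdefault(b.g1_seq, IntervalSet())
        s2 = kept2.setdefault(b.g2_seq, IntervalSet())
        if s1.overlaps(b.g1_start, b.g1_end) or s2.overlaps(b.g2_start, b.g2_end):
            continue
        s1.add(b.g1_start, b.g1_end)
        s2.add(b.g2_start, b.g2_end)
        out.append(b)
    out.sort(key=lambda b: (b.g1_seq, b.g1_start))
    return out


def prune_coding(
    blocks: Sequence[PairwiseBlock],
    cds1: Sequence[AnnotationRecord],
    cds2: Sequence[AnnotationRecord],
) -> List[PairwiseBlock]:
    """Remove blocks overlapping protein-coding annotation in either
    genome — zero tolerance, because alignments that touch exons overshoot
    into flanking fossils and fake conservation."""

    def _index(cds: Sequence[AnnotationRecord]) -> Dict[str, List[Tuple[int, int]]]:
        d: Dict[str, List[Tuple[int, int]]] = {}
        for r in cds:
            d.setdefault(r.seq_id, []).append(r.interval)
        for v in d.values():
            v.sort()
        return d

    ix1, ix2 = _index(cds1), _index(cds2)

    def _hits(ix: Dict[str, List[Tuple[int, int]]], seq: str, s: int, e: int) -> bool:
        return any(iv[0] < e and s < iv[1] for iv in ix.get(seq, []))

    return [
        b
        for b in blocks
        if not _hits(ix1, b.g1_seq, b.g1_start, b.g1_end)
        and not _hits(ix2, b.g2_seq, b.g2_start, b.g2_end)
    ]


def build_link_graph(
    blocks: Sequence[PairwiseBlock],
    max_gap: int = 1_000_000,
    max_between: int = 5,
) -> LinkGraph:
    """Two blocks are linked iff, in BOTH genomes, they lie on the same
    sequence, their interval gap is <= max_gap, and at most ``max_between``
    other input blocks lie strictly between them in interval (midpoint)
    order on that sequence."""
    n = len(blocks)
    g = nx.Graph()
    g.add_nodes_from(range(n))

    def _ranks(side: int) -> Dict[int, Tuple[str, int]]:
        def key(i: int):
            b = blocks[i]
            if side == 1:
                return (b.g1_seq, b.g1_start + b.g1_end, b.g1_start)
            return (b.g2_seq, b.g2_start + b.g2_end, b.g2_start)

        order = sorted(range(n), key=key)
        ranks = {}
        for pos, i in enumerate(order):
            seq = blocks[i].g1_seq if side == 1 else blocks[i].g2_seq
            ranks[i] = (seq, pos)
        return ranks

    r1, r2 = _ranks(1), _ranks(2)

    def _linked(i: int, j: int) -> bool:
        bi, bj = blocks[i], blocks[j]
        for side, ranks in ((1, r1), (2, r2)):
            if side == 1:
                seq_i, seq_j = bi.g1_seq, bj.g1_seq
                iv_i, iv_j = bi.g1_interval, bj.g1_interval
            else:
                seq_i, seq_j = bi.g2_seq, bj.g2_seq
                iv_i, iv_j = bi.g2_interval, bj.g2_interval
            if seq_i != seq_j:
                return False
            if interval_gap(iv_i, iv_j) > max_gap:
                return False
            if abs(ranks[i][1] - ranks[j][1]) - 1 > max_between:
                return False
        return True

    # candidate pairs: within max_between+1 ranks on genome 1, verified on
    # both sides (rank distance bounds "blocks strictly between")
    by_seq1: Dict[str, List[int]] = {}
    for i in range(n):
        by_seq1.setdefault(blocks[i].g1_seq, []).append(i)
    for seq, idxs in by_seq1.items():
        idxs.sort(key=lambda i: r1[i][1])
        for a in range(len(idxs)):
            for b in range(a + 1, min(a + max_between + 2, len(idxs))):
                if _linked(idxs[a], idxs[b]):
                    g.add_edge(idxs[a], idxs[b])
    return LinkGraph(g)


def link_filter(
    blocks: Sequence[PairwiseBlock],
    max_gap: int = 1_000_000,
    max_between: int = 5,
    min_links: int = 2,
) -> List[PairwiseBlock]:
    """Retain blocks linked, directly or indirectly, to at least
    ``min_links`` others: connected components of size >= min_links + 1."""
    lg = build_link_graph(blocks, max_gap=max_gap, max_between=max_between)
    keep = set()
    for comp in lg.components():
        if len(comp) >= min_links + 1:
            keep |= comp
    out = [blocks[i] for i in sorted(keep)]
    log.info("link_filter: %d blocks in, %d retained", len(blocks), len(out))
    return out


def project_interval(
    interval: Tuple[str, int, int],
    blocks: Sequence[PairwiseBlock],
) -> Optional[Tuple[str, int, int]]:
    """Map an interval in genome 2 to genome 1 through one-to-one blocks.

    Block-level, not base-level: the union of genome-1 spans of the blocks
    overlapping the interval, clipped proportionally (outward-rounded, so
    projecting and back-projecting contains the original).  Returns None
    if nothing overlaps, or — with a warning — if the overlapping blocks
    lie on different genome-1 sequences.
    """
    seq, s, e = interval
    spans = []
    for b in blocks:
        if b.g2_seq != seq or b.g2_start >= e or s >= b.g2_end:
            continue
        lo, hi = max(s, b.g2_start), min(e, b.g2_end)
        len2 = b.g2_end - b.g2_start
        len1 = b.g1_end - b.g1_start
        if b.strand == "+":
            f_lo = (lo - b.g2_start) / len2
            f_hi = (hi - b.g2_start) / len2
        else:
            f_lo = (b.g2_end - hi) / len2
            f_hi = (b.g2_end - lo) / len2
        p_lo = b.g1_start + int(f_lo * len1)  # floor: outward on the left
        p_hi = b.g1_start + int(-(-f_hi * len1 // 1))  # ceil: outward right
        spans.append((b.g1_seq, p_lo, max(p_hi, p_lo + 1)))
    if not spans:
        return None
    seqs = {sp[0] for sp in spans}
    if len(seqs) > 1:
        warnings.warn(f"interval {interval} projects to multiple sequences: {seqs}")
        return None
    g1_seq = spans[0][0]
    return (g1_seq, min(sp[1] for sp in spans), max(sp[2] for sp in spans))
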