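"""Independent brute-force oracles used by the test suite.

Each function recomputes a pipeline quantity by direct enumeration or
per-base bitmaps, sharing no code with the implementation it checks.
"""

from __future__ import annotations

import sys
from typing import Dict, List, Sequence, Tuple

import numpy as np

from paleofossil.scoring import AA_INDEX


def codon_score(model, codon: str, aa: str) -> int:
    b5 = {c: i for i, c in enumerate("ACGTN")}
    c = codon.upper()
    idx = b5[c[0]] * 25 + b5[c[1]] * 5 + b5[c[2]]
    return int(model.subst125()[idx, AA_INDEX[aa]])


def enumerate_best_score(dna: str, prot: str, model) -> int:
    """Optimal local frameshift-aware alignment score by exhaustive
    enumeration of every column sequence (tiny inputs only).

    Grammar: the alignment starts and ends with a codon<->aa column;
    between codon columns there may be runs of codon<->gap or gap<->aa
    columns (affine per maximal same-type run) or a single +-1 frameshift;
    a +1 frameshift skips one nucleotide, a -1 frameshift re-reads one.
    """
    best = 0
    n, m = len(dna), len(prot)
    go, ge, fs = model.gap_open, model.gap_extend, model.frameshift
    sys.setrecursionlimit(200_000)

    def rec(i: int, j: int, score: int, last: str) -> None:
        nonlocal best
        if last == "M" and score > best:
            best = score
        if i + 3 <= n and j + 1 <= m:
            rec(i + 3, j + 1, score + codon_score(model, dna[i : i + 3], prot[j]), "M")
        if last == "M":
            if i + 4 <= n and j + 1 <= m:  # +1 shift: skip one nucleotide
                rec(i + 4, j + 1, score - fs + codon_score(model, dna[i + 1 : i + 4], prot[j]), "M")
            if i >= 1 and i + 2 <= n and j + 1 <= m:  # -1 shift: re-read one
                rec(i + 2, j + 1, score - fs + codon_score(model, dna[i - 1 : i + 2], prot[j]), "M")
        if i + 3 <= n:
            rec(i + 3, j, score - (ge if last == "I" else go), "I")
        if j + 1 <= m:
            rec(i, j + 1, score - (ge if last == "D" else go), "D")

    for i0 in range(n - 2):
        for j0 in range(m):
            rec(i0 + 3, j0 + 1, codon_score(model, dna[i0 : i0 + 3], prot[j0]), "M")
    return best


def bitmap_covered(interval: Tuple[int, int], others: Sequence[Tuple[int, int]]) -> int:
    s0, e0 = interval
    bits = np.zeros(e0 - s0, dtype=bool)
    for s, e in others:
        lo, hi = max(s, s0) - s0, min(e, e0) - s0
        if hi > lo:
            bits[lo:hi] = True
    return int(bits.sum())


def greedy_overlap_reference(items, key_fn, interval_fn):
    """O(n^2) reference for best-first overlap-free selection.

    ``key_fn`` gives the (ascending) sort key; ``interval_fn`` maps an item
    to (seq_id, start, end).
    """
    order = sorted(items, key=key_fn)
    kept = []
    for it in order:
        seq, s, e = interval_fn(it)
        ok = True
        for k in kept:
            ks, kss, kse = interval_fn(k)
            if ks == seq and kss < e and s < kse:
                ok = False
                break
        if ok:
            kept.append(it)
    return kept


def one_to_one_reference(blocks):
    """O(n^2) reference for most-similar one-to-one block selection."""
    order = sorted(
        range(len(blocks)),
        key=lambda i: (
            -blocks[i].score,
            blocks[i].g1_seq, blocks[i].g1_start,
            blocks[i].g2_seq, blocks[i].g2_start,
        ),
    )
    kept: List = []
    for i in order:
        b = blocks[i]
        clash = False
        for k in kept:
            if (
                k.g1_seq == b.g1_seq and k.g1_start < b.g1_end and b.g1_start < k.g1_end
            ) or (
                k.g2_seq == b.g2_seq and k.g2_start < b.g2_end and b.g2_start < k.g2_end
            ):
                clash = True
                break
        if not clash:
            kept.append(b)
    return kept


def link_filter_reference(blocks, max_gap=1_000_000, max_between=5, min_links=2):
    """All-pairs link graph + connected-component search, by definition."""

    def order_on(side):
        def key(i):
            b = blocks[i]
            return (
                (b.g1_seq, b.g1_start + b.g1_end, b.g1_start) if side == 1
                else (b.g2_seq, b.g2_start + b.g2_end, b.g2_start)
            )
        return sorted(range(len(blocks)), key=lambda i: (key(i), i))

    def between_count(i, j, side) -> int:
        bi, bj = blocks[i], blocks[j]
        if side == 1:
            seq_i, seq_j = bi.g1_seq, bj.g1_seq
            mid = lambda b: (b.g1_start + b.g1_end)
        else:
            seq_i, seq_j = bi.g2_seq, bj.g2_seq
            mid = lambda b: (b.g2_start + b.g2_end)
        ordered = order_on(side)
        pi, pj = ordered.index(i), ordered.index(j)
        lo, hi = min(pi, pj), max(pi, pj)
        return hi - lo - 1

    def gap_of(i, j, side) -> int:
        bi, bj = blocks[i], blocks[j]
        if side == 1:
            a = (bi.g1_start, bi.g1_end)
            b = (bj.g1_start, bj.g1_end)
        else:
            a = (bi.g2_start, bi.g2_end)
            b = (bj.g2_start, bj.g2_end)
        return max(0, max(a[0], b[0]) - min(a[1], b[1]))

    n = len(blocks)
    adj: Dict[int, set] = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            bi, bj = blocks[i], blocks[j]
            if bi.g1_seq != bj.g1_seq or bi.g2_seq != bj.g2_seq:
                continue
            if gap_of(i, j, 1) > max_gap or gap_of(i, j, 2) > max_gap:
                continue
            if between_count(i, j, 1) > max_between or between_count(i, j, 2) > max_between:
                continue
            adj[i].add(j)
            adj[j].add(i)
    seen: set = set()
    keep: set = set()
    for i in range(n):
        if i in seen:
            continue
        comp = {i}
        stack = [i]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in comp:
                    comp.add(v)
                    stack.append(v)
        seen |= comp
        if len(comp) >= min_links + 1:
            keep |= comp
    return [blocks[i] for i in sorted(keep)]


def tectonic_reference(calls, min_sep=30_000, max_sep=3_000_000):
    out = []
    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            a, b = calls[i], calls[j]
            if not (a.is_te and b.is_te):
                continue
            if a.seq_id != b.seq_id or a.class_family != b.class_family:
                continue
            lo, hi = (a, b) if a.start <= b.start else (b, a)
            sep = hi.start - lo.end
            if min_sep <= sep <= max_sep:
                out.append((lo.start, hi.start, sep))
    return sorted(out)
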