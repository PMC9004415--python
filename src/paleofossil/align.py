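"""Frameshift-aware local DNA-to-protein alignment and genome search.

The aligner finds local alignments between a DNA sequence and a
stop-augmented protein.  Alignment columns are:

* ``("M", codon, aa)``   — a codon aligned to an amino acid (3 nt, 1 aa)
* ``("I", codon, None)`` — a codon aligned to a gap (3 nt)
* ``("D", None, aa)``    — a gap aligned to an amino acid (1 aa)
* ``("F", +1|-1, nt)``   — a frameshift between two codon columns; +1
  skips one extra nucleotide, -1 re-reads one

Gaps are affine (per maximal same-type run), frameshifts carry a flat cost
and may occur only between codon columns, and an alignment begins and ends
with a codon column.  The dynamic program is exact over its input and is
verified against an independent exhaustive enumeration on small instances.

Genome-scale search uses the classical seed-and-extend layout: exact
amino-acid k-mer seeds from the six reading frames (never taken inside
soft-masked runs), a two-hit diagonal filter, and the exact DP replayed on
each candidate window with a numba-compiled kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .io_formats import SeqRecord
from .scoring import (
    AA_INDEX,
    CODON_TO_AA,
    GENETIC_CODE,
    ScoringModel,
    evalue,
    per_genome_evalue,
)

Column = tuple

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_B5 = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGTN"):
    _B5[ord(_b)] = _i
    _B5[ord(_b.lower())] = _i

_AA_CODE = np.full(256, -1, dtype=np.int8)
for _a, _i in AA_INDEX.items():
    _AA_CODE[ord(_a)] = _i


@dataclass
class FrameshiftEvent:
    position: int  # column index within the alignment
    direction: int  # +1 or -1


@dataclass
class TranslatedAlignment:
    """A local codon-level alignment of a DNA interval to a protein range.

    DNA coordinates are 0-based half-open on the forward strand; for
    ``strand == "-"`` the columns read along the reverse complement.
    """

    dna_id: str
    dna_start: int
    dna_end: int
    strand: str
    prot_id: str
    prot_start: int
    prot_end: int
    columns: List[Column]
    score: int
    evalue_chrom: float = float("nan")
    evalue_genome: float = float("nan")

    def frameshift_events(self) -> List[FrameshiftEvent]:
        return [
            FrameshiftEvent(i, col[1])
            for i, col in enumerate(self.columns)
            if col[0] == "F"
        ]

    def nucleotides_consumed(self) -> int:
        n = 0
        for col in self.columns:
            if col[0] in ("M", "I"):
                n += 3
            elif col[0] == "F":
                n += col[1]
        return n

    def aa_consumed(self) -> int:
        return sum(1 for c in self.columns if c[0] in ("M", "D"))

    def recompute_score(self, model: ScoringModel) -> int:
        """Score of the column list under a model (consistency check)."""
        s = 0
        prev_gap: Optional[str] = None
        for col in self.columns:
            if col[0] == "M":
                c = col[1].upper()
                ci = _B5[ord(c[0])] * 25 + _B5[ord(c[1])] * 5 + _B5[ord(c[2])]
                s += int(model.subst125()[ci, AA_INDEX[col[2]]])
                prev_gap = None
            elif col[0] == "F":
                s -= model.frameshift
                prev_gap = None
            else:
                s -= model.gap_extend if prev_gap == col[0] else model.gap_open
                prev_gap = col[0]
        return s

    def is_disrupted(self) -> bool:
        """True if the alignment has a frameshift or a premature stop
        (a stop codon aligned to a non-stop amino acid)."""
        for col in self.columns:
            if col[0] == "F":
                return True
            if col[0] == "M":
                codon = col[1].upper()
                if "N" not in codon and GENETIC_CODE[codon] == "*" and col[2] != "*":
                    return True
        return False


# ---------------------------------------------------------------------------
# DP kernel

_PTR_STOP, _PTR_H, _PTR_I, _PTR_D, _PTR_FSM, _PTR_FSP = 0, 1, 2, 3, 4, 5


@njit(cache=True)
def _dp_kernel(dna5, prot, subst125, gap_open, gap_extend, frameshift):
    """Fill H/I/D matrices with traceback pointers.

    H[i, j]: best alignment ending with a codon column consuming DNA up to
    nt i and protein up to aa j.  I: ends with codon<->gap; D: ends with
    gap<->aa.  Frameshift transitions route H -> H with DNA steps of 2
    (-1 shift) or 4 (+1 shift).
    """
    n = dna5.shape[0]
    m = prot.shape[0]
    NEG = np.int32(-(10 ** 9))
    H = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    I = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    D = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrI = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1: from H, 2: from I, 3: from D
    ptrD = np.zeros((n + 1, m + 1), dtype=np.uint8)

    for i in range(3, n + 1):
        c = dna5[i - 3] * 25 + dna5[i - 2] * 5 + dna5[i - 1]
        for j in range(1, m + 1):
            s = subst125[c, prot[j - 1]]

            best = np.int32(0)
            ptr = _PTR_STOP
            v = H[i - 3, j - 1]
            if v > best:
                best = v
                ptr = _PTR_H
            v = I[i - 3, j - 1]
            if v > best:
                best = v
                ptr = _PTR_I
            v = D[i - 3, j - 1]
            if v > best:
                best = v
                ptr = _PTR_D
            if i >= 2:
                v = H[i - 2, j - 1] - frameshift
                if v > best:
                    best = v
                    ptr = _PTR_FSM
            if i >= 4:
                v = H[i - 4, j - 1] - frameshift
                if v > best:
                    best = v
                    ptr = _PTR_FSP
            H[i, j] = s + best
            ptrH[i, j] = ptr

            # codon <-> gap (consumes 3 nt)
            bi = H[i - 3, j] - gap_open
            pi = 1
            v = I[i - 3, j] - gap_extend
            if v > bi:
                bi = v
                pi = 2
            v = D[i - 3, j] - gap_open
            if v > bi:
                bi = v
                pi = 3
            I[i, j] = bi
            ptrI[i, j] = pi

        # gap <-> aa (consumes 1 aa); same i, sequential in j
        for j in range(1, m + 1):
            bd = H[i, j - 1] - gap_open
            pd = 1
            v = D[i, j - 1] - gap_extend
            if v > bd:
                bd = v
                pd = 2
            v = I[i, j - 1] - gap_open
            if v > bd:
                bd = v
                pd = 3
            D[i, j] = bd
            ptrD[i, j] = pd

    return H, I, D, ptrH, ptrI, ptrD


def _traceback(i, j, dna_str, prot_str, H, I, D, ptrH, ptrI, ptrD):
    """Walk pointers back from H[i, j]; return (dna_start, prot_start, columns)."""
    cols: List[Column] = []
    state = "H"
    while True:
        if state == "H":
            p = ptrH[i, j]
            cols.append(("M", dna_str[i - 3 : i], prot_str[j - 1]))
            if p == _PTR_STOP:
                return i - 3, j - 1, cols[::-1]
            if p == _PTR_H:
                i, j = i - 3, j - 1
            elif p == _PTR_I:
                i, j, state = i - 3, j - 1, "I"
            elif p == _PTR_D:
                i, j, state = i - 3, j - 1, "D"
            elif p == _PTR_FSM:
                cols.append(("F", -1, ""))
                i, j = i - 2, j - 1
            else:  # _PTR_FSP: one skipped nucleotide
                cols.append(("F", 1, dna_str[i - 4]))
                i, j = i - 4, j - 1
        elif state == "I":
            p = ptrI[i, j]
            cols.append(("I", dna_str[i - 3 : i], None))
            i = i - 3
            state = "H" if p == 1 else ("I" if p == 2 else "D")
        else:
            p = ptrD[i, j]
            cols.append(("D", None, prot_str[j - 1]))
            j = j - 1
            state = "H" if p == 1 else ("D" if p == 2 else "I")


def _has_unmasked_seed(columns: Sequence[Column]) -> bool:
    """An alignment must contain a codon column fully outside soft-masked
    (lowercase) sequence: alignments may extend into masked runs but are
    never seeded inside them."""
    for col in columns:
        if col[0] == "M" and col[1].isupper():
            return True
    return False


def _align_oriented(
    dna_str: str, prot_str: str, model: ScoringModel, min_score: int
) -> List[Tuple[int, int, int, int, int, List[Column]]]:
    """All non-overlapping (on DNA) local alignments on one orientation.

    Returns tuples (dna_start, dna_end, prot_start, prot_end, score, cols),
    greedily selected best-first so no returned alignment shares a DNA base
    with a higher-scoring one.
    """
    dna5 = _B5[np.frombuffer(dna_str.encode(), dtype=np.uint8)]
    if np.any(dna5 < 0):
        raise ValueError("bad DNA letter")
    prot = _AA_CODE[np.frombuffer(prot_str.encode(), dtype=np.uint8)]
    if np.any(prot < 0):
        raise ValueError("bad protein letter")
    H, I, D, ptrH, ptrI, ptrD = _dp_kernel(
        dna5, prot, model.subst125(),
        np.int32(model.gap_open), np.int32(model.gap_extend),
        np.int32(model.frameshift),
    )
    cand = np.argwhere(H >= min_score)
    if cand.size == 0:
        return []
    scores = H[cand[:, 0], cand[:, 1]]
    order = np.lexsort((cand[:, 1], cand[:, 0], -scores))
    from .intervals import IntervalSet

    kept = IntervalSet()
    out = []
    for idx in order:
        i, j = int(cand[idx, 0]), int(cand[idx, 1])
        if kept.overlaps(i - 1, i):
            continue
        ds, ps, cols = _traceback(i, j, dna_str, prot_str, H, I, D, ptrH, ptrI, ptrD)
        if kept.overlaps(ds, i):
            continue
        if not _has_unmasked_seed(cols):
            continue
        kept.add(ds, i)
        out.append((ds, i, ps, j, int(H[i, j]), cols))
    return out


def reverse_complement(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def align_local(
    dna: SeqRecord, prot: SeqRecord, model: ScoringModel, min_score: int
) -> List[TranslatedAlignment]:
    """Local frameshift-aware alignments of a protein against both strands.

    The protein must be stop-augmented (end with ``*``).  Among returned
    alignments no DNA base is shared with a lower-scoring one; ties break
    by (dna_start, prot_start, '+' strand first).
    """
    if not dna.residues:
        raise ValueError("empty DNA")
    if not prot.residues.endswith("*"):
        raise ValueError(f"protein {prot.id} is not stop-augmented")
    if min_score <= 0:
        raise ValueError("min_score must be positive")

    n = len(dna.residues)
    raw: List[TranslatedAlignment] = []
    for strand, seq in (("+", dna.residues), ("-", reverse_complement(dna.residues))):
        for ds, de, ps, pe, score, cols in _align_oriented(
            seq, prot.residues, model, min_score
        ):
            if strand == "+":
                start, end = ds, de
            else:
                start, end = n - de, n - ds
            raw.append(
                TranslatedAlignment(
                    dna_id=dna.id, dna_start=start, dna_end=end, strand=strand,
                    prot_id=prot.id, prot_start=ps, prot_end=pe,
                    columns=cols, score=score,
                )
            )
    return _drop_dna_overlaps(raw)


def _drop_dna_overlaps(alns: List[TranslatedAlignment]) -> List[TranslatedAlignment]:
    """Greedy best-first selection so no two alignments share a DNA base
    (either strand); deterministic tie-break."""
    from .intervals import IntervalSet

    order = sorted(
        alns,
        key=lambda a: (-a.score, a.dna_start, a.prot_start, 0 if a.strand == "+" else 1),
    )
    kept_by_seq: Dict[str, IntervalSet] = {}
    out = []
    for a in order:
        ks = kept_by_seq.setdefault(a.dna_id, IntervalSet())
        if ks.overlaps(a.dna_start, a.dna_end):
            continue
        ks.add(a.dna_start, a.dna_end)
        out.append(a)
    out.sort(key=lambda a: (a.dna_id, a.dna_start, a.prot_id))
    return out


# ---------------------------------------------------------------------------
# derived statistics


def aa_identity(aln: TranslatedAlignment) -> float:
    """Fraction of codon<->aa columns whose codon translates exactly to the
    aligned amino acid; gaps and frameshifts excluded."""
    n = matches = 0
    for col in aln.columns:
        if col[0] != "M":
            continue
        n += 1
        codon = col[1].upper()
        if "N" not in codon and GENETIC_CODE[codon] == col[2]:
            matches += 1
    if n == 0:
        raise ValueError("alignment has no codon<->aa columns")
    return matches / n


def reverse_decoy(genome: Sequence[SeqRecord]) -> List[SeqRecord]:
    """Reversed (but NOT complemented) genome: a decoy with the same
    composition but destroyed codon structure, for false-positive control."""
    return [SeqRecord(r.id + "_rev", r.residues[::-1], "dna") for r in genome]


def disruption_stats(alns: Sequence[TranslatedAlignment]) -> Dict[str, Optional[float]]:
    """Fraction of alignments with a frameshift or premature stop."""
    n = len(alns)
    if n == 0:
        return {"n": 0, "frac_disrupted": None}
    d = sum(1 for a in alns if a.is_disrupted())
    return {"n": n, "frac_disrupted": d / n}


def attach_evalues(
    alns: Sequence[TranslatedAlignment],
    model: ScoringModel,
    chrom_lengths: Dict[str, int],
    total_protein_len: int,
) -> None:
    """Fill per-chromosome and per-genome E-values in place."""
    genome_len = sum(chrom_lengths.values())
    for a in alns:
        clen = chrom_lengths[a.dna_id]
        a.evalue_chrom = evalue(a.score, clen, total_protein_len, model)
        a.evalue_genome = per_genome_evalue(a.evalue_chrom, clen, genome_len)


# ---------------------------------------------------------------------------
# seeded genome search


@dataclass
class SearchParams:
    """Seeding heuristics for genome-scale search.

    Seeds are exact amino-acid ``seed_k``-mers between the translated
    reading frames and the protein set; two seeds on nearby diagonals
    within ``max_seed_dist`` nucleotides trigger a window DP.
    """

    seed_k: int = 4
    diag_bucket: int = 24  # nt; two-hit requires same (protein, diagonal bucket)
    max_seed_dist: int = 450
    window_pad: int = 45
    max_cluster_span: int = 1500  # nt; longer seed chains are split
    max_extension: int = 450  # nt; window growth beyond the outermost seeds
    gapless_min: int = 45  # min gapless X-drop extension score to run the DP
    gapless_xdrop: int = 20


def _frame_kmers(seq5: np.ndarray, is_upper: np.ndarray, k: int):
    """Yield (kmer_code, nt_start_position) arrays over the 3 reading
    frames of one orientation.  Seed positions require every base of every
    codon to be uppercase and unambiguous."""
    n = seq5.shape[0]
    for frame in range(3):
        n_codons = (n - frame) // 3
        if n_codons < k:
            continue
        codons = (
            seq5[frame : frame + 3 * n_codons : 3].astype(np.int64) * 16
            + seq5[frame + 1 : frame + 1 + 3 * n_codons : 3] * 4
            + seq5[frame + 2 : frame + 2 + 3 * n_codons : 3]
        )
        ok = (
            (seq5[frame : frame + 3 * n_codons : 3] < 4)
            & (seq5[frame + 1 : frame + 1 + 3 * n_codons : 3] < 4)
            & (seq5[frame + 2 : frame + 2 + 3 * n_codons : 3] < 4)
        )
        up = (
            is_upper[frame : frame + 3 * n_codons : 3]
            & is_upper[frame + 1 : frame + 1 + 3 * n_codons : 3]
            & is_upper[frame + 2 : frame + 2 + 3 * n_codons : 3]
        )
        aa = np.where(ok, CODON_TO_AA[np.where(ok, codons, 0)], -1)
        valid = ok & up
        # k-mer codes over consecutive frame positions
        code = np.zeros(n_codons - k + 1, dtype=np.int64)
        vall = np.ones(n_codons - k + 1, dtype=bool)
        for t in range(k):
            code = code * 21 + aa[t : t + n_codons - k + 1]
            vall &= valid[t : t + n_codons - k + 1]
        pos = frame + 3 * np.arange(n_codons - k + 1)
        yield code[vall], pos[vall]


@njit(cache=True)
def _gapless_best(seq5, prot, subst125, p, q, xdrop):
    """Best gapless codon-level extension through seed (nt p, aa q);
    X-drop terminated.  The cheap verification between seeding and DP."""
    n = seq5.shape[0]
    m = prot.shape[0]
    best = np.int32(0)
    s = np.int32(0)
    t = 0
    while p + 3 * t + 3 <= n and q + t < m:
        c = seq5[p + 3 * t] * 25 + seq5[p + 3 * t + 1] * 5 + seq5[p + 3 * t + 2]
        s += subst125[c, prot[q + t]]
        if s > best:
            best = s
        if s < best - xdrop:
            break
        t += 1
    total = best
    best = np.int32(0)
    s = np.int32(0)
    t = 1
    while p - 3 * t >= 0 and q - t >= 0:
        c = seq5[p - 3 * t] * 25 + seq5[p - 3 * t + 1] * 5 + seq5[p - 3 * t + 2]
        s += subst125[c, prot[q - t]]
        if s > best:
            best = s
        if s < best - xdrop:
            break
        t += 1
    return total + best


def _protein_index(prots: Sequence[SeqRecord], k: int):
    """Sorted k-mer index over the concatenated protein set."""
    codes, pidx, ppos = [], [], []
    for t, p in enumerate(prots):
        aa = _AA_CODE[np.frombuffer(p.residues.encode(), dtype=np.uint8)].astype(np.int64)
        if np.any(aa < 0):
            raise ValueError(f"bad amino acid in {p.id}")
        if len(aa) < k:
            continue
        code = np.zeros(len(aa) - k + 1, dtype=np.int64)
        for t2 in range(k):
            code = code * 21 + aa[t2 : t2 + len(aa) - k + 1]
        codes.append(code)
        pidx.append(np.full(len(code), t, dtype=np.int64))
        ppos.append(np.arange(len(code), dtype=np.int64))
    if not codes:
        return None
    codes = np.concatenate(codes)
    pidx = np.concatenate(pidx)
    ppos = np.concatenate(ppos)
    order = np.argsort(codes, kind="stable")
    return codes[order], pidx[order], ppos[order]


def _candidate_windows(
    seq5, is_upper, prots, index, params: SearchParams,
    prot_codes=None, subst125=None,
) -> Dict[int, List[Tuple[int, int]]]:
    """Two-hit seed clustering with gapless verification; returns
    {protein index: [(win_start, win_end)]}."""
    idx_codes, idx_pidx, idx_ppos = index
    all_nt, all_pi, all_pp = [], [], []
    for code, pos in _frame_kmers(seq5, is_upper, params.seed_k):
        lo = np.searchsorted(idx_codes, code, "left")
        hi = np.searchsorted(idx_codes, code, "right")
        counts = hi - lo
        if counts.sum() == 0:
            continue
        rep = np.repeat(np.arange(len(code)), counts)
        flat = np.concatenate([np.arange(l, h) for l, h in zip(lo, hi) if h > l]) \
            if counts.max() else np.empty(0, dtype=np.int64)
        all_nt.append(pos[rep])
        all_pi.append(idx_pidx[flat])
        all_pp.append(idx_ppos[flat])
    if not all_nt:
        return {}
    nt = np.concatenate(all_nt)
    pi = np.concatenate(all_pi)
    pp = np.concatenate(all_pp)
    diag = nt - 3 * pp
    bucket = diag // params.diag_bucket
    order = np.lexsort((nt, bucket, pi))
    nt, pi, pp, bucket = nt[order], pi[order], pp[order], bucket[order]
    same = (pi[1:] == pi[:-1]) & (bucket[1:] == bucket[:-1])
    near = nt[1:] - nt[:-1] <= params.max_seed_dist
    pair = same & near
    windows: Dict[int, List[Tuple[int, int]]] = {}
    i = 0
    n_seed = len(nt)
    while i < n_seed - 1:
        if not pair[i]:
            i += 1
            continue
        j = i
        while (
            j < n_seed - 1
            and pair[j]
            and nt[j + 1] - nt[i] <= params.max_cluster_span
        ):
            j += 1
        # cluster spans seeds i..j
        p = int(pi[i])
        if prot_codes is not None:
            mid = (i + j) // 2
            ok = False
            for k in {i, mid, j}:
                if _gapless_best(
                    seq5, prot_codes[p], subst125,
                    int(nt[k]), int(pp[k]), np.int32(params.gapless_xdrop),
                ) >= params.gapless_min:
                    ok = True
                    break
            if not ok:
                i = j + 1
                continue
        plen = len(prots[p].residues)
        ext_lo = min(3 * int(pp[i : j + 1].min()), params.max_extension)
        ext_hi = min(
            3 * (params.seed_k + plen - int(pp[i : j + 1].max())),
            params.max_extension,
        )
        lo_nt = int(nt[i]) - ext_lo - params.window_pad
        hi_nt = int(nt[j]) + 3 * params.seed_k + ext_hi + params.window_pad
        windows.setdefault(p, []).append((max(0, lo_nt), min(len(seq5), hi_nt)))
        i = j + 1
    from .intervals import merge

    return {p: merge(ws) for p, ws in windows.items()}


def search_genome(
    genome: Sequence[SeqRecord],
    proteins: Sequence[SeqRecord],
    model: ScoringModel,
    min_score: int,
    params: Optional[SearchParams] = None,
) -> List[TranslatedAlignment]:
    """Seeded search of a genome against a stop-augmented protein set.

    Returns raw alignments with score >= min_score on both strands,
    best-first pruned per chromosome so overlapping weaker alignments of
    the *same search* are already resolved (final cross-protein resolution
    is the fossil-call stage's job).
    """
    params = params or SearchParams()
    for p in proteins:
        if not p.residues.endswith("*"):
            raise ValueError(f"protein {p.id} is not stop-augmented")
    index = _protein_index(proteins, params.seed_k)
    if index is None:
        return []
    prot_codes = [
        _AA_CODE[np.frombuffer(p.residues.encode(), dtype=np.uint8)]
        for p in proteins
    ]
    subst125 = model.subst125()
    out: List[TranslatedAlignment] = []
    for chrom in genome:
        n = len(chrom.residues)
        for strand in "+-":
            seq = chrom.residues if strand == "+" else reverse_complement(chrom.residues)
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            seq5 = _B5[arr]
            is_upper = (arr < ord("a")) & (seq5 >= 0)
            wins = _candidate_windows(
                seq5, is_upper, proteins, index, params, prot_codes, subst125
            )
            for p_idx, intervals in wins.items():
                prot = proteins[p_idx]
                for ws, we in intervals:
                    for ds, de, ps, pe, score, cols in _align_oriented(
                        seq[ws:we], prot.residues, model, min_score
                    ):
                        if strand == "+":
                            start, end = ws + ds, ws + de
                        else:
                            start, end = n - (ws + de), n - (ws + ds)
                        out.append(
                            TranslatedAlignment(
                                dna_id=chrom.id, dna_start=start, dna_end=end,
                                strand=strand, prot_id=prot.id,
                                prot_start=ps, prot_end=pe,
                                columns=cols, score=score,
                            )
                        )
    # overlapping windows can rediscover the same alignment
    seen = set()
    uniq = []
    for a in out:
        key = (a.dna_id, a.dna_start, a.dna_end, a.strand, a.prot_id, a.score)
        if key not in seen:
            seen.add(key)
            uniq.append(a)
    uniq.sort(key=lambda a: (a.dna_id, a.dna_start, a.prot_id))
    return uniq


# ---------------------------------------------------------------------------
# E-value calibration of the seeded search


def calibrate_evalues(
    model: ScoringModel,
    proteins: Sequence[SeqRecord],
    seed: int = 7,
    dna_len: int = 800_000,
    gc: float = 0.41,
    params: Optional[SearchParams] = None,
) -> Tuple[float, float]:
    """Fit the E-value scale (lambda, K) of the *seeded search* on shuffled DNA.

    Random DNA of the genome's composition is searched against the real
    protein set; observed counts of hits with score >= s are regressed on
    the Karlin-Altschul form  count(s) = K m n exp(-lambda s)  by weighted
    least squares on the log counts.  Fitting both parameters empirically —
    rather than using the analytic ungapped lambda — makes the reported
    E-values describe the gapped, frameshift-aware, seeded search actually
    performed, so the decoy false-positive control agrees with the
    threshold semantics.  Updates ``model.lambda_`` and ``model.k_``.
    """
    rng = np.random.default_rng(seed)
    pb = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    dna = "".join(rng.choice(list("ACGT"), size=dna_len, p=pb))
    decoy = [SeqRecord("calib", dna, "dna")]
    params = params or SearchParams()
    floor = params.gapless_min  # below this, seeding truncates the tail
    hits = search_genome(decoy, proteins, model, floor, params)
    scores = np.array([a.score for a in hits])
    m = sum(len(p.residues) for p in proteins)
    if len(scores) < 30:
        return model.lambda_, model.k_  # too few decoy hits to fit
    grid = np.arange(floor + 3, int(scores.max()) + 1)
    counts = np.array([(scores >= s).sum() for s in grid], dtype=float)
    keep = counts >= 3
    if keep.sum() < 4:
        return model.lambda_, model.k_
    x, y, w = grid[keep], np.log(counts[keep]), counts[keep]
    A = np.vstack([np.ones(len(x)), x]).T * np.sqrt(w)[:, None]
    coef, *_ = np.linalg.lstsq(A, y * np.sqrt(w), rcond=None)
    lam = float(-coef[1])
    if lam <= 0:
        return model.lambda_, model.k_
    k = float(np.exp(coef[0]) / (dna_len * m))
    model.lambda_ = lam
    model.k_ = k
    return lam, k
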