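"""Ground-truthed genome simulation for exercising the fossil pipeline.

The simulated world: an ancestral genome carries conserved anchor segments
(exapted, slow-evolving sequence) and planted protein fossils decayed to a
target amino-acid identity with frameshifts, premature stops and indels.
Two descendant lineages then diverge by neutral substitutions and small
indels; each gains young lineage-specific fossils; some ancestral fossils
are split in one lineage by a large insertion (so their halves drift apart
— the tectonic scenario); and a TE family is inserted *independently* at
homologous positions of both lineages on scaffolds whose conserved flanks
have been lost (the non-homologous-insertion trap).  True orthologous
alignment blocks are emitted for conserved segments only, and every
planted feature is recorded in a ground-truth registry.

One integer seed determines every emitted byte.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ancient_ages import CladeMap
from .genome_pairs import PairwiseBlock
from .io_formats import (
    AnnotationRecord,
    GeneModel,
    SeqRecord,
    write_fasta,
    write_gff3,
    write_maf,
    write_repeatmasker_out,
)
from .scoring import CODON_TO_AA, CODONS, aa_background, codon_usage

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)

#: TE families used for simulated protein names; token -> class/family
TE_FAMILIES = {
    "L1": "LINE/L1",
    "CR1": "LINE/CR1",
    "RTE": "LINE/RTE",
    "Nimb": "LINE/Nimb",
    "Hero": "LINE/R2-Hero",
    "Gypsy": "LTR/Gypsy",
    "DIRS": "LTR/DIRS",
    "Penelope": "Penelope/Penelope",
    "Harbinger": "DNA/PIF-Harbinger",
    "hAT": "DNA/hAT-Tip100",
    "Polinton": "DNA/Polinton",
    "Crypton": "DNA/Crypton-A",
}

_EXAPTED_TAGS = ("_HSgene", "_Hsa_", "UN-GIN", "_Xtr_eg_tp")


@dataclass
class SimConfig:
    """Stated world of the simulation.

    Rates are per-unit probabilities; ``frameshift_per_fossil`` and
    ``stop_per_fossil`` are expected event counts per planted fossil.
    """

    seed: int = 0
    genome_length: int = 1_000_000
    n_te_proteins: int = 60
    n_host_proteins: int = 20
    protein_length: Tuple[int, int] = (150, 400)
    n_ancestral_fossils: int = 50
    n_lineage_fossils: int = 50
    target_aa_identity: float = 0.5
    young_aa_identity: float = 0.70
    indel_rate: float = 0.01  # per codon, 3-nt in-frame indels during decay
    frameshift_per_fossil: float = 1.0
    stop_per_fossil: float = 1.0
    divergence_subst_rate: float = 0.10  # per neutral bp per lineage
    divergence_indel_rate: float = 0.002  # small-indel events per neutral bp
    conserved_subst_rate: float = 0.02  # per conserved bp per lineage
    n_split_fossils: int = 3
    split_gap_range: Tuple[int, int] = (30_000, 120_000)
    n_trap_insertions: int = 3
    gc: float = 0.41
    anchor_spacing: int = 8_000
    anchor_length: int = 300
    exapted_name_frac: float = 0.10
    host_fossil_frac: float = 0.20
    known_rmsk_frac: float = 0.60
    n_decoy_genes: int = 20
    cds_overlap_frac: float = 0.04
    trap_scaffold_length: int = 30_000

    def __post_init__(self) -> None:
        for name in ("target_aa_identity", "young_aa_identity", "indel_rate",
                     "divergence_subst_rate", "divergence_indel_rate",
                     "conserved_subst_rate", "gc", "exapted_name_frac",
                     "host_fossil_frac", "known_rmsk_frac", "cds_overlap_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.split_gap_range
        if not 0 < lo <= hi:
            raise ValueError("bad split_gap_range")


@dataclass
class TruthFossil:
    """One planted fossil as the simulator knows it."""

    fossil_id: str
    source_protein: str
    source_class: str  # "TE:<class/family>" or "host_gene"
    strand: str
    interval_A: Optional[Tuple[str, int, int]]
    interval_B: Optional[Tuple[str, int, int]]
    age_true: str  # "old" | "lineage"
    disrupted: bool
    split_partner: Optional[str] = None
    is_trap: bool = False
    cds_overlap_planned: float = 0.0


@dataclass
class GroundTruth:
    fossils: List[TruthFossil]
    blocks: List[PairwiseBlock]  # genuinely orthologous (conserved segments)
    trap_blocks: List[PairwiseBlock]  # homologous inserts, non-homologous insertions
    genome_names: Tuple[str, str] = ("genomeA", "genomeB")

    def all_blocks(self) -> List[PairwiseBlock]:
        """What a genome aligner would produce: orthology plus trap homology."""
        return list(self.blocks) + list(self.trap_blocks)


@dataclass
class PlantedAncestralFossil:
    protein_id: str
    source_class: str
    strand: str
    start: int
    end: int
    disrupted: bool


@dataclass
class Ancestor:
    seq: np.ndarray  # uint8 codes 0..3
    anchors: List[Tuple[int, int]]
    fossils: List[PlantedAncestralFossil]

    @property
    def conserved(self) -> List[Tuple[int, int]]:
        ivs = list(self.anchors) + [(f.start, f.end) for f in self.fossils]
        return sorted(ivs)


@dataclass
class World:
    cfg: SimConfig
    proteins: List[SeqRecord]
    genome_A: List[SeqRecord]
    genome_B: List[SeqRecord]
    genes_A: List[GeneModel]
    genes_B: List[GeneModel]
    rmsk_A: List[AnnotationRecord]
    truth: GroundTruth
    clade_map: CladeMap


# ---------------------------------------------------------------------------
# sequence helpers


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return bytes(_LETTERS[codes]).decode()


def _from_str(s: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(s.encode(), dtype=np.uint8)]


_RC = np.array([3, 2, 1, 0], dtype=np.uint8)


def _revcomp(codes: np.ndarray) -> np.ndarray:
    return _RC[codes][::-1]


def decay_mix_fraction(target_identity: float, gc: float) -> float:
    """Probability that a codon is randomised (vs kept synonymous) so the
    expected amino-acid identity equals the target."""
    u = codon_usage(gc)
    q = aa_background(u)
    m = float(np.sum(q * q))
    return min(max((1 - target_identity) / (1 - m), 0.0), 1.0)


# ---------------------------------------------------------------------------
# protein library


def make_protein_library(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> List[SeqRecord]:
    """Simulated TE + host protein library; deterministic per seed.

    A configurable fraction of TE proteins carry exapted-gene name tags
    (``_HSgene`` etc.) to exercise the name-based exclusion.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    q = aa_background(codon_usage(cfg.gc))[:20]
    q = q / q.sum()
    aas = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
    lo, hi = cfg.protein_length
    records: List[SeqRecord] = []
    tokens = list(TE_FAMILIES)
    n_exapted = int(round(cfg.exapted_name_frac * cfg.n_te_proteins))
    tag_cycle = itertools.cycle(_EXAPTED_TAGS)
    for i in range(cfg.n_te_proteins):
        tok = tokens[i % len(tokens)]
        length = int(rng.integers(lo, hi + 1))
        residues = bytes(aas[rng.choice(20, size=length, p=q)]).decode()
        if i < n_exapted:
            tag = next(tag_cycle)
            if tag == "UN-GIN":
                name = f"UN-GIN-{i}_{tok}_pol"
            else:
                name = f"{tok}-{i}{tag}pol" if tag.endswith("_") else f"{tok}-{i}{tag}_pol"
        else:
            name = f"{tok}-{i}_SIM_pol"
        records.append(SeqRecord(name, residues, "protein"))
    for i in range(cfg.n_host_proteins):
        length = int(rng.integers(lo, hi + 1))
        residues = bytes(aas[rng.choice(20, size=length, p=q)]).decode()
        records.append(SeqRecord(f"NP_{900000 + i}.1", residues, "protein"))
    return records


def protein_classes(proteins: Sequence[SeqRecord]) -> Dict[str, str]:
    """Source class of each library protein, parsed from its name."""
    out = {}
    for p in proteins:
        if p.id.startswith("NP_"):
            out[p.id] = "host_gene"
        else:
            tok = p.id.split("-", 1)[0]
            out[p.id] = "TE:" + TE_FAMILIES.get(tok, "Unknown")
    return out


# ---------------------------------------------------------------------------
# fossil decay


def make_fossil_dna(
    protein_residues: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    target_identity: Optional[float] = None,
) -> Tuple[str, bool, int, int]:
    """Reverse-translate a protein and decay it.

    Per codon: usage-weighted synonymous choice, randomised with the
    mixing probability that hits the target amino-acid identity in
    expectation; then Poisson-many premature stops and +-1 nt frameshifts,
    and in-frame 3-nt indels at ``indel_rate`` per codon.

    Returns (dna, disrupted, n_frameshifts, n_stops).
    """
    target = cfg.target_aa_identity if target_identity is None else target_identity
    u = codon_usage(cfg.gc)
    r = decay_mix_fraction(target, cfg.gc)
    codons: List[str] = []
    aa_index = {a: i for i, a in enumerate("ACDEFGHIKLMNPQRSTVWY*")}
    syn_cache: Dict[str, Tuple[List[str], np.ndarray]] = {}
    for aa in protein_residues:
        if rng.random() < r:
            codons.append(CODONS[rng.choice(64, p=u)])
        else:
            if aa not in syn_cache:
                idx = [i for i in range(64) if CODON_TO_AA[i] == aa_index[aa]]
                w = u[idx] / u[idx].sum()
                syn_cache[aa] = ([CODONS[i] for i in idx], w)
            opts, w = syn_cache[aa]
            codons.append(opts[rng.choice(len(opts), p=w)])

    n_stop = int(rng.poisson(cfg.stop_per_fossil))
    stops = ["TAA", "TAG", "TGA"]
    if n_stop and len(codons) > 2:
        for pos in rng.choice(len(codons) - 1, size=min(n_stop, len(codons) - 1), replace=False):
            codons[int(pos)] = stops[int(rng.integers(3))]

    # in-frame 3-nt indels
    kept: List[str] = []
    for c in codons:
        roll = rng.random()
        if roll < cfg.indel_rate / 2:
            continue  # codon deleted
        kept.append(c)
        if roll > 1 - cfg.indel_rate / 2:
            kept.append(CODONS[rng.choice(64, p=u)])
    dna = "".join(kept)

    n_fs = int(rng.poisson(cfg.frameshift_per_fossil))
    for _ in range(n_fs):
        if len(dna) < 9:
            break
        pos = int(rng.integers(3, len(dna) - 3))
        if rng.random() < 0.5:
            dna = dna[:pos] + dna[pos + 1 :]
        else:
            dna = dna[:pos] + "ACGT"[int(rng.integers(4))] + dna[pos:]

    return dna, (n_fs > 0 or n_stop > 0), n_fs, n_stop


def plant_fossil(
    genome: SeqRecord,
    protein: SeqRecord,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    forbidden: Sequence[Tuple[int, int]] = (),
) -> Tuple[SeqRecord, TruthFossil]:
    """Insert one decayed copy of a (stop-augmented) protein into a genome
    at a uniformly chosen position outside ``forbidden`` zones and outside
    soft-masked runs; the truth entry records the exact interval and
    disruption flags.  Raises after 100 failed placement attempts.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if not protein.residues.endswith("*"):
        raise ValueError("protein must be stop-augmented")
    dna, disrupted, _, _ = make_fossil_dna(protein.residues, cfg, rng)
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        dna = _to_str(_revcomp(_from_str(dna)))
    for _ in range(100):
        pos = int(rng.integers(0, len(genome.residues) + 1))
        if any(s <= pos < e for s, e in forbidden):
            continue
        if 0 < pos < len(genome.residues) and genome.residues[pos - 1 : pos + 1].islower():
            continue
        new = SeqRecord(
            genome.id, genome.residues[:pos] + dna + genome.residues[pos:], "dna"
        )
        truth = TruthFossil(
            fossil_id=f"{protein.id}@{genome.id}:{pos}",
            source_protein=protein.id,
            source_class=protein_classes([protein])[protein.id],
            strand=strand,
            interval_A=(genome.id, pos, pos + len(dna)),
            interval_B=None,
            age_true="lineage",
            disrupted=disrupted,
        )
        return new, truth
    raise RuntimeError("could not place fossil outside forbidden/masked zones")


# ---------------------------------------------------------------------------
# ancestor construction


def make_ancestor(
    cfg: SimConfig, proteins: Sequence[SeqRecord], rng: np.random.Generator
) -> Ancestor:
    """Random ancestral chromosome with conserved anchors and planted,
    already-decayed ancestral fossils (TE and host-gene)."""
    seq = _random_dna(rng, cfg.genome_length, cfg.gc)
    anchors = []
    pos = cfg.anchor_spacing // 2
    while pos + cfg.anchor_length < cfg.genome_length:
        jitter = int(rng.integers(-cfg.anchor_spacing // 4, cfg.anchor_spacing // 4))
        s = max(0, pos + jitter)
        anchors.append((s, s + cfg.anchor_length))
        pos += cfg.anchor_spacing

    classes = protein_classes(proteins)
    usable = [p for p in proteins if not any(t in p.id for t in _EXAPTED_TAGS)]
    te = [p for p in usable if classes[p.id].startswith("TE:")]
    host = [p for p in usable if classes[p.id] == "host_gene"]
    n_host = int(round(cfg.host_fossil_frac * cfg.n_ancestral_fossils))
    picks = [host[int(rng.integers(len(host)))] for _ in range(n_host)] + [
        te[int(rng.integers(len(te)))] for _ in range(cfg.n_ancestral_fossils - n_host)
    ]

    occupied = sorted(anchors)
    fossils: List[PlantedAncestralFossil] = []
    parts: List[Tuple[int, str, PlantedAncestralFossil]] = []
    for p in picks:
        dna, disrupted, _, _ = make_fossil_dna(p.residues + "*", cfg, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            dna = _to_str(_revcomp(_from_str(dna)))
        for _ in range(200):
            s = int(rng.integers(0, cfg.genome_length - len(dna)))
            e = s + len(dna)
            if all(e + 100 <= os or oe + 100 <= s for os, oe in occupied):
                occupied.append((s, e))
                occupied.sort()
                f = PlantedAncestralFossil(
                    protein_id=p.id, source_class=classes[p.id],
                    strand=strand, start=s, end=e, disrupted=disrupted,
                )
                fossils.append(f)
                parts.append((s, dna, f))
                break
        else:
            raise RuntimeError("ancestor too crowded to place fossil")

    for s, dna, _f in parts:  # overwrite in place: fossils replace neutral DNA
        seq[s : s + len(dna)] = _from_str(dna)
    fossils.sort(key=lambda f: f.start)
    return Ancestor(seq=seq, anchors=anchors, fossils=fossils)


# ---------------------------------------------------------------------------
# lineage divergence


@dataclass
class _Insertion:
    pos: int
    seq: np.ndarray
    tag: Optional[str] = None


@dataclass
class _Lineage:
    seq: np.ndarray
    pieces: List[Tuple[int, int, int]]  # (anc_start, anc_end, dest_start)
    novel: Dict[str, Tuple[int, int]]

    def map_interval(self, s: int, e: int) -> List[Tuple[int, int, int, int]]:
        """Images of ancestor [s, e): (anc_s, anc_e, dest_s, dest_e) runs."""
        out = []
        for a_s, a_e, d_s in self.pieces:
            lo, hi = max(s, a_s), min(e, a_e)
            if hi > lo:
                out.append((lo, hi, d_s + (lo - a_s), d_s + (hi - a_s)))
        return out


def _diverge(
    anc: Ancestor,
    cfg: SimConfig,
    rng: np.random.Generator,
    insertions: List[_Insertion],
) -> _Lineage:
    """Apply one lineage's edits: the given large insertions, plus small
    neutral indels and per-base substitutions (slow inside conserved
    segments, fast outside)."""
    L = len(anc.seq)
    conserved = anc.conserved
    cons_mask = np.zeros(L, dtype=bool)
    for s, e in conserved:
        cons_mask[s:e] = True

    neutral_pos = np.nonzero(~cons_mask)[0]
    n_indel = rng.binomial(len(neutral_pos), cfg.divergence_indel_rate)
    indel_pos = np.sort(rng.choice(neutral_pos, size=n_indel, replace=False))
    indel_is_del = rng.random(n_indel) < 0.5
    indel_len = rng.integers(1, 11, size=n_indel)

    events: List[Tuple[int, str, object]] = [
        (ins.pos, "bigI", ins) for ins in insertions
    ]
    for p, isdel, ln in zip(indel_pos, indel_is_del, indel_len):
        if isdel:
            events.append((int(p), "D", int(ln)))
        else:
            events.append((int(p), "I", _random_dna(rng, int(ln), cfg.gc)))
    events.sort(key=lambda t: (t[0], t[1]))

    rates = np.where(cons_mask, cfg.conserved_subst_rate, cfg.divergence_subst_rate)
    sub_mask = rng.random(L) < rates
    sub_shift = rng.integers(1, 4, size=int(sub_mask.sum())).astype(np.uint8)
    mutated = anc.seq.copy()
    mutated[sub_mask] = (mutated[sub_mask] + sub_shift) % 4

    parts: List[np.ndarray] = []
    pieces: List[Tuple[int, int, int]] = []
    novel: Dict[str, Tuple[int, int]] = {}
    cur = 0
    dpos = 0
    for pos, kind, payload in events:
        if pos < cur:
            continue  # swallowed by an earlier deletion
        if pos > cur:
            parts.append(mutated[cur:pos])
            pieces.append((cur, pos, dpos))
            dpos += pos - cur
            cur = pos
        if kind == "D":
            end = min(int(cur) + int(payload), L)
            # a deletion never eats into conserved sequence
            nxt = next((s for s, e in conserved if s >= cur), L)
            cur = min(end, nxt)
        else:
            ins_seq = payload.seq if kind == "bigI" else payload
            tag = payload.tag if kind == "bigI" else None
            parts.append(ins_seq)
            if tag:
                novel[tag] = (dpos, dpos + len(ins_seq))
            dpos += len(ins_seq)
    if cur < L:
        parts.append(mutated[cur:L])
        pieces.append((cur, L, dpos))
        dpos += L - cur
    return _Lineage(seq=np.concatenate(parts), pieces=pieces, novel=novel)


def evolve_pair(
    anc: Ancestor, cfg: SimConfig, proteins: Sequence[SeqRecord],
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[SeqRecord], List[SeqRecord], GroundTruth]:
    """Evolve two descendant genomes from the ancestor and emit truth.

    Lineage A additionally receives the fossil-splitting insertions; trap
    insertions go to dedicated scaffold pairs in both genomes.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    classes = protein_classes(proteins)
    te_prots = [p for p in proteins if classes[p.id].startswith("TE:")
                and not any(t in p.id for t in _EXAPTED_TAGS)]
    cons = anc.conserved

    def _neutral_position() -> int:
        for _ in range(1000):
            p = int(rng.integers(0, len(anc.seq)))
            if all(not (s - 50 <= p < e + 50) for s, e in cons):
                return p
        raise RuntimeError("no neutral position found")

    # --- young lineage-specific fossils ---------------------------------
    ins_A: List[_Insertion] = []
    ins_B: List[_Insertion] = []
    young_meta: Dict[str, Tuple[str, str, str, bool]] = {}
    for i in range(cfg.n_lineage_fossils):
        p = te_prots[int(rng.integers(len(te_prots)))]
        dna, disrupted, _, _ = make_fossil_dna(
            p.residues + "*", cfg, rng, target_identity=cfg.young_aa_identity
        )
        strand = "+" if rng.random() < 0.5 else "-"
        codes = _from_str(dna)
        if strand == "-":
            codes = _revcomp(codes)
        tag = f"young{i}"
        dest = ins_A if i % 2 == 0 else ins_B
        dest.append(_Insertion(_neutral_position(), codes, tag))
        young_meta[tag] = (p.id, classes[p.id], strand, disrupted)

    # --- splitting insertions (tectonic scenario) ------------------------
    te_anc = [f for f in anc.fossils if f.source_class.startswith("TE:")]
    n_split = min(cfg.n_split_fossils, len(te_anc))
    split_idx = rng.choice(len(te_anc), size=n_split, replace=False)
    split_fossils = [te_anc[int(i)] for i in split_idx]
    split_mid: Dict[int, int] = {}
    for f in split_fossils:
        gap_len = int(rng.integers(cfg.split_gap_range[0], cfg.split_gap_range[1] + 1))
        mid = (f.start + f.end) // 2
        split_mid[id(f)] = mid
        ins_A.append(_Insertion(mid, _random_dna(rng, gap_len, cfg.gc), None))

    lin_A = _diverge(anc, cfg, rng, ins_A)
    lin_B = _diverge(anc, cfg, rng, ins_B)

    # --- truth for ancestral fossils -------------------------------------
    fossils: List[TruthFossil] = []

    def _single(lin: _Lineage, s: int, e: int, chrom: str):
        runs = lin.map_interval(s, e)
        if not runs:
            return None
        return (chrom, runs[0][2], runs[-1][3])

    for k, f in enumerate(anc.fossils):
        base = f"anc{k}"
        if id(f) in split_mid:
            mid = split_mid[id(f)]
            halves = [(f.start, mid), (mid, f.end)]
            ids = [f"{base}.a", f"{base}.b"]
            for (hs, he), fid, partner in zip(halves, ids, ids[::-1]):
                fossils.append(
                    TruthFossil(
                        fossil_id=fid, source_protein=f.protein_id,
                        source_class=f.source_class, strand=f.strand,
                        interval_A=_single(lin_A, hs, he, "chrA"),
                        interval_B=_single(lin_B, hs, he, "chrB"),
                        age_true="old", disrupted=f.disrupted,
                        split_partner=partner,
                    )
                )
        else:
            fossils.append(
                TruthFossil(
                    fossil_id=base, source_protein=f.protein_id,
                    source_class=f.source_class, strand=f.strand,
                    interval_A=_single(lin_A, f.start, f.end, "chrA"),
                    interval_B=_single(lin_B, f.start, f.end, "chrB"),
                    age_true="old", disrupted=f.disrupted,
                )
            )

    for tag, (pid, sclass, strand, disrupted) in young_meta.items():
        in_a = tag in lin_A.novel
        lin = lin_A if in_a else lin_B
        d_s, d_e = lin.novel[tag]
        iv = (("chrA" if in_a else "chrB"), d_s, d_e)
        fossils.append(
            TruthFossil(
                fossil_id=tag, source_protein=pid, source_class=sclass,
                strand=strand,
                interval_A=iv if in_a else None,
                interval_B=None if in_a else iv,
                age_true="lineage", disrupted=disrupted,
            )
        )

    # --- true orthologous blocks -----------------------------------------
    blocks: List[PairwiseBlock] = []
    for s, e in cons:
        runs_a = lin_A.map_interval(s, e)
        runs_b = lin_B.map_interval(s, e)
        for a_s, a_e, da_s, _da_e in runs_a:
            for b_s, b_e, db_s, _db_e in runs_b:
                lo, hi = max(a_s, b_s), min(a_e, b_e)
                if hi <= lo:
                    continue
                blocks.append(
                    PairwiseBlock(
                        g1_seq="chrA", g1_start=da_s + (lo - a_s),
                        g1_end=da_s + (hi - a_s),
                        g2_seq="chrB", g2_start=db_s + (lo - b_s),
                        g2_end=db_s + (hi - b_s),
                        strand="+", score=float(hi - lo),
                    )
                )

    genome_A = [SeqRecord("chrA", _to_str(lin_A.seq), "dna")]
    genome_B = [SeqRecord("chrB", _to_str(lin_B.seq), "dna")]

    # --- trap scaffolds ---------------------------------------------------
    trap_blocks: List[PairwiseBlock] = []
    trap_protein = te_prots[int(rng.integers(len(te_prots)))] if te_prots else None
    for t in range(cfg.n_trap_insertions):
        pos = cfg.trap_scaffold_length // 2
        name_a, name_b = f"trap{t}_A", f"trap{t}_B"
        ivs = {}
        for name, genome in ((name_a, genome_A), (name_b, genome_B)):
            dna, disrupted, _, _ = make_fossil_dna(
                trap_protein.residues + "*", cfg, rng,
                target_identity=cfg.young_aa_identity,
            )
            flank = _random_dna(rng, cfg.trap_scaffold_length, cfg.gc)
            seq = _to_str(flank[:pos]) + dna + _to_str(flank[pos:])
            genome.append(SeqRecord(name, seq, "dna"))
            ivs[name] = (pos, pos + len(dna), disrupted)
        (a_s, a_e, dis_a), (b_s, b_e, dis_b) = ivs[name_a], ivs[name_b]
        trap_blocks.append(
            PairwiseBlock(
                g1_seq=name_a, g1_start=a_s, g1_end=a_e,
                g2_seq=name_b, g2_start=b_s, g2_end=b_e,
                strand="+", score=float(min(a_e - a_s, b_e - b_s)),
            )
        )
        sclass = classes[trap_protein.id]
        fossils.append(
            TruthFossil(
                fossil_id=f"trap{t}.A", source_protein=trap_protein.id,
                source_class=sclass, strand="+",
                interval_A=(name_a, a_s, a_e), interval_B=None,
                age_true="lineage", disrupted=dis_a, is_trap=True,
            )
        )
        fossils.append(
            TruthFossil(
                fossil_id=f"trap{t}.B", source_protein=trap_protein.id,
                source_class=sclass, strand="+",
                interval_A=None, interval_B=(name_b, b_s, b_e),
                age_true="lineage", disrupted=dis_b, is_trap=True,
            )
        )

    truth = GroundTruth(fossils=fossils, blocks=blocks, trap_blocks=trap_blocks)
    return genome_A, genome_B, truth


# ---------------------------------------------------------------------------
# decoy gene models and RepeatMasker-like annotations


def _decoy_genes(
    cfg: SimConfig,
    rng: np.random.Generator,
    chrom: str,
    chrom_len: int,
    avoid: List[Tuple[int, int]],
    overlap_targets: List[Tuple[TruthFossil, float]],
) -> List[GeneModel]:
    """Two-exon decoy genes in free space, plus genes engineered to cover a
    stated fraction of chosen fossils (to exercise the coding filter at its
    boundary)."""
    genes: List[GeneModel] = []
    taken = sorted(avoid)

    def _free(s: int, e: int) -> bool:
        return all(e <= ts or te <= s for ts, te in taken)

    i = 0
    attempts = 0
    while i < cfg.n_decoy_genes and attempts < 2000:
        attempts += 1
        exon = 300
        intron = int(rng.integers(400, 1500))
        s = int(rng.integers(0, max(1, chrom_len - (2 * exon + intron))))
        e = s + 2 * exon + intron
        if not _free(s - 100, e + 100):
            continue
        taken.append((s, e))
        taken.sort()
        acc = f"XR_{100000 + i}.1" if i % 5 == 4 else f"NM_{100000 + i}.1"
        genes.append(
            GeneModel(
                gene_name=f"GENE{i}", accession=acc, seq_id=chrom,
                start=s, end=e, strand="+" if i % 2 == 0 else "-",
                exons=[(s, s + exon), (e - exon, e)],
                cds=[(s, s + exon), (e - exon, e)],
            )
        )
        i += 1

    for j, (tf, frac) in enumerate(overlap_targets):
        _, fs, fe = tf.interval_A
        cov = max(1, int(frac * (fe - fs)))
        exon1 = (fe - cov, fe + max(1, 300 - cov))  # spans the fossil edge
        intron_end = exon1[1] + 800
        # the far exon must not graze another planted feature
        while not _free(intron_end, intron_end + 300) and intron_end < chrom_len:
            intron_end += 200
        exon2 = (intron_end, intron_end + 300)
        genes.append(
            GeneModel(
                gene_name=f"OVGENE{j}", accession=f"NM_{200000 + j}.1",
                seq_id=chrom, start=exon1[0], end=exon2[1], strand="+",
                exons=[exon1, exon2], cds=[exon1, exon2],
            )
        )
        tf.cds_overlap_planned = cov / (fe - fs)
    genes.sort(key=lambda g: g.start)
    return genes


def _rmsk_annotations(
    cfg: SimConfig, rng: np.random.Generator, truth: GroundTruth
) -> List[AnnotationRecord]:
    """RepeatMasker-like annotation of genome A: a configurable "known"
    subset of planted TE fossils with true class/family, plus one Unknown
    repeat family laid over fossils of a single TE type, plus a little
    simple-repeat annotation."""
    te_in_a = [
        f for f in truth.fossils
        if f.interval_A is not None and f.source_class.startswith("TE:")
        and not f.is_trap and f.split_partner is None
    ]
    n_known = int(round(cfg.known_rmsk_frac * len(te_in_a)))
    order = rng.permutation(len(te_in_a))
    records: List[AnnotationRecord] = []
    for k in order[:n_known]:
        f = te_in_a[int(k)]
        chrom, s, e = f.interval_A
        j1, j2 = int(rng.integers(0, 11)), int(rng.integers(0, 11))
        records.append(
            AnnotationRecord(
                chrom, max(0, s - j1), e + j2, f.strand,
                f.source_protein.split("_")[0], f.source_class[3:],
            )
        )

    # an Unknown family over fossils of the most common planted type
    by_type: Dict[str, List[TruthFossil]] = {}
    for f in te_in_a:
        by_type.setdefault(f.source_class, []).append(f)
    if by_type:
        best = max(by_type.values(), key=len)
        for f in best[:6]:
            chrom, s, e = f.interval_A
            records.append(
                AnnotationRecord(chrom, s, e, f.strand, "REP-1_SIM", "Unknown")
            )

    chrom_len = None
    for f in truth.fossils:
        if f.interval_A and f.interval_A[0] == "chrA":
            chrom_len = max(chrom_len or 0, f.interval_A[2])
    if chrom_len:
        records.append(
            AnnotationRecord("chrA", 100, 160, "+", "(AT)n", "Simple_repeat")
        )
    records.sort(key=lambda r: (r.seq_id, r.start))
    return records


# ---------------------------------------------------------------------------
# the whole world


def build_world(cfg: SimConfig) -> World:
    """Deterministically build the complete simulated world."""
    rng = np.random.default_rng(cfg.seed)
    proteins = make_protein_library(cfg, rng)
    anc = make_ancestor(cfg, proteins, rng)
    genome_A, genome_B, truth = evolve_pair(anc, cfg, proteins, rng)

    chrA_len = len(genome_A[0].residues)
    chrB_len = len(genome_B[0].residues)
    avoid_A = [
        (f.interval_A[1], f.interval_A[2])
        for f in truth.fossils
        if f.interval_A and f.interval_A[0] == "chrA"
    ] + [(b.g1_start, b.g1_end) for b in truth.blocks]
    avoid_B = [
        (f.interval_B[1], f.interval_B[2])
        for f in truth.fossils
        if f.interval_B and f.interval_B[0] == "chrB"
    ] + [(b.g2_start, b.g2_end) for b in truth.blocks]

    candidates = [
        f for f in truth.fossils
        if f.age_true == "old" and f.split_partner is None
        and f.interval_A and f.interval_A[0] == "chrA"
    ]
    n_overlap = int(round(cfg.cds_overlap_frac * len(candidates)))
    targets = []
    for j in range(n_overlap):
        frac = 0.08 if j % 2 == 0 else 0.20  # one side of the >10% boundary each
        targets.append((candidates[j], frac))

    genes_A = _decoy_genes(cfg, rng, "chrA", chrA_len, avoid_A, targets)
    genes_B = _decoy_genes(cfg, rng, "chrB", chrB_len, avoid_B, [])
    rmsk_A = _rmsk_annotations(cfg, rng, truth)
    clade_map = CladeMap({"genomeB": "old"}, age_order=("old",))
    return World(
        cfg=cfg, proteins=proteins, genome_A=genome_A, genome_B=genome_B,
        genes_A=genes_A, genes_B=genes_B, rmsk_A=rmsk_A, truth=truth,
        clade_map=clade_map,
    )


def emit(world: World, outdir) -> Dict[str, Path]:
    """Write the world to files (FASTA, GFF3, .out, MAF, truth TSV);
    byte-deterministic for a fixed seed."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome_A": out / "genomeA.fa",
        "genome_B": out / "genomeB.fa",
        "proteins": out / "proteins.fa",
        "genes_A": out / "genomeA.gff3",
        "genes_B": out / "genomeB.gff3",
        "rmsk_A": out / "genomeA.rmsk.out",
        "maf": out / "A_to_B.maf",
        "truth": out / "truth.tsv",
    }
    write_fasta(world.genome_A, paths["genome_A"])
    write_fasta(world.genome_B, paths["genome_B"])
    write_fasta(world.proteins, paths["proteins"])
    write_gff3(world.genes_A, paths["genes_A"])
    write_gff3(world.genes_B, paths["genes_B"])
    write_repeatmasker_out(world.rmsk_A, paths["rmsk_A"])
    sizes = {r.id: len(r.residues) for r in world.genome_A + world.genome_B}
    write_maf(world.truth.all_blocks(), sizes, paths["maf"])

    rows = []
    for f in world.truth.fossils:
        rows.append(
            {
                "fossil_id": f.fossil_id,
                "source_protein": f.source_protein,
                "source_class": f.source_class,
                "strand": f.strand,
                "seq_A": f.interval_A[0] if f.interval_A else "",
                "start_A": f.interval_A[1] if f.interval_A else "",
                "end_A": f.interval_A[2] if f.interval_A else "",
                "seq_B": f.interval_B[0] if f.interval_B else "",
                "start_B": f.interval_B[1] if f.interval_B else "",
                "end_B": f.interval_B[2] if f.interval_B else "",
                "age_true": f.age_true,
                "disrupted": f.disrupted,
                "split_partner": f.split_partner or "",
                "is_trap": f.is_trap,
                "cds_overlap_planned": f.cds_overlap_planned,
            }
        )
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths
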