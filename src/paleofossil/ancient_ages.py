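"""Date fossils by conservation across genome pairs, and the downstream
Results machinery: unknown-repeat classification, long-range "genome
tectonics" pairs, and nearest-gene context.

A fossil is *conserved* relative to another genome when at least 30% of it
is covered by the coding-pruned, link-filtered one-to-one alignments to
that genome; its age is the oldest clade label among genomes it is
conserved in.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .fossil_calls import FossilCall
from .genome_pairs import PairwiseBlock
from .intervals import covered_length
from .io_formats import AnnotationRecord, GeneModel

#: the default clade ladder, young -> old
DEFAULT_AGE_ORDER = ("Amniote", "Tetrapod", "Sarcopterygian", "Gnathostome")


@dataclass
class CladeMap:
    """Maps each comparison genome to the clade age its conservation
    implies; labels are strictly ordered young -> old."""

    genome_labels: Dict[str, str]
    age_order: Tuple[str, ...] = DEFAULT_AGE_ORDER

    def __post_init__(self) -> None:
        if len(set(self.age_order)) != len(self.age_order):
            raise ValueError("age labels must be strictly ordered (unique)")
        for g, lab in self.genome_labels.items():
            if lab not in self.age_order:
                raise ValueError(f"genome {g}: unknown age label {lab!r}")

    def label_rank(self, label: str) -> int:
        return self.age_order.index(label)

    def oldest(self, labels: Sequence[str]) -> str:
        if not labels:
            return "—"
        return max(labels, key=self.label_rank)


@dataclass
class ConservationProfile:
    call: FossilCall
    covered_fraction: Dict[str, float]
    conserved: Dict[str, bool]
    age: str  # an age label, or "—" when conserved nowhere


@dataclass
class TectonicPair:
    """Two same-type fossils far apart on one sequence: candidate fragments
    of a single ancestral element rifted by younger insertions."""

    call_a: FossilCall
    call_b: FossilCall
    separation_bp: int
    same_type: bool = True


@dataclass
class GeneContext:
    nearest_gene: str
    relation: str  # "intergenic" | "intronic"
    intergene_length_kb: Optional[int] = None
    intron_length_kb: Optional[int] = None


def conservation_profile(
    call: FossilCall,
    blocks_per_genome: Dict[str, Sequence[PairwiseBlock]],
    clade_map: CladeMap,
    min_frac: float = 0.30,
) -> ConservationProfile:
    """Per-genome coverage of a fossil by (already pruned and linked)
    alignment blocks; conserved at coverage >= min_frac ("at least 30%"),
    aged by the oldest conserved clade."""
    fracs: Dict[str, float] = {}
    conserved: Dict[str, bool] = {}
    for genome, blocks in blocks_per_genome.items():
        if genome not in clade_map.genome_labels:
            raise KeyError(f"genome {genome!r} missing from clade map")
        ivs = [
            b.g1_interval
            for b in blocks
            if b.g1_seq == call.seq_id
        ]
        frac = covered_length(call.interval, ivs) / call.length
        fracs[genome] = frac
        conserved[genome] = frac >= min_frac
    age = clade_map.oldest(
        [clade_map.genome_labels[g] for g, ok in conserved.items() if ok]
    )
    return ConservationProfile(call=call, covered_fraction=fracs, conserved=conserved, age=age)


def classify_unknown_repeat(
    repeat_name: str,
    instances: Sequence[AnnotationRecord],
    fossils: Sequence[FossilCall],
    min_overlap_bp: int = 100,
    min_consistency: float = 0.80,
    min_instances: int = 3,
) -> Optional[str]:
    """Classify an "Unknown" repeat family from large, consistent overlaps
    with TE protein fossils.

    Collect fossils overlapping the repeat's instances by at least
    ``min_overlap_bp``; if at least ``min_instances`` such overlaps exist
    and at least ``min_consistency`` of them agree on one TE class/family,
    return that type, else None.
    """
    overlap_types: List[str] = []
    for inst in instances:
        if inst.name != repeat_name:
            raise ValueError(f"instance named {inst.name!r}, expected {repeat_name!r}")
        for f in fossils:
            if not f.is_te or f.seq_id != inst.seq_id:
                continue
            ov = min(f.end, inst.end) - max(f.start, inst.start)
            if ov >= min_overlap_bp:
                overlap_types.append(f.class_family)
    if len(overlap_types) < min_instances:
        return None
    (top, n_top), = Counter(overlap_types).most_common(1)
    if n_top / len(overlap_types) >= min_consistency:
        return top
    return None


def tectonic_pairs(
    calls: Sequence[FossilCall],
    min_sep: int = 30_000,
    max_sep: int = 3_000_000,
) -> List[TectonicPair]:
    """All unordered same-sequence, same-class/family pairs whose
    end-to-start separation lies in [min_sep, max_sep], sorted by
    separation."""
    groups: Dict[Tuple[str, str], List[FossilCall]] = {}
    for c in calls:
        if not c.is_te:
            continue
        groups.setdefault((c.seq_id, c.class_family), []).append(c)
    out: List[TectonicPair] = []
    for (_, _), grp in groups.items():
        grp = sorted(grp, key=lambda c: c.start)
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                a, b = grp[i], grp[j]
                sep = b.start - a.end
                if sep > max_sep:
                    break
                if sep >= min_sep:
                    out.append(TectonicPair(a, b, sep))
    out.sort(key=lambda p: p.separation_bp)
    return out


def nearest_gene(
    call: FossilCall,
    genes: Sequence[GeneModel],
    accession_filter: str = "NM_",
) -> GeneContext:
    """Gene context of a call, among genes with the given accession prefix.

    If the call lies wholly inside an intron of a gene, report that intron
    and its length; otherwise report the nearest gene by distance to its
    span and the length of the intergene gap between the two flanking gene
    spans.  Lengths are kb, rounded.
    """
    cand = [
        g for g in genes
        if g.accession.startswith(accession_filter) and g.seq_id == call.seq_id
    ]
    if not cand:
        raise ValueError(f"no genes with accession {accession_filter!r} on {call.seq_id}")

    for g in sorted(cand, key=lambda g: g.start):
        for (is_, ie) in g.introns():
            if is_ <= call.start and call.end <= ie:
                return GeneContext(
                    nearest_gene=g.gene_name,
                    relation="intronic",
                    intron_length_kb=round((ie - is_) / 1000),
                )

    def dist(g: GeneModel) -> int:
        if g.end <= call.start:
            return call.start - g.end
        if call.end <= g.start:
            return g.start - call.end
        return 0

    nearest = min(cand, key=lambda g: (dist(g), g.start))
    prev_end = max((g.end for g in cand if g.end <= call.start), default=None)
    next_start = min((g.start for g in cand if g.start >= call.end), default=None)
    if prev_end is not None and next_start is not None:
        intergene = next_start - prev_end
    elif prev_end is not None:
        intergene = call.end - prev_end
    elif next_start is not None:
        intergene = next_start - call.start
    else:
        intergene = 0
    return GeneContext(
        nearest_gene=nearest.gene_name,
        relation="intergenic",
        intergene_length_kb=round(intergene / 1000),
    )


REPORT_COLUMNS = [
    "type", "aligned_protein", "chromosome", "start", "length_bp",
    "nearest_gene", "intergene_length_kb", "intron_length_kb",
    "found_in", "evalue", "age",
]


def age_report(
    profiles: Sequence[ConservationProfile],
    gene_contexts: Optional[Sequence[Optional[GeneContext]]] = None,
) -> pd.DataFrame:
    """One report row per fossil call, in the standard column order."""
    if gene_contexts is None:
        gene_contexts = [None] * len(profiles)
    rows = []
    for prof, ctx in zip(profiles, gene_contexts):
        c = prof.call
        rows.append(
            {
                "type": c.class_family if c.is_te else "host_gene",
                "aligned_protein": c.protein_id,
                "chromosome": c.seq_id,
                "start": c.start,
                "length_bp": c.length,
                "nearest_gene": ctx.nearest_gene if ctx else "",
                "intergene_length_kb": ctx.intergene_length_kb if ctx else None,
                "intron_length_kb": ctx.intron_length_kb if ctx else None,
                "found_in": c.provenance,
                "evalue": c.evalue_genome,
                "age": prof.age,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_age_report(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_age_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str})
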