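"""Turn raw translated alignments into a fossil-call set.

The filtering chain is fixed and auditable: exclude exapted-protein names
-> align -> significance filter -> drop weaker overlapping homologies ->
remove calls inside protein-coding annotation -> drop host-gene calls that
are really TE-derived coding sequence.  Each rule's boundary behaviour
(">10%", "at most 10%", "nonzero overlap", same strand / same class) is
pinned by tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

from .align import TranslatedAlignment
from .intervals import IntervalSet, covered_length, merge
from .io_formats import AnnotationRecord, SeqRecord

#: protein-name substrings marking exapted genes shipped inside TE protein
#: libraries; hits to these are host genes, not fossils, and are excluded.
EXAPTED_NAME_PATTERNS = ("_HSgene", "_Hsa_", "UN-GIN", "_Xtr_eg_tp")

#: RepeatMasker classes that do not count as TE coverage when cleaning
#: host-gene calls (simple sequence is not evidence of TE ancestry).
EXEMPT_CLASSES = ("Low_complexity", "Simple_repeat")


@dataclass
class FossilCall:
    """A genomic interval attributed to a source protein.

    ``source_class`` is ``"TE:<class/family>"`` or ``"host_gene"``;
    ``provenance`` is ``"direct"`` or ``"projected:<genome>"`` for calls
    lifted from another genome through the inter-genome alignments.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    protein_id: str
    source_class: str
    score: int
    evalue_genome: float
    disrupted: bool = False
    provenance: str = "direct"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"call {self.protein_id}: end <= start")

    @property
    def is_te(self) -> bool:
        return self.source_class.startswith("TE:")

    @property
    def class_family(self) -> str:
        """The TE class/family string, e.g. ``LINE/L1``."""
        if not self.is_te:
            raise ValueError("host-gene call has no TE class/family")
        return self.source_class[3:]

    @property
    def te_class(self) -> str:
        return self.class_family.split("/", 1)[0]

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)


def calls_from_alignments(
    alns: Sequence[TranslatedAlignment],
    source_class_of: Dict[str, str],
) -> List[FossilCall]:
    """Build calls from alignments given a protein -> source-class map."""
    out = []
    for a in alns:
        out.append(
            FossilCall(
                seq_id=a.dna_id, start=a.dna_start, end=a.dna_end,
                strand=a.strand, protein_id=a.prot_id,
                source_class=source_class_of[a.prot_id],
                score=a.score, evalue_genome=a.evalue_genome,
                disrupted=a.is_disrupted(),
            )
        )
    return out


def exclude_exapted_proteins(
    proteins: Sequence[SeqRecord],
    patterns: Sequence[str] = EXAPTED_NAME_PATTERNS,
) -> List[SeqRecord]:
    """Drop proteins whose names mark them as exapted host genes."""
    return [p for p in proteins if not any(pat in p.id for pat in patterns)]


def drop_weaker_overlaps(calls: Sequence[FossilCall]) -> List[FossilCall]:
    """Keep only the strongest of overlapping homologies.

    Greedy by descending score; a call is kept iff it shares no genomic
    base — on either strand — with an already-kept call.  Ties break by
    (lower per-genome E-value, lower start, protein id).
    """
    order = sorted(
        calls,
        key=lambda c: (-c.score, c.evalue_genome, c.start, c.protein_id),
    )
    kept_by_seq: Dict[str, IntervalSet] = {}
    out = []
    for c in order:
        ks = kept_by_seq.setdefault(c.seq_id, IntervalSet())
        if ks.overlaps(c.start, c.end):
            continue
        ks.add(c.start, c.end)
        out.append(c)
    out.sort(key=lambda c: (c.seq_id, c.start))
    return out


def _coverage(call: FossilCall, intervals: Iterable[Tuple[int, int]]) -> float:
    return covered_length(call.interval, intervals) / call.length


def remove_coding_overlaps(
    calls: Sequence[FossilCall],
    cds_intervals: Sequence[AnnotationRecord],
    max_frac: float = 0.10,
) -> List[FossilCall]:
    """Remove calls more than ``max_frac`` covered by protein-coding
    annotation (union, strand-agnostic).  Exactly 10% is kept: the rule
    is ">10% removed"."""
    by_seq: Dict[str, List[Tuple[int, int]]] = {}
    for r in cds_intervals:
        by_seq.setdefault(r.seq_id, []).append(r.interval)
    by_seq = {k: merge(v) for k, v in by_seq.items()}
    return [
        c for c in calls if _coverage(c, by_seq.get(c.seq_id, [])) <= max_frac
    ]


def filter_hostgene_vs_te(
    calls: Sequence[FossilCall],
    rmsk: Sequence[AnnotationRecord],
    max_frac: float = 0.10,
    exempt_classes: Sequence[str] = EXEMPT_CLASSES,
) -> List[FossilCall]:
    """Drop host-gene calls >``max_frac`` covered by RepeatMasker TE
    annotation (classes other than Low_complexity/Simple_repeat).

    Such calls are true-but-unwanted homologies: host coding sequence that
    itself evolved from a TE.  TE calls pass through untouched.
    """
    by_seq: Dict[str, List[Tuple[int, int]]] = {}
    for r in rmsk:
        if r.te_class in exempt_classes:
            continue
        by_seq.setdefault(r.seq_id, []).append(r.interval)
    by_seq = {k: merge(v) for k, v in by_seq.items()}
    out = []
    for c in calls:
        if c.is_te:
            out.append(c)
        elif _coverage(c, by_seq.get(c.seq_id, [])) <= max_frac:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# novelty rules


def classify_novelty_table1(
    call: FossilCall, rmsk: Sequence[AnnotationRecord], max_frac: float = 0.10
) -> bool:
    """Novel iff at most ``max_frac`` of the call is covered by same-strand
    RepeatMasker TE annotations with a *known* class/family ("Unknown"
    does not count)."""
    if not call.is_te:
        raise ValueError("table-1 novelty applies to TE calls")
    ivs = [
        r.interval
        for r in rmsk
        if r.seq_id == call.seq_id
        and r.strand == call.strand
        and r.te_class not in ("Unknown", *EXEMPT_CLASSES)
    ]
    return _coverage(call, ivs) <= max_frac


def classify_not_new(call: FossilCall, rmsk: Sequence[AnnotationRecord]) -> bool:
    """"Not new" iff the call has nonzero overlap with a same-strand
    annotation of the same TE *class* (DNA, LINE, LTR, ...)."""
    te_class = call.te_class  # raises for host-gene calls
    if not te_class:
        raise ValueError(f"call {call.protein_id}: unparseable class")
    for r in rmsk:
        if (
            r.seq_id == call.seq_id
            and r.strand == call.strand
            and r.te_class == te_class
            and r.start < call.end
            and call.start < r.end
        ):
            return True
    return False


def pseudogene_novelty(
    call: FossilCall,
    known_pseudogenes: Sequence[AnnotationRecord],
    max_frac: float = 0.10,
) -> bool:
    """A host-gene call is novel iff at most ``max_frac`` of it overlaps
    same-strand known pseudogenes."""
    if call.is_te:
        raise ValueError("pseudogene novelty applies to host-gene calls")
    ivs = [
        r.interval
        for r in known_pseudogenes
        if r.seq_id == call.seq_id and r.strand == call.strand
    ]
    return _coverage(call, ivs) <= max_frac
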