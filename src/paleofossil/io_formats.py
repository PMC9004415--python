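"""Readers and writers for every external format the pipeline touches.

Internal convention: every coordinate held in memory is 0-based, half-open,
on the forward strand.  Each reader converts at the boundary (RepeatMasker
``.out`` and GFF3 are 1-based inclusive; MAF starts are strand-relative) and
each writer converts back.  Round-trip tests per dialect pin this down.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import AlignIO, SeqIO

log = logging.getLogger(__name__)

DNA_LETTERS = set("ACGTNacgtn")
AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY*")


# ---------------------------------------------------------------------------
# domain types


@dataclass
class SeqRecord:
    """A named sequence; ``kind`` is ``"dna"`` or ``"protein"``.

    Lowercase letters in DNA mark soft-masked positions and are preserved
    verbatim through read/write.
    """

    id: str
    residues: str
    kind: str = "dna"

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AnnotationRecord:
    """A stranded genomic interval carrying a repeat name and class/family.

    ``class_family`` is e.g. ``"LINE/CR1"``, ``"Unknown"``,
    ``"Low_complexity"``, ``"CDS"`` or ``"pseudogene"``; the part before a
    ``/`` is the class, the part after it the family.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    name: str
    class_family: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"annotation {self.name}: end ({self.end}) <= start ({self.start})"
            )
        if self.strand not in "+-":
            raise ValueError(f"annotation {self.name}: bad strand {self.strand!r}")

    @property
    def te_class(self) -> str:
        return self.class_family.split("/", 1)[0]

    @property
    def te_family(self) -> str:
        parts = self.class_family.split("/", 1)
        return parts[1] if len(parts) == 2 else ""

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)


@dataclass
class GeneModel:
    """A transcript-level gene model: ordered disjoint exons, CDS within."""

    gene_name: str
    accession: str
    seq_id: str
    start: int
    end: int
    strand: str
    exons: List[Tuple[int, int]] = field(default_factory=list)
    cds: List[Tuple[int, int]] = field(default_factory=list)

    def introns(self) -> List[Tuple[int, int]]:
        """Gaps between consecutive exons."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


# ---------------------------------------------------------------------------
# FASTA


def _infer_kind(residues: str) -> str:
    return "dna" if set(residues) <= DNA_LETTERS else "protein"


def read_fasta(path, kind: Optional[str] = None) -> List[SeqRecord]:
    """Read FASTA, preserving record order and letter case.

    The sequence kind (dna/protein) is inferred from the alphabet unless
    given.  Duplicate ids and empty sequences are errors.
    """
    records: List[SeqRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        residues = str(rec.seq)
        if not residues:
            raise ValueError(f"empty sequence for FASTA id: {rec.id}")
        records.append(SeqRecord(rec.id, residues, kind or _infer_kind(residues)))
    return records


def write_fasta(records: Sequence[SeqRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def append_stop(prot: SeqRecord) -> SeqRecord:
    """Append the stop symbol ``*`` to a protein, so fossil stop codons can
    be matched explicitly.

    Refuses proteins that already carry a ``*`` — idempotent use is a bug in
    the caller, not something to paper over.
    """
    if prot.kind != "protein":
        raise ValueError(f"append_stop: {prot.id} is not a protein record")
    if not prot.residues:
        raise ValueError(f"append_stop: empty protein {prot.id}")
    if "*" in prot.residues:
        raise ValueError(f"append_stop: {prot.id} already contains '*'")
    return SeqRecord(prot.id, prot.residues + "*", "protein")


# ---------------------------------------------------------------------------
# RepeatMasker


def read_repeatmasker(path, dialect: str = "out") -> List[AnnotationRecord]:
    """Read repeat annotations in RepeatMasker ``.out`` or UCSC rmsk-table
    dialect, normalising to 0-based half-open forward-strand coordinates.

    ``.out`` is whitespace-aligned with three header lines and 1-based
    inclusive coordinates; the rmsk table is tab-separated with
    ``genoStart``/``genoEnd`` already 0-based half-open.  The RepeatMasker
    ``C`` strand marker maps to ``-``.
    """
    records: List[AnnotationRecord] = []
    if dialect == "out":
        with open(path) as fh:
            lines = fh.read().splitlines()
        for lineno, line in enumerate(lines[3:], start=4):
            if not line.strip():
                continue
            f = line.split()
            try:
                seq_id = f[4]
                start = int(f[5]) - 1
                end = int(f[6])
                strand = "-" if f[8] in ("C", "-") else "+"
                name = f[9]
                class_family = f[10]
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: unparseable .out line {lineno}: {line!r}") from exc
            records.append(AnnotationRecord(seq_id, start, end, strand, name, class_family))
    elif dialect == "rmsk_table":
        with open(path) as fh:
            lines = fh.read().splitlines()
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                seq_id = f[5]
                start = int(f[6])
                end = int(f[7])
                strand = "-" if f[9] in ("C", "-") else "+"
                name = f[10]
                rep_class = f[11]
                rep_family = f[12] if len(f) > 12 else ""
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: unparseable rmsk line {lineno}: {line!r}") from exc
            cf = f"{rep_class}/{rep_family}" if rep_family and rep_family != rep_class else rep_class
            records.append(AnnotationRecord(seq_id, start, end, strand, name, cf))
    else:
        raise ValueError(f"unknown RepeatMasker dialect: {dialect}")
    return records


_OUT_HEADER = (
    "   SW   perc perc perc  query     position in query     matching"
    "  repeat       position in repeat\n"
    "score   div. del. ins.  sequence  begin end    (left)   repeat"
    "       class/family  begin end    (left)  ID\n"
    "\n"
)


def write_repeatmasker_out(records: Sequence[AnnotationRecord], path) -> None:
    """Fixture-grade ``.out`` writer (synthetic annotations, round-trips
    through :func:`read_repeatmasker`)."""
    with open(path, "w") as fh:
        fh.write(_OUT_HEADER)
        for i, r in enumerate(records, start=1):
            strand = "C" if r.strand == "-" else "+"
            fh.write(
                f"  100   10.0  0.0  0.0  {r.seq_id}  {r.start + 1} {r.end} (0)  "
                f"{strand}  {r.name}  {r.class_family}  1 100 (0)  {i}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 (CDS + gene models)


def read_cds(path) -> Tuple[List[AnnotationRecord], List[GeneModel]]:
    """Read a GFF3 file; return (CDS annotation records, gene models).

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    CDS features lacking a parent transcript are kept as orphan intervals
    with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    cds_records: List[AnnotationRecord] = []
    genes: List[GeneModel] = []

    for mrna in db.features_of_type(("mRNA", "transcript")):
        gene_name = mrna.attributes.get("gene", [None])[0]
        if gene_name is None:
            parents = list(db.parents(mrna, featuretype="gene"))
            if parents:
                gene_name = parents[0].attributes.get(
                    "Name", parents[0].attributes.get("ID", ["?"])
                )[0]
            else:
                gene_name = mrna.attributes.get("Name", [mrna.id])[0]
        accession = mrna.attributes.get("transcript_id", [mrna.id])[0]
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
        genes.append(
            GeneModel(
                gene_name=gene_name,
                accession=accession,
                seq_id=mrna.seqid,
                start=mrna.start - 1,
                end=mrna.end,
                strand=mrna.strand,
                exons=exons or cds,
                cds=cds,
            )
        )

    n_orphans = 0
    for f in db.features_of_type("CDS"):
        if "Parent" not in f.attributes:
            n_orphans += 1
        name = f.attributes.get("Parent", [f.id or "orphan_CDS"])[0]
        cds_records.append(
            AnnotationRecord(f.seqid, f.start - 1, f.end, f.strand, name, "CDS")
        )
    if n_orphans:
        warnings.warn(f"{path}: {n_orphans} CDS feature(s) without a parent transcript")
    return cds_records, genes


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene -> mRNA -> exon/CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(genes):
            gid = f"gene{i}"
            tid = g.accession
            fh.write(
                f"{g.seq_id}\tpaleofossil\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={gid};Name={g.gene_name}\n"
            )
            fh.write(
                f"{g.seq_id}\tpaleofossil\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={tid};Parent={gid};gene={g.gene_name};"
                f"transcript_id={tid}\n"
            )
            for j, (s, e) in enumerate(g.exons):
                fh.write(
                    f"{g.seq_id}\tpaleofossil\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={tid}.exon{j};Parent={tid}\n"
                )
            for j, (s, e) in enumerate(g.cds):
                fh.write(
                    f"{g.seq_id}\tpaleofossil\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={tid}.cds{j};Parent={tid}\n"
                )


# ---------------------------------------------------------------------------
# MAF (pairwise genome-genome blocks)


def read_maf(path):
    """Read a pairwise MAF file into :class:`~paleofossil.genome_pairs.PairwiseBlock`\\ s.

    MAF ``s`` line starts are 0-based and strand-relative; reverse-strand
    starts are converted to forward-strand absolute coordinates
    (``fwd_start = srcSize - (start + size)``).  The block strand is the
    orientation of the second row relative to the first.  Rows whose aligned
    texts differ in length raise with the block index.
    """
    from .genome_pairs import PairwiseBlock

    # Bio.AlignIO discards the "a" line annotations; recover scores by a
    # pre-scan (blocks come back in file order)
    scores: List[float] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("a"):
                kv = dict(p.split("=", 1) for p in line[1:].split() if "=" in p)
                scores.append(float(kv.get("score", 0.0)))

    blocks: List[PairwiseBlock] = []
    with open(path) as fh:
        for idx, aln in enumerate(AlignIO.parse(fh, "maf")):
            if len(aln) != 2:
                raise ValueError(f"MAF block {idx}: expected 2 rows, got {len(aln)}")
            rows = []
            texts = {len(str(rec.seq)) for rec in aln}
            if len(texts) != 1:
                raise ValueError(f"MAF block {idx}: row length mismatch")
            for rec in aln:
                start = rec.annotations["start"]
                size = rec.annotations["size"]
                strand = rec.annotations["strand"]
                src_size = rec.annotations["srcSize"]
                if strand == -1:
                    fwd_start = src_size - (start + size)
                else:
                    fwd_start = start
                rows.append((rec.id, fwd_start, fwd_start + size, strand))
            strand = "+" if rows[0][3] == rows[1][3] else "-"
            score = scores[idx] if idx < len(scores) else 0.0
            blocks.append(
                PairwiseBlock(
                    g1_seq=rows[0][0], g1_start=rows[0][1], g1_end=rows[0][2],
                    g2_seq=rows[1][0], g2_start=rows[1][1], g2_end=rows[1][2],
                    strand=strand, score=score,
                )
            )
    return blocks


def write_maf(blocks, seq_sizes: Dict[str, int], path) -> None:
    """Write pairwise blocks as a MAF file.

    The alignment text is a placeholder run of ``N``/gap columns of the
    right lengths (block coordinates, strand and score are authoritative;
    column-level text is not carried by :class:`PairwiseBlock`).
    """
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=paleofossil\n")
        for b in blocks:
            l1 = b.g1_end - b.g1_start
            l2 = b.g2_end - b.g2_start
            width = max(l1, l2)
            t1 = "N" * l1 + "-" * (width - l1)
            t2 = "N" * l2 + "-" * (width - l2)
            fh.write(f"a score={b.score:g}\n")
            fh.write(
                f"s {b.g1_seq} {b.g1_start} {l1} + {seq_sizes[b.g1_seq]} {t1}\n"
            )
            if b.strand == "+":
                s2 = b.g2_start
            else:
                s2 = seq_sizes[b.g2_seq] - b.g2_end
            strand2 = b.strand
            fh.write(
                f"s {b.g2_seq} {s2} {l2} {strand2} {seq_sizes[b.g2_seq]} {t2}\n"
            )
            fh.write("\n")


# ---------------------------------------------------------------------------
# translated MAF (DNA <-> protein alignments, own documented dialect)
#
# a score=<int> E=<float> EG=<float>
# s <dna_id> <fwd_start> <span> <strand> <srcSize> <codon text>
# s <prot_id> <start> <span> + <srcSize> <aa text>
#
# Column encoding: each codon<->aa column contributes 3 DNA letters and one
# aa letter padded to 3 (`M--`); codon<->gap is 3 letters over `---`;
# gap<->aa is `---` over aa; a frameshift column is `>..`/`<..` in the DNA
# row over `#--` in the protein row (+1 consumes one DNA letter, shown after
# `>`; -1 consumes none and is shown as `<--`).


def write_translated_maf(alignments, seq_sizes: Dict[str, int], prot_sizes: Dict[str, int], path) -> None:
    from .align import TranslatedAlignment  # noqa: F401  (type of items)

    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=paleofossil-translated\n")
        for a in alignments:
            dna_txt, aa_txt = [], []
            for col in a.columns:
                kind = col[0]
                if kind == "M":
                    dna_txt.append(col[1])
                    aa_txt.append(col[2] + "--")
                elif kind == "I":
                    dna_txt.append(col[1])
                    aa_txt.append("---")
                elif kind == "D":
                    dna_txt.append("---")
                    aa_txt.append(col[2] + "--")
                else:  # frameshift
                    if col[1] == 1:
                        dna_txt.append(">" + col[2] + "-")
                    else:
                        dna_txt.append("<--")
                    aa_txt.append("#--")
            fh.write(f"a score={a.score} E={a.evalue_chrom:g} EG={a.evalue_genome:g}\n")
            fh.write(
                f"s {a.dna_id} {a.dna_start} {a.dna_end - a.dna_start} {a.strand} "
                f"{seq_sizes[a.dna_id]} {''.join(dna_txt)}\n"
            )
            fh.write(
                f"s {a.prot_id} {a.prot_start} {a.prot_end - a.prot_start} + "
                f"{prot_sizes[a.prot_id]} {''.join(aa_txt)}\n"
            )
            fh.write("\n")


def read_translated_maf(path):
    """Read the translated-MAF dialect written by :func:`write_translated_maf`."""
    from .align import TranslatedAlignment

    out = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        ln = lines[i]
        if ln.startswith("a "):
            meta = dict(kv.split("=") for kv in ln[2:].split())
            s1 = lines[i + 1].split()
            s2 = lines[i + 2].split()
            dna_id, dna_start, dna_span, strand = s1[1], int(s1[2]), int(s1[3]), s1[4]
            prot_id, prot_start, prot_span = s2[1], int(s2[2]), int(s2[3])
            dna_txt, aa_txt = s1[6], s2[6]
            if len(dna_txt) != len(aa_txt):
                raise ValueError(f"{path}: row length mismatch in block at line {i + 1}")
            columns = []
            for k in range(0, len(dna_txt), 3):
                d = dna_txt[k : k + 3]
                p = aa_txt[k : k + 3]
                if p[0] == "#":
                    if d[0] == ">":
                        columns.append(("F", 1, d[1]))
                    else:
                        columns.append(("F", -1, ""))
                elif d == "---":
                    columns.append(("D", None, p[0]))
                elif p == "---":
                    columns.append(("I", d, None))
                else:
                    columns.append(("M", d, p[0]))
            out.append(
                TranslatedAlignment(
                    dna_id=dna_id, dna_start=dna_start, dna_end=dna_start + dna_span,
                    strand=strand, prot_id=prot_id, prot_start=prot_start,
                    prot_end=prot_start + prot_span, columns=columns,
                    score=int(meta["score"]), evalue_chrom=float(meta["E"]),
                    evalue_genome=float(meta["EG"]),
                )
            )
            i += 3
        else:
            i += 1
    return out
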