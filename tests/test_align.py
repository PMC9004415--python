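import numpy as np
import pytest

from paleofossil import (
    SeqRecord,
    aa_identity,
    align_local,
    attach_evalues,
    disruption_stats,
    reverse_decoy,
    search_genome,
)
from paleofossil.align import SearchParams, reverse_complement
from paleofossil.scoring import AA_INDEX, CODONS, GENETIC_CODE

AAS20 = "ACDEFGHIKLMNPQRSTVWY"


def best_codon(model, aa):
    return CODONS[int(np.argmax(model.subst[:, AA_INDEX[aa]]))]


def reverse_translate(model, prot):
    return "".join(best_codon(model, a) for a in prot)


def test_exact_reverse_translation_scores_sum_of_row_maxima(model):
    prot = "MKV*"
    dna = reverse_translate(model, prot)
    alns = align_local(SeqRecord("d", dna), SeqRecord("p", prot, "protein"), model, 5)
    assert len(alns) == 1
    a = alns[0]
    assert a.score == sum(int(model.subst[:, AA_INDEX[x]].max()) for x in prot)
    assert not a.frameshift_events()
    assert aa_identity(a) == 1.0


def test_single_deleted_nucleotide_yields_one_minus_frameshift(model):
    assert model.frameshift < model.gap_open + model.gap_extend
    prot = "MKVLLEDAKR*"
    dna = reverse_translate(model, prot)
    dna = dna[:16] + dna[17:]  # delete one nucleotide inside the fossil
    alns = align_local(SeqRecord("d", dna), SeqRecord("p", prot, "protein"), model, 10)
    a = max(alns, key=lambda x: x.score)
    ev = a.frameshift_events()
    assert len(ev) == 1 and ev[0].direction == -1
    # frameshifts are interior by construction
    assert 0 < ev[0].position < len(a.columns) - 1


def test_alignment_bookkeeping_invariants(model):
    rng = np.random.default_rng(31)
    for _ in range(25):
        prot = "".join(rng.choice(list(AAS20), size=rng.integers(4, 12))) + "*"
        dna = reverse_translate(model, prot)
        # sprinkle mutations
        dna = "".join(
            c if rng.random() > 0.2 else "ACGT"[int(rng.integers(4))] for c in dna
        )
        for a in align_local(SeqRecord("d", dna), SeqRecord("p", prot, "protein"), model, 8):
            assert a.nucleotides_consumed() == a.dna_end - a.dna_start
            assert a.aa_consumed() == a.prot_end - a.prot_start
            assert a.recompute_score(model) == a.score


def test_strand_symmetry(model):
    """Aligning the reverse complement flips strand labels but preserves
    scores and coordinates exactly."""
    rng = np.random.default_rng(5)
    prot = "".join(rng.choice(list(AAS20), size=8)) + "*"
    dna = reverse_translate(model, prot)
    dna = "A" * 7 + dna + "CC"
    fwd = align_local(SeqRecord("d", dna), SeqRecord("p", prot, "protein"), model, 10)
    rev = align_local(
        SeqRecord("d", reverse_complement(dna)), SeqRecord("p", prot, "protein"), model, 10
    )
    n = len(dna)
    key_f = sorted((a.score, a.dna_start, a.dna_end, a.strand) for a in fwd)
    key_r = sorted((a.score, n - a.dna_end, n - a.dna_start,
                    "+" if a.strand == "-" else "-") for a in rev)
    assert key_f == key_r


def test_no_overlapping_weaker_alignment_returned(model):
    rng = np.random.default_rng(77)
    prot = "".join(rng.choice(list(AAS20), size=10)) + "*"
    dna = reverse_translate(model, prot) * 3
    alns = align_local(SeqRecord("d", dna), SeqRecord("p", prot, "protein"), model, 10)
    ivs = sorted((a.dna_start, a.dna_end) for a in alns)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        assert e1 <= s2  # pairwise disjoint on the genome


def test_soft_mask_blocks_seeding_but_not_extension(model):
    prot = "MKVLLEDAKR*"
    dna = reverse_translate(model, prot)
    # fully lowercased fossil: no seed, no alignment
    masked = dna.lower()
    assert align_local(SeqRecord("d", masked), SeqRecord("p", prot, "protein"), model, 10) == []
    # half-masked: alignment may extend into the masked run
    half = dna[: len(dna) // 2] + dna[len(dna) // 2 :].lower()
    alns = align_local(SeqRecord("d", half), SeqRecord("p", prot, "protein"), model, 10)
    assert alns and max(a.score for a in alns) == sum(
        int(model.subst[:, AA_INDEX[x]].max()) for x in prot
    )


def test_hard_masking_only_lowers_scores(model):
    """Replacing soft-masked runs with N can only lower or preserve scores
    (N scores as the minimum over its expansions)."""
    rng = np.random.default_rng(13)
    for _ in range(10):
        prot = "".join(rng.choice(list(AAS20), size=8)) + "*"
        dna = reverse_translate(model, prot)
        cut = rng.integers(3, len(dna) - 3)
        soft = dna[:cut] + dna[cut:].lower()
        hard = dna[:cut] + "N" * (len(dna) - cut)
        a_soft = align_local(SeqRecord("d", soft), SeqRecord("p", prot, "protein"), model, 5)
        a_hard = align_local(SeqRecord("d", hard), SeqRecord("p", prot, "protein"), model, 5)
        best_soft = max((a.score for a in a_soft), default=0)
        best_hard = max((a.score for a in a_hard), default=0)
        assert best_hard <= best_soft


def test_aa_identity_matches_naive_recount(model):
    rng = np.random.default_rng(19)
    for _ in range(300):
        prot = "".join(rng.choice(list(AAS20), size=rng.integers(4, 10))) + "*"
        dna = reverse_translate(model, prot)
        dna = "".join(
            c if rng.random() > 0.3 else "ACGT"[int(rng.integers(4))] for c in dna
        )
        alns = align_local(SeqRecord("d", dna), SeqRecord("p", prot, "protein"), model, 8)
        for a in alns:
            m_cols = [c for c in a.columns if c[0] == "M"]
            naive = sum(
                1 for c in m_cols
                if "N" not in c[1].upper() and GENETIC_CODE[c[1].upper()] == c[2]
            )
            assert aa_identity(a) == pytest.approx(naive / len(m_cols))


def test_aa_identity_zero_and_error(model):
    from paleofossil.align import TranslatedAlignment

    aln = TranslatedAlignment("d", 0, 3, "+", "p", 0, 1,
                              [("M", "AAA", "W")], 0)
    assert aa_identity(aln) == 0.0  # AAA encodes K, not W
    empty = TranslatedAlignment("d", 0, 3, "+", "p", 0, 0, [("I", "AAA", None)], 0)
    with pytest.raises(ValueError):
        aa_identity(empty)


def test_reverse_decoy_reverses_without_complement():
    out = reverse_decoy([SeqRecord("g", "ACGT")])
    assert out[0].residues == "TGCA"
    assert out[0].id == "g_rev"
    # involution modulo the id suffix
    back = reverse_decoy(out)
    assert back[0].residues == "ACGT"


def test_disruption_stats(model):
    from paleofossil.align import TranslatedAlignment

    clean = TranslatedAlignment("d", 0, 3, "+", "p", 0, 1, [("M", "ATG", "M")], 5)
    stopped = TranslatedAlignment("d", 0, 3, "+", "p", 0, 1, [("M", "TAA", "K")], 5)
    shifted = TranslatedAlignment("d", 0, 8, "+", "p", 0, 2,
                                  [("M", "ATG", "M"), ("F", -1, ""), ("M", "AAA", "K")], 5)
    assert disruption_stats([clean]) == {"n": 1, "frac_disrupted": 0.0}
    assert disruption_stats([clean, stopped])["frac_disrupted"] == 0.5
    assert shifted.is_disrupted()
    assert disruption_stats([]) == {"n": 0, "frac_disrupted": None}
    # a genuine stop-to-stop match is not a disruption
    stop_match = TranslatedAlignment("d", 0, 3, "+", "p", 0, 1, [("M", "TAA", "*")], 5)
    assert not stop_match.is_disrupted()


def test_search_genome_finds_planted_copy(model):
    rng = np.random.default_rng(55)
    prot = "".join(rng.choice(list(AAS20), size=120)) + "*"
    fossil = reverse_translate(model, prot)
    genome = (
        "".join(rng.choice(list("ACGT"), size=3000))
        + fossil
        + "".join(rng.choice(list("ACGT"), size=3000))
    )
    hits = search_genome(
        [SeqRecord("chr", genome)], [SeqRecord("p", prot, "protein")], model, 60
    )
    assert hits
    best = max(hits, key=lambda a: a.score)
    assert best.dna_start >= 2990 and best.dna_end <= 3000 + len(fossil) + 10
    attach_evalues(hits, model, {"chr": len(genome)}, len(prot))
    assert best.evalue_genome < 1e-6


def test_search_genome_minus_strand_coordinates(model):
    rng = np.random.default_rng(56)
    prot = "".join(rng.choice(list(AAS20), size=100)) + "*"
    fossil = reverse_complement(reverse_translate(model, prot))
    genome = (
        "".join(rng.choice(list("ACGT"), size=2000))
        + fossil
        + "".join(rng.choice(list("ACGT"), size=2000))
    )
    hits = search_genome(
        [SeqRecord("chr", genome)], [SeqRecord("p", prot, "protein")], model, 60
    )
    best = max(hits, key=lambda a: a.score)
    assert best.strand == "-"
    assert abs(best.dna_start - 2000) < 10
    assert abs(best.dna_end - (2000 + len(fossil))) < 10
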