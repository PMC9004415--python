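import numpy as np
import pytest

from paleofossil.fossil_calls import (
    FossilCall,
    classify_not_new,
    classify_novelty_table1,
    drop_weaker_overlaps,
    exclude_exapted_proteins,
    filter_hostgene_vs_te,
    pseudogene_novelty,
    remove_coding_overlaps,
)
from paleofossil.io_formats import AnnotationRecord, SeqRecord
from oracles import greedy_overlap_reference


def mk_call(start, end, score=100, seq="chr1", strand="+", prot="P1",
            cls="TE:LINE/L1", ev=1e-5):
    return FossilCall(seq, start, end, strand, prot, cls, score, ev)


def ann(start, end, strand="+", cls="LINE/L1", seq="chr1", name="rep"):
    return AnnotationRecord(seq, start, end, strand, name, cls)


# ---------------------------------------------------------------------------
# exapted-name exclusion


@pytest.mark.parametrize(
    "name,kept",
    [
        ("L1_HSgene_p1", False),
        ("Foo_Hsa_bar", False),
        ("UN-GIN-22_x", False),
        ("frog_Xtr_eg_tp", False),
        ("L1-2_LCh_pol", True),
    ],
)
def test_exclude_exapted_protein_names(name, kept):
    out = exclude_exapted_proteins([SeqRecord(name, "MKL", "protein")])
    assert bool(out) == kept


def test_exclusion_is_a_partition():
    rng = np.random.default_rng(2)
    tags = ["_HSgene", "_Hsa_", "UN-GIN", "_Xtr_eg_tp", "_SIM", "_pol", "_LCh"]
    prots = [
        SeqRecord(f"P{i}{tags[int(rng.integers(len(tags)))]}", "MK", "protein")
        for i in range(100)
    ]
    kept = exclude_exapted_proteins(prots)
    removed = [p for p in prots if p not in kept]
    assert len(kept) + len(removed) == len(prots)
    assert all(any(t in p.id for t in ("_HSgene", "_Hsa_", "UN-GIN", "_Xtr_eg_tp"))
               for p in removed)


# ---------------------------------------------------------------------------
# strongest-overlap retention


def test_identical_intervals_keep_only_stronger():
    calls = [mk_call(0, 100, score=90), mk_call(0, 100, score=80)]
    out = drop_weaker_overlaps(calls)
    assert len(out) == 1 and out[0].score == 90


def test_disjoint_calls_all_kept():
    calls = [mk_call(0, 100), mk_call(100, 200), mk_call(500, 600)]
    assert len(drop_weaker_overlaps(calls)) == 3


def test_overlap_is_strand_agnostic():
    calls = [mk_call(0, 100, score=90, strand="+"),
             mk_call(50, 150, score=80, strand="-")]
    out = drop_weaker_overlaps(calls)
    assert len(out) == 1 and out[0].score == 90


def test_drop_weaker_matches_quadratic_reference():
    rng = np.random.default_rng(40)
    calls = []
    for i in range(1000):
        s = int(rng.integers(0, 50_000))
        calls.append(
            mk_call(
                s, s + int(rng.integers(50, 800)),
                score=int(rng.integers(10, 500)),
                seq=f"chr{int(rng.integers(3))}",
                prot=f"P{i}", ev=float(rng.uniform(0, 1)),
            )
        )
    mine = drop_weaker_overlaps(calls)
    ref = greedy_overlap_reference(
        calls,
        key_fn=lambda c: (-c.score, c.evalue_genome, c.start, c.protein_id),
        interval_fn=lambda c: (c.seq_id, c.start, c.end),
    )
    key = lambda c: (c.seq_id, c.start, c.end, c.protein_id)
    assert sorted(map(key, mine)) == sorted(map(key, ref))
    # output is overlap-free
    by_seq = {}
    for c in mine:
        by_seq.setdefault(c.seq_id, []).append((c.start, c.end))
    for ivs in by_seq.values():
        ivs.sort()
        assert all(e1 <= s2 for (_, e1), (s2, _) in zip(ivs, ivs[1:]))


# ---------------------------------------------------------------------------
# coding-overlap removal (">10%")


def test_coding_overlap_boundary():
    cds = [ann(0, 10, cls="CDS"), ann(200, 211, cls="CDS")]
    kept_call = mk_call(0, 100)       # exactly 10% covered -> kept
    removed_call = mk_call(200, 300)  # 11% covered -> removed
    out = remove_coding_overlaps([kept_call, removed_call], cds)
    assert out == [kept_call]


def test_coding_overlap_matches_bitmap_oracle():
    from oracles import bitmap_covered

    rng = np.random.default_rng(41)
    for _ in range(1000):
        s = int(rng.integers(0, 5000))
        call = mk_call(s, s + int(rng.integers(20, 400)))
        cds = [
            ann(int(x), int(x) + int(rng.integers(5, 200)), cls="CDS")
            for x in rng.integers(0, 5500, size=rng.integers(0, 6))
        ]
        out = remove_coding_overlaps([call], cds)
        frac = bitmap_covered(call.interval, [c.interval for c in cds]) / call.length
        assert (call in out) == (frac <= 0.10)


# ---------------------------------------------------------------------------
# host-gene vs TE cleanup


def test_hostgene_covered_by_sine_removed():
    call = mk_call(0, 100, cls="host_gene")
    assert filter_hostgene_vs_te([call], [ann(0, 50, cls="SINE/MIR")]) == []


def test_hostgene_simple_repeat_exempt():
    call = mk_call(0, 100, cls="host_gene")
    rmsk = [ann(0, 100, cls="Simple_repeat"), ann(0, 100, cls="Low_complexity")]
    assert filter_hostgene_vs_te([call], rmsk) == [call]


def test_te_calls_pass_through_untouched():
    call = mk_call(0, 100, cls="TE:LINE/L1")
    assert filter_hostgene_vs_te([call], [ann(0, 100, cls="SINE/MIR")]) == [call]


# ---------------------------------------------------------------------------
# novelty rules


def test_novelty_table1():
    call = mk_call(0, 100)
    assert classify_novelty_table1(call, [])  # 0% covered -> novel
    assert not classify_novelty_table1(call, [ann(0, 50, cls="LINE/L2")])
    # Unknown class does not count as known annotation
    assert classify_novelty_table1(call, [ann(0, 50, cls="Unknown")])
    # opposite strand does not count
    assert classify_novelty_table1(call, [ann(0, 50, strand="-", cls="LINE/L2")])
    # exactly 10% is still novel ("at most 10%")
    assert classify_novelty_table1(call, [ann(0, 10, cls="LINE/L2")])
    assert not classify_novelty_table1(call, [ann(0, 11, cls="LINE/L2")])


def test_not_new_rule():
    call = mk_call(100, 200, cls="TE:LINE/L1")
    # one shared base, same strand, same class -> not new
    assert classify_not_new(call, [ann(199, 300, cls="LINE/CR1")])
    # large overlap but opposite strand -> new
    assert not classify_not_new(call, [ann(100, 200, strand="-", cls="LINE/L1")])
    # different class -> new
    assert not classify_not_new(call, [ann(100, 200, cls="LTR/Gypsy")])
    # zero overlap -> new
    assert not classify_not_new(call, [ann(200, 300, cls="LINE/L1")])


def test_pseudogene_novelty_boundary():
    call = mk_call(0, 100, cls="host_gene")
    pg = lambda e: [ann(0, e, cls="pseudogene")]
    assert pseudogene_novelty(call, pg(10))       # exactly 10% -> novel
    assert not pseudogene_novelty(call, pg(11))   # 11% -> not novel
    # opposite-strand pseudogenes do not count
    assert pseudogene_novelty(call, [ann(0, 50, strand="-", cls="pseudogene")])


def test_pseudogene_novelty_matches_oracle():
    from oracles import bitmap_covered

    rng = np.random.default_rng(42)
    for _ in range(500):
        s = int(rng.integers(0, 3000))
        call = mk_call(s, s + int(rng.integers(20, 300)), cls="host_gene")
        pgs = [
            ann(int(x), int(x) + int(rng.integers(5, 150)),
                strand="+" if rng.random() < 0.5 else "-", cls="pseudogene")
            for x in rng.integers(0, 3300, size=rng.integers(0, 5))
        ]
        same = [p.interval for p in pgs if p.strand == call.strand]
        frac = bitmap_covered(call.interval, same) / call.length
        assert pseudogene_novelty(call, pgs) == (frac <= 0.10)


# ---------------------------------------------------------------------------
# filter idempotence


def test_filter_chain_is_idempotent():
    rng = np.random.default_rng(43)
    calls = []
    for i in range(200):
        s = int(rng.integers(0, 20_000))
        calls.append(
            mk_call(
                s, s + int(rng.integers(30, 400)),
                score=int(rng.integers(10, 500)), prot=f"P{i}",
                cls="host_gene" if i % 4 == 0 else "TE:LINE/L1",
            )
        )
    cds = [ann(int(x), int(x) + 100, cls="CDS") for x in rng.integers(0, 20_000, 20)]
    rmsk = [ann(int(x), int(x) + 200, cls="SINE/MIR") for x in rng.integers(0, 20_000, 20)]

    def chain(cs):
        cs = drop_weaker_overlaps(cs)
        cs = remove_coding_overlaps(cs, cds)
        return filter_hostgene_vs_te(cs, rmsk)

    once = chain(calls)
    twice = chain(once)
    assert [c.protein_id for c in twice] == [c.protein_id for c in once]
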