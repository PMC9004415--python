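"""The 64x21 codon <-> amino-acid scoring model and E-value machinery.

A fossil is compared to a protein at codon resolution: the substitution
matrix is indexed by (codon, amino acid-or-stop), so it can prefer e.g.
``aac`` (asparagine) matched to N over a serine codon, which a 20x20
amino-acid matrix cannot express.  Scores are integer log-odds::

    s(c, a) = round(t * ln( P(c, a) / (p_c * q_a) ))

where ``P`` is the aligned-column distribution (from counts plus a
pseudocount), ``p``/``q`` the codon and amino-acid backgrounds, and ``t``
the log-odds temperature (``scale_t``).  Gap and frameshift costs come from
event frequencies by the same rule.

Significance follows the Karlin-Altschul form ``E = K m n exp(-lambda S)``.
``lambda`` is solved from the ungapped stationarity equation
``sum p_c q_a exp(lambda s) = 1``; ``K`` is fitted empirically by running
the full seeded search on shuffled DNA (see :func:`paleofossil.align.calibrate_evalues`),
so the reported E-values describe the search actually performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Optional, Tuple, Union

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy.optimize import brentq

BASES = "ACGT"
CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AAS = "ACDEFGHIKLMNPQRSTVWY*"
AA_INDEX = {a: i for i, a in enumerate(AAS)}

GENETIC_CODE: Dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    GENETIC_CODE[_stop] = "*"

#: codon index (0..63) -> amino-acid index (0..20)
CODON_TO_AA = np.array([AA_INDEX[GENETIC_CODE[c]] for c in CODONS], dtype=np.int8)


@dataclass
class ScoringModel:
    """Integer scoring parameters plus the E-value scale.

    ``subst`` is (64, 21); ``gap_open``/``gap_extend`` are affine costs in
    protein-length units (one gap unit = one codon or one amino acid);
    ``frameshift`` is the cost of a +-1 nucleotide shift between codon
    columns.  ``lambda_`` and ``k_`` parameterise E-values; ``scale_t`` is
    the temperature the matrix was built at.
    """

    subst: np.ndarray
    gap_open: int
    gap_extend: int
    frameshift: int
    lambda_: float
    k_: float
    scale_t: float
    background_codon: np.ndarray = field(repr=False, default=None)
    background_aa: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.subst = np.asarray(self.subst, dtype=np.int32)
        if self.subst.shape != (64, 21):
            raise ValueError("subst must be 64x21")
        for name in ("gap_open", "gap_extend", "frameshift"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive cost")
        self._subst125: Optional[np.ndarray] = None

    # -- degenerate-base handling ------------------------------------------
    def subst125(self) -> np.ndarray:
        """Substitution matrix over base-5 codon codes (A,C,G,T,N).

        A codon containing N scores as the minimum over its expansions —
        conservative, so hard-masking can only lower scores.
        """
        if self._subst125 is None:
            m = np.empty((125, 21), dtype=np.int32)
            for b0 in range(5):
                for b1 in range(5):
                    for b2 in range(5):
                        idx = b0 * 25 + b1 * 5 + b2
                        e0 = range(4) if b0 == 4 else (b0,)
                        e1 = range(4) if b1 == 4 else (b1,)
                        e2 = range(4) if b2 == 4 else (b2,)
                        rows = [
                            self.subst[x * 16 + y * 4 + z]
                            for x in e0 for y in e1 for z in e2
                        ]
                        m[idx] = np.min(rows, axis=0)
            self._subst125 = m
        return self._subst125

    def expected_background_score(self) -> float:
        p = self.background_codon
        q = self.background_aa
        if p is None or q is None:
            return float("nan")
        return float(np.sum(p[:, None] * q[None, :] * self.subst))


# ---------------------------------------------------------------------------
# backgrounds


def codon_usage(gc: float = 0.41) -> np.ndarray:
    """I.i.d.-base codon usage at the given GC content (64-vector)."""
    pb = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    u = np.empty(64)
    for i in range(64):
        u[i] = pb[i // 16] * pb[(i // 4) % 4] * pb[i % 4]
    return u


def aa_background(usage: np.ndarray) -> np.ndarray:
    """Amino-acid (plus stop) marginal of a codon usage vector."""
    q = np.zeros(21)
    np.add.at(q, CODON_TO_AA, usage)
    return q


# ---------------------------------------------------------------------------
# model construction


def model_from_counts(
    column_counts: Union[np.ndarray, Dict[Tuple[str, str], float]],
    background_codon: np.ndarray,
    background_aa: np.ndarray,
    pseudocount: float = 0.0,
    scale_t: float = 3.0,
    gap_open_freq: float = 0.008,
    gap_extend_freq: float = 0.25,
    frameshift_freq: float = 0.004,
) -> ScoringModel:
    """Build a scoring model from aligned-column counts by log-odds.

    ``column_counts`` is a (64, 21) array or a {(codon, aa): count} dict.
    Gap and frameshift costs come from the supplied event frequencies by
    the same log-odds rule (cost = -t ln freq, rounded).
    """
    if isinstance(column_counts, dict):
        counts = np.zeros((64, 21))
        for (codon, aa), v in column_counts.items():
            counts[CODON_INDEX[codon.upper()], AA_INDEX[aa]] = v
    else:
        counts = np.asarray(column_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative column count")
    total = counts.sum()
    if total == 0:
        raise ValueError("zero total counts")
    p = np.asarray(background_codon, dtype=float)
    q = np.asarray(background_aa, dtype=float)
    if np.any((p[:, None] * q[None, :] == 0) & (counts > 0)):
        raise ValueError("zero background frequency with nonzero count")

    prob = counts + pseudocount
    prob /= prob.sum()
    bg = p[:, None] * q[None, :]
    with np.errstate(divide="ignore"):
        lod = np.where(prob > 0, np.log(np.where(prob > 0, prob, 1.0) / np.where(bg > 0, bg, 1.0)), -np.inf)
    subst = np.round(scale_t * lod)
    floor = subst[np.isfinite(subst)].min() if np.isfinite(subst).any() else 0
    subst = np.where(np.isfinite(subst), subst, min(floor, -8 * scale_t)).astype(np.int32)

    gap_open = max(1, round(-scale_t * math.log(gap_open_freq)))
    gap_extend = max(1, round(-scale_t * math.log(gap_extend_freq)))
    frameshift = max(1, round(-scale_t * math.log(frameshift_freq)))

    lambda_ = _solve_lambda(subst, p, q)
    return ScoringModel(
        subst=subst, gap_open=gap_open, gap_extend=gap_extend,
        frameshift=frameshift, lambda_=lambda_, k_=0.3, scale_t=scale_t,
        background_codon=p, background_aa=q,
    )


def _solve_lambda(subst: np.ndarray, p: np.ndarray, q: np.ndarray) -> float:
    """Positive root of sum p_c q_a exp(lambda s) = 1 (ungapped scale)."""
    w = (p[:, None] * q[None, :]).ravel()
    s = subst.ravel().astype(float)
    if not (np.sum(w * s) < 0 and s.max() > 0):
        return 1.0  # degenerate matrix: no solvable scale

    def f(lam: float) -> float:
        return float(np.sum(w * np.exp(lam * s))) - 1.0

    hi = 1e-4
    while f(hi) < 0 and hi < 100:
        hi *= 2
    return float(brentq(f, 1e-9, hi))


def decay_column_counts(target_identity: float = 0.5, gc: float = 0.41) -> np.ndarray:
    """Expected codon<->aa column distribution for a fossil decayed to a
    target amino-acid identity.

    The generating channel: a source amino acid ``a`` (background
    frequency) emits, with probability ``1 - r``, a usage-weighted
    synonymous codon of ``a``; otherwise a usage-draw over all 64 codons.
    ``r`` is solved so the expected identity equals the target.  This is
    the same channel the synthetic fossils are decayed with, so the
    default model is matched to the data it is asked to find.
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    u = codon_usage(gc)
    q = aa_background(u)
    m = float(np.sum(q * q))  # chance identity under usage
    r = (1 - target_identity) / (1 - m)
    r = min(max(r, 0.0), 1.0)

    counts = np.zeros((64, 21))
    for a in range(21):
        syn = CODON_TO_AA == a
        u_syn = u[syn] / u[syn].sum()
        counts[syn, a] += q[a] * (1 - r) * u_syn
        counts[:, a] += q[a] * r * u
    return counts * 1e6


@lru_cache(maxsize=8)
def default_model(
    target_identity: float = 0.5,
    gc: float = 0.41,
    scale_t: float = 3.0,
    pseudocount: float = 1.0,
) -> ScoringModel:
    """The decay-matched default model (cached)."""
    u = codon_usage(gc)
    return model_from_counts(
        decay_column_counts(target_identity, gc),
        background_codon=u,
        background_aa=aa_background(u),
        pseudocount=pseudocount,
        scale_t=scale_t,
    )


# ---------------------------------------------------------------------------
# E-values


def evalue(score: float, dna_len: int, total_protein_len: int, model: ScoringModel) -> float:
    """Per-chromosome E-value of a score against the whole protein set."""
    if dna_len <= 0 or total_protein_len <= 0:
        raise ValueError("lengths must be positive")
    return model.k_ * dna_len * total_protein_len * math.exp(-model.lambda_ * score)


def per_genome_evalue(evalue_chrom: float, chrom_len: int, genome_len: int) -> float:
    """Rescale a per-chromosome E-value to the whole genome."""
    if not 0 < chrom_len <= genome_len:
        raise ValueError("need 0 < chrom_len <= genome_len")
    return evalue_chrom * genome_len / chrom_len


def min_score_for_evalue(
    e_threshold: float, dna_len: int, total_protein_len: int, model: ScoringModel
) -> int:
    """Smallest integer score whose E-value is <= the threshold."""
    s = math.log(model.k_ * dna_len * total_protein_len / e_threshold) / model.lambda_
    return max(1, math.ceil(s))
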