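"""Exact local-alignment scoring with SRV (score ratio value) normalization.

The all-to-all BLAST stage of classical reciprocal-best-hit pipelines is
replaced here by exact Smith–Waterman with affine gaps under BLOSUM62 and
the standard gapped-BLOSUM62 Karlin–Altschul statistics.  Raw scores are
normalized per query against the query's self-hit score, giving the SRV on
a 0–100 scale: srv = 100 * raw / self_score(query).  A hit is retained when
its Karlin–Altschul E-value K*m*n*exp(-lambda*raw) is at most ``evalue_max``.

A gap of length L costs ``gap_open + L * gap_extend`` (the BLAST protein
convention with open 11, extend 1).  The ambiguity residue X scores 0
against every residue including itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .genome_io import ProteinRecord, Proteome

#: residue order used for sequence encoding; X last
RESIDUES = "ACDEFGHIKLMNPQRSTVWYX"
_INDEX = {aa: i for i, aa in enumerate(RESIDUES)}


def _load_blosum62() -> np.ndarray:
    """21x21 integer BLOSUM62 with the X row/column zeroed.

    Asserts the two structural properties downstream code relies on:
    symmetry, and diagonal dominance over each row (which makes the
    ungapped diagonal sum the self-hit optimum).
    """
    bl = substitution_matrices.load("BLOSUM62")
    m = np.zeros((21, 21), dtype=np.int32)
    for i, a in enumerate(RESIDUES[:20]):
        for j, b in enumerate(RESIDUES[:20]):
            m[i, j] = int(bl[a, b])
    assert np.array_equal(m, m.T), "substitution matrix must be symmetric"
    core = m[:20, :20]
    assert all(
        core[i, i] == core[i].max() for i in range(20)
    ), "BLOSUM62 diagonal must dominate each row"
    return m


BLOSUM62 = _load_blosum62()


@dataclass
class ScoringScheme:
    """Alignment scoring parameters and hit-retention cutoffs."""

    substitution_matrix: np.ndarray = field(default_factory=lambda: BLOSUM62.copy())
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    evalue_max: float = 1e-4
    srv_min: float = 35.0

    def __post_init__(self) -> None:
        m = np.asarray(self.substitution_matrix, dtype=np.int32)
        if m.shape != (21, 21) or not np.array_equal(m, m.T):
            raise ValueError("substitution matrix must be a symmetric 21x21 array")
        self.substitution_matrix = m
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        if not 0.0 <= self.srv_min <= 100.0:
            raise ValueError("srv_min outside [0, 100]")


@dataclass(frozen=True)
class AlignmentHit:
    """A scored pairwise comparison retained by the E-value filter."""

    query_locus: str
    subject_locus: str
    raw_score: int
    srv: float
    evalue: float


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_INDEX[c] for c in seq], dtype=np.int8)
    except KeyError as e:
        raise ValueError(f"non-amino-acid character {e.args[0]!r}") from None


@njit(cache=True)
def _sw_kernel(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    n = a.shape[0]
    m = b.shape[0]
    NEG = -(10**9)
    H = np.zeros(m + 1, dtype=np.int64)
    E = np.full(m + 1, NEG, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        h_diag = H[0]
        f = NEG
        for j in range(1, m + 1):
            e = E[j] - gap_extend
            t = H[j] - gap_open - gap_extend
            if t > e:
                e = t
            E[j] = e
            f = f - gap_extend
            t = H[j - 1] - gap_open - gap_extend
            if t > f:
                f = t
            s = h_diag + sub[a[i - 1], b[j - 1]]
            h = 0
            if s > h:
                h = s
            if e > h:
                h = e
            if f > h:
                h = f
            h_diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


def local_align_score(a: str, b: str, scheme: ScoringScheme | None = None) -> int:
    """Optimal affine-gap Smith–Waterman local alignment score (>= 0)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    scheme = scheme or ScoringScheme()
    return int(
        _sw_kernel(
            encode(a),
            encode(b),
            scheme.substitution_matrix,
            scheme.gap_open,
            scheme.gap_extend,
        )
    )


def self_score(a: str, scheme: ScoringScheme | None = None) -> int:
    """Self-hit score: the ungapped diagonal sum.

    Equal to ``local_align_score(a, a)`` because the BLOSUM62 diagonal
    dominates each row, so the self alignment never benefits from gaps or
    off-diagonal pairings.
    """
    if not a:
        raise ValueError("sequence must be non-empty")
    scheme = scheme or ScoringScheme()
    enc = encode(a)
    return int(scheme.substitution_matrix[enc, enc].sum())


def evalue(raw_score: int, m: int, n: int, scheme: ScoringScheme) -> float:
    return scheme.K * m * n * math.exp(-scheme.lam * raw_score)


def srv(
    query: ProteinRecord, subject: ProteinRecord, scheme: ScoringScheme | None = None
) -> AlignmentHit:
    """Score a query/subject pair and normalize to the 0-100 SRV scale.

    SRV is asymmetric: it is the raw score over the *query's* self score,
    so a short query aligned to a longer subject can reach SRV 100 while
    the reverse direction does not.
    """
    scheme = scheme or ScoringScheme()
    raw = local_align_score(query.sequence, subject.sequence, scheme)
    ss = self_score(query.sequence, scheme)
    s = 100.0 * raw / ss if ss > 0 else 0.0
    ev = evalue(raw, len(query.sequence), len(subject.sequence), scheme)
    return AlignmentHit(query.locus_tag, subject.locus_tag, raw, s, ev)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def all_vs_all(
    A: Proteome,
    B: Proteome,
    scheme: ScoringScheme | None = None,
    prefilter: bool = False,
    prefilter_k: int = 4,
) -> list[AlignmentHit]:
    """Hits of every query in A against every subject in B, E-value filtered.

    With ``prefilter`` on, pairs sharing no ``prefilter_k``-mer are skipped
    before alignment; the retained hit set must match the unfiltered one
    (pairs without a shared word essentially never clear the E-value cutoff).
    """
    scheme = scheme or ScoringScheme()
    hits: list[AlignmentHit] = []
    enc_b = {r.locus_tag: encode(r.sequence) for r in B}
    kmers_b = (
        {r.locus_tag: _kmer_set(r.sequence, prefilter_k) for r in B}
        if prefilter
        else None
    )
    sub, go, ge = scheme.substitution_matrix, scheme.gap_open, scheme.gap_extend
    for q in A:
        kq = _kmer_set(q.sequence, prefilter_k) if prefilter else None
        eq = encode(q.sequence)
        ssq = self_score(q.sequence, scheme)
        for s in B:
            if prefilter and kq is not None and kmers_b is not None:
                if not (kq & kmers_b[s.locus_tag]):
                    continue
            raw = int(_sw_kernel(eq, enc_b[s.locus_tag], sub, go, ge))
            ev = evalue(raw, len(q.sequence), len(s.sequence), scheme)
            if ev <= scheme.evalue_max:
                val = 100.0 * raw / ssq if ssq > 0 else 0.0
                hits.append(AlignmentHit(q.locus_tag, s.locus_tag, raw, val, ev))
    return hits


def cross_hits(
    A: Proteome,
    B: Proteome,
    scheme: ScoringScheme | None = None,
    prefilter: bool = True,
    prefilter_k: int = 4,
) -> tuple[list[AlignmentHit], list[AlignmentHit]]:
    """Both direction hit lists for an unordered genome pair.

    The raw Smith–Waterman score is symmetric, so each pair is aligned
    once and the two directions differ only in the self-score used for
    SRV normalization.  Returns (A-as-query hits, B-as-query hits).
    """
    scheme = scheme or ScoringScheme()
    self_a = {r.locus_tag: self_score(r.sequence, scheme) for r in A}
    self_b = {r.locus_tag: self_score(r.sequence, scheme) for r in B}
    enc_a = {r.locus_tag: encode(r.sequence) for r in A}
    enc_b = {r.locus_tag: encode(r.sequence) for r in B}
    kmers_b = (
        {r.locus_tag: _kmer_set(r.sequence, prefilter_k) for r in B}
        if prefilter
        else None
    )
    sub, go, ge = scheme.substitution_matrix, scheme.gap_open, scheme.gap_extend
    ab: list[AlignmentHit] = []
    ba: list[AlignmentHit] = []
    for qa in A:
        kq = _kmer_set(qa.sequence, prefilter_k) if prefilter else None
        for sb in B:
            if kq is not None and kmers_b is not None:
                if not (kq & kmers_b[sb.locus_tag]):
                    continue
            raw = int(_sw_kernel(enc_a[qa.locus_tag], enc_b[sb.locus_tag], sub, go, ge))
            ev = evalue(raw, len(qa.sequence), len(sb.sequence), scheme)
            if ev > scheme.evalue_max:
                continue
            sa = self_a[qa.locus_tag]
            sbv = self_b[sb.locus_tag]
            ab.append(
                AlignmentHit(
                    qa.locus_tag, sb.locus_tag, raw,
                    100.0 * raw / sa if sa > 0 else 0.0, ev,
                )
            )
            ba.append(
                AlignmentHit(
                    sb.locus_tag, qa.locus_tag, raw,
                    100.0 * raw / sbv if sbv > 0 else 0.0, ev,
                )
            )
    return ab, ba


def write_hits_tsv(hits: list[AlignmentHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_locus\tsubject_locus\traw_score\tsrv\tevalue\n")
        for h in hits:
            fh.write(
                f"{h.query_locus}\t{h.subject_locus}\t{h.raw_score}"
                f"\t{h.srv:.2f}\t{h.evalue:.3e}\n"
            )
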