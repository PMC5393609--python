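import numpy as np
import pytest

from panrbh import (
    AlignmentHit,
    ProteinRecord,
    Proteome,
    ScoringScheme,
    all_rbbh_pairs,
    best_hit,
    build_families,
    rbbh_pairs,
)
from panrbh.orthology import read_families_tsv, write_families_tsv
from panrbh.scoring import cross_hits


def hit(q, s, raw, srv_val):
    return AlignmentHit(q, s, raw, srv_val, 1e-10)


class TestBestHit:
    def test_single_hit(self):
        h = hit("a", "b", 100, 50.0)
        assert best_hit([h]) is h

    def test_no_hits(self):
        assert best_hit([]) is None

    def test_tie_breaks_lexicographic(self):
        hits = [hit("a", "b_010", 100, 50.0), hit("a", "b_002", 100, 50.0)]
        assert best_hit(hits).subject_locus == "b_002"

    def test_srv_breaks_raw_tie_before_name(self):
        hits = [hit("a", "b_001", 100, 40.0), hit("a", "b_002", 100, 60.0)]
        assert best_hit(hits).subject_locus == "b_002"


def _toy_proteomes():
    rng = np.random.default_rng(9)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    seqs = ["".join(rng.choice(aa, size=80)) for _ in range(3)]
    A = Proteome("A", [ProteinRecord("A", f"a{i}", s) for i, s in enumerate(seqs)])
    B = Proteome("B", [ProteinRecord("B", f"b{i}", s) for i, s in enumerate(seqs)])
    return A, B


class TestRbbhPairs:
    def test_identical_gene_pair(self, scheme):
        A = Proteome("A", [ProteinRecord("A", "a1", "MKVLAEDGHIKWWYNPQRST")])
        B = Proteome("B", [ProteinRecord("B", "b1", "MKVLAEDGHIKWWYNPQRST")])
        ab, ba = cross_hits(A, B, scheme)
        pairs = rbbh_pairs(A, B, ab, ba, scheme)
        assert len(pairs) == 1
        assert pairs[0].srv_ab == pytest.approx(100.0)
        assert pairs[0].srv_ba == pytest.approx(100.0)

    def test_non_mutual_best_is_rejected(self):
        """a0's best is b0 but b0's best is a1 -> no pair involving a0."""
        ab = [hit("a0", "b0", 90, 50.0), hit("a1", "b0", 95, 55.0)]
        ba = [hit("b0", "a1", 95, 55.0), hit("b0", "a0", 90, 50.0)]
        A = Proteome("A", [ProteinRecord("A", "a0", "MK"), ProteinRecord("A", "a1", "MK")])
        B = Proteome("B", [ProteinRecord("B", "b0", "MK")])
        pairs = rbbh_pairs(A, B, ab, ba)
        assert [(p.locus_a, p.locus_b) for p in pairs] == [("a1", "b0")]

    def test_one_sided_srv_below_threshold_rejected(self):
        ab = [hit("a0", "b0", 90, 40.0)]
        ba = [hit("b0", "a0", 90, 30.0)]
        A = Proteome("A", [ProteinRecord("A", "a0", "MK")])
        B = Proteome("B", [ProteinRecord("B", "b0", "MK")])
        assert rbbh_pairs(A, B, ab, ba) == []

    def test_symmetric_under_genome_swap(self, scheme):
        A, B = _toy_proteomes()
        ab, ba = cross_hits(A, B, scheme)
        fwd = rbbh_pairs(A, B, ab, ba, scheme)
        rev = rbbh_pairs(B, A, ba, ab, scheme)
        assert {(p.locus_a, p.locus_b) for p in fwd} == {
            (p.locus_b, p.locus_a) for p in rev
        }

    def test_matches_bruteforce_oracle(self, scheme, diverged_sim):
        """RBH pairing equals an independent enumeration over the same
        hit tables on 5 genomes."""
        proteomes, _ = diverged_sim
        gids = sorted(proteomes)
        for i, ga in enumerate(gids):
            for gb in gids[i + 1 :]:
                A, B = proteomes[ga], proteomes[gb]
                ab, ba = cross_hits(A, B, scheme)
                got = {(p.locus_a, p.locus_b)
                       for p in rbbh_pairs(A, B, ab, ba, scheme)}
                assert got == brute_rbbh(ab, ba, scheme.srv_min)


def brute_rbbh(ab, ba, srv_min):
    """All-pairs RBH oracle: direct argmax per query without shared code."""
    out = set()
    queries = {h.query_locus for h in ab}
    for qa in queries:
        mine = [h for h in ab if h.query_locus == qa]
        top = sorted(mine, key=lambda h: (-h.raw_score, -h.srv, h.subject_locus))[0]
        theirs = [h for h in ba if h.query_locus == top.subject_locus]
        if not theirs:
            continue
        rtop = sorted(theirs, key=lambda h: (-h.raw_score, -h.srv, h.subject_locus))[0]
        if rtop.subject_locus == qa and top.srv >= srv_min and rtop.srv >= srv_min:
            out.add((qa, top.subject_locus))
    return out


class TestBuildFamilies:
    def test_shared_single_gene_over_three_genomes(self, scheme):
        seq = "MKVLAEDGHIKWWYNPQRST"
        prots = {
            g: Proteome(g, [ProteinRecord(g, f"{g}_1", seq)]) for g in "ABC"
        }
        pairs = all_rbbh_pairs(prots, scheme)
        fams = build_families(pairs, prots, "A")
        assert len(fams) == 1 and len(fams[0]) == 3

    def test_partial_overlap_toy(self, scheme):
        rng = np.random.default_rng(2)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        s1 = "".join(rng.choice(aa, size=80))
        s2 = "".join(rng.choice(aa, size=80))
        G1 = Proteome("G1", [ProteinRecord("G1", "a1", s1),
                             ProteinRecord("G1", "a2", s2)])
        G2 = Proteome("G2", [ProteinRecord("G2", "b1", s1)])
        prots = {"G1": G1, "G2": G2}
        pairs = all_rbbh_pairs(prots, scheme)
        fams = build_families(pairs, prots, "G1")
        sets = sorted(sorted(f.members.values()) for f in fams)
        assert sets == [["a1", "b1"], ["a2"]]

    def test_families_partition_all_loci(self, scheme, diverged_sim):
        proteomes, _ = diverged_sim
        pairs = all_rbbh_pairs(proteomes, scheme)
        fams = build_families(pairs, proteomes, "g1")
        total = sum(len(p) for p in proteomes.values())
        assert sum(len(f) for f in fams) == total
        seen = set()
        for f in fams:
            for g, locus in f.members.items():
                assert (g, locus) not in seen
                seen.add((g, locus))

    def test_zero_divergence_recovers_planted_families(self, scheme, small_sim):
        proteomes, truth = small_sim
        pairs = all_rbbh_pairs(proteomes, scheme)
        fams = build_families(pairs, proteomes, "g1")
        got = {frozenset(f.members.items()) for f in fams}
        expected = {frozenset(f.members.items()) for f in truth.families}
        assert got == expected

    def test_unknown_reference_rejected(self, small_sim):
        proteomes, _ = small_sim
        with pytest.raises(ValueError):
            build_families([], proteomes, "nope")

    def test_component_method_agrees_at_zero_divergence(self, scheme, small_sim):
        """On clean input the connected-components alternative yields the
        same membership sets as the reference-pivot construction."""
        proteomes, _ = small_sim
        pairs = all_rbbh_pairs(proteomes, scheme)
        pivot = build_families(pairs, proteomes, "g1")
        comp = build_families(pairs, proteomes, "g1", method="components")
        assert {frozenset(f.members.items()) for f in pivot} == {
            frozenset(f.members.items()) for f in comp
        }


def test_families_tsv_round_trip(tmp_path, small_sim, scheme):
    proteomes, truth = small_sim
    gids = sorted(proteomes)
    path = tmp_path / "families.tsv"
    write_families_tsv(truth.families, gids, path)
    back, back_gids = read_families_tsv(path)
    assert back_gids == gids
    assert [(f.family_id, f.members) for f in back] == [
        (f.family_id, f.members) for f in truth.families
    ]
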