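"""Reciprocal-best-hit ortholog pairing and cross-genome family construction.

Two loci from different genomes are called orthologs when each is the
other's best-scoring hit (reciprocal best hit, RBH) and the SRV is at or
above ``srv_min`` in *both* directions.  Families are built by a
reference-pivot sweep: every locus of the reference genome seeds a family,
and each subsequent genome's loci join the family of their RBH partner in
the earliest already-processed genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .genome_io import Proteome
from .scoring import AlignmentHit, ScoringScheme, cross_hits

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthologPair:
    locus_a: str
    locus_b: str
    genome_a: str
    genome_b: str
    srv_ab: float
    srv_ba: float


@dataclass
class OrthologFamily:
    family_id: str
    members: dict[str, str] = field(default_factory=dict)  # genome_id -> locus

    def __len__(self) -> int:
        return len(self.members)


def best_hit(hits: list[AlignmentHit]) -> AlignmentHit | None:
    """Best subject for one query: max raw score, ties broken by higher
    SRV then lexicographically smallest subject locus tag."""
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.raw_score, -h.srv, h.subject_locus))


def rbbh_pairs(
    A: Proteome,
    B: Proteome,
    hits_ab: list[AlignmentHit],
    hits_ba: list[AlignmentHit],
    scheme: ScoringScheme | None = None,
) -> list[OrthologPair]:
    """Reciprocal best hits between two genomes with two-sided SRV filter.

    ``hits_ab`` must have A loci as queries, ``hits_ba`` B loci.  A pair
    (a, b) is emitted iff a's best hit in B is b, b's best hit in A is a,
    and both SRVs are >= ``srv_min``.
    """
    scheme = scheme or ScoringScheme()
    by_query_ab: dict[str, list[AlignmentHit]] = {}
    for h in hits_ab:
        by_query_ab.setdefault(h.query_locus, []).append(h)
    by_query_ba: dict[str, list[AlignmentHit]] = {}
    for h in hits_ba:
        by_query_ba.setdefault(h.query_locus, []).append(h)

    best_ab = {q: best_hit(hs) for q, hs in by_query_ab.items()}
    best_ba = {q: best_hit(hs) for q, hs in by_query_ba.items()}

    pairs: list[OrthologPair] = []
    for a_locus in A.locus_tags:
        fwd = best_ab.get(a_locus)
        if fwd is None:
            continue
        rev = best_ba.get(fwd.subject_locus)
        if rev is None or rev.subject_locus != a_locus:
            continue
        if fwd.srv < scheme.srv_min or rev.srv < scheme.srv_min:
            continue
        pairs.append(
            OrthologPair(
                a_locus, fwd.subject_locus, A.genome_id, B.genome_id,
                fwd.srv, rev.srv,
            )
        )
    return pairs


def all_rbbh_pairs(
    proteomes: dict[str, Proteome],
    scheme: ScoringScheme | None = None,
    prefilter: bool = True,
) -> list[OrthologPair]:
    """RBH pairs for every unordered genome pair (scores computed once)."""
    scheme = scheme or ScoringScheme()
    ids = list(proteomes)
    pairs: list[OrthologPair] = []
    for i, ga in enumerate(ids):
        for gb in ids[i + 1 :]:
            ab, ba = cross_hits(proteomes[ga], proteomes[gb], scheme, prefilter)
            pairs.extend(rbbh_pairs(proteomes[ga], proteomes[gb], ab, ba, scheme))
    return pairs


def build_families(
    pairs: list[OrthologPair],
    proteomes: dict[str, Proteome],
    reference: str,
    method: str = "reference_pivot",
) -> list[OrthologFamily]:
    """Consolidate pairwise RBH pairs into cross-genome ortholog families.

    Default reference-pivot construction: the reference genome's loci each
    seed a family; genomes are then processed in the given dict order and
    each locus joins the family of its RBH partner in the earliest
    processed genome.  When partners point at distinct families the link
    with the highest min(srv_ab, srv_ba) wins (logged); a family already
    holding a locus of the joining genome is skipped.  Every locus ends up
    in exactly one family.

    ``method="components"`` instead takes connected components of the RBH
    graph (for sensitivity analysis); components holding two loci of one
    genome keep the higher-min-SRV link and the other locus is split off.
    """
    if method == "components":
        return _component_families(pairs, proteomes)
    if method != "reference_pivot":
        raise ValueError(f"unknown family construction method {method!r}")
    if reference not in proteomes:
        raise ValueError(f"reference genome {reference!r} not among proteomes")
    order = [reference] + [g for g in proteomes if g != reference]

    # partner[(genome_of_locus, locus)][other_genome] -> (other_locus, min_srv)
    partner: dict[tuple[str, str], dict[str, tuple[str, float]]] = {}
    for p in pairs:
        m = min(p.srv_ab, p.srv_ba)
        partner.setdefault((p.genome_a, p.locus_a), {})[p.genome_b] = (p.locus_b, m)
        partner.setdefault((p.genome_b, p.locus_b), {})[p.genome_a] = (p.locus_a, m)

    families: list[OrthologFamily] = []
    locus_family: dict[tuple[str, str], OrthologFamily] = {}

    def new_family(gid: str, locus: str) -> None:
        fam = OrthologFamily(f"F{len(families) + 1:05d}", {gid: locus})
        families.append(fam)
        locus_family[(gid, locus)] = fam

    for locus in proteomes[reference].locus_tags:
        new_family(reference, locus)

    for gi, gid in enumerate(order[1:], start=1):
        processed = order[:gi]
        for locus in proteomes[gid].locus_tags:
            links = partner.get((gid, locus), {})
            candidates = []  # (processing position, family, min_srv)
            for pos, pg in enumerate(processed):
                if pg in links:
                    other_locus, msrv = links[pg]
                    fam = locus_family.get((pg, other_locus))
                    if fam is not None:
                        candidates.append((pos, fam, msrv))
            if len({id(c[1]) for c in candidates}) > 1:
                logger.warning(
                    "locus %s/%s is RBH partner of %d distinct families; "
                    "keeping the highest-SRV link",
                    gid, locus, len({id(c[1]) for c in candidates}),
                )
                candidates.sort(key=lambda c: (-c[2], c[0]))
            placed = False
            for _, fam, _ in candidates:
                if gid not in fam.members:
                    fam.members[gid] = locus
                    locus_family[(gid, locus)] = fam
                    placed = True
                    break
            if not placed:
                new_family(gid, locus)
    return families


def _component_families(
    pairs: list[OrthologPair],
    proteomes: dict[str, Proteome],
) -> list[OrthologFamily]:
    """Union-find over the RBH graph; same-genome conflicts within a
    component are resolved by dropping the weakest min-SRV links first."""
    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for g, prot in proteomes.items():
        for locus in prot.locus_tags:
            parent[(g, locus)] = (g, locus)

    # strongest links first, so conflicting weaker links are skipped
    for p in sorted(pairs, key=lambda p: -min(p.srv_ab, p.srv_ba)):
        a, b = (p.genome_a, p.locus_a), (p.genome_b, p.locus_b)
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        members: dict[str, set] = {}
        for node in parent:
            if find(node) in (ra, rb):
                members.setdefault(node[0], set()).add(node)
        if any(len(v) > 1 for v in members.values()):
            logger.warning(
                "component merge of %s and %s would duplicate a genome; skipped",
                a, b,
            )
            continue
        parent[rb] = ra

    groups: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for node in parent:
        groups.setdefault(find(node), []).append(node)
    families = []
    for i, key in enumerate(sorted(groups)):
        families.append(
            OrthologFamily(f"F{i + 1:05d}", dict(sorted(groups[key])))
        )
    return families


def write_families_tsv(
    families: list[OrthologFamily], genome_ids: list[str], path
) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\t" + "\t".join(genome_ids) + "\n")
        for fam in families:
            cells = [fam.members.get(g, "-") for g in genome_ids]
            fh.write(fam.family_id + "\t" + "\t".join(cells) + "\n")


def read_families_tsv(path) -> tuple[list[OrthologFamily], list[str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        genome_ids = header[1:]
        families = []
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            members = {
                g: c for g, c in zip(genome_ids, cells[1:]) if c != "-"
            }
            families.append(OrthologFamily(cells[0], members))
    return families, genome_ids
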