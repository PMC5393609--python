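"""Distance-based core-genome phylogeny via neighbor joining.

Pairwise genome distances are derived from the SRVs of core-family member
pairs (1 minus the mean two-way SRV fraction), and a classic neighbor-
joining tree is built from the resulting matrix.  NJ tie-breaks are
lexicographic on a canonical node label (the smallest leaf name in the
subtree) so the output is deterministic under taxon-order permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome_io import Proteome
from .orthology import OrthologFamily
from .scoring import ScoringScheme, local_align_score, self_score

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.taxa) + "\n")
            for i, t in enumerate(self.taxa):
                fh.write(t + "\t" + "\t".join(f"{v:.6f}" for v in self.d[i]) + "\n")


@dataclass
class TreeNode:
    """Minimal unrooted-tree node; branch length is to the parent."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name or ""]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def core_distance_matrix(
    families: list[OrthologFamily],
    proteomes: dict[str, Proteome],
    scheme: ScoringScheme | None = None,
) -> DistanceMatrix:
    """d(i,j) = 1 - mean over core families of the two-way SRV fraction.

    For each family with members in all genomes, SRV(i->j) and SRV(j->i)
    are averaged (the raw score is symmetric; only the self-score
    normalization differs), divided by 100, averaged over families, and
    subtracted from 1.  Distances live in [0, 1].
    """
    scheme = scheme or ScoringScheme()
    taxa = sorted(proteomes)
    if len(taxa) < 3:
        raise ValueError("need >= 3 genomes for a phylogeny")
    core = [f for f in families if set(f.members) >= set(taxa)]
    if not core:
        raise ValueError(
            "no core families; lower srv_min or use fewer genomes"
        )
    seqs = {
        (g, r.locus_tag): r.sequence for g in taxa for r in proteomes[g]
    }
    selfs = {
        key: self_score(seq, scheme) for key, seq in seqs.items()
    }
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            acc = 0.0
            for fam in core:
                ka = (taxa[i], fam.members[taxa[i]])
                kb = (taxa[j], fam.members[taxa[j]])
                raw = local_align_score(seqs[ka], seqs[kb], scheme)
                srv_ij = 100.0 * raw / selfs[ka] if selfs[ka] > 0 else 0.0
                srv_ji = 100.0 * raw / selfs[kb] if selfs[kb] > 0 else 0.0
                acc += (srv_ij + srv_ji) / 200.0
            sim = acc / len(core)
            d[i, j] = d[j, i] = max(0.0, 1.0 - sim)
    return DistanceMatrix(taxa, d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classic neighbor joining with deterministic lexicographic tie-break.

    Iteratively joins the pair minimizing the Q-criterion
    Q(i,j) = (r-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k), computes branch
    lengths by the standard two-point formulas, and finishes by joining
    the last three nodes at a single internal vertex.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    labels: list[str] = list(dm.taxa)  # canonical label = min leaf name
    D = dm.d.copy()

    while len(nodes) > 3:
        r = len(nodes)
        sums = D.sum(axis=1)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                la, lb = sorted((labels[i], labels[j]))
                key = (q, la, lb)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = li, lj
        parent = TreeNode(children=[ni, nj])
        new_d = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.zeros((r - 1, r - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = new_d[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    # join the final three nodes at one internal vertex (three-point formulas)
    a, b, c = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    a.length, b.length, c.length = la, lb, lc
    order = np.argsort([labels[0], labels[1], labels[2]], kind="stable")
    kids = [nodes[k] for k in order]
    return TreeNode(children=kids)


def _fmt(x: float) -> str:
    if x < 0:
        logger.warning("clamping negative branch length %g to 0", x)
        x = 0.0
    return f"{x:.6g}"


def write_newick(tree: TreeNode) -> str:
    """Serialize an unrooted tree to Newick with 6-significant-digit
    branch lengths; small negative NJ lengths are clamped to 0."""

    def rec(node: TreeNode) -> str:
        if not node.children:
            return f"{node.name}:{_fmt(node.length)}"
        inner = ",".join(rec(c) for c in node.children)
        return f"({inner}):{_fmt(node.length)}"

    inner = ",".join(rec(c) for c in tree.children)
    return f"({inner});"
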