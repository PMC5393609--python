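"""Synthetic multi-genome proteome generator with known ground truth.

The generator emulates the statistical structure a pan-genome pipeline is
meant to recover: a conserved core gene pool shared by every genome,
accessory genes whose per-added-genome novelty follows the power law
n(N) = kappa * N^(-alpha) (optionally shared into later genomes), per-copy
sequence divergence driving the SRV distribution, optional host-clade
structure (lower within-clade than between-clade divergence), and planted
lipobox / LPXTG surface motifs with recorded positions.

Everything is drawn from one ``numpy`` generator seeded from
``SimulationParams.seed``, so the same parameters regenerate byte-identical
FASTA output and truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome_io import ProteinRecord, Proteome, write_protein_fasta
from .orthology import OrthologFamily
from .pangenome import PanGenomePartition, partition

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_HYDRO = list("AVLIMFWC")


@dataclass
class SimulationParams:
    n_genomes: int = 9
    core_size: int = 60
    kappa: float = 120.0
    alpha: float = 0.7
    shared_accessory_prob: float = 0.15
    divergence: float = 0.05
    gene_length_range: tuple[int, int] = (120, 400)
    clade_assignment: dict[str, int] | None = None
    within_clade_divergence: float | None = None
    n_lipobox: int = 0
    n_lpxtg: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("need >= 2 genomes")
        if not 0.0 <= self.divergence <= 0.5:
            raise ValueError("divergence outside [0, 0.5]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        lo, hi = self.gene_length_range
        if lo < 46 or hi < lo:
            raise ValueError("gene lengths must be >= 46 and ordered")
        if self.core_size == 0 and self.clade_assignment:
            raise ValueError("clade structure requires core genes")


@dataclass
class TruthTables:
    families: list[OrthologFamily]
    partition: PanGenomePartition
    motifs: pd.DataFrame
    clades: dict[str, int] | None = None


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(AA20, size=length))


def mutate_sequence(seq: str, p_sub: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``p_sub`` to a
    uniformly drawn *different* residue; length is preserved."""
    if not 0.0 <= p_sub <= 1.0:
        raise ValueError("p_sub outside [0, 1]")
    if p_sub == 0.0 or not seq:
        return seq
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < p_sub
    n = int(mask.sum())
    if n:
        # draw among the 19 alternatives by offsetting past the original
        idx = {a: i for i, a in enumerate(AA20)}
        orig = np.array([idx.get(c, 0) for c in arr[mask]])
        offs = rng.integers(1, 20, size=n)
        arr[mask] = AA20[(orig + offs) % 20]
    return "".join(arr)


def shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    """Composition-preserving shuffle (destroys positional motifs)."""
    arr = np.array(list(seq))
    rng.shuffle(arr)
    return "".join(arr)


def _plant_lipobox(seq: str, rng: np.random.Generator) -> tuple[str, int]:
    motif = (
        rng.choice(list("LVI")) + rng.choice(list("AST")) + rng.choice(list("GA")) + "C"
    )
    prefix = "MKK" + "".join(rng.choice(_HYDRO, size=7)) + motif
    return prefix + seq[len(prefix) :], 11


def _plant_lpxtg(seq: str, rng: np.random.Generator) -> tuple[str, int]:
    motif = "LP" + rng.choice(AA20) + "TG"
    stretch = "".join(rng.choice(_HYDRO, size=15))
    tail = "".join(rng.choice(list("KR"), size=10))
    suffix = motif + stretch + tail
    return seq[: len(seq) - len(suffix)] + suffix, len(seq) - len(suffix) + 1


def plant_motifs(
    proteomes: dict[str, Proteome],
    n_lipobox: int,
    n_lpxtg: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Rewrite randomly chosen loci in place to carry surface motifs.

    Lipobox proteins get an N-terminal signal-like prefix ending in
    [LVI]-[AST]-[GA]-C; LPXTG proteins get a C-terminal sortase motif,
    hydrophobic stretch, and K/R tail.  Returns the motif truth table.
    """
    all_loci = [
        (gid, i) for gid in sorted(proteomes) for i in range(len(proteomes[gid].records))
    ]
    need = n_lipobox + n_lpxtg
    if need > len(all_loci):
        raise ValueError("more motif proteins requested than loci available")
    chosen = rng.choice(len(all_loci), size=need, replace=False)
    rows = []
    for k, ci in enumerate(chosen):
        gid, i = all_loci[int(ci)]
        rec = proteomes[gid].records[i]
        if k < n_lipobox:
            new_seq, pos = _plant_lipobox(rec.sequence, rng)
            feature = "lipoprotein"
        else:
            new_seq, pos = _plant_lpxtg(rec.sequence, rng)
            feature = "LPXTG_anchor"
        proteomes[gid].records[i] = ProteinRecord(
            gid, rec.locus_tag, new_seq, rec.product
        )
        rows.append(
            {"genome_id": gid, "locus_tag": rec.locus_tag, "feature": feature,
             "motif_start": pos}
        )
    return pd.DataFrame(rows, columns=["genome_id", "locus_tag", "feature", "motif_start"])


def simulate_pangenome(
    params: SimulationParams,
) -> tuple[dict[str, Proteome], TruthTables]:
    """Generate per-genome proteomes plus machine-readable truth tables."""
    rng = np.random.default_rng(params.seed)
    gids = [f"g{i + 1}" for i in range(params.n_genomes)]
    lo, hi = params.gene_length_range

    clades = params.clade_assignment
    within = params.within_clade_divergence
    if clades is not None and within is None:
        within = params.divergence / 5.0

    # per-genome ordered gene lists: (family_id, sequence, product)
    genome_genes: dict[str, list[tuple[str, str, str]]] = {g: [] for g in gids}
    families: list[OrthologFamily] = []

    # conserved core pool, one copy per genome
    for c in range(params.core_size):
        fid = f"T{len(families) + 1:05d}"
        length = int(rng.integers(lo, hi + 1))
        ancestor = random_protein(length, rng)
        clade_anc: dict[int, str] = {}
        if clades is not None:
            for cl in sorted(set(clades.values())):
                clade_anc[cl] = mutate_sequence(ancestor, params.divergence, rng)
        members: dict[str, str] = {}
        for g in gids:
            if clades is not None:
                seq = mutate_sequence(clade_anc[clades[g]], within, rng)
            else:
                seq = mutate_sequence(ancestor, params.divergence, rng)
            genome_genes[g].append((fid, seq, f"core protein {c + 1}"))
            members[g] = ""  # locus assigned later
        families.append(OrthologFamily(fid, members))

    # accessory genes: novelty for the N-th genome follows kappa * N^(-alpha)
    for n_idx, g in enumerate(gids, start=1):
        n_new = int(round(params.kappa * n_idx ** (-params.alpha)))
        for a in range(n_new):
            fid = f"T{len(families) + 1:05d}"
            length = int(rng.integers(lo, hi + 1))
            ancestor = random_protein(length, rng)
            members = {g: ""}
            genome_genes[g].append((fid, mutate_sequence(ancestor, params.divergence, rng),
                                    f"accessory protein {fid}"))
            if params.shared_accessory_prob > 0:
                for h in gids[n_idx:]:
                    if rng.random() < params.shared_accessory_prob:
                        members[h] = ""
                        genome_genes[h].append(
                            (fid, mutate_sequence(ancestor, params.divergence, rng),
                             f"accessory protein {fid}")
                        )
            families.append(OrthologFamily(fid, members))

    proteomes: dict[str, Proteome] = {}
    fam_by_id = {f.family_id: f for f in families}
    for g in gids:
        recs = []
        for i, (fid, seq, product) in enumerate(genome_genes[g]):
            locus = f"{g}_{i + 1:04d}"
            recs.append(ProteinRecord(g, locus, seq, product))
            fam_by_id[fid].members[g] = locus
        proteomes[g] = Proteome(g, recs)

    motifs = plant_motifs(proteomes, params.n_lipobox, params.n_lpxtg, rng)
    truth = TruthTables(
        families=families,
        partition=partition(families, gids),
        motifs=motifs,
        clades=dict(clades) if clades is not None else None,
    )
    return proteomes, truth


def write_fixture(
    proteomes: dict[str, Proteome],
    truth: TruthTables,
    params: SimulationParams,
    outdir: str | Path,
) -> None:
    """Write per-genome FASTA, truth tables (TSV), and a params echo (YAML)."""
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    for g, prot in sorted(proteomes.items()):
        write_protein_fasta(prot, outdir / "genomes" / f"{g}.faa")
    gids = sorted(proteomes)
    from .orthology import write_families_tsv

    write_families_tsv(truth.families, gids, outdir / "truth_families.tsv")
    truth.motifs.to_csv(outdir / "truth_motifs.tsv", sep="\t", index=False)
    with open(outdir / "truth_partition.tsv", "w") as fh:
        fh.write("family_id\tclass\n")
        for fam in truth.families:
            if fam.family_id in truth.partition.core:
                cls = "core"
            elif len(fam.members) == 1:
                cls = "unique"
            else:
                cls = "accessory"
            fh.write(f"{fam.family_id}\t{cls}\n")
    d = asdict(params)
    d["gene_length_range"] = list(d["gene_length_range"])
    with open(outdir / "params.yaml", "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)
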