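"""Genome and proteome I/O plus basic genome attribute statistics.

Protein FASTA headers are expected to carry the locus tag as the first
whitespace-separated token; everything after it is kept as the free-text
product annotation.  Nucleotide FASTA files are only used for size and G+C
statistics; contigs whose header mentions "plasmid" are excluded from the
chromosomal statistics.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

_NON_AA = re.compile(r"[^ACDEFGHIKLMNPQRSTVWYX]")


@dataclass(frozen=True)
class ProteinRecord:
    """One annotated protein-coding locus."""

    genome_id: str
    locus_tag: str
    sequence: str
    product: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"{self.locus_tag}: empty sequence")
        m = _NON_AA.search(self.sequence)
        if m:
            raise ValueError(
                f"{self.locus_tag}: non-amino-acid character "
                f"{m.group()!r} at position {m.start() + 1}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """Ordered collection of protein records for one genome."""

    genome_id: str
    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"{self.genome_id}: empty proteome")
        seen: set[str] = set()
        for r in self.records:
            if r.locus_tag in seen:
                raise ValueError(
                    f"{self.genome_id}: duplicate locus tag {r.locus_tag!r}"
                )
            seen.add(r.locus_tag)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, locus_tag: str) -> ProteinRecord:
        for r in self.records:
            if r.locus_tag == locus_tag:
                return r
        raise KeyError(locus_tag)

    @property
    def locus_tags(self) -> list[str]:
        return [r.locus_tag for r in self.records]


@dataclass
class GenomeStats:
    genome_id: str
    size_mbp: float
    gc_percent: float
    orf_count: int | None
    protein_count: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_percent <= 100.0:
            raise ValueError("gc_percent outside [0, 100]")
        if self.size_mbp <= 0:
            raise ValueError("size_mbp must be positive")
        if self.orf_count is not None and self.protein_count > self.orf_count:
            raise ValueError("protein_count exceeds orf_count")


def read_protein_fasta(path: str | Path, genome_id: str | None = None) -> Proteome:
    """Read a per-genome protein FASTA into a :class:`Proteome`.

    The first header token is the locus tag, the remainder the product.
    Trailing stop-codon symbols ``*`` are stripped from sequences.
    """
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        product = rec.description.split(None, 1)[1] if " " in rec.description else ""
        records.append(ProteinRecord(gid, rec.id, seq, product))
    if not records:
        raise ValueError(f"{path}: no FASTA entries")
    return Proteome(gid, records)


def write_protein_fasta(proteome: Proteome, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.locus_tag, description=r.product)
        for r in proteome
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def compute_genome_stats(
    nucleotide_fasta: str | Path,
    proteome: Proteome,
    orf_count: int | None = None,
) -> GenomeStats:
    """Genome size (Mbp) and G+C% from a nucleotide FASTA.

    Ambiguous bases are excluded from both the numerator and denominator of
    the G+C fraction; contigs flagged "plasmid" in their header are skipped.
    """
    total = 0
    gc = 0
    at = 0
    n_contigs = 0
    for rec in SeqIO.parse(str(nucleotide_fasta), "fasta"):
        if "plasmid" in rec.description.lower():
            continue
        n_contigs += 1
        s = str(rec.seq).upper()
        total += len(s)
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if n_contigs == 0:
        raise ValueError(f"{nucleotide_fasta}: no (non-plasmid) contigs")
    if gc + at == 0:
        raise ValueError(f"{nucleotide_fasta}: zero unambiguous bases")
    return GenomeStats(
        genome_id=proteome.genome_id,
        size_mbp=total / 1e6,
        gc_percent=100.0 * gc / (gc + at),
        orf_count=orf_count,
        protein_count=len(proteome),
    )


def filter_min_length(proteome: Proteome, min_len: int = 46) -> Proteome:
    """Keep records of length >= ``min_len`` (default keeps >= 46 aa).

    Used by the surface-protein screens to drop very short predicted
    products (<= 45 aa); orthology is run on the unfiltered proteome.
    An all-short proteome yields an empty record list, bypassing the
    non-empty invariant deliberately.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [r for r in proteome if len(r) >= min_len]
    out = object.__new__(Proteome)
    out.genome_id = proteome.genome_id
    out.records = kept
    return out


def summarize_table(stats: Iterable[GenomeStats]) -> pd.DataFrame:
    """Per-genome attribute rows plus a mean row.

    Size means are rounded to 2 decimals and count means half-up to the
    nearest integer; the protein-count mean is additionally reported
    truncated (some published tables truncate it).
    """
    stats = list(stats)
    if not stats:
        raise ValueError("no genomes")
    rows = [
        {
            "genome_id": s.genome_id,
            "size_mbp": round(s.size_mbp, 2),
            "gc_percent": round(s.gc_percent, 1),
            "orf_count": s.orf_count,
            "protein_count": s.protein_count,
        }
        for s in stats
    ]
    df = pd.DataFrame(rows)
    mean_size = round(float(df["size_mbp"].mean()), 2)
    orfs = df["orf_count"].dropna()
    mean_orf = int(orfs.mean() + 0.5) if len(orfs) else None
    mean_prot = float(df["protein_count"].mean())
    mean_row = {
        "genome_id": "mean",
        "size_mbp": mean_size,
        "gc_percent": round(float(df["gc_percent"].mean()), 1),
        "orf_count": mean_orf,
        "protein_count": int(mean_prot + 0.5),
    }
    df = pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
    df.attrs["protein_count_mean_truncated"] = int(mean_prot)
    df.attrs["protein_count_mean_exact"] = mean_prot
    return df


def published_genome_attributes() -> pd.DataFrame:
    """Published genome attributes of the nine *L. ruminis* study strains.

    Strain, host gut source, assembly size (Mbp), G+C%, ORF and protein
    counts, shipped as package data for worked examples and summaries.
    """
    ref = importlib.resources.files("panrbh") / "data" / "lruminis_genome_attributes.tsv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")
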