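"""Rule-based screening for surface-associated protein features.

Four transparent sequence rules stand in for trained secretome predictors,
each anchored to the published anatomy of the motif it detects:

* **lipoprotein** — the lipobox [LVI]-[AST]-[GA]-C near the N-terminus
  (the signal-peptidase-II cleavage site of bacterial lipoproteins),
  preceded by a hydrophobic h-region;
* **LPXTG_anchor** — the C-terminal sortase recognition motif L-P-x-T-G
  followed by a hydrophobic (membrane-spanning) stretch and a positively
  charged cytoplasmic tail;
* **TM_protein** — one or more membrane-spanning helices called by a
  Kyte–Doolittle sliding-window hydropathy rule;
* **sec_signal** — a minimal Sec signal-peptide heuristic: positive
  n-region residues followed by a strongly hydrophobic h-region window.

Proteins of 45 residues or fewer are excluded before screening.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import ProteinRecord, Proteome, filter_min_length
from .orthology import OrthologFamily
from .pangenome import PanGenomePartition

HYDROPHOBIC = set("AVLIMFWC")

#: Kyte–Doolittle hydropathy scale; X treated as neutral (0).
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

_LIPOBOX = re.compile(r"[LVI][AST][GA]C")
_LPXTG = re.compile(r"LP.TG")


@dataclass
class MotifParams:
    lipobox_window_end: int = 40
    lipobox_min_hydrophobic: int = 6  # within the 10 residues before the motif
    lpxtg_search_tail: int = 50
    lpxtg_min_hydrophobic: int = 5  # within the 15 residues after the motif
    lpxtg_min_positive: int = 2  # K/R within the final 10 residues
    tm_window: int = 19
    tm_threshold: float = 1.6
    tm_min_separation: int = 5
    sec_n_region: int = 5
    sec_h_window: int = 8
    sec_h_end: int = 30
    sec_h_threshold: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "lipobox_window_end", "lpxtg_search_tail", "lpxtg_min_hydrophobic",
            "lpxtg_min_positive", "tm_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tm_threshold <= 0:
            raise ValueError("tm_threshold must be positive")


@dataclass(frozen=True)
class SurfaceCall:
    locus_tag: str
    genome_id: str
    feature: str  # lipoprotein | LPXTG_anchor | TM_protein | sec_signal
    motif_start: int | None  # 1-based
    detail: str


def _hydropathy(seq: str) -> np.ndarray:
    return np.array([KYTE_DOOLITTLE[c] for c in seq])


def find_lipobox(record: ProteinRecord, params: MotifParams | None = None) -> SurfaceCall | None:
    """First lipobox match starting within the N-terminal window whose
    preceding (up to) 10 residues contain enough hydrophobics."""
    params = params or MotifParams()
    seq = record.sequence
    for m in _LIPOBOX.finditer(seq):
        start = m.start()  # 0-based
        if start + 1 > params.lipobox_window_end:
            break
        preceding = seq[max(0, start - 10) : start]
        n_h = sum(c in HYDROPHOBIC for c in preceding)
        if n_h >= params.lipobox_min_hydrophobic:
            return SurfaceCall(
                record.locus_tag, record.genome_id, "lipoprotein",
                start + 1, m.group(),
            )
    return None


def find_lpxtg(record: ProteinRecord, params: MotifParams | None = None) -> SurfaceCall | None:
    """LPXTG sortase motif near the C-terminus with a hydrophobic stretch
    after the motif and a K/R-positive final tail."""
    params = params or MotifParams()
    seq = record.sequence
    tail_start = max(0, len(seq) - params.lpxtg_search_tail)
    final10 = seq[-10:]
    n_pos = final10.count("K") + final10.count("R")
    if n_pos < params.lpxtg_min_positive:
        return None
    for m in _LPXTG.finditer(seq):
        if m.start() < tail_start:
            continue
        after = seq[m.end() : m.end() + 15]
        n_h = sum(c in HYDROPHOBIC for c in after)
        if n_h >= params.lpxtg_min_hydrophobic:
            return SurfaceCall(
                record.locus_tag, record.genome_id, "LPXTG_anchor",
                m.start() + 1, m.group(),
            )
    return None


def count_tm_helices(record: ProteinRecord, params: MotifParams | None = None) -> int:
    """Number of putative membrane-spanning helices.

    Window means of Kyte–Doolittle hydropathy at or above the threshold
    mark candidate positions; maximal runs of candidates separated by at
    least ``tm_min_separation`` non-candidate positions each count as one
    helix.
    """
    params = params or MotifParams()
    seq = record.sequence
    w = params.tm_window
    if len(seq) < w:
        return 0
    h = _hydropathy(seq)
    means = np.convolve(h, np.ones(w) / w, mode="valid")
    qualifying = np.flatnonzero(means >= params.tm_threshold)
    if qualifying.size == 0:
        return 0
    gaps = np.diff(qualifying) - 1
    return 1 + int((gaps >= params.tm_min_separation).sum())


def sec_signal_heuristic(record: ProteinRecord, params: MotifParams | None = None) -> SurfaceCall | None:
    """Minimal Sec signal: >= 1 K/R within the first ``sec_n_region``
    residues plus a fully hydrophobic-average window inside the h-region."""
    params = params or MotifParams()
    seq = record.sequence
    n_region = seq[: params.sec_n_region]
    if n_region.count("K") + n_region.count("R") < 1:
        return None
    w = params.sec_h_window
    lo, hi = params.sec_n_region, min(len(seq), params.sec_h_end)
    region = seq[lo:hi]
    if len(region) < w:
        return None
    h = _hydropathy(region)
    means = np.convolve(h, np.ones(w) / w, mode="valid")
    idx = np.flatnonzero(means >= params.sec_h_threshold)
    if idx.size == 0:
        return None
    return SurfaceCall(
        record.locus_tag, record.genome_id, "sec_signal",
        lo + int(idx[0]) + 1, f"h-window mean {means[idx[0]]:.2f}",
    )


def screen_proteome(
    proteome: Proteome,
    partition: PanGenomePartition | None = None,
    families: list[OrthologFamily] | None = None,
    params: MotifParams | None = None,
    min_len: int = 46,
) -> pd.DataFrame:
    """Run all four detectors over a length-filtered proteome.

    Returns one row per call with columns genome_id, locus_tag, feature,
    motif_start, detail, core_or_accessory.  The core/accessory flag is
    looked up through the locus's ortholog family when a partition and
    families are supplied, else left empty.
    """
    params = params or MotifParams()
    locus_class: dict[str, str] = {}
    if partition is not None and families is not None:
        for fam in families:
            cls = "core" if fam.family_id in partition.core else "accessory"
            for g, locus in fam.members.items():
                if g == proteome.genome_id:
                    locus_class[locus] = cls
    rows = []
    for rec in filter_min_length(proteome, min_len):
        calls: list[SurfaceCall] = []
        for det in (find_lipobox, find_lpxtg, sec_signal_heuristic):
            c = det(rec, params)
            if c is not None:
                calls.append(c)
        n_tm = count_tm_helices(rec, params)
        if n_tm >= 1:
            calls.append(
                SurfaceCall(rec.locus_tag, rec.genome_id, "TM_protein",
                            None, f"{n_tm} helices")
            )
        for c in calls:
            rows.append(
                {
                    "genome_id": c.genome_id,
                    "locus_tag": c.locus_tag,
                    "feature": c.feature,
                    "motif_start": c.motif_start,
                    "detail": c.detail,
                    "core_or_accessory": locus_class.get(c.locus_tag, ""),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "locus_tag", "feature", "motif_start", "detail",
            "core_or_accessory",
        ],
    )
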