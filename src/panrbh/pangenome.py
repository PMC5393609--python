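"""Pan/core/accessory partitioning, development curves, and Heap's-law fits.

Definitions follow the usual flower-plot arithmetic: the *pan-genome* is
the set of all ortholog families; *core* families have a member in every
genome; *unique* (strain-specific) families occur in exactly one genome and
are counted as a subset of the *accessory* genome (everything not core), so
pan = core + accessory always holds.

Openness is judged by fitting the per-added-genome novelty to the power law
n(N) = kappa * N^(-alpha): an exponent alpha < 1 means the pan-genome keeps
growing without bound as genomes are added (open); alpha >= 1 means it
saturates (closed).  Under this model the cumulative pan size grows like
N^gamma with gamma = 1 - alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .orthology import OrthologFamily

logger = logging.getLogger(__name__)


@dataclass
class PanGenomePartition:
    genome_ids: list[str]
    pan_size: int
    core: set[str]
    accessory: set[str]
    unique: dict[str, int]
    per_genome_totals: dict[str, int]

    @property
    def core_size(self) -> int:
        return len(self.core)

    @property
    def accessory_size(self) -> int:
        return len(self.accessory)

    @property
    def unique_total(self) -> int:
        return sum(self.unique.values())


@dataclass
class DevelopmentCurve:
    N: np.ndarray
    pan_median: np.ndarray
    core_median: np.ndarray
    new_genes_median: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "N": self.N,
                "pan_median": self.pan_median,
                "core_median": self.core_median,
                "new_genes_median": self.new_genes_median,
            }
        )


@dataclass
class HeapsFit:
    kappa: float
    alpha: float
    gamma: float
    kappa_pan: float
    rss: float
    verdict: str  # "open" | "closed"
    core_decay: dict = field(default_factory=dict)


def partition(
    families: list[OrthologFamily], genome_ids: list[str]
) -> PanGenomePartition:
    """Classify families by presence pattern into core/accessory/unique."""
    gset = set(genome_ids)
    for fam in families:
        extra = set(fam.members) - gset
        if extra:
            raise ValueError(
                f"family {fam.family_id} names unknown genomes: {sorted(extra)}"
            )
    core: set[str] = set()
    accessory: set[str] = set()
    unique: dict[str, int] = {g: 0 for g in genome_ids}
    totals: dict[str, int] = {g: 0 for g in genome_ids}
    for fam in families:
        for g in fam.members:
            totals[g] += 1
        if len(fam.members) == len(genome_ids):
            core.add(fam.family_id)
        else:
            accessory.add(fam.family_id)
            if len(fam.members) == 1:
                (g,) = fam.members
                unique[g] += 1
    return PanGenomePartition(
        genome_ids=list(genome_ids),
        pan_size=len(families),
        core=core,
        accessory=accessory,
        unique=unique,
        per_genome_totals=totals,
    )


def _presence_matrix(
    families: list[OrthologFamily], genome_ids: list[str]
) -> np.ndarray:
    idx = {g: j for j, g in enumerate(genome_ids)}
    P = np.zeros((len(families), len(genome_ids)), dtype=bool)
    for i, fam in enumerate(families):
        for g in fam.members:
            P[i, idx[g]] = True
    return P


def development_curves(
    families: list[OrthologFamily],
    genome_ids: list[str],
    n_permutations: int = 200,
    seed: int = 0,
    orderings: list[list[str]] | None = None,
) -> DevelopmentCurve:
    """Pan/core/new-gene medians over genome-addition orders.

    For each ordering of the genomes the cumulative pan size (union),
    core size (intersection) and first-seen family count are tracked;
    per-N medians over orderings are reported.  By default
    ``n_permutations`` random orders are drawn from ``seed``; passing
    explicit ``orderings`` (e.g. the single additive order in which
    genomes were collected) overrides the random draw.
    """
    P = _presence_matrix(families, genome_ids)
    G = len(genome_ids)
    if orderings is not None:
        idx = {g: j for j, g in enumerate(genome_ids)}
        orders = [np.array([idx[g] for g in o]) for o in orderings]
        if any(len(o) != G for o in orders):
            raise ValueError("each ordering must list every genome once")
    else:
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(G) for _ in range(n_permutations)]
    n_ord = len(orders)
    pan = np.empty((n_ord, G))
    core = np.empty((n_ord, G))
    new = np.empty((n_ord, G))
    for p, order in enumerate(orders):
        seen = np.zeros(P.shape[0], dtype=bool)
        in_all = np.ones(P.shape[0], dtype=bool)
        prev = 0.0
        for k, g in enumerate(order):
            seen |= P[:, g]
            in_all &= P[:, g]
            pan[p, k] = seen.sum()
            core[p, k] = in_all.sum()
            new[p, k] = pan[p, k] - prev
            prev = pan[p, k]
    return DevelopmentCurve(
        N=np.arange(1, G + 1),
        pan_median=np.median(pan, axis=0),
        core_median=np.median(core, axis=0),
        new_genes_median=np.median(new, axis=0),
    )


def fit_heaps(curve: DevelopmentCurve) -> HeapsFit:
    """Nonlinear least-squares Heap's-law fit of the development curve.

    The per-added-genome novelty n(N) = kappa * N^(-alpha) is fitted over
    N >= 2 (the N = 1 point conflates genome size with gain rate) with a
    log-log linear initialization; the cumulative pan curve is fitted as
    kappa' * N^gamma.  The core curve gets a descriptive exponential-decay
    fit only.  Verdict: "open" iff alpha < 1.
    """
    N = np.asarray(curve.N, dtype=float)
    mask = N >= 2
    x = N[mask]
    y = np.asarray(curve.new_genes_median, dtype=float)[mask]
    if np.all(y == 0):
        logger.warning("all new-gene medians are zero; Heap's fit undefined")
        return HeapsFit(
            kappa=0.0, alpha=float("inf"), gamma=0.0,
            kappa_pan=float(curve.pan_median[-1]), rss=0.0, verdict="closed",
        )
    pos = y > 0
    if pos.sum() < 3:
        raise ValueError("need >= 3 distinct N values with positive medians")

    def power(n, kappa, alpha):
        return kappa * n ** (-alpha)

    slope, intercept = np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)
    p0 = (float(np.exp(intercept)), float(-slope))
    popt, _ = curve_fit(power, x[pos], y[pos], p0=p0, maxfev=10000)
    kappa, alpha = float(popt[0]), float(popt[1])
    rss = float(np.sum((y[pos] - power(x[pos], *popt)) ** 2))

    pan = np.asarray(curve.pan_median, dtype=float)

    def growth(n, kp, gamma):
        return kp * n**gamma

    gs, gi = np.polyfit(np.log(N), np.log(pan), 1)
    gopt, _ = curve_fit(growth, N, pan, p0=(float(np.exp(gi)), float(gs)), maxfev=10000)
    kappa_pan, gamma = float(gopt[0]), float(gopt[1])

    core_decay: dict = {}
    c = np.asarray(curve.core_median, dtype=float)
    try:
        def decay(n, kc, tau, omega):
            return kc * np.exp(-n / tau) + omega

        import warnings
        from scipy.optimize import OptimizeWarning

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            copt, _ = curve_fit(
                decay, N, c, p0=(c[0] - c[-1] or 1.0, 2.0, c[-1]), maxfev=10000
            )
        core_decay = {"kappa_c": float(copt[0]), "tau": float(copt[1]),
                      "omega": float(copt[2])}
    except RuntimeError:  # descriptive only; flat curves may not converge
        core_decay = {}

    return HeapsFit(
        kappa=kappa,
        alpha=alpha,
        gamma=gamma,
        kappa_pan=kappa_pan,
        rss=rss,
        verdict="open" if alpha < 1 else "closed",
        core_decay=core_decay,
    )


def functional_profile(
    core_family_ids: set[str],
    families: list[OrthologFamily],
    annotation_map: dict[str, str],
    reference: str | None = None,
) -> dict[str, float]:
    """Percent of core families per functional category letter.

    ``annotation_map`` maps locus tags to single-letter categories; a
    family is categorized by the first mapped member (reference member
    first when given), otherwise counted as "unknown".  Percentages sum
    to 100 up to rounding.
    """
    by_id = {f.family_id: f for f in families}
    counts: dict[str, int] = {}
    total = 0
    for fid in sorted(core_family_ids):
        fam = by_id[fid]
        loci = list(fam.members.items())
        if reference is not None:
            loci.sort(key=lambda kv: (kv[0] != reference, kv[0]))
        cat = "unknown"
        for _, locus in loci:
            if locus in annotation_map:
                cat = annotation_map[locus]
                break
        counts[cat] = counts.get(cat, 0) + 1
        total += 1
    if total == 0:
        return {}
    return {c: 100.0 * n / total for c, n in sorted(counts.items())}


def partition_report(part: PanGenomePartition) -> str:
    lines = [
        f"pan\t{part.pan_size}",
        f"core\t{part.core_size}",
        f"accessory\t{part.accessory_size}",
        f"unique_total\t{part.unique_total}",
    ]
    for g in part.genome_ids:
        lines.append(f"unique:{g}\t{part.unique[g]}")
    return "\n".join(lines) + "\n"
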