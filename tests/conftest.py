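import numpy as np
import pytest

from panrbh import ScoringScheme, SimulationParams, simulate_pangenome


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def small_sim():
    """Four zero-divergence genomes with shared accessory genes."""
    params = SimulationParams(
        n_genomes=4, core_size=10, kappa=12.0, alpha=0.7,
        shared_accessory_prob=0.2, divergence=0.0,
        gene_length_range=(60, 120), seed=3,
    )
    return simulate_pangenome(params)


@pytest.fixture(scope="session")
def diverged_sim():
    """Five moderately diverged genomes, orthology still recoverable."""
    params = SimulationParams(
        n_genomes=5, core_size=12, kappa=15.0, alpha=0.7,
        shared_accessory_prob=0.2, divergence=0.05,
        gene_length_range=(60, 120), seed=7,
    )
    return simulate_pangenome(params)


def sw_bruteforce(a: str, b: str, scheme: ScoringScheme) -> int:
    """Independent cubic-time affine-gap Smith-Waterman oracle.

    Enumerates every gap length explicitly instead of carrying E/F state,
    so it shares no recurrence structure with the production kernel.
    Gap of length L costs gap_open + L * gap_extend.
    """
    from panrbh.scoring import RESIDUES

    idx = {c: i for i, c in enumerate(RESIDUES)}
    sub = scheme.substitution_matrix
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = 0
            best = max(best, H[i - 1, j - 1] + sub[idx[a[i - 1]], idx[b[j - 1]]])
            for k in range(1, i + 1):
                best = max(best, H[i - k, j] - scheme.gap_open - k * scheme.gap_extend)
            for k in range(1, j + 1):
                best = max(best, H[i, j - k] - scheme.gap_open - k * scheme.gap_extend)
            H[i, j] = best
    return int(H.max())


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
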