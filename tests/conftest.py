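import numpy as np
import pandas as pd
import pytest

from crosstalk_mir import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact study with planted DE genes, enriched pathways and regulons."""
    cfg = SimulationConfig(n_tumor=20, n_normal=20, n_genes=500, n_mirnas=40,
                           n_pathways=6, pathway_size_range=(10, 18),
                           n_de_genes=40, planted_logfc=2.5, nb_dispersion=0.1,
                           n_crosstalk_pairs=2, regulon_size=8,
                           regulon_strength=0.8, seed=42)
    return generate_study(cfg)


@pytest.fixture()
def toy_counts():
    """4 genes x 4 samples with equal library sizes."""
    counts = pd.DataFrame(
        [[10, 10, 10, 10],
         [0, 0, 20, 20],
         [40, 40, 20, 20],
         [50, 50, 50, 50]],
        index=["g1", "g2", "g3", "g4"],
        columns=["t1", "t2", "n1", "n2"])
    labels = pd.Series(["tumor", "tumor", "normal", "normal"],
                       index=counts.columns)
    return counts, labels


def hypergeom_sf_bruteforce(k: int, n_universe: int, n_pathway: int,
                            n_draw: int) -> float:
    """P(X >= k) for a hypergeometric table, by exact integer summation."""
    from math import comb

    total = comb(n_universe, n_draw)
    acc = 0
    for i in range(k, min(n_pathway, n_draw) + 1):
        if n_draw - i <= n_universe - n_pathway:
            acc += comb(n_pathway, i) * comb(n_universe - n_pathway, n_draw - i)
    return acc / total


def bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """Textbook step-up BH: adj_i = min over j>=rank(i) of p_(j) * m / j."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [min(1.0, p[order[j]] * m / (j + 1))
                      for j in range(rank_pos, m)]
        adj[idx] = min(candidates)
    return adj
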