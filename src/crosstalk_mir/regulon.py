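"""miRNA regulon inference and master regulator analysis.

Dependence between each miRNA and each gene is estimated with the
Kraskov-Stoegbauer-Grassberger (KSG) k-nearest-neighbor mutual information
estimator (algorithm 1):

    MI = psi(k) + psi(n) - < psi(n_x + 1) + psi(n_y + 1) >

where the k-th neighbor distance in the joint space (max-norm) sets the
marginal search radii.  A miRNA's regulon is the set of genes whose MI
clears a permutation-based FDR threshold (or a fixed top-k rule).  A miRNA
is called a master regulator of a pathway pair when its targets are
Fisher-enriched in both pathways (BH-adjusted p < 0.01 on each side) and
the miRNA is itself differentially expressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma

from .dea import bh_adjust
from .pea import fisher_enrichment

logger = logging.getLogger(__name__)

#: jitter scale (relative to each vector's spread) used to break count ties
_JITTER = 1e-10


@dataclass(frozen=True)
class Regulon:
    """Inferred target set of one miRNA with per-target MI and rule metadata."""

    mirna: str
    targets: frozenset[str]
    mi: dict[str, float]
    rule: str
    params: dict = field(default_factory=dict)


def _jitter(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    scale = np.ptp(v)
    if scale == 0:
        scale = 1.0
    return v + rng.uniform(-1.0, 1.0, size=v.shape) * _JITTER * scale


def ksg_mi(x, y, k: int = 3, seed: int = 0) -> float:
    """KSG (algorithm 1) mutual information estimate in nats.

    Ties, ubiquitous in count data, are broken by seeded uniform jitter of
    relative scale 1e-10 before the neighbor search.  A constant vector
    carries no information and returns 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("ksg_mi: vectors must have equal length")
    n = x.size
    if n <= k:
        raise ValueError(f"ksg_mi: need n > k (n={n}, k={k})")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("ksg_mi: constant vector, MI = 0")
        return 0.0
    rng = np.random.default_rng(seed)
    x = _jitter(x, rng)
    y = _jitter(y, rng)

    z = np.column_stack([x, y])
    tree = cKDTree(z)
    # distance to the k-th neighbor in the max-norm joint space
    eps = tree.query(z, k=k + 1, p=np.inf)[0][:, -1]

    xs = np.sort(x)
    ys = np.sort(y)
    # strictly-within-eps marginal counts, excluding the point itself
    nx = (np.searchsorted(xs, x + eps, side="left")
          - np.searchsorted(xs, x - eps, side="right")) - 1
    ny = (np.searchsorted(ys, y + eps, side="left")
          - np.searchsorted(ys, y - eps, side="right")) - 1
    mi = (digamma(k) + digamma(n)
          - float(np.mean(digamma(nx + 1) + digamma(ny + 1))))
    return float(mi)


#: sample-count cutoff for the O(n^2) distance-matrix KSG path
_BLOCK_N_MAX = 600


def _ksg_block(mm: np.ndarray, gg: np.ndarray, k: int, seed: int) -> np.ndarray:
    """KSG (algorithm 1) for all miRNA x gene pairs via distance matrices.

    Same estimator as :func:`ksg_mi`, vectorized for small sample counts:
    the Chebyshev joint k-NN radius comes from elementwise maxima of the
    two 1-D distance matrices.
    """
    rng = np.random.default_rng(seed)
    n = mm.shape[1]
    mm = np.stack([_jitter(v, rng) for v in mm]) if mm.size else mm
    gg = np.stack([_jitter(v, rng) for v in gg]) if gg.size else gg
    dg = [np.abs(g[:, None] - g[None, :]) for g in gg]
    out = np.zeros((mm.shape[0], gg.shape[0]))
    base = digamma(k) + digamma(n)
    for i, x in enumerate(mm):
        if np.ptp(x) == 0:
            continue
        dx = np.abs(x[:, None] - x[None, :])
        for j, y in enumerate(gg):
            if np.ptp(y) == 0:
                continue
            dz = np.maximum(dx, dg[j])
            # row includes the self distance 0, so index k is the k-th neighbor
            eps = np.partition(dz, k, axis=1)[:, k]
            nx = (dx < eps[:, None]).sum(axis=1) - 1
            ny = (dg[j] < eps[:, None]).sum(axis=1) - 1
            out[i, j] = base - float(np.mean(digamma(nx + 1) + digamma(ny + 1)))
    return out


def mi_matrix(mirna_expr: pd.DataFrame, gene_expr: pd.DataFrame, k: int = 3,
              log_transform: bool = True, seed: int = 0) -> pd.DataFrame:
    """KSG MI between every miRNA (rows) and gene (columns) on matched samples."""
    common = [s for s in mirna_expr.columns if s in gene_expr.columns]
    if len(common) <= k:
        raise ValueError("mi_matrix: not enough matched samples")
    mm = mirna_expr[common].to_numpy(dtype=float)
    gg = gene_expr[common].to_numpy(dtype=float)
    if log_transform:
        mm = np.log2(mm + 1.0)
        gg = np.log2(gg + 1.0)
    if len(common) <= _BLOCK_N_MAX:
        out = _ksg_block(mm, gg, k=k, seed=seed)
    else:
        out = np.zeros((mm.shape[0], gg.shape[0]))
        for i in range(mm.shape[0]):
            for j in range(gg.shape[0]):
                out[i, j] = ksg_mi(mm[i], gg[j], k=k, seed=seed)
    return pd.DataFrame(out, index=mirna_expr.index, columns=gene_expr.index)


def permutation_null(mirna_expr: pd.DataFrame, gene_expr: pd.DataFrame,
                     k: int = 3, n_permutations: int = 5,
                     log_transform: bool = True, seed: int = 0,
                     ) -> dict[str, np.ndarray]:
    """Null MI distribution per miRNA from sample-shuffled profiles.

    Each permutation shuffles the miRNA's sample order and recomputes MI
    against every gene; the null values are pooled across genes and
    permutations (n_permutations x n_genes values per miRNA).
    """
    rng = np.random.default_rng(seed)
    null: dict[str, np.ndarray] = {}
    for mirna in mirna_expr.index:
        vals = []
        for _ in range(n_permutations):
            perm = rng.permutation(mirna_expr.shape[1])
            shuffled = pd.DataFrame(
                mirna_expr.loc[[mirna]].to_numpy()[:, perm],
                index=[mirna], columns=mirna_expr.columns)
            mi = mi_matrix(shuffled, gene_expr, k=k,
                           log_transform=log_transform,
                           seed=int(rng.integers(2**31)))
            vals.append(mi.to_numpy().ravel())
        null[mirna] = np.concatenate(vals)
    return null


def build_regulon(mi: pd.DataFrame, rule: str = "permutation_fdr",
                  null: dict[str, np.ndarray] | None = None,
                  alpha: float = 0.05, top_k: int | None = None,
                  ) -> dict[str, Regulon]:
    """Turn an MI matrix into per-miRNA target sets.

    ``rule="permutation_fdr"``: per miRNA, empirical p of each gene's MI
    against the pooled permutation null, BH across genes, targets at
    FDR < alpha (default 0.05).  ``rule="top_k"``: the top_k genes by MI.
    """
    regulons: dict[str, Regulon] = {}
    if rule == "permutation_fdr":
        if null is None:
            raise ValueError("permutation_fdr rule needs a permutation null")
        for mirna in mi.index:
            obs = mi.loc[mirna].to_numpy()
            nv = np.sort(null[mirna])
            # empirical upper-tail p with add-one smoothing
            ge = nv.size - np.searchsorted(nv, obs, side="left")
            pvals = (1.0 + ge) / (1.0 + nv.size)
            fdr = bh_adjust(pvals)
            sel = fdr < alpha
            targets = frozenset(mi.columns[sel])
            regulons[mirna] = Regulon(
                mirna=mirna, targets=targets,
                mi={g: float(mi.loc[mirna, g]) for g in targets},
                rule=rule, params={"alpha": alpha, "n_null": int(nv.size)})
    elif rule == "top_k":
        if top_k is None:
            raise ValueError("top_k rule needs top_k")
        for mirna in mi.index:
            row = mi.loc[mirna].sort_values(ascending=False)
            targets = frozenset(row.index[:top_k])
            regulons[mirna] = Regulon(
                mirna=mirna, targets=targets,
                mi={g: float(row[g]) for g in targets},
                rule=rule, params={"top_k": top_k})
    else:
        raise ValueError(f"unknown regulon rule {rule!r}")
    return regulons


def mra_pair(regulons: dict[str, Regulon], pair: tuple[str, str],
             collection, de_mirnas, alpha: float = 0.01) -> pd.DataFrame:
    """Master regulator analysis of one pathway pair.

    For every miRNA with a regulon, tests Fisher over-representation of its
    targets in each pathway of the pair (within the collection's universe),
    BH-adjusts across miRNAs separately per pathway, and flags ``is_mr``
    when both adjusted p-values are below ``alpha`` and the miRNA is
    differentially expressed.
    """
    if not regulons:
        return pd.DataFrame(columns=[
            "mirna", "pair", "n_a", "targets_in_a", "n_b", "targets_in_b",
            "p_a", "p_b", "fdr_a", "fdr_b", "is_mr"])
    name_a, name_b = pair
    uni = collection.universe
    if uni is None:
        raise ValueError("mra_pair: collection must be restricted to a universe")
    genes_a = collection.sets[name_a]
    genes_b = collection.sets[name_b]
    de_mirnas = set(de_mirnas)
    rows = []
    for mirna in sorted(regulons):
        targets = frozenset(regulons[mirna].targets) & uni
        rows.append({
            "mirna": mirna,
            "pair": f"{name_a}|{name_b}",
            "n_a": len(genes_a), "targets_in_a": len(targets & genes_a),
            "n_b": len(genes_b), "targets_in_b": len(targets & genes_b),
            "p_a": fisher_enrichment(targets, genes_a, uni),
            "p_b": fisher_enrichment(targets, genes_b, uni),
        })
    out = pd.DataFrame(rows)
    out["fdr_a"] = bh_adjust(out["p_a"].to_numpy())
    out["fdr_b"] = bh_adjust(out["p_b"].to_numpy())
    out["is_mr"] = ((out["fdr_a"] < alpha) & (out["fdr_b"] < alpha)
                    & out["mirna"].isin(de_mirnas))
    return out


def delta_index(ex_bc: float, ex_ns: float, logfc: float) -> float:
    """Expression-change magnitude (ex_bc - ex_ns) * logFC for a DE miRNA.

    Positive whenever the direction of the mean-expression change agrees
    with the sign of the log fold change.
    """
    for v in (ex_bc, ex_ns, logfc):
        if not np.isfinite(v):
            raise ValueError("delta_index: inputs must be finite")
    return (ex_bc - ex_ns) * logfc


def delta_table(dea_results: pd.DataFrame, mirnas=None) -> pd.DataFrame:
    """Delta index per miRNA from a DEA result table.

    Uses the normalized group means (``mean_tumor``, ``mean_normal``) and
    ``logFC`` columns; restricted to ``mirnas`` when given.
    """
    sub = dea_results if mirnas is None else dea_results.loc[
        [m for m in mirnas if m in dea_results.index]]
    out = pd.DataFrame({
        "mirna": sub.index,
        "logFC": sub["logFC"].to_numpy(),
        "ex_bc": sub["mean_tumor"].to_numpy(),
        "ex_ns": sub["mean_normal"].to_numpy(),
    })
    out["delta"] = (out["ex_bc"] - out["ex_ns"]) * out["logFC"]
    return out.sort_values("delta", ascending=False, ignore_index=True)
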