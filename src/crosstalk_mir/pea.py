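"""Pathway enrichment analysis of DE genes by one-sided Fisher exact test.

Pathways are restricted to the quantile-filtered gene universe before
testing; enrichment significance is BH-adjusted p < alpha (default 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .dea import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayCollection:
    """Named gene sets plus the gene universe they are tested against."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] | None = field(default=None)

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, universe, min_size: int = 5) -> "PathwayCollection":
        """Intersect every pathway with ``universe``; drop sets below ``min_size``."""
        uni = frozenset(universe)
        restricted = {}
        for name, genes in self.sets.items():
            kept = genes & uni
            if len(kept) >= min_size:
                restricted[name] = frozenset(kept)
            else:
                logger.info("dropping pathway %r (%d genes after restriction)",
                            name, len(kept))
        return PathwayCollection(sets=restricted, universe=uni)


def fisher_enrichment(deg, pathway, universe) -> float:
    """One-sided over-representation p of ``deg`` genes in ``pathway``.

    Hypergeometric upper tail of the 2x2 table DEG-membership x
    pathway-membership within ``universe``.
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("fisher_enrichment: empty universe")
    deg = frozenset(deg) & uni
    pw = frozenset(pathway) & uni
    k = len(deg & pw)
    return float(hypergeom.sf(k - 1, len(uni), len(pw), len(deg)))


def enrich_all(deg, collection: PathwayCollection, alpha: float = 0.01) -> pd.DataFrame:
    """Fisher enrichment of every pathway in the collection.

    Returns one row per pathway with the restricted pathway size
    (``n_pathway``), the DEG overlap (``n_common``), the raw p, the BH FDR
    and the significance call ``fdr < alpha``, sorted by FDR ascending.
    """
    if collection.universe is None:
        raise ValueError("enrich_all: collection must be restricted to a universe first")
    uni = collection.universe
    deg = frozenset(deg) & uni
    names = sorted(collection.sets)
    rows = []
    for name in names:
        pw = collection.sets[name]
        rows.append({
            "pathway": name,
            "n_pathway": len(pw),
            "n_common": len(deg & pw),
            "pvalue": fisher_enrichment(deg, pw, uni),
        })
    out = pd.DataFrame(rows, columns=["pathway", "n_pathway", "n_common", "pvalue"])
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy()) if len(out) else []
    out["significant"] = out["fdr"] < alpha
    out = out.sort_values(["fdr", "pvalue", "pathway"], kind="mergesort",
                          ignore_index=True)
    logger.info("enrich_all: %d/%d pathways significant at FDR<%g",
                int(out["significant"].sum()), len(out), alpha)
    return out
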