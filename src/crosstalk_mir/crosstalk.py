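"""Per-sample pathway activity and the pathway-pair Discriminating Score.

For a pathway x and a sample, activity is summarized by the mean M_x and
sample standard deviation S_x of the member genes' log2(count+1)
expression.  The Discriminating Score of an ordered pathway pair (x, y) in
one sample is

    DS = (M_x - M_y) / (S_x + S_y),

a signal-to-noise contrast of the two pathways' activities: larger |DS|
means a larger difference in activity relative to the within-pathway
spread.  The Euclidean-style comparator |M_x - M_y| is provided as a
baseline metric.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pea import PathwayCollection

logger = logging.getLogger(__name__)

#: Replacement magnitude for DS when S_x + S_y == 0 but M_x != M_y.
DS_CAP = 1e6


@dataclass(frozen=True)
class PathwayActivity:
    """Mean (M) and sample SD (S) of member-gene expression, pathways x samples."""

    M: pd.DataFrame
    S: pd.DataFrame

    @property
    def pathways(self) -> list[str]:
        return list(self.M.index)

    @property
    def samples(self) -> list[str]:
        return list(self.M.columns)


def pathway_activity(expr: pd.DataFrame, collection: PathwayCollection,
                     log_transform: bool = True) -> PathwayActivity:
    """Summarize each pathway's member-gene expression per sample.

    ``expr`` holds normalized counts (features x samples); values are taken
    to log2(x+1) scale unless ``log_transform`` is False.  Pathway genes
    absent from the matrix are ignored with a warning; pathways with fewer
    than 2 present genes are dropped, and an error is raised if none remain.
    S uses the sample standard deviation (ddof=1).
    """
    data = np.log2(expr + 1.0) if log_transform else expr
    m_rows, s_rows, names = [], [], []
    for name in sorted(collection.sets):
        genes = sorted(collection.sets[name])
        present = [g for g in genes if g in data.index]
        if len(present) < len(genes):
            logger.warning("pathway %r: %d/%d genes absent from matrix, ignored",
                           name, len(genes) - len(present), len(genes))
        if len(present) < 2:
            logger.warning("pathway %r dropped: <2 genes present", name)
            continue
        sub = data.loc[present]
        m_rows.append(sub.mean(axis=0))
        s_rows.append(sub.std(axis=0, ddof=1))
        names.append(name)
    if not names:
        raise ValueError("pathway_activity: no pathway has >=2 genes in the matrix")
    M = pd.DataFrame(m_rows, index=names)
    S = pd.DataFrame(s_rows, index=names)
    return PathwayActivity(M=M, S=S)


def ds_score(mx, sx, my, sy, cap: float = DS_CAP):
    """Discriminating Score (M_x - M_y) / (S_x + S_y), elementwise.

    Zero-spread pairs (S_x + S_y == 0) give 0 when the means agree, and a
    signed cap of magnitude ``cap`` otherwise.
    """
    mx, sx = np.asarray(mx, dtype=float), np.asarray(sx, dtype=float)
    my, sy = np.asarray(my, dtype=float), np.asarray(sy, dtype=float)
    if any(np.isnan(a).any() for a in (mx, sx, my, sy)):
        raise ValueError("ds_score: NaN input")
    num = mx - my
    den = sx + sy
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0),
                       np.where(num == 0, 0.0, np.sign(num) * cap))
    if np.any((den == 0) & (num != 0)):
        logger.warning("ds_score: zero denominator with unequal means; capped at %g", cap)
    return out if out.shape else float(out)


def pair_name(a: str, b: str) -> str:
    """Canonical column label for the unordered pathway pair {a, b}."""
    x, y = sorted((a, b))
    return f"{x}|{y}"


def ds_matrix(activity: PathwayActivity, cap: float = DS_CAP) -> pd.DataFrame:
    """Samples x pathway-pairs matrix of Discriminating Scores.

    Columns cover all C(P, 2) unordered pairs in lexicographic canonical
    order "x|y" with x < y; DS is computed as ds_score(M_x, S_x, M_y, S_y).
    """
    paths = sorted(activity.pathways)
    if len(paths) < 2:
        raise ValueError("ds_matrix: need at least 2 pathways")
    cols = {}
    for a, b in itertools.combinations(paths, 2):
        cols[pair_name(a, b)] = ds_score(activity.M.loc[a], activity.S.loc[a],
                                         activity.M.loc[b], activity.S.loc[b], cap=cap)
    out = pd.DataFrame(cols, index=activity.samples)
    out.index.name = "sample_id"
    return out


def euclidean_crosstalk(activity: PathwayActivity) -> pd.DataFrame:
    """Baseline comparator: per-sample |M_x - M_y| for every pathway pair.

    The 1-D Euclidean distance between the two pathways' activity means;
    equals |DS| * (S_x + S_y) wherever the spread is positive.
    """
    paths = sorted(activity.pathways)
    if len(paths) < 2:
        raise ValueError("euclidean_crosstalk: need at least 2 pathways")
    cols = {}
    for a, b in itertools.combinations(paths, 2):
        cols[pair_name(a, b)] = np.abs(activity.M.loc[a] - activity.M.loc[b])
    out = pd.DataFrame(cols, index=activity.samples)
    out.index.name = "sample_id"
    return out
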