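"""Differential expression analysis for tumor-vs-normal count matrices.

Implements the first stage of the cross-talk pipeline: a quantile-based
expression filter, library-size equalization, an exact negative-binomial
(NB) test with a single common dispersion, Benjamini-Hochberg adjustment,
and the DE call (|log2 FC| > 1 and FDR < 0.01 by default).

The exact test conditions on the per-group totals of library-equalized
pseudo-counts.  Under NB sampling with common dispersion ``phi`` and equal
library sizes, the tumor-group total given the grand total follows a
beta-binomial law with shape parameters ``n_tumor/phi`` and
``n_normal/phi``; as ``phi -> 0`` this degenerates to the binomial
conditional law of the Poisson two-sample test.  The two-sided p-value sums
the probabilities of all outcomes no more likely than the observed one.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

logger = logging.getLogger(__name__)

TUMOR, NORMAL = "tumor", "normal"

#: phi below this is treated as the Poisson (binomial-conditional) limit.
_POISSON_PHI = 1e-8


def quantile_filter(matrix: pd.DataFrame, q: float = 0.25) -> pd.DataFrame:
    """Drop low-expression features.

    Retains exactly the features whose mean across samples is strictly
    greater than the ``q`` linear-interpolation quantile of all per-feature
    means.  Samples are untouched.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("quantile_filter: empty expression matrix")
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile_filter: q must be in (0, 1), got {q}")
    means = matrix.mean(axis=1)
    cut = float(np.quantile(means.to_numpy(), q))
    kept = matrix.loc[means > cut]
    logger.info("quantile_filter: kept %d/%d features (mean > %.4g)",
                kept.shape[0], matrix.shape[0], cut)
    return kept


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector")
    if np.isnan(p).any():
        raise ValueError("bh_adjust: NaN p-value in input")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("bh_adjust: p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def normalize_libraries(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample's counts so library sizes equal their geometric mean."""
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")
    target = math.exp(float(np.mean(np.log(lib))))
    return counts * (target / lib)


def _check_integer_counts(counts: pd.DataFrame) -> None:
    arr = counts.to_numpy()
    frac = arr != np.floor(arr)
    if frac.any():
        i = int(np.argwhere(frac)[0, 0])
        raise ValueError(
            f"nb_exact_test: non-integer count in feature {counts.index[i]!r}")
    if (arr < 0).any():
        i = int(np.argwhere(arr < 0)[0, 0])
        raise ValueError(
            f"nb_exact_test: negative count in feature {counts.index[i]!r}")


def _split_labels(counts: pd.DataFrame, labels: pd.Series):
    labels = labels.reindex(counts.columns)
    if labels.isna().any():
        missing = counts.columns[labels.isna()].tolist()
        raise ValueError(f"labels missing for samples: {missing}")
    bad = set(labels.unique()) - {TUMOR, NORMAL}
    if bad:
        raise ValueError(f"unexpected labels {sorted(bad)}; expected tumor/normal")
    t_cols = labels.index[labels == TUMOR]
    n_cols = labels.index[labels == NORMAL]
    if len(t_cols) < 2 or len(n_cols) < 2:
        raise ValueError("each group needs at least 2 samples")
    return t_cols, n_cols


def _group_conditional_loglik(y: np.ndarray, r: float) -> float:
    """Conditional NB log-likelihood of one group's counts given their total.

    ``y`` is genes x samples for a single group, ``r = 1/phi``.
    """
    n = y.shape[1]
    z = y.sum(axis=1)
    ll = (gammaln(y + r).sum(axis=1)
          + gammaln(n * r)
          - gammaln(z + n * r)
          - n * gammaln(r))
    return float(ll.sum())


def estimate_common_dispersion(pseudo: pd.DataFrame, labels: pd.Series) -> float:
    """Common NB dispersion maximizing the conditional log-likelihood.

    Works on library-equalized integer pseudo-counts; features with zero
    total are uninformative and skipped.  Returns phi >= 0.
    """
    t_cols, n_cols = _split_labels(pseudo, labels)
    yt = pseudo[t_cols].to_numpy(dtype=float)
    yn = pseudo[n_cols].to_numpy(dtype=float)
    keep = (yt.sum(axis=1) + yn.sum(axis=1)) > 0
    yt, yn = yt[keep], yn[keep]
    if yt.shape[0] == 0:
        return 0.0

    def neg_cl(log_phi: float) -> float:
        r = 1.0 / math.exp(log_phi)
        return -(_group_conditional_loglik(yt, r) + _group_conditional_loglik(yn, r))

    # coarse grid, then bounded refinement around the best cell
    grid = np.linspace(math.log(1e-6), math.log(10.0), 25)
    vals = [neg_cl(g) for g in grid]
    i = int(np.argmin(vals))
    if i == 0:  # boundary: effectively Poisson
        return 0.0
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(neg_cl, bounds=(lo, hi), method="bounded")
    phi = float(math.exp(res.x))
    logger.info("estimated common dispersion phi=%.4g", phi)
    return phi


def _exact_pvalue(a: int, s: int, r_t: float, r_n: float) -> float:
    """Two-sided exact p for tumor total ``a`` given grand total ``s``.

    Sums, over the beta-binomial conditional law, the probabilities of all
    outcomes with probability <= that of the observed outcome (the classic
    small-probabilities two-sided rule).
    """
    if s == 0:
        return 1.0
    x = np.arange(s + 1)
    logpmf = (gammaln(x + r_t) - gammaln(x + 1)
              + gammaln(s - x + r_n) - gammaln(s - x + 1))
    logpmf -= logpmf.max()
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()
    return float(min(1.0, pmf[pmf <= pmf[a] * (1.0 + 1e-9)].sum()))


def _binomial_pvalue(a: int, s: int, n_t: int, n_n: int) -> float:
    """Poisson-limit conditional test: binomial(s, n_t/(n_t+n_n))."""
    if s == 0:
        return 1.0
    x = np.arange(s + 1)
    logp = math.log(n_t / (n_t + n_n))
    logq = math.log(n_n / (n_t + n_n))
    logpmf = (gammaln(s + 1) - gammaln(x + 1) - gammaln(s - x + 1)
              + x * logp + (s - x) * logq)
    pmf = np.exp(logpmf)
    return float(min(1.0, pmf[pmf <= pmf[a] * (1.0 + 1e-9)].sum()))


def nb_exact_test(counts: pd.DataFrame, labels: pd.Series,
                  dispersion: float | str = "auto") -> pd.DataFrame:
    """Exact NB test per feature between tumor and normal groups.

    Parameters
    ----------
    counts
        Raw integer counts, features x samples.
    labels
        Sample -> {"tumor", "normal"}.
    dispersion
        Common dispersion phi (variance = mu + phi mu^2), or ``"auto"`` to
        estimate it by conditional maximum likelihood.

    Returns
    -------
    DataFrame indexed by feature with columns ``logFC`` (log2 tumor/normal on
    normalized means, pseudo-count 0.5), ``pvalue``, ``fdr``, ``mean_tumor``,
    ``mean_normal`` and ``is_de``.
    """
    _check_integer_counts(counts)
    t_cols, n_cols = _split_labels(counts, labels)
    for name, cols in ((TUMOR, t_cols), (NORMAL, n_cols)):
        if counts[cols].to_numpy().sum() == 0:
            raise ValueError(f"nb_exact_test: group {name!r} has zero total count")

    norm = normalize_libraries(counts)
    pseudo = norm.round().astype(np.int64)

    if dispersion == "auto":
        phi = estimate_common_dispersion(pseudo, labels)
    else:
        phi = float(dispersion)
        if phi < 0:
            raise ValueError("dispersion must be nonnegative")

    n_t, n_n = len(t_cols), len(n_cols)
    a_vec = pseudo[t_cols].sum(axis=1).to_numpy()
    s_vec = a_vec + pseudo[n_cols].sum(axis=1).to_numpy()

    pvals = np.ones(counts.shape[0])
    for i, (a, s) in enumerate(zip(a_vec, s_vec)):
        if phi <= _POISSON_PHI:
            pvals[i] = _binomial_pvalue(int(a), int(s), n_t, n_n)
        else:
            pvals[i] = _exact_pvalue(int(a), int(s), n_t / phi, n_n / phi)

    mean_t = norm[t_cols].mean(axis=1)
    mean_n = norm[n_cols].mean(axis=1)
    logfc = np.log2((mean_t + 0.5) / (mean_n + 0.5))
    fdr = bh_adjust(pvals)
    res = pd.DataFrame({
        "logFC": logfc,
        "pvalue": pvals,
        "fdr": fdr,
        "mean_tumor": mean_t,
        "mean_normal": mean_n,
    }, index=counts.index)
    res["is_de"] = (res["logFC"].abs() > 1.0) & (res["fdr"] < 0.01)
    res.index.name = "feature_id"
    return res


def call_de(results: pd.DataFrame, logfc_cut: float = 1.0,
            fdr_cut: float = 0.01) -> set[str]:
    """Features with |logFC| strictly above ``logfc_cut`` and FDR below ``fdr_cut``."""
    if results.shape[0] == 0:
        return set()
    mask = (results["logFC"].abs() > logfc_cut) & (results["fdr"] < fdr_cut)
    return set(results.index[mask])
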