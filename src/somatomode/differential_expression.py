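"""Wilcoxon rank-sum differential expression with detection-rate filters.

Per gene, a two-sided Wilcoxon rank-sum (Mann-Whitney) test compares
depth-normalized expression between two cell groups: exact enumeration over
all group assignments when both groups have at most 8 cells, tie-corrected
normal approximation otherwise. Fold change is the log2 ratio of group mean
linear normalized expression with a 1e-9 pseudocount. A gene "passes" when
raw P < 0.05, log2 fold change > 0.25, and the larger of the two per-group
detection fractions exceeds 0.1 (the min.pct rule). Benjamini-Hochberg
q-values are reported as an extra column but play no role in the pass flag.
"""

from __future__ import annotations

import warnings
from math import comb
from itertools import combinations
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .marker_positivity import cp10k

__all__ = ["wilcoxon_de", "positive_markers", "condition_deg", "EXACT_MAX_N"]

EXACT_MAX_N = 8
PSEUDOCOUNT = 1e-9


def _exact_rank_sum_p(values: np.ndarray, n_a: int) -> np.ndarray:
    """Exact two-sided permutation p-values of the rank-sum statistic.

    ``values`` is genes x cells with the first ``n_a`` columns in group A.
    Enumerates all C(n, n_a) assignments on midranks (handles ties exactly);
    p is the fraction of assignments whose rank sum is at least as far from
    its permutation mean as the observed one.
    """
    n = values.shape[1]
    combos = np.zeros((comb(n, n_a), n))
    for i, idx in enumerate(combinations(range(n), n_a)):
        combos[i, list(idx)] = 1.0
    ranks = stats.rankdata(values, axis=1)
    w_all = ranks @ combos.T  # genes x n_combos
    w_obs = ranks[:, :n_a].sum(axis=1)
    mu = n_a * (n + 1) / 2.0
    dev_obs = np.abs(w_obs - mu)[:, None]
    return (np.abs(w_all - mu) >= dev_obs - 1e-12).mean(axis=1)


def _asymptotic_p(x_a: np.ndarray, x_b: np.ndarray) -> np.ndarray:
    """Tie-corrected normal-approximation Mann-Whitney p per gene (columns)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes emit p=nan warnings
        res = stats.mannwhitneyu(
            x_a, x_b, axis=0, alternative="two-sided", method="asymptotic"
        )
    p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isfinite(p), p, 1.0)  # all-tied genes carry no evidence


def _group_values(adata: ad.AnnData, group: Sequence) -> np.ndarray:
    if isinstance(group, np.ndarray) and group.dtype == bool:
        mask = group
    else:
        mask = adata.obs_names.isin(list(group))
    return np.asarray(mask, dtype=bool)


def wilcoxon_de(
    adata: ad.AnnData,
    group_a: Sequence,
    group_b: Sequence,
    p_cutoff: float = 0.05,
    lfc_cutoff: float = 0.25,
    min_pct: float = 0.1,
    absolute_lfc: bool = False,
) -> pd.DataFrame:
    """Rank-sum DE between two cell groups of a count matrix.

    Groups are boolean masks over cells or iterables of cell ids. Returns a
    DataFrame indexed by gene with columns log2fc, p, q, pct_1, pct_2,
    passes; ``.attrs`` records group sizes and the thresholds. With
    ``absolute_lfc`` the fold-change filter uses |log2fc| instead of the
    positive side only.
    """
    mask_a = _group_values(adata, group_a)
    mask_b = _group_values(adata, group_b)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must contain at least one cell")
    if np.any(mask_a & mask_b):
        raise ValueError("groups must be disjoint")

    X = adata.X.toarray() if sparse.issparse(adata.X) else np.asarray(adata.X, dtype=float)
    norm = cp10k(X)
    x_a, x_b = norm[mask_a], norm[mask_b]

    if max(n_a, n_b) <= EXACT_MAX_N:
        p = _exact_rank_sum_p(np.vstack([x_a, x_b]).T, n_a)
    else:
        p = _asymptotic_p(x_a, x_b)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    mean_a, mean_b = x_a.mean(axis=0), x_b.mean(axis=0)
    log2fc = np.log2((mean_a + PSEUDOCOUNT) / (mean_b + PSEUDOCOUNT))
    raw = X
    pct_1 = (raw[mask_a] > 0).mean(axis=0)
    pct_2 = (raw[mask_b] > 0).mean(axis=0)
    q = multipletests(p, method="fdr_bh")[1]
    fc_stat = np.abs(log2fc) if absolute_lfc else log2fc
    passes = (p < p_cutoff) & (fc_stat > lfc_cutoff) & (np.maximum(pct_1, pct_2) > min_pct)

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "pct_1": pct_1,
            "pct_2": pct_2,
            "passes": passes,
        },
        index=pd.Index(adata.var_names, name="gene"),
    )
    out.attrs.update(
        {
            "n_a": n_a,
            "n_b": n_b,
            "p_cutoff": p_cutoff,
            "lfc_cutoff": lfc_cutoff,
            "min_pct": min_pct,
            "exact": max(n_a, n_b) <= EXACT_MAX_N,
        }
    )
    return out


def positive_markers(
    adata: ad.AnnData,
    cluster_labels: Sequence,
    lfc_threshold: float = 0.1,
) -> dict[str, pd.DataFrame]:
    """Positive marker genes per cluster (each cluster vs all other cells).

    Only genes up-regulated in the cluster with log2 fold change above
    ``lfc_threshold`` are retained, sorted by p. Singleton clusters are
    tested with a warning (the approximation is poor at n=1).
    """
    labels = np.asarray(list(cluster_labels))
    if len(labels) != adata.n_obs:
        raise ValueError("cluster_labels length must match the number of cells")
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    out: dict[str, pd.DataFrame] = {}
    for cl in uniq:
        mask = labels == cl
        if mask.sum() == 1:
            warnings.warn(f"cluster {cl!r} has a single cell; test is approximate only")
        table = wilcoxon_de(adata, mask, ~mask)
        table = table[table["log2fc"] > lfc_threshold].sort_values("p")
        out[str(cl)] = table
    return out


def condition_deg(
    adata: ad.AnnData,
    class_labels: Sequence,
    condition: str,
    reference: str = "control",
    condition_key: str = "condition",
    **de_kwargs,
) -> dict[str, pd.DataFrame]:
    """Per-class DE between a condition (CCI or AEW) and the reference.

    Runs :func:`wilcoxon_de` within each neuron class, comparing cells of
    ``condition`` against ``reference`` cells of the same class. Classes
    missing either condition are skipped with a warning and absent from the
    result.
    """
    labels = np.asarray(list(class_labels))
    if len(labels) != adata.n_obs:
        raise ValueError("class_labels length must match the number of cells")
    cond = adata.obs[condition_key].to_numpy()
    out: dict[str, pd.DataFrame] = {}
    for cl in pd.unique(labels):
        in_class = labels == cl
        mask_a = in_class & (cond == condition)
        mask_b = in_class & (cond == reference)
        if mask_a.sum() == 0 or mask_b.sum() == 0:
            warnings.warn(
                f"class {cl!r} lacks cells in {condition!r} or {reference!r}; skipped"
            )
            continue
        out[str(cl)] = wilcoxon_de(adata, mask_a, mask_b, **de_kwargs)
    return out
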