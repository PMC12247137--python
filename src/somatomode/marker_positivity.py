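"""QC filtering and fraction-of-positive-cells marker thresholding.

Single-cell counts are noisy and zero-inflated, so mean expression is a poor
group summary. The thresholding approach used here instead defines, per
gene, a "maximum" expression level as the mean of the top three per-cell
values, sets a positivity threshold at 5% of that maximum, and calls a cell
positive when its expression strictly exceeds the threshold. DRG neurons are
then classified from four marker genes: itch-related (Mrgpra3+ or Nmb+ but
no pain marker), pain-related (Tac1+ or Calca+ but no itch marker), or
itch/pain-related (at least one marker of each modality).

QC precedes thresholding: cells must have more than 500 detected genes and a
mitochondrial UMI rate below 20% (both strict), and mitochondrial genes are
removed from the retained matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin

from .calcium_response import round_half_away

__all__ = [
    "QcReport",
    "PositivityResult",
    "NeuronClassAssignment",
    "MarkerPositivityClassifier",
    "qc_filter",
    "cp10k",
    "gene_positivity",
    "compute_positivity",
    "classify_neurons",
    "marker_venn",
]

NEURON_CLASSES = ("itch", "pain", "itch_pain", "unclassified")


@dataclass
class QcReport:
    """Per-cell QC metrics and the retained/dropped decision.

    ``per_cell`` columns: n_genes (detected genes), mito_rate, retained.
    """

    per_cell: pd.DataFrame
    n_cells_before: int
    n_cells_after: int
    n_genes_before: int
    n_genes_after: int
    min_genes: int
    max_mito_rate: float


@dataclass
class PositivityResult:
    """Per-gene thresholds and per-cell positivity calls.

    ``per_gene`` columns: max_level (mean of the top-3 per-cell values),
    threshold (threshold_frac x max_level), n_positive, fraction.
    ``positive`` is a cells x genes boolean DataFrame.
    """

    per_gene: pd.DataFrame
    positive: pd.DataFrame
    threshold_frac: float


@dataclass
class NeuronClassAssignment:
    """Itch / pain / itch_pain labels per cell.

    ``counts`` and ``percentages`` cover the classified set (cells positive
    for at least one of the four markers); ``percentages`` are
    half-away-from-zero rounded to one decimal with the classified total as
    denominator. ``marker_fractions`` are per-marker positive fractions over
    all cells.
    """

    labels: pd.Series
    counts: dict[str, int]
    percentages: dict[str, float]
    n_classified: int
    marker_fractions: dict[str, float]


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)


def qc_filter(
    adata: ad.AnnData, min_genes: int = 500, max_mito_rate: float = 0.20
) -> tuple[ad.AnnData, QcReport]:
    """Keep cells with > ``min_genes`` detected genes and mito rate < ``max_mito_rate``.

    Both inequalities are strict (a cell with exactly 500 genes or exactly
    20% mitochondrial UMIs is dropped). Mitochondrial gene rows are removed
    from the retained matrix. Cells are counted on the full matrix,
    mitochondrial genes included.
    """
    X = adata.X
    n_genes_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel()
    if "mito" in adata.var:
        mito_mask = adata.var["mito"].to_numpy(dtype=bool)
    else:
        warnings.warn(
            "no 'mito' annotation in var; mitochondrial rate treated as 0",
            stacklevel=2,
        )
        mito_mask = np.zeros(adata.n_vars, dtype=bool)
    mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_rate = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    retained = (n_genes_detected > min_genes) & (mito_rate < max_mito_rate)

    report = QcReport(
        per_cell=pd.DataFrame(
            {"n_genes": n_genes_detected, "mito_rate": mito_rate, "retained": retained},
            index=adata.obs_names,
        ),
        n_cells_before=adata.n_obs,
        n_cells_after=int(retained.sum()),
        n_genes_before=adata.n_vars,
        n_genes_after=int((~mito_mask).sum()),
        min_genes=min_genes,
        max_mito_rate=max_mito_rate,
    )
    filtered = adata[retained, ~mito_mask].copy()
    return filtered, report


def cp10k(adata_or_X, target_sum: float = 1e4) -> np.ndarray:
    """Depth-normalize to counts per ``target_sum`` per cell (linear scale)."""
    X = adata_or_X.X if isinstance(adata_or_X, ad.AnnData) else adata_or_X
    X = _dense(X)
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return X / totals * target_sum


def gene_positivity(expr: Sequence[float], threshold_frac: float = 0.05) -> pd.Series:
    """Top-3/5% positivity rule for one gene's expression vector.

    max_level is the mean of the three largest per-cell values (zeros count
    when fewer than three cells express the gene); the threshold is
    ``threshold_frac`` x max_level and positivity is strict (> threshold),
    so an all-zero gene has fraction 0.
    """
    x = np.asarray(expr, dtype=float)
    if x.ndim != 1:
        raise ValueError("expression vector must be 1-D")
    if x.size < 3:
        raise ValueError("need at least 3 cells to define the top-3 maximum level")
    top3 = np.partition(x, -3)[-3:]
    max_level = float(top3.mean())
    threshold = threshold_frac * max_level
    positive = x > threshold
    return pd.Series(
        {
            "max_level": max_level,
            "threshold": threshold,
            "n_positive": int(positive.sum()),
            "fraction": float(positive.mean()),
        }
    )


class MarkerPositivityClassifier(BaseEstimator, TransformerMixin):
    """Threshold-based positivity calls and itch/pain classification.

    ``fit`` learns, per gene, the "maximum" level (mean of the top-3
    per-cell values, after per-cell depth normalization when ``normalize``)
    and the positivity threshold ``threshold_frac * max_level``.
    ``transform`` returns boolean positivity calls; ``predict`` maps the
    four marker genes to itch / pain / itch_pain / unclassified labels.

    Accepts an AnnData, a DataFrame (columns = genes), or a plain array
    combined with ``gene_names``.
    """

    def __init__(
        self,
        itch_markers: tuple[str, ...] = ("Mrgpra3", "Nmb"),
        pain_markers: tuple[str, ...] = ("Tac1", "Calca"),
        threshold_frac: float = 0.05,
        normalize: bool = True,
        target_sum: float = 1e4,
        gene_names: tuple[str, ...] | None = None,
    ):
        self.itch_markers = itch_markers
        self.pain_markers = pain_markers
        self.threshold_frac = threshold_frac
        self.normalize = normalize
        self.target_sum = target_sum
        self.gene_names = gene_names

    def _extract(self, X) -> tuple[np.ndarray, list[str], list[str]]:
        if isinstance(X, ad.AnnData):
            return _dense(X.X), list(X.var_names), list(X.obs_names)
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), list(X.columns), list(X.index.astype(str))
        arr = _dense(X)
        if self.gene_names is None:
            raise ValueError("gene_names is required when X is a bare array")
        names = list(self.gene_names)
        if len(names) != arr.shape[1]:
            raise ValueError("gene_names length must match the number of columns")
        return arr, names, [str(i) for i in range(arr.shape[0])]

    def _values(self, arr: np.ndarray) -> np.ndarray:
        return cp10k(arr, self.target_sum) if self.normalize else arr

    def fit(self, X, y=None) -> "MarkerPositivityClassifier":
        arr, genes, _ = self._extract(X)
        if not (0 < self.threshold_frac < 1):
            raise ValueError("threshold_frac must lie in (0, 1)")
        missing = [m for m in (*self.itch_markers, *self.pain_markers) if m not in genes]
        if missing:
            raise ValueError(f"marker genes missing from the matrix: {missing}")
        if arr.shape[0] == 0:
            # Degenerate empty matrix: nothing can be positive.
            self.genes_ = genes
            self.max_level_ = np.zeros(arr.shape[1])
            self.threshold_ = np.zeros(arr.shape[1])
            return self
        if arr.shape[0] < 3:
            raise ValueError("need at least 3 cells to define top-3 maximum levels")
        vals = self._values(arr)
        top3 = np.partition(vals, -3, axis=0)[-3:, :]
        self.genes_ = genes
        self.max_level_ = top3.mean(axis=0)
        self.threshold_ = self.threshold_frac * self.max_level_
        return self

    def transform(self, X) -> pd.DataFrame:
        """Boolean positivity calls (strict >) as a cells x genes DataFrame."""
        if not hasattr(self, "threshold_"):
            raise RuntimeError("fit before transform")
        arr, genes, cells = self._extract(X)
        if genes != self.genes_:
            raise ValueError("gene set/order differs from the fitted matrix")
        vals = self._values(arr)
        return pd.DataFrame(vals > self.threshold_, index=cells, columns=genes)

    def predict(self, X) -> np.ndarray:
        """Per-cell class labels: itch / pain / itch_pain / unclassified."""
        pos = self.transform(X)
        itch = pos[list(self.itch_markers)].any(axis=1).to_numpy()
        pain = pos[list(self.pain_markers)].any(axis=1).to_numpy()
        labels = np.full(len(pos), "unclassified", dtype=object)
        labels[itch & ~pain] = "itch"
        labels[pain & ~itch] = "pain"
        labels[itch & pain] = "itch_pain"
        return labels


def compute_positivity(
    adata: ad.AnnData, threshold_frac: float = 0.05, normalize: bool = True
) -> PositivityResult:
    """Apply the top-3/5% rule to every gene of a count matrix."""
    est = MarkerPositivityClassifier(
        itch_markers=(), pain_markers=(), threshold_frac=threshold_frac, normalize=normalize
    ).fit(adata)
    pos = est.transform(adata)
    per_gene = pd.DataFrame(
        {
            "max_level": est.max_level_,
            "threshold": est.threshold_,
            "n_positive": pos.sum(axis=0).to_numpy(),
            "fraction": pos.mean(axis=0).to_numpy(),
        },
        index=pd.Index(est.genes_, name="gene"),
    )
    return PositivityResult(per_gene=per_gene, positive=pos, threshold_frac=threshold_frac)


def classify_neurons(
    adata: ad.AnnData,
    itch_markers: tuple[str, ...] = ("Mrgpra3", "Nmb"),
    pain_markers: tuple[str, ...] = ("Tac1", "Calca"),
    threshold_frac: float = 0.05,
    normalize: bool = True,
) -> NeuronClassAssignment:
    """Classify neurons from marker positivity.

    The class percentages use the classified set (cells positive for at
    least one marker) as denominator; per-marker fractions use all cells.
    """
    est = MarkerPositivityClassifier(
        itch_markers=itch_markers,
        pain_markers=pain_markers,
        threshold_frac=threshold_frac,
        normalize=normalize,
    ).fit(adata)
    labels = pd.Series(est.predict(adata), index=adata.obs_names, name="neuron_class")
    pos = est.transform(adata)
    classified = labels[labels != "unclassified"]
    n_classified = len(classified)
    counts = {c: int((classified == c).sum()) for c in ("itch", "pain", "itch_pain")}
    percentages = {
        c: round_half_away(100.0 * n / n_classified) if n_classified else float("nan")
        for c, n in counts.items()
    }
    marker_fractions = {
        m: float(pos[m].mean()) for m in (*itch_markers, *pain_markers)
    }
    return NeuronClassAssignment(
        labels=labels,
        counts=counts,
        percentages=percentages,
        n_classified=n_classified,
        marker_fractions=marker_fractions,
    )


def marker_venn(positive: pd.DataFrame, markers: Sequence[str] | None = None) -> dict[tuple[str, ...], int]:
    """Counts for every non-empty positivity combination over k markers.

    Returns a dict mapping each marker combination (tuple, in marker order)
    to the number of cells positive for exactly those markers; the counts
    sum to the number of cells positive for at least one marker.
    """
    if markers is None:
        markers = list(positive.columns)
    markers = list(markers)
    if len(markers) < 2:
        raise ValueError("need at least 2 markers for an overlap breakdown")
    sub = positive[markers].to_numpy(dtype=bool)
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(markers) + 1):
        for combo in combinations(range(len(markers)), r):
            in_combo = np.zeros(len(markers), dtype=bool)
            in_combo[list(combo)] = True
            exact = np.all(sub[:, in_combo], axis=1) & ~np.any(sub[:, ~in_combo], axis=1)
            out[tuple(markers[i] for i in combo)] = int(exact.sum())
    return out
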