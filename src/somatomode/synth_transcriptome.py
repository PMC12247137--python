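"""Synthetic DRG single-cell UMI count matrices with planted structure.

Emulates the study design the transcriptomic arm needs to be testable: six
samples (two each of control, CCI chronic-pain, and AEW chronic-itch mice),
neurons partitioned into itch-competent / pain-competent / dual / negative
classes via four marker genes (Mrgpra3 and Nmb for itch, Tac1 and Calca for
pain), mouse-style ``mt-`` mitochondrial genes, a small planted fraction of
low-quality cells (shallow libraries, high mitochondrial content) for QC to
act on, and planted condition-specific expression shifts for the
differential-expression arm.

Counts are gene-wise negative binomial with per-cell lognormal library-size
factors, thinned by a mean-dependent dropout model; the matrix is a pure
function of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "PlantedEffect",
    "TranscriptomeSimConfig",
    "CellGroundTruth",
    "generate_counts",
    "make_fixture_classes",
    "MOUSE_MITO_GENES",
    "ITCH_MARKERS",
    "PAIN_MARKERS",
]

ITCH_MARKERS = ("Mrgpra3", "Nmb")
PAIN_MARKERS = ("Tac1", "Calca")
MARKERS = ITCH_MARKERS + PAIN_MARKERS

MOUSE_MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)

CELL_CLASSES = ("itch_only", "pain_only", "both", "none")

# Class fractions consistent with the control-group marker arithmetic:
# 420 itch-only, 146 pain-only, 405 dual out of 1242 neurons, the remaining
# 271 negative for all four markers.
_DEFAULT_CLASS_FRACTIONS = {
    "itch_only": 420 / 1242,
    "pain_only": 146 / 1242,
    "both": 405 / 1242,
    "none": 271 / 1242,
}

# Per-marker expression probabilities within marker-competent cells, chosen
# so the marginal per-marker prevalences over all cells approximate the
# control-group proportions (Mrgpra3 4.3%, Nmb 66.1%, Tac1 29.1%, Calca
# 36.7%). itch-competent share = 0.664, pain-competent share = 0.444.
_DEFAULT_MARKER_PROBS = {
    "Mrgpra3": 0.065,
    "Nmb": 0.995,
    "Tac1": 0.655,
    "Calca": 0.826,
}


@dataclass(frozen=True)
class PlantedEffect:
    """A condition-specific expression shift on one gene.

    ``classes=None`` applies the shift in every neuron class; otherwise only
    cells of the listed classes are shifted. ``log2fc`` multiplies the NB
    mean by ``2**log2fc`` in cells of ``condition``.
    """

    gene: str
    condition: str
    log2fc: float
    classes: tuple[str, ...] | None = None


def _default_samples() -> tuple[tuple[str, str], ...]:
    return (
        ("ctrl1", "control"),
        ("ctrl2", "control"),
        ("cci1", "CCI"),
        ("cci2", "CCI"),
        ("aew1", "AEW"),
        ("aew2", "AEW"),
    )


def _default_effects() -> tuple[PlantedEffect, ...]:
    up_cci = tuple(PlantedEffect(f"Bg{i:04d}", "CCI", 1.5) for i in range(50))
    up_aew = tuple(PlantedEffect(f"Bg{i:04d}", "AEW", 1.5) for i in range(50, 100))
    return up_cci + up_aew


@dataclass
class TranscriptomeSimConfig:
    """Configuration for :func:`generate_counts`.

    Notable defaults: 400 cells per sample over 6 samples, 3000 background
    genes (``Bg0000``...) plus 4 markers and 13 mito genes; marker NB mean 20
    with size (inverse-overdispersion) 4 in expressing cells and leaky mean
    0.005 elsewhere; background gene means drawn once per config from
    LogNormal(ln 5, 0.5) — the moderately-to-well expressed gene complement
    the tests act on, near-Poisson (size 10) as UMI counts are; dropout
    probability exp(-dropout_lambda * mu^2) per cell and gene (only sparse
    measurements are thinned noticeably); 5% of cells are planted
    low-quality (library scale 0.05, mito scale 4) so both QC rules have
    something to remove.
    """

    n_cells_per_sample: int = 400
    samples: tuple[tuple[str, str], ...] = field(default_factory=_default_samples)
    n_background_genes: int = 3000
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_FRACTIONS)
    )
    marker_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MARKER_PROBS)
    )
    marker_mean: float = 20.0
    marker_dispersion: float = 4.0
    leak_mean: float = 0.005
    background_mean_log: float = 1.6094379124341003  # ln 5
    background_mean_sigma: float = 0.5
    background_dispersion: float = 10.0
    mito_mean: float = 100.0
    de_base_mean: float = 5.0
    planted_effects: tuple[PlantedEffect, ...] = field(default_factory=_default_effects)
    dropout_lambda: float = 1.2
    libsize_sigma: float = 0.25
    low_quality_fraction: float = 0.05
    low_quality_lib_scale: float = 0.05
    low_quality_mito_scale: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells_per_sample <= 0 or self.n_background_genes <= 0:
            raise ValueError("cell and gene counts must be positive")
        total = sum(self.class_fractions.get(c, 0.0) for c in CELL_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class_fractions must be nonnegative")
        for name in ("marker_mean", "mito_mean", "de_base_mean", "leak_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("marker_dispersion", "background_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        conditions = {cond for _, cond in self.samples}
        genes = set(self.gene_names())
        for eff in self.planted_effects:
            if eff.gene not in genes:
                raise ValueError(f"planted effect on unknown gene {eff.gene!r}")
            if eff.condition not in conditions:
                raise ValueError(f"planted effect on absent condition {eff.condition!r}")

    def gene_names(self) -> list[str]:
        bg = [f"Bg{i:04d}" for i in range(self.n_background_genes)]
        return list(MARKERS) + list(MOUSE_MITO_GENES) + bg


@dataclass
class CellGroundTruth:
    """Planted per-cell truth and the planted DE gene set.

    ``cells`` columns: cell_id, sample, condition, planted_class,
    Mrgpra3/Nmb/Tac1/Calca (planted marker expression booleans),
    low_quality. ``effects`` is the planted effect table.
    """

    cells: pd.DataFrame
    effects: pd.DataFrame

    @property
    def class_counts(self) -> dict[str, int]:
        counts = self.cells["planted_class"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in CELL_CLASSES}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial draws parametrized by mean and size (dispersion)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        p = dispersion / (dispersion + mean[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


def generate_counts(config: TranscriptomeSimConfig) -> tuple[ad.AnnData, CellGroundTruth]:
    """Simulate a cells x genes UMI matrix plus per-cell ground truth.

    The returned AnnData carries obs columns sample / condition /
    planted_class / low_quality and var columns mito / role.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    n_genes = len(genes)
    gene_index = {g: j for j, g in enumerate(genes)}
    n_cells = config.n_cells_per_sample * len(config.samples)

    # --- per-cell metadata -------------------------------------------------
    sample_ids = np.repeat([s for s, _ in config.samples], config.n_cells_per_sample)
    conditions = np.repeat([c for _, c in config.samples], config.n_cells_per_sample)
    fractions = np.array([config.class_fractions[c] for c in CELL_CLASSES])
    classes = rng.choice(CELL_CLASSES, size=n_cells, p=fractions / fractions.sum())
    low_quality = rng.random(n_cells) < config.low_quality_fraction

    itch_competent = np.isin(classes, ("itch_only", "both"))
    pain_competent = np.isin(classes, ("pain_only", "both"))
    marker_on = {}
    for m in ITCH_MARKERS:
        marker_on[m] = itch_competent & (rng.random(n_cells) < config.marker_probs[m])
    for m in PAIN_MARKERS:
        marker_on[m] = pain_competent & (rng.random(n_cells) < config.marker_probs[m])
    # Competent cells must express at least one marker of their modality;
    # fall back to the high-prevalence marker of the pair.
    none_itch = itch_competent & ~(marker_on["Mrgpra3"] | marker_on["Nmb"])
    marker_on["Nmb"] = marker_on["Nmb"] | none_itch
    none_pain = pain_competent & ~(marker_on["Tac1"] | marker_on["Calca"])
    marker_on["Calca"] = marker_on["Calca"] | none_pain

    # --- per-gene base means ----------------------------------------------
    base_mean = np.zeros(n_genes)
    for m in MARKERS:
        base_mean[gene_index[m]] = config.leak_mean
    for g in MOUSE_MITO_GENES:
        base_mean[gene_index[g]] = config.mito_mean
    bg_slice = slice(len(MARKERS) + len(MOUSE_MITO_GENES), n_genes)
    base_mean[bg_slice] = rng.lognormal(
        mean=config.background_mean_log,
        sigma=config.background_mean_sigma,
        size=config.n_background_genes,
    )
    for eff in config.planted_effects:
        base_mean[gene_index[eff.gene]] = config.de_base_mean

    # --- per-cell x per-gene mean matrix ----------------------------------
    lib = rng.lognormal(mean=0.0, sigma=config.libsize_sigma, size=n_cells)
    lib_nonmito = np.where(low_quality, lib * config.low_quality_lib_scale, lib)
    lib_mito = np.where(low_quality, lib * config.low_quality_mito_scale, lib)
    mito_mask = np.array([g.startswith("mt-") for g in genes])

    mu = np.outer(lib_nonmito, base_mean)
    mu[:, mito_mask] = np.outer(lib_mito, base_mean[mito_mask])
    for m in MARKERS:
        j = gene_index[m]
        mu[marker_on[m], j] = config.marker_mean * lib_nonmito[marker_on[m]]
    for eff in config.planted_effects:
        j = gene_index[eff.gene]
        rows = conditions == eff.condition
        if eff.classes is not None:
            rows = rows & np.isin(classes, eff.classes)
        mu[rows, j] = mu[rows, j] * (2.0 ** eff.log2fc)

    # --- sampling ----------------------------------------------------------
    counts = np.zeros((n_cells, n_genes), dtype=np.int64)
    disp = np.full(n_genes, config.background_dispersion)
    for m in MARKERS:
        disp[gene_index[m]] = config.marker_dispersion
    for j in range(n_genes):
        counts[:, j] = _nb_draw(rng, mu[:, j], disp[j])
    # Mean-dependent dropout: low-expression measurements vanish often,
    # well-expressed ones rarely (p_drop = exp(-lambda * mu^2)).
    p_drop = np.exp(-config.dropout_lambda * mu**2)
    counts[rng.random(counts.shape) < p_drop] = 0

    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    obs = pd.DataFrame(
        {
            "sample": sample_ids,
            "condition": conditions,
            "planted_class": classes,
            "low_quality": low_quality,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    roles = (
        ["itch_marker"] * len(ITCH_MARKERS)
        + ["pain_marker"] * len(PAIN_MARKERS)
        + ["mito"] * len(MOUSE_MITO_GENES)
        + ["background"] * config.n_background_genes
    )
    var = pd.DataFrame(
        {"mito": mito_mask, "role": roles}, index=pd.Index(genes, name="gene")
    )
    adata = ad.AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var)

    truth_cells = obs.reset_index().copy()
    for m in MARKERS:
        truth_cells[m] = marker_on[m]
    effects = pd.DataFrame(
        [
            {
                "gene": e.gene,
                "condition": e.condition,
                "log2fc": e.log2fc,
                "classes": "all" if e.classes is None else ",".join(e.classes),
            }
            for e in config.planted_effects
        ]
    )
    return adata, CellGroundTruth(cells=truth_cells, effects=effects)


def make_fixture_classes(
    counts_per_class: Mapping[str, int], marker_level: float = 10.0
) -> tuple[ad.AnnData, CellGroundTruth]:
    """Build a minimal deterministic matrix with exact marker-class counts.

    Each requested cell expresses one representative marker per modality at
    ``marker_level`` (Nmb for itch-competent classes, Tac1 for
    pain-competent ones) plus a housekeeping gene ``Actb`` so every cell has
    a nonzero library. Running positivity thresholding and classification on
    the result recovers exactly the requested class counts.
    """
    bad = [c for c in counts_per_class if c not in CELL_CLASSES]
    if bad:
        raise ValueError(f"unknown classes {bad}; expected {CELL_CLASSES}")
    if any(v < 0 for v in counts_per_class.values()):
        raise ValueError("requested counts must be >= 0")
    n = {c: int(counts_per_class.get(c, 0)) for c in CELL_CLASSES}
    total = sum(n.values())
    genes = list(MARKERS) + ["Actb"]
    X = np.zeros((total, len(genes)))
    classes: list[str] = []
    row = 0
    for cls in CELL_CLASSES:
        for _ in range(n[cls]):
            X[row, genes.index("Actb")] = marker_level
            if cls in ("itch_only", "both"):
                X[row, genes.index("Nmb")] = marker_level
            if cls in ("pain_only", "both"):
                X[row, genes.index("Tac1")] = marker_level
            classes.append(cls)
            row += 1
    cell_ids = [f"fix{i:05d}" for i in range(total)]
    obs = pd.DataFrame(
        {
            "sample": "fixture",
            "condition": "control",
            "planted_class": classes,
            "low_quality": False,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    var = pd.DataFrame(
        {
            "mito": [False] * len(genes),
            "role": ["itch_marker", "itch_marker", "pain_marker", "pain_marker", "background"],
        },
        index=pd.Index(genes, name="gene"),
    )
    adata = ad.AnnData(X=sparse.csr_matrix(X), obs=obs, var=var)
    truth_cells = obs.reset_index().copy()
    truth_cells["Mrgpra3"] = False
    truth_cells["Nmb"] = np.isin(classes, ("itch_only", "both"))
    truth_cells["Tac1"] = np.isin(classes, ("pain_only", "both"))
    truth_cells["Calca"] = False
    return adata, CellGroundTruth(
        cells=truth_cells,
        effects=pd.DataFrame(columns=["gene", "condition", "log2fc", "classes"]),
    )
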