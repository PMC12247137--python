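"""End-to-end pipeline runs with manifests for reproducibility.

Each run writes its stage tables (CSV), a JSON summary of the headline
numbers, and a JSON manifest echoing inputs, thresholds and seeds so every
output is reproducible from the manifest alone. Manifests carry no
timestamps: reruns with identical configs are byte-identical.
"""

from __future__ import annotations

import importlib.metadata
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import anndata as ad
import pandas as pd

from . import calcium_response as cr
from . import differential_expression as de
from . import io as smio
from . import marker_positivity as mp

__all__ = ["CalciumRunConfig", "TranscriptomeRunConfig", "run_calcium_pipeline", "run_transcriptome_pipeline"]


def _version() -> str:
    try:
        return importlib.metadata.version("somatomode")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class CalciumRunConfig:
    """Inputs and thresholds for the calcium analysis run."""

    recording_csv: str
    epochs_yaml: str
    out_dir: str
    threshold_pct: float = 20.0
    baseline_s: float = 60.0
    exclusion_s: float = 60.0
    mechanical_margin_s: float = 10.0
    chemical_observation_s: float = 660.0
    n_detectable: int | None = None

    def validate(self) -> None:
        if self.threshold_pct < 0:
            raise ValueError("activation threshold must be >= 0")
        if self.baseline_s <= 0:
            raise ValueError("baseline_s must be > 0")


@dataclass
class TranscriptomeRunConfig:
    """Inputs and thresholds for the transcriptomic analysis run."""

    counts_dir: str
    out_dir: str
    itch_markers: tuple[str, ...] = ("Mrgpra3", "Nmb")
    pain_markers: tuple[str, ...] = ("Tac1", "Calca")
    threshold_frac: float = 0.05
    min_genes: int = 500
    max_mito_rate: float = 0.20
    run_de: bool = False
    de_conditions: tuple[str, ...] = ("CCI", "AEW")
    de_p_cutoff: float = 0.05
    de_lfc_cutoff: float = 0.25
    de_min_pct: float = 0.1
    skip_qc: bool = False

    def validate(self) -> None:
        if not (0 < self.threshold_frac < 1):
            raise ValueError("positivity threshold fraction must lie in (0, 1)")
        if not (0 < self.de_p_cutoff < 1):
            raise ValueError("DE p cutoff must lie in (0, 1)")
        if not (0 <= self.max_mito_rate <= 1):
            raise ValueError("mito rate cutoff must lie in [0, 1]")


def run_calcium_pipeline(config: CalciumRunConfig) -> dict:
    """ΔF/F0 -> response calls -> overlap summaries, written to out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = smio.read_recording(config.recording_csv, config.epochs_yaml)
    dff = cr.compute_dff(rec, baseline_s=config.baseline_s)
    calls = cr.call_responses(
        dff,
        rec.epochs,
        threshold_pct=config.threshold_pct,
        exclusion_s_after_injection=config.exclusion_s,
        mechanical_margin_s=config.mechanical_margin_s,
        chemical_observation_s=config.chemical_observation_s,
    )

    dff_df = pd.DataFrame(dff.dff.T, columns=list(dff.neuron_ids))
    dff_df.insert(0, "time_s", dff.time)
    dff_df.to_csv(out / "dff.csv", index=False, float_format="%.4f")
    calls.calls.to_csv(out / "response_calls.csv", index=False, float_format="%.4f")

    labels = [e.label for e in rec.epochs]
    overlaps = {}
    for a, b in combinations(dict.fromkeys(labels), 2):
        overlaps[f"{a}_vs_{b}"] = cr.summarize_overlap(calls, a, b).as_dict()
    activated = {lab: calls.n_activated(lab) for lab in dict.fromkeys(labels)}
    summary: dict = {"n_neurons": rec.n_neurons, "activated_counts": activated, "overlap": overlaps}
    if config.n_detectable is not None:
        summary["activated_pct_of_detectable"] = {
            lab: cr.activated_fraction(calls, lab, config.n_detectable)
            for lab in dict.fromkeys(labels)
        }
        summary["n_detectable"] = config.n_detectable
    smio.write_json(summary, out / "summary.json")

    manifest = {
        "pipeline": "calcium",
        "version": _version(),
        "inputs": {"recording_csv": str(config.recording_csv), "epochs_yaml": str(config.epochs_yaml)},
        "thresholds": {
            "activation_pct": config.threshold_pct,
            "baseline_s": config.baseline_s,
            "exclusion_s": config.exclusion_s,
            "mechanical_margin_s": config.mechanical_margin_s,
            "chemical_observation_s": config.chemical_observation_s,
        },
        "n_detectable": config.n_detectable,
        "outputs": ["dff.csv", "response_calls.csv", "summary.json"],
    }
    smio.write_json(manifest, out / "manifest.json")
    return summary


def run_transcriptome_pipeline(config: TranscriptomeRunConfig) -> dict:
    """QC -> positivity -> classification (-> optional per-class DE)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    adata = smio.read_counts_10x(config.counts_dir)
    for m in (*config.itch_markers, *config.pain_markers):
        if m not in adata.var_names:
            raise ValueError(f"marker gene {m!r} missing from the count matrix")

    if config.skip_qc:
        filtered, qc_summary = adata, None
    else:
        filtered, qc = mp.qc_filter(adata, config.min_genes, config.max_mito_rate)
        qc.per_cell.to_csv(out / "qc_per_cell.csv")
        if qc.n_cells_after == 0:
            raise ValueError("QC retained no cells; nothing to analyze")
        qc_summary = {
            "n_cells_before": qc.n_cells_before,
            "n_cells_after": qc.n_cells_after,
            "n_genes_after": qc.n_genes_after,
        }

    positivity = mp.compute_positivity(filtered, threshold_frac=config.threshold_frac)
    positivity.per_gene.to_csv(out / "positivity_per_gene.csv", float_format="%.6g")
    assignment = mp.classify_neurons(
        filtered,
        itch_markers=config.itch_markers,
        pain_markers=config.pain_markers,
        threshold_frac=config.threshold_frac,
    )
    assignment.labels.to_frame().to_csv(out / "neuron_classes.csv")
    markers = [*config.itch_markers, *config.pain_markers]
    venn = mp.marker_venn(positivity.positive, markers)

    summary: dict = {
        "qc": qc_summary,
        "n_cells": int(filtered.n_obs),
        "n_classified": assignment.n_classified,
        "class_counts": assignment.counts,
        "class_percentages": assignment.percentages,
        "marker_fractions": {m: round(f, 6) for m, f in assignment.marker_fractions.items()},
        "venn_counts": {"+".join(k): v for k, v in venn.items()},
    }

    if config.run_de and "condition" in filtered.obs:
        de_out = {}
        for cond in config.de_conditions:
            tables = de.condition_deg(
                filtered,
                assignment.labels.to_numpy(),
                cond,
                p_cutoff=config.de_p_cutoff,
                lfc_cutoff=config.de_lfc_cutoff,
                min_pct=config.de_min_pct,
            )
            for cls, table in tables.items():
                path = out / f"deg_{cond}_vs_control_{cls}.csv"
                table.to_csv(path, float_format="%.6g")
                de_out[f"{cond}:{cls}"] = int(table["passes"].sum())
        summary["de_passing_genes"] = de_out

    smio.write_json(summary, out / "summary.json")
    manifest = {
        "pipeline": "transcriptome",
        "version": _version(),
        "inputs": {"counts_dir": str(config.counts_dir)},
        "thresholds": {
            "positivity_fraction": config.threshold_frac,
            "qc_min_genes": config.min_genes,
            "qc_max_mito_rate": config.max_mito_rate,
            "de_p": config.de_p_cutoff,
            "de_log2fc": config.de_lfc_cutoff,
            "de_min_pct": config.de_min_pct,
        },
        "markers": {"itch": list(config.itch_markers), "pain": list(config.pain_markers)},
        "skip_qc": config.skip_qc,
        "outputs": sorted(p.name for p in out.glob("*.csv")) + ["summary.json"],
    }
    smio.write_json(manifest, out / "manifest.json")
    return summary
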