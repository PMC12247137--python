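"""Readers and writers for the pipeline's standard on-disk formats.

Recordings travel as a CSV trace matrix (first column ``time_s``, one column
per neuron) with a YAML sidecar of epochs; count matrices use the 10x-style
Matrix Market triplet layout (``matrix.mtx`` features x barcodes,
``features.tsv``, ``barcodes.tsv``) plus ``metadata.tsv`` for cell
annotations. All round-trips are lossless up to float formatting.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy import io as scio
from scipy import sparse

from .calcium_response import Epoch, FluorescenceRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_counts_10x",
    "read_counts_10x",
    "write_json",
]


def write_recording(rec: FluorescenceRecording, out_dir: str | Path, stem: str = "recording") -> dict:
    """Write traces as CSV and epochs (+frame rate) as a YAML sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    yaml_path = out_dir / f"{stem}.epochs.yaml"
    df = pd.DataFrame(rec.traces.T, columns=list(rec.neuron_ids))
    df.insert(0, "time_s", rec.time)
    df.to_csv(csv_path, index=False, float_format="%.6f")
    meta = {
        "frame_rate": float(rec.frame_rate),
        "epochs": [
            {"label": e.label, "onset": float(e.onset), "offset": float(e.offset), "kind": e.kind}
            for e in rec.epochs
        ],
    }
    yaml_path.write_text(yaml.safe_dump(meta, sort_keys=False))
    return {"traces": str(csv_path), "epochs": str(yaml_path)}


def read_recording(csv_path: str | Path, epochs_path: str | Path | None = None) -> FluorescenceRecording:
    """Read a recording written by :func:`write_recording`."""
    csv_path = Path(csv_path)
    if epochs_path is None:
        epochs_path = csv_path.with_suffix("").with_suffix(".epochs.yaml") \
            if csv_path.name.endswith(".csv") else None
        epochs_path = csv_path.parent / (csv_path.stem + ".epochs.yaml")
    try:
        df = pd.read_csv(csv_path)
    except Exception as err:  # pragma: no cover - passthrough with context
        raise IOError(f"cannot read recording CSV {csv_path}: {err}") from err
    if "time_s" not in df.columns:
        raise IOError(f"{csv_path}: first column must be 'time_s'")
    meta = yaml.safe_load(Path(epochs_path).read_text())
    epochs = tuple(
        Epoch(d["label"], float(d["onset"]), float(d["offset"]), d.get("kind", "mechanical"))
        for d in meta.get("epochs", [])
    )
    if not epochs:
        raise IOError(f"{epochs_path}: missing or empty 'epochs' section")
    neuron_ids = tuple(c for c in df.columns if c != "time_s")
    return FluorescenceRecording(
        traces=df[list(neuron_ids)].to_numpy(dtype=float).T,
        frame_rate=float(meta["frame_rate"]),
        epochs=epochs,
        neuron_ids=neuron_ids,
    )


def write_counts_10x(adata: ad.AnnData, out_dir: str | Path) -> dict:
    """Write a count matrix in the 10x triplet layout plus metadata.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    scio.mmwrite(out_dir / "matrix.mtx", X.T.tocoo().astype(int))  # features x barcodes
    feats = pd.DataFrame(
        {
            "gene_id": adata.var_names,
            "gene_name": adata.var_names,
            "feature_type": "Gene Expression",
        }
    )
    feats.to_csv(out_dir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(out_dir / "barcodes.tsv", sep="\t", header=False, index=False)
    meta = adata.obs.copy()
    meta.insert(0, "barcode", adata.obs_names)
    meta.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    if len(adata.var.columns):
        var = adata.var.copy()
        var.insert(0, "gene", adata.var_names)
        var.to_csv(out_dir / "features_meta.tsv", sep="\t", index=False)
    return {"dir": str(out_dir)}


def read_counts_10x(in_dir: str | Path) -> ad.AnnData:
    """Read the layout written by :func:`write_counts_10x`."""
    in_dir = Path(in_dir)
    try:
        mat = scio.mmread(in_dir / "matrix.mtx").tocsr().T.tocsr()  # cells x genes
    except Exception as err:
        raise IOError(f"cannot read {in_dir / 'matrix.mtx'}: {err}") from err
    genes = pd.read_csv(in_dir / "features.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(in_dir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    obs = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
    meta_path = in_dir / "metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t").set_index("barcode")
        obs = meta.reindex(barcodes)
        obs.index.name = "cell_id"
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    vmeta_path = in_dir / "features_meta.tsv"
    if vmeta_path.exists():
        vmeta = pd.read_csv(vmeta_path, sep="\t").set_index("gene")
        var = vmeta.reindex(genes)
        var.index.name = "gene"
    else:
        var["mito"] = [g.startswith("mt-") for g in genes]
    return ad.AnnData(X=mat.astype(np.int64), obs=obs, var=var)


def write_json(obj: dict, path: str | Path) -> None:
    """Write a JSON summary with stable key order (reproducible bytes)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
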