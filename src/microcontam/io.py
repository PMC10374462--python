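"""Readers and writers for the pipeline's on-disk formats.

Counts travel as MatrixMarket triplets (genes as rows) with gene/cell id
sidecars, or as dense CSV; metadata as TSV; marker panels, signatures and
ground truth as JSON; gene-set collections as GMT; configs as YAML. All
formats are plain text and round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .errors import FormatError, InputError
from .normalize import MarkerPanel
from .signatures import SignatureSet
from .simulate import GroundTruth, SimulationConfig


# ---------------------------------------------------------------------------
# expression datasets

def write_counts(dataset: ad.AnnData, path: str | Path,
                 fmt: str = "mtx") -> Path:
    """Write counts plus metadata into directory ``path``.

    ``fmt="mtx"``: matrix.mtx (genes x cells) + genes.txt + cells.txt;
    ``fmt="csv"``: counts.csv with gene rows and cell columns. Cell and gene
    metadata always land in cell_meta.tsv / gene_meta.tsv.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = dataset.X
    counts = np.asarray(X.todense() if hasattr(X, "todense") else X).T
    if fmt == "mtx":
        spio.mmwrite(path / "matrix.mtx", sparse.coo_matrix(counts),
                     field="integer")
        (path / "genes.txt").write_text("\n".join(dataset.var_names) + "\n")
        (path / "cells.txt").write_text("\n".join(dataset.obs_names) + "\n")
    elif fmt == "csv":
        pd.DataFrame(counts, index=dataset.var_names,
                     columns=dataset.obs_names).to_csv(path / "counts.csv")
    else:
        raise InputError(f"unknown counts format {fmt!r} (mtx|csv)")
    dataset.obs.to_csv(path / "cell_meta.tsv", sep="\t")
    dataset.var.to_csv(path / "gene_meta.tsv", sep="\t")
    return path


def read_counts(path: str | Path) -> ad.AnnData:
    """Load a dataset written by :func:`write_counts` (auto-detects format)."""
    path = Path(path)
    if (path / "matrix.mtx").exists():
        mat = np.asarray(spio.mmread(path / "matrix.mtx").todense(),
                         dtype=np.int64)
        genes = (path / "genes.txt").read_text().splitlines()
        cells = (path / "cells.txt").read_text().splitlines()
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix is {mat.shape[0]}x{mat.shape[1]} but sidecars list "
                f"{len(genes)} genes and {len(cells)} cells")
        counts = pd.DataFrame(mat, index=genes, columns=cells)
    elif (path / "counts.csv").exists():
        counts = pd.read_csv(path / "counts.csv", index_col=0)
    else:
        raise FormatError(f"no matrix.mtx or counts.csv under {path}")

    obs = pd.read_csv(path / "cell_meta.tsv", sep="\t", index_col=0)
    var = pd.read_csv(path / "gene_meta.tsv", sep="\t", index_col=0)
    if not obs.index.equals(counts.columns.astype(obs.index.dtype)):
        if len(obs) != counts.shape[1]:
            raise FormatError("cell metadata rows do not match matrix columns")
        obs = obs.loc[counts.columns]
    if len(var) != counts.shape[0]:
        raise FormatError("gene metadata rows do not match matrix rows")
    var = var.loc[counts.index]
    return ad.AnnData(X=counts.to_numpy().T.astype(np.int64), obs=obs, var=var)


# ---------------------------------------------------------------------------
# tables with provenance headers

def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None,
                index: bool = True) -> Path:
    """TSV with a small self-describing comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# written by microcontam\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# ---------------------------------------------------------------------------
# panels, signatures, gene sets

def write_marker_panel(panel: MarkerPanel, path: str | Path) -> Path:
    path = Path(path)
    payload = {"target": panel.target_type, "on": panel.on_markers,
               "off": panel.off_markers,
               "specificity_scores": panel.specificity_scores}
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def read_marker_panel(path: str | Path) -> MarkerPanel:
    d = json.loads(Path(path).read_text())
    return MarkerPanel(target_type=d["target"], on_markers=list(d.get("on", [])),
                       off_markers={k: list(v) for k, v in
                                    d.get("off", {}).items()},
                       specificity_scores=d.get("specificity_scores", {}))


def write_signatures(sig: SignatureSet, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(sig.to_dict(), indent=2) + "\n")
    return path


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one gene set per line — name, description, member genes."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line needs name, description and >= 1 "
                              f"gene: {line[:60]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              description: str = "microcontam") -> Path:
    path = Path(path)
    lines = ["\t".join([name, description, *sorted(genes)])
             for name, genes in sets.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# ground truth and configuration

def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=2) + "\n")
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


def write_sim_config(config: SimulationConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return path


def read_sim_config(path: str | Path) -> SimulationConfig:
    return SimulationConfig.from_dict(yaml.safe_load(Path(path).read_text()))
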