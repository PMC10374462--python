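"""Gene filtering, log2 CPM normalization, and marker-panel derivation.

Counts live in an AnnData (cells x genes); normalized matrices are kept as a
genes x cells frame of ``log2(CPM + pseudocount)``, the scale on which marker
sums and contamination scores are defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .errors import InputError, MarkerSelectionError

log = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class NormalizedMatrix:
    """genes x cells matrix of log2(CPM + pseudocount)."""

    values: pd.DataFrame
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    source: str | None = None

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cells(self) -> pd.Index:
        return self.values.columns

    def cpm(self) -> pd.DataFrame:
        """Undo the log transform: counts per million."""
        return 2.0 ** self.values - self.pseudocount


@dataclass
class MarkerPanel:
    """Named marker sets for a target cell type.

    ``off_markers`` maps each contaminant type to genes specific to it that a
    clean recorded cell should not express; ``on_markers`` are genes high in
    the recorded type itself.
    """

    target_type: str
    on_markers: list[str] = field(default_factory=list)
    off_markers: dict[str, list[str]] = field(default_factory=dict)
    specificity_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        off_all = {g for genes in self.off_markers.values() for g in genes}
        overlap = off_all & set(self.on_markers)
        if overlap:
            raise InputError(f"on/off marker sets overlap: {sorted(overlap)[:5]}")

    def off(self, contaminant: str) -> list[str]:
        try:
            return self.off_markers[contaminant]
        except KeyError:
            raise InputError(f"no off-marker list for contaminant {contaminant!r}")


def _counts_matrix(dataset: ad.AnnData) -> np.ndarray:
    X = dataset.X
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def filter_genes(dataset: ad.AnnData, drop_flags: set[str] | list[str]) -> ad.AnnData:
    """Drop genes carrying any of the boolean flags in ``gene_meta``.

    Typical use removes mitochondrial genes before normalization. The empty
    flag set is the identity; removing every gene is an error.
    """
    drop_flags = set(drop_flags)
    for flag in drop_flags:
        if flag not in dataset.var.columns:
            raise InputError(f"unknown gene flag {flag!r}; "
                             f"available: {sorted(dataset.var.columns)}")
    if not drop_flags:
        return dataset.copy()
    mask = np.zeros(dataset.n_vars, dtype=bool)
    for flag in drop_flags:
        mask |= dataset.var[flag].astype(bool).to_numpy()
    if mask.all():
        raise InputError("all genes flagged; filtered matrix would be empty")
    log.info("filter_genes: removed %d of %d genes (flags: %s)",
             int(mask.sum()), dataset.n_vars, sorted(drop_flags))
    return dataset[:, ~mask].copy()


def cpm_log2(dataset: ad.AnnData,
             pseudocount: float = DEFAULT_PSEUDOCOUNT) -> NormalizedMatrix:
    """log2(CPM + pseudocount) per gene and cell.

    With the default pseudocount of 1, zero counts map to exactly 0.
    """
    if pseudocount <= 0:
        raise InputError("pseudocount must be positive")
    counts = _counts_matrix(dataset).T.astype(float)  # genes x cells
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = dataset.obs_names[np.where(totals <= 0)[0]].tolist()
        raise InputError(f"cells with zero total counts: {bad[:10]}")
    values = np.log2(1e6 * counts / totals + pseudocount)
    frame = pd.DataFrame(values, index=dataset.var_names.copy(),
                         columns=dataset.obs_names.copy())
    return NormalizedMatrix(values=frame, pseudocount=pseudocount)


def mean_log2cpm_by_type(normed: NormalizedMatrix,
                         labels: pd.Series) -> pd.DataFrame:
    """Per-gene mean normalized expression within each cell-type label."""
    labels = labels.loc[normed.cells]
    return normed.values.T.groupby(labels, observed=True).mean().T


def select_markers(reference: ad.AnnData, target_type: str, n: int = 50,
                   mode: str = "off",
                   pseudocount: float = DEFAULT_PSEUDOCOUNT,
                   label_col: str = "cell_type") -> MarkerPanel:
    """Derive a marker panel for ``target_type`` from a labelled reference.

    Specificity of gene g for type T is
    ``s(g) = mean log2CPM in T − max over other types of mean log2CPM``;
    the top-n genes with s(g) > 0 are selected, ties broken by gene id.
    ``mode="off"`` stores them as off markers keyed by the contaminant type
    (the target itself); ``mode="on"`` stores them as on markers.
    """
    if mode not in ("on", "off"):
        raise InputError(f"mode must be 'on' or 'off', got {mode!r}")
    labels = reference.obs[label_col]
    types = labels.unique()
    if len(types) < 2:
        raise InputError("reference must contain at least 2 cell types")
    if target_type not in set(types):
        raise InputError(f"target type {target_type!r} not in reference")
    if n > reference.n_vars:
        raise InputError(f"requested n={n} markers but only "
                         f"{reference.n_vars} genes present")

    normed = cpm_log2(reference, pseudocount)
    means = mean_log2cpm_by_type(normed, labels)
    others = [t for t in means.columns if t != target_type]
    score = means[target_type] - means[others].max(axis=1)

    if n == 0:
        return MarkerPanel(target_type=target_type)
    eligible = score[score > 0]
    if len(eligible) < n:
        raise MarkerSelectionError(
            f"only {len(eligible)} genes have positive specificity for "
            f"{target_type!r}; requested {n}")
    # stable: descending score, ascending gene id on ties
    order = eligible.sort_index().sort_values(ascending=False, kind="stable")
    chosen = order.index[:n].tolist()
    scores = {g: float(eligible[g]) for g in chosen}
    if mode == "off":
        return MarkerPanel(target_type=target_type,
                           off_markers={target_type: chosen},
                           specificity_scores=scores)
    return MarkerPanel(target_type=target_type, on_markers=chosen,
                       specificity_scores=scores)
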