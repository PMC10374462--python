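"""Per-cell microglial contamination scores.

For a Patch-seq cell c of neuron type N and contaminant type M, the score is

    CS = (P − d_NM) / (d_MM − d_NM), clipped to [0, 1]

where P is the summed log2 CPM of the M off-marker panel in cell c, d_NM is
the median of that sum over dissociated reference cells of type N, and d_MM
the median over dissociated reference cells of type M. A score of 0 means no
excess contaminant-marker expression over clean reference cells of the same
type; 1 means marker expression at the level of dissociated contaminant cells.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd

from .errors import DegenerateReferenceError, InputError, ReferenceError_
from .normalize import DEFAULT_PSEUDOCOUNT, MarkerPanel, NormalizedMatrix, cpm_log2
from .simulate import MICROGLIA

log = logging.getLogger(__name__)


def summed_marker_expression(normed: NormalizedMatrix, panel: MarkerPanel,
                             contaminant: str = MICROGLIA) -> pd.Series:
    """Per-cell sum of normalized expression over the contaminant off markers.

    An empty panel yields 0 for every cell. Panel genes absent from the
    matrix are an error (no silent intersection).
    """
    genes = panel.off(contaminant) if panel.off_markers else []
    missing = [g for g in genes if g not in normed.genes]
    if missing:
        raise InputError(f"panel genes missing from matrix: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    if not genes:
        return pd.Series(0.0, index=normed.cells, name="P")
    return normed.values.loc[genes].sum(axis=0).rename("P")


def reference_medians(reference_normed: NormalizedMatrix, labels: pd.Series,
                      panel: MarkerPanel, neuron_type: str,
                      contaminant: str = MICROGLIA) -> tuple[float, float]:
    """Median summed marker expression in reference cells of ``neuron_type``
    (d_NM) and in reference contaminant cells (d_MM).

    Medians use the midpoint convention for even group sizes. d_MM must
    exceed d_NM for the score denominator to be positive.
    """
    sums = summed_marker_expression(reference_normed, panel, contaminant)
    labels = labels.loc[sums.index]
    for group in (neuron_type, contaminant):
        if (labels == group).sum() == 0:
            raise ReferenceError_(f"no reference cells of type {group!r}")
    d_nm = float(np.median(sums[labels == neuron_type]))
    d_mm = float(np.median(sums[labels == contaminant]))
    if d_mm <= d_nm:
        raise DegenerateReferenceError(
            f"reference contaminant median ({d_mm:.3f}) does not exceed the "
            f"{neuron_type!r} median ({d_nm:.3f}); score denominator "
            "would be non-positive")
    return d_nm, d_mm


def contamination_score(P, d_NM: float, d_MM: float):
    """The score formula; accepts scalars or arrays for P.

    Negative numerators (cell below its clean reference median) are set to 0;
    values above the contaminant reference median clip at 1.
    """
    if d_MM <= d_NM:
        raise DegenerateReferenceError(
            f"d_MM ({d_MM}) must exceed d_NM ({d_NM})")
    raw = (np.asarray(P, dtype=float) - d_NM) / (d_MM - d_NM)
    clipped = np.clip(raw, 0.0, 1.0)
    return float(clipped) if np.isscalar(P) else clipped


def score_dataset(patchseq: ad.AnnData, reference: ad.AnnData,
                  panel: MarkerPanel, contaminant: str = MICROGLIA,
                  cell_type_col: str = "cell_type",
                  pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Contamination table for every Patch-seq cell.

    Reference medians are computed once per neuron type from the dissociated
    reference only. Returns a frame with columns
    cell_id (index), cell_type, P, d_NM, d_MM, score.
    """
    ps_types = patchseq.obs[cell_type_col]
    ref_types = set(reference.obs[cell_type_col].unique())
    unknown = sorted(set(ps_types.unique()) - ref_types)
    if unknown:
        raise InputError(f"Patch-seq cell types absent from reference: {unknown}")

    ps_normed = cpm_log2(patchseq, pseudocount)
    ref_normed = cpm_log2(reference, pseudocount)
    P = summed_marker_expression(ps_normed, panel, contaminant)

    table = pd.DataFrame({"cell_type": ps_types.to_numpy(), "P": P},
                         index=P.index)
    table["d_NM"] = np.nan
    table["d_MM"] = np.nan
    table["score"] = np.nan
    for ntype in ps_types.unique():
        d_nm, d_mm = reference_medians(ref_normed, reference.obs[cell_type_col],
                                       panel, ntype, contaminant)
        rows = table["cell_type"] == ntype
        table.loc[rows, "d_NM"] = d_nm
        table.loc[rows, "d_MM"] = d_mm
        table.loc[rows, "score"] = contamination_score(
            table.loc[rows, "P"].to_numpy(), d_nm, d_mm)
    log.info("contamination scores: %.2f +/- %.2f (mean +/- SD, n=%d)",
             table["score"].mean(), table["score"].std(), len(table))
    return table
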