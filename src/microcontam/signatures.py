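"""Contamination-signature extraction.

High/low contamination groups are the top and bottom quartiles (deciles when
high contamination is rare) of cells ranked by score. Differential expression
between groups uses the two-sided Wilcoxon rank-sum test, with a gene passing
at |log2FC| > 2.5 and p < 0.01. Three signatures follow: the Patch-seq
contamination signature (up in high-contamination Patch-seq cells), the
general microglia signature (up in dissociated microglia vs neurons), and the
Patch-seq distinct signature (the set difference) — the genes that mark
contamination through the pipette but not dissociated microglia.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import InputError
from .normalize import DEFAULT_PSEUDOCOUNT, NormalizedMatrix, cpm_log2

log = logging.getLogger(__name__)

FC_THRESHOLD = 2.5
P_THRESHOLD = 0.01
EXACT_MAX_GROUP = 10  # exact rank-sum enumeration when both groups this small


# ---------------------------------------------------------------------------
# groups

def define_contamination_groups(scores: pd.Series,
                                scheme: str = "quartile") -> pd.Series:
    """Label cells high/low/excluded by score percentile.

    Quartile cuts at the empirical 25th/75th percentiles, decile at
    10th/90th; ties at a boundary go to the extreme group.
    """
    if scheme == "quartile":
        lo_q, hi_q, min_n = 25.0, 75.0, 8
    elif scheme == "decile":
        lo_q, hi_q, min_n = 10.0, 90.0, 20
    else:
        raise InputError(f"unknown scheme {scheme!r} (quartile|decile)")
    scores = pd.Series(scores)
    if len(scores) < min_n:
        raise InputError(f"{scheme} grouping needs >= {min_n} cells, "
                         f"got {len(scores)}")
    lo_cut, hi_cut = np.percentile(scores.to_numpy(), [lo_q, hi_q])
    if lo_cut == hi_cut:
        raise InputError("degenerate percentile cuts (scores nearly constant)")
    labels = pd.Series("excluded", index=scores.index, name="group")
    labels[scores <= lo_cut] = "low"
    labels[scores >= hi_cut] = "high"
    log.info("contamination groups (%s): %d high, %d low, %d excluded",
             scheme, (labels == "high").sum(), (labels == "low").sum(),
             (labels == "excluded").sum())
    return labels


# ---------------------------------------------------------------------------
# rank-sum machinery

def exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Wilcoxon rank-sum p by enumerating all label
    arrangements; midranks handle ties. Intended for small groups."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    mu = n1 * (n1 + n2 + 1) / 2.0  # mean rank sum of group 1
    obs = abs(ranks[:n1].sum() - mu)
    combos = np.fromiter(
        itertools.chain.from_iterable(
            itertools.combinations(range(n1 + n2), n1)),
        dtype=np.intp).reshape(-1, n1)
    sums = ranks[combos].sum(axis=1)
    return float(np.mean(np.abs(sums - mu) >= obs - 1e-9))


def ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p: exact enumeration when both groups are small,
    otherwise the tie-corrected normal approximation. Genes with identical
    values everywhere get p = 1 by convention."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise InputError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if len(x) <= EXACT_MAX_GROUP and len(y) <= EXACT_MAX_GROUP:
        return exact_ranksum_p(x, y)
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic").pvalue)


def _log2fc(cpm_high: np.ndarray, cpm_low: np.ndarray, pc: float) -> float:
    return float(np.log2((cpm_high.mean() + pc) / (cpm_low.mean() + pc)))


def differential_expression(normed: NormalizedMatrix, groups: pd.Series,
                            fc_threshold: float = FC_THRESHOLD,
                            p_threshold: float = P_THRESHOLD) -> pd.DataFrame:
    """Per-gene rank-sum DE between the high and low contamination groups.

    log2FC compares group means on the de-logged (CPM) scale with the
    normalization pseudocount re-added:
    ``log2((mean CPM_high + pc) / (mean CPM_low + pc))``.
    Returns a frame indexed by gene with columns log2fc, p, direction, pass.
    """
    groups = groups.loc[normed.cells]
    hi = normed.cells[(groups == "high").to_numpy()]
    lo = normed.cells[(groups == "low").to_numpy()]
    if len(hi) == 0 or len(lo) == 0:
        raise InputError("both high and low groups must be non-empty")
    vals_hi = normed.values[hi].to_numpy()
    vals_lo = normed.values[lo].to_numpy()
    pc = normed.pseudocount
    cpm_hi = 2.0 ** vals_hi - pc
    cpm_lo = 2.0 ** vals_lo - pc

    n_genes = len(normed.genes)
    pvals = np.empty(n_genes)
    lfc = np.empty(n_genes)
    for i in range(n_genes):
        pvals[i] = ranksum_p(vals_hi[i], vals_lo[i])
        lfc[i] = _log2fc(cpm_hi[i], cpm_lo[i], pc)
    out = pd.DataFrame({"log2fc": lfc, "p": pvals}, index=normed.genes)
    out["direction"] = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none"))
    out["pass"] = (np.abs(lfc) > fc_threshold) & (pvals < p_threshold)
    log.info("differential expression: %d/%d genes pass "
             "(|log2FC| > %g, p < %g)", int(out["pass"].sum()), n_genes,
             fc_threshold, p_threshold)
    return out


# ---------------------------------------------------------------------------
# signatures

@dataclass
class SignatureSet:
    """The three contamination signatures and their overlap."""

    patchseq_contamination: set[str]
    general_microglia: set[str]
    shared: set[str] = field(init=False)
    patchseq_distinct: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.shared = self.patchseq_contamination & self.general_microglia
        self.patchseq_distinct = self.patchseq_contamination - self.general_microglia

    def to_dict(self) -> dict[str, list[str]]:
        return {k: sorted(getattr(self, k)) for k in
                ("patchseq_contamination", "general_microglia", "shared",
                 "patchseq_distinct")}


def general_microglia_signature(reference: ad.AnnData, microglia_label: str,
                                neuron_labels: list[str] | set[str],
                                fc_threshold: float = FC_THRESHOLD,
                                p_threshold: float = P_THRESHOLD,
                                pseudocount: float = DEFAULT_PSEUDOCOUNT,
                                cell_type_col: str = "cell_type") -> set[str]:
    """Genes up-regulated in dissociated microglia vs pooled reference
    neurons, under the same DE machinery and thresholds."""
    labels = reference.obs[cell_type_col]
    neuron_labels = set(neuron_labels)
    keep = labels.isin(neuron_labels | {microglia_label})
    sub = reference[keep.to_numpy()]
    groups = pd.Series(
        np.where(sub.obs[cell_type_col] == microglia_label, "high", "low"),
        index=sub.obs_names)
    if (groups == "high").sum() == 0 or (groups == "low").sum() == 0:
        raise InputError("reference must contain both microglia and neurons")
    de = differential_expression(cpm_log2(sub, pseudocount), groups,
                                 fc_threshold, p_threshold)
    return set(de.index[(de["pass"]) & (de["direction"] == "up")])


def derive_signatures(patchseq_de: pd.DataFrame,
                      general: set[str]) -> SignatureSet:
    """Assemble the signature set from the Patch-seq DE table (up-regulated
    passing genes) and the general microglia gene set."""
    patchseq = set(patchseq_de.index[(patchseq_de["pass"])
                                     & (patchseq_de["direction"] == "up")])
    sig = SignatureSet(patchseq_contamination=patchseq, general_microglia=set(general))
    log.info("signatures: %d patch-seq, %d general, %d shared, %d distinct",
             len(sig.patchseq_contamination), len(sig.general_microglia),
             len(sig.shared), len(sig.patchseq_distinct))
    return sig


# ---------------------------------------------------------------------------
# clustering association

def cluster_contamination_association(normed: NormalizedMatrix,
                                      scores: pd.Series, n_hvg: int = 2000,
                                      n_components: int = 20, k: int = 4,
                                      seed: int = 0) -> dict:
    """Do unsupervised expression clusters align with contamination?

    Top-``n_hvg`` genes by variance are z-scaled, reduced by PCA and
    clustered with seeded k-means; the report carries the one-way R² of
    contamination score on cluster labels and per-cluster mean scores.
    """
    if n_hvg > len(normed.genes):
        raise InputError(f"n_hvg={n_hvg} exceeds gene count {len(normed.genes)}")
    if k < 2:
        raise InputError("need at least 2 clusters")
    scores = pd.Series(scores).loc[normed.cells]
    variances = normed.values.var(axis=1)
    hvg = variances.sort_values(ascending=False, kind="stable").index[:n_hvg]
    mat = normed.values.loc[hvg].to_numpy()  # hvg x cells
    sd = mat.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    z = ((mat - mat.mean(axis=1, keepdims=True)) / sd[:, None]).T  # cells x hvg
    n_components = min(n_components, z.shape[0] - 1, z.shape[1])
    pcs = PCA(n_components=n_components, random_state=seed).fit_transform(z)
    labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(pcs)

    s = scores.to_numpy()
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    ss_within = float(sum(np.sum((s[labels == c] - s[labels == c].mean()) ** 2)
                          for c in np.unique(labels)))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_within / ss_tot
    cluster_means = {int(c): float(s[labels == c].mean())
                     for c in np.unique(labels)}
    return {"r2": r2, "cluster_means": cluster_means,
            "labels": pd.Series(labels, index=normed.cells, name="cluster"),
            "n_hvg": int(n_hvg), "k": int(k)}
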