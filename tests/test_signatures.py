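"""Contamination groups, rank-sum DE, signature set algebra, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from microcontam import normalize, signatures
from microcontam import simulate as sim
from microcontam.errors import InputError
from microcontam.normalize import NormalizedMatrix


class TestGroups:
    def test_quartile_order_statistics(self):
        s = pd.Series(range(1, 9), index=[f"c{i}" for i in range(8)])
        labels = signatures.define_contamination_groups(s, "quartile")
        assert set(s[labels == "low"]) == {1, 2}
        assert set(s[labels == "high"]) == {7, 8}

    def test_decile_order_statistics(self):
        s = pd.Series(range(1, 21))
        labels = signatures.define_contamination_groups(s, "decile")
        assert set(s[labels == "low"]) == {1, 2}
        assert set(s[labels == "high"]) == {19, 20}

    def test_boundary_ties_go_to_extreme_group(self):
        s = pd.Series([1, 2, 2, 3, 4, 5, 6, 7])  # 25th pct = 2
        labels = signatures.define_contamination_groups(s, "quartile")
        assert (labels[s <= 2] == "low").all()

    def test_degenerate_and_small_inputs_rejected(self):
        with pytest.raises(InputError, match="degenerate"):
            signatures.define_contamination_groups(pd.Series([1.0] * 10),
                                                   "quartile")
        with pytest.raises(InputError, match=">= 8"):
            signatures.define_contamination_groups(pd.Series([1, 2, 3]),
                                                   "quartile")


def _enumerated_two_sided_p(x, y):
    """Independent brute-force oracle: enumerate every label arrangement."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    mu = n1 * (len(pooled) + 1) / 2
    obs = abs(ranks[:n1].sum() - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestRankSum:
    def test_hand_example(self):
        assert signatures.exact_ranksum_p([1, 2], [3, 4]) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, rng.integers(3, 7)).astype(float)
        y = rng.integers(0, 4, rng.integers(3, 7)).astype(float)
        assert signatures.exact_ranksum_p(x, y) == pytest.approx(
            _enumerated_two_sided_p(x, y))

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=6), rng.normal(size=6)
        ours = signatures.exact_ranksum_p(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact").pvalue
        assert ours == pytest.approx(ref)

    def test_normal_approximation_close_to_exact_at_n30(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.0, 1.0, 30)
        y = rng.normal(0.5, 1.0, 30)
        approx = signatures.ranksum_p(x, y)  # asymptotic path at this size
        exact = stats.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact").pvalue
        assert abs(approx - exact) < 0.02

    def test_constant_gene_p_is_one(self):
        assert signatures.ranksum_p([1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0


def _normed_from(values, genes, cells, pc=1.0):
    return NormalizedMatrix(pd.DataFrame(values, index=genes, columns=cells),
                            pseudocount=pc)


class TestDifferentialExpression:
    def _groups(self, n_hi, n_lo):
        cells = [f"h{i}" for i in range(n_hi)] + [f"l{i}" for i in range(n_lo)]
        return cells, pd.Series(["high"] * n_hi + ["low"] * n_lo, index=cells)

    def test_identical_groups_give_zero_lfc_no_pass(self):
        cells, groups = self._groups(3, 3)
        normed = _normed_from(np.tile([[2.0]], (1, 6)), ["g"], cells)
        de = signatures.differential_expression(normed, groups)
        assert de.loc["g", "log2fc"] == 0.0
        assert not de.loc["g", "pass"]
        assert de.loc["g", "p"] == 1.0

    def test_label_swap_negates_lfc(self):
        rng = np.random.default_rng(3)
        cells, groups = self._groups(5, 5)
        normed = _normed_from(rng.uniform(0, 8, (4, 10)),
                              [f"g{i}" for i in range(4)], cells)
        de = signatures.differential_expression(normed, groups)
        swapped = groups.map({"high": "low", "low": "high"})
        de2 = signatures.differential_expression(normed, swapped)
        np.testing.assert_allclose(de["log2fc"], -de2["log2fc"], atol=1e-12)

    def test_recovers_contamination_genes_on_synthetic_run(self, default_run):
        normed = normalize.cpm_log2(default_run["patchseq_f"])
        groups = signatures.define_contamination_groups(
            default_run["scores"]["score"], "quartile")
        de = signatures.differential_expression(normed, groups)
        up = set(de.index[(de["pass"]) & (de["direction"] == "up")])
        cat = default_run["catalog"]
        targets = (set(cat.genes_of_class("microglia_marker"))
                   | set(cat.genes_of_class("activated_program")))
        recall = len(up & targets) / len(targets)
        assert recall >= 0.8

    def test_empty_group_rejected(self):
        cells, groups = self._groups(3, 3)
        normed = _normed_from(np.ones((1, 6)), ["g"], cells)
        with pytest.raises(InputError):
            signatures.differential_expression(
                normed, pd.Series("low", index=cells))


class TestSignatureSets:
    def test_set_algebra_example(self):
        de = pd.DataFrame({"log2fc": [3.0, 3.0, 3.0], "p": [0.001] * 3,
                           "direction": ["up"] * 3, "pass": [True] * 3},
                          index=["a", "b", "c"])
        sig = signatures.derive_signatures(de, {"b", "c", "d"})
        assert sig.shared == {"b", "c"}
        assert sig.patchseq_distinct == {"a"}

    def test_disjoint_inputs(self):
        de = pd.DataFrame({"log2fc": [3.0], "p": [0.001], "direction": ["up"],
                           "pass": [True]}, index=["a"])
        sig = signatures.derive_signatures(de, {"x"})
        assert sig.patchseq_distinct == {"a"}

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.sets(st.text("abcdefg", min_size=1, max_size=2)),
           st.sets(st.text("abcdefg", min_size=1, max_size=2)))
    def test_partition_invariant(self, patchseq, general):
        sig = signatures.SignatureSet(patchseq_contamination=patchseq,
                                      general_microglia=general)
        assert sig.shared | sig.patchseq_distinct == sig.patchseq_contamination
        assert sig.shared & sig.patchseq_distinct == set()

    def test_activated_program_never_in_general_signature(
            self, small_reference, small_catalog, small_config):
        general = signatures.general_microglia_signature(
            small_reference, sim.MICROGLIA, small_config.neuron_types)
        act = set(small_catalog.genes_of_class("activated_program"))
        assert general & act == set()
        markers = set(small_catalog.genes_of_class("microglia_marker"))
        assert len(general & markers) / len(markers) >= 0.9


class TestClusterAssociation:
    def _mixture_dataset(self, catalog, config, f_values, seed):
        rng = np.random.default_rng(seed)
        profiles = np.column_stack([
            sim.expected_patchseq_profile(catalog, config, "Ntype1", f)
            for f in f_values])
        counts = rng.poisson(profiles * (2e4 / profiles.sum(axis=0)))
        import anndata as ad
        data = ad.AnnData(X=counts.T.astype(np.int64),
                          obs=pd.DataFrame(index=[f"c{i}" for i in
                                                  range(len(f_values))]),
                          var=pd.DataFrame(index=catalog.base_mean.index))
        return normalize.cpm_log2(data)

    def test_bimodal_contamination_drives_clusters(self, small_catalog,
                                                   small_config):
        f = np.array([0.0] * 40 + [0.8] * 40)
        normed = self._mixture_dataset(small_catalog, small_config, f, seed=5)
        scores = pd.Series(f, index=normed.cells)
        report = signatures.cluster_contamination_association(
            normed, scores, n_hvg=200, seed=0)
        assert report["r2"] >= 0.5

    def test_null_scores_unexplained_by_clusters(self, small_catalog,
                                                 small_config):
        f = np.zeros(300)
        normed = self._mixture_dataset(small_catalog, small_config, f, seed=6)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores = pd.Series(rng.normal(size=300), index=normed.cells)
            report = signatures.cluster_contamination_association(
                normed, scores, n_hvg=200, seed=seed)
            assert report["r2"] < 0.05

    def test_seeded_determinism(self, small_catalog, small_config):
        f = np.linspace(0, 1, 60)
        normed = self._mixture_dataset(small_catalog, small_config, f, seed=7)
        scores = pd.Series(f, index=normed.cells)
        a = signatures.cluster_contamination_association(normed, scores,
                                                         n_hvg=100, seed=3)
        b = signatures.cluster_contamination_association(normed, scores,
                                                         n_hvg=100, seed=3)
        assert (a["labels"] == b["labels"]).all()

    def test_oversized_hvg_rejected(self, small_catalog, small_config):
        normed = self._mixture_dataset(small_catalog, small_config,
                                       np.zeros(10), seed=8)
        with pytest.raises(InputError):
            signatures.cluster_contamination_association(
                normed, pd.Series(np.zeros(10), index=normed.cells),
                n_hvg=10**6)
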