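"""Synthetic Patch-seq data generator with known contamination ground truth.

The generator emulates the statistical structure that the downstream analyses
assume: a dissociated-cell reference with cell-type-specific negative-binomial
expression profiles (neuron subtypes, microglia, astrocytes), Patch-seq cells
as convex mixtures of a neuronal profile and an *activated* microglial profile,
a logit-linear model for the per-cell contamination fraction (donor and
cell-type random effects plus break-in-time and soma-depth covariates), and
electrophysiology features linearly shifted by contamination with donor and
cell-type random intercepts.

The mixture acts at the mean level: the expected expression of a Patch-seq
cell is ``(1 - f) * lambda_neuron + f * lambda_microglia_activated``, where
``f`` is the cell's true contamination fraction. The activated microglial
profile equals the dissociated microglial profile plus an activation gene
program that is absent from every reference cell type — mimicking transcripts
picked up through the patch pipette from activated microglial processes that
a dissociated reference never shows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError

MICROGLIA = "Microglia"
ASTROCYTE = "Astrocyte"

#: gene classes used in the catalog
GENE_CLASSES = (
    "neuron_marker",
    "microglia_marker",
    "astrocyte_marker",
    "activated_program",
    "housekeeping",
    "mitochondrial",
)


@dataclass(frozen=True)
class EphysFeatureSpec:
    """One simulated electrophysiology feature.

    ``gamma`` is the contamination effect on the standardized scale of the
    (possibly log10-transformed) feature: the latent feature is built with
    total variance close to 1, scaled by ``scale`` and shifted by ``baseline``
    so that downstream standardization recovers ``gamma`` per unit
    contamination fraction. ``transform == "log10"`` features are emitted as
    ``10**latent`` so the pipeline's log10 step recovers linearity.
    """

    name: str
    baseline: float
    gamma: float
    donor_sd: float = 0.3
    celltype_sd: float = 0.2
    residual_sd: float = 0.9
    scale: float = 1.0
    transform: str = "none"  # "none" | "log10"


def default_ephys_features() -> list[EphysFeatureSpec]:
    """Feature panel with effect sizes in the range reported for real data:
    contamination lowers input resistance and depolarizes AP trough and
    resting potential; the half-width feature carries a null effect."""
    return [
        EphysFeatureSpec("input_resistance", baseline=np.log10(150.0), gamma=-0.68,
                         scale=0.25, transform="log10"),
        EphysFeatureSpec("rheobase", baseline=np.log10(80.0), gamma=0.30,
                         scale=0.20, transform="log10"),
        EphysFeatureSpec("ap_trough", baseline=-45.0, gamma=0.65, scale=4.0),
        EphysFeatureSpec("resting_potential", baseline=-70.0, gamma=0.24, scale=3.0),
        EphysFeatureSpec("ap_halfwidth", baseline=np.log10(1.2), gamma=0.0,
                         scale=0.10, transform="log10"),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults describe a human-like Patch-seq cohort: 50 donors contributing 20
    pyramidal-like cells each across 5 transcriptomic types, with donor
    identity the dominant source of contamination variability and negative
    break-in-time and soma-depth effects on the logit contamination fraction.
    The field's conventional marker panel size (50 per cell type) is kept. All
    distributional choices are stand-ins: the real datasets are observational
    and define no generative model.
    """

    n_genes: int = 1000
    n_neuron_types: int = 5
    n_donors: int = 50
    cells_per_donor: int = 20
    reference_cells_per_type: int = 100
    markers_per_type: int = 50
    nb_dispersion: float = 0.3
    library_size_mean: int = 20000
    library_size_sigma: float = 0.3
    # logit-linear contamination model
    contamination_logit_intercept: float = 0.5
    donor_sd: float = 1.0
    celltype_sd: float = 0.3
    beta_breakin: float = -0.15   # per hour
    beta_depth: float = -0.0015   # per micrometer
    logit_noise_sd: float = 0.5
    # activated microglia program
    activated_program_size: int = 40
    activated_log2fc: float = 5.0
    n_mito_genes: int = 13
    ephys_features: list[EphysFeatureSpec] = field(default_factory=default_ephys_features)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_neuron_types": self.n_neuron_types,
            "n_donors": self.n_donors,
            "cells_per_donor": self.cells_per_donor,
            "reference_cells_per_type": self.reference_cells_per_type,
            "markers_per_type": self.markers_per_type,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigError(f"{name} must be >= 1, got {value}")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        for name in ("donor_sd", "celltype_sd", "logit_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        demand = (self.markers_per_type * (self.n_neuron_types + 2)
                  + self.activated_program_size + self.n_mito_genes)
        if demand > self.n_genes:
            raise ConfigError(
                f"gene demand {demand} (markers, activated program, mitochondrial) "
                f"exceeds n_genes={self.n_genes}")
        for feat in self.ephys_features:
            if feat.transform not in ("none", "log10"):
                raise ConfigError(
                    f"unknown transform tag {feat.transform!r} for feature {feat.name}")

    @property
    def neuron_types(self) -> list[str]:
        return [f"Ntype{k + 1}" for k in range(self.n_neuron_types)]

    @property
    def reference_types(self) -> list[str]:
        return self.neuron_types + [MICROGLIA, ASTROCYTE]

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        d = {k: plain(v) for k, v in dataclasses.asdict(self).items()
             if k != "ephys_features"}
        d["ephys_features"] = [
            {k: plain(v) for k, v in dataclasses.asdict(f).items()}
            for f in self.ephys_features]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        feats = d.pop("ephys_features", None)
        cfg = cls(**d) if feats is None else cls(
            ephys_features=[EphysFeatureSpec(**f) for f in feats], **d)
        return cfg


@dataclass
class GeneCatalog:
    """Gene identities, classes and expected counts per reference cell type.

    ``base_mean`` is a genes x cell-types frame of expected counts before
    library-size scaling. Marker genes are specific by construction: a
    microglia marker's base mean in microglia is >= 8x its maximum across
    neuron types.
    """

    gene_meta: pd.DataFrame       # index gene_id; columns: gene_class, mito (bool)
    base_mean: pd.DataFrame       # index gene_id; columns: cell types

    @property
    def gene_ids(self) -> pd.Index:
        return self.gene_meta.index

    def genes_of_class(self, gene_class: str) -> list[str]:
        return list(self.gene_meta.index[self.gene_meta["gene_class"] == gene_class])


@dataclass
class GroundTruth:
    """Simulation record used as the oracle for parameter recovery."""

    f_true: pd.Series                 # per Patch-seq cell, in [0, 1]
    donor_effects: pd.Series          # logit-scale random intercepts
    celltype_effects: pd.Series
    activated_genes: list[str]
    ephys_gamma: dict[str, float]     # standardized effect per feature

    def to_dict(self) -> dict:
        return {
            "f_true": self.f_true.to_dict(),
            "donor_effects": self.donor_effects.to_dict(),
            "celltype_effects": self.celltype_effects.to_dict(),
            "activated_genes": list(self.activated_genes),
            "ephys_gamma": dict(self.ephys_gamma),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        f_true = pd.Series(d["f_true"], name="f_true")
        f_true.index.name = "cell_id"
        return cls(
            f_true=f_true,
            donor_effects=pd.Series(d["donor_effects"]),
            celltype_effects=pd.Series(d["celltype_effects"]),
            activated_genes=list(d["activated_genes"]),
            ephys_gamma=dict(d["ephys_gamma"]),
        )


# ---------------------------------------------------------------------------
# catalog

MARKER_MEAN = 40.0       # expected counts of a marker in its own type
OFF_TARGET_MEAN = 1.0    # marker leakage into other types (40/1 >= 8x specificity)
HOUSEKEEPING_MEAN = 5.0
MITO_MEAN = 50.0


def build_gene_catalog(config: SimulationConfig) -> GeneCatalog:
    """Lay out gene classes and per-cell-type expected counts.

    Deterministic given the config: genes are assigned to classes in a fixed
    order (neuron markers per type, microglia markers, astrocyte markers,
    activation program, mitochondrial, housekeeping remainder).
    """
    types = config.reference_types
    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    gene_class = np.full(n, "housekeeping", dtype=object)
    marker_of = np.full(n, "", dtype=object)

    pos = 0
    for t in config.neuron_types:
        gene_class[pos:pos + config.markers_per_type] = "neuron_marker"
        marker_of[pos:pos + config.markers_per_type] = t
        pos += config.markers_per_type
    gene_class[pos:pos + config.markers_per_type] = "microglia_marker"
    marker_of[pos:pos + config.markers_per_type] = MICROGLIA
    pos += config.markers_per_type
    gene_class[pos:pos + config.markers_per_type] = "astrocyte_marker"
    marker_of[pos:pos + config.markers_per_type] = ASTROCYTE
    pos += config.markers_per_type
    gene_class[pos:pos + config.activated_program_size] = "activated_program"
    pos += config.activated_program_size
    gene_class[pos:pos + config.n_mito_genes] = "mitochondrial"
    pos += config.n_mito_genes

    base = pd.DataFrame(0.0, index=pd.Index(gene_ids, name="gene_id"), columns=types)
    for j, t in enumerate(types):
        col = np.full(n, 0.0)
        is_marker = np.isin(gene_class, ["neuron_marker", "microglia_marker",
                                         "astrocyte_marker"])
        col[is_marker] = OFF_TARGET_MEAN
        col[(marker_of == t)] = MARKER_MEAN
        col[gene_class == "housekeeping"] = HOUSEKEEPING_MEAN
        col[gene_class == "mitochondrial"] = MITO_MEAN
        # activated_program stays at 0 in every reference type
        base[t] = col

    gene_meta = pd.DataFrame(
        {"gene_class": gene_class, "marker_of": marker_of,
         "mito": gene_class == "mitochondrial"},
        index=base.index)
    return GeneCatalog(gene_meta=gene_meta, base_mean=base)


# ---------------------------------------------------------------------------
# count sampling

def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2 (Poisson as
    dispersion -> 0)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion < 1e-9:
        out[pos] = rng.poisson(mean[pos])
        return out
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean[pos])
    out[pos] = rng.poisson(lam)
    return out


def _size_factors(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    # lognormal with mean exactly 1 so CPM normalization has something to undo
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=n)


def _sample_cells(rng: np.random.Generator, profiles: np.ndarray,
                  config: SimulationConfig) -> np.ndarray:
    """Draw NB counts for cells whose expected profiles are the columns of
    ``profiles`` (genes x cells), after per-cell library-size scaling."""
    n_cells = profiles.shape[1]
    totals = profiles.sum(axis=0)
    totals[totals == 0] = 1.0
    sf = _size_factors(rng, n_cells, config.library_size_sigma)
    scale = config.library_size_mean / totals * sf
    counts = np.empty(profiles.shape, dtype=np.int64)
    for c in range(n_cells):
        counts[:, c] = _nb_counts(rng, profiles[:, c] * scale[c],
                                  config.nb_dispersion)
    return counts


def simulate_reference(catalog: GeneCatalog, config: SimulationConfig,
                       seed: int | None = None) -> ad.AnnData:
    """Dissociated-cell reference: pure cells of each type, NB counts."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    types = config.reference_types
    n_per = config.reference_cells_per_type
    labels = np.repeat(types, n_per)
    profiles = catalog.base_mean[labels].to_numpy()
    counts = _sample_cells(rng, profiles, config)
    cell_ids = [f"ref_{t}_{i}" for t in types for i in range(n_per)]
    obs = pd.DataFrame({"cell_type": labels},
                       index=pd.Index(cell_ids, name="cell_id"))
    return ad.AnnData(X=counts.T.astype(np.int64), obs=obs,
                      var=catalog.gene_meta.copy())


def _activated_profile(catalog: GeneCatalog, config: SimulationConfig) -> np.ndarray:
    """Microglial profile as sampled through the pipette: the dissociated
    profile plus the activation program at ``2**activated_log2fc`` expected
    counts (the program is zero in every reference type)."""
    lam = catalog.base_mean[MICROGLIA].to_numpy().copy()
    act = (catalog.gene_meta["gene_class"] == "activated_program").to_numpy()
    lam[act] = 2.0 ** config.activated_log2fc
    return lam


def simulate_patchseq(catalog: GeneCatalog, config: SimulationConfig,
                      seed: int | None = None) -> tuple[ad.AnnData, GroundTruth]:
    """Patch-seq cohort: neuron/microglia mixtures with logit-linear
    contamination fractions and full per-cell metadata."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_cells = config.n_donors * config.cells_per_donor
    donors = [f"donor{d + 1:03d}" for d in range(config.n_donors)]
    donor_of = np.repeat(donors, config.cells_per_donor)

    u = pd.Series(rng.normal(0.0, config.donor_sd, config.n_donors), index=donors)
    v = pd.Series(rng.normal(0.0, config.celltype_sd, config.n_neuron_types),
                  index=config.neuron_types)
    cell_type = rng.choice(config.neuron_types, size=n_cells)

    # recording times: cells within a donor recorded sequentially; first = 0 h
    breakin = np.empty(n_cells)
    for d in donors:
        idx = np.where(donor_of == d)[0]
        gaps = rng.exponential(scale=0.75, size=len(idx))
        times = np.concatenate([[0.0], np.cumsum(gaps[:-1])])
        breakin[idx] = times
    depth = rng.uniform(100.0, 1000.0, n_cells)
    seal = rng.lognormal(np.log(3.0), 0.4, n_cells)

    lp = (config.contamination_logit_intercept
          + u.loc[donor_of].to_numpy()
          + v.loc[cell_type].to_numpy()
          + config.beta_breakin * breakin
          + config.beta_depth * depth
          + rng.normal(0.0, config.logit_noise_sd, n_cells))
    f = expit(lp)

    lam_micro = _activated_profile(catalog, config)
    lam_neuron = catalog.base_mean[cell_type].to_numpy()
    profiles = (1.0 - f) * lam_neuron + f * lam_micro[:, None]
    counts = _sample_cells(rng, profiles, config)

    # donor-level covariates; histology tracks the donor effect so that the
    # binned IBA1/GFAP association the analyses test for exists in truth
    donor_sex = pd.Series(rng.choice(["M", "F"], config.n_donors), index=donors)
    donor_age = pd.Series(rng.uniform(20.0, 60.0, config.n_donors), index=donors)
    donor_cond = pd.Series(rng.choice(["epilepsy", "tumor"], config.n_donors),
                           index=donors)
    iba1 = pd.Series(np.clip(rng.normal(1.0 + 0.6 * u / max(config.donor_sd, 1e-9),
                                        0.5), 0.0, 3.0), index=donors)
    gfap = pd.Series(np.clip(rng.normal(1.0 + 0.3 * u / max(config.donor_sd, 1e-9),
                                        0.5), 0.0, 3.0), index=donors)

    cell_ids = [f"ps_{i:05d}" for i in range(n_cells)]
    obs = pd.DataFrame({
        "donor_id": donor_of,
        "cell_type": cell_type,
        "break_in_time": breakin,
        "soma_depth": depth,
        "seal_resistance": seal,
        "sex": donor_sex.loc[donor_of].to_numpy(),
        "age": donor_age.loc[donor_of].to_numpy(),
        "condition": donor_cond.loc[donor_of].to_numpy(),
        "iba1_score": iba1.loc[donor_of].to_numpy(),
        "gfap_score": gfap.loc[donor_of].to_numpy(),
    }, index=pd.Index(cell_ids, name="cell_id"))

    adata = ad.AnnData(X=counts.T.astype(np.int64), obs=obs,
                       var=catalog.gene_meta.copy())
    truth = GroundTruth(
        f_true=pd.Series(f, index=obs.index, name="f_true"),
        donor_effects=u,
        celltype_effects=v,
        activated_genes=catalog.genes_of_class("activated_program"),
        ephys_gamma={feat.name: feat.gamma for feat in config.ephys_features},
    )
    return adata, truth


def expected_patchseq_profile(catalog: GeneCatalog, config: SimulationConfig,
                              cell_type: str, f: float) -> pd.Series:
    """Noiseless expected profile of a Patch-seq cell — the analytic oracle
    for mixture monotonicity checks."""
    lam_neuron = catalog.base_mean[cell_type]
    lam_micro = pd.Series(_activated_profile(catalog, config),
                          index=catalog.base_mean.index)
    return (1.0 - f) * lam_neuron + f * lam_micro


def simulate_ephys(truth: GroundTruth, cell_meta: pd.DataFrame,
                   config: SimulationConfig,
                   seed: int | None = None) -> pd.DataFrame:
    """Per-cell electrophysiology features shifted by true contamination.

    Each feature's latent value is
    ``baseline + scale * (gamma * f + donor + celltype + noise)`` with the
    bracket built to have variance near 1, so the configured ``gamma`` is the
    effect on the standardized scale the downstream models estimate.
    log10-tagged features are exponentiated (``10**latent``).
    """
    if not truth.f_true.index.isin(cell_meta.index).all() or \
            not cell_meta.index.isin(truth.f_true.index).all():
        raise ConfigError("ground truth does not cover the metadata cells")
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    donors = cell_meta["donor_id"].unique()
    types = cell_meta["cell_type"].unique()
    f = truth.f_true.loc[cell_meta.index].to_numpy()
    out = {}
    for feat in config.ephys_features:
        if feat.transform not in ("none", "log10"):
            raise ConfigError(f"unknown transform tag {feat.transform!r}")
        du = pd.Series(rng.normal(0.0, feat.donor_sd, len(donors)), index=donors)
        tv = pd.Series(rng.normal(0.0, feat.celltype_sd, len(types)), index=types)
        latent = (feat.gamma * f
                  + du.loc[cell_meta["donor_id"]].to_numpy()
                  + tv.loc[cell_meta["cell_type"]].to_numpy()
                  + rng.normal(0.0, feat.residual_sd, len(f)))
        latent = feat.baseline + feat.scale * latent
        out[feat.name] = 10.0 ** latent if feat.transform == "log10" else latent
    return pd.DataFrame(out, index=cell_meta.index)


def ephys_transforms(config: SimulationConfig) -> dict[str, str]:
    """Transform-tag manifest for the configured feature panel."""
    return {feat.name: feat.transform for feat in config.ephys_features}
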