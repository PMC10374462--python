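# microcontam

Patch-seq records a neuron's electrophysiology and then aspirates its
cytoplasm and nucleus through the same pipette for single-cell RNA-seq. On
the way out, the pipette also collects mRNA from the fine processes of
surrounding microglia, so many Patch-seq "neuronal" transcriptomes carry a
microglial contamination signal that can confound both transcriptomic and
transcriptome–physiology analyses. `microcontam` is an analysis pipeline for
quantifying that contamination and modeling its correlates:

1. **Contamination scoring.** For a Patch-seq cell *c* of neuron type *N*,
   with *P* the summed log2 CPM of a panel of microglia-specific "off"
   markers (default 50 genes), and *d<sub>N,M</sub>*, *d<sub>M,M</sub>* the
   medians of that sum over dissociated reference cells of type *N* and over
   dissociated microglia:

   CS = (P − d<sub>N,M</sub>) / (d<sub>M,M</sub> − d<sub>N,M</sub>),
   clipped to [0, 1].

   0 means no excess microglial expression over clean reference cells of the
   same type; 1 means microglial marker expression at the level of
   dissociated microglia.
2. **Signature extraction.** Rank-sum differential expression between the
   top and bottom score quartiles (pass at |log2FC| > 2.5, p < 0.01) defines
   the *Patch-seq contamination signature*; the same machinery applied
   microglia-vs-neurons in the dissociated reference defines the *general
   microglia signature*; their set difference is the *Patch-seq distinct*
   signature — transcripts that mark contamination through the pipette but
   not dissociated microglia (an activated-microglia program).
3. **Enrichment.** Upper-tail hypergeometric over-representation of any
   signature in user-supplied (GMT) gene sets, with Benjamini–Hochberg FDR.
4. **Variance partitioning.** A REML linear mixed model
   `score ~ sex + condition + scale(age) + scale(break-in time) +
   scale(seal resistance) + scale(soma depth) + t-type + histology bins +
   (1 | donor)` decomposed by Nakagawa marginal/conditional R²: each fixed
   factor's share is the marginal-R² drop when it is replaced by a random
   intercept; the donor share is conditional minus marginal R².
5. **Ephys association.** Per feature,
   `feature ~ score + scale(soma depth) + (1 | t-type) + (1 | donor)` on
   log10-scaled (where skewed), standardized features, with the score left
   unstandardized so betas are feature-SDs per unit score.

Because the underlying cohorts are controlled-access or large downloads, the
package ships a first-class synthetic-data generator
(`microcontam.simulate`) that emulates the statistical structure these
analyses assume — negative-binomial cell-type profiles, Patch-seq cells as
neuron/microglia mixtures with a logit-linear contamination fraction (donor
and cell-type random effects, break-in-time and depth covariates), an
activation gene program present only in the contaminating source, and ephys
features linearly shifted by contamination — together with the ground truth
needed to verify every stage by parameter recovery.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (1000 Patch-seq cells, 50 donors, 5 neuron types), writing
tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_score.py
python analysis/03_signatures_enrichment.py
python analysis/04_variance_partition.py
python analysis/05_ephys_association.py
```

Output from a run (seed 0):

```
contamination score: 0.59 +/- 0.20 (mean +/- SD, n=1000)
Spearman correlation with true contamination fraction: 0.992

patch-seq contamination signature: 90 genes
general microglia signature: 50 genes
shared: 50; patch-seq distinct: 40
top enrichment for the distinct signature: class:activated_program (overlap 40/40, q = 1.53e-71)

full model: marginal R² = 63.5%, conditional R² = 84.3%

contamination effects (beta per unit score, feature-SD units):
  input_resistance   beta = -0.54 [-0.93, -0.15]* (true gamma -0.68)
  ap_trough          beta = +0.79 [+0.41, +1.17]* (true gamma +0.65)
```

The score rank-tracks the simulated contamination fraction almost perfectly;
the distinct signature recovers the full activated-microglia program and
nothing else; and the mixed models recover the configured ephys effect
directions and magnitudes (contamination lowers input resistance and
depolarizes the AP trough), with 95% CIs covering the truth.

The same steps are available as a CLI (`microcontam simulate|score|
signatures|enrich|varpart|ephys-assoc|run`) for use on any dataset in the
supported plain-text formats (MTX/CSV counts, TSV metadata, JSON panels,
GMT gene sets).

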