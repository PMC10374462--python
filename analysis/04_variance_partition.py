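#!/usr/bin/env python
"""Partition contamination-score variance across donors and covariates.

Fits the REML mixed model score ~ sex + condition + scale(age) +
scale(break-in time) + scale(seal resistance) + scale(soma depth) + t-type +
histology bins + (1 | donor), then decomposes variance explained: each fixed
factor's share is the marginal-R² drop when it is replaced by a random
intercept; the donor share is conditional minus marginal R².
"""

from pathlib import Path

from microcontam import io, varpart

SEED = 0
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    patchseq_meta = io.read_table(ROOT / "data/patchseq/cell_meta.tsv")
    scores = io.read_table(ROOT / "scores.tsv")["score"]
    meta = patchseq_meta.join(scores)

    frame = varpart.prepare_covariates(meta, response="score",
                                       min_cells_per_type=20)
    spec = varpart.LmmSpec(response="score",
                           fixed=[*frame.categorical, *frame.continuous],
                           random=[frame.group])
    part = varpart.partition_variance(spec, frame)
    io.write_table(part.to_frame(), ROOT / "variance_partition.tsv",
                   seed=SEED, index=False)

    print(f"full model: marginal R² = {part.r2_marginal:.1%}, "
          f"conditional R² = {part.r2_conditional:.1%}")
    print("variance shares (largest first):")
    for _, row in part.to_frame().iterrows():
        print(f"  {row['factor']:<18} {row['r2_share']:.1%}")


if __name__ == "__main__":
    main()
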