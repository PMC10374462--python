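"""Contamination–electrophysiology association.

Skewed features (input resistance, rheobase, AP half-width) are log10-scaled
and every feature is standardized before modeling; the contamination score is
deliberately left unstandardized so effect sizes are per unit score. Each
feature is modeled independently as

    feature ~ contamination score [+ scale(soma depth)]
              + (1 | t-type) + (1 | donor)

and the table of contamination betas with 95% CIs is the main output.
Univariate statistics (Pearson, Kruskal–Wallis, rank-sum) accompany it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, InputError
from .signatures import ranksum_p
from .varpart import LmmSpec, ModelFrame, fit_lmm

log = logging.getLogger(__name__)


def prepare_ephys(ephys: pd.DataFrame,
                  transforms: dict[str, str] | None = None) -> pd.DataFrame:
    """log10-transform tagged features, then z-scale every feature.

    ``transforms`` maps feature name to "log10" or "none"; untagged features
    are left untransformed. Standardization uses the sample SD (n−1).
    Applying the function again (without tags) is a no-op up to rounding.
    """
    transforms = transforms or {}
    out = ephys.copy().astype(float)
    for name, tag in transforms.items():
        if name not in out.columns:
            raise InputError(f"transform tag for unknown feature {name!r}")
        if tag == "none":
            continue
        if tag != "log10":
            raise InputError(f"unknown transform tag {tag!r} for {name!r}")
        col = out[name]
        bad = col[col <= 0]
        if len(bad):
            raise InputError(
                f"feature {name!r} has non-positive values under log10 tag "
                f"(e.g. cell {bad.index[0]!r}: {bad.iloc[0]})")
        out[name] = np.log10(col)
    for name in out.columns:
        sd = out[name].std(ddof=1)
        if sd == 0 or np.isnan(sd):
            raise InputError(f"feature {name!r} is constant; cannot standardize")
        out[name] = (out[name] - out[name].mean()) / sd
    return out


def ephys_contamination_model(ephys_std: pd.DataFrame, scores: pd.Series,
                              meta: pd.DataFrame,
                              include_depth: bool = True,
                              depth_col: str = "soma_depth",
                              donor_col: str = "donor_id",
                              ttype_col: str = "cell_type") -> pd.DataFrame:
    """Mixed-model contamination effect per electrophysiology feature.

    Returns one row per feature: beta (per unit contamination score, in
    feature-SD units), SE, normal-approximation 95% CI and p value, cell
    count and convergence flag.
    """
    cells = ephys_std.index.intersection(scores.index).intersection(meta.index)
    if len(cells) == 0:
        raise InputError("no cells shared between ephys, scores and metadata")
    meta = meta.loc[cells]
    for col, what in ((donor_col, "donors"), (ttype_col, "t-types")):
        if meta[col].nunique() < 2:
            raise InputError(f"need >= 2 {what} for random intercepts")

    base = pd.DataFrame({
        "score": pd.Series(scores).loc[cells].astype(float),
        "donor_id": meta[donor_col].to_numpy(),
        "ttype": meta[ttype_col].to_numpy(),
    }, index=cells)
    fixed = ["score"]
    if include_depth:
        depth = meta[depth_col].astype(float)
        base["depth"] = (depth - depth.mean()) / depth.std(ddof=1)
        fixed.append("depth")

    rows = []
    for feat in ephys_std.columns:
        data = base.copy()
        data["y"] = ephys_std.loc[cells, feat].astype(float)
        spec = LmmSpec(response="y", fixed=fixed, random=["ttype", "donor_id"])
        frame = ModelFrame(data=data, response="y", continuous=fixed,
                           categorical=[], group="donor_id")
        try:
            fit = fit_lmm(spec, frame)
            name = next(p for p in fit.fe_params.index if "score" in p)
            beta = float(fit.fe_params[name])
            se = float(fit.fe_bse[name])
            z = beta / se if se > 0 else np.nan
            p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
            rows.append({"feature": feat, "beta": beta, "se": se,
                         "ci_low": beta - 1.96 * se, "ci_high": beta + 1.96 * se,
                         "p": p, "n": fit.n_obs, "converged": fit.converged})
        except (FitError, ValueError, np.linalg.LinAlgError) as exc:
            log.warning("fit failed for feature %s: %s", feat, exc)
            rows.append({"feature": feat, "beta": np.nan, "se": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                         "n": len(cells), "converged": False})
    return pd.DataFrame(rows).set_index("feature")


def univariate_associations(scores: pd.Series, covariates: pd.DataFrame,
                            continuous: list[str] | None = None,
                            group_cols: list[str] | None = None,
                            binary_cols: list[str] | None = None) -> pd.DataFrame:
    """Tidy table of univariate score–covariate statistics.

    Pearson correlation (two-sided t-based p) for continuous covariates,
    Kruskal–Wallis across multi-level groups, two-sided rank-sum for binary
    groupings.
    """
    scores = pd.Series(scores)
    rows = []
    for col in continuous or []:
        paired = pd.concat([scores.rename("score"),
                            covariates[col].astype(float)], axis=1).dropna()
        if len(paired) < 3:
            raise InputError(f"fewer than 3 paired observations for {col!r}")
        r, p = stats.pearsonr(paired["score"], paired[col])
        rows.append({"variable": col, "test": "pearson", "statistic": float(r),
                     "p": float(p), "n": len(paired)})
    for col in group_cols or []:
        paired = pd.concat([scores.rename("score"), covariates[col]],
                           axis=1).dropna()
        groups = [g["score"].to_numpy() for _, g in paired.groupby(col,
                                                                   observed=True)]
        if len(groups) < 2:
            raise InputError(f"need >= 2 groups for {col!r}")
        h, p = stats.kruskal(*groups)
        rows.append({"variable": col, "test": "kruskal-wallis",
                     "statistic": float(h), "p": float(p), "n": len(paired)})
    for col in binary_cols or []:
        paired = pd.concat([scores.rename("score"), covariates[col]],
                           axis=1).dropna()
        levels = sorted(paired[col].unique())
        if len(levels) != 2:
            raise InputError(f"column {col!r} is not binary: {levels}")
        a = paired.loc[paired[col] == levels[0], "score"].to_numpy()
        b = paired.loc[paired[col] == levels[1], "score"].to_numpy()
        rows.append({"variable": col, "test": "wilcoxon-ranksum",
                     "statistic": float(np.median(b) - np.median(a)),
                     "p": ranksum_p(a, b), "n": len(paired)})
    return pd.DataFrame(rows)
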