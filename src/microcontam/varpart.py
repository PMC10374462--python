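"""Mixed-model variance partitioning of contamination scores.

A Gaussian linear mixed model (REML) relates the per-cell contamination score
to donor-level and cell-level covariates with a random intercept per donor:

    score ~ sex + condition + scale(age) + scale(break_in_time)
            + scale(seal_resistance) + scale(soma_depth) + t-type
            + histology bins + (1 | donor)

Variance explained follows the Nakagawa decomposition: marginal R² is the
fixed-effect share of total variance, conditional R² adds the random
intercepts. Each fixed factor's share is the drop in marginal R² when that
factor is replaced by a random intercept (continuous covariates are binned
into quintiles for the reduced model so the replace-not-drop scheme stays
estimable); the donor share is conditional minus marginal R² of the full
model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

from .errors import FitError, InputError

log = logging.getLogger(__name__)

DEFAULT_CONTINUOUS = ("age", "break_in_time", "seal_resistance", "soma_depth")
DEFAULT_CATEGORICAL = ("sex", "condition")
DEFAULT_HISTOLOGY = ("iba1_score", "gfap_score")


@dataclass
class ModelFrame:
    """Analysis-ready covariate frame.

    ``continuous`` columns are z-scaled (mean 0, SD 1); ``categorical``
    columns (including the collapsed t-type and histology bins) enter as
    factors; ``group`` is the donor/animal random-intercept factor.
    """

    data: pd.DataFrame
    response: str
    continuous: list[str]
    categorical: list[str]
    group: str
    n_dropped: int = 0


@dataclass
class LmmSpec:
    """Model description: response, fixed terms, random-intercept factors."""

    response: str
    fixed: list[str]
    random: list[str]


@dataclass
class LMMFit:
    """REML fit summary used by the R² machinery."""

    fe_params: pd.Series
    fe_bse: pd.Series
    re_variances: dict[str, float]
    resid_var: float
    fitted_fixed: np.ndarray
    llf: float
    converged: bool
    n_obs: int
    spec: LmmSpec
    dropped_terms: list[str] = field(default_factory=list)


def collapse_ttype(label: str) -> str:
    """Aggregate fine transcriptomic-type labels to subclass + first marker
    gene (e.g. 'Sst Hspe Sema3c' -> 'Sst Hspe')."""
    return " ".join(str(label).split()[:2])


def _zscale(col: pd.Series) -> pd.Series:
    sd = col.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        raise InputError(f"cannot scale constant covariate {col.name!r}")
    return (col - col.mean()) / sd


def prepare_covariates(meta: pd.DataFrame, response: str = "score",
                       donor_col: str = "donor_id",
                       ttype_col: str = "cell_type",
                       time_col: str | None = None,
                       continuous=DEFAULT_CONTINUOUS,
                       categorical=DEFAULT_CATEGORICAL,
                       histology_cols=DEFAULT_HISTOLOGY,
                       histology_cut: float = 1.0,
                       min_cells_per_type: int = 20) -> ModelFrame:
    """Build the model frame the mixed models consume.

    Break-in time is hours elapsed since the donor's first recorded cell
    (computed from ``time_col`` when the metadata carries raw recording times;
    a donor's only cell gets 0). Histology marker scores are binned low
    (<= cut) / high (> cut). T-type labels collapse to their first two
    tokens, and types with fewer than ``min_cells_per_type`` cells are
    excluded. Continuous covariates are z-scaled; rows with missing values in
    any used column are dropped and counted.
    """
    if donor_col not in meta.columns:
        raise InputError(f"metadata lacks donor column {donor_col!r}")
    data = meta.copy()
    continuous = [c for c in continuous if c in data.columns or c == "break_in_time"]

    if time_col is not None:
        if time_col not in data.columns:
            raise InputError(f"metadata lacks time column {time_col!r}")
        t = data[time_col]
        if np.issubdtype(t.dtype, np.datetime64):
            hours = (t - t.groupby(data[donor_col]).transform("min"))
            data["break_in_time"] = hours.dt.total_seconds() / 3600.0
        else:
            t = t.astype(float)
            data["break_in_time"] = t - t.groupby(data[donor_col]).transform("min")
    elif "break_in_time" not in data.columns and "break_in_time" in continuous:
        raise InputError("no break_in_time column and no time_col to derive it")

    cat_cols = [c for c in categorical if c in data.columns]
    for col in histology_cols:
        if col in data.columns:
            bin_col = f"{col.replace('_score', '')}_bin"
            data[bin_col] = np.where(data[col].astype(float) > histology_cut,
                                     "high", "low")
            cat_cols.append(bin_col)

    if ttype_col in data.columns:
        data["ttype"] = data[ttype_col].map(collapse_ttype)
        sizes = data["ttype"].value_counts()
        keep_types = sizes.index[sizes >= min_cells_per_type]
        data = data[data["ttype"].isin(keep_types)]
        cat_cols.append("ttype")

    used = [response, donor_col, *continuous, *cat_cols]
    used = [c for c in dict.fromkeys(used) if c in data.columns]
    before = len(data)
    data = data.dropna(subset=used)
    n_dropped = before - len(data)
    if n_dropped:
        log.info("prepare_covariates: dropped %d cells with missing values",
                 n_dropped)
    if data.empty:
        raise InputError("no cells left after filtering")

    for col in continuous:
        data[col] = _zscale(data[col].astype(float))
    if donor_col != "donor_id":
        data = data.rename(columns={donor_col: "donor_id"})
        used = ["donor_id" if c == donor_col else c for c in used]
    return ModelFrame(data=data[used].copy(), response=response,
                      continuous=list(continuous), categorical=cat_cols,
                      group="donor_id", n_dropped=n_dropped)


def _term_expr(data: pd.DataFrame, term: str) -> str:
    if pd.api.types.is_numeric_dtype(data[term]):
        return f"Q('{term}')"
    return f"C(Q('{term}'))"


def _drop_aliased(data: pd.DataFrame, terms: list[str]) -> tuple[list[str], list[str]]:
    """Greedily drop fixed terms that add no rank to the design."""
    kept: list[str] = []
    dropped: list[str] = []
    rank = 1  # intercept
    for term in terms:
        trial = "1 + " + " + ".join(_term_expr(data, t) for t in kept + [term])
        X = patsy.dmatrix(trial, data, return_type="matrix")
        new_rank = np.linalg.matrix_rank(np.asarray(X))
        if new_rank > rank:
            kept.append(term)
            rank = new_rank
        else:
            dropped.append(term)
    if dropped:
        log.warning("dropping aliased fixed terms: %s", dropped)
    return kept, dropped


def fit_lmm(spec: LmmSpec, frame: ModelFrame | pd.DataFrame) -> LMMFit:
    """REML fit of a Gaussian LMM with independent random intercepts.

    A single random factor maps onto the grouping structure directly;
    multiple (crossed) random factors are encoded as variance components
    within one all-spanning group.
    """
    data = frame.data if isinstance(frame, ModelFrame) else frame
    data = data.copy()
    if not spec.random:
        raise InputError("spec must name at least one random factor")
    for r in spec.random:
        if data[r].nunique() < 2:
            raise InputError(f"random factor {r!r} needs >= 2 levels")

    fixed, dropped = _drop_aliased(data, list(spec.fixed))
    rhs = " + ".join(["1"] + [_term_expr(data, t) for t in fixed])
    formula = f"Q('{spec.response}') ~ {rhs}"

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if len(spec.random) == 1:
            model = sm.MixedLM.from_formula(formula, data=data,
                                            groups=data[spec.random[0]])
        else:
            data["__grp__"] = 0
            vcf = {r: f"0 + C(Q('{r}'))" for r in spec.random}
            model = sm.MixedLM.from_formula(formula, data=data,
                                            groups="__grp__",
                                            vc_formula=vcf, re_formula="0")
        result = model.fit(reml=True, method=["bfgs", "powell", "cg"],
                           maxiter=500)
        fe_params = result.fe_params
        fe_bse = result.bse_fe

    if len(spec.random) == 1:
        re_vars = {spec.random[0]: float(np.asarray(result.cov_re)[0, 0])}
    else:
        names = model.exog_vc.names
        re_vars = {n: float(v) for n, v in zip(names, result.vcomp)}
    fitted_fixed = model.exog @ fe_params.to_numpy()
    return LMMFit(
        fe_params=fe_params,
        fe_bse=fe_bse,
        re_variances=re_vars,
        resid_var=float(result.scale),
        fitted_fixed=np.asarray(fitted_fixed),
        llf=float(result.llf),
        converged=bool(result.converged),
        n_obs=int(model.nobs),
        spec=spec,
        dropped_terms=dropped,
    )


def nakagawa_r2(fit: LMMFit) -> tuple[float, float]:
    """(marginal, conditional) R²: fixed-effect variance over total, and
    fixed plus random-intercept variance over total."""
    if not fit.converged:
        raise FitError("refusing to compute R² from a non-converged fit")
    var_f = float(np.var(fit.fitted_fixed, ddof=1)) if fit.n_obs > 1 else 0.0
    var_a = float(sum(fit.re_variances.values()))
    var_e = fit.resid_var
    total = var_f + var_a + var_e
    if total <= 0:
        raise FitError("all variance components are zero; R² undefined")
    return var_f / total, (var_f + var_a) / total


@dataclass
class VariancePartition:
    """Per-factor shares of contamination-score variance."""

    shares: dict[str, float]
    donor_share: float
    r2_marginal: float
    r2_conditional: float
    clipped: list[str] = field(default_factory=list)
    failed: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"factor": k, "r2_share": v} for k, v in self.shares.items()]
        rows.append({"factor": "donor_id", "r2_share": self.donor_share})
        out = pd.DataFrame(rows).sort_values("r2_share", ascending=False,
                                             kind="stable")
        return out.reset_index(drop=True)


def _reduced_random_col(data: pd.DataFrame, term: str) -> tuple[pd.DataFrame, str]:
    """Column used as the random intercept replacing a fixed term: the factor
    itself when categorical, its quintile bins when continuous."""
    if pd.api.types.is_numeric_dtype(data[term]):
        col = f"{term}__qbin"
        data = data.copy()
        data[col] = pd.qcut(data[term], 5, labels=False, duplicates="drop")
        if data[col].nunique() < 2:
            raise FitError(f"covariate {term!r} has fewer than 2 quintile bins")
        data[col] = data[col].astype(str)
        return data, col
    return data, term


def partition_variance(spec: LmmSpec, frame: ModelFrame) -> VariancePartition:
    """Iterative fixed-effect replacement variance decomposition.

    share(factor) = R²m(full) − R²m(model with that factor moved to a random
    intercept), clipped at 0; donor share = R²c(full) − R²m(full).
    """
    full = fit_lmm(spec, frame)
    if not full.converged:
        raise FitError("full model did not converge")
    r2m, r2c = nakagawa_r2(full)
    shares: dict[str, float] = {}
    clipped: list[str] = []
    failed: dict[str, str] = {}
    fixed = [t for t in spec.fixed if t not in full.dropped_terms]
    for term in fixed:
        try:
            data, rand_col = _reduced_random_col(frame.data, term)
            red_spec = LmmSpec(response=spec.response,
                               fixed=[t for t in fixed if t != term],
                               random=list(spec.random) + [rand_col])
            red_frame = ModelFrame(data=data, response=frame.response,
                                   continuous=frame.continuous,
                                   categorical=frame.categorical,
                                   group=frame.group)
            red = fit_lmm(red_spec, red_frame)
            if not red.converged:
                raise FitError("reduced model did not converge")
            r2m_red, _ = nakagawa_r2(red)
            diff = r2m - r2m_red
            if diff < 0:
                clipped.append(term)
            shares[term] = max(diff, 0.0)
        except (FitError, InputError, ValueError) as exc:
            failed[term] = str(exc)
            shares[term] = float("nan")
    return VariancePartition(shares=shares, donor_share=max(r2c - r2m, 0.0),
                             r2_marginal=r2m, r2_conditional=r2c,
                             clipped=clipped, failed=failed)
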