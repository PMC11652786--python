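"""Linear mixed-effects models of connectivity on gestational and postnatal
age.

Two granularities:

* per channel pair — z ~ 1 + GA + PNA with a random intercept for sex
  (one observation per subject per pair makes a subject intercept
  unidentifiable), BH-FDR across pairs per covariate;
* hemisphere-wide — observations are (subject, pair) rows per pair class
  (inter, left_intra, right_intra), z ~ 1 + GA + PNA with random intercepts
  for subject and for sex. Subjects are nested in sex, so the crossed
  specification is fitted equivalently as groups=sex with subject dummies
  as a variance component. Bonferroni across the three models (α = 0.05/3).

Covariates are used on their natural scales (weeks, hours); centering is a
config switch. Only subjects with more than half their channels valid enter
the hemispheric models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .config import PipelineConfig
from .connectivity import fdr_bh
from .montage import PAIR_CLASSES

log = logging.getLogger(__name__)

EFFECTS = ("ga", "pna")


@dataclass
class LMEResult:
    """Fitted fixed effects for one scope (a channel pair or a pair class)."""

    scope: str                          # "pair(i,j)" | "inter" | "left_intra" | "right_intra"
    coef: dict = field(default_factory=dict)    # effect -> estimate
    se: dict = field(default_factory=dict)
    tvalue: dict = field(default_factory=dict)
    pvalue: dict = field(default_factory=dict)
    conf_int: dict = field(default_factory=dict)  # effect -> (lo, hi)
    n_observations: int = 0
    n_subjects: int = 0
    dof_residual: float = np.nan
    converged: bool = False
    error: str | None = None
    bonferroni_alpha: float = np.nan
    significant: dict = field(default_factory=dict)


def _prepare(z_long: pd.DataFrame, meta_df: pd.DataFrame,
             config: PipelineConfig) -> pd.DataFrame:
    """Merge z rows with demographics; listwise-drop subjects missing GA or
    PNA; optionally center covariates."""
    meta = meta_df.rename(columns={
        "gestational_age_wk": "ga", "postnatal_age_h": "pna"})
    meta = meta[["subject_id", "ga", "pna", "sex"]].copy()
    meta["subject_id"] = meta["subject_id"].astype(str)
    df = z_long.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df = df.merge(meta, on="subject_id", how="left")
    df = df.dropna(subset=["ga", "pna", "z"])
    if config.center_covariates:
        df["ga"] = df["ga"] - df["ga"].mean()
        df["pna"] = df["pna"] - df["pna"].mean()
    df["sex"] = df["sex"].fillna("unknown")
    return df


def _extract(fit, scope: str, n_sub: int) -> LMEResult:
    res = LMEResult(scope=scope)
    params = fit.params
    bse = fit.bse
    pvals = fit.pvalues
    ci = fit.conf_int()
    name_map = {"ga": "ga", "pna": "pna"}
    for eff, col in name_map.items():
        res.coef[eff] = float(params[col])
        res.se[eff] = float(bse[col])
        res.tvalue[eff] = float(params[col] / bse[col])
        res.pvalue[eff] = float(pvals[col])
        res.conf_int[eff] = (float(ci.loc[col, 0]), float(ci.loc[col, 1]))
    res.n_observations = int(fit.model.nobs)
    res.n_subjects = n_sub
    res.dof_residual = float(fit.model.nobs - len(fit.fe_params))
    res.converged = bool(getattr(fit, "converged", True))
    return res


def _fit_mixed(df: pd.DataFrame, config: PipelineConfig, scope: str,
               hemispheric: bool) -> LMEResult:
    n_sub = df["subject_id"].nunique()
    design = df[["ga", "pna"]].to_numpy()
    design = np.column_stack([np.ones(len(df)), design])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        return LMEResult(scope=scope, n_observations=len(df),
                         n_subjects=n_sub, error="rank_deficient")
    if np.std(df["z"].to_numpy()) == 0.0:
        # constant response: no age association by construction
        res = LMEResult(scope=scope, n_observations=len(df),
                        n_subjects=n_sub, converged=True)
        for eff in EFFECTS:
            res.coef[eff] = 0.0
            res.se[eff] = 0.0
            res.tvalue[eff] = 0.0
            res.pvalue[eff] = 1.0
            res.conf_int[eff] = (0.0, 0.0)
        return res
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if config.sex_as_fixed:
                formula = "z ~ ga + pna + C(sex)"
                if hemispheric:
                    model = smf.mixedlm(formula, df, groups="subject_id")
                else:
                    fit = smf.ols(formula, df).fit()
                    return _extract(fit, scope, n_sub)
            elif hemispheric:
                model = smf.mixedlm(
                    "z ~ ga + pna", df, groups="sex", re_formula="1",
                    vc_formula={"subject": "0 + C(subject_id)"},
                )
            else:
                model = smf.mixedlm("z ~ ga + pna", df, groups="sex")
            fit = model.fit(reml=config.reml, method="lbfgs")
        res = _extract(fit, scope, n_sub)
        if not res.converged:
            res.error = "non_convergence"
        return res
    except (np.linalg.LinAlgError, ValueError) as exc:
        log.warning("LME for %s failed: %s", scope, exc)
        return LMEResult(scope=scope, n_observations=len(df),
                         n_subjects=n_sub, error=str(exc))


def pairwise_lme(
    z_long: pd.DataFrame,
    meta_df: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-pair mixed model z ~ GA + PNA with a sex random intercept.

    Returns one row per tested pair and covariate with coef/SE/t/p and
    BH-FDR q across pairs (separately per covariate). Pairs with fewer than
    ``min_pair_datapoints`` subjects, rank-deficient designs, or
    non-converged fits are excluded from the FDR family and flagged.
    """
    config = config or PipelineConfig()
    df = _prepare(z_long, meta_df, config)
    rows = []
    for (i, j), sub in df.groupby(["ch_i", "ch_j"], sort=True):
        scope = f"pair({i},{j})"
        if len(sub) < config.min_pair_datapoints:
            continue
        res = _fit_mixed(sub, config, scope, hemispheric=False)
        for eff in EFFECTS:
            rows.append({
                "ch_i": i, "ch_j": j,
                "pair_class": sub["pair_class"].iloc[0],
                "effect": eff,
                "coef": res.coef.get(eff, np.nan),
                "se": res.se.get(eff, np.nan),
                "t": res.tvalue.get(eff, np.nan),
                "p": res.pvalue.get(eff, np.nan),
                "n": res.n_observations,
                "converged": res.converged,
                "error": res.error,
            })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = np.nan
    out["significant_fdr"] = False
    for eff in EFFECTS:
        fam = (out["effect"] == eff) & out["converged"] & out["error"].isna()
        if fam.any():
            qv, rej = fdr_bh(out.loc[fam, "p"].to_numpy(), config.fdr_q)
            out.loc[fam, "q"] = qv
            out.loc[fam, "significant_fdr"] = rej
    return out


def hemispheric_lme(
    z_long: pd.DataFrame,
    meta_df: pd.DataFrame,
    valid_fraction: dict[str, float] | None = None,
    config: PipelineConfig | None = None,
    classes: tuple[str, ...] = PAIR_CLASSES,
) -> dict[str, LMEResult]:
    """Three hemisphere-wide mixed models (inter, left_intra, right_intra).

    ``valid_fraction`` maps subject_id to the fraction of channels that
    survived pruning; subjects at or below ``min_channel_fraction`` are
    excluded. Each result carries a Bonferroni significance decision at
    α = 0.05 / n_model_bonferroni.
    """
    config = config or PipelineConfig()
    df = _prepare(z_long, meta_df, config)
    if valid_fraction is not None:
        keep = {s for s, f in valid_fraction.items()
                if f > config.min_channel_fraction}
        df = df[df["subject_id"].isin(keep)]
    results: dict[str, LMEResult] = {}
    alpha = 0.05 / config.n_model_bonferroni
    for cls in classes:
        sub = df[df["pair_class"] == cls]
        if sub.empty:
            continue
        res = _fit_mixed(sub, config, cls, hemispheric=True)
        res.bonferroni_alpha = alpha
        res.significant = {
            eff: bool(res.pvalue.get(eff, np.nan) < alpha) for eff in EFFECTS
        }
        results[cls] = res
    return results


def cohort_summary(meta_df: pd.DataFrame) -> dict:
    """Cohort means/SDs of GA (weeks) and PNA (hours) plus sex counts,
    computed over non-missing values, rounded to 2 decimals."""
    ga = pd.to_numeric(meta_df["gestational_age_wk"], errors="coerce").dropna()
    pna = pd.to_numeric(meta_df["postnatal_age_h"], errors="coerce").dropna()

    def stat(x, f):
        if x.empty:
            return None
        v = f(x)
        return None if pd.isna(v) else round(float(v), 2)

    sex_counts = meta_df["sex"].value_counts(dropna=True).to_dict()
    return {
        "n": int(len(meta_df)),
        "ga_mean": stat(ga, pd.Series.mean),
        "ga_sd": stat(ga, lambda x: x.std(ddof=1)),
        "pna_mean": stat(pna, pd.Series.mean),
        "pna_sd": stat(pna, lambda x: x.std(ddof=1)),
        "n_female": int(sex_counts.get("female", 0)),
        "n_male": int(sex_counts.get("male", 0)),
    }
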