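"""Cohort-level statistical validation experiments.

These run the connectivity and mixed-model machinery on cohorts of
connectivity-level simulations (the generator's latent tier, at the 4 Hz
analysis rate) so the statistical properties of the inference stage can be
measured at realistic sample sizes in minutes:

* :func:`null_fdr_experiment` — global null (identity true correlation, no
  covariate effects): the proportion of channel pairs rejected by the
  BH-FDR-corrected group t-test must stay at the nominal level.
* :func:`pna_recovery_experiment` — cohorts with a known interhemispheric
  postnatal-age slope: the hemispheric mixed model's 95% confidence interval
  should cover the injected slope in ~95% of replicate cohorts.
"""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig
from .connectivity import group_ttest, sfc_matrix, z_table
from .inference import hemispheric_lme, pairwise_lme
from .montage import Montage, build_default_montage
from .synth import (
    SimParams,
    make_cohort_truths,
    sample_cohort,
    simulate_latent,
)


def _cohort_matrices(params, seed, montage, n_samples, rate, exact):
    """Simulate one cohort at the connectivity level and return
    (matrices, meta_df rows)."""
    import pandas as pd

    metas = sample_cohort(params, seed)
    truths = make_cohort_truths(metas, params, seed, montage)
    ss = np.random.SeedSequence([seed, 808]).spawn(len(metas))
    matrices = []
    for meta, truth, sub in zip(metas, truths, ss):
        rng = np.random.default_rng(sub)
        lat = simulate_latent(truth.true_correlation, n_samples, rate, rng,
                              params.band, exact=exact)
        cm = sfc_matrix(lat, np.ones(montage.n_channels, bool),
                        subject_id=meta.subject_id,
                        channel_ids=montage.channel_ids,
                        min_samples=min(600, n_samples))
        matrices.append(cm)
    meta_df = pd.DataFrame([
        {"subject_id": m.subject_id, "gestational_age_wk": m.gestational_age_wk,
         "postnatal_age_h": m.postnatal_age_h, "sex": m.sex}
        for m in metas
    ])
    return matrices, meta_df


def null_fdr_experiment(
    seed: int,
    n_replicates: int = 200,
    n_subjects: int = 41,
    duration: float = 120.0,
    rate: float = 4.0,
    montage: Montage | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Global-null calibration of the FDR-corrected group t-map.

    Each replicate simulates a cohort with identity true correlation, no
    covariate effects and no between-subject heterogeneity (in-expectation
    correlation imposition, so each subject's matrix carries genuine
    sampling noise), then counts FDR rejections across the 190 pairs.
    Returns the pooled rejection proportion and its Monte-Carlo error.
    """
    montage = montage or build_default_montage()
    config = config or PipelineConfig()
    params = SimParams(
        n_subjects=n_subjects,
        r_left=0.0, r_right=0.0, r_inter=0.0,
        beta_pna_inter=0.0, beta_ga_inter=0.0,
        subject_re_sd=0.0, sex_re_sd=0.0, conn_noise_sd=0.0,
        exact_correlation=False,
    )
    n_samples = int(round(duration * rate))
    rep_props = np.empty(n_replicates)
    for rep in range(n_replicates):
        matrices, _ = _cohort_matrices(
            params, seed + 1000 * rep, montage, n_samples, rate, exact=False)
        tmap = group_ttest(matrices, montage, config)
        tested = tmap["p"].notna()
        rep_props[rep] = tmap.loc[tested, "significant_fdr"].mean()
    prop = float(rep_props.mean())
    mc_error = float(rep_props.std(ddof=1) / np.sqrt(n_replicates))
    return {"rejection_proportion": prop, "mc_error": mc_error,
            "n_replicates": n_replicates, "bound": 0.05 + 2 * mc_error}


def pna_recovery_experiment(
    seed: int,
    n_replicates: int = 20,
    n_subjects: int = 200,
    duration: float = 300.0,
    rate: float = 4.0,
    montage: Montage | None = None,
    config: PipelineConfig | None = None,
    params: SimParams | None = None,
) -> dict:
    """Coverage of the injected interhemispheric postnatal-age slope.

    Each replicate simulates a cohort with the default slope
    (``beta_pna_inter``), runs the hemispheric mixed model on the
    interhemispheric pairs, and records whether the 95% CI of the PNA fixed
    effect covers the injected value. Returns the coverage fraction and the
    mean estimate across replicates.
    """
    montage = montage or build_default_montage()
    config = config or PipelineConfig()
    params = params or SimParams(n_subjects=n_subjects)
    params.n_subjects = n_subjects
    n_samples = int(round(duration * rate))
    covered = np.zeros(n_replicates, dtype=bool)
    estimates = np.empty(n_replicates)
    for rep in range(n_replicates):
        rep_seed = seed + 1000 * rep
        # in-expectation imposition: per-subject correlation sampling noise
        # is the residual the mixed model is supposed to average over
        matrices, meta_df = _cohort_matrices(
            params, rep_seed, montage, n_samples, rate, exact=False)
        zt = z_table(matrices, montage)
        results = hemispheric_lme(zt, meta_df, None, config, classes=("inter",))
        res = results["inter"]
        lo, hi = res.conf_int["pna"]
        covered[rep] = lo <= params.beta_pna_inter <= hi
        estimates[rep] = res.coef["pna"]
    return {
        "coverage": float(covered.mean()),
        "mean_estimate": float(estimates.mean()),
        "true_beta": params.beta_pna_inter,
        "n_replicates": n_replicates,
    }


def pairwise_recovery(
    seed: int,
    n_subjects: int = 200,
    duration: float = 300.0,
    rate: float = 4.0,
    montage: Montage | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Mean estimated PNA coefficient over interhemispheric pairs from the
    per-pair mixed models, against the injected slope."""
    montage = montage or build_default_montage()
    config = config or PipelineConfig()
    params = SimParams(n_subjects=n_subjects)
    n_samples = int(round(duration * rate))
    matrices, meta_df = _cohort_matrices(
        params, seed, montage, n_samples, rate, exact=False)
    zt = z_table(matrices, montage)
    table = pairwise_lme(zt, meta_df, config)
    inter = table[(table["pair_class"] == "inter") & (table["effect"] == "pna")]
    return {
        "mean_pna_coef_inter": float(inter["coef"].mean()),
        "true_beta": params.beta_pna_inter,
        "n_pairs": int(len(inter)),
    }
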