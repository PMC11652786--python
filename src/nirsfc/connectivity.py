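"""Channel-pair spontaneous functional connectivity (sFC).

Per subject: Pearson correlation between every valid channel pair of the
preprocessed 4 Hz series, Fisher z-transformed. At the group level: a
one-sample t-test of z against zero per pair (two-sided p; the direction is
read off the sign of t), with Benjamini-Hochberg FDR across the tested
pairs. Pairs observed in fewer than ``min_pair_datapoints`` subjects carry
no statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .montage import Montage, classify_pair, enumerate_pairs

R_CLAMP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    subject_id: str
    z: np.ndarray                  # (nch, nch) Fisher-z, symmetric where valid
    valid: np.ndarray              # (nch, nch) bool, both channels survived QC
    n_samples: int
    channel_ids: tuple[int, ...]


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilizing atanh with clamping at |r| = 1 − 1e−7."""
    return np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP))


def sfc_matrix(
    series: np.ndarray,
    valid_channels: np.ndarray,
    subject_id: str = "",
    channel_ids: tuple[int, ...] = tuple(range(1, 21)),
    min_samples: int = 600,
) -> ConnectivityMatrix:
    """Fisher-z Pearson correlation matrix of a (n_samples, n_channels)
    series; needs at least ``min_samples`` rows (150 s at 4 Hz)."""
    series = np.asarray(series, dtype=float)
    valid_channels = np.asarray(valid_channels, dtype=bool)
    if series.shape[0] < min_samples:
        raise ValueError(
            f"need ≥ {min_samples} samples for a stable correlation matrix"
        )
    if valid_channels.sum() < 2:
        raise ValueError("need at least two valid channels")
    nch = series.shape[1]
    r = np.corrcoef(series, rowvar=False)
    z = fisher_z(r)
    valid = np.outer(valid_channels, valid_channels)
    z = np.where(valid, z, np.nan)
    return ConnectivityMatrix(
        subject_id=subject_id, z=z, valid=valid,
        n_samples=series.shape[0], channel_ids=channel_ids,
    )


def fdr_bh(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (adjusted q-values, reject)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def group_ttest(
    matrices: list[ConnectivityMatrix],
    montage: Montage,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Group one-sample t-map over Fisher-z connectivity.

    One row per channel pair: pair class, n available subjects, t, two-sided
    p, BH-FDR q, and raw/FDR significance flags. Pairs with fewer than
    ``min_pair_datapoints`` subjects get NaN statistics and are excluded
    from the FDR family.
    """
    config = config or PipelineConfig()
    if len(matrices) < 2:
        raise ValueError("need at least two subjects")
    ids = matrices[0].channel_ids
    idx = {cid: k for k, cid in enumerate(ids)}
    rows = []
    for (i, j) in enumerate_pairs(montage):
        zs = np.array([
            m.z[idx[i], idx[j]] for m in matrices
            if m.valid[idx[i], idx[j]] and np.isfinite(m.z[idx[i], idx[j]])
        ])
        n = zs.size
        if n >= config.min_pair_datapoints:
            mean_z = zs.mean()
            if zs.std(ddof=1) == 0.0:
                # degenerate: identical z across subjects
                t = 0.0 if mean_z == 0.0 else np.inf * np.sign(mean_z)
                p = 1.0 if mean_z == 0.0 else 0.0
            else:
                t, p = stats.ttest_1samp(zs, 0.0)
        else:
            t = p = mean_z = np.nan
        rows.append({
            "ch_i": i, "ch_j": j,
            "pair_class": classify_pair(montage, (i, j)),
            "n": n, "mean_z": mean_z, "t": t, "p": p,
        })
    df = pd.DataFrame(rows)
    tested = df["p"].notna()
    df["q"] = np.nan
    df["significant_raw"] = False
    df["significant_fdr"] = False
    if tested.any():
        qvals, reject = fdr_bh(df.loc[tested, "p"].to_numpy(), config.fdr_q)
        df.loc[tested, "q"] = qvals
        df.loc[tested, "significant_raw"] = df.loc[tested, "p"] < 0.05
        df.loc[tested, "significant_fdr"] = reject
    return df


def z_table(
    matrices: list[ConnectivityMatrix], montage: Montage
) -> pd.DataFrame:
    """Long-format table (subject_id, ch_i, ch_j, pair_class, z) across
    subjects, restricted to valid finite entries."""
    ids = matrices[0].channel_ids
    idx = {cid: k for k, cid in enumerate(ids)}
    rows = []
    for m in matrices:
        for (i, j) in enumerate_pairs(montage):
            if m.valid[idx[i], idx[j]] and np.isfinite(m.z[idx[i], idx[j]]):
                rows.append({
                    "subject_id": m.subject_id, "ch_i": i, "ch_j": j,
                    "pair_class": classify_pair(montage, (i, j)),
                    "z": float(m.z[idx[i], idx[j]]),
                })
    return pd.DataFrame(rows)
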