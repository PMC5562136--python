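"""Righting-response processing and genotype comparison.

A righting trial records the seconds an inverted sea star needs to turn
oral-side down; trials run three times in each of three periods (ambient
before the heat trial, at elevated temperature, and after the return to
ambient).  Individuals that fail to right within one hour in any trial are
treated as unresponsive and dropped entirely.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import LibraryMeta

UNRESPONSIVE_CUTOFF_S = 3600.0
PERIODS = ("ambient_pre", "elevated", "ambient_post")


def filter_unresponsive(
    records: pd.DataFrame, cutoff_s: float = UNRESPONSIVE_CUTOFF_S
) -> tuple[pd.DataFrame, list[str]]:
    """Drop every trial of any individual with a trial above the cutoff."""
    if records.empty:
        return records.copy(), []
    over = records["time_s"] > cutoff_s
    excluded = sorted(records.loc[over, "individual_id"].unique())
    kept = records[~records["individual_id"].isin(excluded)].reset_index(drop=True)
    return kept, excluded


def righting_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-individual min/mean/sd of righting time, per period and overall."""
    rows = []
    for ind, grp in records.groupby("individual_id", sort=False):
        for period, sub in list(grp.groupby("period", sort=False)) + [("overall", grp)]:
            t = sub["time_s"].to_numpy(dtype=float)
            rows.append(
                {
                    "individual_id": ind,
                    "period": period,
                    "n_trials": len(t),
                    "min_time": float(t.min()),
                    "mean_time": float(t.mean()),
                    "sd_time": float(np.std(t, ddof=1)) if len(t) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _per_individual_values(
    summary: pd.DataFrame, meta_geno: pd.DataFrame, statistic: str
) -> tuple[np.ndarray, np.ndarray]:
    if statistic not in ("mean", "min"):
        raise ValueError("statistic must be 'mean' or 'min'")
    col = "mean_time" if statistic == "mean" else "min_time"
    overall = summary[summary["period"] == "overall"].set_index("individual_id")[col]
    geno = meta_geno.set_index("individual_id")["genotype"]
    wild = overall[geno.reindex(overall.index) == "wild"].to_numpy(dtype=float)
    ins = overall[geno.reindex(overall.index) == "ins"].to_numpy(dtype=float)
    if len(wild) < 2 or len(ins) < 2:
        raise ValueError("need at least 2 individuals per genotype")
    return wild, ins


def _genotype_table(meta) -> pd.DataFrame:
    if isinstance(meta, LibraryMeta):
        return meta.table[["individual_id", "genotype"]].drop_duplicates()
    return pd.DataFrame(meta)[["individual_id", "genotype"]].drop_duplicates()


def genotype_compare(
    summary: pd.DataFrame, meta, statistic: str = "mean"
) -> tuple[float, float, float]:
    """Welch t-test of per-individual righting times across genotypes.

    Returns (t, two-sided p, ratio wild/ins of genotype means), so a ratio
    of 1.8 means heterozygotes right themselves 1.8x faster.
    """
    wild, ins = _per_individual_values(summary, _genotype_table(meta), statistic)
    if np.allclose(wild.var(ddof=1) + ins.var(ddof=1), 0.0):
        # degenerate (noise-free) groups: the t statistic is 0 or +/-inf
        if np.isclose(wild.mean(), ins.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(wild.mean() - ins.mean()) * np.inf), 0.0
    else:
        t, p = stats.ttest_ind(wild, ins, equal_var=False)
    ratio = float(wild.mean() / ins.mean())
    return float(t), float(p), ratio


def genotype_permutation(
    summary: pd.DataFrame,
    meta,
    statistic: str = "mean",
    K: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for the genotype difference in mean righting time.

    Shuffles genotype labels over individuals K times; p is the fraction of
    shuffles with |mean difference| at least the observed (the observed
    labelling counts as one draw, so p >= 1/(K+1)).
    """
    wild, ins = _per_individual_values(summary, _genotype_table(meta), statistic)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pooled = np.concatenate([wild, ins])
    n_w = len(wild)
    obs = abs(wild.mean() - ins.mean())
    hits = 0
    for _ in range(K):
        perm = rng.permutation(pooled)
        if abs(perm[:n_w].mean() - perm[n_w:].mean()) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (K + 1)
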