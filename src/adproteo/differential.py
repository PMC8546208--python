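"""Inferential statistics: cohort balance, group regression, covariate screen.

Differential abundance is ordinary least squares of log2 abundance on the
disease indicator (control = 0, AD = 1), so the coefficient is the AD - control
log2 fold change and its t-test is algebraically the equal-variance two-sample
t-test.  A feature is significant at p < 0.05 with |log2FC| >= 0.7 (no
multiple-testing correction by default — the raw-p + fold-change-floor rule is
a deliberate, documented reproduction choice; BH-FDR is available behind a
flag).  Features whose abundance is itself associated with sex, age or PMI
(univariate regression p < 0.05) are flagged and dropped from the retained set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import COVARIATES, DataModelError, IntensityMatrix, SampleTable

P_THRESHOLD = 0.05
LOG2FC_THRESHOLD = 0.7
#: exact Wilcoxon null enumeration up to this per-group size, normal
#: approximation (tie-corrected, continuity-corrected) above
EXACT_WILCOXON_MAX_N = 25


def _exact_wilcoxon_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by dynamic programming over label assignments.

    Enumerates the permutation null of the rank-sum statistic (mid-ranks for
    ties, doubled so all weights are integers) with the shift algorithm:
    ``dp[j, s]`` counts size-``j`` subsets of the pooled sample whose doubled
    ranks sum to ``s``.  Two-sided p is the null probability of a rank sum at
    least as far from its expectation as observed.
    """
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2.0 * stats.rankdata(pooled)).astype(int)
    n1 = len(x)
    w_obs = int(ranks2[:n1].sum())
    total = int(ranks2.sum())
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        for j in range(n1, 0, -1):
            dp[j, r:] += dp[j - 1, : total + 1 - r]
    counts = dp[n1]
    mu = n1 * total / len(pooled)
    dev = np.abs(np.arange(total + 1) - mu)
    extreme = dev >= abs(w_obs - mu) - 1e-9
    return float(counts[extreme].sum() / counts.sum())


def wilcoxon_rank_sum(x, y, exact_max_n: int = EXACT_WILCOXON_MAX_N) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact permutation null (dynamic programming, tie-aware mid-ranks) when
    both groups have at most ``exact_max_n`` observations; normal
    approximation with tie correction above that.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise DataModelError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("constant values in both groups; p set to 1", stacklevel=2)
        return 1.0
    if max(len(x), len(y)) <= exact_max_n:
        return _exact_wilcoxon_p(x, y)
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (tables as unlikely as observed)."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def test_group_balance(samples: SampleTable, region: str) -> pd.DataFrame:
    """Compare sex (Fisher exact), age and PMI (Wilcoxon) between groups."""
    f = samples.for_region(region).frame.drop_duplicates(subset="brain_id")
    counts = f["group"].value_counts()
    if counts.get("AD", 0) < 1 or counts.get("control", 0) < 1:
        raise DataModelError(f"region {region}: both groups need at least one sample")
    rows = []
    table = pd.crosstab(f["group"], f["sex"]).reindex(
        index=["AD", "control"], columns=["M", "F"], fill_value=0
    )
    rows.append({"region": region, "variable": "sex", "test": "fisher_exact", "p_value": fisher_exact_2x2(table)})
    for var in ("age", "pmi"):
        x = f.loc[f["group"] == "AD", var].to_numpy(float)
        y = f.loc[f["group"] == "control", var].to_numpy(float)
        rows.append(
            {"region": region, "variable": var, "test": "wilcoxon_rank_sum", "p_value": wilcoxon_rank_sum(x, y)}
        )
    return pd.DataFrame(rows)


def _simple_regression(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OLS of each row of ``y`` on the single regressor ``x``.

    Returns (slope, two-sided p of the slope t-test).  ``y`` is
    (n_features, n_samples).
    """
    y = np.atleast_2d(np.asarray(y, float))
    x = np.asarray(x, float)
    n = x.size
    if n < 3:
        raise DataModelError("need at least 3 observations for the slope t-test")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise DataModelError("constant regressor")
    yc = y - y.mean(axis=1, keepdims=True)
    slope = (yc @ xc) / sxx
    resid = yc - slope[:, None] * xc[None, :]
    sigma2 = (resid**2).sum(axis=1) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / np.where(se > 0, se, 1.0), np.inf * np.sign(slope))
    t = np.where((se == 0) & (slope == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return slope, p


@dataclass
class DifferentialRecord:
    feature_id: str
    region: str
    log2fc: float
    p_value: float
    significant: bool
    covariate_flags: tuple[str, ...] = ()
    retained: bool = False
    status: str = "quantitative"


def fit_group_regression(
    feature_values: pd.Series,
    samples: SampleTable,
    p_threshold: float = P_THRESHOLD,
    fc_threshold: float = LOG2FC_THRESHOLD,
) -> DifferentialRecord:
    """OLS of one feature's abundance on the disease indicator."""
    group = samples.group_of().reindex(feature_values.index)
    x = (group == "AD").to_numpy(float)
    counts = group.value_counts()
    if counts.get("AD", 0) < 2 or counts.get("control", 0) < 2:
        raise DataModelError("need at least 2 samples per group")
    slope, p = _simple_regression(feature_values.to_numpy(float)[None, :], x)
    log2fc, p_value = float(slope[0]), float(p[0])
    region = samples.frame["region"].iloc[0]
    return DifferentialRecord(
        feature_id=str(feature_values.name),
        region=region,
        log2fc=log2fc,
        p_value=p_value,
        significant=bool(p_value < p_threshold and abs(log2fc) >= fc_threshold),
    )


def screen_covariates(
    feature_values: pd.Series, samples: SampleTable, p_threshold: float = P_THRESHOLD
) -> tuple[str, ...]:
    """Flag covariates (sex/age/PMI) whose univariate regression p < 0.05."""
    frame = samples.frame.set_index("sample_id").reindex(feature_values.index)
    y = feature_values.to_numpy(float)[None, :]
    flags = []
    for cov in COVARIATES:
        x = (frame[cov] == "M").to_numpy(float) if cov == "sex" else frame[cov].to_numpy(float)
        if np.all(x == x[0]):
            warnings.warn(f"covariate {cov!r} is constant; not flagged", stacklevel=2)
            continue
        if np.all(y == y[0, 0]):
            continue
        _, p = _simple_regression(y, x)
        if p[0] < p_threshold:
            flags.append(cov)
    return tuple(flags)


def run_differential(
    matrix: IntensityMatrix,
    samples: SampleTable,
    decisions: pd.DataFrame | None = None,
    p_threshold: float = P_THRESHOLD,
    fc_threshold: float = LOG2FC_THRESHOLD,
    screen: bool = True,
    bh_fdr: bool = False,
) -> pd.DataFrame:
    """Differential table for one imputed, single-region layer.

    One row per quantitative/on-off-like feature with the fold change,
    p-value, significance, covariate flags, direction, and the ``retained``
    verdict (significant with no covariate flag).  ``bh_fdr`` additionally
    reports Benjamini-Hochberg q-values (reporting only; the significance
    rule stays raw-p, matching the reproduction target).
    """
    if decisions is not None:
        keep = decisions.loc[decisions["status"].isin(["quantitative", "on_off_like"]), "feature_id"]
        matrix = matrix.subset_features([f for f in keep if f in set(matrix.feature_ids)])
        status = decisions.set_index("feature_id")["status"].reindex(matrix.feature_ids)
    else:
        status = pd.Series("quantitative", index=matrix.feature_ids)
    if matrix.values.isna().any().any():
        raise DataModelError("differential analysis expects a complete (imputed) matrix")

    frame = samples.frame.set_index("sample_id").reindex(matrix.sample_ids)
    if frame.isna().any().any():
        raise DataModelError("matrix contains samples absent from the sample table")
    group_x = (frame["group"] == "AD").to_numpy(float)
    if (group_x == 1).sum() < 2 or (group_x == 0).sum() < 2:
        raise DataModelError("need at least 2 samples per group")
    y = matrix.values.to_numpy(float)
    log2fc, p = _simple_regression(y, group_x)
    significant = (p < p_threshold) & (np.abs(log2fc) >= fc_threshold)

    flags = [[] for _ in range(len(y))]
    if screen:
        for cov in COVARIATES:
            x = (frame[cov] == "M").to_numpy(float) if cov == "sex" else frame[cov].to_numpy(float)
            if np.all(x == x[0]):
                warnings.warn(f"covariate {cov!r} is constant; not flagged", stacklevel=2)
                continue
            _, p_cov = _simple_regression(y, x)
            for i in np.flatnonzero(p_cov < p_threshold):
                flags[i].append(cov)

    out = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "region": frame["region"].iloc[0],
            "status": status.to_numpy(),
            "log2fc": log2fc,
            "p_value": p,
            "significant": significant,
            "covariate_flags": [",".join(f) for f in flags],
            "retained": significant & np.array([len(f) == 0 for f in flags]),
            "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")),
        }
    )
    if bh_fdr:
        out["q_value"] = stats.false_discovery_control(p, method="bh")
    return out


def summarize_differential(table: pd.DataFrame) -> dict[str, int]:
    """Table-1-style bookkeeping: up/down counts, filtered and unfiltered."""
    sig = table[table["significant"]]
    ret = table[table["retained"]]
    return {
        "n_tested": int(len(table)),
        "up_significant": int((sig["log2fc"] > 0).sum()),
        "down_significant": int((sig["log2fc"] < 0).sum()),
        "up_retained": int((ret["log2fc"] > 0).sum()),
        "down_retained": int((ret["log2fc"] < 0).sum()),
        "covariate_excluded": int((table["significant"] & (table["covariate_flags"] != "")).sum()),
    }
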