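"""Pre-ranked gene-set enrichment and list-based annotation.

The enrichment score is the classic weighted Kolmogorov-Smirnov-like running
sum: walking down the ranked list, hits increment proportionally to
``|metric|^w`` (w = 1, normalized to sum 1) and misses decrement ``1/(N - Nh)``;
the ES is the maximum signed deviation.  Significance comes from gene-label
permutations (pre-ranked input has no phenotype labels to permute), NES is
ES over the mean |permuted ES| of the same sign, and q-values are
Benjamini-Hochberg across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DataModelError, GeneSetCollection

GSEA_WEIGHT = 1.0
DEFAULT_MIN_SET = 15
DEFAULT_MAX_SET = 500


@dataclass
class RankedList:
    """Feature ids ordered by a descending real-valued ranking metric.

    Ties in the metric are broken by stable feature-id order so the ES is
    deterministic.
    """

    ids: list[str]
    metric: np.ndarray

    @classmethod
    def from_series(cls, series: pd.Series) -> "RankedList":
        if series.index.duplicated().any():
            raise DataModelError("ranked list ids must be unique")
        series = series.dropna().astype(float)
        order = sorted(range(len(series)), key=lambda i: (-series.iloc[i], series.index[i]))
        return cls(ids=[series.index[i] for i in order], metric=series.to_numpy()[order])

    def __post_init__(self):
        if len(self.ids) != len(self.metric):
            raise DataModelError("ids and metric lengths differ")
        if len(set(self.ids)) != len(self.ids):
            raise DataModelError("ranked list ids must be unique")
        if np.any(np.diff(self.metric) > 0):
            raise DataModelError("metric must be in descending order")


def enrichment_score(ranked: RankedList, members: set[str], weight: float = GSEA_WEIGHT) -> float:
    """Signed maximum deviation of the weighted running sum."""
    hit = np.fromiter((fid in members for fid in ranked.ids), bool, count=len(ranked.ids))
    return _es_from_hits(np.abs(ranked.metric), hit, weight)


def _es_from_hits(abs_metric: np.ndarray, hit: np.ndarray, weight: float) -> float:
    n = len(hit)
    n_hits = int(hit.sum())
    if n_hits == 0 or n_hits == n:
        raise DataModelError("gene set must hit a strict subset of the ranked list")
    w = abs_metric[hit] ** weight
    total = w.sum()
    steps = np.full(n, -1.0 / (n - n_hits))
    if total > 0:
        steps[hit] = w / total
    else:  # all-zero metric degenerates to the unweighted statistic
        steps[hit] = 1.0 / n_hits
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def prerank_gsea(
    ranked: RankedList,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = DEFAULT_MIN_SET,
    max_size: int = DEFAULT_MAX_SET,
    weight: float = GSEA_WEIGHT,
) -> pd.DataFrame:
    """Pre-ranked GSEA over a gene-set collection.

    Sets are restricted to members present in the ranked list and filtered to
    ``[min_size, max_size]``; skipped sets are reported with ``skipped=True``
    and no statistics.  The permutation p-value for a set of size k uses the
    null ES of k randomly drawn labels, compared within the same ES sign.
    """
    if n_perm < 100:
        raise DataModelError("n_perm must be >= 100")
    rng = np.random.default_rng(int(seed) % (2**31))
    abs_metric = np.abs(ranked.metric)
    universe = set(ranked.ids)
    n = len(ranked.ids)

    rows = []
    perm_cache: dict[int, np.ndarray] = {}
    for name, members in sets.sets.items():
        present = [m for m in members if m in universe]
        k = len(present)
        if k == 0 or not (min_size <= k <= max_size) or k == n:
            rows.append({"set_name": name, "n_hits": k, "skipped": True})
            continue
        es = enrichment_score(ranked, set(present), weight)
        if k not in perm_cache:
            null = np.empty(n_perm)
            hit = np.zeros(n, dtype=bool)
            for b in range(n_perm):
                hit[:] = False
                hit[rng.choice(n, size=k, replace=False)] = True
                null[b] = _es_from_hits(abs_metric, hit, weight)
            perm_cache[k] = null
        null = perm_cache[k]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same_sign) == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.nan
        else:
            extreme = (same_sign >= es).sum() if es >= 0 else (same_sign <= es).sum()
            p = (1.0 + extreme) / (1.0 + len(same_sign))
            denom = float(np.mean(np.abs(same_sign)))
            nes = es / denom if denom > 0 else np.nan
        rows.append(
            {"set_name": name, "n_hits": k, "skipped": False, "es": es, "nes": nes, "p_value": p}
        )
    out = pd.DataFrame(rows)
    scored = out.loc[~out["skipped"]]
    if len(scored):
        out.loc[scored.index, "fdr_q"] = stats.false_discovery_control(
            scored["p_value"].to_numpy(), method="bh"
        )
    return out


def rank_by_region_difference(
    medians: pd.DataFrame, region_a: str, region_b: str | None = None
) -> RankedList:
    """Ranking metric: fold-change difference between two regions (or one
    region's fold change when ``region_b`` is None)."""
    if region_a not in medians.columns:
        raise DataModelError(f"unknown region {region_a!r}")
    metric = medians[region_a].copy()
    if region_b is not None:
        if region_b not in medians.columns:
            raise DataModelError(f"unknown region {region_b!r}")
        metric = metric - medians[region_b]
    return RankedList.from_series(metric)
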