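"""PTM-state quantification.

Phosphorylation state: phosphopeptide log2 intensity minus the parent
protein's log2 intensity (both post-normalization), i.e. a raw-scale ratio —
isolating site-level regulation from protein-level change.  The state matrix
then feeds the same filter/impute/regression chain as any intensity layer.

Acetylation stoichiometry (site occupancy): after exhaustive chemical
acetylation of free lysines with a heavy (d3) reagent, the occupancy of a
site is ``d0 / (d0 + d3)`` — endogenous intensity over total.  Group
comparison uses a two-sided Wilcoxon on the raw ratios, restricted to sites
with at least 40% valid ratios in each disease group, with no imputation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datamodel import DataModelError, FeatureAnnotation, IntensityMatrix, SampleTable
from .differential import wilcoxon_rank_sum

STOICH_MIN_VALID = 0.40


def compute_phospho_state(
    phospho: IntensityMatrix,
    protein: IntensityMatrix,
    annotation: FeatureAnnotation,
) -> IntensityMatrix:
    """Per-sample log2(phosphopeptide) - log2(parent protein).

    Both matrices must be log2-normalized over the same samples.  A state
    value is missing whenever either input is missing; phosphopeptides whose
    parent protein is not quantified (or not annotated) are dropped with a
    warning carrying the count.
    """
    if phospho.scale != "log2" or protein.scale != "log2":
        raise DataModelError("phospho-state expects log2-normalized inputs")
    if list(phospho.sample_ids) != list(protein.sample_ids):
        raise DataModelError("phospho and protein matrices must share the same samples in order")
    parent = annotation.phospho_parent_map()
    quantified = set(protein.feature_ids)
    keep, parents = [], []
    for fid in phospho.feature_ids:
        acc = parent.get(fid)
        if acc is not None and acc in quantified:
            keep.append(fid)
            parents.append(acc)
    n_dropped = len(phospho.feature_ids) - len(keep)
    if n_dropped:
        warnings.warn(f"{n_dropped} phosphopeptide(s) without a quantified parent protein dropped", stacklevel=2)
    if not keep:
        raise DataModelError("no phosphopeptide has a quantified parent protein")
    state = phospho.values.loc[keep].to_numpy() - protein.values.loc[parents].to_numpy()
    return IntensityMatrix(
        pd.DataFrame(state, index=keep, columns=phospho.sample_ids), layer="phospho_state", scale="log2"
    )


def compute_stoichiometry(
    acetyl: IntensityMatrix,
    annotation: FeatureAnnotation,
    strict_pairs: bool = False,
) -> pd.DataFrame:
    """Per-site, per-sample occupancy ratios ``d0 / (d0 + d3)`` in [0, 1].

    When one channel is missing the ratio is algebraically forced if the
    absence is real (d3 absent -> fully occupied, 1.0; d0 absent -> 0.0); this
    permissive default maximizes site coverage.  ``strict_pairs`` instead
    requires both channels and leaves half-pairs missing.
    """
    if acetyl.scale != "raw":
        raise DataModelError("stoichiometry expects raw-scale channel intensities")
    pairs = annotation.acetyl_pairs()
    if pairs.empty:
        raise DataModelError("annotation contains no acetyl channel pairs")
    values = acetyl.values
    out = {}
    for site_key, row in pairs.iterrows():
        d0_id, d3_id = row.get("d0"), row.get("d3")
        d0 = values.loc[d0_id] if isinstance(d0_id, str) and d0_id in values.index else pd.Series(np.nan, index=values.columns)
        d3 = values.loc[d3_id] if isinstance(d3_id, str) and d3_id in values.index else pd.Series(np.nan, index=values.columns)
        ratio = d0 / (d0 + d3)
        if not strict_pairs:
            ratio = ratio.where(~(d0.notna() & d3.isna()), 1.0)
            ratio = ratio.where(~(d0.isna() & d3.notna()), 0.0)
        out[site_key] = ratio
    table = pd.DataFrame(out).T
    table.index.name = "site_key"
    return table


def compare_stoichiometry(
    table: pd.DataFrame,
    samples: SampleTable,
    min_valid: float = STOICH_MIN_VALID,
) -> pd.DataFrame:
    """Two-sided Wilcoxon on occupancy ratios per site, 40%-validity gated.

    Sites with under ``min_valid`` valid ratios in either disease group are
    skipped (no imputation is ever applied to occupancies).
    """
    group = samples.group_of().reindex(table.columns)
    if group.isna().any():
        raise DataModelError("ratio table contains samples absent from the sample table")
    ad_cols = table.columns[(group == "AD").to_numpy()]
    ctl_cols = table.columns[(group == "control").to_numpy()]
    rows = []
    for site_key, ratios in table.iterrows():
        ad = ratios[ad_cols].dropna()
        ctl = ratios[ctl_cols].dropna()
        if len(ad) / len(ad_cols) < min_valid - 1e-12 or len(ctl) / len(ctl_cols) < min_valid - 1e-12:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = wilcoxon_rank_sum(ad.to_numpy(), ctl.to_numpy())
        med_ad, med_ctl = float(ad.median()), float(ctl.median())
        rows.append(
            {
                "site_key": site_key,
                "p_value": p,
                "median_ratio_ad": med_ad,
                "median_ratio_control": med_ctl,
                "direction": "up" if med_ad > med_ctl else ("down" if med_ad < med_ctl else "none"),
            }
        )
    return pd.DataFrame(rows, columns=["site_key", "p_value", "median_ratio_ad", "median_ratio_control", "direction"])


def stoichiometry_validity(table: pd.DataFrame, samples: SampleTable) -> pd.DataFrame:
    """Validity profile of the ratio table, for the qualitative ON/OFF rule."""
    group = samples.group_of().reindex(table.columns)
    n_ad = int((group == "AD").sum())
    n_ctl = int((group == "control").sum())
    present = table.notna()
    valid_ad = present.loc[:, (group == "AD").to_numpy()].sum(axis=1)
    valid_ctl = present.loc[:, (group == "control").to_numpy()].sum(axis=1)
    return pd.DataFrame(
        {
            "feature_id": table.index,
            "n_ad": n_ad,
            "n_control": n_ctl,
            "n_valid_ad": valid_ad.to_numpy(),
            "n_valid_control": valid_ctl.to_numpy(),
            "frac_valid_ad": valid_ad.to_numpy() / n_ad,
            "frac_valid_control": valid_ctl.to_numpy() / n_ctl,
        }
    )
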