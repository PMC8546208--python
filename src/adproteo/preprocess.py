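"""Per-region pre-processing: replicate merging, log2 + median normalization,
validity filtering and downshifted-normal imputation.

The filtering rules operate on the fraction of valid (non-missing) values per
disease group:

* qualitative ON/OFF — at least 70% valid in one group and under 10% in the
  other;
* quantitative — at least 66% valid in both groups, plus "on-off-like"
  features (under 33% in one group, at least 66% in the other).

Missing values of retained features are imputed per sample column from a
normal distribution shrunk to ``width`` times the column SD and shifted down
by ``downshift`` column SDs — the standard left-censored (MNAR) replacement
for label-free intensities.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import DataModelError, IntensityMatrix, SampleTable, collapse_replicates

#: guard for >= / < comparisons against decimal thresholds (0.70, 0.66, ...)
#: whose binary doubles may sit a ulp away from an exact count ratio
_EPS = 1e-12

QUALITATIVE_HIGH = 0.70
QUALITATIVE_LOW = 0.10
QUANTITATIVE_MIN = 0.66
ON_OFF_LIKE_MAX = 0.33


@dataclass
class ImputationParams:
    """Downshifted-normal imputation parameters (in units of per-sample SD)."""

    width: float = 0.3
    downshift: float = 1.8
    seed: int = 0

    def __post_init__(self):
        if self.width <= 0:
            raise DataModelError("imputation width must be > 0")


def merge_technical_replicates(matrix: IntensityMatrix, samples: SampleTable) -> IntensityMatrix:
    """Median-average technical replicates into one column per (brain, region).

    The median is taken over present values only; a cell missing in every
    replicate stays missing.  Without replicates the matrix is unchanged.
    """
    if not samples.has_replicates():
        return matrix
    f = samples.frame.set_index("sample_id")
    merged_id = (f["brain_id"] + "_" + f["region"]).reindex(matrix.sample_ids)
    if merged_id.isna().any():
        raise DataModelError("matrix contains samples absent from the sample table")
    merged = matrix.values.T.groupby(merged_id.to_numpy()).median().T
    # keep first-appearance column order
    order = list(dict.fromkeys(merged_id))
    return IntensityMatrix(merged.loc[:, order], matrix.layer, matrix.scale)


def log2_median_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """log2-transform and subtract each sample's median of present values."""
    if matrix.scale != "raw":
        raise DataModelError("matrix is already on the log2 scale")
    if matrix.values.notna().sum(axis=0).eq(0).any():
        empty = matrix.values.columns[matrix.values.notna().sum(axis=0) == 0][0]
        raise DataModelError(f"sample {empty!r} has no present values")
    log2 = np.log2(matrix.values)
    normalized = log2 - log2.median(axis=0, skipna=True)
    return IntensityMatrix(normalized, matrix.layer, scale="log2")


def compute_validity(matrix: IntensityMatrix, samples: SampleTable) -> pd.DataFrame:
    """Per-feature valid-value fractions in each disease group.

    Returns a frame with columns ``feature_id, n_ad, n_control, n_valid_ad,
    n_valid_control, frac_valid_ad, frac_valid_control`` (fractions are exact
    count ratios).
    """
    group = samples.group_of().reindex(matrix.sample_ids)
    if group.isna().any():
        raise DataModelError("matrix contains samples absent from the sample table")
    n_ad = int((group == "AD").sum())
    n_control = int((group == "control").sum())
    if n_ad == 0 or n_control == 0:
        raise DataModelError("both disease groups must have at least one sample")
    present = matrix.values.notna()
    valid_ad = present.loc[:, (group == "AD").to_numpy()].sum(axis=1)
    valid_control = present.loc[:, (group == "control").to_numpy()].sum(axis=1)
    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "n_ad": n_ad,
            "n_control": n_control,
            "n_valid_ad": valid_ad.to_numpy(),
            "n_valid_control": valid_control.to_numpy(),
            "frac_valid_ad": valid_ad.to_numpy() / n_ad,
            "frac_valid_control": valid_control.to_numpy() / n_control,
        }
    )


def _ge(x: np.ndarray, threshold: float) -> np.ndarray:
    return x >= threshold - _EPS


def _lt(x: np.ndarray, threshold: float) -> np.ndarray:
    return x < threshold - _EPS


def classify_on_off(
    profiles: pd.DataFrame,
    high: float = QUALITATIVE_HIGH,
    low: float = QUALITATIVE_LOW,
) -> pd.DataFrame:
    """Qualitative ON/OFF rule: >=70% valid in one group, <10% in the other."""
    ad = profiles["frac_valid_ad"].to_numpy(float)
    ctl = profiles["frac_valid_control"].to_numpy(float)
    status = np.full(len(profiles), "none", dtype=object)
    status[_ge(ad, high) & _lt(ctl, low)] = "qualitative_on_AD"
    status[_ge(ctl, high) & _lt(ad, low)] = "qualitative_off_AD"
    return pd.DataFrame({"feature_id": profiles["feature_id"].to_numpy(), "status": status})


def filter_quantitative(
    profiles: pd.DataFrame,
    min_valid: float = QUANTITATIVE_MIN,
    on_off_max: float = ON_OFF_LIKE_MAX,
) -> pd.DataFrame:
    """Quantitative admission rule: >=66% in both groups, or on-off-like
    (<33% in one group and >=66% in the other)."""
    ad = profiles["frac_valid_ad"].to_numpy(float)
    ctl = profiles["frac_valid_control"].to_numpy(float)
    status = np.full(len(profiles), "excluded", dtype=object)
    status[_ge(ad, min_valid) & _ge(ctl, min_valid)] = "quantitative"
    on_off = (_lt(ad, on_off_max) & _ge(ctl, min_valid)) | (_lt(ctl, on_off_max) & _ge(ad, min_valid))
    status[on_off] = "on_off_like"
    return pd.DataFrame({"feature_id": profiles["feature_id"].to_numpy(), "status": status})


def _column_rng(seed: int, sample_id: str) -> np.random.Generator:
    # substream keyed by the sample id so draws do not depend on column order
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(sample_id.encode())])


def impute_downshifted_normal(matrix: IntensityMatrix, params: ImputationParams) -> IntensityMatrix:
    """Replace missing cells column-wise from N(mean - downshift*sd, (width*sd)^2).

    ``mean``/``sd`` are the per-sample statistics of the present (normalized)
    log2 values.  Present values are untouched; draws are reproducible under a
    fixed seed and independent of column order.
    """
    if matrix.scale != "log2":
        raise DataModelError("imputation expects log2-normalized intensities")
    out = matrix.values.copy()
    for sample_id in out.columns:
        col = out[sample_id]
        present = col.dropna()
        n_missing = len(col) - len(present)
        if n_missing == 0:
            continue
        if len(present) < 2:
            raise DataModelError(f"sample {sample_id!r} has fewer than 2 present values; SD undefined")
        mean, sd = float(present.mean()), float(present.std(ddof=1))
        rng = _column_rng(params.seed, sample_id)
        draws = rng.normal(mean - params.downshift * sd, params.width * sd, size=n_missing)
        out.loc[col.isna(), sample_id] = draws
    return IntensityMatrix(out, matrix.layer, scale="log2")


@dataclass
class RegionPreprocessResult:
    """Everything pre-processing produces for one region and layer."""

    region: str
    samples: SampleTable  # replicate-collapsed, region-restricted
    normalized: IntensityMatrix  # log2, median-centred, missing retained
    validity: pd.DataFrame
    qualitative: pd.DataFrame  # ON/OFF decisions, all features
    quantitative: pd.DataFrame  # quantitative/on_off_like/excluded, all features
    imputed: IntensityMatrix  # retained features only, fully imputed


def preprocess_region(
    matrix: IntensityMatrix,
    samples: SampleTable,
    region: str,
    params: ImputationParams | None = None,
) -> RegionPreprocessResult:
    """Run the full per-region chain on one layer.

    Order of operations: restrict to the region, median-average technical
    replicates on the raw scale, log2 + median normalize, compute validity,
    apply the qualitative and quantitative rules, impute only the retained
    (quantitative or on-off-like) features.
    """
    params = params or ImputationParams()
    region_samples = samples.for_region(region)
    region_matrix = matrix.subset_samples(region_samples.sample_ids)
    merged = merge_technical_replicates(region_matrix, region_samples)
    collapsed = collapse_replicates(region_samples)
    normalized = log2_median_normalize(merged)
    validity = compute_validity(normalized, collapsed)
    qualitative = classify_on_off(validity)
    quantitative = filter_quantitative(validity)
    retained = quantitative.loc[quantitative["status"] != "excluded", "feature_id"]
    imputed = impute_downshifted_normal(normalized.subset_features(retained), params)
    return RegionPreprocessResult(
        region=region,
        samples=collapsed,
        normalized=normalized,
        validity=validity,
        qualitative=qualitative,
        quantitative=quantitative,
        imputed=imputed,
    )
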