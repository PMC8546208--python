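"""Shared data model for the regional brain proteomics pipeline.

The pipeline operates on three intensity layers (protein groups,
phosphopeptides, paired d0/d3 acetyl channels) measured over a case/control
cohort sampled in four brain regions (hippocampus HP, hippocampal subfield
CA1, entorhinal cortex EC, perirhinal cortex PRC).  All tables are thin,
validated wrappers around pandas objects; missing intensities are always
``NaN`` — never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

REGIONS: tuple[str, ...] = ("HP", "CA1", "EC", "PRC")
GROUPS: tuple[str, ...] = ("AD", "control")
SEXES: tuple[str, ...] = ("M", "F")
LAYERS: tuple[str, ...] = ("protein", "phosphopeptide", "acetyl", "phospho_state")
COVARIATES: tuple[str, ...] = ("sex", "age", "pmi")

SAMPLE_COLUMNS = ["sample_id", "brain_id", "region", "group", "sex", "age", "pmi", "tech_rep"]


class DataModelError(ValueError):
    """Raised when an input table violates the data-model invariants."""


class SampleTable:
    """Per-sample design metadata (group, region, covariates, replicates).

    Invariants enforced at construction:

    * ``sample_id`` unique; ``(brain_id, region, tech_rep)`` unique;
    * each ``brain_id`` carries exactly one group, sex, age and PMI;
    * region/group/sex labels come from the closed vocabularies above.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in SAMPLE_COLUMNS if c not in frame.columns]
        if missing:
            raise DataModelError(f"sample table missing columns: {missing}")
        frame = frame.loc[:, SAMPLE_COLUMNS].reset_index(drop=True).copy()
        frame["age"] = frame["age"].astype(float)
        frame["pmi"] = frame["pmi"].astype(float)
        frame["tech_rep"] = frame["tech_rep"].astype(int)

        if frame["sample_id"].duplicated().any():
            dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise DataModelError(f"duplicate sample_id: {dup!r}")
        key = frame[["brain_id", "region", "tech_rep"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise DataModelError(f"duplicate (brain_id, region, tech_rep): {key[key.duplicated()].iloc[0]}")
        for col, allowed in (("region", REGIONS), ("group", GROUPS), ("sex", SEXES)):
            bad = set(frame[col]) - set(allowed)
            if bad:
                raise DataModelError(f"unknown {col} label(s): {sorted(bad)}")
        for col in ("age", "pmi"):
            if (frame[col] <= 0).any():
                raise DataModelError(f"{col} must be positive")
        if (frame["tech_rep"] < 1).any():
            raise DataModelError("tech_rep must be >= 1")
        per_brain = frame.groupby("brain_id")[["group", "sex", "age", "pmi"]].nunique()
        bad_brains = per_brain.index[(per_brain > 1).any(axis=1)]
        if len(bad_brains):
            raise DataModelError(f"brain(s) with inconsistent metadata: {list(bad_brains)}")
        self.frame = frame

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def for_region(self, region: str) -> "SampleTable":
        if region not in REGIONS:
            raise DataModelError(f"unknown region label: {region!r}")
        return SampleTable(self.frame[self.frame["region"] == region])

    def group_of(self) -> pd.Series:
        """group label indexed by sample_id."""
        return self.frame.set_index("sample_id")["group"]

    def n_per_group(self) -> dict[str, int]:
        counts = self.frame["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS}

    def has_replicates(self) -> bool:
        return bool((self.frame["tech_rep"] > 1).any())

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleTable) and self.frame.equals(other.frame)


def collapse_replicates(samples: SampleTable) -> SampleTable:
    """One row per (brain, region); merged sample id is ``{brain}_{region}``.

    If no technical replicates exist the table is returned unchanged so that
    sample ids stay stable through :func:`preprocess.merge_technical_replicates`.
    """
    if not samples.has_replicates():
        return samples
    frame = samples.frame.drop_duplicates(subset=["brain_id", "region"]).copy()
    frame["sample_id"] = frame["brain_id"] + "_" + frame["region"]
    frame["tech_rep"] = 1
    return SampleTable(frame)


@dataclass
class IntensityMatrix:
    """Features x samples abundance table for one omic layer.

    ``values`` is a DataFrame indexed by feature id with sample-id columns;
    missing measurements are ``NaN``.  ``scale`` is ``"raw"`` (strictly
    positive intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    layer: str
    scale: str = "raw"

    def __post_init__(self):
        if self.layer not in LAYERS:
            raise DataModelError(f"unknown layer: {self.layer!r}")
        if self.scale not in ("raw", "log2"):
            raise DataModelError(f"unknown scale: {self.scale!r}")
        idx = self.values.index
        if idx.duplicated().any():
            raise DataModelError(f"duplicate feature id: {idx[idx.duplicated()][0]!r}")
        if pd.Index(self.values.columns).duplicated().any():
            raise DataModelError("duplicate sample columns")
        vals = self.values.to_numpy(dtype=float)
        if self.scale == "raw" and np.nanmin(vals, initial=np.inf) <= 0:
            raise DataModelError("raw-scale intensities must be strictly positive (missing is NaN, never 0)")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def subset_samples(self, sample_ids: Iterable[str]) -> "IntensityMatrix":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.values.columns]
        if missing:
            raise DataModelError(f"sample id(s) not in matrix: {missing[:5]}")
        return IntensityMatrix(self.values.loc[:, ids].copy(), self.layer, self.scale)

    def subset_features(self, feature_ids: Iterable[str]) -> "IntensityMatrix":
        return IntensityMatrix(self.values.loc[list(feature_ids)].copy(), self.layer, self.scale)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, IntensityMatrix)
            and self.layer == other.layer
            and self.scale == other.scale
            and self.values.equals(other.values)
        )


class FeatureAnnotation:
    """Feature-level annotation: parent protein, PTM sites, acetyl channel.

    For the acetyl layer every ``site_key`` groups at most one endogenous (d0)
    and one chemically labelled (d3) channel of the same peptide.
    """

    COLUMNS = ["feature_id", "protein_accession", "peptide_sequence", "ptm_sites", "acetyl_channel", "site_key"]

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for col in self.COLUMNS:
            if col not in frame.columns:
                frame[col] = ""
        frame = frame.loc[:, self.COLUMNS].fillna("").astype(str).reset_index(drop=True)
        if frame["feature_id"].duplicated().any():
            raise DataModelError("duplicate feature_id in annotation")
        bad = set(frame["acetyl_channel"]) - {"", "d0", "d3"}
        if bad:
            raise DataModelError(f"unknown acetyl channel(s): {sorted(bad)}")
        acetyl = frame[frame["acetyl_channel"] != ""]
        counts = acetyl.groupby(["site_key", "acetyl_channel"]).size()
        if (counts > 1).any():
            raise DataModelError("a site_key maps to more than one feature per acetyl channel")
        self.frame = frame

    def phospho_parent_map(self) -> pd.Series:
        """feature_id -> protein accession (empty accessions dropped)."""
        f = self.frame[self.frame["protein_accession"] != ""]
        return f.set_index("feature_id")["protein_accession"]

    def acetyl_pairs(self) -> pd.DataFrame:
        """One row per site_key with columns d0/d3 holding feature ids (or NaN)."""
        acetyl = self.frame[self.frame["acetyl_channel"] != ""]
        return acetyl.pivot(index="site_key", columns="acetyl_channel", values="feature_id")


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. Hallmark-style GMT content)."""

    sets: Mapping[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        clean: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            uniq = list(dict.fromkeys(members))
            if not uniq:
                raise DataModelError(f"gene set {name!r} is empty")
            clean[name] = uniq
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def filtered(self, universe: Iterable[str], min_size: int = 1, max_size: int | None = None) -> "GeneSetCollection":
        uni = set(universe)
        out = {}
        for name, members in self.sets.items():
            present = [m for m in members if m in uni]
            if len(present) >= min_size and (max_size is None or len(present) <= max_size):
                out[name] = present
        return GeneSetCollection(out)
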