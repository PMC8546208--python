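"""Readers and writers for the pipeline's plain-text formats.

Matrices and metadata travel as tab-separated text; gene sets as GMT;
annotation lists as newline-delimited accessions.  Missing intensities are an
empty cell or ``NA`` on read and are written back as ``NA`` — a zero is a
measured value, never a stand-in for missing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    DataModelError,
    FeatureAnnotation,
    GeneSetCollection,
    IntensityMatrix,
    SampleTable,
)

_NA_VALUES = ["", "NA"]


def read_intensity_matrix(path, layer: str, scale: str = "raw", samples: SampleTable | None = None) -> IntensityMatrix:
    """Read a features-x-samples TSV (first column feature ids, header sample ids)."""
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=_NA_VALUES, keep_default_na=False)
    frame.index = frame.index.astype(str)
    frame.index.name = "feature_id"
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise DataModelError(f"duplicate feature id in {path}: {dup!r}")
    values = frame.astype(float)
    if scale == "raw" and np.nanmin(values.to_numpy(), initial=np.inf) < 0:
        raise DataModelError(f"negative intensity in {path}")
    matrix = IntensityMatrix(values, layer=layer, scale=scale)
    if samples is not None:
        unknown = set(matrix.sample_ids) - set(samples.sample_ids)
        if unknown:
            raise DataModelError(f"matrix columns not in sample table: {sorted(unknown)[:5]}")
    return matrix


def write_intensity_matrix(matrix: IntensityMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_sample_table(path) -> SampleTable:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "brain_id": str})
    return SampleTable(frame)


def write_sample_table(samples: SampleTable, path) -> None:
    samples.frame.to_csv(path, sep="\t", index=False)


def read_feature_annotation(path) -> FeatureAnnotation:
    frame = pd.read_csv(path, sep="\t", dtype=str, na_values=_NA_VALUES, keep_default_na=False)
    return FeatureAnnotation(frame.fillna(""))


def write_feature_annotation(annotation: FeatureAnnotation, path) -> None:
    annotation.frame.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name, description, then members, tab-separated."""
    sets: dict[str, list[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataModelError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise DataModelError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [m for m in fields[2:] if m]
            sets[name] = list(dict.fromkeys(members))
    if not sets:
        raise DataModelError(f"{path}: no gene sets found")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as handle:
        for name, members in collection.sets.items():
            handle.write("\t".join([name, "na", *members]) + "\n")


def read_accession_list(path) -> list[str]:
    """Plain newline-delimited accession list (AMP / kinase annotation input)."""
    with open(path) as handle:
        ids = [line.strip() for line in handle if line.strip()]
    if not ids:
        raise DataModelError(f"{path}: empty accession list")
    return list(dict.fromkeys(ids))


def write_accession_list(ids, path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))
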