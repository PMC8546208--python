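"""Set-based annotation of quantified features against curated accession
lists (antimicrobial peptides, kinases, or any custom list)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .datamodel import DataModelError


@dataclass
class AnnotationReport:
    """Per-region detection of list members plus dysregulation bookkeeping."""

    list_name: str
    detected: dict[str, set[str]]  # region -> detected accessions
    all_regions: set[str]
    counts: dict[str, int]
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def annotate_against_list(
    quantified: Mapping[str, Iterable[str]],
    accessions: Iterable[str],
    list_name: str = "custom",
    results: pd.DataFrame | None = None,
) -> AnnotationReport:
    """Intersect per-region quantified accessions with a curated list.

    ``quantified`` maps region to the accessions quantified there.  The
    report carries per-region detections, the all-region intersection and
    Venn-style counts; if a differential table (``feature_id``/``region``/
    ``retained``/``direction`` columns) is given, each detected id is joined
    with its dysregulation status per region.
    """
    listed = list(dict.fromkeys(accessions))
    if not listed:
        raise DataModelError("empty accession list")
    listed_set = set(listed)
    detected = {region: set(ids) & listed_set for region, ids in quantified.items()}
    if not detected:
        raise DataModelError("no regions supplied")
    all_regions = set.intersection(*detected.values())
    union = set.union(*detected.values())
    counts = {f"detected_{region}": len(ids) for region, ids in detected.items()}
    counts["detected_any_region"] = len(union)
    counts["detected_all_regions"] = len(all_regions)

    rows = []
    status_map = {}
    if results is not None and len(results):
        for _, rec in results.iterrows():
            key = (rec["feature_id"], rec["region"])
            if rec.get("retained", False):
                status_map[key] = rec.get("direction", "changed")
    for acc in sorted(union):
        row = {"accession": acc, "in_all_regions": acc in all_regions}
        for region in quantified:
            if acc not in detected[region]:
                row[region] = "absent"
            else:
                row[region] = status_map.get((acc, region), "detected")
        rows.append(row)
    table = pd.DataFrame(rows)
    return AnnotationReport(
        list_name=list_name, detected=detected, all_regions=all_regions, counts=counts, table=table
    )


def detect_kinases(
    protein_quantified: Mapping[str, Iterable[str]],
    phospho_parent_accessions: Mapping[str, Iterable[str]],
    kinase_list: Iterable[str],
) -> AnnotationReport:
    """Kinome detection: combine global and phospho layers per region."""
    combined = {
        region: set(protein_quantified.get(region, ())) | set(phospho_parent_accessions.get(region, ()))
        for region in set(protein_quantified) | set(phospho_parent_accessions)
    }
    return annotate_against_list(combined, kinase_list, list_name="kinase")
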