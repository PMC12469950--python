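"""End-to-end kinship pipeline: genotypes + metadata + mtDNA profiles in,
breeder estimate out.  Thin glue over the per-module operations."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import ibs, mtdna, pedigree
from .matrix import GenotypeMatrix


@dataclass
class KinshipPipelineResult:
    ibs: ibs.IBSMatrix
    normalized: ibs.NormalizedIBSMatrix
    anchor_groups: tuple[str, str] | None
    lineages: mtdna.LineageAssignment
    calls: list[ibs.KinshipCall]
    estimate: pedigree.BreederEstimate


def run_kinship_pipeline(
    genotypes: GenotypeMatrix,
    metadata: pd.DataFrame,
    profiles: list[mtdna.RepeatProfile],
    anchor_by: str = "nest",
    min_overlap: int = 500,
    thresholds: ibs.KinshipThresholds | None = None,
    link_threshold: float = 0.5,
    detection_threshold: float = 0.05,
    min_gap_days: int = 7,
) -> KinshipPipelineResult:
    """IBS -> anchored normalization -> calls -> lineages -> breeder estimate.

    ``anchor_by`` selects the grouping used to pick the two most distinct
    groups for the normalization anchor: ``"nest"`` (default, the natural
    unit when nest labels exist) or ``"site"``.
    """
    md = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    group_col = {"nest": "nest_id", "site": "site"}[anchor_by]
    groups = {s: str(md.loc[s, group_col]) for s in genotypes.sample_ids if s in md.index}

    raw = ibs.ibs_matrix(genotypes, min_overlap=min_overlap)
    av_min, pair = ibs.anchor_value(raw, groups)
    normalized = ibs.normalize_ibs(raw, av_min)
    normalized.anchor_groups = pair
    calls = ibs.classify_matrix(normalized, thresholds)

    nests = {s: str(md.loc[s, "nest_id"]) for s in genotypes.sample_ids if s in md.index}
    lineages = mtdna.assign_maternal_lineages(
        profiles,
        link_threshold=link_threshold,
        nests=nests,
        detection_threshold=detection_threshold,
    )
    nest_profiles = mtdna.nest_consensus_profiles(
        profiles, nests, detection_threshold=detection_threshold
    )

    estimate = pedigree.estimate_breeders(
        calls,
        lineages,
        metadata,
        min_gap_days=min_gap_days,
        nest_profiles=nest_profiles,
    )
    return KinshipPipelineResult(raw, normalized, pair, lineages, calls, estimate)
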