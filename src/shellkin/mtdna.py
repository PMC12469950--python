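"""mtDNA 3' D-loop tandem-repeat haplotyping.

The 3' end of the control region carries a variable number of copies of an
8-bp repeat motif ("TATATATC").  Individuals are heteroplasmic: a PCR of the
region yields a ladder of bands, one per repeat copy number present, with
intensities proportional to the fraction of mtDNA molecules carrying that
copy number.  Because mtDNA is maternally transmitted through a bottleneck,
offspring of one female share her band *support* while the fractions drift,
which makes thresholded band profiles a maternal-lineage marker.

This module does the arithmetic (amplicon sizes), profile comparison
(Bray-Curtis similarity on band fractions) and single-linkage maternal
lineage assignment with a one-mother-per-nest constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

#: Length of the amplified flanking sequence outside the repeat array, in bp.
#: Calibrated from the primer pair used for this marker: a 13-copy allele
#: amplifies at 193 bp, so flank = 193 - 13*8.  Override for other primers.
FLANK_BP = 89

#: Repeat motif length in bp.
MOTIF_BP = 8


def amplicon_length(copies: int, flank_bp: int = FLANK_BP) -> int:
    """Amplicon size in bp for an allele with ``copies`` repeat units.

    Affine in the copy number with slope exactly ``MOTIF_BP``:
    13 copies -> 193 bp, 26 copies -> 297 bp.
    """
    if copies < 0:
        raise ValueError(f"repeat copy number must be >= 0, got {copies}")
    return flank_bp + MOTIF_BP * int(copies)


@dataclass
class RepeatProfile:
    """Per-individual distribution of repeat copy numbers.

    ``bands`` maps copy number (int >= 1) to an intensity fraction in (0, 1].
    Fractions are expected to sum to ~1 for a freshly measured profile;
    thresholding and renormalization happen in :func:`pattern_from_profile`
    and :func:`profile_similarity`.
    """

    sample_id: str
    bands: dict[int, float]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError(f"{self.sample_id}: empty repeat profile")
        for c, f in self.bands.items():
            if int(c) < 1:
                raise ValueError(f"{self.sample_id}: copy number {c} < 1")
            if not (0.0 < f <= 1.0):
                raise ValueError(f"{self.sample_id}: band fraction {f} outside (0,1]")
        self.bands = {int(c): float(f) for c, f in sorted(self.bands.items())}

    @property
    def dominant_copy_number(self) -> int:
        """Copy number of the strongest band; ties break toward more copies."""
        best = max(self.bands.items(), key=lambda cf: (cf[1], cf[0]))
        return best[0]

    def thresholded(self, detection_threshold: float) -> dict[int, float]:
        """Bands at or above the detection threshold, renormalized to sum 1."""
        kept = {c: f for c, f in self.bands.items() if f >= detection_threshold}
        if not kept:
            raise ValueError(
                f"{self.sample_id}: no band reaches detection threshold "
                f"{detection_threshold}"
            )
        total = sum(kept.values())
        return {c: f / total for c, f in kept.items()}


@dataclass
class BandPattern:
    """Detectable gel pattern derived from a profile: sorted amplicon sizes."""

    sample_id: str
    copies: list[int]
    fractions: list[float]
    amplicon_lengths: list[int]


def pattern_from_profile(
    profile: RepeatProfile,
    detection_threshold: float = 0.05,
    flank_bp: int = FLANK_BP,
) -> BandPattern:
    """Drop bands below the detection threshold and compute amplicon sizes."""
    if not (0.0 <= detection_threshold < 1.0):
        raise ValueError("detection threshold must be in [0, 1)")
    kept = profile.thresholded(detection_threshold)
    copies = sorted(kept)
    return BandPattern(
        sample_id=profile.sample_id,
        copies=copies,
        fractions=[kept[c] for c in copies],
        amplicon_lengths=[amplicon_length(c, flank_bp) for c in copies],
    )


def profile_similarity(
    a: RepeatProfile, b: RepeatProfile, detection_threshold: float = 0.0
) -> float:
    """1 - Bray-Curtis dissimilarity between thresholded fraction vectors.

    Since both thresholded vectors sum to 1 this reduces to the shared mass
    ``sum_c min(a_c, b_c)``: 1 for identical profiles, 0 for disjoint
    copy-number supports.  Symmetric by construction.
    """
    fa = a.thresholded(detection_threshold) if detection_threshold else a.thresholded(0.0)
    fb = b.thresholded(detection_threshold) if detection_threshold else b.thresholded(0.0)
    return float(sum(min(fa.get(c, 0.0), fb.get(c, 0.0)) for c in set(fa) | set(fb)))


@dataclass
class LineageAssignment:
    """Maternal-lineage labels per sample plus a representative profile each."""

    assignments: dict[str, str]
    representatives: dict[str, dict[int, float]] = field(default_factory=dict)

    def label(self, sample_id: str) -> str:
        return self.assignments[sample_id]

    def partition(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, lab in self.assignments.items():
            out.setdefault(lab, []).append(s)
        return {lab: sorted(ms) for lab, ms in out.items()}


def assign_maternal_lineages(
    profiles: list[RepeatProfile],
    link_threshold: float = 0.5,
    nests: dict[str, str] | None = None,
    detection_threshold: float = 0.05,
) -> LineageAssignment:
    """Single-linkage clustering of profiles into maternal lineages.

    Two samples are linked when their profile similarity reaches
    ``link_threshold``; samples from the same nest are pre-linked because a
    nest has exactly one mother.  Single linkage is deliberate: bottleneck
    drift makes sibling profiles chain-like rather than spherical.  Labels
    are canonical (``L01``, ``L02``, ... ordered by smallest member ID), so
    the result is invariant to the input order of profiles.
    """
    if not profiles:
        raise ValueError("no profiles to cluster")
    by_id = {p.sample_id: p for p in profiles}
    if len(by_id) != len(profiles):
        raise ValueError("duplicate sample IDs among profiles")
    ids = sorted(by_id)

    g = nx.Graph()
    g.add_nodes_from(ids)
    if nests:
        by_nest: dict[str, list[str]] = {}
        for s in ids:
            if s in nests:
                by_nest.setdefault(str(nests[s]), []).append(s)
        for members in by_nest.values():
            for a, b in zip(members, members[1:]):
                g.add_edge(a, b)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if profile_similarity(by_id[a], by_id[b], detection_threshold) >= link_threshold:
                g.add_edge(a, b)

    clusters = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    assignments: dict[str, str] = {}
    representatives: dict[str, dict[int, float]] = {}
    for k, members in enumerate(clusters, start=1):
        label = f"L{k:02d}"
        pooled: dict[int, float] = {}
        for s in members:
            assignments[s] = label
            for c, f in by_id[s].thresholded(detection_threshold).items():
                pooled[c] = pooled.get(c, 0.0) + f
        total = sum(pooled.values())
        representatives[label] = {c: f / total for c, f in sorted(pooled.items())}
    return LineageAssignment(assignments, representatives)


def nest_consensus_profiles(
    profiles: list[RepeatProfile],
    nests: dict[str, str],
    detection_threshold: float = 0.05,
) -> dict[str, RepeatProfile]:
    """Pooled repeat profile per nest: the clutch's estimate of its mother.

    Averaging thresholded fractions over all sampled clutch members undoes
    most of the per-offspring bottleneck noise, so consensus profiles track
    the maternal pool much more closely than any single hatchling does.
    """
    pooled: dict[str, dict[int, float]] = {}
    counts: dict[str, int] = {}
    for p in profiles:
        nest = nests.get(p.sample_id)
        if nest is None:
            continue
        acc = pooled.setdefault(str(nest), {})
        for c, f in p.thresholded(detection_threshold).items():
            acc[c] = acc.get(c, 0.0) + f
        counts[str(nest)] = counts.get(str(nest), 0) + 1
    return {
        nest: RepeatProfile(
            f"nest:{nest}", {c: f / counts[nest] for c, f in sorted(acc.items())}
        )
        for nest, acc in pooled.items()
    }


# ---------------------------------------------------------------------------
# TSV interchange


def write_profiles_tsv(profiles: list[RepeatProfile], path) -> None:
    rows = [
        {"sample_id": p.sample_id, "copy_number": c, "fraction": f}
        for p in profiles
        for c, f in p.bands.items()
    ]
    pd.DataFrame(rows, columns=["sample_id", "copy_number", "fraction"]).to_csv(
        path, sep="\t", index=False
    )


def read_profiles_tsv(path) -> list[RepeatProfile]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        out.append(
            RepeatProfile(str(sid), dict(zip(grp["copy_number"].astype(int), grp["fraction"])))
        )
    return out


def write_lineages_tsv(assignment: LineageAssignment, path) -> None:
    df = pd.DataFrame(
        sorted(assignment.assignments.items()), columns=["sample_id", "lineage"]
    )
    df.to_csv(path, sep="\t", index=False)
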