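"""Sibship reconstruction and breeder inference from kinship calls.

Combines three evidence streams — normalized-IBS pair categories, mtDNA
maternal-lineage labels, and nest metadata (nest ID, lay date) — into:

* maternal families (offspring groups sharing one inferred mother),
* paternal groups (full-sib partitions, one inferred father each),
* reproductive events: multiple paternity (a nest spanning >= 2 paternal
  groups), sperm storage (one father's full sibs spanning two clutches of
  one mother laid >= ``min_gap_days`` apart), and repeat clutches (one
  mother with >= 2 nests in a calendar year).

Linking rules
-------------
A *maternal* link between two offspring requires a full- or half-sib call
plus either a shared nest or a shared mtDNA lineage; half-sib-strength
edges between samples with different nests *and* different lineages cannot
be maternal (mtDNA vetoes the mother), but they are exactly the signature
of paternal half sibs, so they are retained as paternal-candidate edges and
used only to merge father identities across maternal families — never to
merge mothers.  Full-sib calls are treated as same-mother links
(hatchling-only sampling excludes parent-offspring pairs; pass
``hatchlings_only=False`` to disable that assumption, in which case
cross-nest full-sib edges with incompatible lineages are also discarded).

With perfect calls the procedure recovers the generating pedigree exactly;
its failure modes on real data are miscalled edges near thresholds and
mtDNA label collisions between unrelated females.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import rand_score

from .ibs import KinshipCall
from .mtdna import LineageAssignment
from .simdata import PedigreeTruth

MATERNAL_CATEGORIES = {"full_sib_or_parent_offspring", "half_sib", "duplicate"}


@dataclass
class SibshipGraph:
    graph: nx.Graph  # nodes: samples; edges kind in {"full", "half"}
    paternal_candidates: list[tuple[str, str, float]]
    metadata: pd.DataFrame  # indexed by sample_id: nest_id, lay_date
    lineages: dict[str, str]


def _meta_index(metadata: pd.DataFrame) -> pd.DataFrame:
    md = metadata.copy()
    if "sample_id" in md.columns:
        md = md.set_index("sample_id")
    return md


def build_sibship_graph(
    calls: list[KinshipCall],
    lineages: LineageAssignment | dict[str, str],
    metadata: pd.DataFrame,
    hatchlings_only: bool = True,
    nest_profiles: dict | None = None,
    nest_match_threshold: float = 0.75,
) -> SibshipGraph:
    """Assemble the sibship graph, applying the mtDNA lineage veto.

    Every sample appearing in the metadata becomes a node (isolated nodes
    are meaningful: single sampled offspring).  Raises if a sample in the
    calls lacks lineage or metadata.

    When per-nest consensus profiles are supplied (see
    :func:`shellkin.mtdna.nest_consensus_profiles`), a cross-nest half-sib
    edge must additionally connect nests whose consensus profiles agree at
    Bray-Curtis similarity >= ``nest_match_threshold``.  This guards the
    main failure mode of lineage labels on a small copy-number alphabet:
    unrelated females sharing a dominant band collide into one
    single-linkage cluster, and any shared father would then masquerade as
    a repeat-nesting mother.  Clutch-level consensus pins down the maternal
    pool tightly enough to break most such ties; edges failing the gate are
    kept as paternal candidates.
    """
    lin = lineages.assignments if isinstance(lineages, LineageAssignment) else dict(lineages)
    md = _meta_index(metadata)
    g = nx.Graph()
    for sid in md.index:
        if sid not in lin:
            raise ValueError(f"sample {sid} has no lineage assignment")
        g.add_node(sid, nest=str(md.loc[sid, "nest_id"]), lineage=lin[sid])

    def nests_match(nest_a: str, nest_b: str) -> bool:
        if nest_profiles is None:
            return True
        pa, pb = nest_profiles.get(nest_a), nest_profiles.get(nest_b)
        if pa is None or pb is None:
            return True
        from .mtdna import profile_similarity

        return profile_similarity(pa, pb) >= nest_match_threshold

    paternal: list[tuple[str, str, float]] = []
    for c in calls:
        if c.category not in MATERNAL_CATEGORIES:
            continue
        for sid in (c.sample_a, c.sample_b):
            if sid not in g:
                raise ValueError(f"sample {sid} missing from metadata")
        nest_a = g.nodes[c.sample_a]["nest"]
        nest_b = g.nodes[c.sample_b]["nest"]
        same_nest = nest_a == nest_b
        same_lineage = g.nodes[c.sample_a]["lineage"] == g.nodes[c.sample_b]["lineage"]
        kind = "full" if c.category in ("full_sib_or_parent_offspring", "duplicate") else "half"
        maternal = same_nest or (kind == "full" and hatchlings_only)
        if not maternal and same_lineage and kind == "half":
            maternal = nests_match(nest_a, nest_b)
        if maternal:
            g.add_edge(c.sample_a, c.sample_b, kind=kind, weight=c.value)
        else:
            paternal.append((c.sample_a, c.sample_b, c.value))
    return SibshipGraph(g, paternal, md, lin)


# ---------------------------------------------------------------------------
# Maternal families


@dataclass
class MaternalFamily:
    family_id: str
    members: list[str]
    nests: list[str]
    lineage: str


def infer_maternal_families(sg: SibshipGraph) -> list[MaternalFamily]:
    """Connected components over sib edges plus same-nest co-membership,
    refined so every family carries a single majority lineage.

    Lineage conflicts (possible only through full-sib edges kept under the
    hatchling assumption) are resolved by majority; minority members whose
    nest majority disagrees are reassigned to the family with the best mean
    edge weight to them, or become singleton families.
    """
    h = sg.graph.copy()
    by_nest: dict[str, list[str]] = {}
    for sid, data in sg.graph.nodes(data=True):
        by_nest.setdefault(data["nest"], []).append(sid)
    for members in by_nest.values():
        for a, b in zip(members, members[1:]):
            h.add_edge(a, b, kind="nest", weight=0.0)

    components = sorted((sorted(c) for c in nx.connected_components(h)), key=lambda c: c[0])
    families: list[list[str]] = []
    for comp in components:
        lineages = {sg.lineages[s] for s in comp}
        if len(lineages) == 1:
            families.append(comp)
            continue
        # majority lineage wins; nests vote as blocks
        counts: dict[str, int] = {}
        for s in comp:
            counts[sg.lineages[s]] = counts.get(sg.lineages[s], 0) + 1
        majority = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        keep, strays = [], []
        for nest in sorted({sg.graph.nodes[s]["nest"] for s in comp}):
            nest_members = [s for s in comp if sg.graph.nodes[s]["nest"] == nest]
            nest_lin = {sg.lineages[s] for s in nest_members}
            if majority in nest_lin or len(nest_lin) > 1:
                keep.extend(nest_members)
            else:
                strays.append(nest_members)
        if keep:
            families.append(sorted(keep))
        families.extend(sorted(s) for s in strays)

    out = []
    for i, members in enumerate(sorted(families, key=lambda m: m[0]), start=1):
        nests = sorted({sg.graph.nodes[s]["nest"] for s in members})
        lin_counts: dict[str, int] = {}
        for s in members:
            lin_counts[sg.lineages[s]] = lin_counts.get(sg.lineages[s], 0) + 1
        lineage = sorted(lin_counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        out.append(MaternalFamily(f"mother_{i:02d}", members, nests, lineage))
    return out


# ---------------------------------------------------------------------------
# Paternal groups


@dataclass
class PaternalGroup:
    group_id: str
    members: list[str]
    family_ids: list[str]
    nests: list[str]


def infer_paternal_groups(
    families: list[MaternalFamily],
    sg: SibshipGraph,
    merge_across_families: bool = True,
) -> list[PaternalGroup]:
    """Full-sib components within each maternal family, one father each;
    father identities merge across families via paternal-candidate edges.

    Within a family, connected components of full-sib edges partition the
    offspring by father (an offspring with no full-sib edge is its own
    group — its father simply sired nobody else sampled).  Two groups in
    *different* families are the same father when any retained
    paternal-candidate (cross-lineage half-sib) edge joins them.
    """
    family_of = {s: fam.family_id for fam in families for s in fam.members}
    group_of: dict[str, int] = {}
    raw_groups: list[list[str]] = []
    for fam in families:
        sub = sg.graph.subgraph(fam.members)
        fs_edges = [(a, b) for a, b, d in sub.edges(data=True) if d["kind"] == "full"]
        fsub = nx.Graph()
        fsub.add_nodes_from(fam.members)
        fsub.add_edges_from(fs_edges)
        for comp in sorted((sorted(c) for c in nx.connected_components(fsub)), key=lambda c: c[0]):
            for s in comp:
                group_of[s] = len(raw_groups)
            raw_groups.append(comp)

    parent = list(range(len(raw_groups)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    if merge_across_families:
        for a, b, _w in sg.paternal_candidates:
            if a not in group_of or b not in group_of:
                continue
            if family_of.get(a) == family_of.get(b):
                continue  # within-family half sibs are maternal, not paternal
            ra, rb = find(group_of[a]), find(group_of[b])
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    merged: dict[int, list[str]] = {}
    for gi, members in enumerate(raw_groups):
        merged.setdefault(find(gi), []).extend(members)
    out = []
    for i, (_root, members) in enumerate(
        sorted(merged.items(), key=lambda kv: sorted(kv[1])[0]), start=1
    ):
        members = sorted(members)
        out.append(
            PaternalGroup(
                f"father_{i:02d}",
                members,
                sorted({family_of[s] for s in members}),
                sorted({sg.graph.nodes[s]["nest"] for s in members}),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Events


@dataclass
class SpermStorageEvent:
    family_id: str
    group_id: str
    nests: tuple[str, str]
    dates: tuple[str, str]
    gap_days: int


@dataclass
class RepeatClutchEvent:
    family_id: str
    year: int
    nests: list[str]
    dates: list[str]
    gaps_days: list[int]


@dataclass
class BreederEstimate:
    families: list[MaternalFamily]
    paternal_groups: list[PaternalGroup]
    n_mothers: int
    n_fathers: int
    nest_father_counts: dict[str, int]
    multiple_paternity_nests: list[str]
    single_offspring_nests: list[str]
    sperm_storage_events: list[SpermStorageEvent]
    repeat_clutch_events: list[RepeatClutchEvent]

    def summary(self) -> dict:
        return {
            "n_mothers": self.n_mothers,
            "n_fathers": self.n_fathers,
            "n_multiple_paternity_nests": len(self.multiple_paternity_nests),
            "n_sperm_storage_events": len(self.sperm_storage_events),
            "n_repeat_clutch_events": len(self.repeat_clutch_events),
        }


def detect_multiple_paternity(
    families: list[MaternalFamily],
    groups: list[PaternalGroup],
    sg: SibshipGraph,
) -> tuple[list[str], list[str]]:
    """Nests whose offspring span >= 2 paternal groups.

    Single-offspring nests can never show paternal substructure and are
    returned separately rather than silently counted as single-father.
    """
    group_of = {s: g.group_id for g in groups for s in g.members}
    nests: dict[str, list[str]] = {}
    for sid, data in sg.graph.nodes(data=True):
        nests.setdefault(data["nest"], []).append(sid)
    flagged, singles = [], []
    for nest in sorted(nests):
        members = nests[nest]
        if len(members) < 2:
            singles.append(nest)
            continue
        if len({group_of[s] for s in members}) >= 2:
            flagged.append(nest)
    return flagged, singles


def _nest_dates(sg: SibshipGraph) -> dict[str, datetime.date]:
    out = {}
    for sid in sg.metadata.index:
        nest = str(sg.metadata.loc[sid, "nest_id"])
        date = sg.metadata.loc[sid, "lay_date"]
        if pd.isna(date):
            continue
        out[nest] = datetime.date.fromisoformat(str(date))
    return out


def detect_sperm_storage(
    families: list[MaternalFamily],
    groups: list[PaternalGroup],
    sg: SibshipGraph,
    min_gap_days: int = 7,
) -> list[SpermStorageEvent]:
    """One father's full sibs spanning two clutches of the same mother.

    Only *within-family* nest spans count (a father appearing in clutches
    of two different mothers is re-mating, not storage), and the clutches
    must be at least ``min_gap_days`` apart to separate storage from one
    nesting event split across days.  Detection rests on cross-nest
    full-sib edges, so the member set used per family is the full-sib
    component, not the merged cross-family father identity.
    """
    dates = _nest_dates(sg)
    family_of = {s: fam.family_id for fam in families for s in fam.members}
    events = []
    for grp in groups:
        by_family: dict[str, list[str]] = {}
        for s in grp.members:
            by_family.setdefault(family_of[s], []).append(s)
        for fam_id in sorted(by_family):
            members = by_family[fam_id]
            # require a full-sib connection across nests within this family
            sub = sg.graph.subgraph(members)
            nests_here = sorted({sg.graph.nodes[s]["nest"] for s in members})
            if len(nests_here) < 2:
                continue
            has_cross_fs = any(
                d["kind"] == "full"
                and sg.graph.nodes[a]["nest"] != sg.graph.nodes[b]["nest"]
                for a, b, d in sub.edges(data=True)
            )
            if not has_cross_fs:
                continue
            dated = [n for n in nests_here if n in dates]
            for i, na in enumerate(dated):
                for nb in dated[i + 1 :]:
                    gap = abs((dates[nb] - dates[na]).days)
                    if gap >= min_gap_days:
                        events.append(
                            SpermStorageEvent(
                                fam_id,
                                grp.group_id,
                                (na, nb),
                                (dates[na].isoformat(), dates[nb].isoformat()),
                                gap,
                            )
                        )
    return events


def detect_repeat_clutches(
    families: list[MaternalFamily], sg: SibshipGraph
) -> list[RepeatClutchEvent]:
    """Maternal families with >= 2 nests laid in the same calendar year."""
    dates = _nest_dates(sg)
    events = []
    for fam in families:
        dated = [(n, dates[n]) for n in fam.nests if n in dates]
        by_year: dict[int, list[tuple[str, datetime.date]]] = {}
        for n, d in dated:
            by_year.setdefault(d.year, []).append((n, d))
        for year in sorted(by_year):
            nests = sorted(by_year[year], key=lambda nd: (nd[1], nd[0]))
            if len(nests) < 2:
                continue
            gaps = [
                (nests[i + 1][1] - nests[i][1]).days for i in range(len(nests) - 1)
            ]
            events.append(
                RepeatClutchEvent(
                    fam.family_id,
                    year,
                    [n for n, _ in nests],
                    [d.isoformat() for _, d in nests],
                    gaps,
                )
            )
    return events


def estimate_breeders(
    calls: list[KinshipCall],
    lineages: LineageAssignment | dict[str, str],
    metadata: pd.DataFrame,
    min_gap_days: int = 7,
    hatchlings_only: bool = True,
    merge_fathers_across_families: bool = True,
    nest_profiles: dict | None = None,
    nest_match_threshold: float = 0.75,
) -> BreederEstimate:
    """Full inference chain: graph -> families -> fathers -> events."""
    sg = build_sibship_graph(
        calls,
        lineages,
        metadata,
        hatchlings_only,
        nest_profiles=nest_profiles,
        nest_match_threshold=nest_match_threshold,
    )
    families = infer_maternal_families(sg)
    groups = infer_paternal_groups(families, sg, merge_fathers_across_families)
    mp_nests, single_nests = detect_multiple_paternity(families, groups, sg)
    storage = detect_sperm_storage(families, groups, sg, min_gap_days)
    repeats = detect_repeat_clutches(families, sg)
    group_of = {s: g.group_id for g in groups for s in g.members}
    nest_counts: dict[str, int] = {}
    for sid, data in sg.graph.nodes(data=True):
        nest_counts.setdefault(data["nest"], 0)
    for nest in nest_counts:
        members = [s for s, d in sg.graph.nodes(data=True) if d["nest"] == nest]
        nest_counts[nest] = len({group_of[s] for s in members})
    return BreederEstimate(
        families=families,
        paternal_groups=groups,
        n_mothers=len(families),
        n_fathers=len(groups),
        nest_father_counts=nest_counts,
        multiple_paternity_nests=mp_nests,
        single_offspring_nests=single_nests,
        sperm_storage_events=storage,
        repeat_clutch_events=repeats,
    )


# ---------------------------------------------------------------------------
# Scoring against simulated truth


@dataclass
class InferenceScore:
    maternal_rand_index: float
    mother_count_error: int
    father_count_error: int
    multiple_paternity_precision: float
    multiple_paternity_recall: float
    sperm_storage_precision: float
    sperm_storage_recall: float
    repeat_clutch_precision: float
    repeat_clutch_recall: float


def _prf(inferred: set, true: set) -> tuple[float, float]:
    precision = len(inferred & true) / len(inferred) if inferred else 1.0
    recall = len(inferred & true) / len(true) if true else 1.0
    return precision, recall


def score_inference(estimate: BreederEstimate, truth: PedigreeTruth) -> InferenceScore:
    """Partition Rand index, signed breeder-count errors, event P/R."""
    true_mother = truth.maternal_partition()
    inferred_family = {s: fam.family_id for fam in estimate.families for s in fam.members}
    samples = sorted(true_mother)
    missing = [s for s in samples if s not in inferred_family]
    if missing:
        raise ValueError(f"sample {missing[0]} absent from the estimate")
    rand = rand_score(
        [true_mother[s] for s in samples], [inferred_family[s] for s in samples]
    )

    mother_err = estimate.n_mothers - truth.n_mothers_participating()
    father_err = estimate.n_fathers - truth.n_fathers_participating()

    true_mp = set(truth.registry.multiple_paternity_nests)
    mp_p, mp_r = _prf(set(estimate.multiple_paternity_nests), true_mp)

    true_storage = {tuple(e["nests"]) for e in truth.registry.sperm_storage_events}
    inf_storage = {tuple(sorted(e.nests)) for e in estimate.sperm_storage_events}
    st_p, st_r = _prf(inf_storage, true_storage)

    # a repeat-clutch event counts as recovered when an inferred event shares
    # at least two nests with it (the repeated nesting itself was detected,
    # even if the family gained or lost a nest elsewhere)
    true_repeat = [frozenset(e["nests"]) for e in truth.registry.repeat_clutch_events]
    inf_repeat = [frozenset(e.nests) for e in estimate.repeat_clutch_events]
    rc_r = (
        sum(any(len(t & i) >= 2 for i in inf_repeat) for t in true_repeat) / len(true_repeat)
        if true_repeat
        else 1.0
    )
    rc_p = (
        sum(any(len(t & i) >= 2 for t in true_repeat) for i in inf_repeat) / len(inf_repeat)
        if inf_repeat
        else 1.0
    )

    return InferenceScore(
        maternal_rand_index=float(rand),
        mother_count_error=int(mother_err),
        father_count_error=int(father_err),
        multiple_paternity_precision=mp_p,
        multiple_paternity_recall=mp_r,
        sperm_storage_precision=st_p,
        sperm_storage_recall=st_r,
        repeat_clutch_precision=rc_p,
        repeat_clutch_recall=rc_r,
    )
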