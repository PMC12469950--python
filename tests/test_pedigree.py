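"""Sibship graph construction, family/father inference and event detection."""

import pandas as pd
import pytest

import shellkin as sk
from shellkin.ibs import KinshipCall
from shellkin.pedigree import (
    build_sibship_graph,
    detect_multiple_paternity,
    detect_repeat_clutches,
    detect_sperm_storage,
    estimate_breeders,
    infer_maternal_families,
    infer_paternal_groups,
)


def meta(rows):
    return pd.DataFrame(rows, columns=["sample_id", "nest_id", "site", "lay_date"])


def call(a, b, v, cat):
    return KinshipCall(a, b, v, 1000, cat)


FS = "full_sib_or_parent_offspring"
HS = "half_sib"


class TestGraph:
    def test_same_nest_triangle_of_full_sib_edges(self):
        md = meta([(s, "N1", "x", "2021-05-01") for s in "abc"])
        calls = [call(*p, 0.45, FS) for p in (("a", "b"), ("a", "c"), ("b", "c"))]
        sg = build_sibship_graph(calls, {s: "L1" for s in "abc"}, md)
        assert sg.graph.number_of_edges() == 3
        assert all(d["kind"] == "full" for *_e, d in sg.graph.edges(data=True))

    def test_lineage_veto_drops_cross_nest_half_sib(self):
        md = meta([("a", "N1", "x", "2021-05-01"), ("b", "N2", "x", "2021-06-01")])
        sg = build_sibship_graph(
            [call("a", "b", 0.25, HS)], {"a": "L1", "b": "L2"}, md
        )
        assert sg.graph.number_of_edges() == 0
        assert sg.paternal_candidates == [("a", "b", 0.25)]

    def test_missing_metadata_names_sample(self):
        md = meta([("a", "N1", "x", "2021-05-01")])
        with pytest.raises(ValueError, match="b"):
            build_sibship_graph([call("a", "b", 0.45, FS)], {"a": "L1", "b": "L1"}, md)

    def test_unrelated_calls_never_create_edges(self):
        md = meta([("a", "N1", "x", "2021-05-01"), ("b", "N1", "x", "2021-05-01")])
        sg = build_sibship_graph(
            [call("a", "b", 0.02, "unrelated")], {"a": "L1", "b": "L1"}, md
        )
        assert sg.graph.number_of_edges() == 0


class TestMaternalFamilies:
    def test_half_sib_bridge_with_shared_lineage_joins_nests(self):
        md = meta(
            [("a", "N1", "x", "2021-05-01"), ("b", "N1", "x", "2021-05-01"),
             ("c", "N2", "x", "2021-06-01"), ("d", "N2", "x", "2021-06-01")]
        )
        calls = [call("a", "b", 0.45, FS), call("c", "d", 0.45, FS),
                 call("b", "c", 0.25, HS)]
        sg = build_sibship_graph(calls, {s: "L1" for s in "abcd"}, md)
        fams = infer_maternal_families(sg)
        assert len(fams) == 1
        assert fams[0].nests == ["N1", "N2"]

    def test_shared_lineage_alone_keeps_nests_apart(self):
        """mtDNA haplotypes are shared among unrelated females; without a
        nuclear sib edge two same-lineage nests stay two mothers."""
        md = meta(
            [("a", "N1", "x", "2021-05-01"), ("b", "N2", "x", "2021-06-01")]
        )
        sg = build_sibship_graph([], {"a": "L1", "b": "L1"}, md)
        assert len(infer_maternal_families(sg)) == 2


class TestPaternalGroups:
    def _two_father_family(self):
        md = meta([(s, "N1", "x", "2021-05-01") for s in "abc"])
        calls = [call("a", "b", 0.45, FS)]  # c unattached: its own father
        sg = build_sibship_graph(calls, {s: "L1" for s in "abc"}, md)
        fams = infer_maternal_families(sg)
        return sg, fams

    def test_full_sib_components_count_fathers(self):
        sg, fams = self._two_father_family()
        groups = infer_paternal_groups(fams, sg)
        assert len(groups) == 2

    def test_cross_nest_full_sib_edge_merges_father_across_clutches(self):
        md = meta(
            [("a", "N1", "x", "2021-05-01"), ("b", "N2", "x", "2021-06-01")]
        )
        sg = build_sibship_graph([call("a", "b", 0.45, FS)], {"a": "L1", "b": "L1"}, md)
        fams = infer_maternal_families(sg)
        groups = infer_paternal_groups(fams, sg)
        assert len(groups) == 1
        assert groups[0].nests == ["N1", "N2"]

    def test_paternal_candidates_merge_father_identities_across_mothers(self):
        md = meta(
            [("a", "N1", "x", "2021-05-01"), ("b", "N2", "x", "2021-06-01")]
        )
        sg = build_sibship_graph([call("a", "b", 0.22, HS)], {"a": "L1", "b": "L2"}, md)
        fams = infer_maternal_families(sg)
        assert len(fams) == 2  # two mothers
        groups = infer_paternal_groups(fams, sg)
        assert len(groups) == 1  # one shared father


class TestEvents:
    def test_nest_with_two_paternal_groups_flagged(self):
        md = meta([(s, "N1", "x", "2021-05-01") for s in "abc"])
        calls = [call("a", "b", 0.45, FS), call("a", "c", 0.25, HS),
                 call("b", "c", 0.25, HS)]
        sg = build_sibship_graph(calls, {s: "L1" for s in "abc"}, md)
        fams = infer_maternal_families(sg)
        groups = infer_paternal_groups(fams, sg)
        flagged, singles = detect_multiple_paternity(fams, groups, sg)
        assert flagged == ["N1"] and singles == []

    def test_all_full_sib_clutch_not_flagged(self):
        md = meta([(s, "N1", "x", "2021-05-01") for s in "abc"])
        calls = [call(*p, 0.5, FS) for p in (("a", "b"), ("a", "c"), ("b", "c"))]
        sg = build_sibship_graph(calls, {s: "L1" for s in "abc"}, md)
        fams = infer_maternal_families(sg)
        flagged, _ = detect_multiple_paternity(fams, infer_paternal_groups(fams, sg), sg)
        assert flagged == []

    def test_single_offspring_nests_reported_separately(self):
        md = meta([("a", "N1", "x", "2021-05-01"), ("b", "N2", "x", "2021-05-02")])
        sg = build_sibship_graph([], {"a": "L1", "b": "L2"}, md)
        fams = infer_maternal_families(sg)
        flagged, singles = detect_multiple_paternity(fams, infer_paternal_groups(fams, sg), sg)
        assert flagged == [] and singles == ["N1", "N2"]

    def test_sperm_storage_requires_cross_nest_full_sibs_and_gap(self):
        md = meta(
            [("a", "N1", "x", "2021-05-01"), ("b", "N2", "x", "2021-05-31")]
        )
        sg = build_sibship_graph([call("a", "b", 0.45, FS)], {"a": "L1", "b": "L1"}, md)
        fams = infer_maternal_families(sg)
        groups = infer_paternal_groups(fams, sg)
        events = detect_sperm_storage(fams, groups, sg, min_gap_days=7)
        assert len(events) == 1 and events[0].gap_days == 30

    def test_within_nest_full_sibs_are_not_storage(self):
        md = meta([(s, "N1", "x", "2021-05-01") for s in "ab"])
        sg = build_sibship_graph([call("a", "b", 0.5, FS)], {s: "L1" for s in "ab"}, md)
        fams = infer_maternal_families(sg)
        assert detect_sperm_storage(fams, infer_paternal_groups(fams, sg), sg) == []

    def test_storage_never_spans_mothers(self):
        """A father re-mating with a second female is not sperm storage."""
        md = meta(
            [("a", "N1", "x", "2021-05-01"), ("b", "N2", "x", "2021-06-15")]
        )
        sg = build_sibship_graph([call("a", "b", 0.22, HS)], {"a": "L1", "b": "L2"}, md)
        fams = infer_maternal_families(sg)
        groups = infer_paternal_groups(fams, sg)
        assert len(groups) == 1  # merged father identity across mothers
        assert detect_sperm_storage(fams, groups, sg) == []

    def test_repeat_clutches_same_year_only(self):
        md = meta(
            [("a", "N1", "x", "2021-05-01"), ("b", "N2", "x", "2021-06-01"),
             ("c", "N3", "x", "2022-05-20")]
        )
        calls = [call("a", "b", 0.25, HS), call("a", "c", 0.25, HS),
                 call("b", "c", 0.25, HS)]
        sg = build_sibship_graph(calls, {s: "L1" for s in "abc"}, md)
        fams = infer_maternal_families(sg)
        events = detect_repeat_clutches(fams, sg)
        assert len(events) == 1
        assert events[0].year == 2021 and events[0].nests == ["N1", "N2"]

    def test_three_nests_in_sixteen_days_single_event(self):
        md = meta(
            [("a", "N13", "x", "2021-05-29"), ("b", "N37", "x", "2021-06-07"),
             ("c", "N02", "x", "2021-06-14")]
        )
        calls = [call("a", "b", 0.25, HS), call("a", "c", 0.25, HS),
                 call("b", "c", 0.25, HS)]
        sg = build_sibship_graph(calls, {s: "L1" for s in "abc"}, md)
        events = detect_repeat_clutches(infer_maternal_families(sg), sg)
        assert len(events) == 1
        assert events[0].nests == ["N13", "N37", "N02"]
        assert events[0].gaps_days == [9, 7]


class TestScoring:
    def test_perfect_calls_recover_generator_registry(self):
        """With noise-free classifications the inference is exact."""
        cfg = sk.SimulationConfig(rng_seed=17, missing_rate=0.0)
        ped = sk.simulate_pedigree(cfg)
        off = ped.offspring.set_index("offspring_id")
        samples = list(off.index)
        calls = []
        for i, a in enumerate(samples):
            for b in samples[i + 1 :]:
                if off.loc[a, "mother_id"] == off.loc[b, "mother_id"]:
                    if off.loc[a, "father_id"] == off.loc[b, "father_id"]:
                        calls.append(call(a, b, 0.5, FS))
                    else:
                        calls.append(call(a, b, 0.25, HS))
                elif off.loc[a, "father_id"] == off.loc[b, "father_id"]:
                    calls.append(call(a, b, 0.25, HS))
        lineages = {s: off.loc[s, "mother_id"] for s in samples}
        est = estimate_breeders(calls, lineages, ped.metadata(), min_gap_days=0)
        score = sk.score_inference(est, ped)
        assert score.maternal_rand_index == 1.0
        assert score.mother_count_error == 0
        assert score.father_count_error == 0
        assert score.multiple_paternity_precision == 1.0
        assert score.multiple_paternity_recall == 1.0
        assert score.sperm_storage_recall == 1.0
        assert score.repeat_clutch_recall == 1.0

    def test_no_information_limit(self):
        """With no kinship calls: one family per nest (mothers overcounted),
        one father per offspring, and zero recall for cross-nest events."""
        cfg = sk.SimulationConfig(rng_seed=17, p_sperm_storage=0.5)
        ped = sk.simulate_pedigree(cfg)
        off = ped.offspring.set_index("offspring_id")
        lineages = {s: off.loc[s, "mother_id"] for s in off.index}
        est = estimate_breeders([], lineages, ped.metadata())
        score = sk.score_inference(est, ped)
        assert est.n_mothers == off["nest_id"].nunique()
        assert est.n_fathers == len(off)
        assert score.sperm_storage_recall == 0.0
        assert score.repeat_clutch_recall == 0.0
        assert score.mother_count_error >= 0  # unlinked nests can only overcount

    def test_id_mismatch_raises(self):
        cfg = sk.SimulationConfig(rng_seed=17)
        ped = sk.simulate_pedigree(cfg)
        md = meta([("zz", "N1", "x", "2021-05-01")])
        est = estimate_breeders([], {"zz": "L1"}, md)
        with pytest.raises(ValueError):
            sk.score_inference(est, ped)


def test_father_count_monotone_in_full_sib_threshold(pipeline_result, default_dataset):
    """Lowering the full-sib cutoff adds edges and can only merge fathers."""
    import shellkin.ibs as ibs_mod

    nm = pipeline_result.normalized
    meta_df = default_dataset["metadata"]
    profiles = default_dataset["profiles"]
    counts = []
    for full_cut in (0.50, 0.40, 0.30):
        th = sk.KinshipThresholds(full_sib=full_cut, half_sib=0.18)
        calls = ibs_mod.classify_matrix(nm, th)
        est = estimate_breeders(
            calls, pipeline_result.lineages, meta_df,
            nest_profiles=sk.mtdna.nest_consensus_profiles(
                profiles, dict(zip(meta_df["sample_id"], meta_df["nest_id"]))
            ),
        )
        counts.append(est.n_fathers)
    assert counts[0] >= counts[1] >= counts[2]
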