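"""Mutation partition, concordance, route classification, clone tree."""

import pandas as pd
import pytest

import cloneroute as cr
from cloneroute.clonality import detect_subclones
from cloneroute.routes import (
    MET_TO_MET_CAVEAT,
    RouteClassifier,
    partition_mutations,
    percent_shared,
)
from cloneroute.tables import ABSENT, CLONAL, PRESENT, SUBCLONAL, UNCERTAIN

from conftest import make_series


def quad():
    return make_series(
        [
            ("normal", "normal", 0.0),
            ("primary", "primary", 0.8),
            ("sALN", "sALN", 0.8),
            ("aDM", "aDM", 0.8),
        ]
    )


COLS = ["primary", "sALN", "aDM"]


def presence_from_sets(sets, n_each):
    """Noise-free presence matrix: sets maps a sample-tuple to a prefix
    ('t' for trunk etc.) and n_each that many mutations present exactly
    in those samples."""
    rows = {}
    for (key, prefix), n in zip(sets.keys(), n_each):
        for i in range(n):
            rows[f"{prefix}{i}"] = {
                c: (PRESENT if c in key else ABSENT) for c in COLS
            }
    return pd.DataFrame.from_dict(rows, orient="index").reindex(columns=COLS)


def analyse(presence, series=None):
    series = series or quad()
    first, _ = cr.assign_first_appearance(presence, series)
    clonality = presence.replace({PRESENT: CLONAL})  # noise-free stand-in
    subclones, _ = detect_subclones(first, clonality, presence)
    partition = partition_mutations(presence, series)
    calls = cr.classify_metastasis_route(partition, subclones, series)
    return partition, subclones, calls


class TestPartition:
    def test_trunk_and_exclusive_sets(self):
        presence = presence_from_sets(
            {
                (("primary", "sALN", "aDM"), "t"): None,
                (("sALN", "aDM"), "s"): None,
                (("aDM",), "a"): None,
            },
            [5, 3, 2],
        )
        part = partition_mutations(presence, quad())
        assert len(part.trunk) == 5
        assert len(part.sets[frozenset({"sALN", "aDM"})]) == 3
        assert len(part.sets[frozenset({"aDM"})]) == 2
        # disjoint exhaustive cover
        assert sum(len(v) for v in part.sets.values()) == len(presence)

    def test_empty_table_gives_empty_partition(self):
        presence = pd.DataFrame(columns=COLS)
        part = partition_mutations(presence, quad())
        assert part.sets == {} and part.trunk == set()

    def test_uncertain_policy_is_reported_not_silent(self):
        presence = pd.DataFrame.from_dict(
            {"m1": {"primary": PRESENT, "sALN": UNCERTAIN, "aDM": ABSENT}},
            orient="index",
        )
        part = partition_mutations(presence, quad())
        assert part.uncertain_count == 1
        assert part.sets[frozenset({"primary"})] == {"m1"}
        part2 = partition_mutations(presence, quad(), uncertain_policy="present")
        assert part2.sets[frozenset({"primary", "sALN"})] == {"m1"}


class TestConcordance:
    @pytest.mark.parametrize(
        "shared,total,pct", [(29, 42, 69), (426, 430, 99), (80, 86, 93), (0, 10, 0)]
    )
    def test_percent_shared_rounds_to_nearest_integer(self, shared, total, pct):
        assert percent_shared(shared, total) == pct

    def test_empty_primary_is_undefined_not_zero(self):
        assert percent_shared(0, 0) is None

    def test_summary_counts_from_presence(self):
        presence = presence_from_sets(
            {
                (("primary", "sALN", "aDM"), "t"): None,
                (("primary",), "p"): None,
                (("aDM",), "a"): None,
            },
            [29, 13, 5],
        )
        part = partition_mutations(presence, quad())
        summary = cr.summarize_concordance(part, quad())
        row = summary[summary.metastasis == "sALN"].iloc[0]
        assert row.shared == 29 and row.primary_total == 42
        assert row.percent_shared == 69


class TestRouteClassification:
    def test_met_to_met_pattern(self):
        # 36 mutations shared exclusively by the metastases; everything the
        # aDM shares with the primary is in the sALN too
        presence = presence_from_sets(
            {
                (("primary", "sALN", "aDM"), "t"): None,
                (("sALN", "aDM"), "s"): None,
                (("aDM",), "a"): None,
                (("sALN",), "n"): None,
            },
            [60, 36, 26, 8],
        )
        _, _, calls = analyse(presence)
        call = {c.metastasis: c for c in calls}["aDM"]
        assert call.route == "met_to_met"
        assert call.source == "sALN"
        assert call.evidence["shared_exclusive"] == 36
        assert call.caveats == [MET_TO_MET_CAVEAT]

    def test_parallel_pattern(self):
        # a primary subclone is absent from the aDM, which carries the trunk
        # plus 77 exclusive mutations
        presence = presence_from_sets(
            {
                (("primary", "sALN", "aDM"), "t"): None,
                (("primary", "sALN"), "q"): None,
                (("aDM",), "a"): None,
            },
            [50, 20, 77],
        )
        _, _, calls = analyse(presence)
        call = {c.metastasis: c for c in calls}["aDM"]
        assert call.route == "parallel"
        assert call.evidence["primary_private_subclones"] >= 1

    def test_linear_pattern(self):
        # every primary subclone is carried into the metastasis
        presence = presence_from_sets(
            {
                (("primary", "sALN", "aDM"), "t"): None,
                (("primary", "sALN", "aDM"), "u"): None,
                (("sALN", "aDM"), "x"): None,  # single shared is below evidence
            },
            [40, 12, 1],
        )
        _, _, calls = analyse(presence)
        assert all(c.route == "linear" for c in calls)

    def test_no_mutations_shared_solely_by_metastases_blocks_met_to_met(self):
        # two metastases from different primary cell populations
        presence = presence_from_sets(
            {
                (("primary", "sALN", "aDM"), "t"): None,
                (("primary", "sALN"), "q"): None,  # advanced clone reaches sALN only
                (("aDM",), "a"): None,
            },
            [50, 15, 77],
        )
        _, _, calls = analyse(presence)
        by = {c.metastasis: c.route for c in calls}
        assert by["sALN"] == "linear"
        assert by["aDM"] == "parallel"

    def test_direction_respects_progression_order(self):
        # containment evidence alone is symmetric; the synchronous
        # metastasis cannot be called as seeded by the later relapse
        presence = presence_from_sets(
            {
                (("primary", "sALN", "aDM"), "t"): None,
                (("sALN", "aDM"), "s"): None,
            },
            [40, 30],
        )
        _, _, calls = analyse(presence)
        by = {c.metastasis: c for c in calls}
        assert by["aDM"].route == "met_to_met" and by["aDM"].source == "sALN"
        assert by["sALN"].route != "met_to_met"

    def test_min_evidence_guards_single_shared_mutation(self):
        presence = presence_from_sets(
            {
                (("primary", "sALN", "aDM"), "t"): None,
                (("sALN", "aDM"), "s"): None,
            },
            [40, 1],
        )
        _, subclones, _ = analyse(presence)
        part = partition_mutations(presence, quad())
        calls = cr.classify_metastasis_route(part, subclones, quad(), min_evidence=2)
        assert {c.metastasis: c.route for c in calls}["aDM"] == "linear"

    def test_min_evidence_below_two_rejected(self):
        presence = presence_from_sets(
            {(("primary", "sALN", "aDM"), "t"): None}, [10]
        )
        part = partition_mutations(presence, quad())
        with pytest.raises(ValueError, match="min_evidence"):
            cr.classify_metastasis_route(part, [], quad(), min_evidence=1)

    def test_noise_free_truth_recovery_is_exact(self):
        # on truth-level presence matrices the generating route is always
        # recovered
        for route in ("linear", "parallel", "met_to_met"):
            for seed in range(10):
                sim = cr.simulate_series(route, seed=seed)
                series = sim.series
                rows = {}
                for mid in sim.truth.expected_vaf.index:
                    rows[mid] = {
                        s.sample_id: (
                            PRESENT
                            if mid in sim.truth.truth_mutations(s)
                            else ABSENT
                        )
                        for s in series.tumors
                    }
                presence = pd.DataFrame.from_dict(rows, orient="index")
                first, _ = cr.assign_first_appearance(presence, series)
                clonality = presence.replace({PRESENT: CLONAL})
                subclones, _ = detect_subclones(first, clonality, presence)
                calls = cr.classify_metastasis_route(
                    presence, subclones, series
                )
                for c in calls:
                    assert c.route == sim.truth.route_truth.route_labels[c.metastasis]

    def test_sklearn_estimator_surface(self):
        presence = presence_from_sets(
            {(("primary", "sALN", "aDM"), "t"): None}, [10]
        )
        first, _ = cr.assign_first_appearance(presence, quad())
        clonality = presence.replace({PRESENT: CLONAL})
        subclones, _ = detect_subclones(first, clonality, presence)
        clf = RouteClassifier().fit(presence, quad(), subclones)
        assert clf.predict() == {"sALN": "linear", "aDM": "linear"}
        assert clf.get_params()["min_evidence"] == 2


class TestCloneTree:
    def test_single_clone_one_sample_two_node_tree(self):
        from cloneroute.clonality import Subclone

        series = make_series(
            [("normal", "normal", 0.0), ("primary", "primary", 0.8)]
        )
        sc = Subclone(
            "SC1", [f"m{i}" for i in range(30)], "primary",
            {"primary": PRESENT},
            {"primary": CLONAL},
        )
        newick, tree = cr.build_clone_tree([sc], series)
        assert ":30" in newick  # branch length = trunk mutation count
        assert len(tree["nodes"]) == 1 and tree["nodes"][0]["parent"] == "normal"

    def test_met_to_met_leaf_attaches_under_saln_lineage(self):
        sim = cr.simulate_series("met_to_met", seed=3)
        res = cr.run_pipeline(sim.table, sim.series)
        import dendropy

        tree = dendropy.Tree.get(data=res.newick, schema="newick")
        adm = tree.find_node_with_taxon_label("aDM")
        saln = tree.find_node_with_taxon_label("sALN")
        # the node carrying the sALN-shared mutations is an ancestor of aDM
        saln_parent_labels = {n.label for n in saln.ancestor_iter()}
        adm_labels = {n.label for n in adm.ancestor_iter()}
        assert saln.parent_node.parent_node is not None
        assert saln_parent_labels & adm_labels  # shared lineage above both
        # aDM hangs strictly deeper than the fork from the primary lineage
        assert sim.truth.route_truth.route_labels["aDM"] == "met_to_met"

    def test_simulated_linear_tree_matches_generating_chain(self):
        sim = cr.simulate_series(
            "linear", seed=23, purity=0.8, mean_depth=500,
            n_primary_subclones=1, met_private_fraction=1.0,
        )
        res = cr.run_pipeline(sim.table, sim.series)
        # chain: normal -> trunk group -> subclone group -> met-private group
        parents = {n["id"]: n["parent"] for n in res.tree["nodes"]}
        depths = {}
        for nid in parents:
            d, cur = 0, nid
            while parents.get(cur) is not None and cur in parents:
                cur = parents[cur]
                d += 1
                if cur == "normal":
                    break
            depths[nid] = d
        assert sorted(depths.values()) == [1, 2, 3]

    def test_conflicting_signatures_are_flagged_unresolved(self):
        from cloneroute.clonality import Subclone

        series = quad()
        a = Subclone(
            "SCa", ["m1", "m2"], "primary",
            {"primary": PRESENT, "sALN": PRESENT, "aDM": ABSENT},
            {"primary": CLONAL, "sALN": CLONAL, "aDM": ABSENT},
        )
        b = Subclone(
            "SCb", ["m3", "m4"], "primary",
            {"primary": ABSENT, "sALN": PRESENT, "aDM": PRESENT},
            {"primary": ABSENT, "sALN": CLONAL, "aDM": CLONAL},
        )
        _, tree = cr.build_clone_tree([a, b], series)
        assert all(n["unresolved"] for n in tree["nodes"])


def test_partition_is_disjoint_cover_of_assigned_mutations():
    sim = cr.simulate_series("met_to_met", seed=40)
    res = cr.run_pipeline(sim.table, sim.series)
    part = res.partition
    total = sum(len(v) for v in part.sets.values())
    assert total + len(part.absent_everywhere) == len(res.presence)
    seen = set()
    for v in part.sets.values():
        assert not (seen & v)
        seen |= v
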