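"""Metastasis seeding-route classification from mutation sharing patterns.

Mutations are partitioned by the exact set of tumor samples in which they
are present (trunk = present in every tumor sample; private and shared-
exclusive sets otherwise). Each metastasis M is then classified, most
specific pattern first:

1. metastasis-to-metastasis: an earlier metastasis M' shares with M at
   least ``min_evidence`` mutations that are not detectable in the
   primary, and everything M shares with the primary is also in M' (up to
   ``containment_tolerance``) — the founder of M disseminated from M';
2. parallel progression: a primary subclone (>= 2 mutations) is absent
   from M while M still carries the mutations common to all other tumor
   samples — M was seeded by an earlier clone than the most advanced one;
3. linear progression: every primary subclone is contained in M (up to
   the tolerance) — M descends from the most advanced primary clone;
4. otherwise unresolved.

Because the containment evidence for metastasis-to-metastasis seeding is
symmetric between the two metastases whenever the shared-exclusive
mutations sit on the common founder lineage, the candidate source must
precede the target in progression order (a synchronous node metastasis can
seed a later distant relapse, not vice versa). Every
metastasis-to-metastasis call carries a mandatory caveat: an unsampled
subclone of the primary could mimic the pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .series import PatientSeries
from .tables import ABSENT, PRESENT, UNCERTAIN, VariantTable

MET_TO_MET_CAVEAT = (
    "an undetected subclone within the primary tumor could also explain "
    "mutations shared exclusively by the metastases"
)

__all__ = [
    "MutationPartition",
    "RouteCall",
    "RouteClassifier",
    "partition_mutations",
    "percent_shared",
    "summarize_concordance",
    "classify_metastasis_route",
    "build_clone_tree",
    "frequency_plot_data",
]


@dataclass
class MutationPartition:
    """Disjoint, exhaustive grouping of mutations by presence pattern."""

    sets: dict  # frozenset(sample ids) -> set of mutation ids
    tumor_ids: list
    uncertain_count: int = 0
    absent_everywhere: list = field(default_factory=list)

    @property
    def trunk(self) -> set:
        return set(self.sets.get(frozenset(self.tumor_ids), set()))

    def present_in(self, sample_id: str) -> set:
        out: set = set()
        for key, muts in self.sets.items():
            if sample_id in key:
                out |= muts
        return out

    def counts(self) -> dict:
        return {tuple(sorted(k)): len(v) for k, v in self.sets.items()}

    def all_mutations(self) -> set:
        out: set = set()
        for muts in self.sets.values():
            out |= muts
        return out


def partition_mutations(
    presence: pd.DataFrame,
    series: PatientSeries,
    uncertain_policy: str = "absent",
) -> MutationPartition:
    """Partition mutations by the exact set of tumor samples carrying them.

    ``uncertain`` presence calls are resolved by policy (default: treated
    as absent) and their number reported, never silently dropped.
    """
    if uncertain_policy not in ("absent", "present"):
        raise ValueError("uncertain_policy must be 'absent' or 'present'")
    tumor_ids = [s.sample_id for s in series.tumors if s.sample_id in presence.columns]
    mat = presence[tumor_ids].to_numpy()
    uncertain_count = int((mat == UNCERTAIN).sum())
    present = mat == PRESENT
    if uncertain_policy == "present":
        present = present | (mat == UNCERTAIN)
    sets: dict = {}
    absent_everywhere = []
    for i, mid in enumerate(presence.index):
        key = frozenset(tid for j, tid in enumerate(tumor_ids) if present[i, j])
        if not key:
            absent_everywhere.append(mid)
        else:
            sets.setdefault(key, set()).add(mid)
    return MutationPartition(
        sets=sets,
        tumor_ids=tumor_ids,
        uncertain_count=uncertain_count,
        absent_everywhere=absent_everywhere,
    )


def percent_shared(shared: int, total: int) -> Optional[int]:
    """Percent of primary-tumor mutations shared with a metastasis,
    rounded to the nearest integer; undefined (None) for an empty primary."""
    if total == 0:
        return None
    return int(math.floor(100.0 * shared / total + 0.5))


def summarize_concordance(
    partition: MutationPartition, series: PatientSeries
) -> pd.DataFrame:
    """Shared counts and percentages between the primary and each metastasis."""
    primary_id = series.primary().sample_id
    primary_set = partition.present_in(primary_id)
    rows = []
    for met in series.metastases:
        met_set = partition.present_in(met.sample_id)
        shared = len(primary_set & met_set)
        total = len(primary_set)
        rows.append(
            {
                "primary": primary_id,
                "metastasis": met.sample_id,
                "shared": shared,
                "primary_total": total,
                "percent_shared": percent_shared(shared, total),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RouteCall:
    metastasis: str
    route: str  # linear | parallel | met_to_met | unresolved
    source: Optional[str] = None  # founding source (primary clone id or metastasis)
    evidence: dict = field(default_factory=dict)
    caveats: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.route == "met_to_met" and not self.source:
            raise ValueError("met_to_met calls must name a source metastasis")


class RouteClassifier(BaseEstimator):
    """Rule-based seeding-route classifier over presence patterns.

    Parameters
    ----------
    min_evidence : int
        Minimum number of metastasis-shared-exclusive mutations required
        to support metastasis-to-metastasis seeding (reuses the >= 2
        subclone convention; one shared mutation can be artifactual).
    containment_tolerance : int
        Mutations allowed to violate a containment requirement before the
        set logic rejects it (0 = strict).
    uncertain_policy : str
        How uncertain presence calls enter the partition.
    """

    def __init__(
        self,
        min_evidence: int = 2,
        containment_tolerance: int = 0,
        uncertain_policy: str = "absent",
    ) -> None:
        self.min_evidence = min_evidence
        self.containment_tolerance = containment_tolerance
        self.uncertain_policy = uncertain_policy

    def fit(
        self,
        presence: pd.DataFrame,
        series: PatientSeries,
        subclones: Optional[list] = None,
    ) -> "RouteClassifier":
        if self.min_evidence < 2:
            raise ValueError("min_evidence must be >= 2 (subclone threshold)")
        self.series_ = series
        self.partition_ = partition_mutations(presence, series, self.uncertain_policy)
        self.subclones_ = subclones or []
        self.route_calls_ = [
            self._classify_one(met) for met in series.metastases
        ]
        return self

    def predict(self) -> dict:
        return {rc.metastasis: rc.route for rc in self.route_calls_}

    # -- rules ---------------------------------------------------------

    def _classify_one(self, met) -> RouteCall:
        part = self.partition_
        series = self.series_
        tol = self.containment_tolerance
        primary_id = series.primary().sample_id
        m_id = met.sample_id
        m_set = part.present_in(m_id)
        p_set = part.present_in(primary_id)

        # (1) metastasis-to-metastasis seeding from an earlier metastasis
        for other in series.metastases:
            o_id = other.sample_id
            if o_id == m_id or other.order_index >= met.order_index:
                continue
            o_set = part.present_in(o_id)
            shared_exclusive = (m_set & o_set) - p_set
            violated = (p_set & m_set) - o_set
            if len(shared_exclusive) >= self.min_evidence and len(violated) <= tol:
                return RouteCall(
                    metastasis=m_id,
                    route="met_to_met",
                    source=o_id,
                    evidence={
                        "shared_exclusive": len(shared_exclusive),
                        "containment_violations": len(violated),
                    },
                    caveats=[MET_TO_MET_CAVEAT],
                )

        # primary subclones = signature groups firmly present in the primary
        primary_subclones = [
            sc for sc in self.subclones_ if sc.presence.get(primary_id) == PRESENT
        ]

        # (2) parallel: an advanced primary subclone is missing from M while
        # M still carries the trunk of the primary lineage (it descends from
        # an earlier clone of the same tumor, not from nothing)
        trunk_shared = len(p_set & m_set)
        missing_subclones = [
            sc for sc in primary_subclones if sc.presence.get(m_id) == ABSENT
        ]
        if missing_subclones and trunk_shared >= self.min_evidence:
            return RouteCall(
                metastasis=m_id,
                route="parallel",
                source=primary_id,
                evidence={
                    "primary_private_subclones": len(missing_subclones),
                    "primary_private_mutations": sum(
                        len(sc.mutations) for sc in missing_subclones
                    ),
                    "trunk_shared": trunk_shared,
                },
            )

        # (3) linear: every primary subclone is carried into M
        violated = 0
        for sc in primary_subclones:
            if sc.presence.get(m_id) != PRESENT:
                violated += len(sc.mutations)
        if violated <= tol:
            return RouteCall(
                metastasis=m_id,
                route="linear",
                source=primary_id,
                evidence={
                    "primary_subclones": len(primary_subclones),
                    "containment_violations": violated,
                },
            )

        return RouteCall(
            metastasis=m_id,
            route="unresolved",
            evidence={"containment_violations": violated},
        )


def classify_metastasis_route(
    partition_or_presence,
    subclones,
    series: PatientSeries,
    min_evidence: int = 2,
    containment_tolerance: int = 0,
    uncertain_policy: str = "absent",
) -> list:
    """Functional wrapper over :class:`RouteClassifier`.

    Accepts either the presence matrix or an already-built partition
    (rebuilt internally from presence in the estimator path).
    """
    if isinstance(partition_or_presence, MutationPartition):
        clf = RouteClassifier(min_evidence, containment_tolerance, uncertain_policy)
        clf.series_ = series
        clf.partition_ = partition_or_presence
        clf.subclones_ = subclones or []
        if clf.min_evidence < 2:
            raise ValueError("min_evidence must be >= 2")
        clf.route_calls_ = [clf._classify_one(m) for m in series.metastases]
        return clf.route_calls_
    clf = RouteClassifier(min_evidence, containment_tolerance, uncertain_policy)
    clf.fit(partition_or_presence, series, subclones)
    return clf.route_calls_


# -- clone tree ---------------------------------------------------------


def build_clone_tree(
    subclones,
    series: PatientSeries,
    route_calls: Optional[list] = None,
):
    """Arrange subclones into a rooted clone tree by presence-set containment.

    Nodes: a normal root, the trunk (full-presence subclone(s)), one node
    per remaining subclone; leaves are the tumor samples, each attached
    under the most derived subclone present in it. Branch lengths are the
    mutation counts acquired on each edge. Subclones whose presence sets
    properly overlap (neither nested nor disjoint — a signature conflict
    that no tree can satisfy, typically a noise artifact) are flagged
    unresolved rather than silently repaired.

    Returns ``(newick string, tree dict)``.
    """
    import dendropy

    tumor_ids = [s.sample_id for s in series.tumors]

    def pset(sc) -> frozenset:
        return frozenset(
            sid for sid, state in sc.presence.items() if state == PRESENT
        )

    nodes = [
        {"id": sc.subclone_id, "set": pset(sc), "n_mutations": len(sc.mutations),
         "first_appearance": sc.first_appearance, "unresolved": False}
        for sc in subclones
        if pset(sc)
    ]
    # conflict flag: properly overlapping, non-nested presence sets
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            inter = a["set"] & b["set"]
            if inter and not (a["set"] <= b["set"] or b["set"] <= a["set"]):
                a["unresolved"] = True
                b["unresolved"] = True

    # parent = previously placed node with the smallest superset
    nodes.sort(key=lambda n: (-len(n["set"]), -n["n_mutations"], n["id"]))
    for i, node in enumerate(nodes):
        parent = None
        best = None
        for prev in nodes[:i]:
            if node["set"] <= prev["set"]:
                if best is None or len(prev["set"]) <= len(best["set"]):
                    parent, best = prev["id"], prev
        node["parent"] = parent if parent is not None else "normal"

    tree = dendropy.Tree()
    tree.seed_node.taxon = None
    tree.seed_node.label = "normal"
    dnodes = {"normal": tree.seed_node}
    for node in nodes:
        d = dnodes[node["parent"]].new_child()
        d.label = node["id"]
        d.edge.length = node["n_mutations"]
        dnodes[node["id"]] = d
    taxa = tree.taxon_namespace
    for sid in tumor_ids:
        carriers = [n for n in nodes if sid in n["set"]]
        if carriers:
            host = min(carriers, key=lambda n: (len(n["set"]), n["id"]))["id"]
        else:
            host = "normal"
        leaf = dnodes[host].new_child()
        leaf.taxon = taxa.new_taxon(label=sid)
        leaf.edge.length = 0
    newick = tree.as_string(
        schema="newick", suppress_rooting=True, suppress_leaf_node_labels=False
    ).strip()

    payload = {
        "nodes": [
            {k: (sorted(v) if isinstance(v, frozenset) else v) for k, v in n.items()}
            for n in nodes
        ],
        "leaves": tumor_ids,
        "route_calls": [
            {
                "metastasis": rc.metastasis,
                "route": rc.route,
                "source": rc.source,
                "evidence": rc.evidence,
                "caveats": rc.caveats,
            }
            for rc in (route_calls or [])
        ],
        "newick": newick,
    }
    return newick, payload


def frequency_plot_data(
    table: VariantTable,
    first_appearance: pd.Series,
    series: PatientSeries,
) -> pd.DataFrame:
    """Long-format BAF pairs for frequency plots: each tumor sample against
    every previous step, colored by first appearance."""
    baf = table.baf
    rows = []
    tumors = series.tumors
    for i, later in enumerate(tumors):
        for earlier in tumors[:i]:
            for mid in table.mutation_ids:
                if mid not in first_appearance.index:
                    continue
                rows.append(
                    {
                        "mutation_id": mid,
                        "sample_x": earlier.sample_id,
                        "sample_y": later.sample_id,
                        "baf_x": baf.at[mid, earlier.sample_id],
                        "baf_y": baf.at[mid, later.sample_id],
                        "first_appearance": first_appearance[mid],
                    }
                )
    return pd.DataFrame(rows)
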