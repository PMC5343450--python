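"""End-to-end pipeline: filter -> presence -> clonality -> route calls."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import clonality as _clonality
from . import filtering as _filtering
from . import routes as _routes
from .series import PatientSeries
from .tables import PRESENT, VariantTable


@dataclass
class PipelineResult:
    table: VariantTable  # post-filter table
    decisions: pd.DataFrame
    popaf_removed: list
    cluster_flagged: list
    presence: pd.DataFrame
    purities: dict  # sample_id -> purity used (user-supplied or estimated)
    purity_sources: dict  # sample_id -> "user" | "estimated" | "unavailable"
    first_appearance: pd.Series
    discarded: list
    clonality: pd.DataFrame
    subclones: list
    singletons: list
    purifications: list
    partition: "_routes.MutationPartition"
    concordance: pd.DataFrame
    route_calls: list
    newick: str
    tree: dict

    def report(self) -> dict:
        """Per-stage record counts and the headline calls."""
        return {
            "input_records": int(len(self.decisions)),
            "after_site_filters": int(self.decisions["verdict"].sum()),
            "popaf_removed": len(self.popaf_removed),
            "cluster_flagged": len(self.cluster_flagged),
            "final_records": len(self.table),
            "assigned": int(len(self.first_appearance)),
            "discarded_absent_everywhere": len(self.discarded),
            "subclones": len(self.subclones),
            "singletons": len(self.singletons),
            "purification_events": len(self.purifications),
            "uncertain_presence_calls": int(self.partition.uncertain_count),
            "purities": {k: round(v, 4) for k, v in self.purities.items() if v is not None},
            "route_calls": {rc.metastasis: rc.route for rc in self.route_calls},
        }


def resolve_purities(
    table: VariantTable,
    presence: pd.DataFrame,
    series: PatientSeries,
    estimator_params: Optional[dict] = None,
):
    """User-supplied purity wins; otherwise estimate from present BAFs.

    Samples where neither is possible get None (clonality there is
    reported uncertain rather than guessed).
    """
    purities: dict = {}
    sources: dict = {}
    baf = table.baf
    for spec in series.tumors:
        sid = spec.sample_id
        if spec.purity is not None:
            purities[sid] = float(spec.purity)
            sources[sid] = "user"
            continue
        mask = presence[sid] == PRESENT
        bafs = baf.loc[mask.to_numpy(), sid].to_numpy()
        try:
            est = _clonality.estimate_purity(bafs, **(estimator_params or {}))
            purities[sid] = est.purity
            sources[sid] = "estimated"
        except ValueError:
            purities[sid] = None
            sources[sid] = "unavailable"
    return purities, sources


def run_pipeline(
    table: VariantTable,
    series: PatientSeries,
    filter_config: Optional[_filtering.FilterConfig] = None,
    population_af: Optional[dict] = None,
    ci_level: float = 0.95,
    tolerance: float = 0.2,
    min_evidence: int = 2,
    containment_tolerance: int = 0,
    uncertain_policy: str = "absent",
    purity_estimator_params: Optional[dict] = None,
) -> PipelineResult:
    cfg = filter_config or _filtering.FilterConfig()

    filtered, decisions = _filtering.apply_site_filters(table, series, cfg)
    filtered, popaf_removed = _filtering.exclude_population_variants(
        filtered, population_af, cfg
    )
    cluster_flags = _filtering.flag_snv_clusters(filtered, cfg)
    cluster_flagged = list(cluster_flags.index[cluster_flags])
    filtered = filtered.drop(cluster_flagged)

    presence = _filtering.build_presence_matrix(filtered, series, cfg)
    purities, purity_sources = resolve_purities(
        filtered, presence, series, purity_estimator_params
    )
    first, discarded = _clonality.assign_first_appearance(presence, series)
    keep = filtered.subset(first.index)
    presence = presence.loc[first.index]
    clonality = _clonality.clonality_matrix(
        keep, presence, series, purities, ci_level, tolerance
    )
    subclones, singletons = _clonality.detect_subclones(first, clonality, presence)
    purifications = _clonality.detect_purification(subclones, series)

    partition = _routes.partition_mutations(presence, series, uncertain_policy)
    concordance = _routes.summarize_concordance(partition, series)
    route_calls = _routes.classify_metastasis_route(
        partition, subclones, series, min_evidence, containment_tolerance
    )
    newick, tree = _routes.build_clone_tree(subclones, series, route_calls)

    return PipelineResult(
        table=keep,
        decisions=decisions,
        popaf_removed=popaf_removed,
        cluster_flagged=cluster_flagged,
        presence=presence,
        purities=purities,
        purity_sources=purity_sources,
        first_appearance=first,
        discarded=discarded,
        clonality=clonality,
        subclones=subclones,
        singletons=singletons,
        purifications=purifications,
        partition=partition,
        concordance=concordance,
        route_calls=route_calls,
        newick=newick,
        tree=tree,
    )
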