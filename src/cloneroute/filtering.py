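"""Multi-sample somatic variant filtering and per-sample presence calls.

The site filter keeps a candidate mutation only if, across the patient
series, (i) the matched normal shows BAF < 0.02, (ii) every sample —
normal included — has read depth >= 50x, and (iii) at least one tumor
sample shows BAF >= 0.05. For retained sites, presence is then rescued in
the other tumor samples down to BAF >= 0.025 provided depth exceeds 200x;
a site with BAF in [0.025, 0.05) that lacks that depth is reported as
``uncertain`` rather than silently resolved. Separate screens remove
known SNPs with population allele frequency > 1%, variants inside
user-supplied exclusion intervals, and SNV clusters (more than a maximum
number of variants within a short window).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .series import PatientSeries
from .tables import ABSENT, PRESENT, UNCERTAIN, VariantTable, compute_baf

__all__ = [
    "FilterConfig",
    "SiteFilter",
    "PresenceCaller",
    "compute_baf",
    "apply_site_filters",
    "build_presence_matrix",
    "exclude_population_variants",
    "flag_snv_clusters",
]


@dataclass
class FilterConfig:
    """Thresholds of the multi-sample somatic filter.

    Defaults follow the targeted deep-sequencing criteria: normal BAF
    below 0.02, a minimum depth of 50 reads in all samples, tumor BAF of
    at least 0.05 in one sample, and presence rescue at BAF >= 0.025 when
    depth exceeds 200 reads (strictly). Known SNPs above 1% population
    allele frequency are excluded. The SNV-cluster window and count are
    configurable conventions, as is the optional exclusion-interval list
    standing in for repetitive/error-prone-region curation.
    """

    normal_baf_max: float = 0.02
    min_depth_all: int = 50
    tumor_baf_min: float = 0.05
    rescue_baf_min: float = 0.025
    rescue_depth_min: int = 200  # strict: depth must exceed this
    popaf_max: float = 0.01  # strict: popAF must exceed this to be removed
    cluster_window: int = 100
    cluster_max: int = 2
    exclusion_intervals: Optional[list] = None  # (chrom, start, end), 1-based incl.

    def __post_init__(self) -> None:
        if not (0.0 <= self.rescue_baf_min <= self.tumor_baf_min <= 1.0):
            raise ValueError("need 0 <= rescue_baf_min <= tumor_baf_min <= 1")
        if self.min_depth_all <= 0 or self.rescue_depth_min <= 0:
            raise ValueError("depth thresholds must be positive")


class SiteFilter(BaseEstimator, TransformerMixin):
    """Multi-sample site filter as a transformer over a VariantTable.

    Parameters mirror :class:`FilterConfig`. ``fit`` binds the patient
    series (to identify the normal sample); ``transform`` returns the
    filtered table and records a per-predicate decision log in
    ``decisions_``.
    """

    def __init__(
        self,
        normal_baf_max: float = 0.02,
        min_depth_all: int = 50,
        tumor_baf_min: float = 0.05,
    ) -> None:
        self.normal_baf_max = normal_baf_max
        self.min_depth_all = min_depth_all
        self.tumor_baf_min = tumor_baf_min

    def fit(self, table: VariantTable, series: PatientSeries) -> "SiteFilter":
        if series is None:
            raise ValueError("a PatientSeries is required to locate the normal sample")
        normal_id = series.normal.sample_id
        if normal_id not in table.sample_ids:
            raise ValueError(
                f"normal sample {normal_id!r} missing from variant table"
            )
        missing = set(series.sample_ids) - set(table.sample_ids)
        if missing:
            raise ValueError(f"series samples missing from table: {sorted(missing)}")
        self.series_ = series
        self.normal_id_ = normal_id
        self.tumor_ids_ = [s for s in series.tumor_ids if s in table.sample_ids]
        return self

    def transform(self, table: VariantTable) -> VariantTable:
        baf = table.baf
        sample_ids = self.series_.sample_ids
        normal_ok = baf[self.normal_id_].to_numpy() < self.normal_baf_max
        depth_ok = (
            table.depth[sample_ids].to_numpy() >= self.min_depth_all
        ).all(axis=1)
        tumor_ok = (
            baf[self.tumor_ids_].to_numpy() >= self.tumor_baf_min
        ).any(axis=1)
        verdict = normal_ok & depth_ok & tumor_ok
        self.decisions_ = pd.DataFrame(
            {
                "normal_baf_ok": normal_ok,
                "depth_ok": depth_ok,
                "tumor_baf_ok": tumor_ok,
                "verdict": verdict,
            },
            index=table.mutation_ids,
        )
        return table.subset(table.mutation_ids[verdict])

    def fit_transform(self, table: VariantTable, series: PatientSeries = None, **kw):
        return self.fit(table, series).transform(table)


class PresenceCaller(BaseEstimator, TransformerMixin):
    """Tri-state per-(mutation, tumor sample) presence calls.

    present  : BAF >= ``baf_min``, or BAF >= ``rescue_baf_min`` with depth
               strictly above ``rescue_depth_min`` (the rescue rule);
    uncertain: BAF in [rescue_baf_min, baf_min) without the rescue depth;
    absent   : otherwise.
    """

    def __init__(
        self,
        baf_min: float = 0.05,
        rescue_baf_min: float = 0.025,
        rescue_depth_min: int = 200,
    ) -> None:
        self.baf_min = baf_min
        self.rescue_baf_min = rescue_baf_min
        self.rescue_depth_min = rescue_depth_min

    def fit(self, table: VariantTable, series: PatientSeries) -> "PresenceCaller":
        self.tumor_ids_ = [s for s in series.tumor_ids if s in table.sample_ids]
        return self

    def transform(self, table: VariantTable) -> pd.DataFrame:
        baf = table.baf[self.tumor_ids_].to_numpy()
        depth = table.depth[self.tumor_ids_].to_numpy()
        out = np.full(baf.shape, ABSENT, dtype=object)
        rescue_zone = (baf >= self.rescue_baf_min) & (baf < self.baf_min)
        deep = depth > self.rescue_depth_min
        out[(baf >= self.baf_min)] = PRESENT
        out[rescue_zone & deep] = PRESENT
        out[rescue_zone & ~deep] = UNCERTAIN
        return pd.DataFrame(out, index=table.mutation_ids, columns=self.tumor_ids_)

    def fit_transform(self, table: VariantTable, series: PatientSeries = None, **kw):
        return self.fit(table, series).transform(table)


def apply_site_filters(
    table: VariantTable, series: PatientSeries, config: Optional[FilterConfig] = None
):
    """Filter a variant table; returns (filtered table, decision log)."""
    config = config or FilterConfig()
    est = SiteFilter(
        normal_baf_max=config.normal_baf_max,
        min_depth_all=config.min_depth_all,
        tumor_baf_min=config.tumor_baf_min,
    )
    filtered = est.fit_transform(table, series)
    return filtered, est.decisions_


def build_presence_matrix(
    table: VariantTable, series: PatientSeries, config: Optional[FilterConfig] = None
) -> pd.DataFrame:
    config = config or FilterConfig()
    est = PresenceCaller(
        baf_min=config.tumor_baf_min,
        rescue_baf_min=config.rescue_baf_min,
        rescue_depth_min=config.rescue_depth_min,
    )
    return est.fit_transform(table, series)


def exclude_population_variants(
    table: VariantTable,
    population_af: Optional[dict] = None,
    config: Optional[FilterConfig] = None,
):
    """Drop known SNPs with population allele frequency strictly above the
    threshold (default 1%). Unannotated mutations count as popAF 0.

    ``population_af`` overrides/extends the table's ``population_af``
    column when given. Returns (filtered table, removed ids).
    """
    config = config or FilterConfig()
    popaf = pd.Series(0.0, index=table.mutation_ids)
    if "population_af" in table.variants.columns:
        popaf = table.variants["population_af"].fillna(0.0).astype(float)
    if population_af:
        for mid, af in population_af.items():
            if mid in popaf.index:
                popaf.loc[mid] = af
    removed = table.mutation_ids[popaf.to_numpy() > config.popaf_max]
    return table.drop(removed), list(removed)


def flag_snv_clusters(
    table: VariantTable, config: Optional[FilterConfig] = None
) -> pd.Series:
    """Flag variants in SNV clusters or inside exclusion intervals.

    A cluster is any run of more than ``cluster_max`` variants whose
    positions span at most ``cluster_window`` bp on one chromosome; every
    member of such a run is flagged. Exclusion intervals are 1-based
    inclusive ``(chrom, start, end)`` triples.
    """
    config = config or FilterConfig()
    flags = pd.Series(False, index=table.mutation_ids)
    v = table.variants
    k = config.cluster_max  # run length that triggers is k + 1
    for chrom, grp in v.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos_sorted = pos[order]
        ids = grp.index.to_numpy()[order]
        n = len(pos_sorted)
        if n > k:
            hit = np.zeros(n, dtype=bool)
            span = pos_sorted[k:] - pos_sorted[:-k]
            starts = np.nonzero(span <= config.cluster_window)[0]
            for s in starts:
                hit[s : s + k + 1] = True
            flags.loc[ids[hit]] = True
    if config.exclusion_intervals:
        try:
            from intervaltree import IntervalTree
        except ImportError:  # pragma: no cover
            IntervalTree = None
        trees: dict = {}
        for chrom, start, end in config.exclusion_intervals:
            trees.setdefault(str(chrom), IntervalTree()).addi(start, end + 1)
        for mid, chrom, pos in zip(v.index, v["chrom"].astype(str), v["pos"]):
            tree = trees.get(chrom)
            if tree is not None and tree.overlaps_point(int(pos)):
                flags.loc[mid] = True
    return flags
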