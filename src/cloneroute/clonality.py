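"""Clonality analysis against the purity-scaled diploid heterozygous level.

Early, fully clonal mutations at copy-number-neutral heterozygous
positions are expected at a variant allele frequency near purity x 0.5 —
the diploid heterozygous level L of the sample. A mutation is called
*clonal* in a sample when the two-sided exact (Clopper-Pearson) binomial
confidence interval for its BAF reaches L*(1 - tau) for a relative
tolerance tau, and *subclonal* when the interval lies entirely below it.

Tumor purity, when not supplied, is estimated from the BAF distribution of
present mutations: kernel density with a fixed bandwidth, take the
highest-BAF major mode as the clonal cluster, purity = 2 x its location
(clipped at 1). The estimator refuses samples with too few mutations
rather than guessing, and purity known from upstream analysis always takes
priority over the estimate.

Mutations are assigned the earliest progression step at which they are
present (first appearance); mutations sharing an identical
(first-appearance, per-sample presence, per-sample clonality) signature
form a subclone when at least two of them agree — singletons are never
promoted to subclones. A subclone that is subclonal in an earlier sample
and clonal in a later one constitutes a purification event, evidence that
the later lesion was founded by that subclone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .series import PatientSeries
from .tables import ABSENT, CLONAL, PRESENT, SUBCLONAL, UNCERTAIN, VariantTable

__all__ = [
    "PurityEstimate",
    "PurityEstimator",
    "ClonalityClassifier",
    "Subclone",
    "PurificationEvent",
    "diploid_het_level",
    "estimate_purity",
    "assign_first_appearance",
    "classify_clonality",
    "binomial_ci",
    "detect_subclones",
    "detect_purification",
]


def diploid_het_level(purity: float) -> float:
    """Expected BAF of a clonal heterozygous diploid mutation: purity x 0.5."""
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must lie in (0, 1], got {purity}")
    return purity * 0.5


@dataclass
class PurityEstimate:
    purity: float
    mode_location: float
    mode_support: int
    n_modes: int


class PurityEstimator(BaseEstimator):
    """1-D mode-based tumor purity estimate from BAFs of present mutations.

    A Gaussian kernel density with fixed bandwidth is evaluated on a grid
    over [0, 0.75]; local maxima with peak density of at least
    ``major_mode_frac`` of the global maximum are "major" modes. The
    clonal cluster is the major mode at the highest BAF, and purity is
    twice its location, clipped at 1. ``mode_support_`` counts the BAFs
    within ``support_window`` of that mode.

    Refuses to fit on fewer than ``min_mutations`` BAFs (raises), since a
    mode found in a handful of points is not evidence.
    """

    def __init__(
        self,
        bandwidth: float = 0.012,
        grid_size: int = 512,
        major_mode_frac: float = 0.25,
        support_window: float = 0.05,
        refine_window: float = 0.03,
        min_mutations: int = 10,
    ) -> None:
        self.bandwidth = bandwidth
        self.grid_size = grid_size
        self.major_mode_frac = major_mode_frac
        self.support_window = support_window
        self.refine_window = refine_window
        self.min_mutations = min_mutations

    def fit(self, bafs, y=None) -> "PurityEstimator":
        bafs = np.asarray(bafs, dtype=float)
        bafs = bafs[np.isfinite(bafs)]
        if len(bafs) < self.min_mutations:
            raise ValueError(
                f"purity estimation needs >= {self.min_mutations} present "
                f"mutations, got {len(bafs)}; supply purity explicitly"
            )
        spread = float(np.std(bafs))
        if spread < 1e-12:
            # degenerate: all BAFs identical, the mode is that value
            loc = float(bafs[0])
            self.modes_ = [loc]
            self.mode_location_ = loc
            self.mode_support_ = int(len(bafs))
            self.purity_ = min(1.0, 2.0 * loc)
            return self
        # fixed bandwidth: gaussian_kde scales its factor by data std
        kde = stats.gaussian_kde(bafs, bw_method=self.bandwidth / spread)
        grid = np.linspace(0.0, 0.75, self.grid_size)
        dens = kde(grid)
        interior = np.zeros(len(grid), dtype=bool)
        interior[1:-1] = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
        peak = dens.max()
        major = interior & (dens >= self.major_mode_frac * peak)
        locs = grid[major]
        self.modes_ = [float(x) for x in locs]
        loc = float(locs.max())
        # refine: symmetric trimmed mean of the cluster around the grid peak
        # (unbiased for the cluster centre, unlike the smoothed KDE argmax)
        for _ in range(3):
            near = bafs[np.abs(bafs - loc) <= self.refine_window]
            if len(near) == 0:
                break
            loc = float(np.mean(near))
        self.mode_location_ = loc
        self.mode_support_ = int(np.sum(np.abs(bafs - loc) <= self.support_window))
        self.purity_ = min(1.0, 2.0 * loc)
        return self

    def estimate_(self) -> PurityEstimate:
        return PurityEstimate(
            purity=self.purity_,
            mode_location=self.mode_location_,
            mode_support=self.mode_support_,
            n_modes=len(self.modes_),
        )


def estimate_purity(bafs, **params) -> PurityEstimate:
    est = PurityEstimator(**params)
    est.fit(bafs)
    return est.estimate_()


def binomial_ci(alt, depth, level: float = 0.95):
    """Vectorised two-sided Clopper-Pearson interval for alt/depth."""
    alt = np.atleast_1d(np.asarray(alt, dtype=float))
    depth = np.atleast_1d(np.asarray(depth, dtype=float))
    alpha = 1.0 - level
    lo = np.where(alt > 0, stats.beta.ppf(alpha / 2, alt, depth - alt + 1), 0.0)
    hi = np.where(
        alt < depth, stats.beta.ppf(1 - alpha / 2, alt + 1, depth - alt), 1.0
    )
    return lo, hi


class ClonalityClassifier(BaseEstimator):
    """Clonal/subclonal calls from read counts, purity and the het level.

    For each observation with depth n and alt count k, form the exact
    two-sided binomial CI at ``ci_level`` and compare it with the lowered
    het level ``L * (1 - tolerance)``, L = purity x 0.5:

    * the CI reaches the level (upper bound >= threshold) -> clonal;
    * the CI lies wholly below it -> subclonal.

    ``predict`` takes aligned arrays (alt, depth, purity) and returns an
    object array of calls; missing purity (NaN) yields ``uncertain``.
    """

    def __init__(self, ci_level: float = 0.95, tolerance: float = 0.2) -> None:
        self.ci_level = ci_level
        self.tolerance = tolerance

    def fit(self, X=None, y=None) -> "ClonalityClassifier":
        return self

    def predict(self, alt, depth, purity) -> np.ndarray:
        alt = np.atleast_1d(np.asarray(alt, dtype=float))
        depth = np.atleast_1d(np.asarray(depth, dtype=float))
        purity = np.broadcast_to(
            np.atleast_1d(np.asarray(purity, dtype=float)), alt.shape
        ).copy()
        _, hi = binomial_ci(alt, depth, self.ci_level)
        thr = purity * 0.5 * (1.0 - self.tolerance)
        out = np.where(hi >= thr, CLONAL, SUBCLONAL).astype(object)
        out[~np.isfinite(purity)] = UNCERTAIN
        return out


def classify_clonality(
    alt, depth, purity, ci_level: float = 0.95, tolerance: float = 0.2
):
    """Functional form of :class:`ClonalityClassifier`; scalar in, scalar out."""
    calls = ClonalityClassifier(ci_level, tolerance).predict(alt, depth, purity)
    if np.isscalar(alt) or np.asarray(alt).ndim == 0:
        return calls.item(0) if calls.size else calls
    return calls


def assign_first_appearance(presence: pd.DataFrame, series: PatientSeries):
    """Earliest progression step at which each mutation is present.

    Only firm ``present`` calls count — an ``uncertain`` call never moves
    a first appearance earlier. Mutations present nowhere go to the
    discard list. Returns (Series mutation -> step label, discard list).
    """
    ordered = [s for s in series.tumors if s.sample_id in presence.columns]
    first = {}
    discarded = []
    pres = presence[[s.sample_id for s in ordered]].to_numpy() == PRESENT
    for i, mid in enumerate(presence.index):
        hits = np.nonzero(pres[i])[0]
        if len(hits) == 0:
            discarded.append(mid)
        else:
            first[mid] = ordered[hits[0]].step_label
    return pd.Series(first, name="first_appearance"), discarded


@dataclass
class Subclone:
    subclone_id: str
    mutations: list  # >= 2 members
    first_appearance: str
    presence: dict  # sample_id -> present/uncertain/absent
    clonality: dict  # sample_id -> clonal/subclonal/absent/uncertain

    def __post_init__(self) -> None:
        if len(self.mutations) < 2:
            raise ValueError("a subclone requires at least two mutations")


@dataclass
class PurificationEvent:
    mutations: list
    source_sample: str  # where the set is subclonal
    target_sample: str  # later sample where it is clonal


def clonality_matrix(
    table: VariantTable,
    presence: pd.DataFrame,
    series: PatientSeries,
    purities: Optional[dict] = None,
    ci_level: float = 0.95,
    tolerance: float = 0.2,
) -> pd.DataFrame:
    """Per-(mutation, tumor sample) calls in
    {clonal, subclonal, absent, uncertain}, honouring the presence matrix:
    absent there is absent here, uncertain there stays uncertain."""
    purities = purities or {}
    clf = ClonalityClassifier(ci_level, tolerance)
    cols = {}
    for spec in series.tumors:
        sid = spec.sample_id
        if sid not in presence.columns:
            continue
        purity = purities.get(sid, spec.purity)
        p = np.nan if purity is None else float(purity)
        calls = clf.predict(
            table.alt[sid].to_numpy(), table.depth[sid].to_numpy(), p
        )
        calls = pd.Series(calls, index=table.mutation_ids)
        state = presence[sid]
        calls[state == ABSENT] = ABSENT
        calls[state == UNCERTAIN] = UNCERTAIN
        cols[sid] = calls
    return pd.DataFrame(cols)


def detect_subclones(
    first_appearance: pd.Series,
    clonality: pd.DataFrame,
    presence: pd.DataFrame,
):
    """Group mutations by identical discrete signature.

    The signature is (first appearance, per-sample presence, per-sample
    clonality); exact match, no distance-based clustering, so grouping is
    deterministic. Groups with >= 2 members become subclones; singletons
    are returned separately and never treated as subclones.
    """
    cols = list(presence.columns)
    groups: dict = {}
    for mid in first_appearance.index:
        sig = (
            first_appearance[mid],
            tuple(presence.loc[mid, c] for c in cols),
            tuple(clonality.loc[mid, c] for c in cols),
        )
        groups.setdefault(sig, []).append(mid)
    subclones = []
    singletons = []
    for i, (sig, members) in enumerate(
        sorted(groups.items(), key=lambda kv: (-len(kv[1]), str(kv[0])))
    ):
        if len(members) >= 2:
            subclones.append(
                Subclone(
                    subclone_id=f"SC{len(subclones) + 1}",
                    mutations=sorted(members),
                    first_appearance=sig[0],
                    presence=dict(zip(cols, sig[1])),
                    clonality=dict(zip(cols, sig[2])),
                )
            )
        else:
            singletons.extend(members)
    return subclones, sorted(singletons)


def detect_purification(subclones, series: PatientSeries):
    """Purification events: a subclone subclonal in an earlier sample and
    clonal in a later one — the later lesion grew out of that subclone."""
    order = {s.sample_id: s.order_index for s in series.tumors}
    events = []
    for sc in subclones:
        for src, src_call in sc.clonality.items():
            if src_call != SUBCLONAL:
                continue
            for tgt, tgt_call in sc.clonality.items():
                if tgt_call == CLONAL and order[tgt] > order[src]:
                    events.append(
                        PurificationEvent(
                            mutations=list(sc.mutations),
                            source_sample=src,
                            target_sample=tgt,
                        )
                    )
    return events
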