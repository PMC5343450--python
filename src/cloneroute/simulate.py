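"""Clonal-evolution simulator for tumor progression series.

Generates a patient series — normal, optional DCIS, primary tumor and one
or two metastases — with a known clone tree, a known seeding topology
(linear, parallel or metastasis-to-metastasis), known per-sample clone
fractions and purity, and binomial read-count noise at targeted-sequencing
depth. Every downstream stage of the pipeline can therefore be scored
against exact truth.

Model
-----
Clones form a rooted tree; each edge carries the set of mutations newly
acquired by the child clone. A mutation's cancer-cell fraction (CCF) in a
sample is the summed fraction of clones whose lineage includes it. Under
the copy-number-neutral heterozygous model the expected variant allele
frequency is ``purity x CCF x 0.5``; an optional multiplicity/copy-number
mode generalises this to ``purity x m x CCF / (purity x CN_t + (1-purity) x 2)``.

Read counts: per-site depth is Poisson around the sample's mean depth
(floored at 1 read), alt counts are Binomial(depth, expected VAF + per-base
error). All randomness flows from one integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .series import PatientSeries, SampleSpec
from .tables import VariantTable, variant_ids

ROUTES = ("linear", "parallel", "met_to_met")

SOMATIC = "somatic"
GERMLINE = "germline"
ARTIFACT = "artifact"


@dataclass(frozen=True)
class CloneNode:
    clone_id: str
    parent_id: Optional[str]  # None marks the root (normal cell)
    branch_mutations: frozenset


@dataclass
class ClonalPhylogeny:
    """Rooted clone tree with pairwise-disjoint branch mutation sets."""

    nodes: dict  # clone_id -> CloneNode

    def __post_init__(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise ValueError("clone graph must have exactly one root")
        seen: set = set()
        for n in self.nodes.values():
            if n.parent_id is not None and n.parent_id not in self.nodes:
                raise ValueError(f"unknown parent {n.parent_id} for {n.clone_id}")
            if n.branch_mutations & seen:
                raise ValueError("branch mutation sets must be pairwise disjoint")
            seen |= n.branch_mutations

    @property
    def root_id(self) -> str:
        return next(n.clone_id for n in self.nodes.values() if n.parent_id is None)

    def lineage(self, clone_id: str) -> list:
        """Clone ids from root to ``clone_id`` inclusive."""
        path = []
        cur: Optional[str] = clone_id
        while cur is not None:
            path.append(cur)
            cur = self.nodes[cur].parent_id
        return path[::-1]

    def lineage_mutations(self, clone_id: str) -> set:
        out: set = set()
        for cid in self.lineage(clone_id):
            out |= self.nodes[cid].branch_mutations
        return out

    def mutation_origin(self) -> dict:
        return {
            m: n.clone_id for n in self.nodes.values() for m in n.branch_mutations
        }

    def all_mutations(self) -> set:
        return {m for n in self.nodes.values() for m in n.branch_mutations}

    def carriers(self, mutation: str) -> set:
        """Clones whose lineage includes ``mutation`` (origin + descendants)."""
        origin = self.mutation_origin().get(mutation)
        if origin is None:
            raise KeyError(f"unknown mutation {mutation!r}")
        return {
            cid for cid in self.nodes if origin in self.lineage(cid)
        }


@dataclass
class SeedingTopology:
    """Truth route label per metastasis plus the seeding edges."""

    route_labels: dict  # metastasis sample_id -> route
    seeding_edges: list  # (source sample_id or clone_id, target sample_id)

    def __post_init__(self) -> None:
        for met, route in self.route_labels.items():
            if route not in ROUTES:
                raise ValueError(f"unknown route {route!r} for {met}")
        targets = {t for _, t in self.seeding_edges}
        for met, route in self.route_labels.items():
            if route == "met_to_met" and met not in targets:
                raise ValueError(f"met_to_met metastasis {met} has no seeding edge")


@dataclass
class TruthBundle:
    phylogeny: ClonalPhylogeny
    mutation_origin: dict
    expected_vaf: pd.DataFrame  # index mutation, columns sample ids
    route_truth: SeedingTopology
    artifact_labels: dict  # mutation -> somatic|germline|artifact
    seed: int

    def truth_mutations(self, sample: SampleSpec) -> set:
        """Mutations with non-zero CCF in a sample, from clone fractions."""
        out: set = set()
        for clone_id, frac in sample.clone_fractions.items():
            if frac > 0:
                out |= self.phylogeny.lineage_mutations(clone_id)
        return out


@dataclass
class SimulatedSeries:
    series: PatientSeries
    table: VariantTable
    truth: TruthBundle


def expected_vaf(
    mutation: str,
    spec: SampleSpec,
    phylogeny: ClonalPhylogeny,
    multiplicity: int = 1,
    tumor_copy_number: int = 2,
) -> float:
    """Expected VAF of a mutation in one sample.

    Copy-number-neutral heterozygous default: purity x CCF x 0.5. With a
    multiplicity ``m`` and tumor total copy number ``CN_t`` the clonal
    expectation generalises to purity*m / (purity*CN_t + (1-purity)*2),
    scaled by CCF.
    """
    origin = phylogeny.mutation_origin().get(mutation)
    if origin is None:
        raise KeyError(f"unknown mutation {mutation!r}")
    purity = spec.purity or 0.0
    if purity == 0.0:
        return 0.0
    ccf = 0.0
    for clone_id, frac in spec.clone_fractions.items():
        if origin in phylogeny.lineage(clone_id):
            ccf += frac
    denom = purity * tumor_copy_number + (1.0 - purity) * 2.0
    return purity * multiplicity * ccf / denom


def _default_steps(route: str) -> list:
    if route == "met_to_met":
        return ["normal", "primary", "sALN", "aDM"]
    return ["normal", "primary", "sALN"]


def generate_phylogeny(
    route: str,
    steps: Optional[list] = None,
    branch_size_range: tuple = (10, 60),
    seed: int = 0,
    n_primary_subclones: int = 2,
    rng: Optional[np.random.Generator] = None,
):
    """Build a clone tree and seeding topology for one requested route.

    The primary tumor evolves as a subclone chain trunk -> P2 -> ... -> Pk.
    * linear: each metastasis is founded by the terminal (most-mutated)
      primary clone.
    * parallel: each metastasis is founded by an ancestral clone while the
      more-derived primary clones remain private to the primary.
    * met_to_met: the sALN is seeded linearly from the primary; the aDM is
      founded by a clone inside the sALN that already carries sALN-private
      mutations, so every mutation shared by primary and aDM is also on the
      sALN lineage.

    Returns ``(phylogeny, topology, sample_clones)`` where ``sample_clones``
    maps each tumor step label to the clones composing that sample.
    """
    if route not in ROUTES:
        raise ValueError(f"route must be one of {ROUTES}, got {route!r}")
    lo, hi = branch_size_range
    if lo < 2:
        raise ValueError("branch_size_range minimum must be >= 2 (subclone rule)")
    steps = list(steps) if steps is not None else _default_steps(route)
    if "primary" not in steps:
        raise ValueError("steps must include a primary sample")
    mets = [s for s in steps if s in ("sALN", "aDM")]
    if not mets:
        raise ValueError("steps must include at least one metastasis")
    if route == "met_to_met" and not ("sALN" in steps and "aDM" in steps):
        raise ValueError("met_to_met requires both sALN and aDM steps")

    rng = rng if rng is not None else np.random.default_rng(seed)
    counter = [0]

    def new_branch() -> frozenset:
        size = int(rng.integers(lo, hi + 1))
        start = counter[0]
        counter[0] += size
        return frozenset(f"m{start + i:05d}" for i in range(size))

    nodes: dict = {"root": CloneNode("root", None, frozenset())}

    def add(clone_id: str, parent_id: str) -> str:
        nodes[clone_id] = CloneNode(clone_id, parent_id, new_branch())
        return clone_id

    trunk = add("T", "root")
    chain = [trunk]
    for i in range(n_primary_subclones):
        chain.append(add(f"P{i + 2}", chain[-1]))
    terminal = chain[-1]

    sample_clones: dict = {}
    if "DCIS" in steps:
        sample_clones["DCIS"] = [trunk]
    sample_clones["primary"] = list(chain)

    route_labels: dict = {}
    edges: list = []
    if route == "met_to_met":
        s_founder = add("S1", terminal)          # sALN founder, sALN-shared branch
        s_private = add("S2", s_founder)         # stays private to the sALN
        a_clone = add("A1", s_founder)           # aDM founder, aDM-private branch
        sample_clones["sALN"] = [s_founder, s_private]
        sample_clones["aDM"] = [s_founder, a_clone]
        route_labels["sALN"] = "linear"
        route_labels["aDM"] = "met_to_met"
        edges.append(("primary", "sALN"))
        edges.append(("sALN", "aDM"))
    else:
        if route == "parallel":
            # founder is one step below the terminal clone so that the
            # terminal clone (>= 2 mutations) remains private to the primary
            founder = chain[-2]
        else:
            founder = terminal
        for i, met in enumerate(mets):
            m_clone = add(f"M{i + 1}", founder)
            sample_clones[met] = [founder, m_clone]
            route_labels[met] = route
            edges.append(("primary", met))

    phylogeny = ClonalPhylogeny(nodes)
    topology = SeedingTopology(route_labels, edges)
    return phylogeny, topology, sample_clones


def build_series(
    phylogeny: ClonalPhylogeny,
    topology: SeedingTopology,
    sample_clones: dict,
    steps: list,
    purity=None,
    purity_range: tuple = (0.3, 0.9),
    mean_depth: float = 300.0,
    terminal_fraction: float = 0.45,
    met_private_fraction: float = 0.7,
    patient_id: str = "SIM",
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> PatientSeries:
    """Attach clone fractions, purity and depth to the simulated samples.

    In the primary the terminal subclone holds ``terminal_fraction`` of the
    malignant cells and its ancestors split the remainder evenly. In a
    metastasis the derived (private-mutation) clone holds
    ``met_private_fraction`` and the founding clone the remnant, so
    metastasis-exclusive mutations occur subclonally. Purity per tumor is
    user-supplied (scalar or dict by step) or drawn uniformly from
    ``purity_range``.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    samples = []
    order = 0
    for step in steps:
        sid = step
        if step == "normal":
            samples.append(SampleSpec(sid, step, order, purity=0.0, mean_depth=mean_depth))
            order += 1
            continue
        if isinstance(purity, dict):
            p = purity[step]
        elif purity is not None:
            p = float(purity)
        else:
            p = float(rng.uniform(*purity_range))
        clones = sample_clones[step]
        if step == "primary":
            k = len(clones)
            if k == 1:
                fracs = {clones[0]: 1.0}
            else:
                rest = (1.0 - terminal_fraction) / (k - 1)
                fracs = {c: rest for c in clones[:-1]}
                fracs[clones[-1]] = terminal_fraction
        elif len(clones) == 2:
            fracs = {clones[0]: 1.0 - met_private_fraction, clones[1]: met_private_fraction}
        else:
            fracs = {c: 1.0 / len(clones) for c in clones}
        samples.append(
            SampleSpec(sid, step, order, purity=p, mean_depth=mean_depth, clone_fractions=fracs)
        )
        order += 1
    return PatientSeries(patient_id, samples)


def _place_variants(n: int, rng: np.random.Generator, start: int = 0) -> pd.DataFrame:
    """Genomic coordinates for simulated mutations, spaced well apart so
    genuine somatic calls never trip the SNV-cluster filter."""
    bases = np.array(list("ACGT"))
    idx = np.arange(start, start + n)
    chrom = (idx // 200 + 1).astype(str)
    pos = 10_000 + (idx % 200) * 1_500 + rng.integers(0, 500, size=n)
    ref = bases[rng.integers(0, 4, size=n)]
    shift = rng.integers(1, 4, size=n)
    alt = bases[(np.searchsorted(bases, ref) + shift) % 4]
    return pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt})


def simulate_read_counts(
    truth_vaf: pd.DataFrame,
    series: PatientSeries,
    seed: int = 0,
    error_rate: float = 0.001,
    fixed_depth: bool = False,
    rng: Optional[np.random.Generator] = None,
    variants: Optional[pd.DataFrame] = None,
) -> VariantTable:
    """Draw depth/alt read counts for every (mutation, sample) pair.

    ``truth_vaf`` holds expected VAFs (index mutation id, columns sample
    ids). Depth ~ Poisson(mean_depth) floored at 1 (or fixed), alt ~
    Binomial(depth, expected VAF + error_rate, capped at 1).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = len(truth_vaf)
    if variants is None:
        variants = _place_variants(n, rng)
    variants = variants.copy()
    variants.index = variant_ids(variants)
    mapping = dict(zip(truth_vaf.index, variants.index))

    depth = {}
    alt = {}
    for spec in series.samples:
        if fixed_depth:
            d = np.full(n, int(spec.mean_depth))
        else:
            d = np.maximum(rng.poisson(spec.mean_depth, size=n), 1)
        p = np.clip(truth_vaf[spec.sample_id].to_numpy(dtype=float) + error_rate, 0.0, 1.0)
        alt[spec.sample_id] = rng.binomial(d, p)
        depth[spec.sample_id] = d
    depth_df = pd.DataFrame(depth, index=variants.index)
    alt_df = pd.DataFrame(alt, index=variants.index)
    table = VariantTable(variants=variants, depth=depth_df, alt=alt_df)
    return table, mapping


def simulate_series(
    route: str,
    seed: int = 0,
    steps: Optional[list] = None,
    branch_size_range: tuple = (10, 60),
    n_primary_subclones: int = 2,
    purity=None,
    purity_range: tuple = (0.3, 0.9),
    mean_depth: float = 300.0,
    terminal_fraction: float = 0.45,
    met_private_fraction: float = 0.7,
    error_rate: float = 0.001,
    fixed_depth: bool = False,
    multiplicity: int = 1,
    tumor_copy_number: int = 2,
    patient_id: str = "SIM",
) -> SimulatedSeries:
    """End-to-end simulation: phylogeny -> series -> read counts -> truth."""
    rng = np.random.default_rng(seed)
    steps = list(steps) if steps is not None else _default_steps(route)
    phylogeny, topology, sample_clones = generate_phylogeny(
        route, steps, branch_size_range, rng=rng,
        n_primary_subclones=n_primary_subclones,
    )
    series = build_series(
        phylogeny, topology, sample_clones, steps,
        purity=purity, purity_range=purity_range, mean_depth=mean_depth,
        terminal_fraction=terminal_fraction,
        met_private_fraction=met_private_fraction,
        patient_id=patient_id, rng=rng,
    )
    mutations = sorted(phylogeny.all_mutations())
    vaf = pd.DataFrame(
        {
            spec.sample_id: [
                expected_vaf(m, spec, phylogeny, multiplicity, tumor_copy_number)
                for m in mutations
            ]
            for spec in series.samples
        },
        index=pd.Index(mutations, name="mutation_id"),
    )
    table, mapping = simulate_read_counts(
        vaf, series, error_rate=error_rate, fixed_depth=fixed_depth, rng=rng
    )
    # re-key truth objects by the genomic variant ids the table uses
    phylo2 = ClonalPhylogeny(
        {
            cid: CloneNode(
                cid, node.parent_id,
                frozenset(mapping[m] for m in node.branch_mutations),
            )
            for cid, node in phylogeny.nodes.items()
        }
    )
    vaf.index = pd.Index([mapping[m] for m in vaf.index], name="mutation_id")
    truth = TruthBundle(
        phylogeny=phylo2,
        mutation_origin=phylo2.mutation_origin(),
        expected_vaf=vaf,
        route_truth=topology,
        artifact_labels={mid: SOMATIC for mid in vaf.index},
        seed=seed,
    )
    return SimulatedSeries(series=series, table=table, truth=truth)


def _default_popaf_distribution(rng: np.random.Generator, size: int) -> np.ndarray:
    """80% common SNPs (popAF 2-50%), 20% rare (popAF <= 1%)."""
    common = rng.uniform(0.02, 0.5, size=size)
    rare = rng.uniform(0.0, 0.01, size=size)
    pick = rng.random(size) < 0.8
    return np.where(pick, common, rare)


def inject_artifacts(
    sim: SimulatedSeries,
    germline_rate: float = 0.1,
    germline_popaf_distribution=None,
    artifact_rate: float = 0.05,
    cluster_artifact_spec: Optional[dict] = None,
    seed: int = 0,
) -> SimulatedSeries:
    """Add the record classes the filters exist to remove.

    * germline heterozygous SNPs: BAF ~ 0.5 in every sample including the
      normal, annotated with a population allele frequency;
    * low-BAF sequencing artifacts: BAF below the tumor presence threshold
      in every tumor;
    * clustered artifacts: runs of k variants within a short window at
      otherwise plausible BAF, catchable only by the cluster scan.

    Rates are fractions of the somatic mutation count. Returns a new
    :class:`SimulatedSeries` with augmented table and truth labels.
    """
    if not (0 <= germline_rate <= 1 and 0 <= artifact_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    spec = cluster_artifact_spec or {"n_clusters": 0, "cluster_size": 3, "span": 100}
    rng = np.random.default_rng(seed)
    series, table, truth = sim.series, sim.table, sim.truth
    n_som = len(table)
    n_germ = int(round(germline_rate * n_som))
    n_art = int(round(artifact_rate * n_som))
    n_clusters = int(spec.get("n_clusters", 0))
    k = int(spec.get("cluster_size", 3))
    span = int(spec.get("span", 100))
    n_new = n_germ + n_art + n_clusters * k
    if n_new == 0:
        return sim

    new_vars = _place_variants(n_new, rng, start=10_000)
    # squeeze each cluster's positions into its span window
    row = n_germ + n_art
    for _ in range(n_clusters):
        base = int(new_vars.iloc[row]["pos"])
        offsets = np.sort(rng.choice(span, size=k, replace=False))
        new_vars.iloc[row : row + k, new_vars.columns.get_loc("pos")] = base + offsets
        new_vars.iloc[row : row + k, new_vars.columns.get_loc("chrom")] = new_vars.iloc[row]["chrom"]
        row += k
    new_vars.index = variant_ids(new_vars)

    labels = []
    vaf_rows = {}
    popaf = np.zeros(n_new)
    dist = germline_popaf_distribution or _default_popaf_distribution
    popaf[:n_germ] = dist(rng, n_germ)
    for i, mid in enumerate(new_vars.index):
        if i < n_germ:
            labels.append(GERMLINE)
            vaf_rows[mid] = {s.sample_id: 0.5 for s in series.samples}
        elif i < n_germ + n_art:
            labels.append(ARTIFACT)
            vaf_rows[mid] = {
                s.sample_id: float(rng.uniform(0.005, 0.03)) if s.is_tumor else 0.0
                for s in series.samples
            }
        else:
            labels.append(ARTIFACT)
            vaf_rows[mid] = {
                s.sample_id: 0.5 * (s.purity or 0.0) for s in series.samples
            }
    new_vaf = pd.DataFrame.from_dict(vaf_rows, orient="index")
    new_vaf = new_vaf.loc[new_vars.index, [s.sample_id for s in series.samples]]

    depth = {}
    alt = {}
    for s in series.samples:
        d = np.maximum(rng.poisson(s.mean_depth, size=n_new), 1)
        p = np.clip(new_vaf[s.sample_id].to_numpy(dtype=float), 0.0, 1.0)
        depth[s.sample_id] = d
        alt[s.sample_id] = rng.binomial(d, p)

    variants = pd.concat([table.variants, new_vars])
    if "population_af" not in variants.columns:
        variants["population_af"] = 0.0
    variants.loc[new_vars.index, "population_af"] = popaf
    depth_df = pd.concat([table.depth, pd.DataFrame(depth, index=new_vars.index)])
    alt_df = pd.concat([table.alt, pd.DataFrame(alt, index=new_vars.index)])
    new_table = VariantTable(variants=variants, depth=depth_df, alt=alt_df)

    new_truth = TruthBundle(
        phylogeny=truth.phylogeny,
        mutation_origin=truth.mutation_origin,
        expected_vaf=pd.concat([truth.expected_vaf, new_vaf]),
        route_truth=truth.route_truth,
        artifact_labels={**truth.artifact_labels, **dict(zip(new_vars.index, labels))},
        seed=truth.seed,
    )
    return SimulatedSeries(series=series, table=new_table, truth=new_truth)


def write_fixture(sim: SimulatedSeries, directory) -> dict:
    """Write variants.tsv, samples.tsv and truth.json into ``directory``."""
    from . import io as _io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": directory / "variants.tsv",
        "samples": directory / "samples.tsv",
        "truth": directory / "truth.json",
    }
    _io.write_variants_tsv(sim.table, paths["variants"], stage="simulate")
    _io.write_series_tsv(sim.series, paths["samples"])
    truth = sim.truth
    payload = {
        "seed": truth.seed,
        "patient_id": sim.series.patient_id,
        "route_labels": truth.route_truth.route_labels,
        "seeding_edges": [list(e) for e in truth.route_truth.seeding_edges],
        "clones": [
            {
                "clone_id": n.clone_id,
                "parent_id": n.parent_id,
                "branch_mutations": sorted(n.branch_mutations),
            }
            for n in truth.phylogeny.nodes.values()
        ],
        "clone_fractions": {
            s.sample_id: s.clone_fractions for s in sim.series.samples
        },
        "mutation_origin": truth.mutation_origin,
        "artifact_labels": truth.artifact_labels,
        "expected_vaf": {
            mid: {
                sid: round(float(v), 6)
                for sid, v in truth.expected_vaf.loc[mid].items()
            }
            for mid in truth.expected_vaf.index
        },
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
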