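"""The multi-sample variant table: per mutation x per sample read counts.

Coordinates are 1-based inclusive throughout (VCF convention). A variant
is identified by the string ``chrom:pos:ref:alt``; the B-allele frequency
(BAF) of a site is alt reads / total reads, 0 at zero depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]


def variant_ids(variants: pd.DataFrame) -> pd.Index:
    """Canonical ``chrom:pos:ref:alt`` identifiers for a variant frame."""
    return pd.Index(
        variants["chrom"].astype(str)
        + ":"
        + variants["pos"].astype(int).astype(str)
        + ":"
        + variants["ref"].astype(str)
        + ":"
        + variants["alt"].astype(str),
        name="mutation_id",
    )


def compute_baf(alt_count, depth):
    """BAF = alt / depth, defined as 0 where depth is 0.

    Accepts scalars or aligned arrays. Raises if any alt count exceeds
    its depth (impossible observation).
    """
    alt_arr = np.asarray(alt_count, dtype=float)
    depth_arr = np.asarray(depth, dtype=float)
    if np.any(alt_arr > depth_arr):
        raise ValueError("alt count exceeds read depth")
    if np.any(alt_arr < 0) or np.any(depth_arr < 0):
        raise ValueError("negative read counts")
    with np.errstate(divide="ignore", invalid="ignore"):
        baf = np.where(depth_arr > 0, alt_arr / np.where(depth_arr > 0, depth_arr, 1), 0.0)
    if np.isscalar(alt_count) and np.isscalar(depth):
        return float(baf)
    return baf


@dataclass
class VariantTable:
    """Per-mutation, per-sample observations for one patient series.

    Attributes
    ----------
    variants : DataFrame
        Indexed by mutation id; columns ``chrom, pos, ref, alt`` and
        optionally ``population_af``.
    depth, alt : DataFrame
        Integer read counts, index = mutation id, columns = sample ids.
    """

    variants: pd.DataFrame
    depth: pd.DataFrame
    alt: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.variants.index.equals(self.depth.index) and self.variants.index.equals(self.alt.index)):
            raise ValueError("variants, depth and alt must share one index")
        if list(self.depth.columns) != list(self.alt.columns):
            raise ValueError("depth and alt must cover the same samples")
        if (self.alt.to_numpy() > self.depth.to_numpy()).any():
            raise ValueError("alt count exceeds read depth")

    @property
    def sample_ids(self) -> list:
        return list(self.depth.columns)

    @property
    def mutation_ids(self) -> pd.Index:
        return self.variants.index

    @property
    def baf(self) -> pd.DataFrame:
        d = self.depth.to_numpy(dtype=float)
        a = self.alt.to_numpy(dtype=float)
        vals = np.where(d > 0, a / np.where(d > 0, d, 1), 0.0)
        return pd.DataFrame(vals, index=self.variants.index, columns=self.depth.columns)

    def __len__(self) -> int:
        return len(self.variants)

    def subset(self, mutation_ids) -> "VariantTable":
        idx = self.variants.index.intersection(pd.Index(mutation_ids))
        # preserve original row order
        idx = self.variants.index[self.variants.index.isin(idx)]
        return VariantTable(
            variants=self.variants.loc[idx].copy(),
            depth=self.depth.loc[idx].copy(),
            alt=self.alt.loc[idx].copy(),
        )

    def drop(self, mutation_ids) -> "VariantTable":
        keep = self.variants.index.difference(pd.Index(mutation_ids), sort=False)
        keep = self.variants.index[self.variants.index.isin(keep)]
        return self.subset(keep)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the on-disk schema: chrom, pos, ref, alt
        [, population_af], then ``<sample>_depth, <sample>_alt, <sample>_baf``
        triplets per sample."""
        out = self.variants.copy()
        baf = self.baf
        for sid in self.sample_ids:
            out[f"{sid}_depth"] = self.depth[sid]
            out[f"{sid}_alt"] = self.alt[sid]
            out[f"{sid}_baf"] = baf[sid].round(6)
        return out.reset_index(drop=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "VariantTable":
        missing = [c for c in VARIANT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        sample_ids = [
            c[: -len("_depth")] for c in frame.columns if c.endswith("_depth")
        ]
        var_cols = [c for c in frame.columns if not any(
            c.endswith(suf) for suf in ("_depth", "_alt", "_baf")
        )]
        variants = frame[var_cols].copy()
        variants["chrom"] = variants["chrom"].astype(str)
        variants["pos"] = variants["pos"].astype(int)
        variants.index = variant_ids(variants)
        if variants.index.has_duplicates:
            dups = variants.index[variants.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate variant records: {dups[:5]}")
        depth = pd.DataFrame(
            {sid: frame[f"{sid}_depth"].to_numpy(dtype=int) for sid in sample_ids},
            index=variants.index,
        )
        alt = pd.DataFrame(
            {sid: frame[f"{sid}_alt"].to_numpy(dtype=int) for sid in sample_ids},
            index=variants.index,
        )
        return cls(variants=variants, depth=depth, alt=alt)


PRESENT = "present"
ABSENT = "absent"
UNCERTAIN = "uncertain"

CLONAL = "clonal"
SUBCLONAL = "subclonal"
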