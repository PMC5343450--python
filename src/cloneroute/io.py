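"""Readers and writers binding the pipeline stages.

Coordinates are 1-based inclusive everywhere internally (the VCF
convention); BED exclusion intervals (0-based half-open) are converted at
the boundary. Every emitted table starts with ``#`` comment lines naming
the producing stage, so downstream provenance is visible in the file.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .series import PatientSeries, SampleSpec
from .tables import VariantTable, variant_ids


def _write_with_header(frame: pd.DataFrame, path, stage: str) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# cloneroute stage={stage}\n")
        frame.to_csv(fh, sep="\t", index=False)


def write_variants_tsv(table: VariantTable, path, stage: str = "unknown") -> None:
    _write_with_header(table.to_frame(), path, stage)


def read_variants_tsv(path) -> VariantTable:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return VariantTable.from_frame(frame)


def write_series_tsv(series: PatientSeries, path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "step_label": s.step_label,
            "order_index": s.order_index,
            "purity": "" if s.purity is None else s.purity,
            "mean_depth": s.mean_depth,
        }
        for s in series.samples
    ]
    frame = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# cloneroute patient={series.patient_id}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_series_tsv(path, patient_id: str = None) -> PatientSeries:
    path = Path(path)
    pid = patient_id
    with open(path) as fh:
        first = fh.readline()
        if pid is None and first.startswith("#") and "patient=" in first:
            pid = first.split("patient=")[1].strip()
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "step_label", "order_index"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    samples = []
    for _, row in frame.iterrows():
        purity = row.get("purity")
        if purity is not None and (pd.isna(purity) or purity == ""):
            purity = None
        samples.append(
            SampleSpec(
                sample_id=str(row["sample_id"]),
                step_label=str(row["step_label"]),
                order_index=int(row["order_index"]),
                purity=None if purity is None else float(purity),
                mean_depth=float(row.get("mean_depth", 300.0)),
            )
        )
    return PatientSeries(pid or "unknown", samples)


def read_variants(path, fmt: str = None, series: PatientSeries = None) -> VariantTable:
    """Read a multi-sample variant table from TSV or VCF.

    Format is inferred from the suffix when not given. When a series is
    supplied, the file's samples are checked against it and any mismatch
    reported as the symmetric difference.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".bcf") or str(path).endswith(".vcf.gz") else "tsv"
    if fmt == "tsv":
        table = read_variants_tsv(path)
    elif fmt == "vcf":
        table = read_variants_vcf(path)
    else:
        raise ValueError(f"unknown variant format {fmt!r}")
    if series is not None:
        file_samples = set(table.sample_ids)
        meta_samples = set(series.sample_ids)
        if file_samples != meta_samples:
            diff = sorted(file_samples ^ meta_samples)
            raise ValueError(
                f"sample ids disagree between variant file and metadata; "
                f"symmetric difference: {diff}"
            )
    return table


def read_variants_vcf(path) -> VariantTable:
    """Read a multi-sample VCF with per-sample DP and AD FORMAT fields."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    depths = []
    alts = []
    for rec in vcf:
        fmts = rec.FORMAT
        for field_name in ("DP", "AD"):
            if field_name not in fmts:
                raise ValueError(
                    f"VCF record {rec.CHROM}:{rec.POS} lacks FORMAT field "
                    f"{field_name} required for samples {samples}"
                )
        alt_allele = rec.ALT[0] if rec.ALT else "."
        rows.append(
            {"chrom": rec.CHROM, "pos": rec.POS, "ref": rec.REF, "alt": alt_allele}
        )
        dp = rec.format("DP")[:, 0].astype(int)
        ad = rec.format("AD")
        alt_counts = ad[:, 1].astype(int) if ad.shape[1] > 1 else ad[:, 0] * 0
        depths.append(dp)
        alts.append(alt_counts)
    vcf.close()
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    variants.index = variant_ids(variants)
    depth = pd.DataFrame(depths, index=variants.index, columns=samples, dtype=int) \
        if rows else pd.DataFrame(index=variants.index, columns=samples, dtype=int)
    alt = pd.DataFrame(alts, index=variants.index, columns=samples, dtype=int) \
        if rows else pd.DataFrame(index=variants.index, columns=samples, dtype=int)
    return VariantTable(variants=variants, depth=depth, alt=alt)


def read_bed_intervals(path) -> list:
    """BED (0-based half-open) -> list of 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: BED line needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            out.append((chrom, start + 1, end))
    return out


def read_truth_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_presence_tsv(presence: pd.DataFrame, path, stage: str = "filter") -> None:
    frame = presence.reset_index()
    _write_with_header(frame, path, stage)


def write_decisions_tsv(decisions: pd.DataFrame, path) -> None:
    _write_with_header(decisions.reset_index(names="mutation_id"), path, "filter")


def write_assignments_tsv(
    first_appearance: pd.Series, clonality: pd.DataFrame, path
) -> None:
    frame = clonality.copy()
    frame.columns = [f"clonality_{c}" for c in frame.columns]
    frame.insert(0, "first_appearance", first_appearance)
    _write_with_header(frame.reset_index(names="mutation_id"), path, "assign")


def write_route_json(route_calls, concordance: pd.DataFrame, path) -> None:
    payload = {
        "route_calls": [
            {
                "metastasis": rc.metastasis,
                "route": rc.route,
                "source": rc.source,
                "evidence": rc.evidence,
                "caveats": rc.caveats,
            }
            for rc in route_calls
        ],
        "concordance": concordance.to_dict(orient="records"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
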