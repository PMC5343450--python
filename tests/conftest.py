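import numpy as np
import pandas as pd
import pytest

from cloneroute.series import PatientSeries, SampleSpec
from cloneroute.tables import VariantTable, variant_ids


def make_table(records, sample_ids):
    """Build a VariantTable from handwritten records.

    Each record: (chrom, pos, ref, alt, {sample: (depth, alt_count)})
    or optionally a 6th element: population AF.
    """
    rows, depth, alt, popaf = [], [], [], []
    has_popaf = any(len(r) > 5 for r in records)
    for rec in records:
        chrom, pos, ref, alt_allele, obs = rec[:5]
        rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt_allele})
        depth.append([obs[s][0] for s in sample_ids])
        alt.append([obs[s][1] for s in sample_ids])
        popaf.append(rec[5] if len(rec) > 5 else 0.0)
    variants = pd.DataFrame(rows)
    variants.index = variant_ids(variants)
    if has_popaf:
        variants["population_af"] = popaf
    return VariantTable(
        variants=variants,
        depth=pd.DataFrame(depth, index=variants.index, columns=sample_ids),
        alt=pd.DataFrame(alt, index=variants.index, columns=sample_ids),
    )


def make_series(steps_purity, patient_id="T", mean_depth=300.0):
    """Series from [(sample_id, step_label, purity), ...] in order."""
    samples = [
        SampleSpec(sid, step, i, purity=purity, mean_depth=mean_depth)
        for i, (sid, step, purity) in enumerate(steps_purity)
    ]
    return PatientSeries(patient_id, samples)


@pytest.fixture
def trio_series():
    return make_series(
        [("normal", "normal", 0.0), ("primary", "primary", 0.8), ("sALN", "sALN", 0.8)]
    )


@pytest.fixture
def quad_series():
    return make_series(
        [
            ("normal", "normal", 0.0),
            ("primary", "primary", 0.8),
            ("sALN", "sALN", 0.8),
            ("aDM", "aDM", 0.8),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20_17)
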