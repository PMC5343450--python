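"""Patient-series metadata: ordered disease steps with purity and depth.

A series is the ordered sequence of samples from one patient —
normal, then (optionally) pre-invasive DCIS, primary tumor, synchronous
axillary lymph-node metastasis (sALN) and asynchronous distant metastasis
(aDM). The order index encodes "previous steps of progression": every
tumor sample is interpreted relative to the samples that precede it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

STEP_LABELS = ("normal", "DCIS", "primary", "sALN", "aDM")
METASTASIS_STEPS = ("sALN", "aDM")


@dataclass
class SampleSpec:
    """One sample of a patient series.

    Parameters
    ----------
    sample_id : str
        Unique identifier, used as the column key in variant tables.
    step_label : str
        One of ``normal, DCIS, primary, sALN, aDM``.
    order_index : int
        Position along the progression (normal first).
    purity : float
        Fraction of malignant cells; 0 for the normal sample, in (0, 1]
        for tumor samples. May be ``None`` for tumors when it is to be
        estimated from the data.
    mean_depth : float
        Mean sequencing depth (reads) at targeted positions.
    clone_fractions : dict
        Mapping clone id -> fraction of *malignant* cells that are exactly
        that clone. Only populated for simulated samples; fractions sum
        to 1.
    """

    sample_id: str
    step_label: str
    order_index: int
    purity: Optional[float] = None
    mean_depth: float = 300.0
    clone_fractions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.step_label not in STEP_LABELS:
            raise ValueError(
                f"unknown step_label {self.step_label!r}; expected one of {STEP_LABELS}"
            )
        if self.step_label == "normal":
            if self.purity not in (None, 0, 0.0):
                raise ValueError("normal sample must have purity 0")
            self.purity = 0.0
        elif self.purity is not None and not (0.0 < self.purity <= 1.0):
            raise ValueError(
                f"tumor purity must lie in (0, 1], got {self.purity} for {self.sample_id}"
            )
        if self.clone_fractions:
            total = sum(self.clone_fractions.values())
            if self.step_label != "normal" and abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"clone fractions for {self.sample_id} sum to {total}, not 1"
                )

    @property
    def is_tumor(self) -> bool:
        return self.step_label != "normal"

    @property
    def is_metastasis(self) -> bool:
        return self.step_label in METASTASIS_STEPS


@dataclass
class PatientSeries:
    """Ordered collection of :class:`SampleSpec` for one patient."""

    patient_id: str
    samples: list

    def __post_init__(self) -> None:
        order = [s.order_index for s in self.samples]
        if len(set(order)) != len(order):
            raise ValueError("order indices must be unique")
        self.samples = sorted(self.samples, key=lambda s: s.order_index)
        normals = [s for s in self.samples if s.step_label == "normal"]
        if len(normals) != 1:
            raise ValueError(
                f"series {self.patient_id} must contain exactly one normal sample, "
                f"found {len(normals)}"
            )

    @property
    def normal(self) -> SampleSpec:
        return next(s for s in self.samples if s.step_label == "normal")

    @property
    def tumors(self) -> list:
        return [s for s in self.samples if s.is_tumor]

    @property
    def metastases(self) -> list:
        return [s for s in self.samples if s.is_metastasis]

    @property
    def sample_ids(self) -> list:
        return [s.sample_id for s in self.samples]

    @property
    def tumor_ids(self) -> list:
        return [s.sample_id for s in self.tumors]

    def get(self, sample_id: str) -> SampleSpec:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(f"sample {sample_id!r} not in series {self.patient_id}")

    def by_step(self, step_label: str) -> list:
        return [s for s in self.samples if s.step_label == step_label]

    def primary(self) -> SampleSpec:
        prim = self.by_step("primary")
        if not prim:
            raise ValueError(f"series {self.patient_id} has no primary sample")
        return prim[0]

    def preceding(self, sample_id: str) -> list:
        """Tumor samples strictly earlier in progression order."""
        target = self.get(sample_id)
        return [
            s for s in self.tumors if s.order_index < target.order_index
        ]
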