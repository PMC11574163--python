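"""Domain containers shared by every pipeline stage.

PSI and expression grids wrap pandas DataFrames (rows = events / genes,
columns = sample ids); the light dataclasses around them carry the identity
and validity rules the readers and the simulator both enforce.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class Tissue(str, enum.Enum):
    TUMOR = "tumor"
    NORMAL = "normal"


class VariantClass(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    IN_FRAME = "in_frame"
    SILENT = "silent"
    OTHER = "other"


#: variant classes that count as functional hits (silent never confers status)
NON_SILENT = frozenset(
    {
        VariantClass.MISSENSE,
        VariantClass.NONSENSE,
        VariantClass.FRAMESHIFT,
        VariantClass.SPLICE_SITE,
        VariantClass.IN_FRAME,
        VariantClass.OTHER,
    }
)

AS_TYPES = ("ES", "AA", "AD", "RI")

_EVENT_SEP = "|"
_EXON_SEP = ":"


@dataclass(frozen=True)
class SpliceEvent:
    """Identity of one alternative-splicing event.

    Exon labels are SpliceSeq gene-level exon numbers kept as opaque strings
    (sub-exons like ``"27.1"`` are legal); they are never genomic coordinates.
    """

    gene: str
    as_type: str
    event_exons: tuple[str, ...]
    upstream_exon: str
    downstream_exon: str

    def __post_init__(self) -> None:
        if self.as_type not in AS_TYPES:
            raise ValueError(
                f"as_type must be one of {AS_TYPES}, got {self.as_type!r}"
            )
        if not self.event_exons:
            raise ValueError("event_exons must be non-empty")
        object.__setattr__(self, "event_exons", tuple(self.event_exons))

    @property
    def event_id(self) -> str:
        """Canonical ``GENE|TYPE|event|up|down`` string."""
        return _EVENT_SEP.join(
            (
                self.gene,
                self.as_type,
                _EXON_SEP.join(self.event_exons),
                self.upstream_exon,
                self.downstream_exon,
            )
        )

    @classmethod
    def from_id(cls, event_id: str) -> "SpliceEvent":
        parts = event_id.split(_EVENT_SEP)
        if len(parts) != 5:
            raise ValueError(
                f"event id {event_id!r} must have 5 '|'-separated fields"
            )
        gene, as_type, exons, up, down = parts
        return cls(gene, as_type, tuple(exons.split(_EXON_SEP)), up, down)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.event_id


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    patient_id: str
    cancer_type: str
    tissue: Tissue

    def __post_init__(self) -> None:
        object.__setattr__(self, "tissue", Tissue(self.tissue))


@dataclass(frozen=True)
class MutationRecord:
    patient_id: str
    gene: str
    variant_class: VariantClass

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant_class", VariantClass(self.variant_class))


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    time: float  # survival/follow-up time in days, strictly positive
    event: int  # 1 = death observed, 0 = right-censored
    arm: str

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(
                f"survival time must be strictly positive, got {self.time}"
            )
        if self.event not in (0, 1):
            raise ValueError(f"event indicator must be 0 or 1, got {self.event}")


class PsiMatrix:
    """Events x samples grid of percent-spliced-in values in [0, 1].

    Missing quantifications are NaN.  Rows are indexed by canonical event id.
    """

    def __init__(self, events: list[SpliceEvent], values: pd.DataFrame):
        ids = [e.event_id for e in events]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate event ids")
        if list(values.index) != ids:
            raise ValueError("values index must equal event ids, in order")
        arr = values.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValueError(
                f"PSI out of [0,1] at event {ids[i]!r}, sample "
                f"{values.columns[j]!r}: {arr[i, j]}"
            )
        self.events = list(events)
        self.values = values.astype(float)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def event(self, event_id: str) -> SpliceEvent:
        for e in self.events:
            if e.event_id == event_id:
                return e
        raise KeyError(f"event {event_id!r} not in matrix")

    def row(self, event_id: str) -> pd.Series:
        if event_id not in self.values.index:
            raise KeyError(f"event {event_id!r} not in matrix")
        return self.values.loc[event_id]

    def __contains__(self, event_id: str) -> bool:
        return event_id in self.values.index

    def __len__(self) -> int:
        return len(self.events)


class ExprMatrix:
    """Genes x samples grid of FPKM expression values (non-negative)."""

    def __init__(self, values: pd.DataFrame):
        arr = values.to_numpy(dtype=float)
        bad = (arr < 0) & ~np.isnan(arr)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"negative FPKM at gene {values.index[i]!r}, sample "
                f"{values.columns[j]!r}: {arr[i, j]}"
            )
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate gene {dup!r}")
        self.values = values.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def row(self, gene: str) -> pd.Series:
        if gene not in self.values.index:
            raise KeyError(f"gene {gene!r} not in expression matrix")
        return self.values.loc[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.values.index


@dataclass
class CohortBundle:
    """One cancer type's linked tables."""

    cancer_type: str
    samples: list[SampleRecord]
    psi: PsiMatrix
    expr: ExprMatrix
    mutations: list[MutationRecord] = field(default_factory=list)
    clinical: list[ClinicalRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in bundle")
        known = set(ids)
        for mat, name in ((self.psi, "psi"), (self.expr, "expr")):
            unknown = set(mat.samples) - known
            if unknown:
                raise ValueError(
                    f"{name} matrix references unknown samples: {sorted(unknown)[:3]}"
                )
        patients = {s.patient_id for s in self.samples}
        for rec in self.mutations:
            if rec.patient_id not in patients:
                raise ValueError(f"mutation for unknown patient {rec.patient_id!r}")
        for rec in self.clinical:
            if rec.patient_id not in patients:
                raise ValueError(f"clinical row for unknown patient {rec.patient_id!r}")

    def samples_by_tissue(self, tissue: Tissue) -> list[SampleRecord]:
        return [s for s in self.samples if s.tissue == tissue]

    def tumor_sample_of(self, patient_id: str) -> str | None:
        """First tumor sample of a patient in file order (duplicates ignored)."""
        for s in self.samples:
            if s.patient_id == patient_id and s.tissue == Tissue.TUMOR:
                return s.sample_id
        return None
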