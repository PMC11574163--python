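"""Readers and writers for every table the pipeline touches.

Dialect: UTF-8 TSV, "." decimal separator, missing cells written as "" and
accepted as "" or "NA".  PSI values are serialized to 4 decimals.  All
validation is total — a malformed cell raises a located error, never a
silent coercion.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from splicescreen.types import (
    ClinicalRecord,
    CohortBundle,
    ExprMatrix,
    MutationRecord,
    PsiMatrix,
    SampleRecord,
    SpliceEvent,
    Tissue,
    VariantClass,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "infer_tissue_from_barcode",
    "read_bundle",
    "read_clinical",
    "read_expr_table",
    "read_gene_list",
    "read_mutations",
    "read_psi_table",
    "read_samples",
    "write_bundle",
    "write_clinical",
    "write_expr_table",
    "write_gene_list",
    "write_mutations",
    "write_psi_table",
    "write_samples",
]


class FormatError(ValueError):
    """The file does not have the expected shape (header, columns)."""


class ValidationError(ValueError):
    """A cell violates a value constraint; the message locates it."""


PSI_ID_COLUMNS = ("symbol", "splice_type", "exons", "from_exon", "to_exon")
MISSING_TOKENS = ("", "NA")

#: MAF Variant_Classification spellings -> internal enum
MAF_VARIANT_MAP = {
    "Missense_Mutation": VariantClass.MISSENSE,
    "Nonsense_Mutation": VariantClass.NONSENSE,
    "Nonstop_Mutation": VariantClass.NONSENSE,
    "Frame_Shift_Del": VariantClass.FRAMESHIFT,
    "Frame_Shift_Ins": VariantClass.FRAMESHIFT,
    "Splice_Site": VariantClass.SPLICE_SITE,
    "Splice_Region": VariantClass.SPLICE_SITE,
    "In_Frame_Del": VariantClass.IN_FRAME,
    "In_Frame_Ins": VariantClass.IN_FRAME,
    "Silent": VariantClass.SILENT,
}
# accept our own lowercase spellings on re-read
MAF_VARIANT_MAP.update({v.value: v for v in VariantClass})


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _parse_number(
    raw: str, *, path, row: int, column: str, lo: float | None, hi: float | None
) -> float:
    raw = raw.strip()
    if raw in MISSING_TOKENS:
        return np.nan
    try:
        val = float(raw)
    except ValueError:
        raise ValidationError(
            f"{path}: row {row}, column {column!r}: not a number: {raw!r}"
        ) from None
    if lo is not None and val < lo or hi is not None and val > hi:
        bound = f"[{lo}, {hi}]" if hi is not None else f">= {lo}"
        raise ValidationError(
            f"{path}: row {row}, column {column!r}: value {val} outside {bound}"
        )
    return val


def infer_tissue_from_barcode(sample_id: str) -> Tissue:
    """TCGA barcode convention: trailing two-digit sample-type code,
    01-09 tumor, 10-19 normal."""
    m = re.search(r"-(\d{2})[A-Z]?$", sample_id)
    if not m:
        raise ValidationError(
            f"sample id {sample_id!r} has no trailing two-digit TCGA sample-type "
            "code; supply an explicit tissue column instead"
        )
    code = int(m.group(1))
    if 1 <= code <= 9:
        return Tissue.TUMOR
    if 10 <= code <= 19:
        return Tissue.NORMAL
    raise ValidationError(
        f"sample id {sample_id!r}: sample-type code {code:02d} is neither "
        "tumor (01-09) nor normal (10-19)"
    )


# ---------------------------------------------------------------- PSI tables


def read_psi_table(path: str | Path) -> PsiMatrix:
    """Parse a SpliceSeq-style PSI table.

    Header: the five event-identity columns of :data:`PSI_ID_COLUMNS`, then
    one column per sample.  Missing PSI is "" or "NA"; values outside [0, 1]
    are rejected with the offending cell named.
    """
    df = _read_tsv(path)
    missing_cols = [c for c in PSI_ID_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(
            f"{path}: PSI table header is missing column(s) {missing_cols}"
        )
    sample_cols = [c for c in df.columns if c not in PSI_ID_COLUMNS]
    events = []
    rows = []
    for idx, rec in df.iterrows():
        ev = SpliceEvent(
            gene=rec["symbol"],
            as_type=rec["splice_type"],
            event_exons=tuple(rec["exons"].split(":")),
            upstream_exon=rec["from_exon"],
            downstream_exon=rec["to_exon"],
        )
        events.append(ev)
        rows.append(
            [
                _parse_number(rec[c], path=path, row=idx + 2, column=c, lo=0.0, hi=1.0)
                for c in sample_cols
            ]
        )
    values = pd.DataFrame(
        rows, index=[e.event_id for e in events], columns=sample_cols, dtype=float
    )
    return PsiMatrix(events, values)


def write_psi_table(psi: PsiMatrix, path: str | Path) -> None:
    rows = []
    for ev in psi.events:
        row = {
            "symbol": ev.gene,
            "splice_type": ev.as_type,
            "exons": ":".join(ev.event_exons),
            "from_exon": ev.upstream_exon,
            "to_exon": ev.downstream_exon,
        }
        vals = psi.values.loc[ev.event_id]
        for s in psi.samples:
            v = vals[s]
            row[s] = "" if np.isnan(v) else f"{v:.4f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------- expression tables


def read_expr_table(path: str | Path) -> ExprMatrix:
    df = _read_tsv(path)
    if "gene" not in df.columns:
        raise FormatError(f"{path}: expression table header is missing 'gene'")
    sample_cols = [c for c in df.columns if c != "gene"]
    parsed = {
        c: [
            _parse_number(v, path=path, row=i + 2, column=c, lo=0.0, hi=None)
            for i, v in enumerate(df[c])
        ]
        for c in sample_cols
    }
    values = pd.DataFrame(parsed, index=df["gene"].tolist(), dtype=float)
    return ExprMatrix(values)


def write_expr_table(expr: ExprMatrix, path: str | Path) -> None:
    out = expr.values.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="")


# ------------------------------------------------------------ mutation table


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Minimal MAF reader: Tumor_Sample_Barcode (patient), Hugo_Symbol,
    Variant_Classification.  Unknown classifications map to ``other`` with a
    logged warning."""
    df = _read_tsv(path)
    required = ("Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: mutation table is missing column(s) {missing}")
    records = []
    for idx, rec in df.iterrows():
        raw = rec["Variant_Classification"]
        vc = MAF_VARIANT_MAP.get(raw)
        if vc is None:
            logger.warning(
                "%s: row %d: unknown variant classification %r mapped to 'other'",
                path,
                idx + 2,
                raw,
            )
            vc = VariantClass.OTHER
        records.append(
            MutationRecord(
                patient_id=rec["Tumor_Sample_Barcode"],
                gene=rec["Hugo_Symbol"],
                variant_class=vc,
            )
        )
    return records


def write_mutations(records: list[MutationRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "Tumor_Sample_Barcode": [r.patient_id for r in records],
            "Hugo_Symbol": [r.gene for r in records],
            "Variant_Classification": [r.variant_class.value for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------ clinical table


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    df = _read_tsv(path)
    required = ("patient_id", "time_days", "event", "arm")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: clinical table is missing column(s) {missing}")
    records = []
    for idx, rec in df.iterrows():
        t = _parse_number(
            rec["time_days"], path=path, row=idx + 2, column="time_days", lo=None, hi=None
        )
        if np.isnan(t) or t <= 0:
            raise ValidationError(
                f"{path}: row {idx + 2}, column 'time_days': survival time must be "
                f"a positive number, got {rec['time_days']!r}"
            )
        if rec["event"] not in ("0", "1"):
            raise ValidationError(
                f"{path}: row {idx + 2}, column 'event': must be 0 or 1, "
                f"got {rec['event']!r}"
            )
        records.append(
            ClinicalRecord(
                patient_id=rec["patient_id"],
                time=t,
                event=int(rec["event"]),
                arm=rec["arm"],
            )
        )
    return records


def write_clinical(records: list[ClinicalRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "time_days": [f"{r.time:g}" for r in records],
            "event": [r.event for r in records],
            "arm": [r.arm for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- sample table


def read_samples(path: str | Path) -> list[SampleRecord]:
    """Sample manifest: sample_id, patient_id, cancer_type and either an
    explicit ``tissue`` column or TCGA-coded sample ids (never a mix)."""
    df = _read_tsv(path)
    required = ("sample_id", "patient_id", "cancer_type")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: sample table is missing column(s) {missing}")
    has_tissue = "tissue" in df.columns
    records = []
    for idx, rec in df.iterrows():
        if has_tissue:
            raw = rec["tissue"].strip()
            if raw == "":
                raise ValidationError(
                    f"{path}: row {idx + 2}: tissue column present but empty; "
                    "mixing explicit and inferred tissue is not allowed"
                )
            try:
                tissue = Tissue(raw)
            except ValueError:
                raise ValidationError(
                    f"{path}: row {idx + 2}: tissue must be 'tumor' or 'normal', "
                    f"got {raw!r}"
                ) from None
        else:
            tissue = infer_tissue_from_barcode(rec["sample_id"])
        records.append(
            SampleRecord(
                sample_id=rec["sample_id"],
                patient_id=rec["patient_id"],
                cancer_type=rec["cancer_type"],
                tissue=tissue,
            )
        )
    return records


def write_samples(records: list[SampleRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "cancer_type": [r.cancer_type for r in records],
            "tissue": [r.tissue.value for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- gene lists


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genes = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


# -------------------------------------------------------------- bundle level

_BUNDLE_FILES = {
    "samples": "{ct}.samples.tsv",
    "psi": "{ct}.psi.tsv",
    "expr": "{ct}.expr.tsv",
    "mutations": "{ct}.mutations.tsv",
    "clinical": "{ct}.clinical.tsv",
}


def write_bundle(bundle: CohortBundle, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ct = bundle.cancer_type
    paths = {k: out_dir / v.format(ct=ct) for k, v in _BUNDLE_FILES.items()}
    write_samples(bundle.samples, paths["samples"])
    write_psi_table(bundle.psi, paths["psi"])
    write_expr_table(bundle.expr, paths["expr"])
    write_mutations(bundle.mutations, paths["mutations"])
    write_clinical(bundle.clinical, paths["clinical"])
    return paths


def read_bundle(in_dir: str | Path, cancer_type: str) -> CohortBundle:
    in_dir = Path(in_dir)
    paths = {k: in_dir / v.format(ct=cancer_type) for k, v in _BUNDLE_FILES.items()}
    return CohortBundle(
        cancer_type=cancer_type,
        samples=read_samples(paths["samples"]),
        psi=read_psi_table(paths["psi"]),
        expr=read_expr_table(paths["expr"]),
        mutations=read_mutations(paths["mutations"]),
        clinical=read_clinical(paths["clinical"]),
    )
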