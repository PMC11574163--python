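"""Driver-gene compilation: mutation-frequency ranking intersected with a
curated driver catalogue.

"Most frequently mutated" is counted as the number of distinct patients with
at least one non-silent mutation in the gene; the per-cancer top-n lists are
unioned and then intersected with the catalogue, yielding one pooled driver
set annotated with the cancer types that contributed each gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from splicescreen.types import MutationRecord, VariantClass

logger = logging.getLogger(__name__)

__all__ = [
    "GeneMutationCount",
    "count_mutated_patients",
    "top_n_genes",
    "compile_driver_set",
]


@dataclass(frozen=True)
class GeneMutationCount:
    gene: str
    n_patients_mutated: int
    rank: int | None = None  # 1-based, assigned by top_n_genes


def count_mutated_patients(
    mutations: list[MutationRecord], include_silent: bool = False
) -> list[GeneMutationCount]:
    """Distinct mutated patients per gene; multiple hits in one patient count
    once.  Silent mutations are excluded unless ``include_silent``."""
    seen: dict[str, set[str]] = {}
    for rec in mutations:
        if rec.variant_class == VariantClass.SILENT and not include_silent:
            continue
        seen.setdefault(rec.gene, set()).add(rec.patient_id)
    return [
        GeneMutationCount(gene, len(patients))
        for gene, patients in sorted(seen.items())
    ]


def top_n_genes(counts: list[GeneMutationCount], n: int = 60) -> list[GeneMutationCount]:
    """First ``n`` genes by count descending, ties broken by symbol ascending.

    The cut is hard: boundary ties are resolved by the same deterministic
    order, so the result has exactly min(n, #genes) entries.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    ranked = sorted(counts, key=lambda c: (-c.n_patients_mutated, c.gene))
    return [
        GeneMutationCount(c.gene, c.n_patients_mutated, rank=i + 1)
        for i, c in enumerate(ranked[:n])
    ]


def compile_driver_set(
    top_lists: dict[str, list[GeneMutationCount]] | dict[str, list[str]],
    catalogue: set[str] | list[str],
) -> dict[str, list[str]]:
    """Union of per-cancer top lists intersected with the driver catalogue.

    Returns ``{gene: [cancer types that contributed it]}``, genes sorted.
    """
    catalogue = set(catalogue)
    if not catalogue:
        raise ValueError("driver catalogue is empty; the screen would be vacuous")
    contributed: dict[str, list[str]] = {}
    for ct in sorted(top_lists):
        for entry in top_lists[ct]:
            gene = entry.gene if isinstance(entry, GeneMutationCount) else entry
            if gene in catalogue:
                contributed.setdefault(gene, [])
                if ct not in contributed[gene]:
                    contributed[gene].append(ct)
    if not contributed:
        logger.warning("driver catalogue is disjoint from all top-n lists")
    return dict(sorted(contributed.items()))
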