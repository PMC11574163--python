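"""Per-patient tumor-vs-adjacent-normal deltas and the paired alteration
frequency.

A dually sampled patient is *altered* for an event when the magnitude of
their within-patient dPSI strictly exceeds the threshold (default 0.15, the
"more than 0.15" rule); patients with a missing PSI on either side are
unevaluable and excluded from the frequency denominator.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np

from splicescreen.types import PsiMatrix, SampleRecord, SpliceEvent, Tissue

logger = logging.getLogger(__name__)

__all__ = ["PairCall", "PairedDelta", "patient_deltas", "alteration_frequency"]

DEFAULT_THRESHOLD = 0.15


class PairCall(str, enum.Enum):
    INCLUDED = "included"  # delta > threshold
    EXCLUDED = "excluded"  # delta < -threshold
    UNCHANGED = "unchanged"
    UNEVALUABLE = "unevaluable"


@dataclass(frozen=True)
class PairedDelta:
    patient_id: str
    event_id: str
    delta_psi: float  # tumor - normal, NaN when unevaluable
    call: PairCall


def patient_deltas(
    psi: PsiMatrix,
    samples: list[SampleRecord],
    event: SpliceEvent | str,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[PairedDelta]:
    """One record per patient with both a tumor and a normal sample.

    Patients with several samples of one tissue use the first in file order.
    """
    event_id = event if isinstance(event, str) else event.event_id
    row = psi.row(event_id)
    tumor_of: dict[str, str] = {}
    normal_of: dict[str, str] = {}
    order: list[str] = []
    for s in samples:
        target = tumor_of if s.tissue == Tissue.TUMOR else normal_of
        if s.patient_id not in target:
            target[s.patient_id] = s.sample_id
        if s.patient_id not in order:
            order.append(s.patient_id)

    out = []
    for p in order:
        if p not in tumor_of or p not in normal_of:
            continue
        t = row.get(tumor_of[p], np.nan)
        n = row.get(normal_of[p], np.nan)
        if np.isnan(t) or np.isnan(n):
            out.append(PairedDelta(p, event_id, float("nan"), PairCall.UNEVALUABLE))
            continue
        delta = float(t) - float(n)
        if delta > threshold:
            call = PairCall.INCLUDED
        elif delta < -threshold:
            call = PairCall.EXCLUDED
        else:
            call = PairCall.UNCHANGED
        out.append(PairedDelta(p, event_id, delta, call))
    if not out:
        logger.warning("no dually sampled patients for event %s", event_id)
    return out


def alteration_frequency(
    deltas: list[PairedDelta], threshold: float = DEFAULT_THRESHOLD
) -> tuple[float, int, int]:
    """Fraction of evaluable patients with |delta| strictly above the
    threshold.  Returns (fraction, numerator, denominator)."""
    evaluable = [d for d in deltas if d.call != PairCall.UNEVALUABLE]
    if not evaluable:
        raise ValueError("no evaluable paired deltas: frequency undefined")
    altered = sum(abs(d.delta_psi) > threshold for d in evaluable)
    return altered / len(evaluable), altered, len(evaluable)
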