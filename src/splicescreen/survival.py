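"""Kaplan-Meier product-limit estimation and the log-rank test.

Right-censored data only.  The convention at tied times is the standard one:
deaths are processed before censorings occurring at the same time, so a
subject censored at t is still at risk for the death at t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from splicescreen.types import ClinicalRecord

__all__ = ["KMCurve", "LogRankResult", "km_estimate", "logrank_test"]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate: S(t) is right-continuous, steps only
    at observed death times, and S(0) = 1."""

    event_times: tuple[float, ...]
    survival_probs: tuple[float, ...]
    n_at_risk: tuple[int, ...]
    n_events: tuple[int, ...]
    n_subjects: int

    def survival_at(self, t: float) -> float:
        s = 1.0
        for time, prob in zip(self.event_times, self.survival_probs):
            if time <= t:
                s = prob
            else:
                break
        return s


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p_value: float
    n_groups: int
    n_events: int


def _times_events(records: list[ClinicalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    if np.any(t <= 0):
        raise ValueError("survival times must be strictly positive")
    return t, e


def km_estimate(records: list[ClinicalRecord]) -> KMCurve:
    """Kaplan-Meier estimator over a list of clinical records."""
    if not records:
        raise ValueError("need at least one record")
    t, e = _times_events(records)
    order = np.lexsort((1 - e, t))  # by time, deaths before censorings at ties
    t, e = t[order], e[order]
    n = len(t)

    times: list[float] = []
    probs: list[float] = []
    at_risk: list[int] = []
    events: list[int] = []
    s = 1.0
    i = 0
    while i < n:
        ti = t[i]
        j = i
        while j < n and t[j] == ti:
            j += 1
        d = int(e[i:j].sum())
        risk = n - i
        if d > 0:
            s *= 1.0 - d / risk
            times.append(float(ti))
            probs.append(s)
            at_risk.append(risk)
            events.append(d)
        i = j
    return KMCurve(tuple(times), tuple(probs), tuple(at_risk), tuple(events), n)


def logrank_test(groups: list[list[ClinicalRecord]]) -> LogRankResult:
    """K-sample log-rank test.

    Observed-minus-expected chi-square over the pooled death times with the
    hypergeometric variance; df = #groups - 1.  For two groups this is the
    Mantel-Cox statistic.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("log-rank needs >= 2 groups")
    for gi, g in enumerate(groups):
        if not g:
            raise ValueError(f"group {gi} has zero subjects")
    ts, es, gs = [], [], []
    for gi, g in enumerate(groups):
        t, e = _times_events(g)
        ts.append(t)
        es.append(e)
        gs.append(np.full(len(t), gi))
    t = np.concatenate(ts)
    e = np.concatenate(es)
    g = np.concatenate(gs)

    death_times = np.unique(t[e == 1])
    obs = np.zeros(k)
    exp = np.zeros(k)
    # Covariance of the O-E vector, summed over death times.
    cov = np.zeros((k, k))
    for ti in death_times:
        at_risk = t >= ti
        n_i = float(at_risk.sum())
        d_i = float(((t == ti) & (e == 1)).sum())
        n_ig = np.array([(at_risk & (g == j)).sum() for j in range(k)], dtype=float)
        d_ig = np.array(
            [((t == ti) & (e == 1) & (g == j)).sum() for j in range(k)], dtype=float
        )
        obs += d_ig
        exp += d_i * n_ig / n_i
        if n_i > 1:
            frac = n_ig / n_i
            scale = d_i * (n_i - d_i) / (n_i - 1)
            cov += scale * (np.diag(frac) - np.outer(frac, frac))
    df = k - 1
    oe = (obs - exp)[:df]
    v = cov[:df, :df]
    n_events = int(e.sum())
    if n_events == 0 or np.allclose(v, 0):
        return LogRankResult(0.0, df, 1.0, k, n_events)
    try:
        chi2 = float(oe @ np.linalg.solve(v, oe))
    except np.linalg.LinAlgError:
        chi2 = float(oe @ np.linalg.pinv(v) @ oe)
    chi2 = max(chi2, 0.0)
    p = float(sps.chi2.sf(chi2, df))
    return LogRankResult(chi2, df, p, k, n_events)
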