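"""Event summaries, cross-cancer filters and the mean |dPSI| ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from splicescreen.events import (
    EventSummary,
    filter_events,
    rank_events,
    summarize_event,
)
from splicescreen.types import PsiMatrix, SampleRecord, SpliceEvent, Tissue

EV = SpliceEvent("PBRM1", "ES", ("27",), "26", "28")


def _matrix(values_by_sample, event=EV):
    df = pd.DataFrame(
        [list(values_by_sample.values())], index=[event.event_id],
        columns=list(values_by_sample),
    )
    return PsiMatrix([event], df)


def _samples(tumor_ids, normal_ids, ct="KIRC"):
    return [
        SampleRecord(s, f"pt-{s}", ct, Tissue.TUMOR) for s in tumor_ids
    ] + [SampleRecord(s, f"pt-{s}", ct, Tissue.NORMAL) for s in normal_ids]


def _summary(ct, quantified=True, delta=0.0, p=1.0):
    return EventSummary(
        EV, ct, 20, 20, quantified,
        0.5 + delta, 0.5, delta, 0.0, p,
    )


class TestSummarize:
    def test_identical_groups_null(self):
        vals = {f"T{i}": 0.5 + 0.01 * i for i in range(4)}
        vals.update({f"N{i}": 0.5 + 0.01 * i for i in range(4)})
        psi = _matrix(vals)
        s = summarize_event(psi, _samples([f"T{i}" for i in range(4)], [f"N{i}" for i in range(4)]), EV, min_n=2)
        assert s.delta_psi == pytest.approx(0.0, abs=1e-15)
        assert s.p_value == pytest.approx(1.0)

    def test_delta_arithmetic(self):
        psi = _matrix({"T1": 0.8, "T2": 0.9, "N1": 0.2, "N2": 0.3})
        s = summarize_event(psi, _samples(["T1", "T2"], ["N1", "N2"]), EV, min_n=2)
        assert s.delta_psi == pytest.approx(0.6, abs=1e-12)
        assert s.delta_psi == pytest.approx(
            s.mean_psi_tumor - s.mean_psi_normal, abs=1e-12
        )

    def test_t_and_p_match_scipy_oracle(self):
        rng = np.random.default_rng(0)
        tum = rng.uniform(0.3, 0.9, 30)
        nor = rng.uniform(0.1, 0.7, 30)
        vals = {f"T{i}": tum[i] for i in range(30)}
        vals.update({f"N{i}": nor[i] for i in range(30)})
        psi = _matrix(vals)
        s = summarize_event(
            psi,
            _samples([f"T{i}" for i in range(30)], [f"N{i}" for i in range(30)]),
            EV,
        )
        t_ref, p_ref = sps.ttest_ind(tum, nor, equal_var=True)
        assert s.t_stat == pytest.approx(t_ref, abs=1e-12)
        assert s.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_below_min_n_is_unquantified(self):
        psi = _matrix({"T1": 0.8, "T2": 0.9, "N1": 0.2, "N2": 0.3})
        s = summarize_event(psi, _samples(["T1", "T2"], ["N1", "N2"]), EV, min_n=10)
        assert not s.quantified and math.isnan(s.delta_psi)

    def test_missing_event_raises(self):
        psi = _matrix({"T1": 0.5})
        with pytest.raises(KeyError):
            summarize_event(psi, [], "NOPE|ES|1|0|2")

    def test_label_swap_antisymmetry(self):
        """Swapping tumor/normal labels negates dPSI and preserves p."""
        rng = np.random.default_rng(1)
        a = rng.uniform(0.2, 0.9, 15)
        b = rng.uniform(0.1, 0.8, 15)
        vals = {f"A{i}": a[i] for i in range(15)}
        vals.update({f"B{i}": b[i] for i in range(15)})
        psi = _matrix(vals)
        ids_a = [f"A{i}" for i in range(15)]
        ids_b = [f"B{i}" for i in range(15)]
        s1 = summarize_event(psi, _samples(ids_a, ids_b), EV)
        s2 = summarize_event(psi, _samples(ids_b, ids_a), EV)
        assert s1.delta_psi == pytest.approx(-s2.delta_psi, abs=1e-15)
        assert s1.p_value == pytest.approx(s2.p_value, abs=1e-15)


class TestFilter:
    def test_12_of_15_quantified_passes_80_pct_rule(self):
        ss = [_summary(f"C{i}", quantified=i < 12, delta=0.3, p=1e-4) for i in range(15)]
        assert filter_events(ss, quantified_frac=0.80, min_detected=12) == [EV.event_id]

    def test_11_of_15_detected_fails_min_detected(self):
        ss = [_summary(f"C{i}", delta=0.3 if i < 11 else 0.0, p=1e-4 if i < 11 else 1.0) for i in range(15)]
        assert filter_events(ss, min_detected=12) == []

    def test_fully_quantified_and_detected_retained(self):
        ss = [_summary(f"C{i}", delta=0.3, p=1e-4) for i in range(15)]
        assert filter_events(ss) == [EV.event_id]

    def test_bad_quantified_frac_is_error(self):
        with pytest.raises(ValueError):
            filter_events([], quantified_frac=1.5)

    def test_filter_monotone_on_threshold_grid(self):
        """Raising min_detected or quantified_frac never grows the set."""
        rng = np.random.default_rng(2)
        summaries = []
        for e in range(10):
            ev = SpliceEvent(f"G{e}", "ES", (str(e),), "0", "9")
            for i in range(15):
                q = rng.random() < 0.9
                d = float(rng.normal(0, 0.2)) if q else math.nan
                summaries.append(
                    EventSummary(ev, f"C{i}", 20, 20, q, 0.5, 0.5, d, 0.0,
                                 float(rng.random()) if q else math.nan)
                )
        prev_by_frac = None
        for frac in (0.5, 0.7, 0.9):
            cur = set(filter_events(summaries, quantified_frac=frac, min_detected=1))
            if prev_by_frac is not None:
                assert cur <= prev_by_frac
            prev_by_frac = cur
        prev_by_det = None
        for det in (3, 6, 9, 12):
            cur = set(filter_events(summaries, quantified_frac=0.5, min_detected=det))
            if prev_by_det is not None:
                assert cur <= prev_by_det
            prev_by_det = cur


class TestRank:
    def test_single_event_rank_one(self):
        ss = [_summary("C0", delta=0.1)]
        ranks = rank_events(ss)
        assert ranks[0].rank == 1

    def test_mean_abs_dpsi_arithmetic(self):
        ev2 = SpliceEvent("KRAS", "ES", ("2",), "1", "3")
        ss = [
            _summary("C0", delta=0.2), _summary("C1", delta=-0.4),
            EventSummary(ev2, "C0", 20, 20, True, 0.5, 0.4, 0.1, 0.0, 0.5),
            EventSummary(ev2, "C1", 20, 20, True, 0.5, 0.4, 0.1, 0.0, 0.5),
        ]
        ranks = rank_events(ss)
        assert [r.event.gene for r in ranks] == ["PBRM1", "KRAS"]
        assert ranks[0].mean_abs_dpsi == pytest.approx(0.3)
        assert ranks[1].mean_abs_dpsi == pytest.approx(0.1)

    def test_empty_input_warns(self, caplog):
        with caplog.at_level("WARNING"):
            assert rank_events([]) == []

    def test_planted_event_ranked_first_on_synthetic_study(self, default_study):
        bundles, gt = default_study
        from splicescreen.events import summarize_bundle

        summaries = []
        for b in bundles:
            summaries.extend(summarize_bundle(b))
        ranks = rank_events(summaries)
        assert ranks[0].event.event_id == gt.planted_event_id
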