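"""End-to-end orchestration: simulate (or load) cohorts, screen drivers,
screen events, call paired alterations, screen factors, stratify patients
and compare survival — one reproducible run with every threshold echoed
into the summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from splicescreen import drivers as drv
from splicescreen import events as evs
from splicescreen import factors as fac
from splicescreen import io as cio
from splicescreen import paired as prd
from splicescreen import strata as st
from splicescreen.simulate import SimConfig, generate_bundles, write_bundles
from splicescreen.survival import km_estimate, logrank_test
from splicescreen.types import CohortBundle, Tissue

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """All thresholds of a pipeline run, mirroring the screening defaults:
    top 60 mutated genes, >= 80% quantified types, detected in >= 12 types,
    paired |dPSI| > 0.15, marker cut 1.75, low-expression percentile 12."""

    out_dir: str = "splicescreen_run"
    sim: SimConfig | None = None
    bundles_dir: str | None = None
    cancer_types: list[str] | None = None
    catalogue: list[str] | None = None  # driver catalogue symbols
    factor_list: list[str] | None = None
    top_n: int = 60
    min_n: int = 10
    quantified_frac: float = 0.80
    min_detected: int = 12
    alpha: float = 0.05
    paired_threshold: float = 0.15
    pdl1_cut: float = 1.75
    low_pct: float = 12.0
    split_rule: str = "median"
    clinical_type: str = "KIRC"
    target_gene: str | None = None  # defaults to the top event's gene
    regulator_gene: str | None = None  # defaults to the top factor
    marker_gene: str = "PD-L1"
    seed: int = 0

    def thresholds(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "top_n", "min_n", "quantified_frac", "min_detected", "alpha",
                "paired_threshold", "pdl1_cut", "low_pct", "split_rule", "seed",
            )
        }


def _load_bundles(cfg: RunConfig) -> tuple[list[CohortBundle], object | None]:
    if cfg.sim is not None:
        sim = cfg.sim
        sim.seed = cfg.seed
        bundles, gt = generate_bundles(sim)
        write_bundles(bundles, gt, Path(cfg.out_dir) / "data")
        return bundles, gt
    if cfg.bundles_dir is None:
        raise ValueError("RunConfig needs either sim or bundles_dir")
    if not cfg.cancer_types:
        raise ValueError("cancer_types required when loading bundles from disk")
    return [cio.read_bundle(cfg.bundles_dir, ct) for ct in cfg.cancer_types], None


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage in order; returns the report dict (also written
    to ``out_dir/summary.json``).  Identical config + seed gives identical
    outputs."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundles, gt = _load_bundles(cfg)

    # ---- stage 1: driver screen --------------------------------------------
    catalogue = cfg.catalogue
    if catalogue is None and cfg.sim is not None:
        catalogue = cfg.sim.driver_genes()
    if catalogue is None:
        raise ValueError("driver catalogue required")
    top_lists = {
        b.cancer_type: drv.top_n_genes(
            drv.count_mutated_patients(b.mutations), cfg.top_n
        )
        for b in bundles
    }
    driver_set = drv.compile_driver_set(top_lists, catalogue)
    pd.DataFrame(
        {"gene": list(driver_set), "cancer_types": [",".join(v) for v in driver_set.values()]}
    ).to_csv(out / "drivers.tsv", sep="\t", index=False)

    # ---- stage 2: event screen ---------------------------------------------
    summaries = []
    for b in bundles:
        keep = [e for e in b.psi.events if e.gene in driver_set]
        summaries.extend(evs.summarize_bundle(b, keep, cfg.min_n))
    retained = evs.filter_events(
        summaries, cfg.quantified_frac, cfg.min_detected, cfg.alpha
    )
    ranks = evs.rank_events(summaries, retained, cfg.alpha)
    type_codes = [b.cancer_type for b in bundles]
    rank_rows = []
    for r in ranks:
        row = {
            "event_id": r.event.event_id,
            "rank": r.rank,
            "mean_abs_dpsi": f"{r.mean_abs_dpsi:.4f}",
            "n_types_quantified": r.n_types_quantified,
            "n_types_detected": r.n_types_detected,
        }
        for ct in type_codes:
            d = r.delta_by_type.get(ct)
            row[ct] = "N.D." if d is None else f"{d:.4f}"
        rank_rows.append(row)
    pd.DataFrame(rank_rows).to_csv(out / "ranks.tsv", sep="\t", index=False)
    if not ranks:
        raise RuntimeError("event screen retained no events")
    top_event = ranks[0].event

    # ---- stage 3: paired alterations for the top event ---------------------
    paired_rows, freq_by_type = [], {}
    for b in bundles:
        if top_event.event_id not in b.psi:
            continue
        deltas = prd.patient_deltas(
            b.psi, b.samples, top_event, cfg.paired_threshold
        )
        for d in deltas:
            paired_rows.append(
                {
                    "cancer_type": b.cancer_type,
                    "patient_id": d.patient_id,
                    "delta_psi": "" if np.isnan(d.delta_psi) else f"{d.delta_psi:.4f}",
                    "call": d.call.value,
                }
            )
        try:
            f, num, den = prd.alteration_frequency(deltas, cfg.paired_threshold)
            freq_by_type[b.cancer_type] = {"freq": f, "n_altered": num, "n": den}
        except ValueError:
            pass
    pd.DataFrame(paired_rows).to_csv(out / "paired.tsv", sep="\t", index=False)

    # ---- stage 4: factor screen --------------------------------------------
    factor_list = cfg.factor_list
    if factor_list is None and cfg.sim is not None:
        factor_list = cfg.sim.factor_genes()
    if factor_list is None:
        raise ValueError("factor list required")
    factor_ranks = fac.screen_factors(bundles, top_event, factor_list, cfg.min_n)
    pd.DataFrame(
        [
            {
                "factor": r.factor,
                "rank": r.rank,
                "summary_r": "" if np.isnan(r.summary_r) else f"{r.summary_r:.4f}",
                "n_types_negative": r.n_types_negative,
            }
            for r in factor_ranks
        ]
    ).to_csv(out / "factors.tsv", sep="\t", index=False)
    top_factor = factor_ranks[0].factor

    dpsi_by_type = ranks[0].delta_by_type
    dexpr_by_type = {
        b.cancer_type: fac.factor_delta_expression(b, top_factor) for b in bundles
    }
    cc_r, cc_p, cc_n = fac.cross_cancer_delta_correlation(dpsi_by_type, dexpr_by_type)

    # ---- stage 5: stratification + survival --------------------------------
    target_gene = cfg.target_gene or top_event.gene
    regulator = cfg.regulator_gene or top_factor
    clin_bundle = next(
        (b for b in bundles if b.cancer_type == cfg.clinical_type), bundles[0]
    )
    survival_report = _strata_survival_stage(
        cfg, clin_bundle, top_event, target_gene, regulator, out
    )

    report = {
        "thresholds": cfg.thresholds(),
        "n_driver_genes": len(driver_set),
        "n_events_retained": len(retained),
        "top_event": top_event.event_id,
        "top_event_mean_abs_dpsi": ranks[0].mean_abs_dpsi,
        "top_factor": top_factor,
        "top_factor_summary_r": factor_ranks[0].summary_r,
        "cross_cancer_delta_corr": {"r": cc_r, "p": cc_p, "n_types": cc_n},
        "paired_alteration_by_type": freq_by_type,
        "survival": survival_report,
    }
    if gt is not None:
        report["ground_truth"] = {
            "planted_event": gt.planted_event_id,
            "planted_event_recovered": top_event.event_id == gt.planted_event_id,
            "regulator": gt.regulator,
            "regulator_recovered": top_factor == gt.regulator,
        }
    (out / "summary.json").write_text(json.dumps(report, indent=1, default=float))
    return report


def _strata_survival_stage(
    cfg: RunConfig, bundle: CohortBundle, top_event, target_gene, regulator, out: Path
) -> dict:
    tumor_sample_of = {}
    for s in bundle.samples_by_tissue(Tissue.TUMOR):
        tumor_sample_of.setdefault(s.patient_id, s.sample_id)

    mut_status = st.classify_mut_status(
        bundle.mutations, bundle.expr, target_gene, tumor_sample_of, cfg.low_pct
    )
    reg_expr = {
        p: bundle.expr.row(regulator).get(sid, np.nan)
        for p, sid in tumor_sample_of.items()
    }
    reg_group = st.split_by_expression(reg_expr, cfg.split_rule)
    psi_row = bundle.psi.row(top_event.event_id)
    psi_vals = {p: psi_row.get(sid, np.nan) for p, sid in tumor_sample_of.items()}
    psi_group = st.split_by_expression(psi_vals, cfg.split_rule)
    flags, pct = st.flag_pdl1_high(
        bundle.expr, cfg.marker_gene, tumor_sample_of, cfg.pdl1_cut, mut_status
    ) if cfg.marker_gene in bundle.expr else ({}, {})

    strata_rows = []
    for p in tumor_sample_of:
        strata_rows.append(
            {
                "patient_id": p,
                "mut_status": mut_status[p].value,
                "psi_group": psi_group.get(p, st.ExprGroup.UNASSIGNED).value,
                "regulator_group": reg_group.get(p, st.ExprGroup.UNASSIGNED).value,
                "pdl1_high": int(flags.get(p, False)),
                "functional_group": st.functional_group(
                    mut_status[p], reg_group.get(p, st.ExprGroup.UNASSIGNED)
                ),
            }
        )
    pd.DataFrame(strata_rows).to_csv(out / "strata.tsv", sep="\t", index=False)

    # log-rank of regulator-low vs -high within target-gene WT, per arm
    by_patient = {r.patient_id: r for r in bundle.clinical}
    survival = {"cancer_type": bundle.cancer_type, "marker_pct_by_stratum": pct}
    arms = sorted({r.arm for r in bundle.clinical})
    km_rows = []
    for arm in arms:
        groups = {"low": [], "high": []}
        for p, status in mut_status.items():
            rec = by_patient.get(p)
            if rec is None or rec.arm != arm or status != st.MutStatus.WT:
                continue
            g = reg_group.get(p)
            if g in (st.ExprGroup.LOW, st.ExprGroup.HIGH):
                groups[g.value].append(rec)
        if min(len(g) for g in groups.values()) < 2:
            survival[arm] = {"note": "too few WT patients per regulator group"}
            continue
        res = logrank_test([groups["low"], groups["high"]])
        survival[arm] = {
            "chi2": res.chi2,
            "p": res.p_value,
            "n_low": len(groups["low"]),
            "n_high": len(groups["high"]),
        }
        for label, recs in groups.items():
            curve = km_estimate(recs)
            for t, s_prob, n_risk in zip(
                curve.event_times, curve.survival_probs, curve.n_at_risk
            ):
                km_rows.append(
                    {
                        "arm": arm,
                        "regulator_group": label,
                        "time_days": f"{t:g}",
                        "survival": f"{s_prob:.4f}",
                        "n_at_risk": n_risk,
                    }
                )
    pd.DataFrame(km_rows).to_csv(out / "km.tsv", sep="\t", index=False)
    return survival
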