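"""Synthetic multi-cancer cohorts with planted, recoverable structure.

The generator emulates the statistical shape of a pan-cancer tumor/normal
splicing study: per-cancer-type PSI tables over driver-gene splice events,
FPKM expression over driver genes plus a splicing-factor panel, per-patient
somatic mutations, and right-censored survival records.  Five effects are
planted and recorded in a :class:`GroundTruth` manifest:

* a differentially spliced event whose tumor-vs-normal mean PSI shift is
  ``planted_delta`` in ``planted_n_types`` of the cancer types, realised as a
  per-patient alteration of size ``planted_delta / frac_altered_patients`` in
  a Bernoulli(``frac_altered_patients``) subset of tumor patients — so the
  group-mean shift and the paired alteration fraction are both calibrated;
* a regulator factor whose (patient-level) expression couples negatively to
  the planted event's PSI with target Pearson ``regulator_r``;
* suppressed regulator expression in tumors of the planted types, giving the
  cross-cancer dPSI-vs-dexpression plot its negative sign;
* a marker gene whose tumor FPKM rises with the planted event's PSI only in
  patients without a mutation in the planted gene;
* an exponential survival hazard multiplied by ``survival_hazard_ratio`` for
  patients who are planted-gene wild-type, regulator-low, and on the first
  treatment arm.

All randomness comes from one seed, streamed to per-cancer-type substreams by
fixed offsets, so identical seeds give byte-identical outputs and adding a
cancer type does not reshuffle the others.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from splicescreen import io as cio
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

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_bundles",
    "write_bundles",
    "read_ground_truth",
    "simulate_survival_arm",
]

DEFAULT_CANCER_TYPES = (
    "BLCA", "BRCA", "COAD", "ESCA", "HNSC", "KICH", "KIRC", "KIRP",
    "LIHC", "LUAD", "LUSC", "PRAD", "READ", "STAD", "UCEC",
)

DEFAULT_PLANTED_EVENT = SpliceEvent("PBRM1", "ES", ("27",), "26", "28")

_VARIANT_CLASSES = (
    VariantClass.MISSENSE,
    VariantClass.NONSENSE,
    VariantClass.FRAMESHIFT,
    VariantClass.SPLICE_SITE,
    VariantClass.IN_FRAME,
    VariantClass.SILENT,
)
_VARIANT_PROBS = (0.55, 0.10, 0.15, 0.05, 0.05, 0.10)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohorts.

    Defaults encode the screening scenario every acceptance check runs under:
    15 cancer types, 60 tumor / 30 normal samples per type (all normals from
    paired patients), 36 driver genes x 3 events, a 172-factor panel, a +0.2
    mean-PSI shift planted in 12 of the 15 types, and a -0.6 regulator
    coupling.
    """

    n_cancer_types: int = 15
    n_tumor: int = 60
    n_normal: int = 30
    n_paired: int = 30
    n_genes: int = 36
    n_events_per_gene: int = 3
    n_factors: int = 172
    planted_event: SpliceEvent = field(default_factory=lambda: DEFAULT_PLANTED_EVENT)
    planted_delta: float = 0.2
    planted_n_types: int = 12
    planted_baseline_psi: float = 0.35
    regulator: str = "RBFOX2"
    regulator_r: float = -0.6
    regulator_tumor_shift: float = -1.0  # log2 drop in planted-type tumors
    psi_noise_sd: float = 0.08  # patient-level PSI noise
    within_patient_sd: float = 0.03  # residual noise between a patient's tissues
    frac_altered_patients: float = 0.5
    mutation_rates: dict = field(default_factory=dict)  # per-gene overrides
    default_mutation_rate: float = 0.08
    planted_gene_mutation_rate: float = 0.4
    marker_gene: str = "PD-L1"
    marker_effect: float = 2.0  # additive FPKM per unit PSI in non-mutant patients
    marker_baseline: float = 1.0
    survival_hazard_ratio: float = 2.5
    hazard_per_day: float = 1.0 / 1000.0
    censor_rate: float = 0.3
    arms: tuple[str, str] = ("nivolumab", "everolimus")
    cancer_types: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_cancer_types", "n_tumor", "n_normal", "n_genes",
            "n_events_per_gene", "n_factors",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.n_paired <= min(self.n_tumor, self.n_normal):
            raise ValueError("n_paired must be <= min(n_tumor, n_normal)")
        for name in ("frac_altered_patients", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 <= self.planted_delta <= 1.0:
            raise ValueError("planted_delta must be in [-1, 1]")
        if self.planted_n_types > self.n_cancer_types:
            raise ValueError("planted_n_types must be <= n_cancer_types")
        if abs(self.regulator_r) >= 0.95:
            raise ValueError(
                "infeasible regulator coupling: |regulator_r| must be < 0.95 "
                "for a clamped-Gaussian PSI link at the configured noise level"
            )
        if not isinstance(self.planted_event, SpliceEvent):
            self.planted_event = SpliceEvent.from_id(str(self.planted_event))

    @property
    def type_codes(self) -> tuple[str, ...]:
        if self.cancer_types is not None:
            codes = tuple(self.cancer_types)
        elif self.n_cancer_types <= len(DEFAULT_CANCER_TYPES):
            codes = DEFAULT_CANCER_TYPES[: self.n_cancer_types]
        else:
            codes = DEFAULT_CANCER_TYPES + tuple(
                f"CT{i:02d}"
                for i in range(len(DEFAULT_CANCER_TYPES), self.n_cancer_types)
            )
        if len(codes) != self.n_cancer_types:
            raise ValueError("cancer_types length must equal n_cancer_types")
        return codes

    @property
    def planted_types(self) -> tuple[str, ...]:
        return self.type_codes[: self.planted_n_types]

    def driver_genes(self) -> list[str]:
        genes = [self.planted_event.gene]
        i = 1
        while len(genes) < self.n_genes:
            genes.append(f"DRV{i:03d}")
            i += 1
        return genes

    def factor_genes(self) -> list[str]:
        factors = [self.regulator]
        i = 1
        while len(factors) < self.n_factors:
            factors.append(f"SF{i:03d}")
            i += 1
        return factors

    def events(self) -> list[SpliceEvent]:
        evs: list[SpliceEvent] = []
        for gene in self.driver_genes():
            start = 0
            if gene == self.planted_event.gene:
                evs.append(self.planted_event)
                start = 1
            for k in range(start, self.n_events_per_gene):
                exon = str(10 + 3 * k)
                evs.append(
                    SpliceEvent(gene, "ES", (exon,), str(10 + 3 * k - 1), str(10 + 3 * k + 1))
                )
        return evs


@dataclass
class GroundTruth:
    """Planted structure of one simulated study, keyed exactly like the
    emitted bundles."""

    planted_event_id: str
    true_delta: dict  # cancer_type -> planted mean dPSI
    regulator: str
    regulator_r: float
    altered: dict  # cancer_type -> {patient_id: bool}
    stratum: dict  # cancer_type -> {patient_id: "high_E27" | "low_E27"}
    hazard: dict  # cancer_type -> {patient_id: hazard per day}
    marker_gene: str
    seed: int


def _clamp01(a: np.ndarray) -> np.ndarray:
    return np.clip(a, 0.0, 1.0)


def simulate_survival_arm(
    n: int,
    hazard_per_day: float,
    hazard_ratio: float,
    frac_exposed: float,
    censor_rate: float,
    rng: np.random.Generator,
    arm: str = "nivolumab",
    patient_prefix: str = "P",
) -> tuple[list[ClinicalRecord], np.ndarray]:
    """Exponential survival for one arm with a Bernoulli exposed stratum.

    Returns the clinical records and the boolean exposure vector.  Used both
    inside :func:`generate_bundles` and standalone for log-rank operating-
    point simulations.
    """
    exposed = rng.random(n) < frac_exposed
    lam = np.where(exposed, hazard_per_day * hazard_ratio, hazard_per_day)
    t_event = rng.exponential(1.0 / lam)
    censored = rng.random(n) < censor_rate
    u = rng.uniform(0.02, 1.0, size=n)
    time = np.where(censored, u * t_event, t_event)
    recs = [
        ClinicalRecord(
            patient_id=f"{patient_prefix}{i:04d}",
            time=float(max(time[i], 1e-6)),
            event=int(not censored[i]),
            arm=arm,
        )
        for i in range(n)
    ]
    return recs, exposed


def _simulate_type(
    cfg: SimConfig, ct: str, type_index: int, planted: bool
) -> tuple[CohortBundle, dict]:
    rng = np.random.default_rng([cfg.seed, type_index])

    # ---- patients & samples -------------------------------------------------
    tumor_patients = [f"{ct}-P{j:03d}" for j in range(cfg.n_tumor)]
    paired = tumor_patients[: cfg.n_paired]
    extra_normal = [
        f"{ct}-P{cfg.n_tumor + j:03d}" for j in range(cfg.n_normal - cfg.n_paired)
    ]
    normal_patients = paired + extra_normal

    samples = [
        SampleRecord(f"{p}-T", p, ct, Tissue.TUMOR) for p in tumor_patients
    ] + [SampleRecord(f"{p}-N", p, ct, Tissue.NORMAL) for p in normal_patients]
    tumor_ids = [f"{p}-T" for p in tumor_patients]
    normal_ids = [f"{p}-N" for p in normal_patients]
    all_patients = tumor_patients + extra_normal

    # ---- mutations ----------------------------------------------------------
    genes = cfg.driver_genes()
    mutations: list[MutationRecord] = []
    mutant_planted: dict[str, bool] = {p: False for p in all_patients}
    for gene in genes:
        rate = cfg.mutation_rates.get(
            gene,
            cfg.planted_gene_mutation_rate
            if gene == cfg.planted_event.gene
            else cfg.default_mutation_rate,
        )
        hits = rng.random(cfg.n_tumor) < rate
        classes = rng.choice(
            len(_VARIANT_CLASSES), size=cfg.n_tumor, p=_VARIANT_PROBS
        )
        for j, p in enumerate(tumor_patients):
            if hits[j]:
                vc = _VARIANT_CLASSES[classes[j]]
                mutations.append(MutationRecord(p, gene, vc))
                if gene == cfg.planted_event.gene and vc != VariantClass.SILENT:
                    mutant_planted[p] = True

    # ---- regulator latent & factor expression -------------------------------
    # Patient-level latent drives both the regulator's measured tumor
    # expression and the planted event's PSI (in both tissues of a patient).
    z = rng.standard_normal(cfg.n_tumor)  # per tumor patient, standardized
    factors = cfg.factor_genes()
    reg_mu_t = 4.0 + (cfg.regulator_tumor_shift if planted else 0.0)
    reg_mu_n = 4.0
    log2_reg_tumor = reg_mu_t + 1.0 * z
    log2_reg_normal = reg_mu_n + rng.standard_normal(len(normal_ids))

    expr_rows: dict[str, np.ndarray] = {}
    n_samples = len(samples)
    for f in factors:
        if f == cfg.regulator:
            vals = np.concatenate(
                [2.0**log2_reg_tumor, 2.0**log2_reg_normal]
            )
        else:
            mu = rng.uniform(2.0, 6.0)
            vals = 2.0 ** (mu + 0.8 * rng.standard_normal(n_samples))
        expr_rows[f] = vals

    for gene in genes:
        mu = rng.uniform(2.0, 6.0)
        expr_rows.setdefault(
            gene, 2.0 ** (mu + 0.5 * rng.standard_normal(n_samples))
        )

    # ---- PSI ----------------------------------------------------------------
    events = cfg.events()
    planted_id = cfg.planted_event.event_id
    psi_rows: list[np.ndarray] = []
    altered = {p: False for p in tumor_patients}

    # per-patient alteration of the planted event (planted types only)
    shift_mag = (
        cfg.planted_delta / cfg.frac_altered_patients
        if cfg.frac_altered_patients > 0
        else 0.0
    )
    if planted and cfg.planted_delta != 0.0 and cfg.frac_altered_patients > 0:
        alt_flags = rng.random(cfg.n_tumor) < cfg.frac_altered_patients
    else:
        alt_flags = np.zeros(cfg.n_tumor, dtype=bool)
    for j, p in enumerate(tumor_patients):
        altered[p] = bool(alt_flags[j])

    # coupling coefficient: chosen so corr(PSI, z) ~= regulator_r given the
    # non-regulator variance components of the planted event's tumor PSI
    var_other = cfg.psi_noise_sd**2 + cfg.within_patient_sd**2
    if planted:
        var_other += shift_mag**2 * cfg.frac_altered_patients * (
            1 - cfg.frac_altered_patients
        )
    b = cfg.regulator_r / math.sqrt(1 - cfg.regulator_r**2) * math.sqrt(var_other)

    for ev in events:
        if ev.event_id == planted_id:
            base_pat_t = (
                cfg.planted_baseline_psi
                + cfg.psi_noise_sd * rng.standard_normal(cfg.n_tumor)
                + b * z
            )
            tumor_vals = _clamp01(
                base_pat_t
                + shift_mag * np.sign(cfg.planted_delta) * alt_flags
                + cfg.within_patient_sd * rng.standard_normal(cfg.n_tumor)
            )
            # paired normals share the patient baseline (and coupling);
            # extra normal-only patients get fresh baselines
            base_extra = cfg.planted_baseline_psi + cfg.psi_noise_sd * (
                rng.standard_normal(len(extra_normal))
            )
            base_pat_n = np.concatenate([base_pat_t[: cfg.n_paired], base_extra])
            normal_vals = _clamp01(
                base_pat_n
                + cfg.within_patient_sd * rng.standard_normal(len(normal_ids))
            )
        else:
            m = rng.uniform(0.1, 0.9)
            conc = 30.0
            base_t = rng.beta(m * conc, (1 - m) * conc, size=cfg.n_tumor)
            base_n = np.concatenate(
                [
                    base_t[: cfg.n_paired],
                    rng.beta(m * conc, (1 - m) * conc, size=len(extra_normal)),
                ]
            )
            tumor_vals = _clamp01(
                base_t + cfg.within_patient_sd * rng.standard_normal(cfg.n_tumor)
            )
            normal_vals = _clamp01(
                base_n + cfg.within_patient_sd * rng.standard_normal(len(normal_ids))
            )
        psi_rows.append(np.concatenate([tumor_vals, normal_vals]))

    sample_ids = tumor_ids + normal_ids
    psi_df = pd.DataFrame(
        np.vstack(psi_rows), index=[e.event_id for e in events], columns=sample_ids
    )
    psi = PsiMatrix(events, psi_df)

    # ---- marker coupled to planted-event PSI in non-mutant patients ---------
    planted_psi_tumor = psi_df.loc[planted_id, tumor_ids].to_numpy()
    base_marker = cfg.marker_baseline * np.exp(0.25 * rng.standard_normal(n_samples))
    marker_vals = base_marker.copy()
    for j, p in enumerate(tumor_patients):
        if not mutant_planted[p]:
            marker_vals[j] += cfg.marker_effect * planted_psi_tumor[j]
    expr_rows[cfg.marker_gene] = marker_vals

    expr_df = pd.DataFrame(expr_rows, index=sample_ids).T
    expr = ExprMatrix(expr_df)

    # ---- survival -----------------------------------------------------------
    arm_first = rng.random(cfg.n_tumor) < 0.5
    reg_low = z < 0.0
    stratum: dict[str, str] = {}
    hazard: dict[str, float] = {}
    clinical: list[ClinicalRecord] = []
    for j, p in enumerate(tumor_patients):
        high = (not mutant_planted[p]) and reg_low[j]
        stratum[p] = "high_E27" if high else "low_E27"
        lam = cfg.hazard_per_day
        if high and arm_first[j]:
            lam *= cfg.survival_hazard_ratio
        hazard[p] = lam
        t_event = rng.exponential(1.0 / lam)
        censored = rng.random() < cfg.censor_rate
        time = rng.uniform(0.02, 1.0) * t_event if censored else t_event
        clinical.append(
            ClinicalRecord(
                patient_id=p,
                time=float(max(time, 1e-6)),
                event=int(not censored),
                arm=cfg.arms[0] if arm_first[j] else cfg.arms[1],
            )
        )

    bundle = CohortBundle(ct, samples, psi, expr, mutations, clinical)
    truth = {
        "delta": cfg.planted_delta if planted else 0.0,
        "altered": altered,
        "stratum": stratum,
        "hazard": hazard,
    }
    return bundle, truth


def generate_bundles(cfg: SimConfig) -> tuple[list[CohortBundle], GroundTruth]:
    """Generate one bundle per cancer type plus the ground-truth manifest."""
    bundles = []
    true_delta, altered, stratum, hazard = {}, {}, {}, {}
    planted_set = set(cfg.planted_types)
    for i, ct in enumerate(cfg.type_codes):
        bundle, truth = _simulate_type(cfg, ct, i, ct in planted_set)
        bundles.append(bundle)
        true_delta[ct] = truth["delta"]
        altered[ct] = truth["altered"]
        stratum[ct] = truth["stratum"]
        hazard[ct] = truth["hazard"]
    gt = GroundTruth(
        planted_event_id=cfg.planted_event.event_id,
        true_delta=true_delta,
        regulator=cfg.regulator,
        regulator_r=cfg.regulator_r,
        altered=altered,
        stratum=stratum,
        hazard=hazard,
        marker_gene=cfg.marker_gene,
        seed=cfg.seed,
    )
    return bundles, gt


def write_bundles(
    bundles: list[CohortBundle], ground_truth: GroundTruth, out_dir: str | Path
) -> dict[str, list[str]]:
    """Write one TSV file set per cancer type plus a ground-truth manifest
    and a run log recording the seed.  Returns the file manifest."""
    if not bundles:
        raise ValueError("empty bundle list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {}
    for b in bundles:
        paths = cio.write_bundle(b, out_dir)
        manifest[b.cancer_type] = [p.name for p in paths.values()]
    gt_path = out_dir / "ground_truth.json"
    gt_path.write_text(json.dumps(asdict(ground_truth), indent=1, sort_keys=True))
    (out_dir / "run_log.json").write_text(
        json.dumps(
            {"seed": ground_truth.seed, "cancer_types": sorted(manifest)}, indent=1
        )
    )
    manifest["_meta"] = [gt_path.name, "run_log.json"]
    return manifest


def read_ground_truth(path: str | Path) -> GroundTruth:
    raw = json.loads(Path(path).read_text())
    return GroundTruth(**raw)
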