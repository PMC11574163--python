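"""Structure, determinism and calibration of the synthetic cohorts."""

import hashlib
import math

import numpy as np
import pytest

from splicescreen import io as cio
from splicescreen.simulate import (
    SimConfig,
    generate_bundles,
    read_ground_truth,
    write_bundles,
)
from splicescreen.types import Tissue


def _hash_dir(d):
    h = hashlib.sha256()
    for p in sorted(d.rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestStructure:
    def test_value_ranges_and_pairing(self, small_study):
        bundles, _ = small_study
        for b in bundles:
            vals = b.psi.values.to_numpy()
            assert np.nanmin(vals) >= 0.0 and np.nanmax(vals) <= 1.0
            assert np.nanmin(b.expr.values.to_numpy()) >= 0.0
            per_patient = {}
            for s in b.samples:
                per_patient.setdefault(s.patient_id, []).append(s.tissue)
            for tissues in per_patient.values():
                assert len(tissues) <= 2
                if len(tissues) == 2:
                    assert set(tissues) == {Tissue.TUMOR, Tissue.NORMAL}

    def test_expected_file_manifest(self, small_study, tmp_path):
        bundles, gt = small_study
        manifest = write_bundles(bundles, gt, tmp_path)
        data_files = [f for ct, fs in manifest.items() if ct != "_meta" for f in fs]
        assert len(data_files) == len(bundles) * 5
        assert (tmp_path / "ground_truth.json").exists()

    def test_empty_bundle_list_is_error(self, small_study, tmp_path):
        _, gt = small_study
        with pytest.raises(ValueError, match="empty"):
            write_bundles([], gt, tmp_path)

    def test_ground_truth_manifest_round_trip(self, small_study, tmp_path):
        bundles, gt = small_study
        write_bundles(bundles, gt, tmp_path)
        back = read_ground_truth(tmp_path / "ground_truth.json")
        assert back == gt

    def test_infeasible_coupling_rejected(self):
        with pytest.raises(ValueError, match="regulator_r"):
            SimConfig(regulator_r=-0.99)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = dict(
            n_cancer_types=2, planted_n_types=2, n_tumor=15, n_normal=8,
            n_paired=8, n_genes=4, n_events_per_gene=2, n_factors=5, seed=1,
        )
        for d in ("a", "b"):
            bundles, gt = generate_bundles(SimConfig(**cfg))
            write_bundles(bundles, gt, tmp_path / d)
        assert _hash_dir(tmp_path / "a") == _hash_dir(tmp_path / "b")

    def test_substreams_stable_when_types_added(self):
        """Adding a cancer type does not reshuffle the existing ones."""
        base = dict(
            n_tumor=10, n_normal=5, n_paired=5, n_genes=3,
            n_events_per_gene=1, n_factors=3, seed=4,
        )
        b3, _ = generate_bundles(SimConfig(n_cancer_types=3, planted_n_types=2, **base))
        b4, _ = generate_bundles(SimConfig(n_cancer_types=4, planted_n_types=2, **base))
        np.testing.assert_array_equal(
            b3[0].psi.values.to_numpy(), b4[0].psi.values.to_numpy()
        )


class TestCalibration:
    def test_null_config_has_no_planted_shift(self):
        """With planted_delta=0 the per-type tumor-normal mean difference of
        the planted event stays within 3 standard errors of zero."""
        cfg = SimConfig(
            n_cancer_types=3, planted_n_types=3, n_tumor=80, n_normal=40,
            n_paired=40, n_genes=4, n_events_per_gene=1, n_factors=4,
            planted_delta=0.0, seed=5,
        )
        bundles, gt = generate_bundles(cfg)
        for b in bundles:
            row = b.psi.row(gt.planted_event_id)
            tum = [row[s.sample_id] for s in b.samples_by_tissue(Tissue.TUMOR)]
            nor = [row[s.sample_id] for s in b.samples_by_tissue(Tissue.NORMAL)]
            tum, nor = np.asarray(tum), np.asarray(nor)
            se = math.sqrt(tum.var(ddof=1) / len(tum) + nor.var(ddof=1) / len(nor))
            assert abs(tum.mean() - nor.mean()) < 3 * se

    def test_regulator_link_hits_target_correlation(self):
        """Monte-Carlo check of the coupling calibration: at n_tumor=500 the
        sample Pearson r between tumor PSI and regulator log-expression is
        within 0.1 of the -0.6 target."""
        cfg = SimConfig(
            n_cancer_types=1, planted_n_types=1, n_tumor=500, n_normal=20,
            n_paired=20, n_genes=3, n_events_per_gene=1, n_factors=4,
            regulator_r=-0.6, psi_noise_sd=0.08, seed=6,
        )
        bundles, gt = generate_bundles(cfg)
        b = bundles[0]
        tumor_ids = [s.sample_id for s in b.samples_by_tissue(Tissue.TUMOR)]
        psi = b.psi.row(gt.planted_event_id).reindex(tumor_ids).to_numpy()
        expr = np.log2(b.expr.row(gt.regulator).reindex(tumor_ids).to_numpy())
        r = np.corrcoef(psi, expr)[0, 1]
        assert r == pytest.approx(-0.6, abs=0.1)

    def test_mean_realized_delta_matches_planted(self):
        """Seed-averaged realized dPSI of the planted event in planted types
        is within 0.02 of planted_delta."""
        deltas = []
        for seed in range(12):
            cfg = SimConfig(
                n_cancer_types=2, planted_n_types=2, n_tumor=60, n_normal=30,
                n_paired=30, n_genes=3, n_events_per_gene=1, n_factors=4,
                seed=seed,
            )
            bundles, gt = generate_bundles(cfg)
            for b in bundles:
                row = b.psi.row(gt.planted_event_id)
                tum = np.mean(
                    [row[s.sample_id] for s in b.samples_by_tissue(Tissue.TUMOR)]
                )
                nor = np.mean(
                    [row[s.sample_id] for s in b.samples_by_tissue(Tissue.NORMAL)]
                )
                deltas.append(tum - nor)
        assert np.mean(deltas) == pytest.approx(0.2, abs=0.02)

    def test_marker_coupled_only_in_non_mutant_patients(self, default_study):
        """Marker FPKM rises with planted-event PSI in wild-type tumor
        patients but not in mutants of the planted gene."""
        bundles, gt = default_study
        b = bundles[0]
        mutant = {
            m.patient_id
            for m in b.mutations
            if m.gene == gt.planted_event_id.split("|")[0]
            and m.variant_class.value != "silent"
        }
        psi_row = b.psi.row(gt.planted_event_id)
        marker = b.expr.row(gt.marker_gene)
        wt_pairs, mut_pairs = [], []
        for s in b.samples_by_tissue(Tissue.TUMOR):
            pair = (psi_row[s.sample_id], marker[s.sample_id])
            (mut_pairs if s.patient_id in mutant else wt_pairs).append(pair)
        r_wt = np.corrcoef(*zip(*wt_pairs))[0, 1]
        r_mut = np.corrcoef(*zip(*mut_pairs))[0, 1]
        assert r_wt > 0.5
        assert abs(r_mut) < 0.45
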