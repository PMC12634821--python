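"""Synthetic paired-dataset generation and recovery evaluation."""

import numpy as np
import pandas as pd
import pytest

import pepmatch as pm
from pepmatch.errors import ContractError
from pepmatch.synthetic import ISOTOPE_SPACING, TRYPSIN_ACCESSION


def run_in_memory(maldi, lcms, **config_kwargs):
    cfg = pm.RunConfig(maldi_csv="mem", lcms_csv="mem", **config_kwargs)
    return pm.run_pipeline(cfg, maldi=maldi, lcms=lcms, write_output=False)


class TestGenerateDataset:
    def test_noise_only_instance(self):
        params = pm.SyntheticParams(
            seed=5, n_true_peptides=0, n_decoy_peptides=0, n_noise_peaks=5
        )
        maldi, lcms, truth = pm.generate_dataset(params)
        assert len(maldi.df) == 5
        assert len(lcms.df) == 0
        assert all(lab.kind == "noise" for lab in truth.labels.values())

    def test_same_seed_reproduces_byte_identical_tables(self):
        a = pm.generate_dataset(pm.SyntheticParams(seed=9))
        b = pm.generate_dataset(pm.SyntheticParams(seed=9))
        assert a[0].df.to_csv(index=False) == b[0].df.to_csv(index=False)
        assert a[1].df.to_csv(index=False) == b[1].df.to_csv(index=False)
        assert a[2].to_json() == b[2].to_json()

    def test_different_seeds_differ(self):
        a = pm.generate_dataset(pm.SyntheticParams(seed=9))
        b = pm.generate_dataset(pm.SyntheticParams(seed=10))
        assert a[0].df.to_csv(index=False) != b[0].df.to_csv(index=False)

    def test_every_peak_labeled_exactly_once(self, default_instance):
        _, maldi, lcms, truth = default_instance
        assert set(truth.labels) == set(maldi.df["peak_id"])

    def test_true_peak_within_tolerance_of_its_peptide(self, default_instance):
        _, maldi, lcms, truth = default_instance
        mz_by_peak = dict(zip(maldi.df["peak_id"], maldi.df["mz"]))
        mh_by_key = {
            (r.accession, r.sequence): r.theoretical_mh
            for r in lcms.df.itertuples()
        }
        for pid, lab in truth.labels.items():
            if lab.kind != "true" or lab.collision:
                continue
            dm = abs(mz_by_peak[pid] - mh_by_key[(lab.accession, lab.sequence)])
            assert dm <= 1.0

    def test_true_masses_mutually_separated(self, default_instance):
        _, _, lcms, truth = default_instance
        true_mhs = np.sort(
            lcms.df[lcms.df["accession"].str.startswith("TRUE")][
                "theoretical_mh"
            ].to_numpy()
        )
        collisions = any(
            lab.collision for lab in truth.labels.values() if lab.kind == "true"
        )
        if not collisions:
            assert np.diff(true_mhs).min() >= 2.0

    def test_isotope_satellites_at_expected_spacing(self, default_instance):
        _, maldi, _, truth = default_instance
        mz_by_peak = dict(zip(maldi.df["peak_id"], maldi.df["mz"]))
        true_peak_by_key = {
            (lab.accession, lab.sequence): pid
            for pid, lab in truth.labels.items()
            if lab.kind == "true"
        }
        n_sat = 0
        for pid, lab in truth.labels.items():
            if lab.kind != "isotope":
                continue
            n_sat += 1
            parent = true_peak_by_key[(lab.accession, lab.sequence)]
            assert mz_by_peak[pid] - mz_by_peak[parent] == pytest.approx(
                ISOTOPE_SPACING, abs=1e-9
            )
        assert n_sat > 0  # prob 0.1 over 200 true peptides

    def test_decoys_absent_from_maldi_table(self, default_instance):
        _, _, _, truth = default_instance
        for lab in truth.labels.values():
            assert lab.accession is None or not lab.accession.startswith("DECOY")


class TestTrypsinControl:
    def test_contains_nominal_843_peak(self):
        maldi, lcms, truth = pm.generate_trypsin_control(seed=3)
        nominal = maldi.df["mz"].round().astype(int).tolist()
        assert 843 in nominal
        assert (lcms.df["sequence"] == "VATVSLPR").any()

    def test_seed_determinism(self):
        a = pm.generate_trypsin_control(seed=3)
        b = pm.generate_trypsin_control(seed=3)
        assert a[0].df.to_csv(index=False) == b[0].df.to_csv(index=False)

    def test_trypsin_ranks_first_for_every_control_peak(self):
        """End-to-end on the control ROI with decoy peptides competing: every
        control peak's top candidate is a trypsin autolysis peptide.  The
        intensity filters are disabled because the control ROI contains no
        noise population to estimate them from."""
        maldi, lcms, truth = pm.generate_trypsin_control(seed=3)
        _, decoy_lcms, _ = pm.generate_dataset(
            pm.SyntheticParams(seed=4, n_true_peptides=0,
                               n_decoy_peptides=500, n_noise_peaks=0)
        )
        combined = pm.LcmsPeptideTable(
            df=pd.concat([lcms.df, decoy_lcms.df], ignore_index=True),
            conditions=lcms.conditions,
        )
        result = run_in_memory(maldi, combined, knee_filter=False, min_snr=0.0)
        top1 = result.scored[result.scored["rank_within_peak"] == 1]
        assert len(top1) == len(maldi.df)
        assert (top1["accession"] == TRYPSIN_ACCESSION).all()


class TestEvaluateRecovery:
    def test_single_true_pair_no_decoys_recovers_fully(self):
        params = pm.SyntheticParams(
            seed=21, n_true_peptides=1, n_decoy_peptides=0, n_noise_peaks=0
        )
        maldi, lcms, truth = pm.generate_dataset(params)
        result = run_in_memory(maldi, lcms, knee_filter=False, min_snr=0.0)
        report = pm.evaluate_recovery(result.scored, truth)
        assert report.top1_recovery == 1.0

    def test_id_mismatch_is_contract_error(self, default_run):
        result, truth = default_run
        bogus = result.scored.copy()
        bogus["peak_id"] = bogus["peak_id"] + 10_000
        with pytest.raises(ContractError):
            pm.evaluate_recovery(bogus, truth)

    def test_shuffled_ranks_recover_at_chance_level(self, default_run):
        """With ranks randomly permuted within each peak, top-1 recovery drops
        to roughly one over the mean number of candidates per peak."""
        result, truth = default_run
        rng = np.random.default_rng(77)
        shuffled = result.scored.copy()
        shuffled["rank_within_peak"] = (
            shuffled.groupby("peak_id")["rank_within_peak"]
            .transform(lambda s: rng.permutation(s.to_numpy()))
        )
        report = pm.evaluate_recovery(shuffled, truth)
        true_ids = {
            pid for pid, lab in truth.labels.items() if lab.kind == "true"
        }
        per_peak = (
            shuffled[shuffled["peak_id"].isin(true_ids)]
            .groupby("peak_id").size()
        )
        chance = float((1.0 / per_peak).mean())
        assert report.top1_recovery == pytest.approx(chance, abs=0.08)

    def test_recovery_degrades_with_mass_error(self):
        """Mean top-1 recovery is non-increasing as the MALDI mass-error SD
        grows (5 replicate seeds per level)."""
        means = []
        for sd in (0.05, 0.2, 0.5):
            recoveries = []
            for seed in range(5):
                params = pm.SyntheticParams(
                    seed=seed, n_true_peptides=60, n_decoy_peptides=300,
                    n_noise_peaks=90, mass_error_sd=sd,
                )
                maldi, lcms, truth = pm.generate_dataset(params)
                result = run_in_memory(maldi, lcms)
                rep = pm.evaluate_recovery(
                    result.scored, truth, result.retained_peak_ids
                )
                recoveries.append(rep.top1_recovery)
            means.append(float(np.mean(recoveries)))
        assert means[0] >= means[1] >= means[2]


class TestWriteDataset:
    def test_round_trip_through_csv_preserves_ids(self, tmp_path):
        params = pm.SyntheticParams(
            seed=13, n_true_peptides=20, n_decoy_peptides=50, n_noise_peaks=30
        )
        maldi, lcms, truth = pm.generate_dataset(params)
        paths = pm.write_dataset(tmp_path, maldi, lcms, truth)
        cfg = pm.RunConfig(
            maldi_csv=str(paths["maldi_csv"]), lcms_csv=str(paths["lcms_csv"])
        )
        reread = pm.read_maldi_csv(paths["maldi_csv"], cfg)
        merged = reread.df.merge(maldi.df, on="peak_id", suffixes=("_r", "_g"))
        assert merged["mz_r"].to_numpy() == pytest.approx(
            merged["mz_g"].to_numpy(), abs=1e-9
        )
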