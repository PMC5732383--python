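"""The synthetic hybrid-zone world: determinism, validity, recoverability."""

import json

import numpy as np
import pandas as pd
import pytest

from hybridcline import (
    HillCline,
    SimulationConfig,
    build_positions,
    read_fasta,
    simulate_alignment,
    simulate_all,
    simulate_specimens,
    simulate_spectra,
    steepness_for_width,
)
from hybridcline.cline import cline_width
from hybridcline.phenotypes import WAVE_GRID, segment_metrics
from hybridcline.simulate import STRUCTURED_FREQS, UNSTRUCTURED_FREQS


class TestConfig:
    def test_steepness_inverts_width(self):
        for E, w in [(70, 40), (76.69, 33.12), (55, 10)]:
            B = steepness_for_width(E, w)
            assert B < 0
            assert cline_width((0, 1, B, E)) == pytest.approx(w, rel=1e-10)

    def test_default_world_magnitudes(self):
        cfg = SimulationConfig.default()
        centers = [p.pc1.center for p in cfg.periods.values()]
        assert centers == pytest.approx([67.67, 73.85, 76.69])
        assert all(0 < p.mix.center < cfg.length_km for p in cfg.periods.values())

    def test_too_small_period_rejected(self):
        from hybridcline.simulate import PeriodConfig, ClineTruth

        with pytest.raises(ValueError):
            PeriodConfig(
                n=5,
                year_range=(2007, 2010),
                pc1=ClineTruth(0, 1, -5, 70),
                mix=ClineTruth(0, 1, -5, 70),
            )

    def test_bad_haplotype_frequencies_rejected(self):
        from hybridcline.simulate import HaplotypeModel

        with pytest.raises(ValueError, match="sum to 1"):
            HaplotypeModel(length=210, n_segregating=5, frequencies=[[0.5, 0.2]])


class TestSimulateSpecimens:
    def test_requested_sample_sizes(self, default_bundle):
        df = default_bundle["specimens"]
        cfg = SimulationConfig.default()
        for period, pc in cfg.periods.items():
            assert (df["id"].str.startswith(period)).sum() == pc.n

    def test_determinism_same_seed(self):
        a, _ = simulate_specimens(seed=7)
        b, _ = simulate_specimens(seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_generated_data_passes_validators(self, tmp_path, default_bundle):
        from hybridcline import read_specimen_table

        path = tmp_path / "specimens.csv"
        default_bundle["specimens"].to_csv(path, index=False)
        table = read_specimen_table(path)
        assert len(table.records) == len(default_bundle["specimens"])
        assert table.rejected == []

    def test_noiseless_world_recovers_true_cline_exactly(self):
        cfg = SimulationConfig.default()
        for pc in cfg.periods.values():
            pc.noise_sd = 0.0
        cfg.missing_morph_rate = 0.0
        df, truth = simulate_specimens(cfg, seed=3)
        t = pd.DataFrame(truth["specimens"])
        for period, pcfg in cfg.periods.items():
            sub = t[t["period"] == period]
            est = HillCline().fit(
                sub["true_distance_km"], sub["latent_size"]
            )
            assert est.center_ == pytest.approx(pcfg.pc1.center, abs=1e-4)
            assert est.width_ == pytest.approx(pcfg.pc1.width, abs=1e-4)

    def test_full_pipeline_recovers_size_cline_from_morphology(self):
        # noiseless morphology -> transect -> per-sex PCA -> Hill fit
        from hybridcline import compute_pca

        cfg = SimulationConfig.default()
        for pc in cfg.periods.values():
            pc.noise_sd = 0.0
        cfg.missing_morph_rate = 0.0
        df, truth = simulate_specimens(cfg, seed=4)
        pos, _ = build_positions(df)
        t = pd.DataFrame(truth["specimens"])[["id", "true_distance_km"]]
        pos = pos.merge(t, on="id")
        pca = compute_pca(pos, sex="male")
        sub = pos[pos["sex"] == "male"].set_index("id")
        scores = pca.scores["PC1"]
        period = sub["period"] == "P2010"
        est = HillCline().fit(
            sub.loc[period, "true_distance_km"],
            scores[sub.index[period]],
        )
        # PC1 is an affine image of the latent size, so center/width transfer
        assert est.center_ == pytest.approx(
            cfg.periods["P2010"].pc1.center, abs=0.01
        )
        assert est.width_ == pytest.approx(cfg.periods["P2010"].pc1.width, rel=0.001)


class TestSimulateSpectra:
    def _chroma_of(self, t):
        from hybridcline.simulate import red_template, yellow_template

        spec = t * red_template(WAVE_GRID) + (1 - t) * yellow_template(WAVE_GRID)
        return segment_metrics(WAVE_GRID, spec).chroma

    def test_mix_endpoints_hit_template_chromas(self):
        recs = [
            {"id": "yellow", "mix_fraction": 0.0},
            {"id": "red", "mix_fraction": 1.0},
        ]
        cfg = SimulationConfig.default()
        cfg.spectrum_noise = 0.0
        df = simulate_spectra(recs, cfg, seed=1)
        w = df["wavelength_nm"].to_numpy(float)
        for sid, t in [("yellow", 0.0), ("red", 1.0)]:
            got = segment_metrics(w, df[sid].to_numpy(float)).chroma
            assert got == pytest.approx(self._chroma_of(t), abs=1e-4)

    def test_noiseless_spectra_recover_chroma_cline_center(self):
        cfg = SimulationConfig.default()
        for pc in cfg.periods.values():
            pc.noise_sd = 0.0
        cfg.spectrum_noise = 0.0
        _, truth = simulate_specimens(cfg, seed=5)
        recs = [r for r in truth["specimens"] if r["period"] == "P1956"]
        df = simulate_spectra(recs, cfg, seed=5)
        w = df["wavelength_nm"].to_numpy(float)
        chroma = np.array(
            [segment_metrics(w, df[r["id"]].to_numpy(float)).chroma for r in recs]
        )
        x = np.array([r["true_distance_km"] for r in recs])
        est = HillCline().fit(x, chroma)
        assert est.center_ == pytest.approx(cfg.periods["P1956"].mix.center, abs=1.0)


class TestSimulateSequences:
    def test_presets_shape(self):
        assert STRUCTURED_FREQS.shape == UNSTRUCTURED_FREQS.shape == (3, 6)
        np.testing.assert_allclose(STRUCTURED_FREQS.sum(axis=1), 1.0)

    def test_alignment_labels_and_lengths(self):
        seqs, labels = simulate_alignment(
            STRUCTURED_FREQS, localities_per_sector=4, n_per_locality=5, seed=9
        )
        assert len(seqs) == 3 * 4 * 5
        assert set(labels["sector"]) == {1, 2, 3}
        assert all(len(s) == 210 for s in seqs.values())

    def test_structured_alignment_carries_sector_signal(self):
        from hybridcline import amova, pairwise_diff_matrix

        seqs, labels = simulate_alignment(STRUCTURED_FREQS, seed=11)
        _, d = pairwise_diff_matrix(seqs)
        res = amova(d, labels["sector"], labels["locality"], n_perm=199, seed=12)
        assert res.f_ct > 0
        assert res.p_values["F_CT"] < 0.05


class TestBundle:
    def test_bundle_files_deterministic(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_all(out_dir=d1, seed=99)
        simulate_all(out_dir=d2, seed=99)
        for f in sorted(d1.iterdir()):
            assert (d2 / f.name).read_bytes() == f.read_bytes()

    def test_truth_round_trips_through_json(self, tmp_path):
        simulate_all(out_dir=tmp_path, seed=42)
        truth = json.loads((tmp_path / "truth.json").read_text())
        cfg = SimulationConfig.default()
        assert truth["periods"]["P2010"]["pc1"]["E"] == pytest.approx(
            cfg.periods["P2010"].pc1.E
        )
        assert len(truth["specimens"]) == sum(p.n for p in cfg.periods.values())

    def test_fasta_outputs_readable_and_linked(self, tmp_path):
        simulate_all(out_dir=tmp_path, seed=13)
        specimens = pd.read_csv(tmp_path / "specimens.csv")
        for period, length in [("P1956", 210), ("P2010", 1008)]:
            seqs = read_fasta(tmp_path / f"seqs_{period}.fasta")
            assert all(len(s) == length for s in seqs.values())
            assert set(seqs) <= set(specimens["id"])
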