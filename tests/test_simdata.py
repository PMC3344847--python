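"""Ground-truth generator: determinism, class structure, round-trip recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from polytome import arrayio, simdata, translatome
from polytome.exceptions import ConfigurationError
from polytome.simdata import NoiseConfig, SimConfig


def _recover_expression(probes):
    corrected = arrayio.background_correct(probes, "none")
    return arrayio.summarize_expression(corrected)


def _recover_with_half(probes):
    # with exact reported background, half correction recovers the signal
    corrected = arrayio.background_correct(probes, "half")
    return arrayio.summarize_expression(corrected)


class TestSimulateTranscriptome:
    def test_same_seed_identical_output(self):
        cfg = SimConfig(seed=11, n_genes=60)
        anns1, truth1 = simdata.simulate_transcriptome(cfg)
        anns2, truth2 = simdata.simulate_transcriptome(cfg)
        pd.testing.assert_frame_equal(truth1, truth2)
        assert [a.sequence for a in anns1] == [a.sequence for a in anns2]

    def test_class_counts_within_binomial_bounds(self):
        props = {"S": 0.5, "R": 0.13, "I": 0.08}
        cfg = SimConfig(seed=5, n_genes=2000, class_proportions=props)
        _, truth = simdata.simulate_transcriptome(cfg, sequences=False)
        counts = truth["true_class"].value_counts()
        for cls, p in props.items():
            # 99% binomial bounds around the expectation
            half_width = 2.576 * np.sqrt(p * (1 - p) * 2000)
            assert abs(counts[cls] - p * 2000) < half_width

    def test_truth_classes_satisfy_their_defining_inequalities(self):
        _, truth = simdata.simulate_transcriptome(
            SimConfig(seed=3, n_genes=1500), sequences=False
        )
        s = truth[truth["true_class"] == "S"]
        assert (s["delta_te"] <= -0.8).all()
        assert (s["te_stress"] < 0.8).all()  # S never collides with R
        r = truth[truth["true_class"] == "R"]
        assert ((r["te_control"] >= 0.8) & (r["te_stress"] >= 0.8)).all()
        i = truth[truth["true_class"] == "I"]
        assert ((i["te_control"] <= 0) & (i["delta_te"] >= 1)).all()

    def test_inducible_class_has_more_uaugs_than_sensitive(self):
        _, truth = simdata.simulate_transcriptome(SimConfig(seed=2, n_genes=800))
        by_class = truth.groupby("true_class")["n_uaug"].mean()
        assert by_class["I"] > by_class["S"]

    def test_sequences_match_truth_features(self):
        anns, truth = simdata.simulate_transcriptome(SimConfig(seed=9, n_genes=40))
        from polytome import seqfeat
        for ann, row in zip(anns, truth.itertuples()):
            fv = seqfeat.extract_features(ann)
            assert fv.n_uaug == row.n_uaug
            assert fv.utr5_len == row.utr5_len
            assert fv.cds_len == row.cds_len

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(seed=1, class_proportions={"S": 0.9, "R": 0.3, "I": 0.1})


class TestSimulateArrays:
    def test_balanced_gene_has_equal_channels(self):
        truth = pd.DataFrame(
            {"transcript_id": ["t0"], "true_class": ["U"], "abundance": [1000.0],
             "te_control": [0.0], "delta_te": [0.0], "te_stress": [0.0]}
        )
        cfg = SimConfig(seed=1, n_genes=1, probes_per_gene=1, noise=NoiseConfig(0, 0, 0))
        probes = simdata.simulate_arrays(truth, cfg, "control")
        assert probes.loc[0, "green_fg"] == pytest.approx(probes.loc[0, "red_fg"])

    def test_doubling_abundance_shifts_a_not_m(self):
        truth = pd.DataFrame(
            {"transcript_id": ["t0", "t1"], "true_class": ["U", "U"],
             "abundance": [500.0, 1000.0], "te_control": [0.7, 0.7],
             "delta_te": [0.0, 0.0], "te_stress": [0.7, 0.7]}
        )
        cfg = SimConfig(seed=1, n_genes=2, probes_per_gene=1, noise=NoiseConfig(0, 0, 0))
        expr = _recover_expression(simdata.simulate_arrays(truth, cfg, "control"))
        expr = expr.set_index("gene_id")
        assert expr.loc["t1", "M"] == pytest.approx(expr.loc["t0", "M"])
        assert expr.loc["t1", "A"] - expr.loc["t0", "A"] == pytest.approx(1.0)

    def test_mass_ratio_realized_within_2pct(self):
        cfg = simdata.jurkat_like(7, n_genes=1000, noise=NoiseConfig(0, 0, 0))
        _, truth = simdata.simulate_transcriptome(cfg, sequences=False)
        for condition, target in [("control", 2.0), ("stress_3h", 1 / 3)]:
            probes = simdata.simulate_arrays(truth, cfg, condition)
            realized = probes["green_fg"].sum() / probes["red_fg"].sum()
            assert realized == pytest.approx(target, rel=0.02)

    def test_noise_free_round_trip_recovers_te_exactly(self):
        cfg = SimConfig(seed=4, n_genes=400, noise=NoiseConfig(0, 0, 0))
        _, truth = simdata.simulate_transcriptome(cfg, sequences=False)
        expr = _recover_expression(simdata.simulate_arrays(truth, cfg, "control"))
        m = expr.set_index("gene_id")["M"].reindex(truth["transcript_id"]).to_numpy()
        assert np.abs(m - truth["te_control"].to_numpy()).max() < 1e-9

    def test_noise_free_round_trip_recovers_classes_exactly(self):
        cfg = SimConfig(seed=4, n_genes=400, noise=NoiseConfig(0, 0, 0))
        _, truth = simdata.simulate_transcriptome(cfg, sequences=False)
        control = _recover_expression(simdata.simulate_arrays(truth, cfg, "control"))
        stress = _recover_expression(simdata.simulate_arrays(truth, cfg, "stress_3h"))
        entries = translatome.assign_classes(
            translatome.compute_translation_change(control, stress)
        )
        predicted = entries.set_index("gene_id")["class_label"]
        expected = truth.set_index("transcript_id")["true_class"]
        assert (predicted.reindex(expected.index) == expected).all()

    def test_noisy_round_trip_keeps_high_fidelity(self):
        # study-level noise: log-normal sd 0.25, 3 probes per gene
        cfg = SimConfig(seed=8, n_genes=1000)
        _, truth = simdata.simulate_transcriptome(cfg, sequences=False)
        expr = _recover_with_half(simdata.simulate_arrays(truth, cfg, "control"))
        m = expr.set_index("gene_id")["M"].reindex(truth["transcript_id"]).to_numpy()
        r = pearsonr(m, truth["te_control"].to_numpy()).statistic
        assert r >= 0.95

    def test_replicate_probe_count(self):
        cfg = SimConfig(seed=1, n_genes=10, probes_per_gene=3)
        _, truth = simdata.simulate_transcriptome(cfg, sequences=False)
        probes = simdata.simulate_arrays(truth, cfg, "control")
        assert len(probes) == 30
        assert probes["gene_id"].value_counts().unique().tolist() == [3]


class TestWriteDataset:
    def test_dataset_files_consumable_and_deterministic(self, tmp_path):
        cfg = SimConfig(seed=6, n_genes=40)
        paths1 = simdata.write_dataset(tmp_path / "a", cfg)
        paths2 = simdata.write_dataset(tmp_path / "b", cfg)
        for key in paths1:
            assert open(paths1[key]).read() == open(paths2[key]).read()
        probes = arrayio.read_probe_table(paths1["control_probes"])
        assert len(probes) == 40 * cfg.probes_per_gene
        from polytome import seqfeat
        anns = seqfeat.parse_annotation(paths1["fasta"], paths1["cds"])
        assert len(anns) == 40
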