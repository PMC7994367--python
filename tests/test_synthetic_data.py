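"""Generator correctness against analytic stationary-distribution oracles."""

import numpy as np
import pandas as pd
import pytest

from sigsom import cg_metrics, oligo
from sigsom import synthetic_data as synth


class TestSpeciesModel:
    def test_s_one_is_independence(self):
        m = synth.build_species_model("x", cg_suppression=1.0)
        assert np.allclose(m.P, np.tile(m.pi, (4, 1)))
        assert m.predicted_obs_exp == pytest.approx(1.0)

    def test_s_zero_forbids_cg(self):
        m = synth.build_species_model("x", cg_suppression=0.0)
        rec, _ = synth.generate_chromosome(
            "x", m, synth.ChromosomePlan("c", 100_000), seed=1)
        assert "CG" not in rec.sequence

    def test_excessive_s_rejected(self):
        with pytest.raises(ValueError):
            synth.build_species_model("x", pi=[0.25] * 4, cg_suppression=5.0)

    def test_bad_pi_rejected(self):
        with pytest.raises(ValueError):
            synth.build_species_model("x", pi=[0.5, 0.5, 0.2, -0.2])

    def test_calibrated_prediction_equals_target(self):
        for s in (0.3, 0.45, 0.57):
            m = synth.build_species_model("x", cg_suppression=s)
            assert m.predicted_obs_exp == pytest.approx(s, abs=1e-9)

    def test_raw_multiplier_construction(self):
        # uncalibrated: P(G|C) = s*pi_G before row renormalization
        pi = np.array([0.3, 0.2, 0.2, 0.3])
        m = synth.build_species_model("x", pi=pi, cg_suppression=0.45,
                                      calibrate=False)
        row_c = pi.copy()
        row_c[2] *= 0.45
        assert np.allclose(m.P[1], row_c / row_c.sum())

    def test_stationary_is_stationary(self):
        m = synth.build_species_model("x", cg_suppression=0.45)
        assert np.allclose(m.stationary @ m.P, m.stationary)


class TestEmission:
    def test_empirical_obs_exp_within_3_sd(self):
        m = synth.build_species_model("x", pi=[0.25] * 4, cg_suppression=0.45)
        rec, _ = synth.generate_chromosome(
            "x", m, synth.ChromosomePlan("c", 2_000_000), seed=2)
        enc = oligo.encode(rec.sequence)
        chunk = 100_000
        per_chunk = [
            cg_metrics.cg_obs_exp(enc[i * chunk : (i + 1) * chunk])
            for i in range(len(enc) // chunk)
        ]
        se = np.std(per_chunk, ddof=1) / np.sqrt(len(per_chunk))
        est = cg_metrics.cg_obs_exp(rec.sequence)
        assert abs(est - m.predicted_obs_exp) <= 3 * se

    def test_dinucleotide_groups_match_analytic_within_3_sd(self):
        m = synth.build_species_model("x", cg_suppression=0.45)
        rec, _ = synth.generate_chromosome(
            "x", m, synth.ChromosomePlan("c", 2_000_000), seed=3)
        cv = oligo.composition(rec.sequence, 2)
        pred = synth.predicted_group_frequencies(m, 2)
        n = cv.total_count
        for lab, p in pred.items():
            sd = np.sqrt(p * (1 - p) / n)
            # 3 binomial SDs plus slack for chain autocorrelation
            assert abs(cv.values[list(cv.labels).index(lab)] - p) <= 6 * sd

    def test_symmetric_construction_cg_gc_near_one(self):
        # independence chain: CG and GC both have expectation pi_C*pi_G
        m = synth.build_species_model("x", cg_suppression=1.0)
        rec, _ = synth.generate_chromosome(
            "x", m, synth.ChromosomePlan("c", 1_000_000), seed=4)
        assert cg_metrics.cg_gc_ratio(rec.sequence) == pytest.approx(1.0, abs=0.05)

    def test_deterministic_given_seed(self, tmp_path):
        models = {"sp": synth.build_species_model("sp", cg_suppression=0.5)}
        plans = {"sp": [synth.ChromosomePlan("c1", 200_000)]}
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        synth.generate_collection(models, plans, seed=9, out_dir=d1)
        synth.generate_collection(models, plans, seed=9, out_dir=d2)
        assert (d1 / "sp.fasta").read_bytes() == (d2 / "sp.fasta").read_bytes()
        other, _ = synth.generate_collection(models, plans, seed=10)
        assert other["sp"][0].sequence != \
            (d1 / "sp.fasta").read_text().split("\n", 1)[1].replace("\n", "")


class TestPlans:
    def test_overlapping_blocks_rejected(self):
        unit = "ACGT" * 10
        plan = synth.ChromosomePlan(
            "c", 10_000,
            repeat_blocks=[synth.RepeatBlock(0, 10, unit),
                           synth.RepeatBlock(100, 10, unit)])
        with pytest.raises(ValueError):
            plan.validate()

    def test_out_of_bounds_rejected(self):
        plan = synth.ChromosomePlan(
            "c", 1000, repeat_blocks=[synth.RepeatBlock(900, 10, "ACGT" * 10)])
        with pytest.raises(ValueError):
            plan.validate()

    def test_duplicate_species_rejected(self):
        m = synth.build_species_model("sp", cg_suppression=0.5)
        with pytest.raises(ValueError, match="duplicate"):
            synth.generate_collection([m, m], {"sp": []}, seed=0)

    def test_truth_covers_every_base(self):
        m = synth.build_species_model("sp", cg_suppression=0.5)
        unit = synth.cg_rich_repeat_unit(100, seed=1)
        plan = synth.ChromosomePlan(
            "c", 500_000,
            repeat_blocks=[synth.RepeatBlock(100_000, 50, unit, spacer_len=20)])
        rec, rows = synth.generate_chromosome("sp", m, plan, seed=5)
        truth = pd.DataFrame(rows).sort_values("start")
        assert truth.iloc[0].start == 0
        assert truth.iloc[-1].end == 500_000
        assert (truth["start"].values[1:] == truth["end"].values[:-1]).all()
        assert len(rec.sequence) == 500_000

    def test_block_windows_elevated_cg(self):
        bg = synth.build_species_model("bg", cg_suppression=0.3)
        unit = synth.cg_rich_repeat_unit(520, seed=7)
        plan = synth.ChromosomePlan(
            "c", 3_000_000,
            repeat_blocks=[synth.RepeatBlock(1_000_000, 1000, unit,
                                             spacer_len=30)])
        rec, rows = synth.generate_chromosome("sp", bg, plan, seed=6)
        block = rec.sequence[1_000_000:1_500_000]
        flank = rec.sequence[:500_000]
        cv_b = oligo.composition(block, 2)
        cv_f = oligo.composition(flank, 2)
        cg_i = list(cv_b.labels).index("CG")
        assert cv_b.values[cg_i] > 5 * cv_f.values[cg_i]

    def test_gradient_weight_parabolic(self):
        # ends emitted from the edge model, center from the center model
        rich = synth.build_species_model("r", pi=[0.2, 0.3, 0.3, 0.2],
                                         cg_suppression=0.9)
        poor = synth.build_species_model("p", pi=[0.35, 0.15, 0.15, 0.35],
                                         cg_suppression=0.3)
        plan = synth.ChromosomePlan("c", 3_000_000, gradient=(rich, poor))
        rec, rows = synth.generate_chromosome("sp", None, plan, seed=8)
        end = rec.sequence[:100_000] + rec.sequence[-100_000:]
        mid = rec.sequence[1_450_000:1_650_000]
        assert cg_metrics.gc_percent(end) > cg_metrics.gc_percent(mid) + 5
        assert rows[0]["zone"] == "gradient"

    def test_label_windows_marks_zones(self):
        from sigsom.genome_io import window_record

        m = synth.build_species_model("sp", cg_suppression=0.5)
        f = synth.build_species_model("f", pi=[0.15, 0.35, 0.35, 0.15],
                                      cg_suppression=0.9)
        plan = synth.ChromosomePlan(
            "c", 1_000_000,
            foreign_segments=[synth.ForeignSegment(300_000, 600_000, f)])
        rec, rows = synth.generate_chromosome("sp", m, plan, seed=11)
        windows, _ = window_record(rec, 100_000, 100_000)
        lab = synth.label_windows(windows, pd.DataFrame(rows))
        zones = dict(zip(lab.window_id, lab.zone))
        assert zones["c:300000-400000"] == "foreign"
        assert zones["c:0-100000"] == "background"
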