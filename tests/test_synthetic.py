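"""The synthetic study generator: determinism, identities, calibration."""

import numpy as np
import pytest

from nocistat.behavior import phase_summaries_with_aa, phase_totals
from nocistat.errors import ValidationError
from nocistat.histomorphometry import average_fields
from nocistat.synthetic import (
    CGCurve,
    MSEffect,
    ScenarioConfig,
    behavior_frame,
    combined_effect,
    simulate_dose_response_experiment,
    simulate_mastcell_sample,
    simulate_rubbing_course,
)


class TestRubbingCourse:
    def test_no_drug_no_noise_reproduces_template(self):
        cfg = ScenarioConfig(seed=1, noise_cv=0.0)
        rec = simulate_rubbing_course(cfg, 0.0, 0.0, 0)
        assert rec.bins == tuple(cfg.control_course)

    def test_full_phase2_suppression_zeroes_bins_4_to_15(self):
        cfg = ScenarioConfig(
            seed=1, noise_cv=0.0,
            cg_curve=CGCurve(emax_phase2=100.0, ed50_phase2=1e-9),
        )
        rec = simulate_rubbing_course(cfg, 30.0, 0.0, 0)
        assert all(b == pytest.approx(0.0, abs=1e-6) for b in rec.bins[3:])
        assert rec.bins[0] > 0  # phase 1 not fully suppressed

    def test_seed_determinism_byte_identical_csv(self, tmp_path):
        for run in range(2):
            cfg = ScenarioConfig(seed=42)
            recs = simulate_dose_response_experiment(cfg, (1.0, 5.0, 10.0), fixed_ms_dose=5.0)
            behavior_frame(recs).to_csv(tmp_path / f"run{run}.csv", index=False)
        assert (tmp_path / "run0.csv").read_bytes() == (tmp_path / "run1.csv").read_bytes()

    def test_adding_a_group_never_perturbs_existing_rats(self):
        cfg = ScenarioConfig(seed=3)
        small = simulate_dose_response_experiment(cfg, (1.0, 5.0, 10.0))
        big = simulate_dose_response_experiment(cfg, (1.0, 5.0, 10.0), fixed_ms_dose=5.0)
        small_by_id = {r.rat_id: r.bins for r in small}
        for r in big:
            if r.rat_id in small_by_id:
                assert r.bins == small_by_id[r.rat_id]

    def test_bins_respect_cap(self):
        cfg = ScenarioConfig(seed=9, noise_cv=1.0)
        for i in range(20):
            rec = simulate_rubbing_course(cfg, 0.0, 0.0, i)
            assert all(0.0 <= b <= 180.0 for b in rec.bins)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            ScenarioConfig(control_course=(200.0,) * 15)
        with pytest.raises(ValidationError):
            ScenarioConfig(interaction_mode="reverse")
        with pytest.raises(ValidationError):
            ScenarioConfig(cg_curve=CGCurve(ed50_phase2=-1))


class TestCombinedEffect:
    def test_ms_effect_is_dose_independent(self):
        cfg = ScenarioConfig()
        assert combined_effect(cfg, 0.0, 5.0, 2) == combined_effect(cfg, 0.0, 15.0, 2)

    def test_inhibit_mode_halves_potency(self):
        cfg = ScenarioConfig(interaction_mode="inhibit", interaction_magnitude=1.0,
                             ms_effect=MSEffect(0.0, 0.0))
        # cg at dose D with magnesium equals cg alone at D/2
        assert combined_effect(cfg, 10.0, 5.0, 2) == pytest.approx(
            combined_effect(cfg, 5.0, 0.0, 2)
        )

    def test_effect_capped_at_100(self):
        cfg = ScenarioConfig()
        assert combined_effect(cfg, 1000.0, 15.0, 2) == 100.0


class TestRoundTripThroughPipelineStatistics:
    def test_recovered_aa_matches_configured_effect_noise_free(self):
        cfg = ScenarioConfig(seed=2, noise_cv=0.0)
        recs = simulate_dose_response_experiment(cfg, (1.0, 10.0, 30.0), fixed_ms_dose=15.0)
        grouped = phase_summaries_with_aa(recs)
        for label, summaries in grouped.items():
            rec = next(r for r in recs if r.group_label == label)
            for phase in (1, 2):
                want = combined_effect(cfg, rec.cg_dose, rec.ms_dose, phase)
                for s in summaries:
                    assert s.aa_pct(phase) == pytest.approx(want, abs=1e-9)


class TestMastCells:
    def test_naive_means_near_calibration(self, default_config):
        totals, degrans = [], []
        for i in range(200):
            s = simulate_mastcell_sample(default_config, "naive", "5 min", i)
            mt, md = average_fields(s)
            totals.append(mt)
            degrans.append(md)
        assert np.mean(totals) == pytest.approx(212.0, rel=0.02)
        assert np.mean(degrans) == pytest.approx(3.0, rel=0.15)

    def test_degranulated_never_exceeds_total(self, default_config):
        for group in ("naive", "vehicle", "formalin", "formalin+ms"):
            for i in range(10):
                s = simulate_mastcell_sample(default_config, group, "25 min", i)
                for f in s.fields:
                    assert f.degranulated <= f.total

    def test_zero_inhibition_makes_ms_indistinguishable(self):
        from nocistat.synthetic import MastCellConfig

        cfg = ScenarioConfig(
            seed=4,
            mastcell=MastCellConfig(ms_inhibition_5min=0.0, ms_inhibition_25min=0.0,
                                    ms_extra_total_reduction_5min=0.0),
        )
        f_means, fm_means = [], []
        for i in range(300):
            f_means.append(average_fields(simulate_mastcell_sample(cfg, "formalin", "25 min", i))[1])
            fm_means.append(average_fields(simulate_mastcell_sample(cfg, "formalin+ms", "25 min", i))[1])
        assert np.mean(f_means) == pytest.approx(np.mean(fm_means), rel=0.05)

    def test_configured_25min_inhibition_recovered(self, default_config):
        """Monte Carlo of the configured effect: I% of MS vs formalin at
        25 min ~ 40% over many simulated cohorts."""
        from nocistat.histomorphometry import degranulation_inhibition

        i_values = []
        for cohort in range(300):
            f = average_fields(simulate_mastcell_sample(default_config, "formalin", "25 min", cohort))[1]
            fm = average_fields(simulate_mastcell_sample(default_config, "formalin+ms", "25 min", cohort))[1]
            if f > 0:
                i_values.append(degranulation_inhibition(f, fm))
        assert np.mean(i_values) == pytest.approx(40.0, abs=5.0)
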