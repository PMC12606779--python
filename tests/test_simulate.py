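"""Synthetic cohort generator: determinism, prevalence, artifact mechanisms
and composed-pipeline recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from fragscore import (
    ScenarioConfig,
    features_frame,
    fit_logistic,
    generate_cohort,
    generate_noncancer_panel,
)
from fragscore.datatypes import PREDEFINED_MODELS, FragmentProfile, Target
from fragscore.features import derive_features
from fragscore.model import predict_proba
from fragscore.qc import check_ipc_shift
from fragscore.simulate import default_curves, simulate_plate


class TestGenerateCohort:
    def test_seed_determinism(self):
        cfg = ScenarioConfig(seed=11)
        r1, p1, t1 = generate_cohort(cfg)
        r2, p2, t2 = generate_cohort(ScenarioConfig(seed=11))
        assert r1 == r2
        assert [(p.SM1, p.MM1, p.SM2, p.MM2) for p in p1] == [
            (p.SM1, p.MM1, p.SM2, p.MM2) for p in p2
        ]
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_differs(self):
        _, p1, _ = generate_cohort(ScenarioConfig(seed=1))
        _, p2, _ = generate_cohort(ScenarioConfig(seed=2))
        assert p1[0].SM1 != p2[0].SM1

    def test_prevalence_within_binomial_band(self):
        """Pooled empirical prevalence over many seeds stays inside the 95%
        binomial band around 20/128."""
        p = 20 / 128
        hits = total = 0
        for seed in range(200):
            _, _, truth = generate_cohort(ScenarioConfig(n_patients=64, seed=seed))
            hits += int(truth["progressed"].sum())
            total += len(truth)
        half_width = 1.96 * math.sqrt(p * (1 - p) / total)
        assert abs(hits / total - p) <= half_width + 1e-12

    def test_invalid_config_rejected_before_sampling(self):
        with pytest.raises(ValueError):
            generate_cohort(ScenarioConfig(prevalence=1.5))
        with pytest.raises(ValueError):
            generate_cohort(ScenarioConfig(n_patients=1))

    def test_lysis_inflates_sm_but_not_fragdiff(self):
        """Universal lysis with no progression effect: raw short-marker
        concentration jumps by a large factor while the fragmentomic
        difference stays at noise scale (the Table-4-style mechanism)."""
        cfg = ScenarioConfig(
            n_patients=150, prevalence=0.0, lysis_rate=1.0,
            noncancer_event_rate=0.0, seed=5,
        )
        _, profiles, truth = generate_cohort(cfg)
        folds, fragdiffs, frag1s = [], [], []
        for prof, (_, t) in zip(profiles, truth.iterrows()):
            folds.append(prof.SM2 / t["true_SM2"])
            f = derive_features(prof)
            fragdiffs.append(f.FragDiff)
            frag1s.append(f.Frag1)
        assert np.mean(folds) > 3.0  # raw SM inflated several-fold
        # fragmentomic change stays at the scale of baseline noise
        assert np.mean(np.abs(fragdiffs)) < np.mean(frag1s)

    def test_null_effect_gives_chance_auc(self):
        cfg = ScenarioConfig(
            n_patients=300, progression_effect_log_mean=math.log(1e-6),
            lysis_rate=0.0, noncancer_event_rate=0.0, seed=8,
        )
        _, profiles, truth = generate_cohort(cfg)
        feats = features_frame(profiles)
        y = truth["progressed"].astype(float).to_numpy()
        fit = fit_logistic(feats, y, PREDEFINED_MODELS[0])
        assert 0.35 <= fit.training_auc <= 0.65

    def test_timestamps_satisfy_gates_by_default(self, default_cohort):
        from fragscore.qc import gate_record

        records, *_ = default_cohort
        for rec in records:
            assert all(v.passed for v in gate_record(rec))

    def test_violation_rates_produce_violations(self):
        cfg = ScenarioConfig(
            n_patients=60, transit_violation_rate=1.0,
            draw_window_violation_rate=1.0, scan_window_violation_rate=1.0,
            seed=3,
        )
        records, *_ = generate_cohort(cfg)
        from fragscore.qc import check_draw_window, check_scan_window, check_transit_time

        assert all(not check_transit_time(r.draws[1]).passed for r in records)
        assert all(not check_draw_window(r).passed for r in records)
        assert all(not check_scan_window(r).passed for r in records)

    def test_pipeline_can_reach_high_auc_regime(self, default_cohort):
        """Existence: the default configuration supports training AUC > 0.9."""
        *_, feats, labels = default_cohort
        fit = fit_logistic(feats, labels, PREDEFINED_MODELS[3])
        assert fit.training_auc > 0.9

    def test_parameter_recovery_at_large_n(self):
        """A large cohort recovers the direction and magnitude of the
        configured progression effect in the FragDiff channel."""
        cfg = ScenarioConfig(
            n_patients=5000, lysis_rate=0.0, noncancer_event_rate=0.0, seed=17
        )
        _, profiles, truth = generate_cohort(cfg)
        feats = features_frame(profiles)
        y = truth["progressed"].to_numpy()
        diff = feats.loc[y, "FragDiff"].mean() - feats.loc[~y, "FragDiff"].mean()
        expected = math.exp(
            cfg.progression_effect_log_mean + cfg.progression_effect_log_sd**2 / 2
        )
        assert diff > 0
        assert diff == pytest.approx(expected, rel=0.35)


class TestSimulatePlate:
    def test_inhibited_sample_caught_by_ipc_qc(self, default_cohort):
        _, profiles, _, _, _ = default_cohort
        cfg = ScenarioConfig(ct_noise_sd=0.1, inhibitor_ct_shift=2.5, seed=2)
        curves = default_curves(cfg)
        rng = np.random.default_rng(2)
        wells = []
        for i, prof in enumerate(profiles[:6]):
            wells.extend(
                simulate_plate(
                    prof, curves, cfg, rng,
                    inhibited_draws=(2,) if i == 0 else (),
                )
            )
        verdicts = {v.subject: v for v in check_ipc_shift(wells, "r1")}
        bad = f"{profiles[0].patient_id}-D2"
        assert not verdicts[bad].passed
        clean = [s for s in verdicts if s != bad]
        assert all(verdicts[s].passed for s in clean)

    def test_tiny_quantity_drops_out_beyond_cycle_count(self):
        cfg = ScenarioConfig(ct_noise_sd=0.0)
        curves = default_curves(cfg)
        prof = FragmentProfile("P", SM1=1e-4, MM1=1e-5, SM2=1e-4, MM2=1e-5)
        wells = simulate_plate(prof, curves, cfg)
        short = [w for w in wells if w.target in (Target.SHORT80, Target.SHORT105)]
        assert all(w.ct is None for w in short)

    def test_triplicates_and_both_multiplexes(self, default_cohort):
        _, profiles, _, _, _ = default_cohort
        cfg = ScenarioConfig()
        wells = simulate_plate(profiles[0], default_curves(cfg), cfg)
        # 2 draws x 2 multiplexes x 3 targets x 3 replicates
        assert len(wells) == 36
        assert {w.multiplex for w in wells} == {1, 2}


class TestNoncancerPanel:
    @pytest.fixture
    def fitted(self, default_cohort):
        *_, feats, labels = default_cohort
        return fit_logistic(feats, labels, PREDEFINED_MODELS[3])

    def _ps(self, fit, panel):
        feats = features_frame(
            [FragmentProfile(r.patient_id, r.SM1, r.MM1, r.SM2, r.MM2)
             for r in panel.itertuples()]
        )
        return 100.0 * predict_proba(fit, feats)

    def test_default_composition(self):
        panel = generate_noncancer_panel(ScenarioConfig(seed=1))
        counts = panel[panel.group == "condition"].condition.value_counts()
        assert counts["acute stroke"] == 3 and counts["viral infection"] == 5
        assert (panel.group == "healthy").sum() == 9

    def test_healthy_ps_change_centers_near_zero(self, fitted):
        panel = generate_noncancer_panel(ScenarioConfig(seed=4), n_healthy=40)
        healthy = panel[panel.group == "healthy"]
        ps = self._ps(fitted, healthy)
        from fragscore import compute_ps_change

        changes = [compute_ps_change(p, ps.mean()) for p in ps]
        assert abs(np.mean(changes)) < 1e-9  # self-referential by definition
        assert np.mean(ps) < 50.0  # healthy subjects score low

    def test_proportional_elevation_mostly_cancels(self, fitted):
        """Both size classes elevated together: fragmentomic cancellation
        keeps the PS shift far smaller than a short-only elevation."""
        prop = generate_noncancer_panel(ScenarioConfig(seed=6))
        short = generate_noncancer_panel(ScenarioConfig(seed=6), short_only=True)
        healthy_mean = self._ps(fitted, prop[prop.group == "healthy"]).mean()
        d_prop = self._ps(fitted, prop[prop.group == "condition"]).mean() - healthy_mean
        d_short = self._ps(fitted, short[short.group == "condition"]).mean() - healthy_mean
        assert d_short > d_prop
        assert d_short > 10.0  # short-only elevation mimics progression
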