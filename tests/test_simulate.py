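"""Generator determinism, moment checks and end-to-end recovery."""

import numpy as np
import pytest

from pigbout import (
    BehaviorClass,
    BoutCriteria,
    Group,
    SimulationConfig,
    filter_by_confidence,
    find_bouts,
    make_box_fixture,
    render_detections,
    render_manual,
    simulate_bout_schedule,
    simulate_pen_day,
    to_presence_series,
)
from pigbout.detection_io import SECONDS_PER_DAY

AGG = BehaviorClass.AGGRESSIVE


def single_class_cfg(rate, seed=1, **kw):
    """Config with one active class at the given daily rate."""
    base = {c: 0.0 for c in BehaviorClass}
    base[AGG] = rate
    return SimulationConfig(seed=seed, base_bouts_per_day=base, day_trend=0.0, **kw)


class TestScheduleGenerator:
    def test_zero_rate_gives_empty_schedule(self, cfg):
        zero = single_class_cfg(0.0)
        assert simulate_bout_schedule(zero, Group.CONTROL, 1, AGG) == []

    def test_deterministic_given_seed_and_arguments(self, cfg):
        a = simulate_bout_schedule(cfg, Group.TREATMENT, 3, AGG)
        b = simulate_bout_schedule(cfg, Group.TREATMENT, 3, AGG)
        assert a == b
        c = simulate_bout_schedule(cfg, Group.CONTROL, 3, AGG)
        assert a != c  # group enters the stream derivation

    def test_schedule_respects_bout_invariants(self, cfg, criteria):
        for day in (1, 14, 28):
            sched = simulate_bout_schedule(cfg, Group.CONTROL, day, AGG)
            onset = criteria.onset_min_s[AGG]
            for b in sched:
                assert b.duration_s >= onset
                assert 0 <= b.start_s < b.end_s <= SECONDS_PER_DAY
            for b1, b2 in zip(sched, sched[1:]):
                assert b2.start_s - b1.end_s >= criteria.termination_gap_s

    def test_poisson_rate_recovered_over_many_days(self):
        # 10^4 simulated days at rate 20, no trend: the mean daily bout
        # count must fall within 3 standard errors of 20
        lam, n_days = 20.0, 10_000
        c = single_class_cfg(lam, seed=2024)
        counts = [
            len(simulate_bout_schedule(c, Group.CONTROL, day, AGG))
            for day in range(1, n_days + 1)
        ]
        se = np.sqrt(lam / n_days)
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_day_trend_scales_expected_counts(self):
        c = single_class_cfg(40.0, seed=5)
        trended = SimulationConfig(
            **{**_as_dict(c), "day_trend": -0.1}
        )
        early = np.mean([
            len(simulate_bout_schedule(trended, Group.CONTROL, d, AGG))
            for d in range(1, 40)
        ])
        late = np.mean([
            len(simulate_bout_schedule(trended, Group.CONTROL, d, AGG))
            for d in range(1, 40)
        ])
        assert early == late  # same days, determinism
        late = np.mean([
            len(simulate_bout_schedule(trended, Group.CONTROL, d + 20, AGG))
            for d in range(1, 40)
        ])
        assert late < early

    def test_infeasible_packing_rejected(self):
        c = single_class_cfg(5000.0)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_bout_schedule(c, Group.CONTROL, 1, AGG)

    def test_treatment_effect_sign_recovered(self):
        # control minus treatment daily bout counts over 28 days is
        # positive in >= 99% of 1000 seeded replicates at base rate 20
        # and count multiplier 0.5
        base = {c: 0.0 for c in BehaviorClass}
        base[AGG] = 20.0
        mult = {c: 0.5 for c in BehaviorClass}
        wins = 0
        n_rep = 1000
        for rep in range(n_rep):
            c = SimulationConfig(
                seed=10_000 + rep, base_bouts_per_day=base,
                treatment_count_multiplier=mult, day_trend=0.0,
            )
            diff = np.mean([
                len(simulate_bout_schedule(c, Group.CONTROL, d, AGG))
                - len(simulate_bout_schedule(c, Group.TREATMENT, d, AGG))
                for d in range(1, 29)
            ])
            wins += diff > 0
        assert wins / n_rep >= 0.99


class TestDetectorRendering:
    def test_noise_free_rendering_is_identity(self, noise_free_cfg, criteria):
        sched = simulate_bout_schedule(noise_free_cfg, Group.CONTROL, 1, AGG)
        dets = render_detections(sched, noise_free_cfg, 0)
        series = to_presence_series(
            filter_by_confidence(dets), sched[0].date, AGG
        )
        expected = np.zeros(SECONDS_PER_DAY, dtype=np.uint8)
        for b in sched:
            expected[b.start_s:b.end_s] = 1
        assert np.array_equal(series.presence, expected)

    def test_total_miss_probability_silences_detector(self):
        c = single_class_cfg(20.0, miss_prob=0.999999, false_positive_rate=0.0)
        # miss_prob must stay < 1 by the config contract; emulate "all
        # missed" with an explicit Bernoulli stream instead
        sched = simulate_bout_schedule(c, Group.CONTROL, 1, AGG)
        rng = np.random.default_rng(0)
        dets = render_detections(sched, c, rng)
        in_bout = sum(b.duration_s for b in sched)
        assert len(dets) < in_bout * 0.01

    def test_miss_rate_moment(self):
        c = single_class_cfg(80.0, seed=6, miss_prob=0.1, false_positive_rate=0.0)
        total_in_bout, detected = 0, 0
        for day in range(1, 10):
            sched = simulate_bout_schedule(c, Group.CONTROL, day, AGG)
            dets = render_detections(sched, c, day)
            total_in_bout += sum(b.duration_s for b in sched)
            detected += len(dets)
        assert total_in_bout > 10_000
        p_hat = detected / total_in_bout
        se = np.sqrt(0.9 * 0.1 / total_in_bout)
        assert abs(p_hat - 0.9) < 3 * se

    def test_false_positive_rate_moment(self):
        c = single_class_cfg(5.0, seed=7, miss_prob=0.0, false_positive_rate=30.0)
        extra = 0
        n_days = 200
        for day in range(1, n_days + 1):
            sched = simulate_bout_schedule(c, Group.CONTROL, day, AGG)
            dets = render_detections(sched, c, day)
            extra += len(dets) - sum(b.duration_s for b in sched)
        lam = 30.0 * 3 * n_days  # per class, three classes per day
        assert abs(extra - lam) < 3 * np.sqrt(lam)

    def test_rendered_confidences_survive_default_filter(self, cfg):
        sched = simulate_bout_schedule(cfg, Group.CONTROL, 1, AGG)
        dets = render_detections(sched, cfg, 1)
        assert all(d.confidence >= 0.45 for d in dets)
        assert dets == filter_by_confidence(dets)


class TestManualRendering:
    def test_zero_noise_is_identity(self, noise_free_cfg):
        sched = simulate_bout_schedule(noise_free_cfg, Group.CONTROL, 2, AGG)
        assert render_manual(sched, noise_free_cfg, 0) == sched

    def test_full_miss_empties_output(self):
        c = single_class_cfg(20.0, manual_miss_prob=0.999999)
        sched = simulate_bout_schedule(c, Group.CONTROL, 1, AGG)
        # with miss probability ~1 essentially everything is dropped
        assert len(render_manual(sched, c, 0)) <= 1

    def test_boundary_jitter_half_normal_moment(self):
        sd = 2.0
        c = single_class_cfg(50.0, seed=8, manual_miss_prob=0.0,
                             manual_boundary_jitter_sd_s=sd)
        disp = []
        for day in range(1, 30):
            sched = simulate_bout_schedule(c, Group.CONTROL, day, AGG)
            coded = render_manual(sched, c, day)
            disp += [abs(m.start_s - t.start_s) for m, t in zip(coded, sched)]
        assert len(disp) > 1000
        # |round(N(0, sd))| has mean close to the half-normal sd*sqrt(2/pi);
        # rounding keeps it within ~0.1 s of the continuous value
        expected = sd * np.sqrt(2 / np.pi)
        se = np.std(disp) / np.sqrt(len(disp))
        assert abs(np.mean(disp) - expected) < 3 * se + 0.1

    def test_output_respects_bout_bounds(self):
        c = single_class_cfg(30.0, manual_boundary_jitter_sd_s=10.0)
        for day in (1, 2, 3):
            sched = simulate_bout_schedule(c, Group.CONTROL, day, AGG)
            for b in render_manual(sched, c, day):
                assert 0 <= b.start_s < b.end_s <= SECONDS_PER_DAY


class TestEndToEndRecovery:
    def test_noise_free_pipeline_recovers_schedule_over_seeds(self, criteria):
        # schedule -> detections -> presence -> bouts is the identity for
        # criterion-satisfying schedules, across 100 seeds and all classes
        for seed in range(100):
            c = SimulationConfig(seed=seed).noise_free()
            day = 1 + seed % 28
            for cls in BehaviorClass:
                sched = simulate_bout_schedule(c, Group.CONTROL, day, cls)
                dets = render_detections(sched, c, seed)
                if not sched:
                    assert dets == []
                    continue
                series = to_presence_series(
                    filter_by_confidence(dets), sched[0].date, cls
                )
                assert find_bouts(series, criteria) == sched


class TestPenDayAndConfig:
    def test_pen_day_is_deterministic(self, cfg):
        a = simulate_pen_day(cfg, Group.TREATMENT, 2)
        b = simulate_pen_day(cfg, Group.TREATMENT, 2)
        assert a.true_bouts == b.true_bouts
        assert a.detections == b.detections
        assert a.manual_bouts == b.manual_bouts
        assert a.date.isoformat() == "2024-07-16"

    def test_true_bouts_disjoint_within_class(self, cfg, criteria):
        pen_day = simulate_pen_day(cfg, Group.CONTROL, 5)
        for cls in BehaviorClass:
            cls_bouts = sorted(
                (b for b in pen_day.true_bouts if b.class_label is cls),
                key=lambda b: b.start_s,
            )
            for b1, b2 in zip(cls_bouts, cls_bouts[1:]):
                assert b2.start_s - b1.end_s >= criteria.termination_gap_s

    def test_yaml_round_trip(self, tmp_path, cfg):
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(miss_prob=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(false_positive_rate=-1)
        with pytest.raises(ValueError):
            SimulationConfig(confidence_beta_a=0)


class TestBoxFixture:
    def test_deterministic(self, cfg):
        assert make_box_fixture(5, cfg, 9) == make_box_fixture(5, cfg, 9)

    def test_class_flip_rate_moment(self):
        flip = 0.2
        c = SimulationConfig(
            seed=3, box_jitter_sd_px=0.0, box_drop_prob=0.0,
            box_spurious_rate=0.0, box_class_flip_prob=flip,
            boxes_per_image_mean=2.0,
        )
        gts, preds = make_box_fixture(600, c, 0)
        assert len(preds) == len(gts) >= 1000
        flipped = sum(
            p.class_label is not g.class_label for p, g in zip(preds, gts)
        )
        n = len(gts)
        se = np.sqrt(flip * (1 - flip) / n)
        assert abs(flipped / n - flip) < 3 * se

    def test_n_images_validated(self, cfg):
        with pytest.raises(ValueError):
            make_box_fixture(0, cfg, 1)


def _as_dict(c: SimulationConfig) -> dict:
    from dataclasses import asdict

    return asdict(c)
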