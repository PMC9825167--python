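"""Simulator contracts: deterministic limits, invariants, ground-truth recovery."""
import numpy as np
import pandas as pd
import pytest

from telosas import (
    SimConfig,
    detect_bands,
    doublings_per_day,
    generate_chip_dataset,
    generate_lane_profile,
    percent_reference,
    relative_length,
    simulate_daily_culture,
    simulate_telomere_trajectory,
    simulate_terra_cts,
    terra_fold,
)
from telosas.simulate import generate_cell_cycle_cts


def deterministic_decay_config(**overrides):
    base = dict(
        shorten_rate_mean=2.0,
        shorten_rate_sd=0.0,
        hdr_prob_per_pd=0.0,
        initial_length=350.0,
        senesce_length=220.0,
        critical_length=120.0,
        max_doublings_per_day=5.0,
        min_doublings_per_day=1.0,
        od_noise_cv=0.0,
        ct_noise_sd=0.0,
        n_days=2,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestTrajectory:
    def test_linear_decay_without_noise_or_events(self):
        # 2 days x 5 doublings = 10 PDs at 2 bp/PD from 350 bp
        cfg = deterministic_decay_config()
        traj = simulate_telomere_trajectory(cfg, seed=0)
        assert traj.pd[-1] == pytest.approx(10.0)
        assert traj.length[-1] == pytest.approx(330.0)
        assert all(e == "none" for e in traj.event)

    def test_forced_type1_event_adds_fixed_gain(self):
        cfg = deterministic_decay_config(
            initial_length=121.5,
            senesce_length=121.0,
            critical_length=119.0,
            hdr_prob_per_pd=1.0,
            type2_fraction=0.0,
            type1_gain=150.0,
            n_days=3,
        )
        traj = simulate_telomere_trajectory(cfg, seed=0)
        i = traj.first_event_index()
        assert i is not None
        assert traj.event[i] == "type1"
        assert traj.length[i] == pytest.approx(traj.length[i - 1] + 150.0)
        # the predecessor record was the first one below the critical length
        assert traj.length[i - 1] < cfg.critical_length

    def test_determinism_bit_identical(self, config):
        a = simulate_telomere_trajectory(config, seed=42)
        b = simulate_telomere_trajectory(config, seed=42)
        assert np.array_equal(a.pd, b.pd)
        assert np.array_equal(a.length, b.length)
        assert np.array_equal(a.event, b.event)

    def test_length_decreases_between_non_event_records(self, config):
        traj = simulate_telomere_trajectory(config, seed=7)
        dl = np.diff(traj.length)
        events = traj.event[1:]
        assert np.all(dl[events == "none"] <= 0)
        assert np.all(dl[events != "none"] > 0)

    def test_pd_strictly_increasing_and_matches_day_starts(self, config):
        traj = simulate_telomere_trajectory(config, seed=3)
        assert np.all(np.diff(traj.pd) > 0)
        assert traj.day_starts[0] == 0.0
        assert traj.day_starts[-1] == pytest.approx(traj.pd[-1])
        assert len(traj.day_starts) == config.n_days + 1

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(initial_length=-5.0)
        with pytest.raises(ValueError):
            SimConfig(critical_length=400.0)  # >= initial_length ordering broken
        with pytest.raises(ValueError):
            SimConfig(hdr_prob_per_pd=1.5)
        with pytest.raises(ValueError):
            SimConfig(terra_fold_short=0.5)


class TestDailyCulture:
    def test_healthy_growth_od_is_exact(self):
        # length never drops below senesce_length within one day of growth
        cfg = deterministic_decay_config(n_days=5)
        traj = simulate_telomere_trajectory(cfg, seed=0)
        growth = simulate_daily_culture(traj, cfg, seed=0)
        assert np.allclose(growth.frame["od_end"], 0.01 * 2**5)  # 0.32

    def test_od_at_critical_length_is_min_doublings(self):
        # hold the telomere at the critical length: one doubling per day
        cfg = deterministic_decay_config(n_days=3)
        from telosas.simulate import TelomereTrajectory

        traj = TelomereTrajectory(
            clone_id="pinned",
            pd=[0.0, 1.0, 2.0, 3.0],
            length=[120.0] * 4,
            event=["none"] * 4,
            day_starts=[0.0, 1.0, 2.0, 3.0],
        )
        growth = simulate_daily_culture(traj, cfg, seed=0)
        assert np.allclose(growth.frame["od_end"], 0.02)

    def test_noise_free_min_od_day_is_min_length_day(self, quiet_config):
        traj = simulate_telomere_trajectory(quiet_config, seed=11)
        growth = simulate_daily_culture(traj, quiet_config, seed=11)
        od = growth.frame["od_end"].to_numpy()
        assert int(od.argmin()) == int(growth.length_truth.argmin())

    def test_pd_accumulates_realized_doublings(self, quiet_config):
        traj = simulate_telomere_trajectory(quiet_config, seed=5)
        growth = simulate_daily_culture(traj, quiet_config, seed=5)
        daily = np.log2(growth.frame["od_end"] / growth.frame["od_start"])
        assert np.allclose(growth.frame["pd_cumulative"], daily.cumsum())
        # without noise, measured PDs equal the trajectory's generative PDs
        assert growth.frame["pd_cumulative"].iloc[-1] == pytest.approx(traj.pd[-1])


class TestGrowthResponse:
    def test_monotone_in_length(self, config):
        lengths = np.linspace(20.0, 400.0, 300)
        d = doublings_per_day(lengths, config)
        assert np.all(np.diff(d) >= 0)
        assert doublings_per_day(config.senesce_length, config) == pytest.approx(
            config.max_doublings_per_day
        )
        assert doublings_per_day(config.critical_length, config) == pytest.approx(
            config.min_doublings_per_day
        )
        # strictly increasing below the senescence-onset length
        senescent = lengths[lengths < config.senesce_length]
        assert np.all(np.diff(doublings_per_day(senescent, config)) > 0)


class TestTerra:
    def test_fold_endpoints_exact(self, config):
        assert terra_fold(config.senesce_length, config) == pytest.approx(1.0)
        assert terra_fold(config.senesce_length + 100, config) == pytest.approx(1.0)
        assert terra_fold(config.critical_length, config) == pytest.approx(6.0)
        assert terra_fold(config.critical_length - 50, config) == pytest.approx(6.0)

    def test_fold_monotone_non_increasing(self, config):
        lengths = np.linspace(50.0, 400.0, 500)
        f = terra_fold(lengths, config)
        assert np.all(np.diff(f) <= 1e-12)

    def test_fold_maps_to_exact_dct_shift_without_noise(self, quiet_config):
        from telosas.simulate import TelomereTrajectory

        # one long and one critically short record: fold 6 = -log2(6) Ct shift
        traj = TelomereTrajectory(
            clone_id="c",
            pd=[0.0, 1.0],
            length=[quiet_config.senesce_length, quiet_config.critical_length],
            event=["none", "none"],
        )
        table = simulate_terra_cts(traj, quiet_config, seed=0)
        dct = table["ct_target"] - table["ct_reference"]
        assert dct.iloc[0] - dct.iloc[1] == pytest.approx(np.log2(6.0))
        pct = percent_reference(table["ct_target"], table["ct_reference"])
        assert pct[1] / pct[0] == pytest.approx(6.0)

    def test_fold_four_shifts_two_cycles(self, quiet_config):
        from telosas.simulate import TelomereTrajectory

        cfg = quiet_config.replace(terra_fold_short=4.0)
        traj = TelomereTrajectory(
            clone_id="c",
            pd=[0.0, 1.0],
            length=[cfg.senesce_length, cfg.critical_length],
            event=["none", "none"],
        )
        table = simulate_terra_cts(traj, cfg, seed=0)
        dct = table["ct_target"] - table["ct_reference"]
        assert dct.iloc[1] - dct.iloc[0] == pytest.approx(-2.0)


class TestLaneProfile:
    def test_single_band_argmax_at_center(self, quiet_config):
        profile = generate_lane_profile([300.0], quiet_config, seed=0, background=0.0)
        peak = profile.coordinates[profile.intensities.argmax()]
        assert peak == pytest.approx(profile.true_centers[0], abs=2e-3)

    def test_two_bands_recovered_within_noise(self, config):
        profile = generate_lane_profile([350.0, 150.0], config, seed=1)
        positions = detect_bands(profile)
        assert len(positions) == 2
        assert np.allclose(
            np.sort(positions),
            np.sort(profile.true_centers),
            atol=3 * config.band_position_noise_sd + 2e-3,
        )

    def test_noise_free_relative_lengths_match_truth(self, quiet_config):
        lengths = [350.0, 220.0, 120.0]
        profile = generate_lane_profile(lengths, quiet_config, seed=0, background=0.0)
        positions = detect_bands(profile)
        assert np.allclose(
            np.sort(relative_length(positions)),
            np.sort(np.asarray(lengths) / 350.0),
            atol=5e-3,
        )

    def test_empty_length_list_rejected(self, config):
        with pytest.raises(ValueError):
            generate_lane_profile([], config, seed=0)


class TestChipDataset:
    def test_unit_ratio_noise_free_gives_fold_one(self, quiet_config):
        from telosas.chip import chip_fold_table

        records = generate_chip_dataset(
            quiet_config, seed=0, enrichment={"1L": 1.0}, n_replicates=2
        )
        folds = chip_fold_table(records, tap=True)
        assert np.allclose(folds["fold_change"], 1.0)

    def test_half_ratio_noise_free_recovered(self, quiet_config):
        from telosas.chip import chip_fold_table

        records = generate_chip_dataset(quiet_config, seed=0, n_replicates=2)
        folds = chip_fold_table(records, tap=True)
        telomeric = folds[folds["locus"] != "ACT1"]
        assert np.allclose(telomeric["fold_change"], 0.5)
        assert np.allclose(folds.loc[folds["locus"] == "ACT1", "fold_change"], 1.0)

    def test_ground_truth_column_matches_request(self, config):
        records = generate_chip_dataset(config, seed=0, enrichment={"15L": 0.3})
        assert set(records["true_ratio"]) == {0.3}


class TestCellCycleTable:
    def test_noise_free_drop_recovers_setpoint(self, quiet_config):
        from telosas.qpcr import cell_cycle_drop, percent_reference

        table = generate_cell_cycle_cts(quiet_config, seed=0, decline_pct=29.0)
        pct = percent_reference(
            table["ct_target"].to_numpy(), table["ct_reference"].to_numpy()
        )
        table = table.assign(pct=pct)
        early = table.loc[table["phase"] == "early_S", "pct"].mean()
        g2 = table.loc[table["phase"] == "G2", "pct"].mean()
        assert cell_cycle_drop(early, g2) == pytest.approx(29.0)
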