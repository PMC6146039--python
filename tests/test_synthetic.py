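"""Synthetic generators: determinism, ground truth and reader compatibility."""
import numpy as np
import pandas as pd
import pytest

from platephen import germination, seed_counter
from platephen.exceptions import ScenarioError
from platephen.plate_io import PlateLayout, read_absorbance_csv, write_absorbance_csv
from platephen.rosette import RosetteTimeSeries, rgr
from platephen.synthetic import (
    GrowthScenario,
    MTTScenario,
    SeedScanScenario,
    color_for_gli,
    generate_growth_images,
    generate_mtt_table,
    generate_seed_scan,
    imaging_times,
    plan_growth,
)

SMALL96 = PlateLayout(2, 3, (75.0, 75.0), 136.0, 67.0, "circle", "mini96")
SMALL48 = PlateLayout(1, 2, (72.0, 72.0), 132.0, 62.0, "circle", "mini48")


class TestSeedScan:
    def test_identical_seed_gives_bit_identical_output(self):
        a_img, a_man = generate_seed_scan(SeedScanScenario(rng_seed=5), SMALL96)
        b_img, b_man = generate_seed_scan(SeedScanScenario(rng_seed=5), SMALL96)
        assert np.array_equal(a_img.pixels, b_img.pixels)
        assert a_man == b_man

    def test_zero_seeds_gives_blank_plate(self):
        scn = SeedScanScenario(mean_seeds=0.0, sd_seeds=0.0, rng_seed=0)
        img, man = generate_seed_scan(scn, SMALL96)
        assert all(w["n_seeds"] == 0 for w in man["wells"].values())
        for well in SMALL96.labels():
            assert not seed_counter.segment_seeds(img, well).any()

    def test_without_clusters_all_objects_are_single_seeds(self):
        scn = SeedScanScenario(cluster_fraction=0.0, mean_seeds=12, sd_seeds=2, rng_seed=2)
        img, man = generate_seed_scan(scn, SMALL96)
        for well in SMALL96.labels():
            objs = seed_counter.measure_objects(seed_counter.segment_seeds(img, well))
            assert len(objs) == man["wells"][well]["n_seeds"]
            assert all(o.solidity >= 0.9 for o in objs)

    def test_oversized_seeds_rejected(self):
        scn = SeedScanScenario(seed_axes_px=(40.0, 30.0))
        with pytest.raises(ScenarioError):
            generate_seed_scan(scn, SMALL96)

    def test_manifest_counts_are_the_rendering_oracle(self):
        img, man = generate_seed_scan(SeedScanScenario(rng_seed=3), SMALL96)
        table, _ = seed_counter.count_plate(img, avg_seed_area_px=94.0)
        truth = np.array([man["wells"][w]["n_seeds"] for w in table["well"]])
        assert np.abs(table["seed_count"].to_numpy() - truth).mean() <= 1.0


class TestMTT:
    def test_noiseless_21_seeds_give_net_0399(self):
        # 21 seeds x 0.019 OD/seed: the cohort-mean worked example
        scn = MTTScenario(sd_seed=0.0, reader_noise_sd=0.0, baseline_sd=0.0, rng_seed=0)
        plate, man = generate_mtt_table(scn, {"A1": 21})
        assert plate.net["A1"] == pytest.approx(0.399, abs=1e-12)

    def test_no_germination_means_near_zero_per_seed_signal(self):
        scn = MTTScenario(germination_fraction=0.0, reader_noise_sd=0.0, rng_seed=1)
        plate, _ = generate_mtt_table(scn, {f"A{i}": 20 for i in range(1, 9)})
        per_seed = plate.net / 20
        assert np.abs(per_seed.to_numpy()).max() < 0.005

    def test_default_cohort_net_mean_within_ten_percent(self):
        rng = np.random.default_rng(4)
        counts = {f"W{i}": max(0, round(rng.normal(21, 5.4))) for i in range(96)}
        plate, _ = generate_mtt_table(MTTScenario(rng_seed=4), counts)
        assert plate.net.mean() == pytest.approx(0.399, rel=0.10)

    def test_manifest_signal_reconstructs_net_exactly(self):
        plate, man = generate_mtt_table(MTTScenario(rng_seed=6), {"A1": 10, "A2": 0})
        for well in ("A1", "A2"):
            expect = man["wells"][well]["true_signal"] + man["wells"][well]["reader_noise"]
            assert plate.net[well] == pytest.approx(expect, abs=1e-12)

    def test_generated_table_round_trips_through_the_reader(self, tmp_path):
        plate, _ = generate_mtt_table(MTTScenario(rng_seed=7), {"A1": 5, "B2": 8})
        for dialect in ("long",):
            path = tmp_path / f"{dialect}.csv"
            write_absorbance_csv(plate, path, dialect=dialect)
            again = read_absorbance_csv(path)
            assert np.abs((again.net - plate.net).to_numpy()).max() < 1e-9


class TestGrowth:
    def test_zero_rate_noiseless_frames_identical_and_rgr_zero(self):
        scn = GrowthScenario(rate_day_per_h=0.0, rate_night_per_h=0.0,
                             a0_noise_sd=0, rate_noise_sd=0, image_noise_sd=0,
                             mortality={"control": 0.0}, rng_seed=0)
        frames, plan = generate_growth_images(scn, SMALL48)
        assert len(frames) == 14
        assert all(np.array_equal(frames[0].pixels, f.pixels) for f in frames[1:])
        areas = plan["plants"]["A1"]["areas"]
        assert len(set(areas)) == 1
        rec = rgr(RosetteTimeSeries("A1", list(zip(plan["times_h"], areas))))
        assert np.all(rec.interval_rgr == 0.0)

    def test_rendered_pixel_count_matches_planned_area_exactly(self):
        scn = GrowthScenario(a0_noise_sd=0, rate_noise_sd=0, image_noise_sd=0,
                             mortality={"control": 0.0}, rng_seed=1)
        frames, plan = generate_growth_images(scn, SMALL48)
        from platephen.rosette import segment_rosette

        for i in (0, 7, 13):
            for well in SMALL48.labels():
                seg = segment_rosette(frames[i], well)
                assert seg.green_area_px == plan["plants"][well]["areas"][i]

    def test_stress_suppression_halves_final_area(self):
        from platephen.plate_io import Treatment

        factor = 0.5
        treatments = {"A1": Treatment("none", 0.0, "control"),
                      "A2": Treatment("none", 0.0, "NaCl150")}
        scn = GrowthScenario(treatments=treatments, a0_noise_sd=0, rate_noise_sd=0,
                             stress_rate_factor={"control": 1.0, "NaCl150": factor},
                             mortality={}, rng_seed=2)
        plan = plan_growth(scn, SMALL48)
        a_ctrl = plan["plants"]["A1"]["areas_exact"]
        a_str = plan["plants"]["A2"]["areas_exact"]
        # suppressing the rate by half halves the log-growth
        ratio = np.log(a_str[-1] / a_str[0]) / np.log(a_ctrl[-1] / a_ctrl[0])
        assert ratio == pytest.approx(factor, abs=0.05)

    def test_mortality_produces_dead_series(self):
        scn = GrowthScenario(mortality={"control": 1.0}, death_window_h=(30.0, 60.0),
                             a0_noise_sd=0, rate_noise_sd=0, rng_seed=3)
        frames, plan = generate_growth_images(scn, SMALL48)
        from platephen.pipeline import analyze_growth_plate

        growth_df, idx_df = analyze_growth_plate(frames)
        assert (growth_df["status"] == "dead").all()
        assert idx_df.empty  # no alive plant reaches day 7

    def test_oversized_blob_rejected(self):
        scn = GrowthScenario(a0_px=50000.0, a0_noise_sd=0, rate_noise_sd=0,
                             mortality={"control": 0.0}, rng_seed=0)
        with pytest.raises(ScenarioError):
            generate_growth_images(scn, SMALL48)

    def test_schedule_is_twice_daily_for_seven_days(self):
        t = imaging_times()
        assert len(t) == 14
        assert np.allclose(np.diff(t)[::2], 6.0) and np.allclose(np.diff(t)[1::2], 18.0)


class TestColorForGli:
    def test_solved_colors_hit_their_targets(self):
        from platephen.color_indices import pixel_indices

        for target in (0.2, 0.35, 0.5, 0.65):
            r, g, b = color_for_gli(target)
            assert float(pixel_indices(r, g, b)[1]) == pytest.approx(target, abs=1e-6)

    def test_unreachable_target_rejected(self):
        with pytest.raises(ScenarioError):
            color_for_gli(0.95)
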