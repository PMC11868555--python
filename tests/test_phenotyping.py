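"""Tests of the plate-reader analysis: IO, preprocessing, growth rates,
diauxie detection, yields and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from maldiauxie import (
    CalibrationCurve,
    CultureConfig,
    DetectionConfig,
    GrowthCurve,
    NoiseModel,
    SmootherConfig,
    compare_growth_rates,
    detect_diauxie,
    estimate_growth_rate,
    find_exponential_phase,
    fluorescence_per_od,
    make_mixture_design,
    preprocess,
    read_plate_table,
    regress_phase_yields,
    simulate_plate,
)
from maldiauxie.phenotyping import average_technical_replicates, phenotype_plate


def _exponential_curve(rate=0.3, od0=0.05, t_end=10.0, n=61, well="X1"):
    t = np.linspace(0.0, t_end, n)
    return GrowthCurve(well, t, od0 * np.exp(rate * t))


class TestPlateIO:
    def test_four_well_fixture(self, tmp_path):
        t = np.round(np.arange(0, 5, 0.25), 3)
        rows = []
        for well in ("A1", "A2", "A3", "B1"):
            for tt in t:
                rows.append({"well": well, "time_h": tt, "od": 0.1 + 0.01 * tt})
        pd.DataFrame(rows).to_csv(tmp_path / "data.csv", index=False)
        layout = pd.DataFrame(
            {
                "well": ["A1", "A2", "A3", "B1"],
                "strain": ["WT"] * 3 + ["blank"],
                "sugar_1": ["galactose"] * 4,
                "conc_1": [0.5] * 4,
                "sugar_2": ["palatinose"] * 4,
                "conc_2": [0.5] * 4,
                "role": ["sample"] * 3 + ["blank"],
            }
        )
        layout.to_csv(tmp_path / "layout.csv", index=False)
        plate = read_plate_table(tmp_path / "data.csv", tmp_path / "layout.csv")
        assert len(plate.samples) == 3
        assert sum(len(v) for v in plate.blanks.values()) == 1

    def test_round_trip_preserves_layout_metadata(self, rendered_plate_files):
        paths, rendered = rendered_plate_files
        plate = read_plate_table(paths["plate"], paths["layout"])
        meta = {c.well: c.meta for c in plate.samples}
        for _, row in rendered.layout.iterrows():
            if row["role"] != "sample":
                continue
            m = meta[row["well"]]
            assert m["strain"] == row["strain"]
            assert m["conc_1"] == pytest.approx(row["conc_1"])
            assert m["conc_2"] == pytest.approx(row["conc_2"])

    def test_layout_well_absent_from_data_is_an_error(self, tmp_path):
        pd.DataFrame({"well": ["A1"] * 3, "time_h": [0, 1, 2], "od": [0.1] * 3}).to_csv(
            tmp_path / "d.csv", index=False
        )
        pd.DataFrame(
            {
                "well": ["A1", "Z9"],
                "strain": ["WT", "WT"],
                "sugar_1": ["g", "g"],
                "conc_1": [1, 1],
                "sugar_2": ["p", "p"],
                "conc_2": [1, 1],
                "role": ["sample", "sample"],
            }
        ).to_csv(tmp_path / "l.csv", index=False)
        with pytest.raises(ValueError, match="Z9"):
            read_plate_table(tmp_path / "d.csv", tmp_path / "l.csv")


class TestPreprocess:
    def test_identity_calibration_zero_blank_unchanged(self):
        curve = _exponential_curve()
        blank = GrowthCurve("B1", curve.time, np.zeros_like(curve.time))
        out = preprocess(curve, [blank], CalibrationCurve.identity())
        assert np.allclose(out.od, curve.od, atol=1e-9)

    def test_saturation_round_trip_noise_free(self):
        noise = NoiseModel(multiplicative_sd=0, additive_sd=0, fluor_additive_sd=0)
        layout = make_mixture_design([0.4], [0.5], 1, blanks=1)
        plate = simulate_plate(layout, CultureConfig(), noise, seed=0)
        tab = plate.calibration
        cal = CalibrationCurve(tab["measured"].to_numpy(), tab["corrected"].to_numpy())
        well = layout.samples.iloc[0]["well"]
        sub = plate.plate[plate.plate.well == well]
        truth = plate.truth[plate.truth.well == well]["B"].to_numpy()
        curve = GrowthCurve(well, sub["time_h"].to_numpy(), sub["od"].to_numpy())
        blank_well = layout.blanks.iloc[0]["well"]
        bsub = plate.plate[plate.plate.well == blank_well]
        blank = GrowthCurve(blank_well, bsub["time_h"].to_numpy(), bsub["od"].to_numpy())
        out = preprocess(curve, [blank], cal)
        mask = truth > 1e-3
        assert np.allclose(out.od[mask], truth[mask], atol=1e-6)

    def test_missing_blank_warns_and_keeps_curve(self):
        curve = _exponential_curve()
        with pytest.warns(UserWarning, match="no blank"):
            out = preprocess(curve, [], None)
        assert np.allclose(out.od, curve.od)

    def test_identical_replicates_average_with_zero_sd(self):
        a = _exponential_curve(well="A1")
        b = _exponential_curve(well="A1")
        avg = average_technical_replicates([a, b])
        assert np.allclose(avg.od, a.od)
        assert np.allclose(avg.meta["od_sd"], 0.0)


class TestGrowthRate:
    def test_pure_exponential_recovered(self):
        est = estimate_growth_rate(_exponential_curve(rate=0.3))
        n = len(est.time)
        inner = slice(n // 10, n - n // 10)
        assert np.max(np.abs(est.mu[inner] - 0.3)) < 1e-3
        assert np.all(est.band >= 0)

    def test_rate_sweep_recovery(self):
        for rate in (0.1, 0.2, 0.3, 0.4, 0.5):
            est = estimate_growth_rate(_exponential_curve(rate=rate))
            n = len(est.time)
            inner = slice(n // 10, n - n // 10)
            assert np.max(np.abs(est.mu[inner] - rate)) < 1e-2

    def test_gp_smoother_agrees_on_clean_exponential(self):
        est = estimate_growth_rate(_exponential_curve(rate=0.3), SmootherConfig(method="gp"))
        n = len(est.time)
        inner = slice(n // 5, n - n // 5)
        assert np.max(np.abs(est.mu[inner] - 0.3)) < 1e-2

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="20"):
            estimate_growth_rate(_exponential_curve(n=10))

    def test_nonpositive_od_rejected(self):
        t = np.linspace(0, 10, 30)
        with pytest.raises(ValueError):
            estimate_growth_rate(GrowthCurve("X", t, np.linspace(-0.1, 1.0, 30)))

    def test_two_peaks_of_diauxic_curve_within_tolerance(self):
        cfg = CultureConfig()  # phase rates 0.25 and 0.12 per hour
        layout = make_mixture_design([0.5], [0.5], 1, blanks=1)
        noise = NoiseModel(multiplicative_sd=0, additive_sd=0, background_od=0, saturation_a=0)
        plate = simulate_plate(layout, cfg, noise, seed=0)
        well = layout.samples.iloc[0]["well"]
        sub = plate.plate[plate.plate.well == well]
        curve = GrowthCurve(well, sub["time_h"].to_numpy(), np.maximum(sub["od"].to_numpy(), 1e-4))
        est = estimate_growth_rate(curve)
        ph = detect_diauxie(curve, est)
        assert ph.is_diauxic
        assert abs(ph.peak_mus[0] - 0.25) < 0.02
        assert abs(ph.peak_mus[1] - 0.12) < 0.02


class TestDiauxieDetection:
    def test_single_phase_logistic_not_diauxic(self):
        t = np.linspace(0, 24, 145)
        od = 1.0 / (1.0 + np.exp(-0.5 * (t - 10.0))) + 0.01
        curve = GrowthCurve("L1", t, od)
        ph = detect_diauxie(curve, estimate_growth_rate(curve))
        assert not ph.is_diauxic
        assert ph.od2 == 0.0
        assert ph.od1 == pytest.approx(od[-1] - od[0])

    def test_phase_one_yield_tracks_sugar_one(self):
        noise = NoiseModel(multiplicative_sd=0, additive_sd=0, background_od=0, saturation_a=0)
        for s10 in (0.3, 0.6):
            cfg = CultureConfig()
            layout = make_mixture_design([s10], [0.5], 1, blanks=1)
            plate = simulate_plate(layout, cfg, noise, seed=0)
            well = layout.samples.iloc[0]["well"]
            sub = plate.plate[plate.plate.well == well]
            curve = GrowthCurve(well, sub["time_h"].to_numpy(), np.maximum(sub["od"].to_numpy(), 1e-4))
            ph = detect_diauxie(curve, estimate_growth_rate(curve))
            truth = cfg.sugar1.Y * s10
            assert ph.is_diauxic
            assert abs(ph.od1 - truth) < 0.05 * truth

    def test_yield_additivity_exact(self, rendered_plate_files):
        paths, _ = rendered_plate_files
        plate = read_plate_table(paths["plate"], paths["layout"])
        cal = CalibrationCurve.from_table(paths["calibration"])
        for raw in plate.samples:
            pre = preprocess(raw, plate.blanks_for(raw), cal)
            ph = detect_diauxie(pre, estimate_growth_rate(pre))
            assert ph.od1 + ph.od2 == pytest.approx(pre.od[-1] - pre.od[0], abs=1e-12)

    def test_no_growth_phenotype(self):
        t = np.linspace(0, 24, 60)
        od = np.full_like(t, 0.05)
        curve = GrowthCurve("N1", t, od)
        ph = detect_diauxie(curve, estimate_growth_rate(curve))
        assert ph.no_growth and not ph.is_diauxic


class TestInvariances:
    def test_time_shift_and_od_scale_invariance(self):
        cfg = CultureConfig()
        noise = NoiseModel(multiplicative_sd=0, additive_sd=0, background_od=0, saturation_a=0)
        layout = make_mixture_design([0.5], [0.5], 1, blanks=1)
        plate = simulate_plate(layout, cfg, noise, seed=0)
        well = layout.samples.iloc[0]["well"]
        sub = plate.plate[plate.plate.well == well]
        t = sub["time_h"].to_numpy()
        od = np.maximum(sub["od"].to_numpy(), 1e-4)
        base = detect_diauxie(*(lambda c: (c, estimate_growth_rate(c)))(GrowthCurve("w", t, od)))
        shifted = detect_diauxie(
            *(lambda c: (c, estimate_growth_rate(c)))(GrowthCurve("w", t + 5.0, od))
        )
        scaled = detect_diauxie(
            *(lambda c: (c, estimate_growth_rate(c)))(GrowthCurve("w", t, 3.0 * od))
        )
        assert base.is_diauxic == shifted.is_diauxic == scaled.is_diauxic
        assert shifted.t_switch == pytest.approx(base.t_switch + 5.0, abs=1e-6)
        assert scaled.od1 == pytest.approx(3.0 * base.od1, rel=1e-9)
        assert scaled.od2 == pytest.approx(3.0 * base.od2, rel=1e-9)


class TestExponentialPhase:
    def test_pure_exponential_window_and_rate(self):
        curve = _exponential_curve(rate=0.3)
        est = estimate_growth_rate(curve)
        phase = find_exponential_phase(est, curve)
        assert phase.mu_midlog == pytest.approx(0.3, abs=1e-3)
        assert phase.lag == pytest.approx(0.0, abs=0.5)

    def test_inserted_lag_recovered(self):
        noise = NoiseModel(multiplicative_sd=0, additive_sd=0, background_od=0, saturation_a=0)
        from maldiauxie import SugarSpec

        cfg = CultureConfig(sugar2=SugarSpec("palatinose", 0.0, 0.12), initial_lag_h=3.0)
        layout = make_mixture_design([0.5], [0.0], 1, blanks=1)
        plate = simulate_plate(layout, cfg, noise, seed=0)
        well = layout.samples.iloc[0]["well"]
        sub = plate.plate[plate.plate.well == well]
        curve = GrowthCurve(well, sub["time_h"].to_numpy(), np.maximum(sub["od"].to_numpy(), 1e-4))
        est = estimate_growth_rate(curve)
        phase = find_exponential_phase(est, curve)
        assert abs(phase.lag - 3.0) < 0.5

    def test_lag_ordering_preserved(self):
        noise = NoiseModel()
        lags = {}
        for L in (1.0, 3.0):
            cfg = CultureConfig(initial_lag_h=L)
            layout = make_mixture_design([0.5], [0.5], 1, blanks=1)
            plate = simulate_plate(layout, cfg, noise, seed=4)
            paths_well = layout.samples.iloc[0]["well"]
            sub = plate.plate[plate.plate.well == paths_well]
            bwell = layout.blanks.iloc[0]["well"]
            bsub = plate.plate[plate.plate.well == bwell]
            cal = CalibrationCurve(
                plate.calibration["measured"].to_numpy(), plate.calibration["corrected"].to_numpy()
            )
            curve = preprocess(
                GrowthCurve(paths_well, sub["time_h"].to_numpy(), sub["od"].to_numpy()),
                [GrowthCurve(bwell, bsub["time_h"].to_numpy(), bsub["od"].to_numpy())],
                cal,
            )
            est = estimate_growth_rate(curve)
            lags[L] = find_exponential_phase(est, curve).lag
        assert lags[1.0] < lags[3.0]


class TestYieldRegression:
    def test_exact_points(self):
        from maldiauxie.phenotyping import DiauxiePhenotype

        phens = []
        for i, (c, y) in enumerate([(0.1, 0.1), (0.2, 0.2), (0.4, 0.4)]):
            phens.append(
                DiauxiePhenotype(
                    well=f"W{i}", is_diauxic=True, t_switch=1.0, od_switch=y, od1=y, od2=0.0,
                    peak_mus=(0.2, 0.1), lag=1.0, mu_midlog=0.2,
                    meta={"sugar_1": "galactose", "conc_1": c, "sugar_2": "palatinose", "conc_2": 0.5},
                )
            )
        reg = regress_phase_yields(phens, phase=1, sugar="galactose")
        assert reg.slope == pytest.approx(1.0, abs=1e-10)
        assert reg.intercept == pytest.approx(0.0, abs=1e-10)
        assert reg.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_fewer_than_three_concentrations_rejected(self):
        from maldiauxie.phenotyping import DiauxiePhenotype

        phens = [
            DiauxiePhenotype(
                well=f"W{i}", is_diauxic=True, t_switch=1.0, od_switch=0.1, od1=0.1, od2=0.0,
                peak_mus=(), lag=0.0, mu_midlog=0.1,
                meta={"sugar_1": "g", "conc_1": 0.1, "sugar_2": "p", "conc_2": 0.5},
            )
            for i in range(4)
        ]
        with pytest.raises(ValueError, match="3 distinct"):
            regress_phase_yields(phens, phase=1, sugar="g")

    def test_synthetic_gradient_recovers_unit_yield(self, rendered_plate_files):
        paths, _ = rendered_plate_files
        plate = read_plate_table(paths["plate"], paths["layout"])
        cal = CalibrationCurve.from_table(paths["calibration"])
        _, phens = phenotype_plate(plate, cal)
        reg = regress_phase_yields(phens, phase=1, sugar="galactose")
        assert reg.r_squared > 0.9
        assert reg.slope == pytest.approx(1.0, abs=0.15)

    def test_shuffled_labels_destroy_correlation(self, rendered_plate_files):
        paths, _ = rendered_plate_files
        plate = read_plate_table(paths["plate"], paths["layout"])
        cal = CalibrationCurve.from_table(paths["calibration"])
        _, phens = phenotype_plate(plate, cal)
        rng = np.random.default_rng(0)
        r2 = []
        for _ in range(100):
            concs = [ph.meta["conc_1"] for ph in phens]
            rng.shuffle(concs)
            shuffled = []
            for ph, c in zip(phens, concs):
                q = type(ph)(**{**ph.__dict__, "meta": {**ph.meta, "conc_1": c}})
                shuffled.append(q)
            r2.append(regress_phase_yields(shuffled, phase=1, sugar="galactose").r_squared)
        assert np.median(r2) < 0.2


class TestFluorescence:
    def test_proportional_channel_gives_constant_ratio(self):
        curve = _exponential_curve()
        curve = GrowthCurve(curve.well, curve.time, curve.od, fluorescence=2.0 * curve.od)
        out = fluorescence_per_od(curve)
        assert np.allclose(out["fluor_per_od"], 2.0)

    def test_zero_fluorescence_gives_zero(self):
        curve = _exponential_curve()
        curve = GrowthCurve(curve.well, curve.time, curve.od, fluorescence=np.zeros_like(curve.od))
        assert np.allclose(fluorescence_per_od(curve)["fluor_per_od"], 0.0)

    def test_missing_channel_is_an_error(self):
        with pytest.raises(ValueError, match="fluorescence"):
            fluorescence_per_od(_exponential_curve())

    def test_reporter_signal_rises_only_after_switch(self):
        cfg = CultureConfig(reporter=True)
        layout = make_mixture_design([0.5], [0.5], 1, blanks=1)
        plate = simulate_plate(layout, cfg, NoiseModel(), seed=2)
        well = layout.samples.iloc[0]["well"]
        sub = plate.plate[plate.plate.well == well]
        bwell = layout.blanks.iloc[0]["well"]
        bsub = plate.plate[plate.plate.well == bwell]
        cal = CalibrationCurve(
            plate.calibration["measured"].to_numpy(), plate.calibration["corrected"].to_numpy()
        )
        curve = preprocess(
            GrowthCurve(
                well, sub["time_h"].to_numpy(), sub["od"].to_numpy(),
                fluorescence=sub["fluor_gfp"].to_numpy(),
            ),
            [GrowthCurve(bwell, bsub["time_h"].to_numpy(), bsub["od"].to_numpy(),
                         fluorescence=bsub["fluor_gfp"].to_numpy())],
            cal,
        )
        est = estimate_growth_rate(curve)
        ph = detect_diauxie(curve, est)
        out = fluorescence_per_od(curve)
        before = out[out.time_h < ph.t_switch - 1.0]["fluor_per_od"]
        after = out[out.time_h > ph.t_switch + 5.0]["fluor_per_od"]
        assert after.mean() > 5 * max(before.abs().mean(), 1.0)


class TestGroupComparison:
    def test_identical_groups(self):
        res = compare_growth_rates([0.30, 0.31, 0.29], [0.30, 0.31, 0.29])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_closed_form_welch(self):
        a = np.array([0.30, 0.31, 0.29])
        b = np.array([0.35, 0.36, 0.34])
        res = compare_growth_rates(a, b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = np.sqrt(va / 3 + vb / 3)
        t_oracle = (a.mean() - b.mean()) / se
        df = (va / 3 + vb / 3) ** 2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
        p_oracle = 2 * stats.t.sf(abs(t_oracle), df)
        assert res.statistic == pytest.approx(t_oracle, abs=1e-10)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_order_swap_negates_statistic(self):
        a, b = [0.30, 0.31, 0.29], [0.35, 0.36, 0.34]
        r1, r2 = compare_growth_rates(a, b), compare_growth_rates(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            compare_growth_rates([0.3], [0.3, 0.4])
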