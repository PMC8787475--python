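"""Spot quantification, competition inversion, logistic fits, variance split."""

import numpy as np
import pandas as pd
import pytest

from phyllodyn import growth as gr
from phyllodyn import synthetic_data as sd
from phyllodyn.synthetic_data import PlantedEffects


def _series_from_curve(Y, k, t_mid, times=(7.0, 13.0, 24.0), spot="s1"):
    rows = [
        {"spot": spot, "isolate": "i1", "treatment": "P20M20", "replicate": 1,
         "occupied": True, "time": t,
         "intensity": float(sd.logistic_intensity(t, Y, k, t_mid))}
        for t in times
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def flat_bundle():
    layout = sd.make_plate_layout(n_isolates=3, treatments=("P20M20",),
                                  n_replicates=4, seed=0)
    eff = PlantedEffects(growth={"competition": 0.0, "background": 0.0, "noise": 0.0})
    images, truth = sd.simulate_plate_images(eff, layout, seed=1)
    return layout, images, truth


class TestQuantifySpots:
    def test_noiseless_flat_background_recovers_truth(self, flat_bundle):
        layout, images, truth = flat_bundle
        series = gr.quantify_spots(images, layout, background="none")
        m = series[series["time"] == 24.0].merge(
            truth.reset_index()[["spot", "I_true_t24"]], on="spot"
        )
        err = (m["intensity"] - m["I_true_t24"]).abs() / m["I_true_t24"]
        assert err.max() < 1e-3

    def test_planted_polynomial_background_corrected(self):
        """With a strong smooth background, correction brings spot errors
        below 2% where the uncorrected readings are far off."""
        layout = sd.make_plate_layout(n_isolates=3, treatments=("P20M20",),
                                      n_replicates=4, seed=0)
        eff = PlantedEffects(growth={"competition": 0.0, "background": 2.0, "noise": 0.0})
        images, truth = sd.simulate_plate_images(eff, layout, seed=1)
        corrected = gr.quantify_spots(images, layout)
        uncorrected = gr.quantify_spots(images, layout, background="none")
        ref = truth.reset_index()[["spot", "I_true_t24"]]
        c = corrected[corrected["time"] == 24.0].merge(ref, on="spot")
        u = uncorrected[uncorrected["time"] == 24.0].merge(ref, on="spot")
        cerr = ((c["intensity"] - c["I_true_t24"]).abs() / c["I_true_t24"]).median()
        uerr = ((u["intensity"] - u["I_true_t24"]).abs() / u["I_true_t24"]).median()
        assert cerr < 0.02
        assert uerr > 0.10

    def test_empty_plate_near_zero(self):
        layout = sd.make_plate_layout(n_isolates=1, treatments=("P20M20",),
                                      n_replicates=1, seed=0)
        layout["occupied"] = False
        eff = PlantedEffects(growth={"background": 0.3, "noise": 0.0})
        images, _ = sd.simulate_plate_images(eff, layout, seed=1)
        series = gr.quantify_spots(images, layout)
        assert (series["intensity"].abs() < 1e-6 * max(1.0, series["raw"].abs().max())).all()

    def test_spot_outside_image_rejected(self, flat_bundle):
        layout, images, _ = flat_bundle
        bad = layout.copy()
        bad.loc[bad.index[0], "cx"] = -5
        with pytest.raises(ValueError, match="outside"):
            gr.quantify_spots(images, bad)


class TestCompetitionCorrect:
    def _bundle(self, c, seed=0):
        layout = sd.make_plate_layout(n_isolates=4, treatments=("P20M20",),
                                      n_replicates=5, seed=seed)
        eff = PlantedEffects(growth={"competition": c, "background": 0.0, "noise": 0.0})
        images, truth = sd.simulate_plate_images(eff, layout, seed=seed + 1)
        series = gr.quantify_spots(images, layout, background="none")
        return layout, truth, series

    def test_zero_competition_identity(self):
        layout, truth, series = self._bundle(0.0)
        corrected, c_est = gr.competition_correct(series, layout)
        rel = (corrected["intensity"] - corrected["intensity_obs"]).abs() / corrected[
            "intensity_obs"
        ].clip(lower=1e-9)
        assert rel[corrected["occupied"]].max() < 0.01

    def test_isolated_spot_unchanged_for_given_c(self):
        layout = sd.make_plate_layout(n_isolates=1, treatments=("P20M20",),
                                      n_replicates=1, seed=0)
        eff = PlantedEffects(growth={"competition": 0.05, "background": 0.0, "noise": 0.0})
        images, _ = sd.simulate_plate_images(eff, layout, seed=1)
        series = gr.quantify_spots(images, layout, background="none")
        corrected, _ = gr.competition_correct(series, layout, c=0.05)
        occ = corrected[corrected["occupied"]]
        assert np.allclose(occ["intensity"], occ["intensity_obs"])

    def test_inverse_recovery_of_planted_suppression(self):
        """Noise-free generator at c=0.05: the correction is an exact inverse
        and the estimated c lands on the planted value."""
        layout, truth, series = self._bundle(0.05)
        corrected, c_est = gr.competition_correct(series, layout)
        assert c_est == pytest.approx(0.05, abs=0.002)
        m = corrected[corrected["time"] == 24.0].merge(
            truth.reset_index()[["spot", "I_true_t24"]], on="spot"
        )
        rel = (m["intensity"] - m["I_true_t24"]).abs() / m["I_true_t24"]
        assert rel.max() < 0.01
        raw_rel = (m["intensity_obs"] - m["I_true_t24"]).abs() / m["I_true_t24"]
        assert rel.median() < raw_rel.median()

    def test_unreplicated_layout_skips_with_warning(self, caplog):
        layout = sd.make_plate_layout(n_isolates=36, treatments=("P20M20",),
                                      n_replicates=1, seed=0)
        eff = PlantedEffects(growth={"competition": 0.05, "background": 0.0, "noise": 0.0})
        images, _ = sd.simulate_plate_images(eff, layout, seed=1)
        series = gr.quantify_spots(images, layout, background="none")
        with caplog.at_level("WARNING"):
            corrected, c_est = gr.competition_correct(series, layout)
        assert c_est == 0.0
        assert "unidentifiable" in caplog.text


class TestFitGrowth:
    def test_exact_curve_recovered_with_closed_form_rate(self):
        """Exact logistic values at days 0, 7, 13, 24 refit to the planted
        parameters, with the rate from the closed-form time-to-yield."""
        Y, k, t_mid = 10.0, 0.5, 8.0
        series = _series_from_curve(Y, k, t_mid, times=(0.0, 7.0, 13.0, 24.0))
        per_spot, per_iso = gr.fit_growth(series, origin_anchor=False)
        fit = per_spot.iloc[0]
        assert fit["Y"] == pytest.approx(Y, abs=1e-3)
        assert fit["k"] == pytest.approx(k, abs=1e-3)
        assert fit["t_mid"] == pytest.approx(t_mid, abs=1e-3)
        assert fit["r"] == pytest.approx(1 / (8 + np.log(19) / 0.5), rel=1e-3)
        assert per_iso.iloc[0]["Y"] == pytest.approx(Y, abs=1e-3)

    def test_all_zero_series_yields_no_rate(self):
        series = _series_from_curve(10.0, 0.5, 8.0)
        series["intensity"] = 0.0
        per_spot, _ = gr.fit_growth(series)
        assert per_spot.iloc[0]["Y"] == 0.0
        assert np.isnan(per_spot.iloc[0]["r"])

    def test_intensity_units_scale_yield_not_rate(self):
        s1 = _series_from_curve(5.0, 0.6, 9.0)
        s2 = s1.copy()
        s2["intensity"] *= 2
        f1, _ = gr.fit_growth(s1)
        f2, _ = gr.fit_growth(s2)
        assert f2.iloc[0]["Y"] == pytest.approx(2 * f1.iloc[0]["Y"], rel=1e-6)
        assert f2.iloc[0]["r"] == pytest.approx(f1.iloc[0]["r"], rel=1e-6)

    def test_replicates_averaged_per_isolate(self):
        times = (0.0, 7.0, 13.0, 24.0)
        a = _series_from_curve(10.0, 0.5, 8.0, times=times, spot="s1")
        b = _series_from_curve(20.0, 0.5, 8.0, times=times, spot="s2")
        b["replicate"] = 2
        per_spot, per_iso = gr.fit_growth(pd.concat([a, b], ignore_index=True),
                                          origin_anchor=False)
        assert len(per_iso) == 1
        assert per_iso.iloc[0]["Y"] == pytest.approx(15.0, rel=1e-3)


class TestGrowthAnova:
    def _fixture_12(self):
        """Balanced 2x2 with 3 replicates; hand-computable sums of squares."""
        rows = []
        means = {("a", "x"): 1.0, ("a", "y"): 2.0, ("b", "x"): 3.0, ("b", "y"): 6.0}
        offsets = [-0.1, 0.0, 0.1]
        i = 0
        for (f, h), mu in means.items():
            for off in offsets:
                rows.append({"isolate": f"i{i}", "treatment": "P20M20",
                             "Y": np.exp(mu + off), "r": np.exp(mu + off)})
                i += 1
        fits = pd.DataFrame(rows)
        iso = pd.DataFrame(
            {"isolate": [f"i{j}" for j in range(12)],
             "F": ["a"] * 6 + ["b"] * 6,
             "H": (["x"] * 3 + ["y"] * 3) * 2}
        )
        return fits, iso

    def test_fractions_match_hand_two_factor_anova(self):
        fits, iso = self._fixture_12()
        tables = gr.growth_anova(fits, iso, terms=["F", "H", "F:H"])
        y = np.log(fits["Y"].to_numpy())
        grand = y.mean()
        ss_total = ((y - grand) ** 2).sum()
        # hand values: F means 1.5 vs 4.5; H means 2 vs 4; interaction 2x2
        ss_f = 6 * (1.5 - 3.0) ** 2 + 6 * (4.5 - 3.0) ** 2
        ss_h = 6 * (2.0 - 3.0) ** 2 + 6 * (4.0 - 3.0) ** 2
        cell_means = [1.0, 2.0, 3.0, 6.0]
        ss_cells = 3 * sum((m - 3.0) ** 2 for m in cell_means)
        ss_int = ss_cells - ss_f - ss_h
        tab = tables["Y"]
        assert tab.loc["F", "SS"] == pytest.approx(ss_f, abs=1e-9)
        assert tab.loc["H", "SS"] == pytest.approx(ss_h, abs=1e-9)
        assert tab.loc["F:H", "SS"] == pytest.approx(ss_int, abs=1e-9)
        assert tab["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_fits_all_zero_fractions(self):
        fits, iso = self._fixture_12()
        fits["Y"] = 5.0
        fits["r"] = 0.1
        tables = gr.growth_anova(fits, iso, terms=["F", "H"])
        assert tables["Y"].loc[["F", "H"], "fraction"].sum() == pytest.approx(0.0, abs=1e-12)
        assert tables["Y"].loc["Residual", "fraction"] == pytest.approx(1.0)

    def test_planted_clade_effect_fraction_recovered(self):
        """A clade shift explaining ~30% of log-Y variance is recovered
        within a few points of the planted fraction."""
        rng = np.random.default_rng(0)
        n_iso = 80
        clades = rng.choice(["A", "B", "C", "D"], size=n_iso)
        shift = {"A": 0.0, "B": 0.0, "C": 0.0, "D": 1.17}
        fracs = []
        for rep in range(20):
            logy = np.array([shift[c] for c in clades]) + rng.normal(0, 0.7, n_iso)
            fits = pd.DataFrame({"isolate": [f"i{j}" for j in range(n_iso)],
                                 "treatment": "P20M20",
                                 "Y": np.exp(logy), "r": np.exp(logy)})
            iso = pd.DataFrame({"isolate": fits["isolate"], "C": clades,
                                "F": rng.choice(["MSH", "SBL"], n_iso)})
            tab = gr.growth_anova(fits, iso, terms=["F", "C"], pool_other=False)["Y"]
            fracs.append(tab.loc["C", "fraction"])
        planted = np.var([shift[c] for c in clades]) / (
            np.var([shift[c] for c in clades]) + 0.49
        )
        assert abs(np.mean(fracs) - planted) < 0.05

    def test_missing_metadata_column_rejected(self):
        fits, iso = self._fixture_12()
        with pytest.raises(KeyError, match="C"):
            gr.growth_anova(fits, iso, terms=["F", "C"])


class TestSummarizeGrowth:
    def test_single_member_groups(self):
        fits = pd.DataFrame({"isolate": ["i1", "i2"], "treatment": ["P20M20"] * 2,
                             "Y": [4.0, 8.0], "r": [0.1, 0.2]})
        iso = pd.DataFrame({"isolate": ["i1", "i2"], "C": ["A", "B"]})
        out = gr.summarize_growth(fits, iso, grouping="C")
        assert out.loc["A", "Y_mean"] == 4.0
        assert np.isnan(out.loc["A", "Y_std"])

    def test_hand_means_two_groups(self):
        fits = pd.DataFrame({"isolate": ["i1", "i2", "i3", "i4"],
                             "treatment": ["P20M20"] * 4,
                             "Y": [4.0, 6.0, 10.0, 14.0], "r": [0.1, 0.2, 0.3, 0.5]})
        iso = pd.DataFrame({"isolate": fits["isolate"], "C": ["A", "A", "B", "B"]})
        out = gr.summarize_growth(fits, iso, grouping="C")
        assert out.loc["A", "Y_mean"] == pytest.approx(5.0)
        assert out.loc["B", "Y_mean"] == pytest.approx(12.0)
        assert out.loc["B", "r_mean"] == pytest.approx(0.4)

    def test_monitoring_temperature_grouping_from_treatment(self):
        fits = pd.DataFrame({"isolate": ["i1"] * 2, "treatment": ["P20M20", "P20M30"],
                             "Y": [8.0, 5.0], "r": [0.08, 0.1]})
        out = gr.summarize_growth(fits, grouping="T_M")
        assert out.loc["20", "Y_mean"] == 8.0
        assert out.loc["30", "Y_mean"] == 5.0


def test_load_growth_table_roundtrip(tmp_path):
    df = pd.DataFrame({"isolate": ["i1", "i2"], "T_P": [20, 30], "T_M": [30, 30],
                       "Y": [5.0, 9.0], "r": [0.1, 0.08], "C": ["A", "B"]})
    path = tmp_path / "growth.tsv"
    df.to_csv(path, sep="\t", index=False)
    out = gr.load_growth_table(path)
    assert list(out["treatment"]) == ["P20M30", "P30M30"]


def test_load_growth_table_missing_columns(tmp_path):
    path = tmp_path / "bad.tsv"
    pd.DataFrame({"isolate": ["i1"]}).to_csv(path, sep="\t", index=False)
    with pytest.raises(ValueError, match="missing"):
        gr.load_growth_table(path)
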