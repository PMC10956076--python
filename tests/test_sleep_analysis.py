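import numpy as np
import pytest
from scipy import stats

from eitrack import (
    EISeries,
    Hypnogram,
    analysis_window,
    bandpass,
    dunn_test,
    kruskal_wallis,
    stage_average,
)
from eitrack.sleep_analysis import STAGES, map_stage


def make_hypnogram(labels, epoch_s=30.0, start=0.0):
    return Hypnogram(
        [(start + i * epoch_s, epoch_s, s) for i, s in enumerate(labels)]
    )


class TestBandpass:
    # the 6000-tap kernel spans 60 s at 100 Hz, so steady-state behavior
    # is probed on long signals with one kernel length trimmed per edge
    fs = 100.0
    mid = slice(8000, -8000)

    def sine(self, f, seconds=400.0):
        t = np.arange(int(seconds * self.fs)) / self.fs
        return np.sin(2 * np.pi * f * t)

    def test_passband_amplitude_preserved(self):
        # amplitude via sqrt(2)*RMS: at 10 samples per cycle the sample
        # grid never lands on the sine peak, so max() would read 0.951
        y = bandpass(self.sine(10.0), self.fs)
        amp = np.sqrt(2) * np.std(y[self.mid])
        assert amp == pytest.approx(1.0, rel=0.01)

    @pytest.mark.parametrize("f", [0.1, 30.0])
    def test_stopband_attenuated(self, f):
        y = bandpass(self.sine(f), self.fs)
        atten = 20 * np.log10(np.abs(y[self.mid]).max() / 1.0)
        assert atten < -20.0

    def test_zero_input_zero_output(self):
        y = bandpass(np.zeros(10_000), self.fs)
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_idempotent_in_passband(self):
        x = self.sine(10.0)
        once = bandpass(x, self.fs)
        twice = bandpass(once, self.fs)
        ratio = np.abs(twice[self.mid]).max() / np.abs(once[self.mid]).max()
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(1000), self.fs)


class TestHypnogram:
    def test_stage_mapping(self):
        assert map_stage("Sleep stage W") == "Awake"
        assert map_stage("Sleep stage 3") == "S3/4"
        assert map_stage("Sleep stage 4") == "S3/4"
        assert map_stage("Movement time") is None

    def test_sleep_onset_and_window(self):
        # onset at 3600 s, first REM run 7200-7800 s
        labels = (["Awake"] * 120 + ["S1"] * 20 + ["S2"] * 60 + ["S3/4"] * 40
                  + ["REM"] * 20 + ["S2"] * 10)
        hyp = make_hypnogram(labels)
        assert hyp.sleep_onset == 3600.0
        assert hyp.first_rem_run() == (7200.0, 7800.0)
        assert analysis_window(hyp) == (2400.0, 7800.0)

    def test_window_clamped_to_recording_start(self):
        hyp = make_hypnogram(["Awake"] * 10 + ["S2"] * 10 + ["REM"] * 5)
        # onset at 300 s < 1200 s
        assert analysis_window(hyp)[0] == 0.0

    def test_no_rem_is_an_error(self):
        hyp = make_hypnogram(["Awake", "S1", "S2"])
        with pytest.raises(ValueError):
            analysis_window(hyp)

    def test_interrupted_nrem_flagged(self):
        good = make_hypnogram(["Awake", "S1", "S2", "S3/4", "REM"])
        bad = make_hypnogram(["Awake", "S1", "Awake", "S2", "REM"])
        assert not good.has_interrupted_nrem()
        assert bad.has_interrupted_nrem()

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            Hypnogram([(0.0, 30.0, "Awake"), (10.0, 30.0, "S1")])


class TestStageAverage:
    def test_constant_index(self):
        hyp = make_hypnogram(["Awake", "S1", "S2", "S3/4", "REM"])
        t = np.arange(0, 150, 0.5)
        series = EISeries(t=t, value=np.full(t.size, 0.5), method="mei")
        summary = stage_average(series, hyp, window=(0.0, 150.0))
        assert np.allclose(summary.table["value"], 0.5)

    def test_rem_only_indicator(self):
        hyp = make_hypnogram(["Awake", "S1", "S2", "S3/4", "REM"])
        t = np.arange(0, 150, 0.5)
        val = np.where((t >= 120) & (t < 150), 1.0, 0.0)
        series = EISeries(t=t, value=val, method="mei")
        s = stage_average(series, hyp, window=(0.0, 150.0))
        table = s.table.set_index("stage")["value"]
        assert table["REM"] == 1.0
        assert table[["Awake", "S1", "S2", "S3/4"]].eq(0.0).all()

    def test_recovers_constructed_group_means(self, rng):
        hyp = make_hypnogram(["Awake", "S1", "S2", "S3/4", "REM"])
        means = {"Awake": 0.10, "S1": 0.12, "S2": 0.15, "S3/4": 0.2, "REM": 0.11}
        t = np.arange(0, 150, 0.1)
        val = np.array([means[hyp.stage_at(ti)] for ti in t])
        series = EISeries(t=t, value=val, method="mei")
        s = stage_average(series, hyp, window=(0.0, 150.0))
        for _, row in s.table.iterrows():
            assert row["value"] == pytest.approx(means[row["stage"]])

    def test_invariant_to_epoch_subdivision(self):
        whole = make_hypnogram(["Awake", "S2", "REM"], epoch_s=60.0)
        split = make_hypnogram(["Awake", "Awake", "S2", "S2", "REM", "REM"],
                               epoch_s=30.0)
        t = np.arange(0, 180, 0.25)
        val = np.sin(t / 11.0) ** 2
        series = EISeries(t=t, value=val, method="mei")
        s1 = stage_average(series, whole, window=(0.0, 180.0))
        s2 = stage_average(series, split, window=(0.0, 180.0))
        np.testing.assert_allclose(
            s1.table["value"].to_numpy(), s2.table["value"].to_numpy(),
            equal_nan=True,
        )


class TestKruskalWallis:
    def test_identical_groups_h_near_zero(self):
        g = [np.arange(5.0), np.arange(5.0), np.arange(5.0)]
        H, p, eta2 = kruskal_wallis(g)
        assert H == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_hand_computed_example(self):
        # ranks are 1..9 exactly; H = 12/(9*10) * sum(R_g^2/3) - 3*10
        groups = [[1, 2, 3], [10, 11, 12], [20, 21, 22]]
        H, p, _ = kruskal_wallis(groups)
        assert H == pytest.approx(7.2, abs=1e-12)

    def test_effect_size_formula_printed_pair(self):
        # eta^2_H = (H - k + 1)/(n - k); the sleep-study statistics pair
        # H = 32.1325 with k = 5 stages and n = 95 gives 0.3126
        eta2 = (32.1325 - 5 + 1) / (95 - 5)
        assert round(eta2, 4) == 0.3126

    def test_matches_scipy_on_random_fixtures(self, rng):
        for _ in range(10):
            groups = [rng.normal(size=rng.integers(4, 12)) for _ in range(4)]
            H, p, _ = kruskal_wallis(groups)
            H_ref, p_ref = stats.kruskal(*groups)
            assert H == pytest.approx(H_ref, abs=1e-8)
            assert p == pytest.approx(p_ref, abs=1e-8)

    def test_ties_match_scipy(self, rng):
        groups = [rng.integers(0, 4, size=10).astype(float) for _ in range(3)]
        H, p, _ = kruskal_wallis(groups)
        H_ref, p_ref = stats.kruskal(*groups)
        assert H == pytest.approx(H_ref, abs=1e-8)

    def test_invariant_under_monotone_transform(self, rng):
        groups = [rng.normal(size=8) for _ in range(3)]
        H1, _, _ = kruskal_wallis(groups)
        H2, _, _ = kruskal_wallis([np.exp(g) for g in groups])
        assert H1 == pytest.approx(H2, abs=1e-10)

    def test_all_tied(self):
        H, p, eta2 = kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])
        assert (H, p) == (0.0, 1.0)


class TestDunn:
    def test_identical_groups_all_corrected_to_one(self):
        g = [np.arange(6.0)] * 3
        out = dunn_test(g)
        assert (out["p_adj"] == 1.0).all()

    def test_extreme_pair_has_largest_z(self, rng):
        groups = [rng.normal(0, 1, 5), rng.normal(5, 1, 5), rng.normal(10, 1, 5)]
        out = dunn_test(groups, labels=["lo", "mid", "hi"])
        zmap = {(r.group_1, r.group_2): abs(r.z) for r in out.itertuples()}
        assert zmap[("lo", "hi")] == max(zmap.values())

    def test_closed_form_no_tie_fixture(self):
        # pooled ranks equal the data; rank means 2, 5, 8;
        # se = sqrt((9*10/12)*(2/3)) = sqrt(5)
        out = dunn_test([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        z = out.set_index(["group_1", "group_2"])["z"]
        assert z[("0", "1")] == pytest.approx(-3 / np.sqrt(5), abs=1e-12)
        assert z[("0", "2")] == pytest.approx(-6 / np.sqrt(5), abs=1e-12)
        p_raw = 2 * stats.norm.sf(6 / np.sqrt(5))
        assert out.set_index(["group_1", "group_2"])["p_adj"][("0", "2")] == \
            pytest.approx(min(1.0, 3 * p_raw), abs=1e-12)

    def test_two_group_z_squared_equals_kruskal_h(self, rng):
        # independent cross-check: for k = 2 the Dunn statistic satisfies
        # z^2 = H (tie-corrected), with H from scipy
        for _ in range(5):
            groups = [rng.normal(size=7), rng.normal(1.0, 1.0, size=9)]
            out = dunn_test(groups)
            H_ref, _ = stats.kruskal(*groups)
            assert out["z"].iloc[0] ** 2 == pytest.approx(H_ref, abs=1e-8)

    def test_phi_squared_definition(self, rng):
        groups = [rng.normal(size=6), rng.normal(2, 1, size=8)]
        out = dunn_test(groups)
        assert out["phi_squared"].iloc[0] == pytest.approx(
            out["z"].iloc[0] ** 2 / 14.0
        )


class TestSyntheticCohort:
    def test_pipeline_detects_stage_dependent_ei(self, rng):
        # 19 virtual participants with deep-sleep-dominant mE/I pattern
        true_means = {"Awake": 0.115, "S1": 0.118, "S2": 0.135,
                      "S3/4": 0.155, "REM": 0.118}
        rows = {s: [] for s in STAGES}
        for _ in range(19):
            for s in STAGES:
                rows[s].append(true_means[s] + rng.normal(0, 0.012))
        groups = [np.array(rows[s]) for s in STAGES]
        H, p, eta2 = kruskal_wallis(groups)
        assert p < 0.01
        assert eta2 > 0.0
        dunn = dunn_test(groups, labels=list(STAGES))
        pair = dunn.set_index(["group_1", "group_2"])["p_adj"]
        assert pair[("Awake", "S3/4")] < 0.01
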