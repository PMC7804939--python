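"""DSI statistic, significance criteria and cell-level selection rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sweepnet.dsi_metrics import (
    CellDsiRecord,
    DegenerateBaselineError,
    ResponseCriteria,
    TrialSet,
    best_frequency,
    cell_dsi,
    dsi,
    fcent_analysis,
    is_significant,
    min_response_filter,
    response_amplitude,
)


def make_trialset(data, fs=30.0, t0=-1.0, resp=(0.0, 1.0)):
    return TrialSet(
        data=data, fs=fs, t0=t0, baseline_window=(t0, 0.0), response_window=resp
    )


class TestDsiFormula:
    @pytest.mark.parametrize(
        "u,d,expected",
        [(2.0, 1.0, 1 / 3), (1.0, -0.5, 1.0), (1.0, 1.0, 0.0), (0.0, 2.0, -1.0)],
    )
    def test_values(self, u, d, expected):
        assert dsi(u, d) == pytest.approx(expected)

    def test_both_clamped_to_zero_is_missing(self):
        assert np.isnan(dsi(-1.0, -2.0))

    @given(st.floats(-5, 5), st.floats(-5, 5))
    @settings(deadline=None, max_examples=200)
    def test_bounded_and_antisymmetric(self, u, d):
        v = dsi(u, d)
        if not np.isnan(v):
            assert -1.0 <= v <= 1.0
            assert dsi(d, u) == pytest.approx(-v)


class TestSignificance:
    def test_all_zero_with_noise_baseline_not_significant(self, rng):
        data = rng.normal(0, 1, (10, 90))
        ts = make_trialset(data, fs=30.0, t0=-1.0, resp=(0.0, 2.0))
        assert not is_significant(ts, ResponseCriteria.imaging())

    def test_constructed_plateau_is_significant(self, rng):
        # 0.6-s supra-threshold plateau in every trial at 30 Hz
        data = rng.normal(0, 0.1, (6, 90))
        data[:, 30:49] += 10.0
        ts = make_trialset(data, fs=30.0, t0=-1.0, resp=(0.0, 2.0))
        assert is_significant(ts, ResponseCriteria.imaging())

    def test_zero_sd_baseline_raises(self):
        data = np.zeros((5, 90))
        data[:, 40:] = 1.0
        ts = make_trialset(data, fs=30.0, t0=-1.0, resp=(0.0, 1.5))
        with pytest.raises(DegenerateBaselineError):
            is_significant(ts, ResponseCriteria.imaging())

    def test_detection_rate_matches_binomial_oracle(self, rng):
        # at 2 Hz sampling the 0.5-s duration rule needs exactly one sample,
        # so a trial passes iff its single response sample exceeds the
        # threshold: per-trial probability p = P(N(h,1) > z), and the cell is
        # counted when more than half of 5 trials pass and the trial average
        # passes.  Compare the empirical rate with the analytic one.
        from scipy.stats import binom, norm

        h, z, n_trials, n_base = 3.0, 3.3, 5, 4000
        p_trial = norm.sf(z - h)
        p_cell_trials = binom.sf(n_trials // 2, n_trials, p_trial)
        p_avg = norm.sf(z / np.sqrt(n_trials) - h)
        expected = p_cell_trials * p_avg  # independent: disjoint noise? (approx)
        hits = 0
        n_rep = 400
        for k in range(n_rep):
            data = rng.normal(0, 1, (n_trials, n_base + 1))
            data[:, -1] += h
            ts = TrialSet(
                data=data, fs=2.0, t0=-n_base / 2.0,
                baseline_window=(-n_base / 2.0, 0.0), response_window=(0.0, 0.5),
            )
            hits += is_significant(ts, ResponseCriteria.imaging())
        rate = hits / n_rep
        # the two criteria share noise, so the product is only a lower bound;
        # allow 4 MC standard errors around the bracketing interval
        se = 4 * np.sqrt(expected * (1 - expected) / n_rep)
        assert expected - se <= rate <= min(p_cell_trials, p_avg) + se

    def test_unit_mode_same_bin_coincidence(self, rng):
        data = rng.poisson(0.25, (9, 20)).astype(float)
        data[:, 12] += 10.0
        ts = TrialSet(
            data=data, fs=20.0, t0=-0.5, baseline_window=(-0.2, 0.0),
            response_window=(0.0, 0.5),
        )
        assert is_significant(ts, ResponseCriteria.unit())

    @given(st.floats(3.3, 8.0), st.floats(0.5, 1.5))
    @settings(deadline=None, max_examples=30)
    def test_stricter_criteria_monotone(self, thr, consec):
        rng = np.random.default_rng(7)
        data = rng.normal(0, 1, (6, 90))
        data[:, 35:70] += 3.0
        ts = make_trialset(data, fs=30.0, t0=-1.0, resp=(0.0, 2.0))
        base = ResponseCriteria.imaging()
        loose = is_significant(ts, base)
        strict = is_significant(
            ts, ResponseCriteria(thr, consec, base.trial_frac, "imaging")
        )
        assert loose or not strict  # raising thresholds never creates significance


class TestAmplitude:
    def test_constant_trace(self):
        data = np.full((5, 60), 0.0)
        data[:, 30:] = 2.5
        ts = make_trialset(data, fs=30.0, t0=-1.0, resp=(0.0, 1.0))
        assert response_amplitude(ts) == pytest.approx(2.5)

    def test_zero_mean_noise_averages_out(self, rng):
        data = rng.normal(0, 1, (500, 60))
        ts = make_trialset(data, fs=30.0, t0=-1.0, resp=(0.0, 1.0))
        assert abs(response_amplitude(ts)) < 0.05

    def test_triangular_bump_mean_equals_integral_over_duration(self):
        # triangle of height 1, base = full 1-s window: mean = area / duration
        n_resp = 30
        tri = np.concatenate([np.linspace(0, 1, 15), np.linspace(1, 0, 15)])
        data = np.concatenate([np.zeros(30), tri])[None, :] * np.ones((5, 1))
        ts = make_trialset(data, fs=30.0, t0=-1.0, resp=(0.0, 1.0))
        area = np.trapezoid(tri, dx=1 / 30.0)
        assert response_amplitude(ts) == pytest.approx(area / 1.0, rel=0.05)


class TestCellDsi:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["rate", "direction", "amplitude", "significant"])

    def test_single_included_rate(self):
        tab = self._table([
            (10.0, "up", 2.0, True), (10.0, "down", 1.0, False),
        ])
        rec = cell_dsi(tab)
        assert rec.dsi == pytest.approx(1 / 3)
        assert rec.n_rates_included == 1

    def test_nonsignificant_rates_excluded(self):
        tab = self._table([
            (10.0, "up", 2.0, True), (10.0, "down", 1.0, False),
            (20.0, "up", 9.0, False), (20.0, "down", 9.0, False),
        ])
        rec = cell_dsi(tab)
        assert rec.dsi == pytest.approx(1 / 3)  # the 20-oct/s row never enters

    def test_no_included_rates_gives_missing(self):
        tab = self._table([(10.0, "up", 1.0, False), (10.0, "down", 1.0, False)])
        rec = cell_dsi(tab)
        assert np.isnan(rec.dsi) and rec.n_rates_included == 0

    def test_per_rate_mode(self):
        tab = self._table([
            (10.0, "up", 2.0, True), (10.0, "down", 1.0, True),
            (20.0, "up", 1.0, True), (20.0, "down", 3.0, True),
        ])
        per = cell_dsi(tab, per_rate=True).set_index("rate")
        assert per.loc[10.0, "dsi"] == pytest.approx(1 / 3)
        assert per.loc[20.0, "dsi"] == pytest.approx(-0.5)


class TestSelection:
    def _cells(self, counts):
        return [CellDsiRecord(dsi=0.0, n_rates_included=1, responsive_count=c) for c in counts]

    def test_k1_keeps_responsive(self):
        cells = self._cells([1, 3, 5])
        assert len(min_response_filter(cells, k=1)) == 3

    def test_k3_drops_weak(self):
        kept = min_response_filter(self._cells([1, 3, 5]), k=3)
        assert [c.responsive_count for c in kept] == [3, 5]

    def test_monotone_in_k(self):
        cells = self._cells([0, 1, 2, 3, 4, 5])
        sizes = [len(min_response_filter(cells, k)) for k in (1, 3, 5)]
        assert sizes == sorted(sizes, reverse=True)


class TestBestFrequency:
    def test_single_responsive_frequency(self):
        tab = pd.DataFrame({
            "freq_khz": [4.0, 8.0], "amplitude": [0.1, 0.9],
            "significant": [False, True],
        })
        assert best_frequency(tab) == 8.0

    def test_tie_breaks_to_lowest(self):
        tab = pd.DataFrame({
            "freq_khz": [4.0, 8.0], "amplitude": [0.9, 0.9],
            "significant": [True, True],
        })
        assert best_frequency(tab) == 4.0

    def test_no_significant_tone_gives_none(self):
        tab = pd.DataFrame({
            "freq_khz": [4.0], "amplitude": [0.5], "significant": [False]
        })
        assert best_frequency(tab) is None

    def test_recovers_known_tuning_peak(self, rng):
        freqs = np.array([4, 5.7, 8, 11.3, 16, 22.6, 32])
        rows = []
        for inten in (50, 70):
            amps = np.exp(-((np.log2(freqs / 11.3)) ** 2)) + rng.normal(0, 0.01, freqs.size)
            for f, a in zip(freqs, amps):
                rows.append({"freq_khz": f, "intensity_db": inten,
                             "amplitude": a, "significant": True})
        assert best_frequency(pd.DataFrame(rows)) == pytest.approx(11.3)


class TestFcentAnalysis:
    def test_relative_position_values(self):
        pairs = pd.DataFrame({
            "bf_khz": [8.0, 8.0], "f_cent_khz": [8.0, 16.0], "dsi": [0.1, 0.2]
        })
        out = fcent_analysis(pairs, bin_width_oct=0.5)
        rel = np.log2(pairs.f_cent_khz / pairs.bf_khz)
        assert np.allclose(sorted(rel), [0.0, 1.0])
        assert out.n.sum() == 2

    def test_away_from_bf_population_crosses_zero(self, rng):
        # cells built to prefer sweeps moving away from BF: DSI has the sign
        # of the sweep centre's position relative to BF
        rows = []
        for cell in range(60):
            bf = 2 ** rng.uniform(2.5, 5.5)
            for fc in (5.7, 8.0, 11.3, 16.0, 22.7, 32.0, 45.3):
                rel = np.log2(fc / bf)
                rows.append({
                    "bf_khz": bf, "f_cent_khz": fc,
                    "dsi": np.tanh(rel) + rng.normal(0, 0.1),
                })
        out = fcent_analysis(pd.DataFrame(rows))
        below = out[out.bin_center_oct < -0.3].mean_dsi
        above = out[out.bin_center_oct > 0.3].mean_dsi
        assert below.mean() < 0 < above.mean()
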