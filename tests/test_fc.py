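"""Flow-cytometry calibration, time-based concentration and window pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evlipo.fc import (
    EV_RICH_WINDOW,
    LPP_RICH_WINDOW,
    Calibration,
    apply_calibration,
    concentration,
    detergent_sensitivity,
    fit_calibration,
    fraction_summaries,
    pooled_windows,
    spike_in_compare,
)


def _beads(pairs):
    return pd.DataFrame(pairs, columns=["measured_intensity", "assigned_value"])


class TestCalibration:
    def test_identity_beads_give_slope_one_intercept_zero(self):
        cal = fit_calibration(_beads([(100.0, 100.0), (1000.0, 1000.0)]))
        assert cal.slope == pytest.approx(1.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)
        assert cal.r_squared == pytest.approx(1.0)

    def test_two_point_system_hand_oracle(self):
        # (200 au -> 100 ERF, 2000 au -> 1000 ERF): slope 1, intercept -log10(2)
        cal = fit_calibration(_beads([(200.0, 100.0), (2000.0, 1000.0)]))
        assert cal.slope == pytest.approx(1.0)
        assert cal.intercept == pytest.approx(-np.log10(2.0))
        assert cal.to_erf(np.array([500.0]))[0] == pytest.approx(250.0)

    def test_single_bead_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration(_beads([(100.0, 100.0)]))
        with pytest.raises(ValueError):
            fit_calibration(_beads([(100.0, 100.0), (100.0, 200.0)]))

    def test_force_unit_slope(self):
        cal = fit_calibration(
            _beads([(100.0, 300.0), (1000.0, 2800.0)]), force_unit_slope=True
        )
        assert cal.slope == 1.0

    def test_identity_calibration_passthrough_and_threshold_boundary(self):
        cal = Calibration(slope=1.0, intercept=0.0, r_squared=1.0)
        events = pd.DataFrame({"fl_au": [0.0, 50.0, 100.0, 200.0]})
        out = apply_calibration(events, cal, threshold=100.0)
        assert np.allclose(out["fl_erf"], [0.0, 50.0, 100.0, 200.0])
        # inclusive >= at the threshold; zero maps to zero, below threshold
        assert out["above_threshold"].tolist() == [False, False, True, True]

    def test_doubling_intensity_doubles_erf_at_unit_slope(self):
        cal = Calibration(slope=1.0, intercept=0.3, r_squared=1.0)
        e = cal.to_erf(np.array([10.0, 20.0]))
        assert e[1] == pytest.approx(2 * e[0])

    def test_calibration_preserves_intensity_ranking(self, rng):
        cal = fit_calibration(_beads([(150.0, 100.0), (900.0, 1000.0), (4000.0, 10000.0)]))
        fl = rng.uniform(1.0, 1e4, 200)
        erf = cal.to_erf(fl)
        assert np.array_equal(np.argsort(fl), np.argsort(erf))


class TestConcentration:
    def test_zero_events(self):
        assert concentration(0, 30.0, 1.0, 20.0) == 0.0

    def test_arithmetic_oracle(self):
        # 300 events / (1 uL/s * 30 s) * dilution 20 = 200 events/uL
        assert concentration(300, 30.0, 1.0, 20.0) == pytest.approx(200.0)

    def test_protocol_dilution_factor(self):
        # 50 uL diluted into 950 uL -> measured sample is 1/20 of the fraction
        dilution = (50.0 + 950.0) / 50.0
        assert dilution == 20.0
        assert concentration(100, 30.0, 1.0, dilution) == pytest.approx(100 / 30 * 20)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            concentration(10, 0.0, 1.0)
        with pytest.raises(ValueError):
            concentration(10, 30.0, -1.0)
        with pytest.raises(ValueError):
            concentration(-1, 30.0, 1.0)

    @settings(deadline=None, max_examples=100)
    @given(
        n=st.integers(min_value=0, max_value=10_000),
        t=st.floats(min_value=0.1, max_value=1e3),
        q=st.floats(min_value=0.01, max_value=10.0),
        d=st.floats(min_value=1.0, max_value=100.0),
    )
    def test_linearity_properties(self, n, t, q, d):
        c = concentration(n, t, q, d)
        assert concentration(2 * n, t, q, d) == pytest.approx(2 * c)
        assert concentration(n, 2 * t, q, d) == pytest.approx(c / 2)
        assert concentration(n, t, 2 * q, d) == pytest.approx(c / 2)
        assert concentration(n, t, q, 2 * d) == pytest.approx(2 * c)


class TestWindows:
    def _events(self, densities):
        return pd.DataFrame({"fraction_density": densities})

    def test_all_events_at_1_14_pool_into_ev_rich(self):
        pools = pooled_windows(self._events([1.14] * 10), 30.0, 1.0).set_index("window")
        assert pools.loc["EV-rich", "n_events"] == 10
        assert pools.loc["LPP-rich", "n_events"] == 0

    def test_boundary_density_1_10_is_lpp_rich_inclusive(self):
        pools = pooled_windows(self._events([1.10]), 30.0, 1.0).set_index("window")
        assert pools.loc["LPP-rich", "n_events"] == 1

    def test_window_conservation(self, rng):
        densities = rng.uniform(1.00, 1.30, 500)
        pools = pooled_windows(self._events(densities), 30.0, 1.0).set_index("window")
        assert (
            pools.loc["LPP-rich", "n_events"]
            + pools.loc["EV-rich", "n_events"]
            + pools.loc["other", "n_events"]
            == 500
        )

    def test_densities_rounded_before_assignment(self):
        # 1.1049 rounds to 1.10 (inside LPP-rich); 1.1051 rounds to 1.11 (gap)
        pools = pooled_windows(self._events([1.1049, 1.1051]), 30.0, 1.0).set_index("window")
        assert pools.loc["LPP-rich", "n_events"] == 1
        assert pools.loc["other", "n_events"] == 1

    def test_fraction_summaries_group_by_rounded_density(self):
        events = pd.DataFrame({"fraction_density": [1.06, 1.061, 1.14, 1.14]})
        out = fraction_summaries(events, 30.0, 1.0, 20.0)
        assert out["density"].tolist() == [1.06, 1.14]
        assert out["n_events"].tolist() == [2, 2]
        assert out["concentration"].iloc[0] == pytest.approx(2 / 30 * 20)


class TestComparisons:
    def _summary(self, counts):
        return pd.DataFrame(
            {
                "window": list(counts),
                "n_events": list(counts.values()),
                "concentration": [v / 30 * 20 for v in counts.values()],
            }
        )

    def test_identical_summaries_give_unit_fold_changes(self):
        s = self._summary({"LPP-rich": 100, "EV-rich": 50})
        out = spike_in_compare(s, s)
        assert (out["fold_change"] == 1.0).all()

    def test_fold_change_arithmetic(self):
        a = self._summary({"EV-rich": 100})
        b = self._summary({"EV-rich": 50})
        out = spike_in_compare(a, b)
        assert out["fold_change"].iloc[0] == pytest.approx(0.5)
        assert out["difference"].iloc[0] == -50

    def test_zero_baseline_flagged_infinite(self):
        a = self._summary({"EV-rich": 0})
        b = self._summary({"EV-rich": 30})
        out = spike_in_compare(a, b)
        assert out["infinite"].iloc[0] and np.isinf(out["fold_change"].iloc[0])
        assert out["difference"].iloc[0] == 30

    def test_window_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spike_in_compare(
                self._summary({"EV-rich": 1}), self._summary({"LPP-rich": 1})
            )

    def test_ldl_spike_in_raises_lpp_rich_counts(self):
        """Generator-built LDL-spiked sample shows more LPP-rich-window events
        than the unspiked control, mirroring a density-shifted complex class."""
        from evlipo.synth import DEFAULT_CLASSES, generate_fc_events

        control, _ = generate_fc_events([(DEFAULT_CLASSES["EV"], 2000)], seed=21)
        spiked, _ = generate_fc_events(
            [
                (DEFAULT_CLASSES["EV"], 1600),
                (DEFAULT_CLASSES["EV-LDL complex"], 400),
                (DEFAULT_CLASSES["LDL"], 2000),
            ],
            seed=21,
        )
        pa = pooled_windows(control, 30.0, 1.0)
        pb = pooled_windows(spiked, 30.0, 1.0)
        out = spike_in_compare(pa, pb).set_index("window")
        assert out.loc["LPP-rich", "difference"] > 0


class TestDetergent:
    def test_total_lysis(self):
        out = detergent_sensitivity({"g": 100}, {"g": 0})
        assert out["percent_lost"].iloc[0] == 100.0

    def test_arithmetic(self):
        out = detergent_sensitivity({"g": 1000}, {"g": 250})
        assert out["percent_lost"].iloc[0] == pytest.approx(75.0)

    def test_post_exceeding_pre_clipped_and_flagged(self):
        out = detergent_sensitivity({"g": 10}, {"g": 20})
        assert out["percent_lost"].iloc[0] == 0.0
        assert "anomaly" in out["flag"].iloc[0]

    def test_zero_pre_is_undefined(self):
        out = detergent_sensitivity({"g": 0}, {"g": 0})
        assert np.isnan(out["percent_lost"].iloc[0])
        assert "undefined" in out["flag"].iloc[0]

    def test_gate_mismatch_rejected(self):
        with pytest.raises(ValueError):
            detergent_sensitivity({"a": 1}, {"b": 1})


def test_swarm_rate_warning():
    cal = Calibration(slope=1.0, intercept=0.0, r_squared=1.0)
    events = pd.DataFrame({"fl_au": np.ones(5000), "time": np.linspace(0, 0.1, 5000)})
    with pytest.warns(UserWarning, match="swarm"):
        apply_calibration(events, cal, threshold=0.0)
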