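import numpy as np
import pandas as pd
import pytest

import canaldyn as cd
from canaldyn.tuning import DSI_THRESHOLD


def _dr(F, directions=None):
    directions = directions if directions is not None else np.arange(0, 360, 30.0)
    return cd.DirectionResponses(F=np.atleast_2d(np.asarray(F, float)), directions_deg=directions)


@pytest.fixture(scope="module")
def noiseless_ta(protocol):
    """Trial average of a noiseless population with known tuning."""
    spec = cd.CohortSpec(
        n_neurons=30, class_fractions=(0.5, 0.5, 0.0), kappa_range=(6.0, 12.0),
        trial_noise_sd=0.0, seed=21,
    )
    bp = cd.make_blueprint(spec)
    ts = cd.simulate_individual(bp, protocol, spec, 0)
    return bp, cd.trial_average(ts)


class TestDirectionResponses:
    def test_constant_trace_gives_zero(self, protocol):
        ta = cd.TrialAverage("c", np.full((2, 180), 0.3), protocol)
        dr = cd.direction_responses(ta)
        assert np.all(dr.F == 0.0)

    def test_square_pulse_amplitude_recovered(self, protocol):
        """A flat-baseline pulse of height h exactly filling a stimulus window
        yields F = h for that direction."""
        data = np.zeros((1, 180))
        s0, s1 = cd.stimulus_window(protocol, 3)
        data[0, s0:s1] = 0.7
        dr = cd.direction_responses(cd.TrialAverage("p", data, protocol))
        assert dr.F[0, 3] == pytest.approx(0.7)
        assert np.all(np.delete(dr.F[0], 3) == 0.0)

    def test_noiseless_direction_cell_peaks_near_preferred(self, noiseless_ta):
        """argmax F(θ) lands on the stimulus direction nearest the preferred
        angle (cells within 1° of a bin boundary are skipped: there the
        'nearest' direction is numerically ill-defined)."""
        bp, ta = noiseless_ta
        dr = cd.direction_responses(ta)
        dir_cells = np.where(bp.selectivity_class == "direction")[0]
        checked = 0
        for i in dir_cells:
            off_boundary = abs((bp.preferred_angle_deg[i] % 30.0) - 15.0)
            if off_boundary < 1.0:
                continue
            best = dr.directions_deg[np.argmax(dr.F[i])]
            dist = abs((best - bp.preferred_angle_deg[i] + 180) % 360 - 180)
            assert dist <= 15.0  # half the inter-stimulus step
            checked += 1
        assert checked > 0

    def test_protocol_mismatch_rejected(self, protocol):
        other = cd.build_protocol(8, 5, 10, 3, 50, 45, 1)
        ta = cd.TrialAverage("x", np.zeros((1, 180)), protocol)
        with pytest.raises(ValueError):
            cd.direction_responses(ta, other)


class TestIndices:
    @pytest.mark.parametrize(
        "f_pref,f_orth,expected",
        [(0.6, 0.2, 0.5), (0.4, 0.4, 0.0), (0.8, 0.0, 1.0)],
    )
    def test_osi_formula(self, f_pref, f_orth, expected):
        F = np.zeros(12)
        F[0] = f_pref
        F[3] = F[9] = f_orth  # ±90° neighbors of direction 0
        assert cd.osi(_dr(F))[0] == pytest.approx(expected)

    def test_osi_plus_variant_uses_only_plus90(self):
        F = np.zeros(12)
        F[0], F[3], F[9] = 1.0, 0.5, 0.1
        both = cd.osi(_dr(F), orthogonal_mode="both")[0]
        plus = cd.osi(_dr(F), orthogonal_mode="plus")[0]
        assert both == pytest.approx((1 - 0.3) / (1 + 0.3))
        assert plus == pytest.approx((1 - 0.5) / (1 + 0.5))

    def test_dsi_formula_and_boundary(self):
        F = np.zeros(12)
        F[0], F[6] = 1.0, 0.5
        d = cd.dsi(_dr(F))[0]
        assert d == pytest.approx(1.0 / 3.0)
        # boundary cell is NOT selective under the strict rule
        assert not (d > DSI_THRESHOLD)

    def test_dsi_zero_when_opposite_equals_preferred(self):
        F = np.zeros(12)
        F[2] = F[8] = 0.9
        assert cd.dsi(_dr(F))[0] == 0.0

    def test_all_zero_responses_flagged_missing(self):
        dr = _dr(np.zeros(12))
        assert np.isnan(cd.osi(dr)[0])
        assert np.isnan(cd.dsi(dr)[0])

    def test_orientation_cell_noiseless_dsi_exactly_zero(self, noiseless_ta):
        bp, ta = noiseless_ta
        dr = cd.direction_responses(ta)
        ori = np.where(bp.selectivity_class == "orientation")[0]
        assert len(ori) > 0
        d = cd.dsi(dr)[ori]
        assert np.all(d == 0.0)

    @pytest.mark.parametrize("scale", [0.1, 3.0, 250.0])
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(0)
        F = rng.uniform(0, 1, (5, 12))
        dr, drs = _dr(F), _dr(F * scale)
        np.testing.assert_allclose(cd.osi(drs), cd.osi(dr), atol=1e-12)
        np.testing.assert_allclose(cd.dsi(drs), cd.dsi(dr), atol=1e-12)


class TestPreferredDirection:
    def test_single_nonzero_response(self):
        F = np.zeros(12)
        F[3] = 0.5  # 90°
        angle, resultant = cd.preferred_direction(_dr(F))
        assert angle[0] == pytest.approx(90.0)
        assert resultant[0] == pytest.approx(1.0)

    def test_antipodal_cancellation_is_missing(self):
        F = np.zeros(12)
        F[0] = F[6] = 1.0
        angle, resultant = cd.preferred_direction(_dr(F))
        assert np.isnan(angle[0])
        assert resultant[0] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_pair_bisected(self):
        F = np.zeros(12)
        F[1] = F[3] = 1.0  # 30° and 90°
        angle, _ = cd.preferred_direction(_dr(F))
        assert angle[0] == pytest.approx(60.0)

    def test_recovery_from_noiseless_direction_cells(self, noiseless_ta):
        """Vector-average preferred direction lands within half a bin (15°)
        of the generating preferred angle for noiseless direction cells."""
        bp, ta = noiseless_ta
        dr = cd.direction_responses(ta)
        angle, _ = cd.preferred_direction(dr)
        for i in np.where(bp.selectivity_class == "direction")[0]:
            dist = abs((angle[i] - bp.preferred_angle_deg[i] + 180) % 360 - 180)
            assert dist < 15.0


class TestHistogram:
    def _table(self, angles, selective=None):
        n = len(angles)
        return pd.DataFrame(
            dict(
                fish_id="f0",
                neuron=np.arange(n),
                osi=0.5,
                dsi=0.9,
                preferred_direction_deg=angles,
                resultant_length=0.8,
                is_direction_selective=selective if selective is not None else [True] * n,
            )
        )

    def test_exact_angles_tally_exactly(self):
        dirs = np.arange(0, 360, 30.0)
        table = self._table([0.0, 0.0, 30.0, 300.0])
        h = cd.direction_histogram(table, dirs)
        assert h.counts[0] == 2 and h.counts[1] == 1 and h.counts[10] == 1
        assert h.fractions.sum() == pytest.approx(1.0)

    def test_nearest_center_rule(self):
        dirs = np.arange(0, 360, 30.0)
        h = cd.direction_histogram(self._table([14.0, 16.0, 351.0]), dirs)
        assert h.counts[0] == 2  # 14° and 351° round to the 0° bin
        assert h.counts[1] == 1  # 16° rounds to 30°

    def test_no_selective_cells_is_flagged_empty(self):
        dirs = np.arange(0, 360, 30.0)
        h = cd.direction_histogram(self._table([10.0], selective=[False]), dirs)
        assert h.empty and h.counts.sum() == 0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cd.direction_histogram(pd.DataFrame(), np.arange(0, 360, 30.0))


class TestTuningTable:
    def test_columns_and_selectivity_flag(self, noiseless_ta):
        _, ta = noiseless_ta
        table = cd.tuning_table(ta)
        assert set(table.columns) >= {
            "fish_id", "neuron", "osi", "dsi", "preferred_direction_deg",
            "resultant_length", "is_direction_selective",
        }
        valid = table["dsi"].notna()
        expected = table.loc[valid, "dsi"] > DSI_THRESHOLD
        assert (table.loc[valid, "is_direction_selective"] == expected).all()

    def test_high_kappa_limits(self, protocol):
        """κ → large: direction cells DSI → 1; orientation cells OSI → 1, DSI = 0."""
        spec = cd.CohortSpec(
            n_neurons=10, class_fractions=(0.5, 0.5, 0.0), kappa_range=(25.0, 25.0),
            trial_noise_sd=0.0, seed=5,
        )
        bp = cd.make_blueprint(spec)
        ts = cd.simulate_individual(bp, protocol, spec, 0)
        table = cd.tuning_table(cd.trial_average(ts))
        dcells = bp.selectivity_class == "direction"
        assert np.all(table.loc[dcells, "dsi"] > 0.95)
        assert np.all(table.loc[~dcells, "dsi"] == 0.0)
        assert np.all(table.loc[~dcells, "osi"] > 0.95)
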