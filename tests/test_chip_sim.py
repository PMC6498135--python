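"""Generator: Poisson occupancy, retention, mode frequencies, determinism,
and the well-table round trip."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seqsecrete import presets
from seqsecrete.chip_sim import (WellTableError, oscillation_sequences,
                                 read_well_table, simulate_chip,
                                 write_well_table)
from seqsecrete.config import ConfigError, SimulationConfig


def small_config(**kw):
    base = dict(n_wells=2000, seed=5, basal_coupling=0.0)
    base.update(kw)
    return SimulationConfig(**base)


class TestOccupancy:
    def test_occupancy_matches_poisson_pmf(self, default_chip):
        """Well occupancies 0..5 follow Poisson(lambda) within 3-sigma
        multinomial error at 18,000 wells."""
        config, wells, _ = default_chip
        counts = wells.loc[wells.time_index == 0, "cell_count"].to_numpy()
        n = len(counts)
        for k in range(6):
            p = stats.poisson.pmf(k, config.loading_rate)
            observed = (counts == k).mean()
            tol = 3 * np.sqrt(p * (1 - p) / n)
            assert abs(observed - p) <= tol, (k, observed, p)

    def test_single_cell_fraction_near_lambda_e_minus_lambda(self, default_chip):
        config, wells, _ = default_chip
        lam = config.loading_rate
        expected = lam * np.exp(-lam)  # 0.3033 at lambda = 0.5
        w0 = wells[wells.time_index == 0]
        frac = (w0.cell_count == 1).mean()
        tol = 3 * np.sqrt(expected * (1 - expected) / len(w0))
        assert abs(frac - expected) <= tol


class TestRetention:
    def test_full_retention_keeps_every_cell(self):
        wells, truth = simulate_chip(small_config(retention_p=1.0))
        assert (truth.cells.last_window == 3).all()
        # observed cell counts never change
        pivot = wells.pivot_table(index=["row", "col"], columns="time_index",
                                  values="cell_count")
        assert (pivot.nunique(axis=1) == 1).all()

    def test_mean_retention_matches_probability(self, default_chip):
        """Fraction of cells surviving each exchange ~ retention_p."""
        config, _, truth = default_chip
        for e in (1, 2, 3):
            at_risk = truth.cells[truth.cells.last_window >= e - 1]
            frac = (at_risk.last_window >= e).mean()
            tol = 3 * np.sqrt(config.retention_p * (1 - config.retention_p)
                              / len(at_risk))
            assert abs(frac - config.retention_p) <= tol

    def test_lost_cells_leave_background_only_wells(self):
        """A lost cell disappears from later bright-field counts."""
        wells, truth = simulate_chip(small_config(retention_p=0.3, seed=9))
        lost = truth.cells[(truth.cells.last_window == 0)
                           & (truth.cells.well_cell_count == 1)]
        assert len(lost) > 0
        merged = wells.merge(lost[["row", "col"]], on=["row", "col"])
        later = merged[merged.time_index > 0]
        assert (later.cell_count == 0).all()


class TestModes:
    def test_realized_mode_frequencies_match_probabilities(self, pattern_cohort):
        """With coupling off, realized per-protein mode frequencies match the
        configured probabilities within 3-sigma multinomial error."""
        config, _, truth, _ = pattern_cohort
        modes = truth.modes
        n = truth.cells.shape[0]
        assert n >= 1500
        for protein in ("CCL2", "TNF", "IL6"):
            probs = config.mode_probs[protein]["low"]  # same for both states
            sub = modes[modes.protein == protein]
            for mode_name, p in probs.items():
                obs = (sub["mode"] == mode_name).mean()
                tol = 3 * np.sqrt(p * (1 - p) / n) + 1e-12
                assert abs(obs - p) <= tol, (protein, mode_name, obs, p)

    def test_truth_calls_consistent_with_modes(self, default_chip):
        """Each realized mode's defining regular pattern holds for its true
        on/off sequence."""
        _, _, truth = default_chip
        m = truth.modes
        assert m.loc[m["mode"] == "ALL_ON", "calls"].str.fullmatch("1+").all()
        assert m.loc[m["mode"] == "ON_OFF", "calls"].str.fullmatch("1+0+").all()
        assert m.loc[m["mode"] == "OFF_ON", "calls"].str.fullmatch("0+1+").all()
        assert (m.loc[m["mode"] == "OTHER_SILENT", "calls"] == "0000").all()
        osc = m.loc[m["mode"] == "OTHER_OSC", "calls"]
        transitions = osc.map(
            lambda s: sum(a != b for a, b in zip(s, s[1:])))
        assert (transitions >= 2).all()

    def test_oscillation_sequences_enumeration(self):
        seqs = oscillation_sequences(4)
        assert seqs.shape == (8, 4)  # 16 total - 1 all-on - 3 - 3 - 1 all-off


class TestDeterminism:
    def test_identical_seed_identical_output(self):
        config = small_config(seed=42, basal_coupling=0.5)
        w1, t1 = simulate_chip(config)
        w2, t2 = simulate_chip(small_config(seed=42, basal_coupling=0.5))
        pd.testing.assert_frame_equal(w1, w2)
        pd.testing.assert_frame_equal(t1.cells, t2.cells)
        pd.testing.assert_frame_equal(t1.modes, t2.modes)

    def test_different_seed_differs(self):
        w1, _ = simulate_chip(small_config(seed=1))
        w2, _ = simulate_chip(small_config(seed=2))
        assert not w1.equals(w2)


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(loading_rate=-1.0), dict(loading_rate=np.nan),
        dict(retention_p=1.5), dict(n_timepoints=1),
        dict(background_sd=-3.0), dict(signal_logmean=np.inf),
        dict(state_mix=-0.1),
    ])
    def test_invalid_parameters_raise(self, bad):
        with pytest.raises(ConfigError):
            SimulationConfig(**bad).validate()

    def test_mode_probs_must_sum_to_one(self):
        config = small_config()
        config.mode_probs["TNF"]["low"]["ALL_ON"] += 0.1
        with pytest.raises(ConfigError):
            config.validate()


class TestWellTable:
    def test_round_trip_identity(self, tmp_path):
        wells, _ = simulate_chip(small_config(n_wells=300))
        path = tmp_path / "wells.csv"
        write_well_table(wells, path)
        back = read_well_table(path)
        assert list(back.columns) == list(wells.columns)
        pd.testing.assert_frame_equal(back, wells)

    def test_empty_table_round_trip(self, tmp_path):
        wells, _ = simulate_chip(small_config(n_wells=50))
        empty = wells.iloc[0:0]
        path = tmp_path / "empty.csv"
        write_well_table(empty, path)
        back = read_well_table(path)
        assert back.empty
        assert list(back.columns) == list(wells.columns)

    def test_hand_written_wells_parse_literally(self, tmp_path):
        path = tmp_path / "hand.csv"
        path.write_text(
            "chip_id,time_index,row,col,cell_count,IL6,TNF\n"
            "chipA,0,0,0,1,120.5,98.0\n"
            "chipA,0,0,1,0,101.0,95.5\n"
            "chipA,1,0,0,1,350.0,99.0\n")
        wells = read_well_table(path)
        assert len(wells) == 3
        assert wells.loc[0, "IL6"] == 120.5
        assert wells.loc[2, "cell_count"] == 1
        assert list(wells.columns[-2:]) == ["IL6", "TNF"]

    @pytest.mark.parametrize("body,msg", [
        ("chip,t,r,c,n,IL6\n", "malformed header"),
        ("chip_id,time_index,row,col,cell_count,IL6\nA,0,0,0,1,-5\n",
         "negative intensity"),
        ("chip_id,time_index,row,col,cell_count,IL6\nA,0,0,0,1,5\nA,0,0,0,1,6\n",
         "duplicate"),
    ])
    def test_malformed_tables_raise_with_line(self, tmp_path, body, msg):
        path = tmp_path / "bad.csv"
        path.write_text(body)
        with pytest.raises(WellTableError, match=msg):
            read_well_table(path)
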