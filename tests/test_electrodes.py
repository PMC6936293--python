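from __future__ import annotations

import itertools

import numpy as np
import pytest

import actinmachine as am
from actinmachine.automaton import EXCITED, REFRACTORY

from _reference import NaiveAutomaton


def full_grid(n=15):
    return am.ConductiveMatrix(np.ones((n, n, n), dtype=bool))


class TestSphere:
    def test_recording_sphere_has_251_voxels(self):
        # strict d < 4 on the integer lattice is d^2 <= 15; brute force count
        brute = sum(
            1
            for d in itertools.product(range(-4, 5), repeat=3)
            if d[0] ** 2 + d[1] ** 2 + d[2] ** 2 < 16
        )
        assert brute == 251
        m = full_grid()
        lat = am.LatticeState.resting(m)
        lat.state[:] = EXCITED
        assert am.record_potential(lat, am.Electrode("c", 7, 7, 7, 4.0)) == 251

    def test_strict_radius_excludes_exact_distance(self):
        m = full_grid()
        lat = am.LatticeState.resting(m)
        lat.state[7 + 4, 7, 7] = EXCITED  # distance exactly 4
        assert am.record_potential(lat, am.Electrode("c", 7, 7, 7, 4.0)) == 0

    def test_no_excitation_means_zero_potential(self):
        lat = am.LatticeState.resting(full_grid())
        assert am.record_potential(lat, am.Electrode("c", 7, 7, 7)) == 0

    def test_sphere_clipped_at_grid_boundary(self):
        m = full_grid(6)
        lat = am.LatticeState.resting(m)
        lat.state[:] = EXCITED
        assert 0 < am.record_potential(lat, am.Electrode("c", 0, 0, 0, 4.0)) < 251


class TestStimulate:
    def test_all_zero_pattern_leaves_lattice_unchanged(self):
        m = full_grid()
        lat = am.LatticeState.resting(m)
        out = am.stimulate(lat, m, [am.Electrode("e0", 7, 7, 7)], am.StimulusPattern((0,)))
        assert not out.state.any()

    def test_one_bit_excites_exactly_the_conductive_sphere(self):
        m = full_grid()
        lat = am.LatticeState.resting(m)
        out = am.stimulate(lat, m, [am.Electrode("e0", 7, 7, 7, 4.0)], am.StimulusPattern((1,)))
        assert (out.state == EXCITED).sum() == 251

    def test_nonconductive_region_not_excited(self):
        m = am.ConductiveMatrix(np.zeros((15, 15, 15), dtype=bool))
        lat = am.LatticeState.resting(m)
        out = am.stimulate(lat, m, [am.Electrode("e0", 7, 7, 7)], am.StimulusPattern((1,)))
        assert not out.state.any()

    def test_refractory_voxels_not_overridden(self):
        m = full_grid()
        lat = am.LatticeState.resting(m)
        lat.state[7, 7, 7] = REFRACTORY
        lat.h[7, 7, 7] = 5
        out = am.stimulate(lat, m, [am.Electrode("e0", 7, 7, 7)], am.StimulusPattern((1,)))
        assert out.state[7, 7, 7] == REFRACTORY and out.h[7, 7, 7] == 5

    def test_adding_a_one_bit_grows_the_excited_set(self):
        m = full_grid()
        els = [am.Electrode("e0", 4, 4, 4), am.Electrode("e1", 10, 10, 10)]
        lat = am.LatticeState.resting(m)
        small = am.stimulate(lat, m, els, am.StimulusPattern((1, 0)))
        large = am.stimulate(lat, m, els, am.StimulusPattern((1, 1)))
        assert np.all(large.state[small.state == EXCITED] == EXCITED)
        assert (large.state == EXCITED).sum() > (small.state == EXCITED).sum()

    def test_electrode_outside_grid_rejected(self):
        m = full_grid()
        lat = am.LatticeState.resting(m)
        with pytest.raises(ValueError):
            am.stimulate(lat, m, [am.Electrode("e0", 99, 7, 7)], am.StimulusPattern((1,)))


class TestStimulusPattern:
    def test_decimal_encoding_is_msb_first(self):
        p = am.StimulusPattern.from_decimal(32, 6)
        assert p.bits == (1, 0, 0, 0, 0, 0)
        assert am.StimulusPattern((0, 0, 0, 0, 0, 1)).decimal == 1
        for d in range(64):
            assert am.StimulusPattern.from_decimal(d, 6).decimal == d


class TestElectrodeTables:
    @pytest.mark.parametrize("name,n", [("E1", 10), ("E2", 8)])
    def test_builtin_tables_parse_and_fit_the_confocal_grid(self, name, n):
        els = am.builtin_electrodes(name)
        assert len(els) == n
        for e in els:
            assert 0 <= e.i < 1024 and 0 <= e.j < 1024 and 0 <= e.z < 30
            assert e.radius == 4

    def test_layouts_share_their_common_rows(self):
        e1 = {e.centre for e in am.builtin_electrodes("E1")}
        e2 = {e.centre for e in am.builtin_electrodes("E2")}
        assert e2 <= e1

    def test_roundtrip_csv(self, tmp_path):
        els = am.builtin_electrodes("E2")
        from actinmachine.electrodes import write_electrodes

        write_electrodes(els, tmp_path / "e.csv")
        assert am.read_electrodes(tmp_path / "e.csv") == els


class TestRunExperiment:
    def test_zero_input_gives_all_zero_traces(self, delaunay_matrix):
        els = am.auto_electrodes(delaunay_matrix, 3)
        trace = am.run_experiment(
            delaunay_matrix, els, am.StimulusPattern((0, 0, 0)), am.AutomatonParams(), 30
        )
        assert not trace.values.any()

    def test_determinism(self, delaunay_matrix):
        els = am.auto_electrodes(delaunay_matrix, 3)
        args = (delaunay_matrix, els, am.StimulusPattern((1, 0, 1)), am.AutomatonParams(3, 5, 3), 40)
        assert np.array_equal(am.run_experiment(*args).values, am.run_experiment(*args).values)

    def test_potential_bounded_by_sphere_population(self, delaunay_matrix):
        els = am.auto_electrodes(delaunay_matrix, 3)
        trace = am.run_experiment(
            delaunay_matrix, els, am.StimulusPattern((1, 1, 1)), am.AutomatonParams(2, 5, 3), 60
        )
        from actinmachine.electrodes import electrode_voxels

        for c, e in enumerate(els):
            bound = len(electrode_voxels(delaunay_matrix, e)[0])
            assert trace.values[:, c].max() <= bound

    def test_far_electrode_arrival_matches_naive_oracle(self, line_matrix):
        els = [am.Electrode("near", 0, 1, 1, 2.0), am.Electrode("far", 30, 1, 1, 2.0)]
        params = am.AutomatonParams(theta=0, delta=20, radius=3)
        trace = am.run_experiment(line_matrix, els, am.StimulusPattern((1, 0)), params, 15)
        arrival = int(np.nonzero(trace.values[:, 1])[0][0]) + 1

        conductive = set(zip(*np.nonzero(line_matrix.grid)))
        naive = NaiveAutomaton(conductive, 0, 20, 3)
        naive.excite([p for p in conductive if (p[0]) ** 2 + (p[1] - 1) ** 2 + (p[2] - 1) ** 2 < 4])
        oracle_arrival = None
        for t in range(1, 16):
            naive.step()
            hit = any(
                naive.state[p] == 1
                for p in conductive
                if (p[0] - 30) ** 2 + (p[1] - 1) ** 2 + (p[2] - 1) ** 2 < 4
            )
            if hit:
                oracle_arrival = t
                break
        assert arrival == oracle_arrival
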