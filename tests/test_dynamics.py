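import numpy as np
import pytest
from hypothesis import given, strategies as st

import tumorca as tc
from tumorca.dynamics import Verdict, stall_allowance
from tumorca.metrics import compute_geometry

from conftest import make_tumor_square


class TestClassifyMicroenvironment:
    @pytest.mark.parametrize(
        "o2,gl,ph,verdict,anaerobic",
        [
            (0.5, 5.0, 7.3, Verdict.PROLIFERATION_PERMITTED, False),
            (0.015, 5.0, 7.3, Verdict.QUIESCENCE_TRIGGER, True),
            (0.005, 5.0, 7.3, Verdict.NECROSIS_TRIGGER, True),
            (0.5, 5.0, 5.9, Verdict.NECROSIS_TRIGGER, False),
            (0.5, 0.05, 7.3, Verdict.QUIESCENCE_TRIGGER, False),
            (0.5, 0.02, 7.3, Verdict.NECROSIS_TRIGGER, False),
            (0.5, 5.0, 6.3, Verdict.QUIESCENCE_TRIGGER, False),
        ],
    )
    def test_threshold_cases(self, params, o2, gl, ph, verdict, anaerobic):
        resp = tc.classify_microenvironment(o2, gl, ph, params)
        assert resp.verdict == verdict
        assert resp.anaerobic == anaerobic

    def test_negative_input_rejected(self, params):
        with pytest.raises(ValueError):
            tc.classify_microenvironment(-0.1, 5.0, 7.0, params)

    @given(st.floats(0, 1), st.floats(0, 6), st.floats(5.0, 8.0))
    def test_scalar_matches_lattice_classification(self, o2, gl, ph):
        p = tc.ModelParams()
        fields = tc.MetabolicFields.uniform(3, p)
        fields.o2[:] = o2
        fields.gl[:] = gl
        fields.h[:] = tc.h_from_ph(ph)
        lattice = tc.dynamics.classify_lattice(fields, p)
        scalar = tc.classify_microenvironment(o2, gl, ph, p)
        assert lattice[0, 0] == int(scalar.verdict)


class TestDivisionProbability:
    def test_mutant_at_seed(self, params):
        assert tc.division_probability(True, 0.0, 0, params) == pytest.approx(0.7)

    def test_zero_at_and_beyond_rmax(self, params):
        for r in (params.rmax, params.rmax + 5):
            assert tc.division_probability(True, r, 8, params) == 0.0
            assert tc.division_probability(False, r, 8, params) == 0.0

    def test_nonmutant_needs_free_neighbors(self, params):
        assert tc.division_probability(False, 3.0, 0, params) == 0.0

    def test_nonmutant_full_neighborhood_at_seed(self, params):
        assert tc.division_probability(False, 0.0, 8, params) == pytest.approx(0.6)

    def test_negative_radius_rejected(self, params):
        with pytest.raises(ValueError):
            tc.division_probability(True, -1.0, 4, params)

    @given(st.booleans(), st.floats(0, 60), st.integers(0, 8))
    def test_bounded_probability(self, mutant, r, n):
        p = tc.ModelParams()
        prob = tc.division_probability(mutant, r, n, p)
        assert 0.0 <= prob <= 1.0

    @given(st.floats(0, 40), st.floats(0, 40), st.integers(0, 8))
    def test_non_increasing_in_radius(self, r1, r2, n):
        p = tc.ModelParams()
        lo, hi = sorted((r1, r2))
        for mutant in (True, False):
            assert (tc.division_probability(mutant, lo, n, p)
                    >= tc.division_probability(mutant, hi, n, p))

    @given(st.floats(0, 30), st.integers(0, 7))
    def test_non_decreasing_in_neighbors(self, r, n):
        p = tc.ModelParams()
        assert (tc.division_probability(False, r, n + 1, p)
                >= tc.division_probability(False, r, n, p))


class TestAttemptMitosis:
    def test_requires_pc_site(self, params, rng_streams):
        grid = tc.CellGrid.blank(9)
        with pytest.raises(ValueError):
            tc.attempt_mitosis((4, 4), grid, rng_streams, params)

    def test_surrounded_pc_stalls(self, params, rng_streams):
        grid = make_tumor_square(n=9, half=1)
        before = grid.stall[4, 4]
        tc.attempt_mitosis((4, 4), grid, rng_streams, params)
        assert grid.stall[4, 4] == before + 1
        assert grid.states[4, 4] == tc.PROLIFERATIVE

    def test_stall_allowance_reached_turns_quiescent(self, params, rng_streams):
        grid = make_tumor_square(n=9, half=1)
        p = params.replace(stall_limit=3, stall_growth=0.0)
        for _ in range(3):
            tc.attempt_mitosis((4, 4), grid, rng_streams, p, t=0)
        assert grid.states[4, 4] == tc.QUIESCENT
        assert grid.stall[4, 4] == 0

    def test_stall_allowance_grows_with_time(self, params):
        p = params.replace(stall_limit=5, stall_growth=0.5)
        assert stall_allowance(p, 0) == 5
        assert stall_allowance(p, 100) == 50

    @pytest.mark.parametrize("nmm,expect_mutant", [(0.0, True), (1.0, False)])
    def test_degenerate_phenotype_inheritance(self, params, nmm, expect_mutant):
        p = params.replace(nmm=nmm, p0=1.0)
        rng = tc.RngStreams.from_seed(5)
        for trial in range(200):
            grid = tc.CellGrid.blank(7)
            grid.states[3, 3] = tc.PROLIFERATIVE
            grid.mutant[3, 3] = True
            tc.attempt_mitosis((3, 3), grid, rng, p)
            daughters = (grid.states == tc.PROLIFERATIVE) & ~grid.mutant
            if expect_mutant:
                assert not daughters.any()
            else:
                assert daughters.sum() == 1

    def test_daughter_placed_on_free_neighbor(self, params, rng_streams):
        p = params.replace(p0=1.0)
        grid = tc.CellGrid.blank(7)
        grid.states[3, 3] = tc.PROLIFERATIVE
        grid.mutant[3, 3] = True
        tc.attempt_mitosis((3, 3), grid, rng_streams, p)
        assert grid.counts()["pc"] == 2
        pcs = np.argwhere(grid.states == tc.PROLIFERATIVE)
        assert np.abs(pcs - [3, 3]).max() <= 1

    def test_empirical_frequency_matches_probability(self, params):
        """Monte-Carlo: observed division rate within 3 SE of the formula."""
        n_trials = 100_000
        p = params
        # nonmutant PC at distance 5 from the seed with 3 free neighbors
        base = tc.CellGrid.blank(11, center=(4, 4))
        i, j = 4, 4 + 5  # r = 5 from center
        base.states[i, j] = tc.PROLIFERATIVE
        base.mutant[i, j] = False
        # block 5 of the 8 neighbors with necrotic cells -> 3 free
        blocked = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (1, -1)]
        for dr, dc in blocked:
            base.states[i + dr, j + dc] = tc.NECROTIC
        expected = tc.division_probability(False, 5.0, 3, p)
        rng = tc.RngStreams.from_seed(42)
        hits = 0
        for _ in range(n_trials):
            grid = base.copy()
            tc.attempt_mitosis((i, j), grid, rng, p, r=5.0)
            hits += int(grid.counts()["pc"] == 2)
        freq = hits / n_trials
        se = np.sqrt(expected * (1 - expected) / n_trials)
        assert abs(freq - expected) < 3 * se


class TestUpdateQuiescent:
    def test_requires_qc_site(self, params, rng_streams):
        grid = tc.CellGrid.blank(9)
        geom = compute_geometry(8.0, params)
        fields = tc.MetabolicFields.uniform(9, params)
        with pytest.raises(ValueError):
            tc.update_quiescent((4, 4), grid, fields, geom, params)

    def test_inside_necrotic_core_dies(self, params):
        # Rt = 8 gives Rn = 7.14; a QC at r = 2 is deep inside the core
        grid = tc.CellGrid.blank(21)
        grid.states[10, 12] = tc.QUIESCENT
        fields = tc.MetabolicFields.uniform(21, params)
        geom = compute_geometry(8.0, params)
        assert geom.rn == pytest.approx(7.14)
        new = tc.update_quiescent((10, 12), grid, fields, geom, params)
        assert new == tc.NECROTIC

    def test_rim_recovers_to_pc_with_phenotype(self, params):
        grid = tc.CellGrid.blank(21)
        grid.states[10, 18] = tc.QUIESCENT  # r = 8 = Rt, inside the rim band
        grid.mutant[10, 18] = True
        fields = tc.MetabolicFields.uniform(21, params)
        fields.o2[:] = 0.001  # nutrients alone would not rescue
        fields.o2[grid.states == 0] = 0.001
        geom = compute_geometry(8.0, params)
        new = tc.update_quiescent((10, 18), grid, fields, geom, params)
        assert new == tc.PROLIFERATIVE
        assert grid.mutant[10, 18]

    def test_sufficient_nutrients_rescue_mid_layer(self, params):
        # r = sqrt(5^2 + 10^2) = 11.18 with Rt = 12 lies between the core
        # radius (11.00) and the rim band start (11.42)
        grid = tc.CellGrid.blank(31)
        grid.states[20, 25] = tc.QUIESCENT
        fields = tc.MetabolicFields.uniform(31, params)
        geom = compute_geometry(12.0, params)
        assert geom.rn < np.hypot(5, 10) < geom.rt - geom.wp
        new = tc.update_quiescent((20, 25), grid, fields, geom, params)
        assert new == tc.PROLIFERATIVE

    def test_depleted_mid_layer_stays_quiescent(self, params):
        grid = tc.CellGrid.blank(31)
        grid.states[20, 25] = tc.QUIESCENT
        fields = tc.MetabolicFields.uniform(31, params)
        fields.o2[20, 25] = 0.015  # hypoxic but not lethal
        geom = compute_geometry(12.0, params)
        new = tc.update_quiescent((20, 25), grid, fields, geom, params)
        assert new == tc.QUIESCENT


class TestApplyNecrosis:
    def test_acidic_pc_dies(self, params):
        grid = tc.CellGrid.blank(5)
        grid.states[2, 2] = tc.PROLIFERATIVE
        fields = tc.MetabolicFields.uniform(5, params)
        fields.h[2, 2] = tc.h_from_ph(5.5)
        tc.apply_necrosis(grid, fields, params)
        assert grid.states[2, 2] == tc.NECROTIC

    def test_necrotic_cells_never_change(self, params):
        grid = tc.CellGrid.blank(5)
        grid.states[2, 2] = tc.NECROTIC
        fields = tc.MetabolicFields.uniform(5, params)  # benign everywhere
        tc.apply_necrosis(grid, fields, params)
        assert grid.states[2, 2] == tc.NECROTIC

    def test_normal_cell_apoptoses_to_empty(self, params):
        grid = tc.CellGrid.blank(5)
        fields = tc.MetabolicFields.uniform(5, params)
        fields.o2[1, 1] = 0.001
        tc.apply_necrosis(grid, fields, params)
        assert grid.states[1, 1] == tc.NORMAL
        assert grid.empty[1, 1]

    def test_normal_death_config_toggle(self, params):
        p = params.replace(normal_death="necrotic")
        grid = tc.CellGrid.blank(5)
        fields = tc.MetabolicFields.uniform(5, p)
        fields.o2[1, 1] = 0.001
        tc.apply_necrosis(grid, fields, p)
        assert grid.states[1, 1] == tc.NECROTIC
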