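"""Per-cell rules: ATP arithmetic, necrosis, hypoxia bands, division."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tumorpet.cells import (
    atp_rate,
    attempt_division,
    death_probability,
    division_probability,
    oxygenation_state,
    survival_step,
    update_agents,
)
from tumorpet.params import PhenotypeConfig, get_preset
from tumorpet.pde import make_field
from tumorpet.world import AgentGrid, CellState


class TestAtpRate:
    @pytest.mark.parametrize(
        "f_G,f_O,expected",
        [
            (5e-14, 4e-15, 1.216e-13),    # normoxic tumor at saturating glucose
            (0.0, 0.0, 0.0),
            (1.02e-13, 2e-15, 2.148e-13),  # hypoxic tumor at saturating glucose
        ],
    )
    def test_hand_arithmetic(self, f_G, f_O, expected):
        assert atp_rate(f_G, f_O) == pytest.approx(expected, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            atp_rate(-1e-15, 0.0)


class TestDeathProbability:
    def test_at_threshold_zero(self):
        assert death_probability(1.0, 1.0, 2.0) == 0.0

    def test_at_zero_local_always_one(self):
        for x in (0.5, 1.0, 2.0, 7.0):
            assert death_probability(0.0, 1.0, x) == 1.0

    def test_half_ratio_squared(self):
        # 1 − R² at R = 0.5
        assert death_probability(0.5, 1.0, 2.0) == pytest.approx(0.75)

    @settings(deadline=None, derandomize=True)
    @given(
        local=st.floats(0, 2),
        thr=st.floats(0.01, 2),
        x=st.floats(0.1, 10),
    )
    def test_always_a_probability_and_zero_above_threshold(self, local, thr, x):
        p = death_probability(local, thr, x)
        assert 0.0 <= p <= 1.0
        if local >= thr:
            assert p == 0.0

    @settings(deadline=None, derandomize=True)
    @given(thr=st.floats(0.5, 2), x=st.floats(0.5, 4))
    def test_monotone_decreasing_in_local_value(self, thr, x):
        values = np.linspace(0, thr, 20)
        probs = [death_probability(v, thr, x) for v in values]
        assert all(a >= b for a, b in zip(probs, probs[1:]))


class TestSurvivalStep:
    def test_survives_when_both_above_thresholds(self, bio):
        cfg = get_preset("A")
        rng = np.random.default_rng(0)
        for _ in range(200):
            out = survival_step(
                CellState.TUMOR_NORMOXIC, 50.0, 5e-3, cfg, bio, rng
            )
            assert out == CellState.TUMOR_NORMOXIC

    def test_anoxia_kills_with_certainty(self, bio):
        cfg = get_preset("A")
        rng = np.random.default_rng(1)
        out = survival_step(CellState.TUMOR_NORMOXIC, 0.0, 5e-3, cfg, bio, rng)
        assert out == CellState.TUMOR_NECROTIC

    def test_atp_death_rate_matches_closed_form(self, bio):
        # starve glucose so the ATP ratio R ≈ 0.5 with exponent 2 → p ≈ 0.75
        from tumorpet.cells import glucose_consumption_rate, oxygen_consumption_rate

        cfg = PhenotypeConfig(necrosis_exponent_atp=2.0)
        # find glucose giving f_ATP = 0.5 × threshold for a hypoxic tumor cell
        # (a normoxic cell's oxidative ATP alone is 84% of the threshold)
        target = 0.5 * bio.death_atp_rate
        f_o = oxygen_consumption_rate(CellState.TUMOR_HYPOXIC, bio)
        need_fg = (target - bio.atp_per_o2 * f_o) / bio.atp_per_glucose
        assert need_fg > 0
        glu = need_fg * bio.km_glucose_M / (bio.vmax_glucose_tumor_hypoxic - need_fg)
        o2 = 50.0  # above the O2 death threshold
        rng = np.random.default_rng(42)
        n = 100_000
        deaths = sum(
            survival_step(CellState.TUMOR_HYPOXIC, o2, glu, cfg, bio, rng)
            == CellState.TUMOR_NECROTIC
            for _ in range(n)
        )
        p_hat = deaths / n
        sigma = np.sqrt(0.75 * 0.25 / n)
        assert abs(p_hat - 0.75) < 3 * sigma


class TestOxygenationState:
    @pytest.mark.parametrize(
        "percent,expected",
        [
            (0.3, CellState.TUMOR_HYPOXIC),
            (1.0, CellState.TUMOR_NORMOXIC),
            (0.5, CellState.TUMOR_HYPOXIC),   # closed upper bound
            (0.08, CellState.TUMOR_HYPOXIC),  # closed lower bound
            (0.51, CellState.TUMOR_NORMOXIC),
        ],
    )
    def test_band_classification(self, percent, expected, bio):
        mmhg = percent * bio.mmhg_per_percent
        assert oxygenation_state(mmhg, bio) == expected


class TestDivisionProbability:
    def test_normoxic_rate_is_one_per_24h(self, bio):
        assert division_probability(50.0, bio) == pytest.approx(1 / 24)
        assert division_probability(bio.normoxia_ref_mmhg, bio) == pytest.approx(1 / 24)

    def test_scales_linearly_below_reference(self, bio):
        half = bio.normoxia_ref_mmhg / 2
        assert division_probability(half, bio) == pytest.approx(1 / 48)

    def test_anoxia_blocks_division(self, bio):
        assert division_probability(0.0, bio) == 0.0


class TestAttemptDivision:
    def _grid_with_center_tumor(self, neighborhood):
        states = np.array(neighborhood, dtype=np.uint8)
        states[1, 1] = int(CellState.TUMOR_NORMOXIC)
        return AgentGrid(states)

    def test_no_site_when_surrounded_by_tumor(self):
        g = self._grid_with_center_tumor(
            np.full((3, 3), int(CellState.TUMOR_HYPOXIC))
        )
        cfg = PhenotypeConfig(vessel_removal_prob=1.0)
        assert attempt_division((1, 1), g, cfg, np.random.default_rng(0)) is None

    def test_uniform_choice_among_normal_neighbors(self):
        # three NORMAL neighbors → each picked ~1/3 of the time
        base = np.full((3, 3), int(CellState.TUMOR_NECROTIC))
        base[0, 0] = base[0, 1] = base[2, 2] = int(CellState.NORMAL)
        cfg = PhenotypeConfig()
        rng = np.random.default_rng(7)
        counts = {(0, 0): 0, (0, 1): 0, (2, 2): 0}
        n = 10_000
        for _ in range(n):
            g = self._grid_with_center_tumor(base.copy())
            site = attempt_division((1, 1), g, cfg, rng)
            counts[site] += 1
        for c in counts.values():
            assert abs(c / n - 1 / 3) < 4 * np.sqrt((1 / 3) * (2 / 3) / n)

    def test_vessel_replaced_only_without_normal_and_with_probability(self):
        base = np.full((3, 3), int(CellState.TUMOR_NECROTIC))
        base[0, 0] = int(CellState.VESSEL)
        always = PhenotypeConfig(vessel_removal_prob=1.0)  # phenotype-F behavior
        g = self._grid_with_center_tumor(base.copy())
        assert attempt_division((1, 1), g, always, np.random.default_rng(1)) == (0, 0)
        never = PhenotypeConfig(vessel_removal_prob=0.0)
        g = self._grid_with_center_tumor(base.copy())
        assert attempt_division((1, 1), g, never, np.random.default_rng(1)) is None

    def test_normal_preferred_over_vessel(self):
        base = np.full((3, 3), int(CellState.VESSEL))
        base[2, 0] = int(CellState.NORMAL)
        g = self._grid_with_center_tumor(base.copy())
        cfg = PhenotypeConfig(vessel_removal_prob=1.0)
        assert attempt_division((1, 1), g, cfg, np.random.default_rng(2)) == (2, 0)


def rich_fields(grid, bio):
    o2 = make_field(grid, bio, "oxygen", init=50.0)
    glu = make_field(grid, bio, "glucose", init=5e-3)
    return o2, glu


class TestUpdateAgents:
    def test_no_tumor_cells_is_a_no_op(self, small_grid, bio):
        o2, glu = rich_fields(small_grid, bio)
        before = small_grid.states.copy()
        ev = update_agents(small_grid, o2, glu, get_preset("A"), bio, np.random.default_rng(0))
        np.testing.assert_array_equal(small_grid.states, before)
        assert ev["visited"] == 0

    def test_starved_cell_with_certain_death_necroses_in_one_step(self, bio):
        states = np.full((9, 9), int(CellState.NORMAL))
        states[4, 4] = int(CellState.TUMOR_NORMOXIC)
        grid = AgentGrid(states)
        o2 = make_field(grid, bio, "oxygen", init=0.0)
        glu = make_field(grid, bio, "glucose", init=0.0)
        update_agents(grid, o2, glu, get_preset("A"), bio, np.random.default_rng(3))
        assert grid.states[4, 4] == int(CellState.TUMOR_NECROTIC)

    def test_mean_first_division_time_is_24h(self, bio):
        # ~1000 well-fed founders on an isolating lattice; the waiting time
        # to the first division should be geometric with mean 24 h.
        n_side = 31
        spacing = 8
        size = n_side * spacing + spacing
        states = np.full((size, size), int(CellState.NORMAL))
        founders = [
            (spacing // 2 + i * spacing, spacing // 2 + j * spacing)
            for i in range(n_side)
            for j in range(n_side)
        ][:1000]
        for r, c in founders:
            states[r, c] = int(CellState.TUMOR_NORMOXIC)
        grid = AgentGrid(states)
        o2, glu = rich_fields(grid, bio)
        rng = np.random.default_rng(12345)
        cfg = get_preset("A")
        waits = np.zeros(len(founders))
        pending = set(range(len(founders)))
        neighborhoods = {
            k: [((r + dr) % size, (c + dc) % size) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
            for k, (r, c) in enumerate(founders)
        }
        for hour in range(1, 400):
            update_agents(grid, o2, glu, cfg, bio, rng)
            for k in list(pending):
                if any(
                    grid.states[p] in (2, 3) for p in neighborhoods[k]
                ):
                    waits[k] = hour
                    pending.discard(k)
            if not pending:
                break
        assert not pending
        # geometric(p=1/24): mean 24, sd √(1-p)/p ≈ 23.5
        se = np.sqrt(1 - 1 / 24) * 24 / np.sqrt(len(founders))
        assert abs(waits.mean() - 24.0) < 3 * se

    def test_necrotic_count_never_decreases(self, bio):
        grid = AgentGrid(np.full((40, 40), int(CellState.NORMAL)))
        grid.states[20, 20] = int(CellState.TUMOR_NORMOXIC)
        # marginal oxygen: deaths and divisions both happen
        o2 = make_field(grid, bio, "oxygen", init=0.5)
        glu = make_field(grid, bio, "glucose", init=2e-5)
        rng = np.random.default_rng(9)
        cfg = get_preset("C")
        prev = 0
        for _ in range(150):
            update_agents(grid, o2, glu, cfg, bio, rng)
            now = int((grid.states == int(CellState.TUMOR_NECROTIC)).sum())
            assert now >= prev
            prev = now

    def test_same_seed_bit_identical_trajectory(self, bio):
        def trajectory():
            grid = AgentGrid(np.full((30, 30), int(CellState.NORMAL)))
            grid.states[15, 15] = int(CellState.TUMOR_NORMOXIC)
            o2, glu = rich_fields(grid, bio)
            rng = np.random.default_rng(77)
            for _ in range(60):
                update_agents(grid, o2, glu, get_preset("B"), bio, rng)
            return grid.states

        np.testing.assert_array_equal(trajectory(), trajectory())

    def test_division_waiting_time_is_geometric(self, bio):
        # χ² goodness-of-fit of simulated waiting times against the geometric
        # law with hourly success probability 1/24.
        from scipy import stats as sps

        rng = np.random.default_rng(2718)
        p = division_probability(50.0, bio)
        n = 10_000
        waits = rng.geometric(p, size=n)  # closed-form reference sampler
        sim = []
        draws = rng.uniform(size=(n, 400))
        for row in draws:
            t = int(np.argmax(row < p)) + 1 if (row < p).any() else 400
            sim.append(t)
        sim = np.array(sim)
        # bin both into identical bins and compare observed vs geometric pmf
        edges = list(range(1, 73, 6)) + [1000]
        obs, _ = np.histogram(sim, bins=edges)
        k = np.arange(1, 1000)
        pmf = (1 - p) ** (k - 1) * p
        exp_probs = [
            pmf[(k >= lo) & (k < hi)].sum() for lo, hi in zip(edges[:-1], edges[1:])
        ]
        exp = np.array(exp_probs) * n
        chi2 = ((obs - exp) ** 2 / exp).sum()
        crit = sps.chi2.ppf(0.99, df=len(obs) - 1)
        assert chi2 < crit
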