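"""Time-stepping engine: stepping, deletion, mass loss, orderings."""

import dataclasses

import numpy as np
import pytest

import stentdamage as sd


def zero_field(n):
    return sd.load_stress_field(np.zeros(n), n)


def config(group="C1", dt=1.0, t_max=150.0, pitting=False, seed=0, **kw):
    corr = sd.CorrosionParams(pitting_enabled=pitting, rng_seed=seed if pitting else None)
    return sd.SimulationConfig(group=group, dt=dt, t_max=t_max, rng_seed=seed,
                               corrosion=corr, **kw)


class TestStep:
    def test_single_cube_uniform_increment(self):
        """One exposed 0.1 mm cube under standard kinetics: dD_U = 0.05 per hour."""
        m = sd.build_slab_mesh(1, 1, 1, 0.1)
        state = sd.init_state(m, zero_field(1), config())
        sd.step(state)
        assert state.D_U[0] == pytest.approx(0.05)
        assert state.D_SC[0] == state.D_P[0] == state.D_f[0] == 0.0

    def test_single_cube_lifetime_twenty_hours(self):
        m = sd.build_slab_mesh(1, 1, 1, 0.1)
        state = sd.init_state(m, zero_field(1), config())
        for _ in range(19):
            sd.step(state)
            assert state.alive[0]
        sd.step(state)
        assert not state.alive[0]
        assert state.removed_log == [(pytest.approx(20.0), 0)]

    def test_control_group_gates_fatigue_off(self):
        """Fatigue parameters present but group C1: D_f stays zero."""
        m = sd.build_slab_mesh(1, 1, 1, 0.1)
        f = sd.load_stress_field(np.array([200.0]), 1)
        state = sd.init_state(m, f, config(group="C1"))
        for _ in range(5):
            sd.step(state)
        assert state.D_f[0] == 0.0
        assert state.D_SC[0] > 0.0  # stress corrosion active above threshold

    def test_coupled_group_accrues_fatigue(self):
        m = sd.build_slab_mesh(1, 1, 1, 0.1)
        f = sd.load_stress_field(np.array([200.0]), 1)
        state = sd.init_state(m, f, config(group="E2", dt=0.1))
        sd.step(state)
        assert state.D_f[0] > 0.0

    def test_stress_corrosion_in_unexposed_elements(self):
        """Stress corrosion needs no surface: the buried centre element of a
        3x3x3 cube accrues D_SC when stressed above threshold."""
        m = sd.build_slab_mesh(3, 3, 3, 0.1)
        f = sd.load_stress_field(np.full(27, 100.0), 27)
        state = sd.init_state(m, f, config(dt=0.1))
        sd.step(state)
        center = 13
        assert not state.exposed[center]
        assert state.D_SC[center] > 0.0
        assert state.D_U[center] == 0.0  # uniform corrosion is surface-only


class TestRun:
    def test_end_exposed_slab_layer_peeling(self):
        """5-layer column corroding from one end: one layer per 20 h, full
        degradation at 100 h (the analytic layer-peeling oracle)."""
        m = sd.build_slab_mesh(5, 1, 1, 0.1)
        m.sealed_faces = sd.seal_all_but_axis_ends(m, axis=0, ends=("min",))
        res = sd.run(config(dt=1.0, t_max=150.0), m, zero_field(5))
        assert res.removed_log == [(pytest.approx(20.0 * (i + 1)), i) for i in range(5)]
        assert res.final_mass_loss == pytest.approx(1.0)

    def test_both_ends_exposed_cascade(self):
        """With both ends open the front advances from both sides: layers die
        at 20, 40, 60 h (5-layer column finishes in 60 h, not 100)."""
        m = sd.build_slab_mesh(5, 1, 1, 0.1)
        m.sealed_faces = sd.seal_all_but_axis_ends(m, axis=0)
        res = sd.run(config(dt=1.0, t_max=150.0), m, zero_field(5))
        times = sorted(t for t, _ in res.removed_log)
        assert times == [pytest.approx(v) for v in (20, 20, 40, 40, 60)]

    def test_front_time_scales_linearly_with_layers(self):
        for nx in (2, 4, 6):
            m = sd.build_slab_mesh(nx, 1, 1, 0.1)
            m.sealed_faces = sd.seal_all_but_axis_ends(m, axis=0, ends=("min",))
            res = sd.run(config(dt=1.0, t_max=400.0), m, zero_field(nx))
            assert res.time_grid[np.argmax(res.mass_loss_fraction >= 1.0)] == pytest.approx(20.0 * nx)

    def test_dt_refinement_consistency(self):
        """Halving dt moves the total degradation time by at most one coarse dt."""
        m = sd.build_slab_mesh(3, 1, 1, 0.1)
        m.sealed_faces = sd.seal_all_but_axis_ends(m, axis=0, ends=("min",))
        totals = {}
        for dt in (0.8, 0.4):
            res = sd.run(config(dt=dt, t_max=120.0), m, zero_field(3))
            totals[dt] = res.time_grid[np.argmax(res.mass_loss_fraction >= 1.0)]
        assert abs(totals[0.8] - totals[0.4]) <= 0.8 + 1e-9

    def test_mass_loss_non_decreasing_and_conserving(self, ring):
        field = sd.analytic_crown_field(ring)
        res = sd.run(config(group="E2", dt=0.05, t_max=40.0, pitting=True, seed=3), ring, field)
        assert np.all(np.diff(res.mass_loss_fraction) >= 0)
        assert res.mass_loss_fraction[0] == 0.0
        assert res.mass_loss_fraction[-1] <= 1.0

    def test_volume_conservation_exact(self, ring):
        field = sd.analytic_crown_field(ring)
        cfg = config(group="C1", dt=0.05, t_max=5.0, pitting=True, seed=5)
        state = sd.init_state(ring, field, cfg)
        total = ring.element_volume.sum()
        for _ in range(60):
            sd.step(state)
            removed = ring.element_volume[~state.alive].sum()
            alive_v = ring.element_volume[state.alive].sum()
            assert removed + alive_v == pytest.approx(total, rel=1e-14)

    def test_damage_components_non_decreasing(self, ring):
        field = sd.analytic_crown_field(ring)
        cfg = config(group="E2", dt=0.05, t_max=5.0, pitting=True, seed=5)
        state = sd.init_state(ring, field, cfg)
        prev = [state.D_U.copy(), state.D_SC.copy(), state.D_P.copy(), state.D_f.copy()]
        for _ in range(60):
            sd.step(state)
            cur = [state.D_U, state.D_SC, state.D_P, state.D_f]
            for a, b in zip(prev, cur):
                assert np.all(b >= a - 1e-15)
            prev = [c.copy() for c in cur]

    def test_determinism_bit_identical(self, ring):
        field = sd.analytic_crown_field(ring)
        cfg = config(group="E2", dt=0.05, t_max=10.0, pitting=True, seed=11)
        r1 = sd.run(cfg, ring, field)
        r2 = sd.run(cfg, ring, field)
        assert r1.removed_log == r2.removed_log
        assert np.array_equal(r1.mass_loss_fraction, r2.mass_loss_fraction)

    def test_field_mesh_mismatch_rejected(self, ring):
        with pytest.raises(ValueError):
            sd.run(config(), ring, zero_field(3))

    def test_missing_seed_for_pitting_rejected(self, ring):
        cfg = sd.SimulationConfig(group="C1", dt=1.0, t_max=10.0, rng_seed=None)
        with pytest.raises(ValueError):
            sd.init_state(ring, sd.analytic_crown_field(ring), cfg)

    def test_pit_propagation_into_reexposed_elements(self):
        """When a pitted surface element dies, the interior element it
        uncovers inherits beta * lambda of the removed pit."""
        m = sd.build_slab_mesh(3, 1, 1, 0.1)
        m.sealed_faces = sd.seal_all_but_axis_ends(m, axis=0, ends=("min",))
        cfg = config(dt=1.0, t_max=100.0, pitting=True, seed=21)
        state = sd.init_state(m, zero_field(3), cfg)
        lam0 = state.lam[0]
        assert lam0 > 0.0
        assert state.lam[1] == 0.0  # interior: no initial draw
        while state.alive[0]:
            sd.step(state)
        assert state.lam[1] == pytest.approx(0.8 * lam0)


@pytest.fixture(scope="module")
def paired_runs():
    ring = sd.build_ring_stent_mesh(n_crowns=6, elements_per_segment=6)
    field = sd.analytic_crown_field(ring, peak_stress=230.0, decay=0.5)
    out = {}
    for g in ("C1", "E1", "E2"):
        cfg = config(group=g, dt=0.005, t_max=40.0, pitting=True, seed=7)
        out[g] = sd.run(cfg, ring, field)
    return ring, out


class TestGroupOrderings:
    def test_first_deletions_in_crown_region(self, paired_runs):
        ring, out = paired_runs
        corolla = set(ring.element_set_labels["corolla"].tolist())
        for res in out.values():
            t0 = res.removed_log[0][0]
            first = {e for t, e in res.removed_log if t == t0}
            assert first <= corolla

    def test_pulsatile_accelerates_mass_loss(self, paired_runs):
        _, out = paired_runs
        n = min(len(r.mass_loss_fraction) for r in out.values())
        assert np.all(out["C1"].mass_loss_fraction[:n] <= out["E1"].mass_loss_fraction[:n] + 1e-12)

    def test_fatigue_accelerates_mass_loss(self, paired_runs):
        _, out = paired_runs
        n = min(len(r.mass_loss_fraction) for r in out.values())
        assert np.all(out["E1"].mass_loss_fraction[:n] <= out["E2"].mass_loss_fraction[:n] + 1e-12)

    def test_fracture_time_ordering(self, paired_runs):
        _, out = paired_runs
        fr = {g: r.fracture_time for g, r in out.items()}
        assert all(v is not None for v in fr.values())
        assert fr["C1"] >= fr["E1"] >= fr["E2"]

    def test_run_continues_past_fracture(self, paired_runs):
        _, out = paired_runs
        for res in out.values():
            assert res.time_grid[-1] > res.fracture_time
            idx = np.searchsorted(res.time_grid, res.fracture_time)
            assert res.mass_loss_fraction[-1] > res.mass_loss_fraction[idx]


class TestMassLossAndRegionStress:
    def test_mass_loss_fractions(self, ring):
        alive = np.ones(ring.n_elements, bool)
        assert sd.mass_loss(ring, alive) == 0.0
        assert sd.mass_loss(ring, ~alive) == 1.0

    def test_equal_volume_quarter(self):
        m = sd.build_slab_mesh(12, 1, 1, 0.1)
        alive = np.ones(12, bool)
        alive[:3] = False
        assert sd.mass_loss(m, alive) == pytest.approx(0.25)

    def test_region_mean_undamaged(self):
        m = sd.build_slab_mesh(4, 1, 1, 0.1)
        f = sd.load_stress_field(np.full(4, 100.0), 4)
        state = sd.init_state(m, f, config())
        assert sd.region_mean_effective_stress(range(4), state) == pytest.approx(100.0)

    def test_region_mean_discounted_by_damage(self):
        m = sd.build_slab_mesh(4, 1, 1, 0.1)
        f = sd.load_stress_field(np.full(4, 100.0), 4)
        state = sd.init_state(m, f, config())
        state.D_U[:] = 0.2
        assert sd.region_mean_effective_stress(range(4), state) == pytest.approx(80.0)

    def test_region_mean_linear_decrease_during_run(self):
        """The reported effective stress of a region falls as it degrades —
        the material-integrity readout decays with damage."""
        m = sd.build_slab_mesh(4, 1, 1, 0.1)
        f = sd.load_stress_field(np.full(4, 50.0), 4)  # below sigma_th: uniform only
        state = sd.init_state(m, f, config(dt=0.5))
        means = [sd.region_mean_effective_stress(range(4), state)]
        for _ in range(10):
            sd.step(state)
            means.append(sd.region_mean_effective_stress(range(4), state))
        assert all(b < a for a, b in zip(means, means[1:]))

    def test_region_fully_degraded_reports_absent(self):
        m = sd.build_slab_mesh(2, 1, 1, 0.1)
        f = sd.load_stress_field(np.full(2, 100.0), 2)
        state = sd.init_state(m, f, config())
        state.alive[:] = False
        assert sd.region_mean_effective_stress(range(2), state) is None
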