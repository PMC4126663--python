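"""Engine layer: SSA correctness, events, growth couplings, determinism."""

import numpy as np
import pytest

from conftest import birth_death_network, make_toy_network
from lysolatch.engine import (
    EventSchedule,
    GrowthModel,
    derive_seeds,
    event_schedule,
    genome_copies,
    integrate_deterministic,
    phage_copies,
    read_trajectory_tsv,
    run_ensemble,
    simulate_ssa,
    write_trajectory_tsv,
)
from lysolatch.model import (
    CellConfig,
    Reaction,
    VariantFlags,
    build_network,
    default_parameters,
)


class TestPhageCopies:
    @pytest.mark.parametrize(
        "m0,t,expected",
        [(1, 0, 1), (1, 2.9, 1), (1, 3, 2), (1, 7, 4), (1, 15, 32), (1, 60, 32), (2, 6, 8)],
    )
    def test_doubling_schedule(self, m0, t, expected):
        assert phage_copies(m0, t) == expected

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            phage_copies(1, 1.0, doubling_period=0)
        with pytest.raises(ValueError):
            phage_copies(0, 1.0)


class TestDeterministicIntegrator:
    def test_birth_death_closed_form(self, params):
        net = birth_death_network(10.0, 1.0)
        cfg = CellConfig(moi=1, volume=1.0)
        det = integrate_deterministic(net, cfg, params, 10.0)
        i5 = np.argmin(np.abs(det.times - 5.0))
        assert det.counts[i5, 0] == pytest.approx(10 * (1 - np.exp(-5.0)), rel=1e-6)

    def test_all_rates_zero_constant_solution(self, params):
        net = make_toy_network(
            [Reaction("r", {"X": 1}, {}, 0.0, "k", 1, 0, "test")], ["X"], {"X": 7}
        )
        cfg = CellConfig(moi=1)
        det = integrate_deterministic(net, cfg, params, 5.0)
        assert np.allclose(det.counts[:, 0], 7.0)

    def test_volume_neutrality_of_concentrations(self, params):
        """(MOI, V) -> (2 MOI, 2 V) leaves every concentration trajectory fixed."""
        c1 = CellConfig(moi=1, volume=1.0)
        c2 = CellConfig(moi=2, volume=2.0)
        d1 = integrate_deterministic(build_network(params, c1), c1, params, 60.0)
        d2 = integrate_deterministic(build_network(params, c2), c2, params, 60.0)
        conc1 = d1.counts / d1.volumes[:, None]
        conc2 = d2.counts / d2.volumes[:, None]
        assert np.max(np.abs(conc1 - conc2)) < 1e-5


class TestSSA:
    def test_same_seed_bit_identical(self, params):
        cfg = CellConfig(moi=2, volume=2.0)
        net = build_network(params, cfg)
        a = simulate_ssa(net, cfg, params, 30.0, seed=7)
        b = simulate_ssa(net, cfg, params, 30.0, seed=7)
        assert np.array_equal(a.counts, b.counts)
        c = simulate_ssa(net, cfg, params, 30.0, seed=8)
        assert not np.array_equal(a.counts, c.counts)

    def test_all_rates_zero_state_constant(self, params):
        net = make_toy_network(
            [Reaction("r", {"X": 1}, {}, 0.0, "k", 1, 0, "test")], ["X"], {"X": 5}
        )
        traj = simulate_ssa(net, CellConfig(moi=1), params, 20.0, seed=1)
        assert np.all(traj.counts[:, 0] == 5)

    def test_grid_alignment_with_offgrid_events(self, params):
        """Output grid stays 0, dt, ..., T even when events fall between samples."""
        cfg = CellConfig(moi=2, volume=1.0, infection_offsets=(0.0, 3.37))
        net = build_network(params, cfg)
        traj = simulate_ssa(net, cfg, params, 12.0, seed=3)
        assert np.allclose(traj.times, np.arange(0, 12.0 + 1e-9, params.output_interval))

    def test_birth_death_stationary_moments(self, params):
        """CME oracle: stationary distribution is Poisson(birth/death)."""
        net = birth_death_network(10.0, 1.0)
        cfg = CellConfig(moi=1)
        vals, _ = run_ensemble(
            net, cfg, params, T=60.0, n=800, seed=11, reduce=lambda tr: tr.counts[-1, 0]
        )
        arr = np.asarray(vals, dtype=float)
        se = arr.std(ddof=1) / np.sqrt(arr.size)
        assert abs(arr.mean() - 10.0) < 3 * se
        fano = arr.var(ddof=1) / arr.mean()
        assert abs(fano - 1.0) < 3 * np.sqrt(2 / arr.size) * 1.5

    def test_infection_event_adds_genome_at_exact_time(self, params):
        cfg = CellConfig(moi=2, volume=1.0, infection_offsets=(0.0, 10.0))
        net = build_network(params, cfg)
        traj = simulate_ssa(net, cfg, params, 20.0, seed=5)
        g = genome_copies(traj, net)
        assert np.all(g[traj.times < 10.0] == 1)
        assert np.all(g[traj.times >= 10.0] == 2)

    def test_replication_matches_phage_copies_everywhere(self, params):
        for moi in (1, 2):
            cfg = CellConfig(
                moi=moi, volume=1.0, variants=VariantFlags(phage_replication=True)
            )
            net = build_network(params, cfg)
            traj = simulate_ssa(net, cfg, params, 30.0, seed=9)
            g = genome_copies(traj, net)
            expected = [phage_copies(moi, t) for t in traj.times]
            assert np.array_equal(g, expected)


class TestGrowth:
    def test_dilution_decays_isolated_species(self, params):
        """With only dilution acting, mean count follows x0 exp(-g t)."""
        net = make_toy_network([], ["X"], {"X": 200})
        g = 0.05
        cfg = CellConfig(moi=1, volume=1.0)
        growth = GrowthModel(rate=g, dilution=True, volume_growth=False)
        vals, _ = run_ensemble(
            net, cfg, params, T=20.0, n=400, seed=13, growth=growth,
            reduce=lambda tr: tr.counts[-1, 0],
        )
        arr = np.asarray(vals, dtype=float)
        expected = 200 * np.exp(-g * 20.0)
        se = arr.std(ddof=1) / np.sqrt(arr.size)
        assert abs(arr.mean() - expected) < 3 * se

    def test_promoters_are_not_diluted(self, params):
        cfg = CellConfig(moi=2, volume=1.0)
        net = build_network(params, cfg)
        growth = GrowthModel(rate=0.02)
        traj = simulate_ssa(net, cfg, params, 30.0, seed=4, growth=growth)
        assert np.all(genome_copies(traj, net) == 2)

    def test_volume_growth_recorded(self, params):
        cfg = CellConfig(moi=1, volume=1.0)
        net = build_network(params, cfg)
        growth = GrowthModel(rate=0.01, volume_growth=True)
        traj = simulate_ssa(net, cfg, params, 10.0, seed=2, growth=growth)
        assert np.allclose(traj.volumes, np.exp(0.01 * traj.times), rtol=1e-9)

    def test_tx_multiplier_interpolation(self):
        gm = GrowthModel(rate=0.0, tx_coupling=True)
        assert gm.tx_multiplier(gm.g_slow) == pytest.approx(2.0)
        assert gm.tx_multiplier(gm.g_fast) == pytest.approx(1.0)
        mid = 0.5 * (gm.g_slow + gm.g_fast)
        assert gm.tx_multiplier(mid) == pytest.approx(1.5)


class TestEnsemble:
    def test_single_run_summary_degenerates(self, params):
        cfg = CellConfig(moi=1)
        net = build_network(params, cfg)
        trajs, summ = run_ensemble(net, cfg, params, 10.0, n=1, seed=21)
        assert np.array_equal(summ.mean, trajs[0].counts.astype(float))
        assert np.all(summ.sd == 0)

    def test_summary_reproducible(self, params):
        cfg = CellConfig(moi=1)
        net = build_network(params, cfg)
        _, s1 = run_ensemble(net, cfg, params, 10.0, n=20, seed=33, keep_trajectories=False)
        _, s2 = run_ensemble(net, cfg, params, 10.0, n=20, seed=33, keep_trajectories=False)
        assert np.array_equal(s1.mean, s2.mean) and np.array_equal(s1.sd, s2.sd)

    def test_seed_stream_is_counter_based(self):
        assert np.array_equal(derive_seeds(5, 10)[:5], derive_seeds(5, 5))
        assert np.all(derive_seeds(5, 1000) >= 0)
        assert np.all(derive_seeds(5, 1000) < 2**31)

    def test_extrinsic_noise_changes_between_cells(self, params):
        flags = VariantFlags(extrinsic_noise_cv=0.5)
        cfg = CellConfig(moi=1, variants=flags)
        net = build_network(params, cfg)
        vals, _ = run_ensemble(
            net, cfg, params, 30.0, n=40, seed=17,
            reduce=lambda tr: tr.counts[-1, tr.species_index("Cro")],
        )
        flat = CellConfig(moi=1)
        vals0, _ = run_ensemble(
            build_network(params, flat), flat, params, 30.0, n=40, seed=17,
            reduce=lambda tr: tr.counts[-1, tr.species_index("Cro")],
        )
        assert np.var(vals) > np.var(vals0)  # extrinsic variability adds spread


class TestEventSchedule:
    def test_schedule_contents(self):
        cfg = CellConfig(
            moi=2, volume=1.0, infection_offsets=(0.0, 4.0),
            variants=VariantFlags(phage_replication=True),
        )
        sched = event_schedule(cfg)
        assert sched.infection_events == ((4.0, 1),)
        times, increments = zip(*sched.replication_events)
        assert times == (3.0, 6.0, 9.0, 12.0, 15.0)
        assert sum(increments) + 2 == phage_copies(2, 15.0)

    def test_merged_sorted(self):
        s = EventSchedule(infection_events=((5.0, 1),), replication_events=((3.0, 2),))
        assert s.merged() == [(3.0, 2), (5.0, 1)]


class TestTrajectoryIO:
    def test_tsv_roundtrip(self, params, tmp_path):
        cfg = CellConfig(moi=1)
        net = build_network(params, cfg)
        traj = simulate_ssa(net, cfg, params, 5.0, seed=1)
        path = tmp_path / "traj.tsv"
        write_trajectory_tsv(traj, path)
        back = read_trajectory_tsv(path)
        assert back.species == traj.species
        assert np.array_equal(back.counts, traj.counts)
        assert np.allclose(back.times, traj.times)
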