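import numpy as np
import pytest

from uwheel.errors import ConfigError, EmptySwarmError, PathError
from uwheel.network import find_path, path_profile, profile_incline_at
from uwheel.physics import wheel_velocity
from uwheel.swarm import get_mode
from uwheel.synthetic import gen_swarm, mca_network
from uwheel.targeting import (
    SimConfig,
    advance_step,
    centroid_and_sigma,
    clip_at_turn,
    simulate_targeting,
)


def make_swarm(params, n=10, seed=0, mode="rolling"):
    return gen_swarm(mode, n, seed=seed, params=params)


class TestAdvanceStep:
    def test_constant_incline_is_exact_ballistic(self, params, straight_net):
        prof = path_profile(straight_net, find_path(straight_net))
        s = make_swarm(params, n=5, seed=1)
        V = wheel_velocity(s.R, 0.0, s.omega, params)
        dt, k = 0.1, 25
        for _ in range(k):
            advance_step(s, prof, params, dt)
        np.testing.assert_allclose(s.x, np.asarray(V) * dt * k, rtol=1e-12)
        assert s.t == pytest.approx(k * dt)

    def test_dead_wheels_do_not_move(self, params, straight_net):
        prof = path_profile(straight_net, find_path(straight_net))
        s = make_swarm(params, n=4, seed=2)
        s.alive[1] = False
        s.x[1] = 3e-3
        advance_step(s, prof, params, 0.1)
        assert s.x[1] == 3e-3

    def test_zero_velocity_wheel_stays_put(self, params, straight_net):
        prof = path_profile(straight_net, find_path(straight_net))
        s = gen_swarm(
            get_mode("rolling", velocity_multiplier=0.0), 3, seed=3, params=params
        )
        s.x[:] = 2e-3
        advance_step(s, prof, params, 0.1)
        assert np.all(s.x == 2e-3)

    def test_two_segment_path_matches_independent_reintegration(
        self, params, toy_net
    ):
        # oracle: explicit per-step loop with scalar interpolation + velocity
        plan = find_path(toy_net)
        prof = path_profile(toy_net, plan)
        s = make_swarm(params, n=1, seed=4)
        dt, steps = 0.1, 300
        x_oracle = 0.0
        R, omega = float(s.R[0]), float(s.omega[0])
        for _ in range(steps):
            phi = profile_incline_at(prof, min(max(x_oracle, 0.0), prof.end_x))
            v = wheel_velocity(R, phi, omega, params)
            x_oracle = max(x_oracle + v * dt, 0.0)
        for _ in range(steps):
            advance_step(s, prof, params, dt)
        assert s.x[0] == pytest.approx(x_oracle, rel=1e-12)

    def test_backward_slip_floored_at_injection_wall(self, params):
        # steep everywhere: large wheels slide downhill but never below x=0
        from uwheel.network import Junction, Network, check_network

        net = check_network(
            Network(
                junctions={
                    "A": Junction("A", 0.0, 80.0),
                    "B": Junction("B", 20e-3, 80.0, kind="terminal"),
                },
                branches={"b": ("A", "B")},
                root="b",
                target="b",
            )
        )
        prof = path_profile(net, find_path(net))
        s = make_swarm(params, n=20, seed=5)
        s.R[:] = 60e-6  # all large: negative V at 80 deg
        from uwheel.physics import rotation_rate

        s.omega[:] = rotation_rate(s.R, params.bead, params.fluid, params.field)
        for _ in range(50):
            advance_step(s, prof, params, 0.1)
        assert np.all(s.x >= 0.0)
        assert np.all(s.x == 0.0)


class TestCentroidAndSigma:
    def test_equal_masses_hand_value(self, params):
        s = make_swarm(params, n=2, seed=6)
        s.mass[:] = 5e-12
        s.x[:] = [1e-3, 3e-3]
        mean, sigma = centroid_and_sigma(s)
        assert mean == pytest.approx(2e-3, rel=1e-12)
        assert sigma == pytest.approx(1e-3, rel=1e-12)

    def test_single_wheel_zero_sigma(self, params):
        s = make_swarm(params, n=1, seed=7)
        s.x[0] = 4e-3
        mean, sigma = centroid_and_sigma(s)
        assert (mean, sigma) == (4e-3, 0.0)

    def test_hundred_wheels_vs_textbook_moments(self, params, rng):
        s = make_swarm(params, n=100, seed=8)
        s.x[:] = rng.uniform(0, 10e-3, 100)
        mean, sigma = centroid_and_sigma(s)
        w, x = s.mass, s.x
        mean_o = sum(wi * xi for wi, xi in zip(w, x)) / sum(w)
        var_o = sum(wi * (xi - mean_o) ** 2 for wi, xi in zip(w, x)) / sum(w)
        assert mean == pytest.approx(mean_o, rel=1e-12)
        assert sigma == pytest.approx(var_o**0.5, rel=1e-12)

    def test_no_alive_wheels_rejected(self, params):
        s = make_swarm(params, n=3, seed=9)
        s.alive[:] = False
        with pytest.raises(EmptySwarmError):
            centroid_and_sigma(s)


class TestClipAtTurn:
    def test_zero_sigma_swarm_fully_survives(self, params):
        s = make_swarm(params, n=6, seed=10)
        s.x[:] = 5e-3
        _, lost_t, lost_p = clip_at_turn(s, 5e-3, parallel_offsets=(5.2e-3,))
        assert lost_t == lost_p == 0.0
        assert s.alive.all()

    def test_hand_built_survivor_set(self, params):
        # turn at 10 mm; equal masses at 6,9,10,11,14 mm
        # centroid 10 mm, sigma = sqrt(mean([16,1,0,1,16])) mm = 2.608 mm
        # keep window +-1.304 mm -> survivors at 9,10,11
        # parallel mouth at 14.5 mm: |14-14.5| = 0.5 < 1.304 -> wheel at 14
        # is lost to the parallel channel, wheel at 6 lost at the turn
        s = make_swarm(params, n=5, seed=11)
        s.mass[:] = 1e-12
        s.x[:] = np.array([6, 9, 10, 11, 14]) * 1e-3
        _, lost_t, lost_p = clip_at_turn(
            s, 10e-3, parallel_offsets=(14.5e-3,), sigma_keep=0.5
        )
        assert list(s.alive) == [False, True, True, True, False]
        assert lost_t == pytest.approx(1e-12)
        assert lost_p == pytest.approx(1e-12)
        assert s.branch[4].endswith("parallel")
        assert s.branch[0].endswith("turn")

    def test_no_parallel_offsets_only_window_rule(self, params):
        s = make_swarm(params, n=5, seed=12)
        s.mass[:] = 1e-12
        s.x[:] = np.array([6, 9, 10, 11, 14]) * 1e-3
        _, lost_t, lost_p = clip_at_turn(s, 10e-3, parallel_offsets=())
        assert lost_p == 0.0
        assert lost_t == pytest.approx(2e-12)

    def test_parallel_precedence_is_conservative(self, params):
        # wheel inside BOTH windows is lost under the conservative default
        # and kept when precedence is disabled
        for precedence, expect_alive in [(True, False), (False, True)]:
            s = make_swarm(params, n=3, seed=13)
            s.mass[:] = 1e-12
            s.x[:] = np.array([8, 10, 12]) * 1e-3
            clip_at_turn(
                s, 10e-3, parallel_offsets=(10.1e-3,),
                parallel_precedence=precedence,
            )
            assert bool(s.alive[1]) is expect_alive


class TestSimulateTargeting:
    def test_single_wheel_flat_no_turns_full_delivery(self, params, straight_net):
        s = make_swarm(params, n=1, seed=14)
        res = simulate_targeting(s, straight_net, params)
        assert res.termination == "reached"
        assert res.efficiency == 1.0
        assert res.per_junction_losses == {}

    def test_two_turn_toy_matches_independent_reimplementation(
        self, params, toy_net
    ):
        cfg = SimConfig()
        s1 = make_swarm(params, n=60, seed=15)
        res = simulate_targeting(s1, toy_net, params, cfg)

        # oracle: independent loop-free reimplementation of the protocol
        s = make_swarm(params, n=60, seed=15)
        prof = path_profile(toy_net, find_path(toy_net))
        total = s.total_mass
        lost = 0.0
        for turn in prof.turns:
            while True:
                w, x = s.mass[s.alive], s.x[s.alive]
                mean = np.sum(w * x) / w.sum()
                if mean > turn.x:
                    break
                phi = np.interp(np.clip(s.x, 0, prof.end_x), prof.xs, prof.phis)
                v = np.asarray(wheel_velocity(s.R, phi, s.omega, params))
                s.x[s.alive] = np.maximum(s.x[s.alive] + v[s.alive] * cfg.dt, 0)
            w, x = s.mass[s.alive], s.x[s.alive]
            mean = np.sum(w * x) / w.sum()
            sigma = np.sqrt(np.sum(w * (x - mean) ** 2) / w.sum())
            if sigma > 0:
                half = cfg.sigma_keep * sigma
                keep = np.abs(s.x - turn.x) <= half
                par = np.zeros(len(s.x), bool)
                for p_off in turn.parallel_offsets:
                    par |= np.abs(s.x - p_off) <= half
                newly_lost = s.alive & ~(keep & ~par)
                lost += s.mass[newly_lost].sum()
                s.alive &= keep & ~par
        expected_eff = (total - lost) / total

        assert res.termination == "reached"
        assert res.efficiency == pytest.approx(expected_eff, rel=1e-12)

    def test_mass_conservation_invariant(self, params, toy_net):
        s = make_swarm(params, n=50, seed=16)
        res = simulate_targeting(s, toy_net, params)
        balance = res.efficiency + res.total_loss_fraction + res.residual_fraction
        assert balance == pytest.approx(1.0, abs=1e-12)

    def test_efficiency_non_increasing_in_turns(self, params):
        effs = []
        for b in ["branch1", "branch2", "branch3", "branch4", "branch5"]:
            s = make_swarm(params, n=300, seed=17)
            res = simulate_targeting(s, mca_network(b), params)
            effs.append(res.efficiency)
        assert np.all(np.diff(effs) <= 1e-12)

    def test_determinism_bit_identical(self, params, toy_net):
        r1 = simulate_targeting(make_swarm(params, n=60, seed=18), toy_net, params)
        r2 = simulate_targeting(make_swarm(params, n=60, seed=18), toy_net, params)
        assert r1.to_dict() == r2.to_dict()

    def test_tighter_keep_window_never_raises_efficiency(self, params, toy_net):
        effs = []
        for sk in [0.7, 0.5, 0.3, 0.1]:
            s = make_swarm(params, n=200, seed=19)
            res = simulate_targeting(
                s, toy_net, params, SimConfig(sigma_keep=sk)
            )
            effs.append(res.efficiency)
        assert np.all(np.diff(effs) <= 1e-12)

    def test_dt_refinement_consistency(self, params, toy_net):
        effs = {}
        for dt in (0.1, 0.05):
            s = make_swarm(params, n=200, seed=20)
            effs[dt] = simulate_targeting(
                s, toy_net, params, SimConfig(dt=dt)
            ).efficiency
        assert abs(effs[0.1] - effs[0.05]) < 0.01

    def test_all_slip_swarm_stalls(self, params):
        from uwheel.network import Junction, Network, check_network

        net = check_network(
            Network(
                junctions={
                    "A": Junction("A", 0.0, 80.0),
                    "B": Junction("B", 20e-3, 80.0, kind="terminal"),
                },
                branches={"b": ("A", "B")},
                root="b",
                target="b",
            )
        )
        from uwheel.physics import rotation_rate

        s = make_swarm(params, n=10, seed=21)
        s.R[:] = 60e-6  # every wheel above the slip threshold at 80 deg
        s.omega[:] = rotation_rate(s.R, params.bead, params.fluid, params.field)
        res = simulate_targeting(s, net, params)
        assert res.termination == "stalled"
        assert res.efficiency == 0.0
        assert res.residual_fraction == pytest.approx(1.0)

    def test_timeout(self, params, straight_net):
        s = make_swarm(params, n=5, seed=22, mode="flipping")
        res = simulate_targeting(
            s, straight_net, params, SimConfig(max_time=0.5)
        )
        assert res.termination == "timed_out"
        assert res.efficiency == 0.0

    def test_traces_are_recorded(self, params, toy_net):
        s = make_swarm(params, n=30, seed=23)
        res = simulate_targeting(s, toy_net, params)
        assert len(res.centroid_trace) == len(res.sigma_trace) > 2
        ts = [t for t, _ in res.centroid_trace]
        assert all(b >= a for a, b in zip(ts, ts[1:]))

    def test_bad_config_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(dt=0.0)
        with pytest.raises(ConfigError):
            SimConfig(sigma_keep=-0.5)
        with pytest.raises(ConfigError):
            SimConfig(max_time=0.01)

    def test_unreachable_target_is_config_error(self, params, mca):
        from uwheel.network import Network

        net = Network(
            junctions=mca.junctions, branches=mca.branches, root=mca.root,
            target="branch99",
        )
        s = make_swarm(params, n=5, seed=24)
        with pytest.raises(PathError):
            simulate_targeting(s, net, params)
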