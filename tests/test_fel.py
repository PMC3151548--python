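"""Transition networks, committors, MFPT, cFEP and kinetic grouping."""

import itertools

import numpy as np
import pytest

from trajscope import fel
from trajscope.errors import DegenerateInputError, TrajscopeError
from trajscope.synth import gen_markov_traj


def mc_hitting(T, start, target, avoid=None, n_walkers=100_000, seed=0,
               max_steps=20_000):
    """Vectorized Monte-Carlo first-passage simulation on a transition matrix.

    Returns (probability of hitting target before `avoid`, mean steps to
    target) over the surviving walkers.
    """
    rng = np.random.default_rng(seed)
    n = T.shape[0]
    cdf = np.cumsum(T, axis=1)
    state = np.full(n_walkers, start)
    steps = np.zeros(n_walkers)
    hit_target = np.zeros(n_walkers, dtype=bool)
    active = np.ones(n_walkers, dtype=bool)
    for _ in range(max_steps):
        if not active.any():
            break
        u = rng.random(active.sum())
        nxt = np.array([np.searchsorted(cdf[s], x, side="right")
                        for s, x in zip(state[active], u)])
        nxt = np.minimum(nxt, n - 1)
        state[active] = nxt
        steps[active] += 1
        done_t = active & (state == target)
        hit_target |= done_t
        active &= state != target
        if avoid is not None:
            active &= state != avoid
    return hit_target.mean(), steps[hit_target].mean()


class TestBuildNetwork:
    def test_alternating_two_state_chain(self):
        mtraj = fel.MicrostateTrajectory.from_labels([0, 1] * 20)
        net = fel.build_network(mtraj, lag=1)
        assert net.transition_matrix[0, 1] == 1.0
        assert net.transition_matrix[1, 0] == 1.0

    def test_constant_trajectory_degenerate(self):
        mtraj = fel.MicrostateTrajectory.from_labels([3] * 10)
        with pytest.raises(DegenerateInputError):
            fel.build_network(mtraj, lag=1)

    def test_row_stochastic(self, twowell_traj):
        mtraj, _ = twowell_traj
        net = fel.build_network(mtraj, lag=1)
        assert np.allclose(net.transition_matrix.sum(axis=1), 1.0)

    def test_estimated_matrix_within_three_standard_errors(self, twowell_traj):
        mtraj, truth = twowell_traj
        net = fel.build_network(mtraj, lag=1)
        T_true = truth["transition_matrix"]
        # map internal state order back to original labels
        perm = mtraj.original_labels
        T_true = T_true[np.ix_(perm, perm)]
        counts = net.counts.sum(axis=1)
        for i in range(net.n_states):
            se = np.sqrt(np.clip(T_true[i] * (1 - T_true[i]), 1e-12, None)
                         / counts[i])
            assert np.all(np.abs(net.transition_matrix[i] - T_true[i])
                          <= 3 * se + 1e-9)

    def test_lag_validation(self):
        mtraj = fel.MicrostateTrajectory.from_labels([0, 1, 0, 1])
        with pytest.raises(TrajscopeError):
            fel.build_network(mtraj, lag=0)
        with pytest.raises(TrajscopeError):
            fel.build_network(mtraj, lag=10)


class TestPfold:
    def test_symmetric_chain_midpoint_half(self):
        # symmetric random walk on A-B-C with reflecting ends (exact counts)
        counts = np.array([[0.0, 100.0, 0.0],
                           [100.0, 0.0, 100.0],
                           [0.0, 100.0, 0.0]])
        net = fel.TransitionNetwork(counts, np.array([100.0, 200.0, 100.0]), 1)
        p = fel.pfold(net, folded=2, unfolded=0)
        assert p.values[1] == pytest.approx(0.5, abs=1e-12)
        assert p.values[2] == 1.0 and p.values[0] == 0.0

    def test_harmonicity_of_interior_nodes(self, twowell_traj):
        mtraj, _ = twowell_traj
        net = fel.build_network(mtraj, lag=1)
        p = fel.pfold(net, 0, 9)
        T = net.transition_matrix
        for i in range(net.n_states):
            if i in (0, 9):
                continue
            assert p.values[i] == pytest.approx(float(T[i] @ p.values),
                                                abs=1e-10)

    def test_matches_first_step_analysis_and_monte_carlo(self):
        rng = np.random.default_rng(5)
        n = 8
        T = rng.random((n, n)) + 0.1
        T /= T.sum(axis=1, keepdims=True)
        net = fel.TransitionNetwork(T * 1000.0, np.ones(n) * 1000, 1)
        source, target = 0, n - 1
        p = fel.pfold(net, target, source)
        # independent oracle 1: dense first-step linear solve
        interior = [i for i in range(n) if i not in (source, target)]
        A = np.eye(len(interior))
        b = np.zeros(len(interior))
        for ii, i in enumerate(interior):
            for jj, j in enumerate(interior):
                A[ii, jj] -= T[i, j]
            b[ii] = T[i, target]
        oracle = np.zeros(n)
        oracle[target] = 1.0
        oracle[interior] = np.linalg.solve(A, b)
        assert np.allclose(p.values, oracle, atol=1e-12)
        # independent oracle 2: Monte-Carlo hitting simulation
        for probe in (2, 5):
            frac, _ = mc_hitting(T, probe, target, avoid=source,
                                 n_walkers=100_000, seed=7)
            assert p.values[probe] == pytest.approx(frac, abs=0.02)

    def test_unreachable_boundary_rejected(self):
        labels = [0, 1] * 10 + [2]  # state 2 only at the end, never left
        mtraj = fel.MicrostateTrajectory.from_labels(labels + [2])
        net = fel.build_network(mtraj, lag=1)
        with pytest.raises(TrajscopeError, match="unreachable"):
            fel.pfold(net, 0, 1)  # state 2 cannot reach either boundary


class TestMfpt:
    def test_target_itself_zero(self, twowell_traj):
        mtraj, _ = twowell_traj
        net = fel.build_network(mtraj, lag=1)
        m = fel.mfpt(net, 4)
        assert m.values[4] == 0.0
        assert np.all(m.values >= 0)

    def test_geometric_escape_closed_form(self):
        # two states; from 1 the chain escapes to 0 with probability p
        p_escape = 0.2
        T = np.array([[1.0, 0.0], [p_escape, 1 - p_escape]])
        net = fel.TransitionNetwork(T * 500, np.array([500.0, 500.0]), 1)
        m = fel.mfpt(net, 0)
        assert m.values[1] == pytest.approx(1.0 / p_escape, rel=1e-12)

    def test_linear_system_residual(self, twowell_traj):
        mtraj, _ = twowell_traj
        net = fel.build_network(mtraj, lag=1)
        m = fel.mfpt(net, 0)
        T = net.transition_matrix
        for i in range(1, net.n_states):
            assert m.values[i] - (1 + T[i] @ m.values) == pytest.approx(
                0.0, abs=1e-10)

    def test_matches_monte_carlo_mean_hitting_time(self):
        rng = np.random.default_rng(6)
        n = 8
        T = rng.random((n, n)) + 0.1
        T /= T.sum(axis=1, keepdims=True)
        net = fel.TransitionNetwork(T * 1000, np.ones(n) * 1000, 1)
        m = fel.mfpt(net, n - 1)
        frac, mean_steps = mc_hitting(T, 0, n - 1, n_walkers=100_000, seed=8)
        assert frac == 1.0
        assert m.values[0] == pytest.approx(mean_steps, rel=0.02)

    def test_unreachable_states_flagged_infinite(self):
        # 2 -> {0,1} but never back
        labels = [2, 2, 0, 1, 0, 1, 0, 1, 0, 1]
        net = fel.build_network(fel.MicrostateTrajectory.from_labels(labels), 1)
        m = fel.mfpt(net, 2)
        assert np.isinf(m.values[0]) and np.isinf(m.values[1])
        assert m.values[2] == 0.0


def two_well_network(inter_p=0.01, seed=21, n_steps=200_000):
    mtraj, truth = gen_markov_traj(10, [0] * 5 + [1] * 5, 0.5, inter_p,
                                   n_steps, seed=seed)
    return mtraj, truth, fel.build_network(mtraj, lag=1)


class TestCfep:
    def test_symmetric_two_well_barrier_near_half(self):
        mtraj, truth, net = two_well_network()
        p = fel.pfold(net, 0, 9)
        profile = fel.cfep(net, p)
        x_bar, dg_bar = profile.barrier()
        # the barrier cut separates the two equally populated wells
        assert abs(x_bar - 0.5) <= 0.06
        assert dg_bar == profile.dg.max() < np.inf

    def test_deeper_barrier_raises_profile_maximum(self):
        _, _, net_easy = two_well_network(inter_p=0.02, seed=22)
        _, _, net_hard = two_well_network(inter_p=0.002, seed=22)
        p_easy = fel.pfold(net_easy, 0, 9)
        p_hard = fel.pfold(net_hard, 0, 9)
        dg_easy = fel.cfep(net_easy, p_easy).barrier()[1]
        dg_hard = fel.cfep(net_hard, p_hard).barrier()[1]
        assert dg_hard > dg_easy

    def test_barrier_cut_is_minimum_cut_exhaustively(self):
        # small two-well chain: compare against enumeration of all cuts
        mtraj, truth = gen_markov_traj(6, [0] * 3 + [1] * 3, 0.5, 0.01,
                                       100_000, seed=23)
        net = fel.build_network(mtraj, lag=1)
        p = fel.pfold(net, 0, 5)
        profile = fel.cfep(net, p)
        i_max = int(np.argmax(profile.dg))
        got_flux = profile.cut_flux[i_max]
        # exhaustive minimum over all 2^(n-2) cuts separating the references
        n = net.n_states
        best = np.inf
        for mask in itertools.product([0, 1], repeat=n):
            if mask[0] != 1 or mask[5] != 0:
                continue
            a = np.array(mask, dtype=bool)
            flux = net.counts[np.ix_(a, ~a)].sum() + net.counts[np.ix_(~a, a)].sum()
            best = min(best, flux)
        assert got_flux == pytest.approx(best, rel=0.35)
        # and the profile maximum dominates every other sampled cut
        assert got_flux == profile.cut_flux.min()

    def test_invariant_under_state_relabeling(self):
        mtraj, truth, net = two_well_network(seed=24, n_steps=100_000)
        p = fel.pfold(net, 0, 9)
        base = fel.cfep(net, p)
        rng = np.random.default_rng(3)
        perm = rng.permutation(10)
        relabeled = fel.MicrostateTrajectory.from_labels(perm[mtraj.labels])
        net2 = fel.build_network(relabeled, lag=1)
        p2 = fel.pfold(net2, int(np.where(relabeled.original_labels ==
                                          perm[0])[0][0]),
                       int(np.where(relabeled.original_labels ==
                                    perm[9])[0][0]))
        other = fel.cfep(net2, p2)
        assert base.barrier()[0] == pytest.approx(other.barrier()[0], rel=0.01)
        assert base.barrier()[1] == pytest.approx(other.barrier()[1], rel=0.01)

    def test_coordinate_must_cover_nodes(self):
        _, _, net = two_well_network(seed=25, n_steps=50_000)
        bad = fel.KineticCoordinate("pfold", np.zeros(3), {})
        with pytest.raises(TrajscopeError):
            fel.cfep(net, bad)


class TestCommitment:
    def test_self_commitment_is_one(self, twowell_traj):
        mtraj, _ = twowell_traj
        subset, p = fel.commitment_matrix(mtraj, None, tau_commit=10)
        assert np.allclose(np.diag(p), 1.0)

    def test_alternating_series_commits_in_one_step(self):
        mtraj = fel.MicrostateTrajectory.from_labels([0, 1] * 30)
        _, p = fel.commitment_matrix(mtraj, None, tau_commit=1)
        assert p[0, 1] == 1.0 and p[1, 0] == 1.0

    def test_two_well_separation(self, twowell_traj):
        mtraj, truth = twowell_traj
        wells = truth["wells"][mtraj.original_labels]
        _, p = fel.commitment_matrix(mtraj, None, tau_commit=100)
        n = mtraj.n_states
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if wells[i] == wells[j]:
                    assert p[i, j] >= 0.5
                else:
                    assert p[i, j] < 0.5

    def test_excessive_tau_rejected(self):
        mtraj = fel.MicrostateTrajectory.from_labels([0, 1, 0, 1])
        with pytest.raises(TrajscopeError):
            fel.commitment_matrix(mtraj, None, tau_commit=10)


class TestKga:
    def test_two_well_partition_recovered_exactly(self, twowell_traj):
        mtraj, truth = twowell_traj
        wells = truth["wells"][mtraj.original_labels]
        part = fel.kga(mtraj, tau_commit=100, n_heavy=10)
        assert np.all(part.basin_of >= 0)
        assert np.array_equal(
            np.equal.outer(part.basin_of, part.basin_of),
            np.equal.outer(wells, wells))

    def test_three_well_partition_recovered_exactly(self):
        wells = [0] * 4 + [1] * 4 + [2] * 4
        mtraj, truth = gen_markov_traj(12, wells, 0.5, 0.002, 80_000, seed=31)
        w = truth["wells"][mtraj.original_labels]
        part = fel.kga(mtraj, tau_commit=100, n_heavy=12)
        assert np.array_equal(np.equal.outer(part.basin_of, part.basin_of),
                              np.equal.outer(w, w))

    def test_long_tau_merges_everything(self, twowell_traj):
        mtraj, _ = twowell_traj
        part = fel.kga(mtraj, tau_commit=20_000, n_heavy=10)
        assert len(set(part.basin_of.tolist())) == 1

    def test_light_states_assigned_in_postprocessing(self, twowell_traj):
        mtraj, truth = twowell_traj
        wells = truth["wells"][mtraj.original_labels]
        part = fel.kga(mtraj, tau_commit=100, n_heavy=4)
        assert part.heavy_states.shape == (4,)
        heavy_wells = {part.basin_of[s] for s in part.heavy_states}
        # every state still lands in the basin of its own well
        assert np.array_equal(np.equal.outer(part.basin_of, part.basin_of),
                              np.equal.outer(wells, wells))

    def test_clamped_heavy_count_warns(self, twowell_traj):
        mtraj, _ = twowell_traj
        with pytest.warns(UserWarning, match="clamped"):
            fel.kga(mtraj, tau_commit=100, n_heavy=999)

    def test_single_basin_representative_mode(self, twowell_traj):
        mtraj, truth = twowell_traj
        wells = truth["wells"][mtraj.original_labels]
        rep = int(np.argmax(mtraj.populations))
        p = fel.commit_to_representative(mtraj, rep, tau_commit=100)
        members = p >= 0.5
        assert np.array_equal(members, wells == wells[rep])


class TestFptDistribution:
    def test_periodic_cycle_single_spike(self):
        k = 5
        labels = list(range(k)) * 40
        mtraj = fel.MicrostateTrajectory.from_labels(labels)
        values, counts = fel.fpt_distribution(mtraj, target=0)
        assert values.tolist() == [k]
        assert counts[0] == 39  # every visit but the last qualifies

    def test_counts_conserved(self, twowell_traj):
        mtraj, _ = twowell_traj
        values, counts = fel.fpt_distribution(mtraj, target=0)
        starts = np.where(mtraj.labels[:-1] == 0)[0]
        nxt = np.array([np.argmax(mtraj.labels[t + 1:] == 0)
                        if (mtraj.labels[t + 1:] == 0).any() else -1
                        for t in starts[:200]])
        qualifying = np.sum([(mtraj.labels[t + 1:] == 0).any()
                             for t in starts])
        assert counts.sum() == qualifying

    def test_two_well_timescale_separation(self, twowell_traj):
        mtraj, _ = twowell_traj
        values, counts = fel.fpt_distribution(mtraj, target=0)
        short = counts[values <= 50].sum()
        long = counts[values > 1000].sum()
        assert short > 0 and long > 0  # both relaxation regimes sampled

    def test_never_visited_target_rejected(self, twowell_traj):
        mtraj, _ = twowell_traj
        with pytest.raises(TrajscopeError):
            fel.fpt_distribution(mtraj, target=99)
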