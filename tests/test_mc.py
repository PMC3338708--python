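"""Move set geometry, Metropolis sampling and parallel tempering."""

import numpy as np
import pytest

import latticego as lg
from latticego import _kernels as K
from latticego.mc import ChainState, assert_valid_state, enumerate_moves

import oracles


def rod_conf(n):
    return lg.LatticeConformation(np.array([[i, 0, 0] for i in range(n)], dtype=np.int64))


class TestRandomCoil:
    def test_coils_are_valid_and_not_all_identical(self):
        confs = [lg.random_coil(48, seed) for seed in range(50)]
        for c in confs:
            assert lg.validate_conformation(c.coords).ok
        assert len({c.coords.tobytes() for c in confs}) > 1

    def test_same_seed_reproduces_coil(self):
        a = lg.random_coil(48, 77)
        b = lg.random_coil(48, 77)
        assert np.array_equal(a.coords, b.coords)

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            lg.random_coil(3, 0)


class TestMoveGeometry:
    def test_rod_interior_bead_has_no_move(self):
        conf = rod_conf(8)
        assert enumerate_moves(conf, 4) == []

    def test_rod_terminal_bead_has_five_geometric_candidates(self):
        conf = rod_conf(8)
        cands = enumerate_moves(conf, 0)
        assert len(cands) == 5
        assert all(c.kind == "end-move" for c in cands)
        # candidates are exactly the neighbor sites of bead 1 minus bead 0
        anchor = conf.coords[1]
        sites = {tuple(c.new_coords[0]) for c in cands}
        expected = {
            tuple(anchor + s)
            for s in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        } - {tuple(conf.coords[0])}
        assert sites == expected
        # one of them (the site of bead 2) collides; 4 are self-avoiding
        legal = [c for c in cands if c.self_avoiding(conf)]
        assert len(legal) == 4

    def test_corner_bead_has_single_flip_to_opposite_corner(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 2, 0]], dtype=np.int64)
        conf = lg.LatticeConformation(coords)
        flips = [c for c in enumerate_moves(conf, 1) if c.kind == "corner-flip"]
        assert len(flips) == 1
        assert tuple(flips[0].new_coords[0]) == (0, 1, 0)

    def test_crankshaft_candidates_preserve_bonds(self):
        # U-shape: flanking beads 0 and 3 are lattice neighbors
        coords = np.array(
            [[0, 0, 0], [0, 1, 0], [1, 1, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
            dtype=np.int64,
        )
        conf = lg.LatticeConformation(coords)
        cranks = [c for c in enumerate_moves(conf, 1) if c.kind == "crankshaft"]
        assert len(cranks) == 3
        for mv in cranks:
            new = conf.coords.copy()
            new[[1, 2]] = mv.new_coords
            diffs = np.diff(new, axis=0)
            assert np.all(np.sum(diffs * diffs, axis=1) == 1)

    def test_propose_move_null_on_locked_bead(self):
        conf = rod_conf(8)
        rng = np.random.default_rng(0)
        results = {lg.propose_move(conf, rng) is None for _ in range(200)}
        assert True in results  # interior beads of a rod yield null proposals


class TestMetropolis:
    def test_uphill_acceptance_frequency_matches_boltzmann(self):
        """A move raising the energy by one unit at T=1 is accepted with
        frequency e^-1."""
        rng = K.seed_rng(42)
        n = 40_000
        acc = sum(K._accept(-1, 1.0, rng) for _ in range(n)) / n
        p = np.exp(-1.0)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(acc - p) < 4 * se

    def test_downhill_always_accepted(self):
        rng = K.seed_rng(1)
        assert all(K._accept(d, 0.5, rng) for d in (0, 1, 5) for _ in range(100))

    def test_states_remain_valid_and_counts_consistent(self, toy18_model):
        conf = lg.random_coil(18, 3)
        st = ChainState.for_model(conf, toy18_model, seed=3)
        e = np.empty(0, dtype=np.int16)
        K.run_equilibrium(st.coords, st.grid, st.nat, st.nformed, 0.6, 500_000, st.rng, e, 0)
        assert_valid_state(st)
        assert -toy18_model.n_native <= st.energy <= 0

    def test_stationary_distribution_matches_exact_boltzmann(
        self, toy8_model, saw8_level_counts, toy8_long_run
    ):
        """Detailed balance: the long-run energy histogram of the N=8 toy
        agrees with exhaustive Boltzmann enumeration within 3 standard
        errors per energy level (block-averaged errors)."""
        T, samples = toy8_long_run
        exact = oracles.boltzmann_level_probs(saw8_level_counts, T)
        n_blocks = 30
        blocks = samples.reshape(n_blocks, -1)
        for e_level, p_exact in exact.items():
            block_means = (blocks == e_level).mean(axis=1)
            p_hat = block_means.mean()
            se = block_means.std(ddof=1) / np.sqrt(n_blocks)
            assert abs(p_hat - p_exact) <= 3 * se + 1e-4, (
                f"level {e_level}: sampled {p_hat:.4f}, exact {p_exact:.4f}, se {se:.5f}"
            )


class TestTrajectories:
    def test_native_start_has_zero_first_passage_time(self, toy8_model):
        rec = lg.run_folding_trajectory(
            toy8_model, 0.5, seed=1, max_steps=100, start=toy8_model.native_conformation
        )
        assert rec.reached and rec.first_passage_time == 0

    def test_same_seed_gives_identical_trajectory(self, toy18_model):
        a = lg.run_folding_trajectory(toy18_model, 0.6, seed=9, max_steps=10**7,
                                      energy_stride=100)
        b = lg.run_folding_trajectory(toy18_model, 0.6, seed=9, max_steps=10**7,
                                      energy_stride=100)
        assert a.first_passage_time == b.first_passage_time
        assert np.array_equal(a.energies, b.energies)

    def test_censoring_is_flagged_not_dropped(self, toy18_model):
        rec = lg.run_folding_trajectory(toy18_model, 0.6, seed=5, max_steps=10)
        assert not rec.reached and rec.steps_run == 10

    def test_fpt_distribution_is_roughly_exponential(self, toy8_model):
        """Two-state folding: the survival curve of N=8 first passage times
        fits a single exponential with a small residual."""
        fpts = []
        for i in range(500):
            rec = lg.run_folding_trajectory(toy8_model, 0.6, seed=i, max_steps=10**6)
            assert rec.reached
            fpts.append(rec.first_passage_time)
        ens = lg.FPTEnsemble(fpts=np.array(fpts), n_censored=0, temperature=0.6)
        est = lg.estimate_rate(ens)
        assert est.reliable
        assert est.k > 0


class TestParallelTempering:
    def test_swap_acceptance_is_unity_for_degenerate_ladder(self, toy8_model):
        temps = np.array([0.6, 0.6 + 1e-12])
        cfg = lg.PTConfig(temperatures=temps, n_sweeps=300, steps_per_sweep=20,
                          burn_sweeps=10, seed=3)
        res = lg.parallel_tempering(toy8_model, cfg)
        assert res.swap_acceptance[0] == pytest.approx(1.0)

    def test_mean_energy_nondecreasing_in_temperature(self, toy8_pt):
        temps, res = toy8_pt
        means = res.samples.mean(axis=1)
        assert np.all(np.diff(means) > -0.05)

    def test_pt_means_match_single_temperature_chains(self, toy8_model, toy8_pt):
        temps, res = toy8_pt
        for ti in (3, 8):
            T = temps[ti]
            conf = lg.random_coil(8, seed=50 + ti)
            st = ChainState.for_model(conf, toy8_model, seed=60 + ti)
            e = np.empty(40_000, dtype=np.int16)
            K.run_equilibrium(st.coords, st.grid, st.nat, st.nformed, float(T),
                              40_000 * 100, st.rng, e, 100)
            ref_blocks = e.astype(float).reshape(20, -1).mean(axis=1)
            pt_blocks = res.samples[ti].astype(float).reshape(20, -1).mean(axis=1)
            se = np.sqrt(ref_blocks.std(ddof=1) ** 2 / 20 + pt_blocks.std(ddof=1) ** 2 / 20)
            assert abs(ref_blocks.mean() - pt_blocks.mean()) < 4 * se + 0.02

    def test_ladder_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            lg.PTConfig(temperatures=np.array([1.0, 0.5]))


def test_trajectory_store_round_trip(tmp_path, toy18_model):
    import latticego.mc as mc

    rec = lg.run_folding_trajectory(
        toy18_model, 0.6, seed=4, max_steps=10**7, energy_stride=200,
        snapshot_stride=200, snapshot_window=(-14, -10),
    )
    path = tmp_path / "run.npz"
    mc.save_trajectory(rec, path)
    back = mc.load_trajectory(path)
    assert back.first_passage_time == rec.first_passage_time
    assert np.array_equal(back.energies, rec.energies)
    assert np.array_equal(back.snapshots, rec.snapshots)
    idx = tmp_path / "index.csv"
    mc.write_trajectory_index([rec], idx)
    header, row = idx.read_text().strip().splitlines()
    assert header == "seed,temperature,fpt,reached"
    assert row.startswith("4,0.6,")
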