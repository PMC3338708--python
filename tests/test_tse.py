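"""Pfold, transition-state ensembles, RMSD and the transition-state network."""

import numpy as np
import pytest

import latticego as lg
from latticego.mc import TrajectoryRecord
from latticego.thermo import BarrierSummary
from latticego.tse import TSECandidate, PfoldEstimate, TSERecord, contact_frequencies

import oracles


def fake_record(snaps, energies):
    snaps = np.asarray(snaps, dtype=np.int64)
    return TrajectoryRecord(
        seed=0, temperature=0.6, max_steps=10, first_passage_time=None, reached=False,
        snapshots=snaps, snapshot_energies=np.asarray(energies, dtype=np.int16),
        snapshot_steps=np.arange(1, len(energies) + 1, dtype=np.int64),
        snapshot_stride=1,
    )


def barrier_at(e):
    return BarrierSummary(
        temperature=0.6, e_folded=-5, e_unfolded=0, e_barrier=e,
        dg_fold=0.0, dg_activation=1.0, two_state=True,
    )


@pytest.fixture(scope="module")
def coil_snaps(toy8_model):
    confs = [lg.random_coil(8, s).coords for s in range(12)]
    return confs


class TestHarvest:
    def test_filter_equals_brute_force(self, coil_snaps):
        energies = [-3, -2, -1, -4, -2, -3, 0, -1, -2, -5, -3, -2]
        rec = fake_record(coil_snaps, energies)
        got = lg.harvest_candidates([rec], barrier_at(-2), window=1)
        expected = [i for i, e in enumerate(energies) if -3 <= e <= -1]
        assert [c.energy for c in got] == [energies[i] for i in expected]
        assert all(np.array_equal(c.coords, coil_snaps[i]) for c, i in zip(got, expected))
        assert got[0].step == expected[0] + 1

    def test_duplicates_removed(self, coil_snaps):
        rec = fake_record([coil_snaps[0], coil_snaps[0], coil_snaps[1]], [-2, -2, -2])
        got = lg.harvest_candidates([rec], barrier_at(-2), window=0)
        assert len(got) == 2

    def test_empty_harvest_raises(self, coil_snaps):
        rec = fake_record(coil_snaps[:3], [0, 0, 0])
        with pytest.raises(ValueError, match="denser snapshot stride|no snapshot"):
            lg.harvest_candidates([rec], barrier_at(-4), window=1)


class TestPfold:
    def test_native_conformation_commits_to_fold(self, toy8_model):
        est = lg.pfold(toy8_model.native_conformation, toy8_model, 0.6, n_trials=20, seed=1)
        assert est.p == 1.0 and est.n_fold == 20

    def test_fully_unfolded_start_commits_to_unfold(self, toy8_model):
        coords = np.array([[i, 0, 0] for i in range(8)], dtype=np.int64)
        est = lg.pfold(coords, toy8_model, 0.6, n_trials=20, seed=2, unfold_threshold=0.2)
        assert est.p == 0.0 and est.n_unfold == 20

    def test_self_consistency_at_larger_trial_count(self, toy8_model, saw8_level_counts):
        """Pfold at M and 10M trials agree within 3 combined binomial SE."""
        # a half-native conformation of the cube toy
        for seed in range(200):
            conf = lg.random_coil(8, seed)
            if lg.go_energy(conf, toy8_model) == -3:
                break
        small = lg.pfold(conf, toy8_model, 0.6, n_trials=100, seed=5)
        big = lg.pfold(conf, toy8_model, 0.6, n_trials=1000, seed=6)
        se = np.sqrt(small.se**2 + big.se**2)
        assert abs(small.p - big.p) <= 3 * se
        assert small.se <= 0.05 + 1e-12  # 100 trials bound the binomial error at 5%

    def test_invalid_threshold_rejected(self, toy8_model):
        with pytest.raises(ValueError, match="unfold_threshold"):
            lg.pfold(toy8_model.native_conformation, toy8_model, 0.6, unfold_threshold=1.5)


def pf(p, se=0.02, flagged=False):
    return PfoldEstimate(p=p, se=se, n_fold=0, n_unfold=0, n_indeterminate=0, flagged=flagged)


class TestSelectTse:
    def test_band_filter_equals_brute_force(self, coil_snaps):
        cands = [TSECandidate(coords=c, energy=-2) for c in coil_snaps]
        ps = [0.5, 0.9, 0.45, 0.62, 0.1, 0.55, 0.39, 0.51, 0.72, 0.5, 0.61, 0.28]
        pfolds = [pf(p) for p in ps]
        rec = lg.select_tse(cands, pfolds, temperature=0.6, band=0.1, min_size=1)
        expected = [i for i, p in enumerate(ps) if abs(p - 0.5) <= 0.1]
        assert rec.size == len(expected)
        assert [m.coords.tobytes() for m in rec.members] == [
            coil_snaps[i].tobytes() for i in expected
        ]

    def test_high_se_and_flagged_estimates_excluded(self, coil_snaps):
        cands = [TSECandidate(coords=coil_snaps[i], energy=-2) for i in range(3)]
        pfolds = [pf(0.5), pf(0.5, se=0.2), pf(0.5, flagged=True)]
        rec = lg.select_tse(cands, pfolds, temperature=0.6, min_size=1)
        assert rec.size == 1

    def test_empty_selection_reports_distribution(self, coil_snaps):
        cands = [TSECandidate(coords=coil_snaps[i], energy=-2) for i in range(4)]
        pfolds = [pf(p) for p in (0.9, 0.95, 0.99, 0.8)]
        with pytest.raises(ValueError, match="empty TSE.*quartiles"):
            lg.select_tse(cands, pfolds, temperature=0.6)

    def test_small_ensemble_warns(self, coil_snaps):
        cands = [TSECandidate(coords=coil_snaps[0], energy=-2)]
        with pytest.warns(UserWarning, match="members"):
            lg.select_tse(cands, [pf(0.5)], temperature=0.6, min_size=50)


class TestCoTse:
    def test_native_member_gives_native_co(self, toy8_model):
        rec = TSERecord(
            members=[TSECandidate(coords=toy8_model.native_conformation.coords, energy=-5)],
            pfolds=[pf(0.5)], temperature=0.6,
        )
        assert lg.co_tse(rec, toy8_model) == pytest.approx(
            lg.contact_order(toy8_model.native_contacts)
        )

    def test_hand_computed_three_member_average(self, toy8_model):
        """Members with known formed-contact sets average member-by-member."""
        chains = oracles.enumerate_saws(8)
        native = set(toy8_model.native_contacts.contacts)
        picked, expected = [], []
        for chain in chains:
            formed = oracles.brute_force_contacts(chain) & native
            if len(formed) in (1, 2, 3) and len(picked) < 3:
                picked.append(TSECandidate(coords=chain, energy=-len(formed)))
                expected.append(np.mean([j - i for i, j in formed]))
            if len(picked) == 3:
                break
        rec = TSERecord(members=picked, pfolds=[pf(0.5)] * 3, temperature=0.6)
        assert lg.co_tse(rec, toy8_model) == pytest.approx(np.mean(expected))


class TestRmsd:
    def test_identity_translation_rotation_all_zero(self, toy18_model):
        c = toy18_model.native_conformation.coords
        assert lg.rmsd_to_native(c, c) == pytest.approx(0.0, abs=1e-12)
        assert lg.rmsd_to_native(c + np.array([5, 5, 5]), c) == pytest.approx(0.0, abs=1e-9)
        rot90z = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]])
        assert lg.rmsd_to_native(c @ rot90z.T, c) == pytest.approx(0.0, abs=1e-9)

    def test_reflection_is_not_superposable(self):
        # a chiral 5-bead chain and its mirror image
        c = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1], [2, 1, 1]])
        mirror = c * np.array([-1, 1, 1])
        assert lg.rmsd_to_native(mirror, c) > 0.3

    def test_never_beats_lattice_rotation_oracle(self):
        """The continuous Kabsch optimum is bounded above by the best of the
        24 proper lattice rotations and agrees for congruent pairs."""
        rng = np.random.default_rng(0)
        for seed in range(40):
            a = lg.random_coil(8, seed).coords
            b = lg.random_coil(8, 1000 + seed).coords
            kabsch = lg.rmsd_to_native(a, b)
            brute = oracles.brute_force_rmsd(a, b)
            assert kabsch <= brute + 1e-9
        for rot in rng.permutation(24)[:5]:
            r = oracles.proper_rotations()[rot]
            a = lg.random_coil(10, int(rot)).coords
            b = (a @ r.T).astype(np.int64) + 7
            assert lg.rmsd_to_native(a, b) == pytest.approx(oracles.brute_force_rmsd(a, b), abs=1e-9)

    def test_symmetry_and_length_mismatch(self):
        a = lg.random_coil(8, 1).coords
        b = lg.random_coil(8, 2).coords
        assert lg.rmsd_to_native(a, b) == pytest.approx(lg.rmsd_to_native(b, a))
        with pytest.raises(ValueError, match="mismatch"):
            lg.rmsd_to_native(a, lg.random_coil(9, 3).coords)

    def test_hand_built_four_mers_match_oracle(self):
        rodc = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        ell = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0]])
        kabsch = lg.rmsd_to_native(rodc, ell)
        brute = oracles.brute_force_rmsd(rodc, ell)
        assert 0 < kabsch <= brute + 1e-9


class TestTsn:
    def build_record(self, toy8_model, patterns):
        """TSE members realized as actual N=8 chains with prescribed numbers
        of formed native contacts are hard to construct directly; instead use
        enumeration to find chains whose formed-contact sets we then count."""
        chains = oracles.enumerate_saws(8)
        native = set(toy8_model.native_contacts.contacts)
        members, formed_sets = [], []
        for chain in chains:
            formed = oracles.brute_force_contacts(chain) & native
            if len(formed) >= 1:
                members.append(TSECandidate(coords=chain, energy=-len(formed)))
                formed_sets.append(formed)
            if len(members) == patterns:
                break
        return (
            TSERecord(members=members, pfolds=[pf(0.5)] * len(members), temperature=0.6),
            formed_sets,
        )

    def test_frequencies_equal_counting_oracle(self, toy8_model):
        rec, formed_sets = self.build_record(toy8_model, 4)
        freqs = contact_frequencies(rec, toy8_model)
        for contact in toy8_model.native_contacts.contacts:
            expected = sum(contact in s for s in formed_sets) / len(formed_sets)
            assert freqs[contact] == pytest.approx(expected)

    def test_threshold_zero_with_all_contacts_gives_native_map(self, toy8_model):
        rec = TSERecord(
            members=[TSECandidate(coords=toy8_model.native_conformation.coords, energy=-5)],
            pfolds=[pf(0.5)], temperature=0.6,
        )
        tsn = lg.transition_state_network(rec, toy8_model, p_star=0.0)
        assert tsn.contacts == toy8_model.native_contacts.contacts
        assert tsn.co_tsn == pytest.approx(lg.contact_order(toy8_model.native_contacts))

    def test_threshold_above_one_gives_empty_network(self, toy8_model):
        rec, _ = self.build_record(toy8_model, 4)
        tsn = lg.transition_state_network(rec, toy8_model, p_star=1.1)
        assert tsn.n == 0
        assert tsn.co_tsn is None and tsn.max_contact_range is None

    def test_network_is_monotone_in_threshold(self, toy8_model):
        rec, _ = self.build_record(toy8_model, 6)
        previous = None
        for p_star in (0.0, 0.3, 0.5, 0.7, 1.0):
            tsn = lg.transition_state_network(rec, toy8_model, p_star)
            assert tsn.contacts <= toy8_model.native_contacts.contacts
            if previous is not None:
                assert tsn.contacts <= previous
            previous = tsn.contacts

    def test_member_relabeling_invariance(self, toy8_model):
        rec, _ = self.build_record(toy8_model, 5)
        shuffled = TSERecord(
            members=rec.members[::-1], pfolds=rec.pfolds[::-1], temperature=0.6
        )
        a = lg.transition_state_network(rec, toy8_model, 0.5)
        b = lg.transition_state_network(shuffled, toy8_model, 0.5)
        assert a.contacts == b.contacts
        assert a.co_tsn == b.co_tsn

    def test_range_spectrum_counts_separations(self, toy8_model):
        rec, formed_sets = self.build_record(toy8_model, 4)
        tsn = lg.transition_state_network(rec, toy8_model, p_star=0.0)
        spec = tsn.range_spectrum
        assert sum(spec.values()) == tsn.n
        assert all(s >= 3 and s % 2 == 1 for s in spec)


def test_tse_report_row_and_range_spectrum(tmp_path, toy8_model):
    from latticego.tse import tse_report_row, write_range_spectrum

    rec = TSERecord(
        members=[TSECandidate(coords=toy8_model.native_conformation.coords, energy=-5)],
        pfolds=[pf(0.5)], temperature=0.6,
    )
    tsn = lg.transition_state_network(rec, toy8_model, p_star=0.5)
    row = tse_report_row("toy8_cp00", rec, toy8_model, tsn, 0.5, 0.2, 1)
    assert row["tse_size"] == 1 and row["n_TSN"] == 5
    assert row["CO"] == row["CO_TSE"] == row["CO_TSN"]
    path = tmp_path / "spectrum.csv"
    write_range_spectrum(tsn, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "separation,count"
    assert sum(int(l.split(",")[1]) for l in lines[1:]) == 5
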