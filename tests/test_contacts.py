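"""Contact detection, ratio maps, difference algebra and pair ranking."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import flexmap as fm
from flexmap import ContractError, PlantedContact, SyntheticSpec
from flexmap.contacts import (
    ContactRatioMap,
    contact_residues,
    read_map_tsv,
    write_map_tsv,
)

from conftest import build_trajectory


def ratio_map_from(delta_entries, residues, cutoff=4.5, min_seq_sep=2, n_frames=100, label=""):
    residues = np.asarray(residues)
    R = residues.size
    ratio = np.zeros((R, R))
    for (ri, rj), v in delta_entries.items():
        i = int(np.flatnonzero(residues == ri)[0])
        j = int(np.flatnonzero(residues == rj)[0])
        ratio[i, j] = ratio[j, i] = v
    return ContactRatioMap(
        residue_numbers=residues,
        ratio=ratio,
        cutoff=cutoff,
        min_seq_sep=min_seq_sep,
        n_frames=n_frames,
        label=label,
    )


class TestFrameContacts:
    def test_below_cutoff_is_contact(self, two_residue_factory):
        m = fm.frame_contacts(two_residue_factory(4.4))
        assert m[0, 1] and m[1, 0]

    def test_exactly_at_cutoff_is_no_contact(self, two_residue_factory):
        # the criterion is strictly "less than"
        assert not fm.frame_contacts(two_residue_factory(4.5)).any()

    def test_close_hydrogens_do_not_count(self):
        spec = [
            ("CA", "C", 201, "ALA"),
            ("HA", "H", 201, "ALA"),
            ("CA", "C", 210, "ALA"),
            ("HA", "H", 210, "ALA"),
        ]
        frames = [[[0, 0, 0], [3.0, 0, 0], [7.0, 0, 0], [3.5, 0, 0]]]
        traj = build_trajectory(spec, frames)
        assert not fm.frame_contacts(traj).any()  # H atoms 0.5 A apart, heavy 7 A

    def test_min_seq_sep_excludes_neighbours(self, two_residue_factory):
        traj = two_residue_factory(3.0, resnums=(201, 202))
        assert not fm.frame_contacts(traj, min_seq_sep=2).any()
        assert fm.frame_contacts(traj, min_seq_sep=1).any()

    def test_nonpositive_cutoff_rejected(self, two_residue_factory):
        with pytest.raises(ContractError):
            fm.frame_contacts(two_residue_factory(4.0), cutoff=0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_kdtree_equals_brute_force_bitwise(self, seed):
        rng = np.random.default_rng(seed)
        n_res, atoms_per = 50, 3
        elements = {"N": "N", "CA": "C", "CB": "C"}
        spec = [
            (name, elements[name], 201 + r, "ALA")
            for r in range(n_res)
            for name in ("N", "CA", "CB")
        ]
        coords = rng.uniform(0, 25, size=(1, n_res * atoms_per, 3))
        traj = build_trajectory(spec, coords)
        a = fm.frame_contacts(traj, method="kdtree")
        b = fm.frame_contacts(traj, method="brute")
        assert np.array_equal(a, b)


class TestRatioMap:
    def test_always_in_contact_gives_one(self, two_residue_factory):
        traj = two_residue_factory(3.0)
        traj = fm.Trajectory(atoms=traj.atoms, coords=np.repeat(traj.coords, 5, axis=0))
        m = fm.contact_ratio_map(traj)
        assert m.pair_ratio(201, 210) == 1.0

    def test_single_frame_matches_frame_contacts(self, demo_pair):
        wt = demo_pair["wt"]
        one = fm.Trajectory(atoms=wt.atoms, coords=wt.coords[:1])
        m = fm.contact_ratio_map(one)
        fc = fm.frame_contacts(wt, frame_index=0)
        assert np.array_equal(m.ratio[~m.excluded] > 0.5, fc[~m.excluded])
        assert set(np.unique(m.ratio)) <= {0.0, 1.0}

    def test_planted_occupancy_recovered_exactly_from_bookkeeping(self):
        spec = SyntheticSpec(
            seed=9, n_frames=200, n_runs=5,
            two_state_pairs=(PlantedContact(210, 250, 0.3),),
        )
        traj, truth = fm.gen_two_state_trajectory(spec)
        m = fm.contact_ratio_map(traj)
        assert m.pair_ratio(210, 250) == truth.realized_occupancy[0]

    def test_symmetry_and_range_on_demo(self, demo_pair):
        m = fm.contact_ratio_map(
            fm.Trajectory(atoms=demo_pair["wt"].atoms, coords=demo_pair["wt"].coords[:50]),
        )
        assert np.array_equal(m.ratio, m.ratio.T)
        assert m.ratio.min() >= 0 and m.ratio.max() <= 1
        assert np.all(m.excluded == m.excluded.T)

    def test_empty_window_rejected(self, two_residue_factory):
        with pytest.raises(ContractError):
            fm.contact_ratio_map(two_residue_factory(3.0), window=np.array([], dtype=int))


class TestDiffMap:
    def test_self_difference_is_zero(self, demo_pair):
        m = fm.contact_ratio_map(
            fm.Trajectory(atoms=demo_pair["wt"].atoms, coords=demo_pair["wt"].coords[:20])
        )
        d = fm.diff_map(m, m)
        assert np.all(d.delta == 0)

    def test_sign_convention_wt_minus_mut(self):
        residues = [201, 205, 256]
        wt = ratio_map_from({(205, 256): 0.9}, residues, label="wt")
        mut = ratio_map_from({(205, 256): 0.1}, residues, label="mut")
        d = fm.diff_map(wt, mut)
        i, j = 1, 2
        assert d.delta[i, j] == pytest.approx(0.8)  # positive = lost in mutant

    def test_antisymmetry_under_argument_swap(self):
        residues = [201, 205, 256]
        a = ratio_map_from({(205, 256): 0.7, (201, 256): 0.2}, residues)
        b = ratio_map_from({(205, 256): 0.4}, residues)
        ab, ba = fm.diff_map(a, b), fm.diff_map(b, a)
        assert np.allclose(ab.delta, -ba.delta)

    def test_incompatible_maps_rejected(self):
        a = ratio_map_from({}, [201, 205, 256], cutoff=4.5)
        b = ratio_map_from({}, [201, 205, 256], cutoff=4.0)
        c = ratio_map_from({}, [201, 205, 257])
        with pytest.raises(ContractError):
            fm.diff_map(a, b)
        with pytest.raises(ContractError):
            fm.diff_map(a, c)

    @given(st.integers(0, 10**6))
    @settings(max_examples=20, deadline=None)
    def test_delta_range_and_symmetry_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        residues = np.arange(201, 211)
        sym = rng.uniform(0, 1, (10, 10))
        sym = (sym + sym.T) / 2
        sym2 = rng.uniform(0, 1, (10, 10))
        sym2 = (sym2 + sym2.T) / 2
        a = ContactRatioMap(residues, sym, 4.5, 2, 10)
        b = ContactRatioMap(residues, sym2, 4.5, 2, 10)
        d = fm.diff_map(a, b)
        assert np.allclose(d.delta, d.delta.T)
        assert d.delta.min() >= -1 and d.delta.max() <= 1


class TestTopPairs:
    def test_direct_ranking(self):
        residues = [203, 205, 237, 256, 258]
        wt = ratio_map_from({(205, 256): 0.8, (237, 258): 0.5}, residues, label="wt")
        mut = ratio_map_from({}, residues, label="mut")
        d = fm.diff_map(wt, mut)
        pairs = fm.top_pairs(d, k=2, direction="lost")
        assert [(p.residue_i, p.residue_j) for p in pairs] == [(205, 256), (237, 258)]

    def test_ties_break_lexicographically(self):
        residues = [203, 237, 256, 257]
        wt = ratio_map_from({(203, 256): 0.6, (237, 257): 0.6}, residues)
        d = fm.diff_map(wt, ratio_map_from({}, residues))
        pairs = fm.top_pairs(d, k=2, direction="lost")
        assert (pairs[0].residue_i, pairs[0].residue_j) == (203, 256)

    def test_k_beyond_available_returns_all(self):
        residues = [201, 205, 210]
        d = fm.diff_map(ratio_map_from({}, residues), ratio_map_from({}, residues))
        assert len(fm.top_pairs(d, k=999, direction="abs")) == 3

    def test_gained_direction_flips_ordering(self):
        residues = [201, 205, 210]
        mut_gain = ratio_map_from({(201, 210): 0.9}, residues)
        d = fm.diff_map(ratio_map_from({}, residues), mut_gain)
        top = fm.top_pairs(d, k=1, direction="gained")[0]
        assert (top.residue_i, top.residue_j) == (201, 210)
        assert top.delta == pytest.approx(-0.9)

    def test_planted_lost_pairs_exactly_recovered(self, demo_pair):
        wt_map = fm.contact_ratio_map(demo_pair["wt"], window=0.5, label="wt")
        mut_map = fm.contact_ratio_map(demo_pair["mut"], window=0.5, label="mut")
        pairs = fm.top_pairs(fm.diff_map(wt_map, mut_map), k=5, direction="lost")
        got = {(p.residue_i, p.residue_j) for p in pairs}
        assert got == {(203, 256), (205, 256), (237, 257), (237, 258), (259, 264)}


class TestMapTsv:
    def test_round_trip_including_na_cells(self, tmp_path, two_residue_factory):
        traj = two_residue_factory(3.0)
        m = fm.contact_ratio_map(traj, label="demo")
        p = write_map_tsv(m, tmp_path / "map.tsv")
        text = p.read_text()
        assert "NA" in text  # diagonal is excluded, not zero
        back = read_map_tsv(p)
        assert np.array_equal(back.residue_numbers, m.residue_numbers)
        assert np.allclose(back.ratio[~back.excluded], m.ratio[~m.excluded])
        assert back.cutoff == m.cutoff and back.min_seq_sep == m.min_seq_sep
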