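"""Virtual Cb construction, disulfide geometry screening, candidate scan."""

import numpy as np
import pytest
from oracles import penalty_grid_oracle, scan_bruteforce

from cryostab.disulfide import (
    ScanParams,
    cb_distance,
    geometry_penalty,
    scan_candidates,
    virtual_cbeta,
)
from cryostab.flexibility import FlexibilityProfile, rmsf_profile
from cryostab.structmodel import Atom, Structure
from cryostab.synthetic import synth_toy_structure, synth_trajectory


def _residue(resseq, atoms, chain="A", resname="ALA"):
    out = []
    for i, (name, xyz) in enumerate(atoms.items(), start=1):
        out.append(
            Atom(i, name, "", resname, chain, resseq, "", np.asarray(xyz, float))
        )
    return out


class TestVirtualCbeta:
    def test_stored_cb_returned_unchanged(self, planted_toy):
        rid = ("A", 1, "")
        np.testing.assert_array_equal(
            virtual_cbeta(planted_toy, rid), planted_toy.atom(rid, "CB").xyz
        )

    def test_glycine_construction_geometry(self):
        """Idealized Cb sits 1.53 A from CA at tetrahedral-like angles."""
        s = Structure(
            _residue(
                1,
                {
                    "N": [1.458, 0.0, 0.0],
                    "CA": [0.0, 0.0, 0.0],
                    "C": 1.525 * np.array([np.cos(np.deg2rad(111)), np.sin(np.deg2rad(111)), 0]),
                },
                resname="GLY",
            )
        )
        cb = virtual_cbeta(s, ("A", 1, ""))
        assert np.linalg.norm(cb - 0.0) == pytest.approx(1.53, abs=0.01)
        # roughly equal angles to N and C (tetrahedral branch)
        u = cb / np.linalg.norm(cb)
        ang_n = np.degrees(np.arccos(np.dot(u, [1, 0, 0])))
        assert 100 < ang_n < 120

    def test_missing_backbone_atom_named_in_error(self):
        s = Structure(_residue(1, {"CA": [0, 0, 0], "C": [1.5, 0, 0]}))
        with pytest.raises(ValueError, match="N"):
            virtual_cbeta(s, ("A", 1, ""))


class TestCbDistance:
    def test_hand_placed_distances(self):
        a = _residue(1, {"N": [-1, 1, 0], "CA": [0, 1, 0], "C": [0.5, 2, 0], "CB": [1, 1, 0]})
        b = _residue(5, {"N": [-1, 1, 3.8], "CA": [0, 1, 3.8], "C": [0.5, 2, 3.8], "CB": [1, 1, 3.8]})
        s = Structure(a + b)
        assert cb_distance(s, ("A", 1, ""), ("A", 5, "")) == pytest.approx(3.8)
        assert cb_distance(s, ("A", 5, ""), ("A", 1, "")) == pytest.approx(
            cb_distance(s, ("A", 1, ""), ("A", 5, ""))
        )

    def test_axis_aligned_four_angstrom(self):
        a = _residue(1, {"N": [-1.458, 0, 0], "CA": [0, 0, 0], "C": [0.5, 1.4, 0], "CB": [0, 0, 0]})
        b = _residue(9, {"N": [2.542, 0, 0], "CA": [4, 0, 0], "C": [4.5, 1.4, 0], "CB": [4, 0, 0]})
        assert cb_distance(Structure(a + b), ("A", 1, ""), ("A", 9, "")) == pytest.approx(4.0)


class TestGeometryPenalty:
    def test_ideal_pair_scores_near_zero(self, planted_toy):
        """A constructed ideal disulfide (Sg-Sg 2.05 A, chi3 87 deg) is ~free."""
        assert geometry_penalty(planted_toy, ("A", 2, ""), ("A", 8, "")) < 0.01

    def test_distant_pair_exceeds_default_cutoff(self, planted_toy):
        pen = geometry_penalty(planted_toy, ("A", 1, ""), ("A", 5, ""))
        assert pen > ScanParams().max_geometry_penalty

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_fine_grid_oracle(self, seed):
        """Coarse grid + local refinement tracks an exhaustive 1-deg scan."""
        s = synth_toy_structure(8, planted_pair=(2, 6), seed=seed)
        for pair in [(2, 6), (1, 4), (3, 8)]:
            a, b = ("A", pair[0], ""), ("A", pair[1], "")
            impl = geometry_penalty(s, a, b)
            oracle = penalty_grid_oracle(s, a, b, step=1.0)
            assert impl == pytest.approx(oracle, abs=0.05)


def _scan_profile(structure, hot=(), base=0.2, hot_value=0.9):
    ids = structure.residue_ids()
    vals = [hot_value if rid[1] in hot else base for rid in ids]
    return FlexibilityProfile(ids, np.array(vals))


class TestScan:
    def test_planted_pair_is_sole_candidate(self, planted_toy, planted_profile):
        out = scan_candidates(planted_toy, planted_profile)
        assert [c.pair for c in out] == [(("A", 2, ""), ("A", 8, ""))]
        c = out[0]
        assert 3.95 <= c.cb_distance <= 4.05
        assert c.geometry_penalty <= ScanParams().max_geometry_penalty
        assert not c.near_ibs

    def test_ibs_exclusion_empties_output(self, planted_toy, planted_profile):
        params = ScanParams(ibs_residues={("A", 2, "")})
        assert scan_candidates(planted_toy, planted_profile, params) == []
        # an IBS residue merely *near* the pair (within cutoff) also excludes it
        params2 = ScanParams(ibs_residues={("A", 8, "")})
        assert scan_candidates(planted_toy, planted_profile, params2) == []

    def test_unplanted_toy_has_no_candidates(self):
        s = synth_toy_structure(10, seed=2)
        profile = _scan_profile(s, hot=(3, 7))
        assert scan_candidates(s, profile, ScanParams(rmsf_threshold=0.0)) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_bruteforce_filter(self, seed):
        """Scan output matches an independently coded all-pairs filter."""
        s = synth_toy_structure(10, planted_pair=(2, 8), seed=seed)
        ens = synth_trajectory(s, 0.25, n_frames=100, seed=seed + 100)
        profile = rmsf_profile(ens)
        params = ScanParams(rmsf_threshold=None)
        ours = scan_candidates(s, profile, params)
        ref = scan_bruteforce(s, profile, params)
        assert [(c.pair, c.cb_distance, c.geometry_penalty) for c in ours] == [
            ((a, b), d, p) for a, b, d, f, p, sc in ref
        ]

    def test_flexibility_filter(self, planted_toy):
        """Neither residue hot -> the pair is rejected."""
        cold = _scan_profile(planted_toy, hot=())
        assert scan_candidates(planted_toy, cold, ScanParams(rmsf_threshold=0.5)) == []
        half_hot = _scan_profile(planted_toy, hot=(2,))
        out = scan_candidates(planted_toy, half_hot, ScanParams(rmsf_threshold=0.5))
        assert [c.pair for c in out] == [(("A", 2, ""), ("A", 8, ""))]

    def test_window_monotonicity(self, planted_toy, planted_profile):
        """Widening the Cb window or penalty cap never drops a candidate."""
        tight = scan_candidates(
            planted_toy, planted_profile, ScanParams(cb_min=3.5, cb_max=4.5)
        )
        wide = scan_candidates(
            planted_toy, planted_profile,
            ScanParams(cb_min=3.0, cb_max=5.0, max_geometry_penalty=20.0),
        )
        assert {c.pair for c in tight} <= {c.pair for c in wide}

    def test_deterministic(self, planted_toy, planted_profile):
        a = scan_candidates(planted_toy, planted_profile)
        b = scan_candidates(planted_toy, planted_profile)
        assert [(c.pair, c.rank_score) for c in a] == [(c.pair, c.rank_score) for c in b]

    def test_empty_profile_rejected(self, planted_toy):
        with pytest.raises(ValueError):
            scan_candidates(planted_toy, FlexibilityProfile([], np.array([])))

    def test_params_validation(self):
        with pytest.raises(ValueError):
            ScanParams(cb_min=4.5, cb_max=5.0, target_cb=4.0)
        with pytest.raises(ValueError):
            ScanParams(min_seq_sep=0)
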