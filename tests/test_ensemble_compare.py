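import itertools

import numpy as np
import pytest

from ensdyn.ensemble_compare import (
    DEFAULT_MASK,
    RegionMask,
    SuperpositionError,
    kabsch_superpose,
    pairwise_rmsd_matrix,
    per_residue_profile,
    rmsd_to_mean,
)
from ensdyn.structure_io import StructureEnsemble
from ensdyn.synthetic_data import SyntheticSpec, make_ensemble

from conftest import toy_model


def _rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


def grid_rmsd_oracle(x, y, n_coarse=24, refine=3):
    """Brute-force minimum RMSD over SO(3) (axis-angle grid + refinement).

    Independent of the SVD route: centers both sets, scans rotations on a
    grid of axes and angles, then refines around the best hit.
    """
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)

    def rmsd_for(R):
        d = x @ R.T - y
        return np.sqrt((d ** 2).sum() / len(x))

    axes = []
    golden = np.pi * (1 + 5 ** 0.5)
    for i in range(60):
        z = 1 - 2 * (i + 0.5) / 60
        r = np.sqrt(1 - z * z)
        th = golden * i
        axes.append((r * np.cos(th), r * np.sin(th), z))
    best = (np.inf, None, None)
    for axis in axes:
        for ang in np.linspace(0, np.pi, n_coarse):
            R = _rotation(axis, ang)
            v = rmsd_for(R)
            if v < best[0]:
                best = (v, axis, ang)
    # local refinement: random search on a geometrically shrinking scale
    v, axis, ang = best
    axis = np.asarray(axis, float)
    rng = np.random.default_rng(0)
    for scale in (0.3, 0.1, 0.03, 0.01, 0.003, 0.001, 3e-4, 1e-4):
        for _ in range(refine * 200):
            a2 = axis + rng.normal(0, scale, 3)
            a2 /= np.linalg.norm(a2)
            g2 = ang + rng.normal(0, scale)
            v2 = rmsd_for(_rotation(a2, g2))
            if v2 < v:
                v, axis, ang = v2, a2, g2
    return v


class TestKabsch:
    def test_identity(self):
        m = toy_model([(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)])
        res = kabsch_superpose(m, m, atom_set=("CA",), mask=None)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_translation_recovered(self):
        coords = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)]
        a = toy_model([(x + 5, y, z) for x, y, z in coords])
        b = toy_model(coords)
        res = kabsch_superpose(a, b, atom_set=("CA",), mask=None)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.translation, [-5, 0, 0], atol=1e-9)

    def test_proper_rotation_only(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(10, 3))
        mirrored = coords * np.array([-1, 1, 1])
        a = toy_model(coords)
        b = toy_model(mirrored)
        res = kabsch_superpose(a, b, atom_set=("CA",), mask=None)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_too_few_or_degenerate(self):
        a = toy_model([(0, 0, 0), (1, 0, 0)])
        with pytest.raises(SuperpositionError, match="paired atoms"):
            kabsch_superpose(a, a, atom_set=("CA",), mask=None)
        line = toy_model([(float(i), 0, 0) for i in range(5)])
        with pytest.raises(SuperpositionError, match="collinear"):
            kabsch_superpose(line, line, atom_set=("CA",), mask=None)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_so3_grid_oracle(self, seed):
        """SVD result equals brute-force rotation search to 1e-3 A."""
        rng = np.random.default_rng(seed)
        base = np.array([(0.0, 0, 0), (3, 0, 0), (0, 3, 0), (0, 0, 3)])
        moved = base.copy()
        moved[3] += rng.normal(0, 1.0, 3)  # one displaced atom
        R = _rotation(rng.normal(size=3), rng.uniform(0, np.pi))
        moved = moved @ R.T + rng.normal(0, 5.0, 3)
        a, b = toy_model(moved), toy_model(base)
        fast = kabsch_superpose(a, b, atom_set=("CA",), mask=None).rmsd
        slow = grid_rmsd_oracle(moved, base)
        assert fast <= slow + 1e-6  # exact optimum cannot exceed grid search
        assert abs(fast - slow) < 1e-3

    def test_brute_force_transform_consistency(self, small_ensemble):
        """Reported RMSD equals RMSD of explicitly transformed coordinates."""
        _, ens, _ = small_ensemble
        a, b = ens.members[0], ens.members[1]
        res = kabsch_superpose(a, b)
        xa, ya = [], []
        look = {(r.seq_num, at.name): at for r in b.residues for at in r.atoms}
        for r in a.residues:
            for at in r.atoms:
                other = look.get((r.seq_num, at.name))
                if other is not None and at.name in ("N", "CA", "C", "O"):
                    xa.append([at.x, at.y, at.z])
                    ya.append([other.x, other.y, other.z])
        xa, ya = np.array(xa), np.array(ya)
        moved = res.apply(xa)
        manual = np.sqrt(((moved - ya) ** 2).sum() / len(xa))
        assert manual == pytest.approx(res.rmsd, abs=1e-6)


class TestPairwiseMatrix:
    def test_single_member_zero(self):
        m = toy_model(np.random.default_rng(1).normal(size=(10, 3)))
        mat = pairwise_rmsd_matrix(StructureEnsemble([m]), mask=None,
                                   atom_set=("CA",))
        assert mat.shape == (1, 1) and mat[0, 0] == 0.0

    def test_rigid_motion_gives_zero(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(20, 3))
        R = _rotation([1, 2, 3], 1.1)
        m1 = toy_model(coords, model_id="1")
        m2 = toy_model(coords @ R.T + [4, 5, 6], model_id="2")
        mat = pairwise_rmsd_matrix(StructureEnsemble([m1, m2]), mask=None,
                                   atom_set=("CA",))
        assert mat[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(mat, mat.T)

    def test_noise_rmsd_closed_form(self):
        """Independent isotropic per-coordinate noise sigma on both members
        gives pairwise RMSD ~ sigma * sqrt(6)."""
        sigma = 0.5
        rng = np.random.default_rng(7)
        base = rng.normal(scale=10.0, size=(500, 3))
        members = [toy_model(base + rng.normal(0, sigma, base.shape),
                             model_id=str(i)) for i in range(5)]
        mat = pairwise_rmsd_matrix(StructureEnsemble(members), mask=None,
                                   atom_set=("CA",))
        off = mat[np.triu_indices(5, k=1)]
        assert off.mean() == pytest.approx(sigma * np.sqrt(6.0), rel=0.10)


class TestPerResidueProfile:
    def test_identical_members_zero(self):
        coords = np.random.default_rng(3).normal(size=(30, 3))
        ens = StructureEnsemble([toy_model(coords, model_id="1"),
                                 toy_model(coords, model_id="2")])
        prof = per_residue_profile(ens, atom_set=("CA",), mask=None)
        assert np.allclose(prof.mean, 0.0, atol=1e-9)
        assert prof.n_pairs == 1

    def test_unmodeled_residue_gets_placeholder(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(scale=5.0, size=(40, 3))
        full = toy_model(coords, model_id="1")
        partial = toy_model(np.delete(coords, 24, axis=0), model_id="2")
        # re-number: drop residue 25 from the second member
        for r in partial.residues:
            if r.seq_num >= 25:
                r.seq_num += 1
        ens = StructureEnsemble([full, partial])
        prof = per_residue_profile(ens, atom_set=("CA",), mask=None)
        i = list(prof.seq_nums).index(25)
        assert prof.mean[i] == pytest.approx(10.0)
        assert prof.n_pairs_with_placeholder[i] == 1
        # placeholder never used where both members model the residue
        both = [k for k, n in enumerate(prof.seq_nums) if n != 25]
        assert prof.n_pairs_with_placeholder[both].sum() == 0

    def test_loop_localization(self, small_ensemble):
        spec, ens, _ = small_ensemble
        prof = per_residue_profile(ens)
        loops = spec.loop_set()
        loop_mean = np.mean([v for n, v in zip(prof.seq_nums, prof.mean)
                             if n in loops])
        core_mean = np.mean([v for n, v in zip(prof.seq_nums, prof.mean)
                             if n not in loops])
        assert loop_mean > 3.0 * core_mean
        peak = prof.seq_nums[np.argmax(prof.max)]
        assert int(peak) in loops

    def test_rigid_transform_invariance(self):
        spec = SyntheticSpec(seed=30, n_models=4, chain_length=40)
        ens, _ = make_ensemble(spec)
        ens_moved, _ = make_ensemble(spec, rigid_transforms=True)
        p1 = per_residue_profile(ens, mask=None)
        p2 = per_residue_profile(ens_moved, mask=None)
        assert np.allclose(p1.mean, p2.mean, atol=1e-6)


class TestRmsdToMean:
    def test_duplicated_member_zero(self):
        coords = np.random.default_rng(6).normal(size=(30, 3))
        ens = StructureEnsemble([toy_model(coords, model_id=str(i))
                                 for i in range(3)])
        rmsds, mean, sd = rmsd_to_mean(ens, atom_set=("CA",), mask=None)
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_pair_equal_rmsds(self):
        rng = np.random.default_rng(8)
        base = rng.normal(scale=8.0, size=(30, 3))
        delta = rng.normal(scale=0.5, size=(30, 3))
        ens = StructureEnsemble([
            toy_model(base + delta, model_id="1"),
            toy_model(base - delta, model_id="2"),
        ])
        rmsds, _, _ = rmsd_to_mean(ens, atom_set=("CA",), mask=None)
        assert rmsds[0] == pytest.approx(rmsds[1], rel=1e-6)

    def test_masked_core_smaller_than_full(self, small_ensemble):
        spec, ens, _ = small_ensemble
        _, core_mean, _ = rmsd_to_mean(ens, mask=DEFAULT_MASK)
        _, full_mean, _ = rmsd_to_mean(ens, mask=None)
        assert core_mean < full_mean


class TestRegionMask:
    def test_membership(self):
        mask = RegionMask(((1, 47), (56, 112)))
        assert 47 in mask and 56 in mask
        assert 50 not in mask and 113 not in mask

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RegionMask(((1, 10), (5, 20)))
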