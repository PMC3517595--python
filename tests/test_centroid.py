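"""Centroid distance-spectrum scoring and Kabsch superposition."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from motifstruct.centroid import (
    CentroidScore,
    MatchThreshold,
    WeightScheme,
    centroid_score,
    distance_spectrum,
    inflate_threshold,
    kabsch_superpose_rmsd,
    match_decision,
    pairwise_max_score,
)
from motifstruct.errors import SizeMismatchError, WeightSchemeMismatchError

from conftest import random_rigid_motion


def oracle_score(a, b, kind="rank_proportional", normalize=False):
    """Direct-definition oracle, coded independently of the implementation:
    explicit python loops over the written-out algorithm steps."""
    def spectrum(x):
        cx = [sum(col) / len(x) for col in zip(*x)]
        d = sorted(
            sum((xi - ci) ** 2 for xi, ci in zip(row, cx)) ** 0.5
            for row in x)
        return d

    v1, v2 = spectrum(list(map(list, a))), spectrum(list(map(list, b)))
    n = len(v1)
    total = 0.0
    for i in range(n):
        if kind == "rank_proportional":
            w = (i + 1) / n
        elif kind == "inverse_rank":
            w = 1.0 / (i + 1)
        else:
            w = 1.0
        total += w * abs(v1[i] - v2[i])
    return total / n if normalize else total


# a chiral 4-point configuration (non-planar scalene tetrahedron)
CHIRAL = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0],
                   [1.0, 2.0, 0.0], [0.5, 0.7, 1.9]])
MIRROR = CHIRAL * np.array([1.0, 1.0, -1.0])


class TestSpectrum:
    def test_collinear_hand_computation(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        np.testing.assert_allclose(distance_spectrum(pts).values, [0, 1, 1])

    def test_single_atom(self):
        np.testing.assert_allclose(
            distance_spectrum(np.array([[5.0, 5, 5]])).values, [0.0])

    def test_rigid_motion_invariant(self, rng):
        pts = rng.normal(0, 2, (12, 3))
        R, t = random_rigid_motion(rng)
        np.testing.assert_allclose(distance_spectrum(pts).values,
                                   distance_spectrum(pts @ R.T + t).values,
                                   atol=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            distance_spectrum(np.empty((0, 3)))


class TestScore:
    def test_worked_example_rank_weights(self):
        a = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        b = np.array([[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]])
        s = centroid_score(a, b, WeightScheme("rank_proportional"),
                           normalize=False)
        # spectra (0,1,1) vs (0,2,2): 0/3 + 2/3 + 3/3 = 5/3
        assert s.value == pytest.approx(5.0 / 3.0, abs=1e-12)

    def test_identity_symmetry_nonnegativity(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 30))
            a, b = rng.normal(0, 3, (n, 3)), rng.normal(0, 3, (n, 3))
            assert centroid_score(a, a).value == 0.0
            sab = centroid_score(a, b).value
            assert sab == pytest.approx(centroid_score(b, a).value, abs=1e-12)
            assert sab >= 0.0

    def test_invariances_rigid_reflection_permutation(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 30))
            a, b = rng.normal(0, 3, (n, 3)), rng.normal(0, 3, (n, 3))
            base = centroid_score(a, b).value
            R, t = random_rigid_motion(rng)
            assert centroid_score(a @ R.T + t, b).value == pytest.approx(
                base, abs=1e-9)
            mirror = a * np.array([1.0, -1.0, 1.0])
            assert centroid_score(mirror, b).value == pytest.approx(
                base, abs=1e-9)
            perm = rng.permutation(n)
            assert centroid_score(a[perm], b).value == pytest.approx(
                base, abs=1e-9)

    def test_agrees_with_direct_definition_oracle(self, rng):
        for kind in ("rank_proportional", "inverse_rank", "uniform"):
            for normalize in (False, True):
                for _ in range(40):
                    n = int(rng.integers(2, 30))
                    a = rng.normal(0, 3, (n, 3))
                    b = rng.normal(0, 3, (n, 3))
                    got = centroid_score(a, b, WeightScheme(kind),
                                         normalize).value
                    assert got == pytest.approx(
                        oracle_score(a, b, kind, normalize), abs=1e-9)

    def test_perturbation_bound(self, rng):
        # displacing every atom by <= delta changes the unnormalized score
        # by <= 2 * delta * sum(w)
        for _ in range(30):
            n = int(rng.integers(3, 25))
            a = rng.normal(0, 3, (n, 3))
            b = rng.normal(0, 3, (n, 3))
            delta = float(rng.uniform(0.01, 0.5))
            d = rng.normal(0, 1, (n, 3))
            d *= delta / np.linalg.norm(d, axis=1, keepdims=True)
            w = WeightScheme("rank_proportional").weights(n)
            s0 = centroid_score(a, b, normalize=False).value
            s1 = centroid_score(a + d, b, normalize=False).value
            assert abs(s1 - s0) <= 2 * delta * w.sum() + 1e-9

    def test_size_mismatch_is_an_error(self, rng):
        with pytest.raises(SizeMismatchError):
            centroid_score(rng.normal(0, 1, (4, 3)), rng.normal(0, 1, (5, 3)))

    def test_mirror_image_scores_zero_but_rmsd_does_not(self):
        # chirality-blindness: spectra identical, proper superposition not
        assert centroid_score(CHIRAL, MIRROR).value == pytest.approx(
            0.0, abs=1e-12)
        assert kabsch_superpose_rmsd(CHIRAL, MIRROR).rmsd > 0.1


class TestDecision:
    def test_boundary_inclusive(self):
        score = CentroidScore(0.16, True, 16)
        assert match_decision(score, MatchThreshold(0.16))
        assert not match_decision(CentroidScore(0.2, True, 16),
                                  MatchThreshold(0.16))
        assert match_decision(CentroidScore(0.0, True, 16),
                              MatchThreshold(0.0))

    def test_scheme_mixing_rejected(self):
        score = CentroidScore(0.1, True, 16, weight_scheme="uniform")
        thr = MatchThreshold(0.2, weight_scheme="rank_proportional")
        with pytest.raises(WeightSchemeMismatchError):
            match_decision(score, thr)


class TestPairwiseMax:
    def test_identical_set_is_zero(self, ideal_helix):
        assert pairwise_max_score([ideal_helix] * 3) == 0.0

    def test_equals_brute_force(self, rng):
        segs = [rng.normal(0, 3, (10, 3)) for _ in range(5)]
        brute = max(centroid_score(a, b).value
                    for a, b in itertools.combinations(segs, 2))
        assert pairwise_max_score(segs) == pytest.approx(brute, abs=1e-12)

    def test_duplicate_leaves_max_unchanged(self, rng):
        segs = [rng.normal(0, 3, (8, 3)) for _ in range(3)]
        assert pairwise_max_score(segs + [segs[0]]) == pytest.approx(
            pairwise_max_score(segs), abs=1e-12)

    def test_fewer_than_two_rejected(self, ideal_helix):
        with pytest.raises(ValueError):
            pairwise_max_score([ideal_helix])


class TestThresholdInflation:
    def test_ten_percent_rule(self):
        assert inflate_threshold(0.142).epsilon == pytest.approx(0.1562)
        assert inflate_threshold(0.0).epsilon == 0.0
        assert inflate_threshold(1.0, 0.5).epsilon == pytest.approx(1.5)

    def test_negative_inflation_rejected(self):
        with pytest.raises(ValueError):
            inflate_threshold(0.1, -0.1)


class TestKabsch:
    def test_self_and_rotated_zero(self, rng):
        a = rng.normal(0, 3, (10, 3))
        assert kabsch_superpose_rmsd(a, a).rmsd == pytest.approx(0, abs=1e-12)
        R, t = random_rigid_motion(rng)
        res = kabsch_superpose_rmsd(a, a @ R.T + t)
        assert res.rmsd == pytest.approx(0, abs=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_scaled_square_closed_form(self):
        sq = np.array([[0.5, 0.5, 0], [-0.5, 0.5, 0],
                       [-0.5, -0.5, 0], [0.5, -0.5, 0]])
        res = kabsch_superpose_rmsd(sq, 2 * sq)
        assert res.rmsd == pytest.approx(np.sqrt(0.5), abs=1e-9)

    def test_agrees_with_svd_superimposer_oracle(self, rng):
        from Bio.SVDSuperimposer import SVDSuperimposer
        for _ in range(25):
            n = int(rng.integers(4, 20))
            a, b = rng.normal(0, 3, (n, 3)), rng.normal(0, 3, (n, 3))
            sup = SVDSuperimposer()
            sup.set(a, b)
            sup.run()
            assert kabsch_superpose_rmsd(a, b).rmsd == pytest.approx(
                sup.get_rms(), abs=1e-7)

    def test_zero_rmsd_implies_zero_centroid_score(self, rng):
        a = rng.normal(0, 3, (10, 3))
        R, t = random_rigid_motion(rng)
        b = a @ R.T + t
        assert kabsch_superpose_rmsd(a, b).rmsd < 1e-9
        assert centroid_score(a, b).value < 1e-9

    def test_degenerate_configuration_warns(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.warns(UserWarning, match="conditioned"):
            kabsch_superpose_rmsd(line, line)
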