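"""Micelle-likeness core: profiles, RD, K fitting, classification, elimination.

The DERIVED expectations are checked against independent brute-force
oracles written here (naive double loops, term-by-term sums), never against
the library's own vectorised code paths.
"""

import math

import numpy as np
import pytest

from oildrop import (
    ComputationError,
    GeometryError,
    InputError,
    SyntheticStructureSpec,
    analyze,
    classify_residues,
    compute_M,
    compute_O,
    compute_RD,
    compute_T,
    compute_TM,
    eliminate_and_recompute,
    fit_K,
    gen_structure,
    kl_divergence,
    orient_to_principal_axes,
    planted_outliers,
)
from oildrop.fod import contact_weight, fit_gaussian

from conftest import random_profile


# ---------------------------------------------------------------- oracles

def oracle_O(points, h, cutoff):
    """Naive double-loop observed profile."""
    n = len(points)
    raw = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            r = math.dist(points[i], points[j])
            if r <= cutoff:
                u = r / cutoff
                g = 1 - 0.5 * (7 * u**2 - 9 * u**4 + 5 * u**6 - u**8)
                raw[i] += (h[i] + h[j]) * g
    return raw / raw.sum()


def oracle_kl(P, Q):
    total = 0.0
    for p, q in zip(P, Q):
        if p > 0:
            total += p * math.log2(p / q)
    return total


def oracle_RD(O, T):
    n = len(O)
    d1 = oracle_kl(O, np.maximum(T, 1e-12))
    d2 = oracle_kl(O, [1.0 / n] * n)
    return d1 / (d1 + d2) if d1 + d2 else 0.0


def oracle_classify(O, T, frac):
    m = max(abs(o - t) for o, t in zip(O, T))
    labels = []
    for o, t in zip(O, T):
        if m and t - o > frac * m:
            labels.append("deficit")
        elif m and o - t > frac * m:
            labels.append("excess")
        else:
            labels.append("accordant")
    return labels


def random_rotation(rng):
    """Uniform-ish proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


# ------------------------------------------------------------ orientation

class TestOrientation:
    def test_oriented_set_is_fixed_point_up_to_sign(self, rng):
        pts = rng.normal(size=(60, 3)) * np.array([5.0, 3.0, 1.0])
        out = orient_to_principal_axes(pts)
        again = orient_to_principal_axes(out)
        np.testing.assert_allclose(np.abs(again), np.abs(out), atol=1e-8)

    def test_rotated_set_reorients_to_same_coordinates(self, rng):
        pts = rng.normal(size=(50, 3)) * np.array([6.0, 3.0, 1.5])
        ref = orient_to_principal_axes(pts)
        for _ in range(5):
            R = random_rotation(rng)
            moved = pts @ R.T + rng.normal(size=3) * 10
            out = orient_to_principal_axes(moved)
            np.testing.assert_allclose(np.abs(out), np.abs(ref), atol=1e-6)

    def test_identical_points_are_degenerate(self):
        with pytest.raises(GeometryError):
            orient_to_principal_axes(np.ones((5, 3)))

    def test_collinear_points_are_degenerate(self):
        pts = np.outer(np.arange(6.0), [1.0, 2.0, 3.0])
        with pytest.raises(GeometryError):
            orient_to_principal_axes(pts)


# ---------------------------------------------------------------- profiles

class TestTheoreticalProfile:
    def test_symmetric_pair_splits_evenly(self):
        pts = np.array([[2.0, 0, 0], [-2.0, 0, 0]])
        T = compute_T(pts, sigma=(1.5, 1.5, 1.5))
        np.testing.assert_allclose(T, [0.5, 0.5])

    def test_core_point_beats_distant_point(self):
        pts = np.array([[0.0, 0, 0], [5.0, 1.0, 1.0], [-4.0, 2.0, -1.0]])
        T = compute_T(pts, sigma=(2.0, 2.0, 2.0))
        assert T[0] > T[1] and T[0] > T[2]

    def test_matches_closed_form_on_toy_coordinates(self):
        pts = np.array([
            [0.0, 0.0, 0.0], [1.0, -1.0, 2.0], [-2.0, 0.5, 1.0],
            [3.0, 2.0, -1.0], [-1.0, -2.0, -2.0],
        ])
        sigma = np.array([2.0, 1.5, 1.0])
        expected = np.array([
            math.exp(-x**2 / (2 * sigma[0] ** 2))
            * math.exp(-y**2 / (2 * sigma[1] ** 2))
            * math.exp(-z**2 / (2 * sigma[2] ** 2))
            for x, y, z in pts
        ])
        expected /= expected.sum()
        np.testing.assert_allclose(compute_T(pts, sigma=sigma), expected, atol=1e-12)

    def test_sigma_is_one_third_of_extent(self, rng):
        pts = orient_to_principal_axes(rng.normal(size=(40, 3)) * [7, 4, 2])
        params = fit_gaussian(pts)
        np.testing.assert_allclose(params.sigma, np.abs(pts).max(axis=0) / 3)

    def test_zero_extent_axis_is_geometry_error(self):
        pts = np.array([[1.0, 1.0, 0.0], [-1.0, -1.0, 0.0], [1.0, -1.0, 0.0]])
        with pytest.raises(GeometryError):
            compute_T(pts)


class TestObservedProfile:
    def test_pair_at_exact_cutoff_has_no_contacts(self):
        pts = np.array([[0.0, 0, 0], [9.0, 0, 0]])
        with pytest.raises(ComputationError, match="contact"):
            compute_O(pts, [0.5, 0.5], cutoff=9.0)

    def test_identical_pair_within_cutoff_splits_evenly(self):
        pts = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        np.testing.assert_allclose(compute_O(pts, [0.7, 0.7], cutoff=9.0), [0.5, 0.5])

    def test_contact_weight_endpoints(self):
        assert contact_weight(0.0) == pytest.approx(1.0)
        assert contact_weight(1.0) == pytest.approx(0.0)
        assert contact_weight(1.2) == 0.0

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            pts = rng.normal(size=(n, 3)) * 4.0
            h = rng.uniform(0.1, 1.0, n)
            np.testing.assert_allclose(
                compute_O(pts, h, cutoff=9.0), oracle_O(pts, h, 9.0), atol=1e-10
            )


class TestInvertedAndMixedProfiles:
    def test_inverted_arithmetic(self):
        np.testing.assert_allclose(
            compute_TM([0.5, 0.3, 0.2]), [0.0, 0.4, 0.6], atol=1e-12
        )

    def test_argmax_maps_to_zero_and_sum_is_one(self, rng):
        T = random_profile(rng, 11)
        TM = compute_TM(T)
        assert TM[np.argmax(T)] == 0.0
        assert TM.sum() == pytest.approx(1.0, abs=1e-12)

    def test_constant_profile_has_no_inversion(self):
        with pytest.raises(ComputationError):
            compute_TM(np.full(4, 0.25))

    def test_mixing_endpoints_and_midpoint(self):
        T = np.array([0.6, 0.4])
        TM = np.array([0.3, 0.7])
        np.testing.assert_allclose(compute_M(T, TM, 0.0), T)
        np.testing.assert_allclose(compute_M(T, TM, 1.0), TM)
        np.testing.assert_allclose(compute_M(T, TM, 0.5), [0.45, 0.55])

    def test_negative_k_rejected(self):
        with pytest.raises(InputError):
            compute_M([0.5, 0.5], [0.5, 0.5], -0.1)


# ------------------------------------------------------------- divergences

class TestDivergenceAndRD:
    def test_identity_is_zero(self, rng):
        P = random_profile(rng, 6)
        assert kl_divergence(P, P) == 0.0

    def test_one_bit_example(self):
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(1.0)

    def test_matches_term_by_term_oracle(self, rng):
        for _ in range(20):
            P = random_profile(rng, 10)
            Q = random_profile(rng, 10)
            assert kl_divergence(P, Q) == pytest.approx(oracle_kl(P, Q), abs=1e-12)

    def test_support_mismatch_is_error(self):
        with pytest.raises(ComputationError):
            kl_divergence([0.5, 0.5], [1.0, 0.0])

    def test_rd_zero_when_observed_matches_target(self, rng):
        T = random_profile(rng, 9)
        assert compute_RD(T, T) == 0.0

    def test_rd_one_when_observed_is_uniform(self, rng):
        n = 8
        T = random_profile(rng, n)
        assert compute_RD(np.full(n, 1 / n), T) == pytest.approx(1.0)

    def test_rd_matches_ratio_oracle(self, rng):
        for _ in range(20):
            O = random_profile(rng, 12)
            T = random_profile(rng, 12)
            assert compute_RD(O, T) == pytest.approx(oracle_RD(O, T), abs=1e-12)

    def test_rd_bounds_on_random_instances(self, rng):
        for _ in range(200):
            O = random_profile(rng, 30)
            T = random_profile(rng, 30)
            assert 0.0 <= compute_RD(O, T) <= 1.0

    def test_mixing_toward_target_shrinks_divergence_and_zeroes_rd(self, rng):
        """Mixing O toward T monotonically shrinks D(O(λ)‖T) and ends at RD = 0.

        The RD ratio itself is not monotone along the path: the mixture can
        pass closer to the uniform reference, shrinking the denominator, so
        only the numerator divergence carries a monotonicity guarantee.
        """
        for _ in range(20):
            O = random_profile(rng, 25)
            T = random_profile(rng, 25)
            lams = np.linspace(0, 1, 11)
            d1 = [kl_divergence((1 - lam) * O + lam * T, T) for lam in lams]
            assert all(b <= a + 1e-12 for a, b in zip(d1, d1[1:]))
            assert compute_RD(T, T) == 0.0
            assert compute_RD(O, T) >= 0.0


# ------------------------------------------------------------------ fit_K

class TestFitK:
    def test_observed_equal_target_gives_zero(self, rng):
        T = random_profile(rng, 10)
        TM = compute_TM(T)
        assert fit_K(T, T, TM) == 0.0

    def test_observed_equal_inverted_gives_one(self, rng):
        T = random_profile(rng, 10)
        TM = compute_TM(T)
        assert fit_K(TM, T, TM) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("k_star", [0.0, 0.2, 0.6, 1.0, 1.5])
    def test_planted_k_recovered_within_refinement_step(self, rng, k_star):
        T = random_profile(rng, 40)
        TM = compute_TM(T)
        O = compute_M(T, TM, k_star)
        assert abs(fit_K(O, T, TM) - k_star) <= 0.001 + 1e-12

    def test_empty_grid_rejected(self, rng):
        T = random_profile(rng, 5)
        with pytest.raises(InputError):
            fit_K(T, T, compute_TM(T), grid=[])


# ---------------------------------------------------------- classification

class TestClassification:
    def test_exact_match_is_all_accordant(self, rng):
        T = random_profile(rng, 7)
        assert classify_residues(T, T) == ["accordant"] * 7

    def test_single_deviation_is_the_only_flag(self):
        T = np.array([0.4, 0.2, 0.2, 0.2])
        O = np.array([0.25, 0.25, 0.25, 0.25])
        # residue 0 carries the dominant deficit at threshold_fraction 0.9
        labels = classify_residues(O, T, threshold_fraction=0.9)
        assert labels[0] == "deficit"
        assert labels[1:] == ["accordant"] * 3

    def test_matches_relabelling_oracle(self, rng):
        for _ in range(20):
            O = random_profile(rng, 12)
            T = random_profile(rng, 12)
            assert classify_residues(O, T, 0.5) == oracle_classify(O, T, 0.5)

    def test_bad_threshold_rejected(self, rng):
        T = random_profile(rng, 5)
        with pytest.raises(InputError):
            classify_residues(T, T, threshold_fraction=0.0)


# ------------------------------------------------------- whole-chain runs

class TestAnalyzeAndEliminate:
    def test_profiles_normalized_and_nonnegative(self):
        model = gen_structure(SyntheticStructureSpec(n=60, seed=5))
        res = analyze(model)
        p = res.profile
        for v in (p.T, p.O, p.TM, p.M):
            assert np.all(v >= 0)
            assert v.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(res.status) == len(model)

    def test_rigid_motion_leaves_rd_and_k_unchanged(self, rng):
        model = gen_structure(SyntheticStructureSpec(n=80, seed=2))
        base = analyze(model)
        for _ in range(3):
            R = random_rotation(rng)
            shift = rng.normal(size=3) * 20
            moved = model.points @ R.T + shift
            import dataclasses

            residues = [
                dataclasses.replace(r, effective_point=moved[i])
                for i, r in enumerate(model.residues)
            ]
            model2 = dataclasses.replace(model, residues=residues)
            res = analyze(model2)
            assert res.rd == pytest.approx(base.rd, abs=1e-9)
            assert res.k_fit == pytest.approx(base.k_fit, abs=1e-9)

    def test_empty_elimination_matches_full_analysis(self):
        model = gen_structure(SyntheticStructureSpec(n=50, seed=3))
        full = analyze(model)
        redo = eliminate_and_recompute(model, [])
        assert redo.rd == full.rd
        assert redo.k_fit == full.k_fit

    def test_eliminating_almost_everything_is_rejected(self):
        model = gen_structure(SyntheticStructureSpec(n=10, seed=1))
        with pytest.raises(InputError):
            eliminate_and_recompute(model, list(range(8)))

    def test_eliminating_planted_outliers_decreases_rd(self):
        spec = SyntheticStructureSpec(
            n=200, mode="planted_outliers", n_outliers=3, seed=0
        )
        model = gen_structure(spec)
        full = analyze(model)
        redo = eliminate_and_recompute(model, planted_outliers(spec))
        assert redo.rd < full.rd
        assert redo.eliminated == planted_outliers(spec)
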