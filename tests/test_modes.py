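import numpy as np
import pytest
import scipy.linalg as sla

import cgnma
from cgnma import (
    NumericalError,
    StructureError,
    best_match_overlaps,
    cooperativity,
    eig_modes,
    fit_bfactor_scale,
    msf,
    sse_preservation,
    transition_overlap,
    weighted_mode_overlap,
)
from cgnma.modes import ModeSet, superpose

from conftest import build_system


def synthetic_modes(vectors: np.ndarray, eigenvalues, n_rigid=0) -> ModeSet:
    """ModeSet from explicit orthonormal columns (tests own the spectrum)."""
    vals = np.asarray(eigenvalues, dtype=float)
    return ModeSet(eigenvalues=vals, eigenvectors=np.asarray(vectors, float),
                   n_rigid=n_rigid, n_sites=vectors.shape[0] // 3)


@pytest.fixture(scope="module")
def cg_modes(exact_cg_module):
    return eig_modes(exact_cg_module, n_rigid=6)


@pytest.fixture(scope="module")
def exact_cg_module():
    s, _, H, K = build_system(30, seed=4)
    return cgnma.schur_project_exact(H, K)


class TestEigModes:
    def test_dumbbell_spectrum(self):
        from test_hessian import two_atom_hessian

        H = two_atom_hessian(k=3.0)
        ms = eig_modes(H)
        assert np.allclose(np.round(ms.eigenvalues, 9), [0, 0, 0, 0, 0, 6.0])
        assert ms.n_rigid == 5

    def test_six_rigid_on_connected_fixture(self, small_system):
        _, _, H, _ = small_system
        ms = eig_modes(H)
        assert ms.n_rigid == 6

    def test_orthonormal_eigenvectors(self, cg_modes):
        V = cg_modes.eigenvectors
        G = V.T @ V
        assert np.abs(G - np.eye(G.shape[0])).max() < 1e-8

    def test_partial_matches_full(self, exact_cg_module):
        full = eig_modes(exact_cg_module)
        part = eig_modes(exact_cg_module, n_modes=10)
        assert np.allclose(part.eigenvalues, full.eigenvalues[:10], atol=1e-8)

    def test_non_symmetric_rejected(self):
        bad = np.arange(36.0).reshape(6, 6)
        with pytest.raises(NumericalError):
            eig_modes(bad)


class TestMSF:
    def test_dumbbell_symmetric_msf(self):
        from test_hessian import two_atom_hessian

        ms = eig_modes(two_atom_hessian(k=2.0))
        prof = msf(ms)
        assert prof.values[0] == pytest.approx(prof.values[1])

    def test_matches_dense_pseudoinverse(self, exact_cg_module, cg_modes):
        prof = msf(cg_modes)
        pinv = np.linalg.pinv(exact_cg_module.toarray(), rcond=1e-10)
        expect = np.array([np.trace(pinv[3 * i:3 * i + 3, 3 * i:3 * i + 3])
                           for i in range(cg_modes.n_sites)])
        assert np.abs(prof.values - expect).max() <= 1e-8 * expect.max()

    def test_scaling_inverse_linear(self, exact_cg_module):
        import scipy.sparse as sp

        m1 = msf(eig_modes(exact_cg_module, n_rigid=6)).values
        scaled = sp.csr_matrix(exact_cg_module.matrix * 4.0)
        m2 = msf(eig_modes(scaled, n_rigid=6)).values
        assert np.allclose(m2, m1 / 4.0, rtol=1e-8)


class TestBfactorScale:
    def test_exact_double(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        scale, r = fit_bfactor_scale(x, 2 * x)
        assert scale == pytest.approx(2.0)
        assert r == pytest.approx(1.0)

    def test_anticorrelated(self):
        x = np.array([1.0, 2.0, 3.0])
        _, r = fit_bfactor_scale(x, -x)
        assert r == pytest.approx(-1.0)

    def test_random_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0.5, 2.0, 50)
        b = rng.uniform(0.5, 2.0, 50)
        scale, r = fit_bfactor_scale(x, b)
        assert scale == pytest.approx(float(x @ b) / float(x @ x))
        assert r == pytest.approx(float(np.corrcoef(x, b)[0, 1]))

    def test_least_rmsd_property(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0.5, 2.0, 30)
        b = rng.uniform(0.5, 2.0, 30)
        scale, _ = fit_bfactor_scale(x, b)
        base = np.linalg.norm(scale * x - b)
        for ds in (-1e-3, 1e-3):
            assert np.linalg.norm((scale + ds) * x - b) >= base

    def test_zero_variance_errors(self):
        with pytest.raises(NumericalError):
            fit_bfactor_scale(np.ones(5), np.arange(5.0))


class TestWeightedOverlap:
    def test_self_overlap_is_one(self, cg_modes):
        assert weighted_mode_overlap(cg_modes, cg_modes) == pytest.approx(1.0)

    def test_sign_flips_invariant(self, cg_modes):
        rng = np.random.default_rng(3)
        V = cg_modes.eigenvectors.copy()
        V[:, 6:] *= rng.choice([-1.0, 1.0], size=V.shape[1] - 6)[None, :]
        flipped = synthetic_modes(V, cg_modes.eigenvalues, n_rigid=6)
        assert weighted_mode_overlap(cg_modes, flipped) == pytest.approx(1.0)

    def test_swapped_modes_hand_formula(self):
        # 4-site toy with an explicit orthonormal basis; swap modes 7 and 8
        rng = np.random.default_rng(1)
        dim = 12
        Q, _ = np.linalg.qr(rng.normal(size=(dim, dim)))
        lam = np.concatenate([np.zeros(6), np.linspace(1.0, 4.0, dim - 6)])
        ref = synthetic_modes(Q, lam, n_rigid=6)
        Vs = Q.copy()
        Vs[:, [6, 7]] = Vs[:, [7, 6]]
        test = synthetic_modes(Vs, lam, n_rigid=6)
        w = 1.0 / lam[6:]
        cross = abs(float(Q[:, 6] @ Q[:, 7]))  # ~0 by orthogonality
        expect = (w[2:].sum() + w[0] * cross + w[1] * cross) / w.sum()
        got = weighted_mode_overlap(ref, test)
        assert got == pytest.approx(expect, abs=1e-10)
        assert got < 1.0

    def test_dimension_mismatch(self, cg_modes):
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.normal(size=(9, 9)))
        other = synthetic_modes(Q, np.linspace(0, 1, 9), n_rigid=0)
        with pytest.raises(ValueError):
            weighted_mode_overlap(cg_modes, other)


class TestBestMatch:
    def test_identity(self, cg_modes):
        rep = best_match_overlaps(cg_modes, cg_modes, n_list=5)
        for a, b, o in rep.rows:
            assert a == b
            assert o == pytest.approx(1.0)

    def test_permutation_recovered(self, cg_modes):
        perm = np.arange(cg_modes.n_modes)
        perm[6:11] = [8, 6, 10, 9, 7]
        V = cg_modes.eigenvectors[:, perm]
        other = synthetic_modes(V, cg_modes.eigenvalues[perm], n_rigid=6)
        # B's non-rigid columns hold A's modes (3, 1, 5, 4, 2) in order, so
        # A mode i is found at B position: 1->2, 2->5, 3->1, 4->4, 5->3
        rep = best_match_overlaps(cg_modes, other, n_list=5)
        got = {a: b for a, b, _ in rep.rows}
        assert got == {1: 2, 2: 5, 3: 1, 4: 4, 5: 3}

    def test_degenerate_rotation_within_pair(self):
        rng = np.random.default_rng(2)
        dim = 12
        Q, _ = np.linalg.qr(rng.normal(size=(dim, dim)))
        lam = np.concatenate([np.zeros(6), [1.0, 1.0], np.linspace(2, 4, 4)])
        A = synthetic_modes(Q, lam, n_rigid=6)
        theta = 0.7
        V = Q.copy()
        V[:, 6] = np.cos(theta) * Q[:, 6] + np.sin(theta) * Q[:, 7]
        V[:, 7] = -np.sin(theta) * Q[:, 6] + np.cos(theta) * Q[:, 7]
        B = synthetic_modes(V, lam, n_rigid=6)
        rep = best_match_overlaps(A, B, n_list=2)
        for a, b, o in rep.rows:
            assert b in (1, 2)
            assert o <= 1.0 + 1e-12
            assert o == pytest.approx(np.cos(theta), abs=1e-9)


class TestCooperativity:
    def test_diagonal_ones(self, cg_modes):
        cm = cooperativity(cg_modes, k=15)
        assert np.allclose(np.diag(cm.C), 1.0)
        assert np.abs(cm.C - cm.C.T).max() == 0.0
        assert cm.C.min() >= -1.0 and cm.C.max() <= 1.0

    def test_k1_cosine_identity(self, cg_modes):
        cm = cooperativity(cg_modes, k=1)
        r = cg_modes.site_vectors(cg_modes.n_rigid)
        i, j = 0, cg_modes.n_sites // 2
        cos = r[i] @ r[j] / (np.linalg.norm(r[i]) * np.linalg.norm(r[j]))
        assert cm.C[i, j] == pytest.approx(cos)

    def test_toy_hand_computed(self):
        # 4 sites, 2 modes, hand-evaluated averages
        n, k = 4, 2
        dim = 3 * n
        V = np.zeros((dim, k))
        rng = np.random.default_rng(4)
        V[:, 0] = rng.normal(size=dim)
        V[:, 1] = rng.normal(size=dim)
        ms = ModeSet(eigenvalues=np.array([1.0, 2.0]), eigenvectors=V, n_rigid=0, n_sites=n)
        cm = cooperativity(ms, k=2)
        r0 = V[:, 0].reshape(n, 3)
        r1 = V[:, 1].reshape(n, 3)
        for i in range(n):
            for j in range(n):
                num = 0.5 * (r0[i] @ r0[j] + r1[i] @ r1[j])
                di = 0.5 * (r0[i] @ r0[i] + r1[i] @ r1[i])
                dj = 0.5 * (r0[j] @ r0[j] + r1[j] @ r1[j])
                assert cm.C[i, j] == pytest.approx(num / np.sqrt(di * dj))

    def test_sign_flip_invariance(self, cg_modes):
        V = cg_modes.eigenvectors.copy()
        V[:, 6] *= -1.0
        other = synthetic_modes(V, cg_modes.eigenvalues, n_rigid=6)
        a = cooperativity(cg_modes, k=5).C
        b = cooperativity(other, k=5).C
        assert np.allclose(a, b)


class TestTransitionOverlap:
    def test_displacement_along_single_mode(self, exact_cg_module, cg_modes):
        s, _, H, K = build_system(30, seed=4)
        X = s.coords[np.asarray(K.kept_indices)]
        mode7 = cg_modes.eigenvectors[:, 6].reshape(-1, 3)
        end = X + 0.05 * mode7
        rep = transition_overlap(X, end, cg_modes, n_list=3)
        top_mode, _, top_ovlp = rep.rows[0]
        assert top_mode == 1
        assert top_ovlp > 0.999

    def test_rigid_rotation_signals_zero_displacement(self, cg_modes):
        s, _, _, K = build_system(30, seed=4)
        X = s.coords[np.asarray(K.kept_indices)]
        th = 0.3
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        with pytest.raises(NumericalError):
            transition_overlap(X, X @ R.T + np.array([5.0, -2.0, 1.0]), cg_modes)

    def test_completeness_sum_of_squares(self, cg_modes):
        s, _, _, K = build_system(30, seed=4)
        X = s.coords[np.asarray(K.kept_indices)]
        rng = np.random.default_rng(6)
        end = X + rng.normal(0.0, 0.02, X.shape)
        rep = transition_overlap(X, end, cg_modes, n_list=3)
        total = float((rep.all_overlaps ** 2).sum())
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_invariant_to_rigid_motion_of_end(self, cg_modes):
        s, _, _, K = build_system(30, seed=4)
        X = s.coords[np.asarray(K.kept_indices)]
        rng = np.random.default_rng(7)
        end = X + rng.normal(0.0, 0.05, X.shape)
        th = 0.8
        R = np.array([[1, 0, 0], [0, np.cos(th), -np.sin(th)],
                      [0, np.sin(th), np.cos(th)]])
        moved = end @ R.T + np.array([3.0, 4.0, -5.0])
        a = transition_overlap(X, end, cg_modes).all_overlaps
        b = transition_overlap(X, moved, cg_modes).all_overlaps
        assert np.abs(a - b).max() < 1e-6

    def test_too_few_sites(self, cg_modes):
        with pytest.raises(ValueError):
            transition_overlap(np.zeros((2, 3)), np.ones((2, 3)), cg_modes)


class TestSSEPreservation:
    def _structure_and_sites(self):
        import cgnma as cg

        s = cg.make_peptide(cg.FixtureSpec(40, "compact-globule", "cbeta", 0.05, 1))
        K = cg.select_sites(s, "calpha")
        return s, K

    def _translation_modeset(self, n_sites):
        dim = 3 * n_sites
        V = np.zeros((dim, 1))
        V[0::3, 0] = 1.0 / np.sqrt(n_sites)
        return ModeSet(eigenvalues=np.array([1.0]), eigenvectors=V, n_rigid=0,
                       n_sites=n_sites)

    def test_translation_mode_zero_deviation(self):
        s, K = self._structure_and_sites()
        ms = self._translation_modeset(len(K))
        per_mode, _, _ = sse_preservation(s, ms, rmsd_target=1.0, n_modes=1, sites=K)
        assert per_mode[0] == pytest.approx(0.0, abs=1e-10)

    def test_zero_target_zero_deviation(self):
        s, K = self._structure_and_sites()
        _, _, H, _ = build_system(40, seed=1, sidechain="cbeta")
        ms = eig_modes(cgnma.schur_project_exact(H, cgnma.select_sites(s, "calpha")),
                       n_rigid=6)
        per_mode, _, _ = sse_preservation(s, ms, rmsd_target=0.0, n_modes=3, sites=K)
        assert np.allclose(per_mode, 0.0, atol=1e-12)

    def test_stretching_one_helix_only(self):
        s, K = self._structure_and_sites()
        n = len(K)
        # synthetic mode: radially stretch the sites of the first SSE segment
        seg = s.sse_segments[0]
        members = [k for k, i in enumerate(K.kept_indices)
                   if seg.first_res <= s.atoms[i].res_index <= seg.last_res]
        X = s.coords[np.asarray(K.kept_indices)]
        V = np.zeros((3 * n, 1))
        center = X[members].mean(axis=0)
        for k in members:
            V[3 * k:3 * k + 3, 0] = X[k] - center
        V /= np.linalg.norm(V)
        ms = ModeSet(eigenvalues=np.array([1.0]), eigenvectors=V, n_rigid=0, n_sites=n)
        per_mode, _, _ = sse_preservation(s, ms, rmsd_target=1.0, n_modes=1, sites=K)
        assert per_mode[0] > 0.1

    def test_no_sse_errors(self):
        import cgnma as cg

        s = cg.make_peptide(cg.FixtureSpec(10, "helix", "cbeta", 0.0, 0))
        s.sse_segments.clear()
        ms = self._translation_modeset(10)
        with pytest.raises(StructureError):
            sse_preservation(s, ms, sites=cg.select_sites(s, "calpha"))


class TestSuperpose:
    def test_exact_recovery(self):
        rng = np.random.default_rng(11)
        P = rng.normal(size=(20, 3))
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        Q = P @ R.T + np.array([1.0, 2.0, 3.0])
        assert np.abs(superpose(Q, P) - P).max() < 1e-10
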