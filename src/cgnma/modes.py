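"""Normal-mode statistics: modes, MSF, B-factor scaling, weighted mode
overlap, best-match tables, cooperativity maps, transition overlaps and
secondary-structure preservation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import NumericalError, StructureError
from .structure import AtomicStructure, SiteSelection, select_sites

#: B = (8 pi^2 / 3) * MSF conversion constant (uncalibrated units)
BFACTOR_PER_MSF = 8.0 * np.pi ** 2 / 3.0


@dataclass
class ModeSet:
    """Ascending eigenpairs of a (coarse-grained) Hessian.

    ``eigenvectors[:, i]`` is the i-th mode (orthonormal, length 3n);
    ``n_rigid`` counts near-zero modes at the head of the spectrum.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_rigid: int
    n_sites: int

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def nonrigid(self) -> tuple[np.ndarray, np.ndarray]:
        """(eigenvalues, eigenvectors) with the rigid block stripped."""
        return self.eigenvalues[self.n_rigid:], self.eigenvectors[:, self.n_rigid:]

    def site_vectors(self, mode: int) -> np.ndarray:
        """(n_sites, 3) displacement of each site in the given mode column."""
        return self.eigenvectors[:, mode].reshape(self.n_sites, 3)


@dataclass
class MSFProfile:
    values: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class CooperativityMatrix:
    C: np.ndarray
    k_modes: int


@dataclass
class OverlapReport:
    """Rows of (index_a, index_b_or_label, overlap)."""

    rows: list


def _as_matrix(H) -> np.ndarray | sp.spmatrix:
    if hasattr(H, "matrix"):
        return H.matrix
    return H


def eig_modes(
    H,
    n_modes: int | None = None,
    rigid_tol: float = 1e-8,
    n_rigid: int | None = None,
) -> ModeSet:
    """Ascending eigenpairs of a symmetric Hessian.

    ``n_modes=None`` performs the full dense decomposition; a small
    ``n_modes`` uses a sparse shift-invert solve.  Rigid modes are counted
    as eigenvalues below ``rigid_tol * lambda_max`` unless ``n_rigid`` is
    pinned explicitly (useful for thresholded matrices whose null space is
    slightly perturbed).
    """
    m = _as_matrix(H)
    dim = m.shape[0]
    if m.shape[0] != m.shape[1]:
        raise NumericalError("Hessian must be square")
    asym = m - m.T
    max_asym = np.abs(asym.data).max() if sp.issparse(asym) and asym.nnz else (
        0.0 if sp.issparse(asym) else float(np.abs(asym).max()))
    scale = np.abs(m.data).max() if sp.issparse(m) and m.nnz else float(np.abs(_dense(m)).max() or 1.0)
    if max_asym > 1e-8 * max(scale, 1.0):
        raise NumericalError("Hessian is not symmetric")

    if n_modes is None or n_modes >= dim - 1:
        vals, vecs = sla.eigh(_dense(m))
    else:
        try:
            # shift well below zero (relative to the mean eigenvalue) so the
            # shifted operator stays well-conditioned despite the rigid modes
            A = m.tocsc() if sp.issparse(m) else m
            diag = A.diagonal() if sp.issparse(A) else np.diag(A)
            sigma = -max(1e-2 * float(np.mean(diag)), 1e-8)
            vals, vecs = spla.eigsh(A, k=n_modes, sigma=sigma, which="LM")
        except (spla.ArpackNoConvergence, RuntimeError) as exc:
            raise NumericalError(f"eigensolver failed: {exc}") from exc
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]

    if n_rigid is None:
        lam_max = max(float(vals.max()), 1e-300)
        n_rigid = int(np.sum(vals < rigid_tol * lam_max))
    return ModeSet(eigenvalues=vals, eigenvectors=vecs,
                   n_rigid=n_rigid, n_sites=dim // 3)


def _dense(m):
    return m.toarray() if sp.issparse(m) else np.asarray(m)


def msf(modes: ModeSet) -> MSFProfile:
    """Per-site mean-square fluctuation from all non-rigid modes.

    ``MSF_i = sum_j (1/lambda_j) * |m_j at site i|^2``, i.e. the trace of
    site i's 3x3 block of the Hessian pseudo-inverse.
    """
    lam, vecs = modes.nonrigid()
    if len(lam) == 0:
        raise NumericalError("no non-rigid modes available")
    contrib = (vecs ** 2) / lam[None, :]
    per_dof = contrib.sum(axis=1)
    return MSFProfile(values=per_dof.reshape(modes.n_sites, 3).sum(axis=1))


def rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3n x 6) of rigid translations/rotations of sites."""
    X = np.asarray(coords, dtype=float)
    n = len(X)
    Xc = X - X.mean(axis=0)
    R = np.zeros((3 * n, 6))
    for a in range(3):
        R[a::3, a] = 1.0
    for a, e in enumerate(np.eye(3)):
        R[:, 3 + a] = np.cross(np.broadcast_to(e, (n, 3)), Xc).ravel()
    Q, _ = np.linalg.qr(R)
    return Q


def kept_site_msf(modes: ModeSet, kept_indices, kept_coords) -> MSFProfile:
    """All-atom MSF restricted to kept sites, in the kept-site rigid gauge.

    The kept block of the all-atom pseudo-inverse carries a rank-6 rigid
    component that a coarse-grained Hessian's pseudo-inverse cannot (its
    null space spans the kept sites' own rigid motions); projecting that
    component out makes the kept-site covariance identical to the inverse
    of the exact Schur complement.
    """
    kept = np.asarray(kept_indices, dtype=int)
    ci = (3 * kept[:, None] + np.arange(3)).ravel()
    lam, vecs = modes.nonrigid()
    Vc = vecs[ci, :]
    C = (Vc / lam[None, :]) @ Vc.T
    Q = rigid_body_basis(kept_coords)
    C = C - Q @ (Q.T @ C)
    C = C - (C @ Q) @ Q.T
    n = len(kept)
    msf_vals = np.array([np.trace(C[3 * i:3 * i + 3, 3 * i:3 * i + 3]) for i in range(n)])
    return MSFProfile(values=msf_vals)


def fit_bfactor_scale(profile: MSFProfile | np.ndarray, bfactors) -> tuple[float, float]:
    """Least-RMSD scale of the MSF onto experimental B-factors + Pearson r."""
    x = profile.values if isinstance(profile, MSFProfile) else np.asarray(profile, float)
    b = np.asarray(bfactors, dtype=float)
    if len(x) != len(b) or len(x) < 3:
        raise ValueError("need equal-length inputs with >= 3 entries")
    denom = float(x @ x)
    if denom == 0 or np.std(x) == 0 or np.std(b) == 0:
        raise NumericalError("zero-variance input")
    scale = float(x @ b) / denom
    r = float(np.corrcoef(x, b)[0, 1])
    return scale, r


def weighted_mode_overlap(ref: ModeSet, test: ModeSet, n_skip: int = 6) -> float:
    """Eigenvalue-weighted same-index mode overlap.

    ``sum_i (w_i / w) |m_i . m^_i|`` over modes ``n_skip+1 .. 3n`` with
    weights ``w_i = 1/lambda_i`` taken from the reference spectrum.
    """
    if ref.eigenvectors.shape[0] != test.eigenvectors.shape[0]:
        raise ValueError("mode sets have different dimensions")
    n_avail = min(ref.n_modes, test.n_modes)
    if n_avail <= n_skip:
        raise ValueError("not enough modes beyond the skipped rigid block")
    lam = ref.eigenvalues[n_skip:n_avail]
    if np.any(lam <= 0):
        raise NumericalError("non-positive reference eigenvalue beyond the rigid block")
    w = 1.0 / lam
    dots = np.abs(np.einsum("di,di->i", ref.eigenvectors[:, n_skip:n_avail],
                            test.eigenvectors[:, n_skip:n_avail]))
    return float((w * dots).sum() / w.sum())


def best_match_overlaps(A: ModeSet, B: ModeSet, n_list: int = 13) -> OverlapReport:
    """For A's first ``n_list`` non-rigid modes, B's best-overlapping mode.

    Mode numbering in the report is 1-based over non-rigid modes, matching
    the usual table convention.
    """
    if A.eigenvectors.shape[0] != B.eigenvectors.shape[0]:
        raise ValueError("mode sets have different dimensions")
    _, va = A.nonrigid()
    _, vb = B.nonrigid()
    n_list = min(n_list, va.shape[1])
    ov = np.abs(va[:, :n_list].T @ vb)  # (n_list, n_B)
    rows = []
    for i in range(n_list):
        j = int(np.argmax(ov[i]))
        rows.append((i + 1, j + 1, float(ov[i, j])))
    return OverlapReport(rows=rows)


def cooperativity(modes: ModeSet, k: int = 15, weight_by_inverse_eigenvalue: bool = False) -> CooperativityMatrix:
    """Normalized site-site displacement covariance over the first k
    non-rigid modes (unweighted average by default)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    lam, vecs = modes.nonrigid()
    if vecs.shape[1] < k:
        raise ValueError(f"only {vecs.shape[1]} non-rigid modes available, need {k}")
    n = modes.n_sites
    R = vecs[:, :k].reshape(n, 3, k)
    if weight_by_inverse_eigenvalue:
        wts = 1.0 / lam[:k]
        wts = wts / wts.sum()
    else:
        wts = np.full(k, 1.0 / k)
    cov = np.einsum("iak,jak,k->ij", R, R, wts)
    diag = np.diag(cov).copy()
    if np.any(diag <= 0):
        raise NumericalError("site with zero displacement in all selected modes")
    C = cov / np.sqrt(np.outer(diag, diag))
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return CooperativityMatrix(C=C, k_modes=k)


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotation R and centroids aligning Q onto P (least-squares)."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Hm = (Q - cq).T @ (P - cp)
    U, _, Vt = np.linalg.svd(Hm)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cp, cq


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body fit of ``mobile`` onto ``target``."""
    R, ct, cm = _kabsch(target, mobile)
    return (mobile - cm) @ R.T + ct


def _coords_of(x) -> np.ndarray:
    if isinstance(x, AtomicStructure):
        return x.coords
    return np.asarray(x, dtype=float)


def transition_overlap(start, end, modes: ModeSet, n_list: int = 3) -> OverlapReport:
    """Overlap of each non-rigid mode with a conformational displacement.

    ``end`` is superposed onto ``start`` first; overlaps are
    ``|m_i . d| / (|m_i| |d|)``.  Returns the top ``n_list`` rows plus the
    full overlap vector on the report (attribute ``all_overlaps``).
    """
    P = _coords_of(start)
    Q = _coords_of(end)
    if P.shape != Q.shape:
        raise ValueError("start and end must have matching site sets")
    if len(P) < 3:
        raise ValueError("need at least 3 shared sites")
    Qfit = superpose(Q, P)
    d = (Qfit - P).ravel()
    nd = np.linalg.norm(d)
    if nd < 1e-10:
        raise NumericalError("zero displacement after superposition")
    d = d / nd
    _, vecs = modes.nonrigid()
    ov = np.abs(vecs.T @ d)
    top = np.argsort(ov)[::-1][:n_list]
    report = OverlapReport(rows=[(int(i + 1), "transition", float(ov[i])) for i in top])
    report.all_overlaps = ov
    return report


def sse_preservation(
    structure: AtomicStructure,
    modes: ModeSet,
    rmsd_target: float = 1.0,
    n_modes: int = 100,
    sites: SiteSelection | None = None,
) -> tuple[np.ndarray, float, float]:
    """Mean internal RMSD of SSE segments under unit-RMSD mode deformations.

    Each mode is scaled so the global site RMSD equals ``rmsd_target``; each
    SSE segment of the deformed structure is then superposed independently
    onto its undeformed self and its internal RMSD recorded.  Returns
    (per-mode segment-average RMSD, fit slope, fit intercept).
    """
    if not structure.sse_segments:
        raise StructureError("structure has no SSE segments")
    sites = sites or select_sites(structure, "calpha")
    if len(sites) != modes.n_sites:
        raise ValueError("mode set does not match the site selection")
    site_res = [(structure.atoms[i].chain, structure.atoms[i].res_index)
                for i in sites.kept_indices]
    seg_idx: list[np.ndarray] = []
    for seg in structure.sse_segments:
        members = [s for s, (ch, ri) in enumerate(site_res)
                   if ch == seg.chain and seg.first_res <= ri <= seg.last_res]
        if len(members) >= 3:
            seg_idx.append(np.array(members, dtype=int))
    if not seg_idx:
        raise StructureError("no SSE segment maps onto >= 3 sites")

    X0 = structure.coords[np.asarray(sites.kept_indices, dtype=int)]
    _, vecs = modes.nonrigid()
    n_modes = min(n_modes, vecs.shape[1])
    n = modes.n_sites
    out = np.zeros(n_modes)
    for m_i in range(n_modes):
        disp = vecs[:, m_i].reshape(n, 3)
        scale = rmsd_target * np.sqrt(n)  # unit eigenvector -> RMSD = scale/sqrt(n)
        X1 = X0 + scale * disp
        rmsds = []
        for idx in seg_idx:
            fit = superpose(X1[idx], X0[idx])
            rmsds.append(np.sqrt(((fit - X0[idx]) ** 2).sum(axis=1).mean()))
        out[m_i] = float(np.mean(rmsds))
    if n_modes >= 2:
        slope, intercept = np.polyfit(np.arange(1, n_modes + 1), out, 1)
    else:
        slope, intercept = 0.0, float(out[0])
    return out, float(slope), float(intercept)
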