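"""Schur-complement coarse-graining of sparse Hessians.

Two routes to the same object:

* :func:`schur_project_exact` — the one-shot projection
  ``H_cc - H_cr H_rr^-1 H_cr^T`` via a sparse factorization of the removed
  block (exact, expensive; the oracle).

* :func:`coarse_grain_iterative` — group-by-group elimination with hard
  thresholding.  Non-kept atoms are binned into cubic spatial cells, small
  cells are merged up to a size cap, the matrix is permuted to
  (kept | group_1 | ... | group_m) order with reverse Cuthill-McKee inside
  each group, and groups are eliminated smallest-first.  At each step the
  coupling block is thresholded at ``xi`` and the correction term at
  ``xi / m``; by the quotient property of Schur complements the result at
  ``xi = 0`` equals the exact projection up to roundoff.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .errors import NumericalError, StructureError
from .hessian import SparseHessian
from .structure import AtomicStructure, SiteSelection


@dataclass
class CoarseGrainConfig:
    """Knobs of the iterative elimination."""

    xi: float = 0.01
    cell_size: float = 18.0
    max_group: int = 500
    ordering: str = "cuthill_mckee"  # or "group_block", "input"
    pinv_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.xi < 0:
            raise ValueError("xi must be >= 0")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.max_group < 1:
            raise ValueError("max_group must be >= 1")
        if self.ordering not in ("cuthill_mckee", "group_block", "input"):
            raise ValueError(f"unknown ordering {self.ordering!r}")


@dataclass
class RemovalPlan:
    """Kept sites K plus the ordered removal groups R_1..R_m.

    Groups are stored in descending-size order; the elimination loop removes
    the last (smallest) group first.
    """

    K: SiteSelection
    groups: list[np.ndarray]

    def __post_init__(self) -> None:
        self.groups = [np.asarray(g, dtype=int) for g in self.groups]
        if any(len(g) == 0 for g in self.groups):
            raise ValueError("empty removal group")
        seen: set[int] = set(self.K.kept_indices)
        for g in self.groups:
            gs = set(g.tolist())
            if seen & gs:
                raise ValueError("removal groups overlap each other or K")
            seen |= gs

    @property
    def m(self) -> int:
        return len(self.groups)


@dataclass
class CGHessian:
    """Coarse-grained Hessian over the kept sites, with provenance."""

    matrix: sp.csr_matrix
    sites: SiteSelection
    provenance: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


def sparsify(A, b: float):
    """Hard-threshold: zero every entry with ``|A_ij| < b``."""
    if b < 0:
        raise ValueError("threshold must be >= 0")
    if sp.issparse(A):
        out = A.copy().tocsr()
        if b > 0 and out.nnz:
            out.data[np.abs(out.data) < b] = 0.0
            out.eliminate_zeros()
        return out
    out = np.array(A, copy=True)
    if b > 0:
        out[np.abs(out) < b] = 0.0
    return out


def _dof(atom_idx: np.ndarray) -> np.ndarray:
    """Expand atom indices to their three Cartesian dof indices."""
    atom_idx = np.asarray(atom_idx, dtype=int)
    return (3 * atom_idx[:, None] + np.arange(3)).ravel()


def schur_project_exact(H: SparseHessian, K: SiteSelection) -> CGHessian:
    """One-shot projection ``H_cc - H_cr H_rr^-1 H_cr^T`` (the oracle).

    The removed block is factorized sparsely (splu).  A singular removed
    block means some removed atoms are decoupled from every kept site; the
    error message names one offending component.
    """
    n = H.n_atoms
    kept = np.asarray(K.kept_indices, dtype=int)
    if len(kept) == 0:
        raise StructureError("K must be nonempty")
    mask = np.zeros(n, dtype=bool)
    mask[kept] = True
    removed = np.nonzero(~mask)[0]
    if len(removed) == 0:
        return CGHessian(matrix=H.matrix.copy(), sites=K,
                         provenance={"method": "exact", "xi": 0.0})

    ci = _dof(kept)
    ri = _dof(removed)
    Hcc = H.matrix[np.ix_(ci, ci)].tocsr()
    Hcr = H.matrix[np.ix_(ci, ri)].tocsr()
    Hrr = H.matrix[np.ix_(ri, ri)].tocsc()

    try:
        lu = spla.splu(Hrr)
        X = lu.solve(Hcr.T.toarray())
    except RuntimeError as exc:
        _raise_singular_removed(H, kept, removed, exc)
    if not np.all(np.isfinite(X)):
        _raise_singular_removed(H, kept, removed, None)

    cg = Hcc.toarray() - Hcr @ X
    cg = (cg + cg.T) / 2.0
    return CGHessian(matrix=sp.csr_matrix(cg), sites=K,
                     provenance={"method": "exact", "xi": 0.0})


def _raise_singular_removed(H: SparseHessian, kept: np.ndarray,
                            removed: np.ndarray, exc) -> None:
    """Diagnose which removed connected component is decoupled from K."""
    adj = (np.abs(H.matrix) > 0).astype(np.int8)
    # atom-level adjacency: collapse 3x3 blocks
    n = H.n_atoms
    coo = adj.tocoo()
    ai, aj = coo.row // 3, coo.col // 3
    atom_adj = sp.coo_matrix((np.ones_like(ai), (ai, aj)), shape=(n, n)).tocsr()
    ncomp, labels = csgraph.connected_components(atom_adj, directed=False)
    kept_labels = set(labels[kept].tolist())
    bad = [int(c) for c in range(ncomp) if c not in kept_labels]
    detail = f" (components without kept sites: {bad})" if bad else ""
    raise NumericalError(
        "removed block H_rr is singular: some removed atoms are decoupled "
        f"from every kept site{detail}") from exc


def spatial_partition(
    structure: AtomicStructure,
    K: SiteSelection,
    cfg: CoarseGrainConfig | None = None,
) -> RemovalPlan:
    """Bin non-kept atoms into cubic cells and merge the small ones.

    Cells of edge ``cell_size`` are anchored at the bounding-box minimum;
    empty cells are dropped, cells are sorted by atom count descending
    (ties broken by lattice coordinates), and the small end is repeatedly
    merged with the next smallest cell while the merged size stays within
    ``max_group``.
    """
    cfg = cfg or CoarseGrainConfig()
    n = len(structure)
    mask = np.zeros(n, dtype=bool)
    mask[np.asarray(K.kept_indices, dtype=int)] = True
    removed = np.nonzero(~mask)[0]
    if len(removed) == 0:
        return RemovalPlan(K=K, groups=[])

    xyz = structure.coords[removed]
    origin = xyz.min(axis=0)
    cells = np.floor((xyz - origin) / cfg.cell_size).astype(int)
    buckets: dict[tuple[int, int, int], list[int]] = {}
    for atom, cell in zip(removed, map(tuple, cells)):
        buckets.setdefault(cell, []).append(int(atom))

    # descending by size, lattice coordinates break ties deterministically
    items = sorted(buckets.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    blocks = [v for _, v in items]

    # merge from the small end: smallest absorbs next smallest while <= cap
    merged: list[list[int]] = []
    pending = list(reversed(blocks))  # ascending size
    while pending:
        cur = pending.pop(0)
        while pending and len(cur) + len(pending[0]) <= cfg.max_group:
            cur = cur + pending.pop(0)
        merged.append(cur)
    merged.sort(key=len, reverse=True)
    groups = [np.array(sorted(g), dtype=int) for g in merged]
    return RemovalPlan(K=K, groups=groups)


def _elimination_permutation(H: SparseHessian, plan: RemovalPlan,
                             cfg: CoarseGrainConfig) -> np.ndarray:
    """Atom permutation: K first, then groups in plan order (RCM inside)."""
    order: list[int] = list(plan.K.kept_indices)
    for g in plan.groups:
        if cfg.ordering == "cuthill_mckee" and len(g) > 1:
            gi = _dof(g)
            sub = H.matrix[np.ix_(gi, gi)]
            block = sp.coo_matrix(sub)
            ai, aj = block.row // 3, block.col // 3
            atom_sub = sp.coo_matrix(
                (np.ones_like(ai), (ai, aj)), shape=(len(g), len(g))).tocsr()
            perm = csgraph.reverse_cuthill_mckee(atom_sub, symmetric_mode=True)
            order.extend(int(g[p]) for p in perm)
        else:
            order.extend(int(a) for a in g)
    return np.asarray(order, dtype=int)


def reorder_for_elimination(H: SparseHessian, plan: RemovalPlan,
                            cfg: CoarseGrainConfig | None = None) -> SparseHessian:
    """Symmetric permutation to (K | R_1 | ... | R_m) order."""
    cfg = cfg or CoarseGrainConfig()
    order = _elimination_permutation(H, plan, cfg)
    di = _dof(order)
    mat = H.matrix[np.ix_(di, di)].tocsr()
    return SparseHessian(matrix=mat, atom_order=H.atom_order[order])


def coarse_grain_iterative(
    H: SparseHessian,
    plan: RemovalPlan,
    cfg: CoarseGrainConfig | None = None,
) -> CGHessian:
    """Iterative thresholded group elimination (the efficient route).

    For i = m..1 with k kept-side dofs and r = k + |R_i| dofs in play:
    ``B = sparsify(H[1..k, k+1..r], xi)``; ``D = H[k+1..r, k+1..r]``;
    ``E = sparsify(B D^-1 B^T, xi/m)``; ``H[1..k,1..k] -= E``.  The final
    kept-block is thresholded at ``xi`` and symmetrized.
    """
    cfg = cfg or CoarseGrainConfig()
    m = plan.m
    if m == 0:
        return CGHessian(matrix=H.matrix.copy(), sites=plan.K,
                         provenance={"method": "exact", "xi": cfg.xi,
                                     "note": "no atoms removed"})

    Hw = reorder_for_elimination(H, plan, cfg)
    cur = Hw.matrix.tocsr()
    group_dofs = [3 * len(g) for g in plan.groups]

    for i in range(m - 1, -1, -1):
        r = cur.shape[0]
        k = r - group_dofs[i]
        B = sparsify(cur[:k, k:], cfg.xi)
        D = cur[k:, k:].toarray()
        D = (D + D.T) / 2.0
        top = cur[:k, :k]

        if B.nnz == 0:
            # group decoupled from everything kept: Eq-4 correction vanishes,
            # but a fully floating group still signals a singular D
            cur = top.tocsr()
            _check_group_nonsingular(D, i)
            continue

        support = np.unique(B.tocoo().row)
        Bsub = B[support, :].toarray()
        try:
            cho = sla.cho_factor(D, lower=True, check_finite=False)
            X = sla.cho_solve(cho, Bsub.T, check_finite=False)
        except sla.LinAlgError as exc:
            raise NumericalError(
                f"diagonal block of removal group {i} is singular "
                "(group decoupled after sparsification)") from exc
        E = Bsub @ X
        E = (E + E.T) / 2.0
        if not np.all(np.isfinite(E)):
            raise NumericalError(f"non-finite correction for removal group {i}")
        if cfg.xi > 0:
            E[np.abs(E) < cfg.xi / m] = 0.0
        Ecoo = sp.coo_matrix(E)
        Esp = sp.coo_matrix(
            (Ecoo.data, (support[Ecoo.row], support[Ecoo.col])), shape=(k, k)).tocsr()
        cur = (top - Esp).tocsr()
        cur = ((cur + cur.T) / 2.0).tocsr()

    out = sparsify(cur, cfg.xi)
    out = ((out + out.T) / 2.0).tocsr()
    if not np.all(np.isfinite(out.data)):
        raise NumericalError("non-finite entries in coarse-grained Hessian")
    return CGHessian(
        matrix=out, sites=plan.K,
        provenance={"method": "iterative", "xi": cfg.xi, "m": m,
                    "group_sizes": [int(len(g)) for g in plan.groups],
                    "ordering": cfg.ordering},
    )


def _check_group_nonsingular(D: np.ndarray, group_id: int) -> None:
    try:
        sla.cho_factor(D, check_finite=False)
    except sla.LinAlgError as exc:
        raise NumericalError(
            f"diagonal block of removal group {group_id} is singular") from exc


def coarse_grain(
    structure: AtomicStructure,
    H: SparseHessian,
    K: SiteSelection,
    cfg: CoarseGrainConfig | None = None,
) -> CGHessian:
    """Convenience pipeline: spatial partition then iterative elimination."""
    cfg = cfg or CoarseGrainConfig()
    plan = spatial_partition(structure, K, cfg)
    return coarse_grain_iterative(H, plan, cfg)


def fit_power_law(sizes, times) -> tuple[float, float]:
    """Least-squares fit of ``t = a * n^b`` in log space; returns (a, b)."""
    sizes = np.asarray(sizes, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(sizes) < 3:
        raise ValueError("need at least 3 points")
    if np.any(sizes <= 0) or np.any(times <= 0):
        raise ValueError("sizes and times must be positive")
    b, loga = np.polyfit(np.log(sizes), np.log(times), 1)
    return float(np.exp(loga)), float(b)


def benchmark_scaling(build_fn, sizes, diagonalize=True):
    """Time coarse-graining (and optionally dense diagonalization) per size.

    ``build_fn(size)`` must return ``(structure, H, K)``.  Returns a list of
    dicts with per-size timings; used by the CLI bench command.
    """
    rows = []
    for size in sizes:
        structure, H, K = build_fn(size)
        t0 = time.perf_counter()
        cg = coarse_grain(structure, H, K)
        t_cg = time.perf_counter() - t0
        row = {"n_atoms": len(structure), "n_sites": len(K), "t_coarse_grain": t_cg}
        if diagonalize:
            dense = cg.toarray()
            t0 = time.perf_counter()
            sla.eigh(dense)
            row["t_diagonalize"] = time.perf_counter() - t0
        rows.append(row)
    return rows
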