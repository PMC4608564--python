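"""Sparse all-atom spring-network Hessians.

Every interaction is a Hookean pair spring along the inter-atom unit vector
r-hat, contributing the 3x3 super-element ``k * outer(r-hat, r-hat)``:
subtracted on the (i, j) off-diagonal blocks and added to both diagonal
blocks, which puts rigid translations (and, at equilibrium, rotations) in
the null space by construction.  Angle and torsion terms are represented as
surrogate springs across the 1-3 and 1-4 atom pairs; non-bonded terms use a
truncated 12-6 Lennard-Jones second derivative or a uniform constant,
depending on the model preset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import NumericalError, TopologyError
from .structure import AtomicStructure, Topology

logger = logging.getLogger(__name__)

#: textbook van der Waals radii per element (Angstrom)
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2}
#: inflated contact radii used by the ssnma_like surrogate so heavy-atom
#: structures (no hydrogens, no minimization) reach protein-like packing
CONTACT_RADII = {"C": 2.89, "N": 2.635, "O": 2.584, "S": 3.06, "H": 2.04}
DEFAULT_VDW_RADII = CONTACT_RADII
DEFAULT_VDW_RADIUS = 2.89

#: d/sigma at the inflection point of the 12-6 potential; V'' < 0 beyond it
LJ_INFLECTION = (26.0 / 7.0) ** (1.0 / 6.0)


@dataclass
class SpringRules:
    """Uniform spring constants per interaction class plus the vdW rule."""

    k_bond: float = 10000.0
    k_angle: float = 2000.0
    k_torsion: float = 500.0
    epsilon: float = 3000.0
    vdw_radii: dict = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))
    cutoff: float = 10.0
    nonbonded_model: str = "lj_truncated"  # or "uniform"
    k_nonbonded: float = 1.0  # used when nonbonded_model == "uniform"
    nonbonded_includes_14: bool = True
    #: clamp V'' on the repulsive branch to its value at the minimum; keeps
    #: unminimized contacts from injecting unphysically stiff springs
    clamp_inner_branch: bool = False
    model_label: str = "custom"

    def __post_init__(self) -> None:
        if min(self.k_bond, self.k_angle, self.k_torsion, self.k_nonbonded) < 0:
            raise ValueError("spring constants must be >= 0")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


def preset_rules(name: str) -> SpringRules:
    """Named parameter sets.

    ``ssnma_like``: distinct bonded constants + truncated LJ non-bonded.
    ``eanm_like``: two-tier (stiff bonded, uniform soft non-bonded).
    ``atomic_anm``: one uniform constant for every pair within the cutoff.
    ``calpha_anm``: uniform springs for CA-only structures, 13 A cutoff.
    """
    if name == "ssnma_like":
        return SpringRules(clamp_inner_branch=True, model_label=name)
    if name == "eanm_like":
        return SpringRules(k_bond=100.0, k_angle=100.0, k_torsion=100.0,
                           nonbonded_model="uniform", k_nonbonded=1.0,
                           nonbonded_includes_14=False, cutoff=8.0, model_label=name)
    if name == "atomic_anm":
        return SpringRules(k_bond=1.0, k_angle=1.0, k_torsion=1.0,
                           nonbonded_model="uniform", k_nonbonded=1.0,
                           nonbonded_includes_14=False, cutoff=8.0, model_label=name)
    if name == "calpha_anm":
        return SpringRules(k_bond=1.0, k_angle=1.0, k_torsion=1.0,
                           nonbonded_model="uniform", k_nonbonded=1.0,
                           nonbonded_includes_14=False, cutoff=13.0, model_label=name)
    raise ValueError(f"unknown preset {name!r}")


@dataclass
class SparseHessian:
    """Symmetric 3N x 3N Hessian in CSR form, organized in 3x3 atom blocks.

    ``atom_order[p]`` is the original atom index occupying block position p.
    """

    matrix: sp.csr_matrix
    atom_order: np.ndarray

    def __post_init__(self) -> None:
        self.atom_order = np.asarray(self.atom_order, dtype=int)
        if self.matrix.shape[0] != self.matrix.shape[1]:
            raise NumericalError("Hessian must be square")
        if self.matrix.shape[0] != 3 * len(self.atom_order):
            raise NumericalError("atom_order inconsistent with matrix dimension")

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atom_order)

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()

    def max_asymmetry(self) -> float:
        d = self.matrix - self.matrix.T
        return 0.0 if d.nnz == 0 else float(np.abs(d.data).max())


def pair_super_element(k: float, xi: np.ndarray, xj: np.ndarray) -> np.ndarray:
    """k * outer(r-hat, r-hat) for the spring between positions xi and xj."""
    if k < 0:
        raise ValueError("spring constant must be >= 0")
    d = np.asarray(xj, dtype=float) - np.asarray(xi, dtype=float)
    r = np.linalg.norm(d)
    if r == 0.0:
        raise NumericalError("coincident atoms in pair spring")
    u = d / r
    return k * np.outer(u, u)


def vdw_spring_constant(elem_i: str, elem_j: str, d: float, rules: SpringRules) -> float:
    """max(0, V_LJ''(d)) for the 12-6 potential, truncated at the inflection.

    sigma is set from the single radius table so the potential minimum sits
    at the sum of the two radii.
    """
    if d <= 0:
        raise ValueError("distance must be > 0")
    if d > rules.cutoff:
        return 0.0
    ri = rules.vdw_radii.get(elem_i.capitalize())
    rj = rules.vdw_radii.get(elem_j.capitalize())
    if ri is None:
        logger.debug("unknown element %r: default vdW radius", elem_i)
        ri = DEFAULT_VDW_RADIUS
    if rj is None:
        logger.debug("unknown element %r: default vdW radius", elem_j)
        rj = DEFAULT_VDW_RADIUS
    sigma = (ri + rj) / 2.0 ** (1.0 / 6.0)
    if d >= sigma * LJ_INFLECTION:
        return 0.0
    s6 = (sigma / d) ** 6
    v2 = 4.0 * rules.epsilon * (156.0 * s6 * s6 - 42.0 * s6) / d ** 2
    if rules.clamp_inner_branch and d < sigma * 2.0 ** (1.0 / 6.0):
        # V'' at the minimum: 72 eps / r_min^2 = 57.146... eps / sigma^2
        v2 = 72.0 * rules.epsilon / (ri + rj) ** 2
    return max(0.0, v2)


def build_hessian(
    structure: AtomicStructure,
    topology: Topology,
    rules: SpringRules,
) -> SparseHessian:
    """Sum pair-spring super-elements over all interaction classes.

    Classification precedence is bond > 1-3 > 1-4; non-bonded springs apply
    to the remaining pairs within the cutoff (and, for the LJ model, also to
    1-4 pairs unless disabled in the rules).
    """
    n = len(structure)
    coords = structure.coords
    elements = structure.elements

    pair_list: list[tuple[int, int]] = []
    k_list: list[float] = []

    p13 = topology.pair_13()
    p14 = topology.pair_14()
    for (i, j) in sorted(topology.bonds):
        pair_list.append((i, j))
        k_list.append(rules.k_bond)
    for (i, j) in sorted(p13):
        pair_list.append((i, j))
        k_list.append(rules.k_angle)
    for (i, j) in sorted(p14):
        pair_list.append((i, j))
        k_list.append(rules.k_torsion)

    nb = set(topology.nonbonded_pairs) - topology.bonds - p13
    if rules.nonbonded_model == "uniform" or not rules.nonbonded_includes_14:
        nb -= p14
    for (i, j) in sorted(nb):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d > rules.cutoff:
            continue
        if rules.nonbonded_model == "uniform":
            k = rules.k_nonbonded
        else:
            k = vdw_spring_constant(elements[i], elements[j], d, rules)
        if k > 0.0:
            pair_list.append((i, j))
            k_list.append(k)

    if not pair_list:
        mat = sp.csr_matrix((3 * n, 3 * n))
        return SparseHessian(matrix=mat, atom_order=np.arange(n))

    pairs = np.asarray(pair_list, dtype=int)
    ks = np.asarray(k_list, dtype=float)
    d = coords[pairs[:, 1]] - coords[pairs[:, 0]]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-8):
        bad = pairs[r < 1e-8][0]
        raise NumericalError(f"coincident interacting atoms {bad[0]} and {bad[1]}")
    u = d / r[:, None]
    blocks = ks[:, None, None] * np.einsum("pa,pb->pab", u, u)  # (P, 3, 3)

    P = len(pairs)
    a = np.repeat(np.arange(3), 3)
    b = np.tile(np.arange(3), 3)
    flat = blocks.reshape(P, 9)
    i3 = 3 * pairs[:, 0]
    j3 = 3 * pairs[:, 1]

    rows = np.concatenate([
        (i3[:, None] + a).ravel(), (j3[:, None] + a).ravel(),
        (i3[:, None] + a).ravel(), (j3[:, None] + a).ravel(),
    ])
    cols = np.concatenate([
        (j3[:, None] + b).ravel(), (i3[:, None] + b).ravel(),
        (i3[:, None] + b).ravel(), (j3[:, None] + b).ravel(),
    ])
    vals = np.concatenate([-flat.ravel(), -flat.ravel(), flat.ravel(), flat.ravel()])

    mat = sp.coo_matrix((vals, (rows, cols)), shape=(3 * n, 3 * n)).tocsr()
    mat.sum_duplicates()
    # exact symmetry: (a+b) and (b+a) are bitwise identical in IEEE arithmetic
    mat = ((mat + mat.T) / 2.0).tocsr()
    return SparseHessian(matrix=mat, atom_order=np.arange(n))


def sparseness(H: SparseHessian | sp.spmatrix | np.ndarray) -> float:
    """Fraction of exactly-zero scalar entries of the full matrix."""
    if isinstance(H, SparseHessian):
        m = H.matrix
    else:
        m = H
    if sp.issparse(m):
        total = m.shape[0] * m.shape[1]
        nz = int(np.count_nonzero(m.data)) if m.nnz else 0
        return 1.0 - nz / total
    m = np.asarray(m)
    return 1.0 - np.count_nonzero(m) / m.size


def save_hessian(H: SparseHessian, mtx_path, sidecar_path=None, metadata: dict | None = None) -> None:
    """MatrixMarket export plus a JSON sidecar with atom order and metadata."""
    from scipy.io import mmwrite

    mmwrite(str(mtx_path), sp.coo_matrix(H.matrix), symmetry="symmetric")
    if sidecar_path is not None:
        doc = {"atom_order": H.atom_order.tolist(), "dim": H.dim}
        if metadata:
            doc.update(metadata)
        with open(sidecar_path, "w") as fh:
            json.dump(doc, fh, indent=1)


def load_hessian(mtx_path, sidecar_path=None) -> SparseHessian:
    from scipy.io import mmread

    mat = sp.csr_matrix(mmread(str(mtx_path)))
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            doc = json.load(fh)
        order = np.asarray(doc["atom_order"], dtype=int)
    else:
        order = np.arange(mat.shape[0] // 3)
    return SparseHessian(matrix=mat, atom_order=order)
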