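"""Deterministic protein-like synthetic structures for desk-scale testing.

Backbones are grown residue by residue from ideal internal coordinates
(NeRF chain extension); geometry presets control the backbone torsions.
The ``compact-globule`` preset slowly modulates the helical torsions so the
helix axis curls into a compact superhelical fold, giving structures that
fill 3-D space the way folded proteins do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import StructureError
from .structure import Atom, AtomicStructure, SSESegment

# ideal backbone internal coordinates (Angstrom / degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.2, 116.2, 121.7
A_CA_C_O, A_N_CA_CB = 120.8, 110.5
OMEGA = 180.0

GEOMETRIES = ("helix", "extended", "compact-globule")
SIDECHAINS = ("none", "cbeta", "stub3")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic peptide."""

    n_residues: int
    geometry: str = "helix"
    sidechain: str = "cbeta"
    jitter_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise StructureError("n_residues must be >= 2")
        if self.jitter_sigma < 0:
            raise StructureError("jitter_sigma must be >= 0")
        if self.geometry not in GEOMETRIES:
            raise StructureError(f"unknown geometry {self.geometry!r}")
        if self.sidechain not in SIDECHAINS:
            raise StructureError(f"unknown sidechain {self.sidechain!r}")


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position atom d given the three preceding atoms a-b-c."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _torsion_schedule(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue (phi, psi) arrays for the requested geometry."""
    n = spec.n_residues
    if spec.geometry == "helix":
        return np.full(n, -57.0), np.full(n, -47.0)
    if spec.geometry == "extended":
        return np.full(n, -139.0), np.full(n, 135.0)
    # compact-globule: 12-residue helices joined by 4-residue turns whose
    # torsions reverse the chain direction, packing helices into a bundle
    i = np.arange(n)
    in_helix = (i % 16) < 12
    phi = np.where(in_helix, -57.0, -90.0)
    psi = np.where(in_helix, -47.0, 150.0)
    return phi, psi


def make_peptide(spec: FixtureSpec) -> AtomicStructure:
    """Build a single-chain peptide from ideal internal coordinates.

    Atom order per residue: N, CA, C, O, then side-chain stubs.  Helix
    fixtures carry a single HELIX segment annotation; extended fixtures a
    SHEET segment.
    """
    phi, psi = _torsion_schedule(spec)
    n = spec.n_residues

    names: list[str] = []
    res_of: list[int] = []
    coords: list[np.ndarray] = []

    # seed residue 0: N at origin, CA on +x, C in the xy-plane
    N0 = np.zeros(3)
    CA0 = np.array([B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(A_N_CA_C)
    C0 = CA0 + B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    backbone = [(N0, CA0, C0)]
    for i in range(1, n):
        Np, CAp, Cp = backbone[-1]
        Ni = _place(Np, CAp, Cp, B_C_N, A_CA_C_N, psi[i - 1])
        CAi = _place(CAp, Cp, Ni, B_N_CA, A_C_N_CA, OMEGA)
        Ci = _place(Cp, Ni, CAi, B_CA_C, A_N_CA_C, phi[i])
        backbone.append((Ni, CAi, Ci))

    res_name = {"none": "GLY", "cbeta": "ALA", "stub3": "LEU"}[spec.sidechain]
    for i, (Ni, CAi, Ci) in enumerate(backbone):
        names += ["N", "CA", "C", "O"]
        res_of += [i] * 4
        # carbonyl O opposite the next N (torsion psi + 180 about CA-C)
        Oi = _place(Ni, CAi, Ci, B_C_O, A_CA_C_O, psi[i] + 180.0)
        coords += [Ni, CAi, Ci, Oi]
        if spec.sidechain != "none":
            # CB off the N-CA axis, using C as torsion reference
            CBi = _place(Ci, Ni, CAi, B_CA_CB, A_N_CA_CB, 122.5)
            names.append("CB")
            res_of.append(i)
            coords.append(CBi)
            if spec.sidechain == "stub3":
                # off-trans torsions: an exactly-trans terminal stub would sit
                # at a 1-4 distance extremum and gain a spurious zero mode;
                # chi1=150 also keeps the stub clear of the preceding carbonyl
                CGi = _place(Ni, CAi, CBi, 1.52, 114.0, 150.0)
                CDi = _place(CAi, CBi, CGi, 1.52, 114.0, -65.0)
                names += ["CG", "CD"]
                res_of += [i, i]
                coords += [CGi, CDi]

    xyz = np.array(coords)
    if spec.jitter_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        xyz = xyz + rng.normal(0.0, spec.jitter_sigma, xyz.shape)

    atoms = [
        Atom(serial=k + 1, name=names[k], element=names[k][0],
             res_index=res_of[k] + 1, res_name=res_name, chain="A",
             coord=xyz[k], occupancy=1.0, bfactor=0.0)
        for k in range(len(names))
    ]
    sse: list[SSESegment] = []
    if spec.geometry == "helix":
        sse = [SSESegment("helix", "A", 1, n)]
    elif spec.geometry == "extended":
        sse = [SSESegment("strand", "A", 1, n)]
    else:  # compact-globule: one HELIX record per 12-residue helical block
        start = 0
        while start < n:
            stop = min(start + 12, n)
            if stop - start >= 4:
                sse.append(SSESegment("helix", "A", start + 1, stop))
            start += 16
    return AtomicStructure(atoms=atoms, sse_segments=sse)


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def make_multimer(spec: FixtureSpec, n_chains: int, packing_radius: float) -> AtomicStructure:
    """Place ``n_chains`` copies of the peptide on a ring (distinct chain ids).

    Raises when any inter-chain atom pair comes closer than 2.0 Angstrom.
    """
    if n_chains < 1:
        raise StructureError("n_chains must be >= 1")
    if n_chains > len(_CHAIN_IDS):
        raise StructureError("too many chains")
    base = make_peptide(spec)
    if n_chains == 1:
        return base
    xyz0 = base.coords - base.coords.mean(axis=0)

    atoms: list[Atom] = []
    sse: list[SSESegment] = []
    chain_coords: list[np.ndarray] = []
    serial = 1
    for c in range(n_chains):
        theta = 2 * np.pi * c / n_chains
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ])
        shift = packing_radius * np.array([np.cos(theta), np.sin(theta), 0.0])
        xyz = xyz0 @ rot.T + shift
        chain_coords.append(xyz)
        cid = _CHAIN_IDS[c]
        for a, pos in zip(base.atoms, xyz):
            atoms.append(Atom(serial=serial, name=a.name, element=a.element,
                              res_index=a.res_index, res_name=a.res_name, chain=cid,
                              coord=pos, occupancy=a.occupancy, bfactor=a.bfactor))
            serial += 1
        for seg in base.sse_segments:
            sse.append(SSESegment(seg.kind, cid, seg.first_res, seg.last_res))

    from scipy.spatial import cKDTree

    for c in range(n_chains):
        tree = cKDTree(chain_coords[c])
        other = chain_coords[(c + 1) % n_chains]
        dmin = tree.query(other, k=1)[0].min()
        if dmin < 2.0:
            raise StructureError(
                f"packing_radius={packing_radius} too small: inter-chain clash {dmin:.2f} A")
    return AtomicStructure(atoms=atoms, sse_segments=sse)


def perturb(structure: AtomicStructure, sigma: float, seed: int = 0) -> AtomicStructure:
    """Gaussian i.i.d. coordinate displacement; sigma=0 is the identity."""
    if sigma < 0:
        raise StructureError("sigma must be >= 0")
    xyz = structure.coords
    if sigma > 0:
        rng = np.random.default_rng(seed)
        xyz = xyz + rng.normal(0.0, sigma, xyz.shape)
    atoms = [
        Atom(serial=a.serial, name=a.name, element=a.element, res_index=a.res_index,
             res_name=a.res_name, chain=a.chain, coord=xyz[i],
             occupancy=a.occupancy, bfactor=a.bfactor)
        for i, a in enumerate(structure.atoms)
    ]
    return AtomicStructure(atoms=atoms, sse_segments=list(structure.sse_segments))


def radius_of_gyration(structure: AtomicStructure) -> float:
    xyz = structure.coords
    return float(np.sqrt(((xyz - xyz.mean(axis=0)) ** 2).sum(axis=1).mean()))
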