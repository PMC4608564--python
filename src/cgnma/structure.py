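"""Atomic structures, PDB input/output, interaction topology and site selection.

Internal atom indices are 0-based and contiguous over the retained atoms;
PDB serials (1-based) appear only in file I/O.  Topology detection is
distance-based: two heavy atoms are bonded when their separation does not
exceed the sum of their covalent radii scaled by ``1 + bond_tolerance``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import StructureError, TopologyError

logger = logging.getLogger(__name__)

#: Single-bond covalent radii (Angstrom), Cordero-style values.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
    "P": 1.07, "SE": 1.20, "FE": 1.32, "ZN": 1.22, "MG": 1.41,
}
DEFAULT_COVALENT_RADIUS = 0.77

#: Residue names dropped by default when reading PDB files.
SOLVENT_RESNAMES = {"HOH", "WAT", "DOD", "SOL", "NA", "CL", "K", "MG", "ZN", "CA", "SO4", "PO4"}


@dataclass
class Atom:
    """A single atom with its residue/chain identity and coordinates (Angstrom)."""

    serial: int
    name: str
    element: str
    res_index: int
    res_name: str
    chain: str
    coord: np.ndarray
    bfactor: float | None = None
    occupancy: float | None = None

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.serial}: coordinate must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.serial}: empty element symbol")


@dataclass
class SSESegment:
    """One secondary-structure segment (helix or strand) as a residue range."""

    kind: str  # "helix" | "strand"
    chain: str
    first_res: int
    last_res: int


@dataclass
class AtomicStructure:
    """Ordered collection of atoms, optionally annotated with SSE segments."""

    atoms: list[Atom]
    sse_segments: list[SSESegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError("structure must contain at least one atom")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise StructureError("atom serials must be unique")
        if any(not a.chain for a in self.atoms):
            raise StructureError("all chains must be non-empty strings")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in atom order."""
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def residues(self) -> list[tuple[str, int]]:
        """Distinct (chain, res_index) pairs in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.res_index), None)
        return list(seen)


@dataclass
class Topology:
    """Bonded and non-bonded interaction lists over 0-based atom indices."""

    bonds: set[tuple[int, int]]
    angles: set[tuple[int, int, int]]
    torsions: set[tuple[int, int, int, int]]
    nonbonded_pairs: set[tuple[int, int]]

    def pair_13(self) -> set[tuple[int, int]]:
        """1-3 pairs (angle end atoms), excluding pairs that are also bonds."""
        out = {tuple(sorted((i, k))) for i, _, k in self.angles}
        return out - self.bonds

    def pair_14(self) -> set[tuple[int, int]]:
        """1-4 pairs (torsion end atoms), excluding 1-2 and 1-3 pairs."""
        out = {tuple(sorted((i, l))) for i, _, _, l in self.torsions}
        return out - self.bonds - self.pair_13()


@dataclass
class SiteSelection:
    """Ordered list K of kept atom indices together with the scheme label."""

    kept_indices: list[int]
    scheme: str = "custom"

    def __post_init__(self) -> None:
        if len(set(self.kept_indices)) != len(self.kept_indices):
            raise StructureError("site selection contains duplicate indices")
        if not self.kept_indices:
            raise StructureError("site selection is empty")

    def __len__(self) -> int:
        return len(self.kept_indices)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    name = name.strip()
    if not name:
        return ""
    # two-letter elements present in protein PDB files
    head = name.lstrip("0123456789")
    if head[:2].upper() in ("FE", "ZN", "MG", "SE", "CL", "NA", "BR", "MN", "CU"):
        return head[:2].capitalize()
    return head[0].upper()


def read_pdb(
    path,
    model: int = 1,
    keep_hydrogens: bool = False,
    keep_solvent: bool = False,
) -> AtomicStructure:
    """Parse a fixed-column PDB file into an :class:`AtomicStructure`.

    Only ATOM records (and non-solvent HETATM when ``keep_solvent`` is off)
    of the requested model are retained.  Alternate locations keep the
    highest-occupancy conformer (ties resolved toward altloc ``'A'``).
    HELIX/SHEET records populate ``sse_segments``.
    """
    sse: list[SSESegment] = []
    raw: list[dict] = []
    current_model = 1
    in_model = True
    n_lines = 0
    try:
        fh = open(path)
    except OSError as exc:
        raise StructureError(f"cannot open PDB file {path!r}: {exc}") from exc
    with fh:
        for line in fh:
            n_lines += 1
            rec = line[:6]
            if rec == "MODEL ":
                current_model = int(line[10:14])
                in_model = current_model == model
                continue
            if rec == "ENDMDL":
                in_model = False
                continue
            if rec == "HELIX ":
                sse.append(SSESegment("helix", line[19].strip() or line[31].strip(),
                                      int(line[21:25]), int(line[33:37])))
                continue
            if rec == "SHEET ":
                sse.append(SSESegment("strand", line[21].strip(),
                                      int(line[22:26]), int(line[33:37])))
                continue
            if rec not in ("ATOM  ", "HETATM") or not in_model:
                continue
            try:
                coord = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            except ValueError as exc:
                raise StructureError(f"{path}: malformed coordinates on line {n_lines}") from exc
            name = line[12:16].strip()
            element = line[76:78].strip() if len(line) >= 78 else ""
            element = element.capitalize() if element else _guess_element(name)
            res_name = line[17:20].strip()
            if rec == "HETATM" and not keep_solvent and res_name in SOLVENT_RESNAMES:
                continue
            if res_name in ("HOH", "WAT") and not keep_solvent:
                continue
            if element == "H" and not keep_hydrogens:
                continue
            try:
                occ = float(line[54:60]) if line[54:60].strip() else None
            except ValueError:
                occ = None
            try:
                bf = float(line[60:66]) if line[60:66].strip() else None
            except ValueError:
                bf = None
            icode = line[26].strip()
            raw.append(dict(
                serial=int(line[6:11]),
                name=name,
                altloc=line[16].strip(),
                element=element,
                res_index=int(line[22:26]),
                icode=icode,
                res_name=res_name,
                chain=line[21].strip() or "A",
                coord=coord,
                occupancy=occ,
                bfactor=bf,
            ))

    # altloc resolution: keep highest occupancy, tie -> altloc 'A' (then first seen)
    best: dict[tuple, dict] = {}
    order: list[tuple] = []
    for r in raw:
        key = (r["chain"], r["res_index"], r["icode"], r["name"])
        if key not in best:
            best[key] = r
            order.append(key)
            continue
        cur = best[key]
        occ_new = r["occupancy"] if r["occupancy"] is not None else 0.0
        occ_cur = cur["occupancy"] if cur["occupancy"] is not None else 0.0
        if occ_new > occ_cur or (occ_new == occ_cur and r["altloc"] == "A" and cur["altloc"] != "A"):
            best[key] = r

    atoms = []
    for key in order:
        r = best[key]
        atoms.append(Atom(serial=r["serial"], name=r["name"], element=r["element"],
                          res_index=r["res_index"], res_name=r["res_name"], chain=r["chain"],
                          coord=r["coord"], bfactor=r["bfactor"], occupancy=r["occupancy"]))
    if not atoms:
        raise StructureError(f"{path}: no atoms retained after filtering")
    return AtomicStructure(atoms=atoms, sse_segments=sse)


def write_pdb(structure: AtomicStructure, path) -> None:
    """Write fixed-column PDB with TER records between chains."""
    try:
        fh = open(path, "w")
    except OSError as exc:
        raise StructureError(f"cannot write PDB file {path!r}: {exc}") from exc
    with fh:
        for seg in structure.sse_segments:
            if seg.kind == "helix":
                fh.write(f"HELIX    1   1 ALA {seg.chain:1s} {seg.first_res:4d}  "
                         f"ALA {seg.chain:1s} {seg.last_res:4d}  1"
                         + " " * 30 + f"{seg.last_res - seg.first_res + 1:5d}\n")
            else:
                fh.write(f"SHEET    1   A 1 ALA {seg.chain:1s}{seg.first_res:4d}  "
                         f"ALA {seg.chain:1s}{seg.last_res:4d}  0\n")
        prev_chain = None
        last = None
        for a in structure.atoms:
            if prev_chain is not None and a.chain != prev_chain:
                fh.write(f"TER   {last.serial + 1:5d}      {last.res_name:>3s} "
                         f"{last.chain:1s}{last.res_index:4d}\n")
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            occ = a.occupancy if a.occupancy is not None else 1.0
            bf = a.bfactor if a.bfactor is not None else 0.0
            fh.write(
                f"ATOM  {a.serial:5d} {name:4s} {a.res_name:>3s} {a.chain:1s}"
                f"{a.res_index:4d}    {a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
                f"{occ:6.2f}{bf:6.2f}          {a.element:>2s}\n"
            )
            prev_chain = a.chain
            last = a
        fh.write(f"TER   {last.serial + 1:5d}      {last.res_name:>3s} "
                 f"{last.chain:1s}{last.res_index:4d}\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def infer_topology(
    structure: AtomicStructure,
    bond_tolerance: float = 0.15,
    nonbonded_cutoff: float = 8.0,
) -> Topology:
    """Detect bonds by covalent-radius distances and enumerate angles,
    torsions and non-bonded pairs.

    Non-bonded pairs are all pairs within ``nonbonded_cutoff`` that are
    neither 1-2 (bond) nor 1-3 (angle-flanked).
    """
    if bond_tolerance <= 0:
        raise TopologyError("bond_tolerance must be > 0")
    coords = structure.coords
    n = len(structure)
    radii = np.array([
        COVALENT_RADII.get(e.upper(), DEFAULT_COVALENT_RADIUS) for e in structure.elements
    ])
    tree = cKDTree(coords)
    max_bond = (radii.max() * 2) * (1.0 + bond_tolerance)
    bonds: set[tuple[int, int]] = set()
    for i, j in tree.query_pairs(max_bond):
        d = np.linalg.norm(coords[i] - coords[j])
        if d <= (radii[i] + radii[j]) * (1.0 + bond_tolerance):
            bonds.add((min(i, j), max(i, j)))

    neigh: list[list[int]] = [[] for _ in range(n)]
    for i, j in bonds:
        neigh[i].append(j)
        neigh[j].append(i)

    angles: set[tuple[int, int, int]] = set()
    for j in range(n):
        nb = sorted(neigh[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                angles.add((nb[a], j, nb[b]))

    torsions: set[tuple[int, int, int, int]] = set()
    for j, k in bonds:
        for i in neigh[j]:
            if i == k:
                continue
            for l in neigh[k]:
                if l == j or l == i:
                    continue
                tors = min((i, j, k, l), (l, k, j, i))
                torsions.add(tors)

    excluded = set(bonds)
    excluded |= {tuple(sorted((i, k))) for i, _, k in angles}
    nonbonded: set[tuple[int, int]] = set()
    for i, j in tree.query_pairs(nonbonded_cutoff):
        p = (min(i, j), max(i, j))
        if p not in excluded:
            nonbonded.add(p)

    return Topology(bonds=bonds, angles=angles, torsions=torsions, nonbonded_pairs=nonbonded)


def bond_graph_components(structure: AtomicStructure, topology: Topology) -> list[set[int]]:
    """Connected components of the bond graph (used by validity checks)."""
    n = len(structure)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in topology.bonds:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    comps: dict[int, set[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return list(comps.values())


# ---------------------------------------------------------------------------
# Site selection
# ---------------------------------------------------------------------------

def select_sites(
    structure: AtomicStructure,
    scheme: str = "calpha",
    custom: Sequence[int] | None = None,
) -> SiteSelection:
    """Select the kept atom indices K.

    ``calpha`` keeps one CA carbon per residue, ``backbone`` keeps
    N/CA/C/O, ``custom`` uses an explicit index list.  Ordering is by
    (chain, res_index) then atom order.
    """
    if scheme == "custom":
        if custom is None:
            raise StructureError("custom scheme requires an index list")
        idx = list(custom)
        if any(i < 0 or i >= len(structure) for i in idx):
            raise StructureError("custom site index out of range")
        return SiteSelection(kept_indices=idx, scheme="custom")
    if scheme not in ("calpha", "backbone"):
        raise StructureError(f"unknown site-selection scheme {scheme!r}")

    wanted = {"CA"} if scheme == "calpha" else {"N", "CA", "C", "O"}
    picked: dict[tuple[str, int, str], int] = {}
    for i, a in enumerate(structure.atoms):
        if a.name in wanted and a.element.upper() != "CA":  # exclude calcium ions
            key = (a.chain, a.res_index, a.name)
            picked.setdefault(key, i)
    indices = [picked[k] for k in sorted(picked, key=lambda k: (k[0], k[1], k[2]))]
    if not indices:
        raise StructureError(f"scheme {scheme!r} selects no atoms")
    return SiteSelection(kept_indices=indices, scheme=scheme)
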