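"""Molecular structure model, perception and pharmacophore typing.

Units: coordinates in Angstrom, partial charges in elementary units.
Indexing is 0-based throughout; PDB serials are preserved for output only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .elements import COVALENT_RADIUS, VDW_RADIUS, normalize_element
from .geometry import best_fit_plane

#: distance tolerance added to the covalent-radius sum for bond perception (A)
BOND_TOLERANCE = 0.45
#: max out-of-plane deviation for a ring to be flagged planar (A)
RING_PLANARITY_TOL = 0.15


class InputError(ValueError):
    """Unusable input (missing file, malformed record, bad arguments)."""


class EmptyStructureError(InputError):
    """A structure with zero atoms where atoms are required."""


ResidueId = tuple[str, int, str]  # (chain id, residue number, residue name)


@dataclass
class Atom:
    element: str
    coords: np.ndarray  # shape (3,), A
    partial_charge: float = 0.0
    vdw_radius: float = 0.0
    name: str = ""
    residue_id: ResidueId = ("A", 1, "UNK")
    is_hydrogen: bool = False
    serial: int | None = None  # input PDB serial, output only

    def __post_init__(self) -> None:
        self.element = normalize_element(self.element)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if self.vdw_radius <= 0.0:
            self.vdw_radius = VDW_RADIUS[self.element]
        self.is_hydrogen = self.element == "H"

    @property
    def covalent_radius(self) -> float:
        return COVALENT_RADIUS[self.element]


@dataclass
class Ring:
    indices: tuple[int, ...]  # ordered along the cycle
    planar: bool


@dataclass
class Structure:
    """An ordered set of atoms with an optional bond/ring topology."""

    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    rings: list[Ring] = field(default_factory=list)
    role: str = "receptor"  # receptor | ligand
    name: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, row in zip(self.atoms, xyz):
            a.coords = row.copy()

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if not a.is_hydrogen]

    def residue_ids(self) -> list[ResidueId]:
        seen: dict[ResidueId, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_id, None)
        return list(seen)

    def atoms_of_residue(self, rid: ResidueId) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.residue_id == rid]

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(len(self.atoms))}
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from(self.bonds)
        return g

    def copy(self) -> "Structure":
        # hot path (MC moves, pose searches): clone atoms without re-running
        # dataclass validation
        atoms = []
        for a in self.atoms:
            b = Atom.__new__(Atom)
            b.element = a.element
            b.coords = a.coords.copy()
            b.partial_charge = a.partial_charge
            b.vdw_radius = a.vdw_radius
            b.name = a.name
            b.residue_id = a.residue_id
            b.is_hydrogen = a.is_hydrogen
            b.serial = a.serial
            atoms.append(b)
        out = Structure.__new__(Structure)
        out.atoms = atoms
        out.bonds = list(self.bonds)
        out.rings = [Ring(r.indices, r.planar) for r in self.rings]
        out.role = self.role
        out.name = self.name
        return out

    def translated(self, shift: np.ndarray) -> "Structure":
        out = self.copy()
        out.set_coords(out.coords + np.asarray(shift, float))
        return out


@dataclass(frozen=True)
class PharmacophoreTag:
    atom_index: int
    tag: str  # cation | anion | hbond_donor | hbond_acceptor | aromatic_ring_member
    h_index: int | None = None  # attached H for donors

    VALID = frozenset(
        {"cation", "anion", "hbond_donor", "hbond_acceptor", "aromatic_ring_member"}
    )

    def __post_init__(self) -> None:
        if self.tag not in self.VALID:
            raise ValueError(f"unknown pharmacophore tag {self.tag!r}")


@dataclass(frozen=True)
class ActiveSite:
    residue_ids: frozenset[ResidueId]
    radius: float


# ---------------------------------------------------------------------------
# perception


def perceive_bonds_and_rings(
    s: Structure,
    bond_tolerance: float = BOND_TOLERANCE,
    planarity_tol: float = RING_PLANARITY_TOL,
) -> Structure:
    """Assign bonds by covalent-radius distance and perceive minimal rings.

    A bond is recorded where the interatomic distance is at most the sum of
    covalent radii plus ``bond_tolerance``. Rings are a minimum cycle basis
    of the bond graph; a ring is flagged planar when no member deviates more
    than ``planarity_tol`` from the best-fit plane. Isolated atoms are fine.
    """
    xyz = s.coords
    bonds: list[tuple[int, int]] = []
    if len(s) >= 2:
        max_cut = max(COVALENT_RADIUS.values()) * 2 + bond_tolerance
        tree = cKDTree(xyz)
        for i, j in sorted(tree.query_pairs(max_cut)):
            cut = s.atoms[i].covalent_radius + s.atoms[j].covalent_radius + bond_tolerance
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            if 0.4 < d <= cut:
                bonds.append((i, j))
    s.bonds = bonds
    g = s.graph()
    rings: list[Ring] = []
    for cycle in nx.minimum_cycle_basis(g):
        ordered = _order_cycle(g, cycle)
        _, _, dev = best_fit_plane(xyz[ordered])
        rings.append(Ring(tuple(ordered), planar=dev <= planarity_tol))
    s.rings = sorted(rings, key=lambda r: r.indices)
    return s


def _order_cycle(g: nx.Graph, nodes: list[int]) -> list[int]:
    """Order a cycle-basis node set into a walk along ring bonds."""
    sub = g.subgraph(nodes)
    start = min(nodes)
    ordered = [start]
    prev = None
    cur = start
    while len(ordered) < len(nodes):
        nbrs = [n for n in sub.neighbors(cur) if n != prev and n not in ordered[1:]]
        if not nbrs:
            break
        nxt = min(nbrs)
        ordered.append(nxt)
        prev, cur = cur, nxt
    return ordered


# ---------------------------------------------------------------------------
# pharmacophore typing

# receptor side-chain templates: residue name -> atom-name based roles
_ANION_ATOMS = {"GLU": {"OE1", "OE2"}, "ASP": {"OD1", "OD2"}}
_CATION_ATOMS = {"ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}}
_AROMATIC_ATOMS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}
_SIDECHAIN_ACCEPTORS = {
    "GLU": {"OE1", "OE2"},
    "ASP": {"OD1", "OD2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "HIS": {"ND1", "NE2"},
    "MET": set(),
}
_SIDECHAIN_DONOR_HEAVY = {
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "TRP": {"NE1"},
    "HIS": {"ND1", "NE2"},
}
_KNOWN_RESIDUES = (
    set(_ANION_ATOMS)
    | set(_CATION_ATOMS)
    | set(_AROMATIC_ATOMS)
    | set(_SIDECHAIN_ACCEPTORS)
    | set(_SIDECHAIN_DONOR_HEAVY)
    | {"GLY", "ALA", "VAL", "LEU", "ILE", "PRO", "CYS", "MET"}
)


def assign_pharmacophore_types(s: Structure) -> list[PharmacophoreTag]:
    """Derive pharmacophoric tags deterministically.

    Receptor structures are typed from residue-name templates (with element
    rules as fallback for unknown residue names, after a warning); ligand
    structures from element and bond environment. Bonds must be perceived;
    donors require explicit hydrogens (heavy-atom donors are emitted with a
    warning when the hydrogen is absent).
    """
    if s.bonds == [] and len(s) > 1:
        raise InputError("assign_pharmacophore_types: perceive bonds first")
    tags: list[PharmacophoreTag] = []
    if s.role == "receptor":
        tags.extend(_receptor_tags(s))
    else:
        tags.extend(_ligand_tags(s))
    return sorted(tags, key=lambda t: (t.atom_index, t.tag, -1 if t.h_index is None else t.h_index))


def _attached_hydrogens(s: Structure, idx: int) -> list[int]:
    adj = s.adjacency()
    return [j for j in adj[idx] if s.atoms[j].is_hydrogen]


def _donor_tags(s: Structure, idx: int) -> list[PharmacophoreTag]:
    hs = _attached_hydrogens(s, idx)
    if hs:
        return [PharmacophoreTag(idx, "hbond_donor", h) for h in hs]
    warnings.warn(
        f"donor heavy atom {s.atoms[idx].name!r} has no hydrogen; "
        "treated as heavy-atom donor (angle checks skipped)",
        stacklevel=3,
    )
    return [PharmacophoreTag(idx, "hbond_donor", None)]


def _receptor_tags(s: Structure) -> list[PharmacophoreTag]:
    tags: list[PharmacophoreTag] = []
    adj = s.adjacency()
    warned: set[str] = set()
    for i, a in enumerate(s.atoms):
        if a.is_hydrogen:
            continue
        resname = a.residue_id[2]
        if resname not in _KNOWN_RESIDUES:
            if resname not in warned:
                warnings.warn(f"unknown residue {resname!r}: element rules only", stacklevel=3)
                warned.add(resname)
            tags.extend(_element_rule_tags(s, i, adj))
            continue
        nm = a.name
        # backbone
        if nm == "O" and a.element == "O":
            tags.append(PharmacophoreTag(i, "hbond_acceptor"))
        elif nm == "N" and a.element == "N" and resname != "PRO":
            tags.extend(_donor_tags(s, i))
        # side chain templates
        if nm in _ANION_ATOMS.get(resname, ()):
            tags.append(PharmacophoreTag(i, "anion"))
        if nm in _CATION_ATOMS.get(resname, ()):
            tags.append(PharmacophoreTag(i, "cation"))
        if nm in _AROMATIC_ATOMS.get(resname, ()):
            tags.append(PharmacophoreTag(i, "aromatic_ring_member"))
        if nm in _SIDECHAIN_ACCEPTORS.get(resname, ()):
            tags.append(PharmacophoreTag(i, "hbond_acceptor"))
        if nm in _SIDECHAIN_DONOR_HEAVY.get(resname, ()):
            tags.extend(_donor_tags(s, i))
    return tags


def _element_rule_tags(
    s: Structure, i: int, adj: dict[int, list[int]]
) -> list[PharmacophoreTag]:
    """Fallback element/bond-environment rules (also the ligand rules)."""
    a = s.atoms[i]
    tags: list[PharmacophoreTag] = []
    heavy_nbrs = [j for j in adj[i] if not s.atoms[j].is_hydrogen]
    hs = _attached_hydrogens(s, i)
    if a.element == "N":
        if len(adj[i]) == 4:  # quaternary / protonated amine
            tags.append(PharmacophoreTag(i, "cation"))
        elif not hs and len(heavy_nbrs) <= 2:
            tags.append(PharmacophoreTag(i, "hbond_acceptor"))
        if hs:
            tags.extend(PharmacophoreTag(i, "hbond_donor", h) for h in hs)
    elif a.element == "O":
        tags.append(PharmacophoreTag(i, "hbond_acceptor"))
        if hs:
            tags.extend(PharmacophoreTag(i, "hbond_donor", h) for h in hs)
        # carboxylate: O bonded to C that carries another terminal O
        if len(heavy_nbrs) == 1 and not hs:
            c = heavy_nbrs[0]
            if s.atoms[c].element == "C":
                other_os = [
                    j
                    for j in adj[c]
                    if j != i
                    and s.atoms[j].element == "O"
                    and len([k for k in adj[j] if not s.atoms[k].is_hydrogen]) == 1
                    and not _attached_hydrogens(s, j)
                ]
                if other_os:
                    tags.append(PharmacophoreTag(i, "anion"))
    return tags


def _ligand_tags(s: Structure) -> list[PharmacophoreTag]:
    tags: list[PharmacophoreTag] = []
    adj = s.adjacency()
    for i, a in enumerate(s.atoms):
        if a.is_hydrogen:
            continue
        tags.extend(_element_rule_tags(s, i, adj))
    # aromatic rings: planar all-carbon rings (each member carries <=1 H)
    for ring in s.rings:
        if not ring.planar:
            continue
        if all(
            s.atoms[i].element == "C" and len(_attached_hydrogens(s, i)) <= 1
            for i in ring.indices
        ):
            tags.extend(PharmacophoreTag(i, "aromatic_ring_member") for i in ring.indices)
    return tags


# ---------------------------------------------------------------------------
# rotatable bonds


def list_rotatable_bonds(s: Structure) -> list[tuple[int, int]]:
    """Acyclic single bonds between two non-terminal heavy atoms.

    Amide C-N bonds (C bearing a short C=O contact) are excluded. Ordering
    is deterministic: sorted by (i, j).
    """
    adj = s.adjacency()
    ring_atoms = [set(r.indices) for r in s.rings]
    out: list[tuple[int, int]] = []
    for i, j in sorted(tuple(sorted(b)) for b in s.bonds):
        ai, aj = s.atoms[i], s.atoms[j]
        if ai.is_hydrogen or aj.is_hydrogen:
            continue
        if any(i in ring and j in ring for ring in ring_atoms):
            continue
        hv_i = [k for k in adj[i] if not s.atoms[k].is_hydrogen]
        hv_j = [k for k in adj[j] if not s.atoms[k].is_hydrogen]
        if len(hv_i) < 2 or len(hv_j) < 2:
            continue  # terminal
        if _is_amide_cn(s, adj, i, j) or _is_amide_cn(s, adj, j, i):
            continue
        out.append((i, j))
    return out


def _is_amide_cn(s: Structure, adj: dict[int, list[int]], c: int, n: int) -> bool:
    if s.atoms[c].element != "C" or s.atoms[n].element != "N":
        return False
    for k in adj[c]:
        if s.atoms[k].element == "O" and np.linalg.norm(
            s.atoms[k].coords - s.atoms[c].coords
        ) <= 1.35:
            return True
    return False


# ---------------------------------------------------------------------------
# active site


def select_active_site(
    receptor: Structure, template: Structure, radius: float = 6.0
) -> ActiveSite:
    """Residues with any heavy atom within ``radius`` of a template heavy atom.

    The 6 A default matches the usual docking-grid convention of taking all
    residues around the template ligand.
    """
    if len(receptor) == 0 or len(template) == 0:
        raise EmptyStructureError("select_active_site: empty receptor or template")
    t_heavy = template.coords[template.heavy_indices()]
    if len(t_heavy) == 0:
        raise InputError("select_active_site: template has no heavy atoms")
    tree = cKDTree(t_heavy)
    included: set[ResidueId] = set()
    for i in receptor.heavy_indices():
        a = receptor.atoms[i]
        if a.residue_id in included:
            continue
        d, _ = tree.query(a.coords)
        if d <= radius:
            included.add(a.residue_id)
    return ActiveSite(residue_ids=frozenset(included), radius=radius)
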