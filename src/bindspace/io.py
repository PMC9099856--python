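"""Reading and writing PDB / SDF structures and pose sets.

PDB files are parsed with gemmi (first model, first altloc); SDF records
with RDKit (sanitization off, hydrogens kept). Writers are plain
fixed-width formatters so that partial charges and pose scores survive a
round trip via an auxiliary SDF property.
"""

from __future__ import annotations

import os
from typing import Iterable

import gemmi
import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .structures import (
    Atom,
    EmptyStructureError,
    InputError,
    Structure,
    perceive_bonds_and_rings,
)

RDLogger.DisableLog("rdApp.*")

#: SDF property carrying the pose score, configurable per call
DEFAULT_SCORE_KEY = "dG"
#: SDF property used to round-trip per-atom partial charges
CHARGE_PROPERTY = "partial_charges"

# built-in per-template partial charges (elementary units); formal charges
# spread over the charged group, small dipoles on polar backbone atoms
_BACKBONE_CHARGES = {"O": -0.4, "C": 0.4, "N": -0.3, "H": 0.3}
_SIDECHAIN_CHARGES: dict[str, dict[str, float]] = {
    "GLU": {"OE1": -0.6, "OE2": -0.6, "CD": 0.2},
    "ASP": {"OD1": -0.6, "OD2": -0.6, "CG": 0.2},
    "ARG": {"NE": 0.2, "NH1": 0.3, "NH2": 0.3, "CZ": 0.2},
    "LYS": {"NZ": 0.4, "HZ1": 0.2, "HZ2": 0.2, "HZ3": 0.2},
    "SER": {"OG": -0.4, "HG": 0.4},
    "THR": {"OG1": -0.4, "HG1": 0.4},
    "TYR": {"OH": -0.4, "HH": 0.4},
    "ASN": {"OD1": -0.4, "ND2": -0.3, "HD21": 0.35, "HD22": 0.35},
    "GLN": {"OE1": -0.4, "NE2": -0.3, "HE21": 0.35, "HE22": 0.35},
}


def apply_template_charges(s: Structure) -> Structure:
    """Assign built-in per-residue partial charges in place.

    Used when the input format carries no charges (plain PDB). Standard
    protonation states are assumed: Asp/Glu deprotonated, Arg/Lys
    protonated, His neutral.
    """
    for a in s.atoms:
        resname = a.residue_id[2]
        q = _SIDECHAIN_CHARGES.get(resname, {}).get(a.name)
        if q is None:
            q = _BACKBONE_CHARGES.get(a.name, 0.0)
        a.partial_charge = q
    return s


# ---------------------------------------------------------------------------
# PDB


def read_pdb_structure(path: str | os.PathLike, role: str = "receptor") -> Structure:
    """Read coordinate records from a PDB file.

    First model only; for alternate locations the first (blank or 'A')
    altloc is kept; insertion codes are ignored. Charges are filled from
    the built-in template table for receptor structures. Bonds and rings
    are not perceived here.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(path, merge_chain_parts=True)
    except Exception as exc:  # gemmi raises RuntimeError on garbage
        raise InputError(f"unreadable PDB file {path}: {exc}") from exc
    atoms: list[Atom] = []
    serial = 0
    if len(st) > 0:
        model = st[0]
        for chain in model:
            for res in chain:
                seen: set[str] = set()
                for at in res:
                    if at.name in seen:
                        continue  # later altloc of an already-kept atom
                    if at.altloc not in ("", "\x00", "A"):
                        continue
                    seen.add(at.name)
                    serial += 1
                    atoms.append(
                        Atom(
                            element=at.element.name,
                            coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            name=at.name,
                            residue_id=(chain.name, res.seqid.num, res.name),
                            serial=at.serial or serial,
                        )
                    )
    if not atoms:
        raise EmptyStructureError(f"{path}: no coordinate records")
    s = Structure(atoms=atoms, role=role, name=os.path.basename(path))
    if role == "receptor":
        apply_template_charges(s)
    return s


def split_hetero_ligand(s: Structure, resname: str) -> tuple[Structure, Structure]:
    """Separate a HETATM ligand (by residue name) from the rest."""
    lig_idx = [i for i, a in enumerate(s.atoms) if a.residue_id[2] == resname]
    if not lig_idx:
        raise InputError(f"no residue named {resname!r} in structure")
    lig = Structure(
        atoms=[s.atoms[i] for i in lig_idx], role="ligand", name=resname
    )
    rest = Structure(
        atoms=[a for i, a in enumerate(s.atoms) if i not in set(lig_idx)],
        role=s.role,
        name=s.name,
    )
    return rest, lig


def write_pdb_structure(s: Structure, path: str | os.PathLike) -> None:
    """Write a structure as PDB ATOM/HETATM records (3-decimal coords)."""
    lines = []
    for i, a in enumerate(s.atoms):
        record = "HETATM" if s.role == "ligand" else "ATOM  "
        chain, resnum, resname = a.residue_id
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"{record}{(a.serial or i + 1):>5d} {name:<4.4s}"
            f"{resname:>4.3s} {chain[:1]}{resnum:>4d}    "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SDF


def read_ligand_file(
    path: str | os.PathLike,
    score_key: str = DEFAULT_SCORE_KEY,
) -> tuple[list[tuple[Structure, float | None]], list[str]]:
    """Read a pose set from an SDF (V2000) or multi-model PDB file.

    Returns ``(poses, errors)``: one ``(Structure, score)`` per readable
    record — the score taken from the named SDF property when present,
    ``None`` otherwise — plus a message per malformed record (0-based
    record index). Remaining records are still returned.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    if path.lower().endswith(".pdb"):
        return _read_multimodel_pdb(path), []
    poses: list[tuple[Structure, float | None]] = []
    errors: list[str] = []
    supplier = Chem.SDMolSupplier(path, sanitize=False, removeHs=False)
    for idx, mol in enumerate(supplier):
        if mol is None:
            errors.append(f"record {idx}: unreadable SDF record")
            continue
        try:
            poses.append(_mol_to_structure(mol, score_key))
        except Exception as exc:
            errors.append(f"record {idx}: {exc}")
    return poses, errors


def _mol_to_structure(mol: Chem.Mol, score_key: str) -> tuple[Structure, float | None]:
    if mol.GetNumConformers() == 0:
        raise InputError("record has no coordinates")
    conf = mol.GetConformer()
    atoms = [
        Atom(
            element=at.GetSymbol(),
            coords=np.array(conf.GetAtomPosition(at.GetIdx())),
            name=f"{at.GetSymbol()}{at.GetIdx() + 1}",
            residue_id=("L", 1, "LIG"),
        )
        for at in mol.GetAtoms()
    ]
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    s = Structure(
        atoms=atoms,
        bonds=sorted(tuple(sorted(b)) for b in bonds),
        role="ligand",
        name=mol.GetProp("_Name") if mol.HasProp("_Name") else "",
    )
    if mol.HasProp(CHARGE_PROPERTY):
        qs = [float(x) for x in mol.GetProp(CHARGE_PROPERTY).split()]
        if len(qs) == len(s.atoms):
            for a, q in zip(s.atoms, qs):
                a.partial_charge = q
    perceive_bonds_and_rings(s) if not bonds else _rings_only(s)
    score = float(mol.GetProp(score_key)) if mol.HasProp(score_key) else None
    return s, score


def _rings_only(s: Structure) -> Structure:
    """Keep file bonds, perceive rings/planarity only."""
    bonds = s.bonds
    perceive_bonds_and_rings(s)
    s.bonds = bonds
    return s


def _read_multimodel_pdb(path: str) -> list[tuple[Structure, float | None]]:
    st = gemmi.read_structure(path)
    out: list[tuple[Structure, float | None]] = []
    for model in st:
        atoms: list[Atom] = []
        for chain in model:
            for res in chain:
                for at in res:
                    atoms.append(
                        Atom(
                            element=at.element.name,
                            coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            name=at.name,
                            residue_id=(chain.name, res.seqid.num, res.name),
                        )
                    )
        if atoms:
            out.append((Structure(atoms=atoms, role="ligand", name=path), None))
    if not out:
        raise EmptyStructureError(f"{path}: no coordinate records")
    return out


def read_sdf_properties(path: str | os.PathLike) -> list[dict[str, str]]:
    """Named data fields of every readable SDF record (strings, raw)."""
    out: list[dict[str, str]] = []
    supplier = Chem.SDMolSupplier(os.fspath(path), sanitize=False, removeHs=False)
    for mol in supplier:
        if mol is None:
            out.append({})
            continue
        out.append({k: mol.GetProp(k) for k in mol.GetPropNames()})
    return out


def write_sdf(
    records: Iterable[tuple[Structure, float | None]],
    path: str | os.PathLike,
    score_key: str = DEFAULT_SCORE_KEY,
    extra: list[dict[str, str]] | None = None,
) -> None:
    """Write structures (+ optional scores) as a multi-record V2000 SDF.

    Partial charges are stored in a ``partial_charges`` property so that
    a round trip through :func:`read_ligand_file` is lossless; ``extra``
    supplies additional per-record data fields (e.g. the source state).
    """
    blocks = []
    for idx, (s, score) in enumerate(records):
        lines = [s.name or "pose", "  bindspace", ""]
        lines.append(
            f"{len(s.atoms):>3d}{len(s.bonds):>3d}  0  0  0  0  0  0  0  0999 V2000"
        )
        for a in s.atoms:
            lines.append(
                f"{a.coords[0]:>10.4f}{a.coords[1]:>10.4f}{a.coords[2]:>10.4f}"
                f" {a.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0"
            )
        for i, j in s.bonds:
            lines.append(f"{i + 1:>3d}{j + 1:>3d}  1  0")
        lines.append("M  END")
        if score is not None:
            lines.extend([f">  <{score_key}>", f"{score:.4f}", ""])
        if extra is not None and idx < len(extra):
            for k, v in extra[idx].items():
                lines.extend([f">  <{k}>", str(v), ""])
        lines.extend(
            [
                f">  <{CHARGE_PROPERTY}>",
                " ".join(f"{a.partial_charge:.4f}" for a in s.atoms),
                "",
                "$$$$",
            ]
        )
        blocks.append("\n".join(lines))
    with open(path, "w") as fh:
        fh.write("\n".join(blocks) + "\n")
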