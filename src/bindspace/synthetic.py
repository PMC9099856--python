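"""Seeded generators for toy pockets, ligands and pose ensembles.

These stand in for a docking engine's outputs: a cylindrical-shell pocket
of pharmacophorically typed residues (anionic, cationic, aromatic,
H-bonding), an MDMA-like cationic ligand, and pose ensembles with planted
cluster structure, planted per-residue interaction frequencies and
per-state ΔG distributions. Every generator is a pure function of its
spec and seed. Frequencies are planted as exact counts (not Bernoulli
draws) so that recovery tests exercise the detector, not sampling noise.

Residue and ligand templates are built from ideal internal coordinates
with polar hydrogens only; protonation is standard (Asp/Glu deprotonated,
Arg/Lys protonated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .ensemble import LigandPose, PoseEnsemble
from .geometry import place_atom, rotation_about_axis, rotation_aligning
from .interactions import InteractionCriteria, MonitoredPair
from .structures import (
    ActiveSite,
    Atom,
    InputError,
    ResidueId,
    Structure,
    assign_pharmacophore_types,
    perceive_bonds_and_rings,
    select_active_site,
)

#: documented rotatable-bond count of the mdma_like fixture
MDMA_LIKE_ROTOR_COUNT = 3

MIN_RESIDUE_SEPARATION = 2.5  # A, between any two placed residues
MIN_POSE_CLEARANCE = 1.6  # A, pose-to-pocket minimum interatomic distance


class SpecError(InputError):
    """Infeasible or inconsistent generator specification."""


# ---------------------------------------------------------------------------
# residue templates (z-matrix style: name, element, refs, bond, angle, dihedral)

_BACKBONE = [
    ("C", "C", ("N", None, "CA"), 1.52, 111.0, 0.0),  # seeded explicitly
    ("O", "O", ("N", "CA", "C"), 1.23, 121.0, 150.0),
    ("H", "H", ("C", "CA", "N"), 1.01, 118.0, 180.0),
]

_SIDECHAINS: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [("CB", "C", ("C", "N", "CA"), 1.53, 110.0, 122.0)],
    "GLU": [
        ("CB", "C", ("C", "N", "CA"), 1.53, 110.0, 122.0),
        ("CG", "C", ("N", "CA", "CB"), 1.52, 112.0, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 112.0, 180.0),
        ("OE1", "O", ("CB", "CG", "CD"), 1.25, 118.0, 0.0),
        ("OE2", "O", ("CB", "CG", "CD"), 1.25, 118.0, 180.0),
    ],
    "ASP": [
        ("CB", "C", ("C", "N", "CA"), 1.53, 110.0, 122.0),
        ("CG", "C", ("N", "CA", "CB"), 1.52, 112.0, 180.0),
        ("OD1", "O", ("CA", "CB", "CG"), 1.25, 118.0, 0.0),
        ("OD2", "O", ("CA", "CB", "CG"), 1.25, 118.0, 180.0),
    ],
    "ARG": [
        ("CB", "C", ("C", "N", "CA"), 1.53, 110.0, 122.0),
        ("CG", "C", ("N", "CA", "CB"), 1.52, 112.0, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 112.0, 180.0),
        ("NE", "N", ("CB", "CG", "CD"), 1.46, 112.0, 180.0),
        ("CZ", "C", ("CG", "CD", "NE"), 1.33, 124.0, 180.0),
        ("HE", "H", ("CG", "CD", "NE"), 1.01, 118.0, 0.0),
        ("NH1", "N", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
        ("NH2", "N", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0),
        ("HH11", "H", ("NE", "CZ", "NH1"), 1.01, 120.0, 0.0),
        ("HH12", "H", ("NE", "CZ", "NH1"), 1.01, 120.0, 180.0),
        ("HH21", "H", ("NE", "CZ", "NH2"), 1.01, 120.0, 0.0),
        ("HH22", "H", ("NE", "CZ", "NH2"), 1.01, 120.0, 180.0),
    ],
    "LYS": [
        ("CB", "C", ("C", "N", "CA"), 1.53, 110.0, 122.0),
        ("CG", "C", ("N", "CA", "CB"), 1.52, 112.0, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 112.0, 180.0),
        ("CE", "C", ("CB", "CG", "CD"), 1.52, 112.0, 180.0),
        ("NZ", "N", ("CG", "CD", "CE"), 1.49, 112.0, 180.0),
        ("HZ1", "H", ("CD", "CE", "NZ"), 1.01, 109.5, 60.0),
        ("HZ2", "H", ("CD", "CE", "NZ"), 1.01, 109.5, 180.0),
        ("HZ3", "H", ("CD", "CE", "NZ"), 1.01, 109.5, 300.0),
    ],
    "PHE": [
        ("CB", "C", ("C", "N", "CA"), 1.53, 110.0, 122.0),
        ("CG", "C", ("N", "CA", "CB"), 1.50, 114.0, 180.0),
        ("CD1", "C", ("CA", "CB", "CG"), 1.39, 120.0, 90.0),
        ("CD2", "C", ("CA", "CB", "CG"), 1.39, 120.0, 270.0),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
    ],
    "THR": [
        ("CB", "C", ("C", "N", "CA"), 1.53, 110.0, 122.0),
        ("OG1", "O", ("N", "CA", "CB"), 1.42, 109.5, 60.0),
        ("CG2", "C", ("N", "CA", "CB"), 1.52, 110.0, 180.0),
        ("HG1", "H", ("CA", "CB", "OG1"), 0.96, 109.0, 180.0),
    ],
    "GLN": [
        ("CB", "C", ("C", "N", "CA"), 1.53, 110.0, 122.0),
        ("CG", "C", ("N", "CA", "CB"), 1.52, 112.0, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 112.0, 180.0),
        ("OE1", "O", ("CB", "CG", "CD"), 1.23, 121.0, 0.0),
        ("NE2", "N", ("CB", "CG", "CD"), 1.33, 117.0, 180.0),
        ("HE21", "H", ("CG", "CD", "NE2"), 1.01, 120.0, 0.0),
        ("HE22", "H", ("CG", "CD", "NE2"), 1.01, 120.0, 180.0),
    ],
}
_SIDECHAINS["TYR"] = _SIDECHAINS["PHE"] + [
    ("OH", "O", ("CD1", "CE1", "CZ"), 1.36, 120.0, 180.0),
    ("HH", "H", ("CE1", "CZ", "OH"), 0.96, 109.0, 0.0),
]

# default partial charges applied on top of bindspace.io template charges
# are handled by io.apply_template_charges; templates here only build geometry.

# aiming point used to orient a residue's business end toward the site axis
_KEY_ATOMS: dict[str, tuple[str, ...]] = {
    "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"),
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "THR": ("OG1",),
    "GLN": ("OE1", "NE2"),
}
# the single atom (or ring) used when planting an interaction
_PLANT_ROLE: dict[str, str] = {
    "GLU": "anion",
    "ASP": "anion",
    "ARG": "cation",
    "LYS": "cation",
    "PHE": "aromatic",
    "TYR": "aromatic",
    "THR": "hbond",
    "GLN": "hbond",
}
_PLANT_ATOM: dict[str, str] = {
    "GLU": "OE1",
    "ASP": "OD1",
    "ARG": "CZ",
    "LYS": "NZ",
    "THR": "OG1",
    "GLN": "OE1",
}


def build_residue(resname: str, residue_id: ResidueId | None = None) -> Structure:
    """One amino-acid residue from its ideal-geometry template."""
    if resname not in _SIDECHAINS:
        raise SpecError(f"no template for residue {resname!r}")
    if residue_id is None:
        residue_id = ("A", 1, resname)
    coords: dict[str, np.ndarray] = {
        "N": np.array([0.0, 0.0, 0.0]),
        "CA": np.array([1.46, 0.0, 0.0]),
    }
    coords["C"] = coords["CA"] + 1.52 * np.array(
        [np.cos(np.deg2rad(69.0)), np.sin(np.deg2rad(69.0)), 0.0]
    )
    elements = {"N": "N", "CA": "C", "C": "C"}
    for name, elem, (a, b, c), bond, angle, dihedral in _BACKBONE[1:] + _SIDECHAINS[resname]:
        coords[name] = place_atom(coords[a], coords[b], coords[c], bond, angle, dihedral)
        elements[name] = elem
    atoms = [
        Atom(element=elements[nm], coords=coords[nm], name=nm, residue_id=residue_id)
        for nm in coords
    ]
    return Structure(atoms=atoms, role="receptor", name=resname)


# ---------------------------------------------------------------------------
# toy ligands


def make_toy_ligand(kind: str = "mdma_like") -> Structure:
    """Hardcoded toy ligands with perceived bonds, rings and charges.

    ``mdma_like``: methylenedioxyphenyl ring system fused to a benzene
    ring plus an N-methyl propan-2-aminium chain — one cationic N, one
    aromatic ring, two ring oxygens, 3 rotatable bonds, net charge +1.
    ``probe_amine``: methylammonium (cation + donor, no ring).
    ``probe_ring``: benzene (one aromatic ring, no donors).
    """
    if kind == "mdma_like":
        s = _build_mdma_like()
    elif kind == "probe_amine":
        s = _build_probe_amine()
    elif kind == "probe_ring":
        s = _build_probe_ring()
    else:
        raise SpecError(f"unknown ligand kind {kind!r}")
    return perceive_bonds_and_rings(s)


def _lig_atom(element: str, xyz: np.ndarray, name: str, q: float = 0.0) -> Atom:
    return Atom(element=element, coords=xyz, name=name, partial_charge=q,
                residue_id=("L", 1, "LIG"))


def _benzene_coords() -> dict[str, np.ndarray]:
    return {
        f"C{i + 1}": 1.39 * np.array(
            [np.cos(np.deg2rad(60 * i)), np.sin(np.deg2rad(60 * i)), 0.0]
        )
        for i in range(6)
    }


def _build_mdma_like() -> Structure:
    c = _benzene_coords()
    # fused methylenedioxy ring on the C3-C4 bond, in the ring plane
    c["O1"] = place_atom(c["C5"], c["C4"], c["C3"], 1.37, 109.0, 180.0)
    c["O2"] = place_atom(c["C2"], c["C3"], c["C4"], 1.37, 109.0, 180.0)
    c["C7"] = place_atom(c["C4"], c["C3"], c["O1"], 1.43, 105.0, 0.0)
    # aminium side chain on C1
    c["CB"] = place_atom(c["C3"], c["C2"], c["C1"], 1.51, 120.0, 180.0)
    c["CA"] = place_atom(c["C2"], c["C1"], c["CB"], 1.53, 112.0, 90.0)
    c["C9"] = place_atom(c["C1"], c["CB"], c["CA"], 1.53, 110.0, 60.0)
    c["N"] = place_atom(c["C1"], c["CB"], c["CA"], 1.49, 110.0, 180.0)
    c["C10"] = place_atom(c["CB"], c["CA"], c["N"], 1.49, 110.0, 180.0)
    c["HN1"] = place_atom(c["CA"], c["C10"], c["N"], 1.01, 109.0, 120.0)
    c["HN2"] = place_atom(c["CA"], c["C10"], c["N"], 1.01, 109.0, 240.0)
    charges = {
        "N": 0.5, "HN1": 0.25, "HN2": 0.25,
        "O1": -0.2, "O2": -0.2, "C7": 0.2, "C3": 0.1, "C4": 0.1,
    }
    atoms = [
        _lig_atom("O" if nm.startswith("O") else ("N" if nm == "N" else ("H" if nm.startswith("H") else "C")),
                  xyz, nm, charges.get(nm, 0.0))
        for nm, xyz in c.items()
    ]
    return Structure(atoms=atoms, role="ligand", name="mdma_like")


def _build_probe_amine() -> Structure:
    c = {"C1": np.array([0.0, 0.0, 0.0]), "N": np.array([1.49, 0.0, 0.0])}
    c["HN1"] = place_atom(np.array([0.0, 1.0, 0.0]), c["C1"], c["N"], 1.01, 109.5, 0.0)
    c["HN2"] = place_atom(np.array([0.0, 1.0, 0.0]), c["C1"], c["N"], 1.01, 109.5, 120.0)
    c["HN3"] = place_atom(np.array([0.0, 1.0, 0.0]), c["C1"], c["N"], 1.01, 109.5, 240.0)
    charges = {"N": 0.4, "HN1": 0.2, "HN2": 0.2, "HN3": 0.2}
    atoms = [
        _lig_atom("N" if nm == "N" else ("H" if nm.startswith("H") else "C"),
                  xyz, nm, charges.get(nm, 0.0))
        for nm, xyz in c.items()
    ]
    return Structure(atoms=atoms, role="ligand", name="probe_amine")


def _build_probe_ring() -> Structure:
    atoms = [_lig_atom("C", xyz, nm) for nm, xyz in _benzene_coords().items()]
    return Structure(atoms=atoms, role="ligand", name="probe_ring")


# ---------------------------------------------------------------------------
# pockets


@dataclass(frozen=True)
class ResiduePlacement:
    resname: str
    resnum: int
    radius: float = 7.5  # A from the site (z) axis
    azimuth: float | None = None  # degrees; None -> even spacing
    z: float | None = None  # None -> alternating +/- 1.5


@dataclass(frozen=True)
class PocketSpec:
    roster: tuple[ResiduePlacement, ...] = (
        ResiduePlacement("GLU", 494),
        ResiduePlacement("ASP", 328),
        ResiduePlacement("ARG", 104),
        ResiduePlacement("PHE", 335),
        ResiduePlacement("PHE", 556),
        ResiduePlacement("THR", 497),
        ResiduePlacement("GLN", 332),
    )
    chain: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.roster:
            raise SpecError("pocket roster must not be empty")


def _key_point(res: Structure) -> np.ndarray:
    resname = res.atoms[0].residue_id[2]
    names = _KEY_ATOMS.get(resname, ("CB",))
    pts = [a.coords for a in res.atoms if a.name in names]
    if not pts:
        pts = [a.coords for a in res.atoms]
    return np.mean(pts, axis=0)


def make_toy_pocket(spec: PocketSpec = PocketSpec()) -> Structure:
    """Residues on a cylindrical shell, business ends aimed at the axis.

    Each residue is rotated so its key group points inward, rolled by a
    seeded random angle, and translated so the key group sits on the
    shell. Placement retries (new roll, small azimuth jitter) until all
    inter-residue separations are >= 2.5 A; an infeasible roster raises
    SpecError. Deterministic under the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    placed: list[Structure] = []
    n = len(spec.roster)
    for k, rp in enumerate(spec.roster):
        base_phi = rp.azimuth if rp.azimuth is not None else 360.0 * k / n
        z = rp.z if rp.z is not None else (1.5 if k % 2 == 0 else -1.5)
        template = build_residue(rp.resname, (spec.chain, rp.resnum, rp.resname))
        ok = False
        for _try in range(60):
            phi = base_phi + float(rng.normal(0.0, 3.0))
            anchor = np.array(
                [rp.radius * np.cos(np.deg2rad(phi)), rp.radius * np.sin(np.deg2rad(phi)), z]
            )
            inward = -anchor / np.linalg.norm(anchor)
            res = template.copy()
            kp = _key_point(res)
            centroid = res.coords.mean(axis=0)
            aim = kp - centroid
            rot = rotation_aligning(aim, inward)
            roll = rotation_about_axis(inward, float(rng.uniform(0.0, 360.0)))
            xyz = (roll * rot).apply(res.coords - kp)
            res.set_coords(xyz + anchor)
            if all(_min_dist(res, other) >= MIN_RESIDUE_SEPARATION for other in placed):
                placed.append(res)
                ok = True
                break
        if not ok:
            raise SpecError(f"cannot place residue {rp.resname}{rp.resnum} without clashes")
    atoms = [a for res in placed for a in res.atoms]
    pocket = Structure(atoms=atoms, role="receptor", name="toy_pocket")
    from .io import apply_template_charges

    apply_template_charges(pocket)
    return perceive_bonds_and_rings(pocket)


def _min_dist(a: Structure, b: Structure) -> float:
    da = a.coords
    db = b.coords
    return float(np.sqrt(((da[:, None, :] - db[None, :, :]) ** 2).sum(-1)).min())


# ---------------------------------------------------------------------------
# pose ensembles with planted structure


@dataclass(frozen=True)
class StateSpec:
    fraction: float
    mean_dg: float  # kcal/mol
    sd_dg: float


@dataclass(frozen=True)
class EnsembleSpec:
    n_poses: int = 100
    per_state: tuple[tuple[str, StateSpec], ...] = (
        ("open", StateSpec(0.5, -7.1, 0.9)),
        ("occluded", StateSpec(0.5, -6.3, 0.6)),
    )
    n_clusters: int = 2
    cluster_spread: float = 0.5  # A, isotropic Gaussian around each centre
    cluster_separation: float = 6.0  # A, centres along the site axis
    planted_frequencies: tuple[tuple[ResidueId, float], ...] = (
        (("A", 494, "GLU"), 0.6),
        (("A", 335, "PHE"), 0.3),
    )
    orientation_mix: tuple[float, float, float] = (0.45, 0.45, 0.10)
    torsion_jitter: float = 10.0  # deg sd of per-pose rotor perturbations
    rotation_jitter: float = 3.0  # deg sd of per-pose rigid-body wobble
    site_label: str = "S2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_poses < 1:
            raise SpecError("n_poses must be >= 1")
        fr = [st.fraction for _, st in self.per_state]
        if any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise SpecError("state fractions must be non-negative and sum to 1")
        if any(st.sd_dg < 0 for _, st in self.per_state):
            raise SpecError("ΔG sd must be non-negative")
        freqs = [f for _, f in self.planted_frequencies]
        if any(not (0 <= f <= 1) for f in freqs):
            raise SpecError("planted frequencies must lie in [0, 1]")
        if sum(freqs) > 1.0 + 1e-9:
            raise SpecError(
                "planted frequencies sum above 1: poses are adjusted toward a "
                "single residue each, so the targets are geometrically incompatible"
            )
        if abs(sum(self.orientation_mix) - 1.0) > 1e-9:
            raise SpecError("orientation fractions must sum to 1")


def _exact_counts(n: int, fractions: list[float]) -> list[int]:
    """Largest-remainder rounding of n * fractions to integers summing <= n."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = [r - c for r, c in zip(raw, counts)]
    short = int(round(sum(raw))) - sum(counts)
    for i in np.argsort(remainder)[::-1][:short]:
        counts[int(i)] += 1
    return counts


def _ligand_feature_points(lig: Structure) -> dict[str, np.ndarray | int | None]:
    tags = assign_pharmacophore_types(lig)
    cation = sorted({t.atom_index for t in tags if t.tag == "cation"})
    aromatic = sorted({t.atom_index for t in tags if t.tag == "aromatic_ring_member"})
    donors = sorted(
        {(t.atom_index, t.h_index) for t in tags if t.tag == "hbond_donor" and t.h_index is not None}
    )
    return {
        "cation_idx": cation[0] if cation else None,
        "ring_idx": aromatic,
        "donor": donors[0] if donors else None,
    }


def plant_pose_ensemble(
    pocket: Structure,
    ligand: Structure,
    spec: EnsembleSpec = EnsembleSpec(),
    criteria: InteractionCriteria = InteractionCriteria(),
) -> PoseEnsemble:
    """A pose ensemble with planted clusters, contacts, states and ΔGs.

    Poses are scattered around cluster centres on the site axis; for each
    residue with a planted frequency f, exactly round(f * n) poses are
    locally adjusted (translation for salt-bridge / pi / cation-pi
    planting, rotation + translation for H-bonds) so the typed criterion
    is met, and the remaining poses are verified/repaired to miss it.
    ΔG values are drawn from the per-state normal distributions; the
    orientation mix is enforced by axis alignment before contact planting.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_poses
    feats = _ligand_feature_points(ligand)
    axis_refs = {  # target ligand-axis directions per orientation label
        0: np.array([1.0, 0.0, 0.0]),  # serotonin_like
        1: np.array([-1.0, 0.0, 0.0]),  # escitalopram_like
        2: np.array([0.0, 0.0, 1.0]),  # intermediate
    }

    # per-pose assignments (exact counts, seeded shuffles)
    state_names = [nm for nm, _ in spec.per_state]
    state_counts = _exact_counts(n, [st.fraction for _, st in spec.per_state])
    state_of = np.repeat(np.arange(len(state_names)), state_counts)
    if len(state_of) < n:  # rounding shortfall -> first state
        state_of = np.concatenate([state_of, np.zeros(n - len(state_of), dtype=int)])
    rng.shuffle(state_of)
    cluster_of = np.arange(n) % max(spec.n_clusters, 1)
    rng.shuffle(cluster_of)
    orient_counts = _exact_counts(n, list(spec.orientation_mix))
    orient_of = np.repeat(np.arange(3), orient_counts)
    if len(orient_of) < n:
        orient_of = np.concatenate([orient_of, np.full(n - len(orient_of), 2, dtype=int)])
    rng.shuffle(orient_of)

    planted = list(spec.planted_frequencies)
    quota = _exact_counts(n, [f for _, f in planted])
    plant_of = np.full(n, -1, dtype=int)
    order = rng.permutation(n)
    pos = 0
    for t, q in enumerate(quota):
        plant_of[order[pos : pos + q]] = t
        pos += q

    centres = _cluster_centres(spec)
    targets = [_plant_target(pocket, rid) for rid, _ in planted]
    target_rids = [rid for rid, _ in planted]
    checker = _ContactChecker(pocket, target_rids, ligand, criteria)

    # one roll per (cluster, orientation) so that same-blob poses of the
    # same orientation are tight under non-superposed rmsd
    rolls = rng.uniform(0.0, 360.0, size=(max(spec.n_clusters, 1), 3))
    poses: list[LigandPose] = []
    for i in range(n):
        centre = centres[int(cluster_of[i])]
        t = int(plant_of[i])
        conf = None
        for _try in range(60):
            cand = _base_pose(
                ligand,
                feats,
                axis_refs[int(orient_of[i])],
                rng,
                roll_deg=float(rolls[int(cluster_of[i]), int(orient_of[i])]),
                torsion_jitter=spec.torsion_jitter,
                rotation_jitter=spec.rotation_jitter,
            )
            if t >= 0:
                cand = _plant_contact(
                    cand, feats, targets[t], criteria, rng, reorient=_try >= 20
                )
                hit = checker.contacted(cand)
                if (
                    target_rids[t] in hit
                    and not (hit - {target_rids[t]})
                    and _min_dist(cand, pocket) >= MIN_POSE_CLEARANCE
                ):
                    conf = cand
                    break
            else:
                jitter = rng.normal(0.0, spec.cluster_spread, 3)
                cand.set_coords(cand.coords - cand.coords.mean(axis=0) + centre + jitter)
                if not checker.contacted(cand) and _min_dist(cand, pocket) >= MIN_POSE_CLEARANCE:
                    conf = cand
                    break
        if conf is None:
            raise SpecError(
                "cannot satisfy planted-frequency targets: geometric conflict "
                f"for pose {i} (target {'none' if t < 0 else str(target_rids[t])})"
            )
        st = spec.per_state[int(state_of[i])][1]
        dg = float(rng.normal(st.mean_dg, st.sd_dg))
        poses.append(
            LigandPose(
                conformer=conf,
                delta_g=dg,
                source_state=state_names[int(state_of[i])],
                site_label=spec.site_label,
            )
        )
    return PoseEnsemble(poses=poses, ligand_name=ligand.name)


def _cluster_centres(spec: EnsembleSpec) -> np.ndarray:
    k = max(spec.n_clusters, 1)
    zs = (np.arange(k) - (k - 1) / 2.0) * spec.cluster_separation
    return np.column_stack([np.zeros(k), np.zeros(k), zs])


def _axis_of(lig: Structure, feats: dict) -> np.ndarray:
    if feats["cation_idx"] is None or not feats["ring_idx"]:
        return np.array([1.0, 0.0, 0.0])
    v = lig.coords[feats["ring_idx"]].mean(axis=0) - lig.coords[feats["cation_idx"]]
    return v / np.linalg.norm(v)


def _base_pose(
    lig: Structure,
    feats: dict,
    target_axis: np.ndarray,
    rng: np.random.Generator,
    roll_deg: float | None = None,
    torsion_jitter: float = 0.0,
    rotation_jitter: float = 0.0,
) -> Structure:
    """Oriented copy of the ligand, centred at the origin.

    ``roll_deg`` fixes the roll about the target axis (None -> random);
    ``torsion_jitter``/``rotation_jitter`` add small per-pose conformer
    and rigid-body wobble (degrees, sd).
    """
    conf = lig.copy()
    if torsion_jitter > 0:
        from .mc import rotate_torsion
        from .structures import list_rotatable_bonds

        for bond in list_rotatable_bonds(conf):
            conf = rotate_torsion(conf, bond, float(rng.normal(0.0, torsion_jitter)))
    centroid = conf.coords.mean(axis=0)
    rot = rotation_aligning(_axis_of(conf, feats), target_axis)
    roll_angle = float(rng.uniform(0.0, 360.0)) if roll_deg is None else roll_deg
    roll = rotation_about_axis(target_axis, roll_angle)
    total = roll * rot
    if rotation_jitter > 0:
        wobble = Rotation.from_rotvec(np.deg2rad(rng.normal(0.0, rotation_jitter, 3)))
        total = wobble * total
    conf.set_coords(total.apply(conf.coords - centroid))
    return conf


@dataclass(frozen=True)
class _PlantTarget:
    residue_id: ResidueId
    role: str  # anion | cation | aromatic | hbond
    point: np.ndarray  # key atom or ring centroid, receptor frame
    cutoff: float  # governing criterion distance
    normal: np.ndarray | None = None  # ring normal for aromatic targets


def _plant_target(pocket: Structure, rid: ResidueId) -> _PlantTarget:
    resname = rid[2]
    role = _PLANT_ROLE.get(resname)
    if role is None:
        raise SpecError(f"cannot plant interactions on residue type {resname!r}")
    idx = pocket.atoms_of_residue(rid)
    if not idx:
        raise SpecError(f"residue {rid} not present in the pocket")
    by_name = {pocket.atoms[i].name: pocket.atoms[i].coords for i in idx}
    normal = None
    if role == "aromatic":
        from .geometry import best_fit_plane

        ring_pts = np.array([by_name[nm] for nm in _KEY_ATOMS[resname]])
        point, normal, _ = best_fit_plane(ring_pts)
    else:
        point = by_name[_PLANT_ATOM[resname]]
    cutoffs = {"anion": 3.2, "cation": 4.0, "aromatic": 4.2, "hbond": 2.9}
    return _PlantTarget(rid, role, point, cutoffs[role], normal)


def _plant_contact(
    conf: Structure,
    feats: dict,
    target: _PlantTarget,
    criteria: InteractionCriteria,
    rng: np.random.Generator,
    reorient: bool = False,
) -> Structure:
    """Translate (and where needed rotate) the pose onto the target.

    Salt-bridge planting is translation-only by default (preserving the
    pose's orientation label); with ``reorient=True`` the ligand axis is
    first pointed into the pocket interior (used when orientation-
    preserving placement keeps clashing).
    """
    inward = -target.point / max(np.linalg.norm(target.point), 1e-9)
    if target.role in ("aromatic", "cation") and target.normal is not None:
        # approach the ring face-on: displace along the ring normal (the
        # side pointing inward), mixed with a little inward pull
        side = 1.0 if float(np.dot(target.normal, inward)) >= 0 else -1.0
        w = float(rng.uniform(0.0, 0.6))
        direction = side * target.normal + w * inward
        direction /= np.linalg.norm(direction)
        goal = target.point + target.cutoff * direction
    else:
        goal = target.point + target.cutoff * inward
    if target.role in ("anion", "hbond"):
        anchor_idx = feats["cation_idx"]
        if anchor_idx is None:
            raise SpecError("ligand has no cationic amine to plant with")
        if reorient:
            pivot = conf.atoms[anchor_idx].coords.copy()
            axis_now = _axis_of(conf, feats)
            rot = rotation_aligning(axis_now, inward)
            roll = rotation_about_axis(inward, float(rng.uniform(0.0, 360.0)))
            conf = conf.copy()
            conf.set_coords((roll * rot).apply(conf.coords - pivot) + pivot)
        if target.role == "hbond" and feats["donor"] is not None:
            d, h = feats["donor"]
            conf = conf.copy()
            rot = rotation_aligning(
                conf.atoms[h].coords - conf.atoms[d].coords, target.point - conf.atoms[d].coords
            )
            pivot = conf.atoms[d].coords.copy()
            conf.set_coords(rot.apply(conf.coords - pivot) + pivot)
        anchor = conf.atoms[anchor_idx].coords
    elif target.role in ("aromatic", "cation"):
        if not feats["ring_idx"]:
            raise SpecError("ligand has no aromatic ring to plant with")
        # stack the ligand ring face-on toward the target (ring or cation):
        # align the ligand ring normal with the approach direction, with a
        # random roll about it
        from .geometry import best_fit_plane

        _, lig_normal, _ = best_fit_plane(conf.coords[feats["ring_idx"]])
        face = target.point - goal
        face /= np.linalg.norm(face)
        conf = conf.copy()
        rot = rotation_aligning(lig_normal, face)
        roll = rotation_about_axis(face, float(rng.uniform(0.0, 360.0)))
        centroid = conf.coords[feats["ring_idx"]].mean(axis=0)
        conf.set_coords((roll * rot).apply(conf.coords - centroid) + centroid)
        anchor = conf.coords[feats["ring_idx"]].mean(axis=0)
    conf = conf.translated(goal - anchor)
    return conf


class _ContactChecker:
    """Detector-backed check of which targeted residues a pose contacts.

    Runs the typed-interaction detector against a site restricted to the
    targeted residues, with pharmacophore tags computed once.
    """

    def __init__(
        self,
        pocket: Structure,
        target_rids: list[ResidueId],
        ligand: Structure,
        criteria: InteractionCriteria,
    ) -> None:
        from .interactions import detect_interactions

        self._detect = detect_interactions
        self.pocket = pocket
        self.criteria = criteria
        self.site = ActiveSite(frozenset(target_rids), radius=0.0)
        self.receptor_tags = assign_pharmacophore_types(pocket)
        self.ligand_tags = assign_pharmacophore_types(ligand)

    def contacted(self, pose: Structure) -> set[ResidueId]:
        if not self.site.residue_ids:
            return set()
        records = self._detect(
            pose,
            self.pocket,
            self.site,
            self.criteria,
            ligand_tags=self.ligand_tags,
            receptor_tags=self.receptor_tags,
        )
        return {r.residue_id for r in records}


def make_graded_poses(
    seed: int = 0,
) -> tuple[list[Structure], Structure, ActiveSite]:
    """Four poses of the toy ligand with 0..3 planted favourable contacts.

    Grades: 0 — no contact (far pose); 1 — a tight salt bridge to the
    anionic residue; 2 — the salt bridge plus a parallel aromatic stack on
    the Phe ring; 3 — additionally an H-bond (amine H turned toward the
    carboxylate). Grades 1-3 share the same amine anchor: grade 1 is
    grade 2 with the ring swung out of the aromatic cutoff about the
    amine, grade 3 is grade 2 rolled about its own ligand axis (amine and
    ring centroid fixed), so consecutive grades differ by one planted
    interaction. The aromatic residue's azimuth is chosen per seed so the
    stacked geometry is reachable from the salt-bridge anchor; candidate
    poses are screened on the Lennard-Jones term (a flat distance floor
    would reject tight salt bridges yet admit repulsive carbon contacts).
    Deterministic under the seed.
    """
    from .geometry import best_fit_plane, interplanar_angle
    from .interactions import InteractionCriteria, detect_interactions
    from .mc import EnergyModel, intermolecular_terms

    criteria = InteractionCriteria()
    emodel = EnergyModel()
    ligand = make_toy_ligand("mdma_like")
    feats = _ligand_feature_points(ligand)
    n_idx = feats["cation_idx"]
    ring_idx = feats["ring_idx"]
    lig_axis = _axis_of(ligand, feats)
    axis_len = float(
        np.linalg.norm(ligand.coords[ring_idx].mean(axis=0) - ligand.atoms[n_idx].coords)
    )
    ltags = assign_pharmacophore_types(ligand)

    for attempt in range(8):
        sub = seed * 37 + attempt
        rng = np.random.default_rng(sub)
        for azimuth in (60.0, 75.0, 90.0, 105.0, 120.0, 135.0):
            pocket = make_toy_pocket(
                PocketSpec(
                    roster=(
                        ResiduePlacement("GLU", 494, radius=6.5, azimuth=0.0, z=0.0),
                        ResiduePlacement("PHE", 335, radius=7.5, azimuth=azimuth, z=0.0),
                    ),
                    seed=sub,
                )
            )
            result = _graded_search(
                pocket, ligand, ltags, feats, lig_axis, axis_len, criteria, emodel, rng
            )
            if result is not None:
                return result
    raise SpecError("graded-pose construction failed after bounded retries")


def _graded_search(pocket, ligand, ltags, feats, lig_axis, axis_len, criteria, emodel, rng):
    from .geometry import best_fit_plane, interplanar_angle
    from .interactions import detect_interactions

    n_idx = feats["cation_idx"]
    ring_idx = feats["ring_idx"]
    glu_id = next(r for r in pocket.residue_ids() if r[2] == "GLU")
    phe_id = next(r for r in pocket.residue_ids() if r[2] == "PHE")
    site = ActiveSite(frozenset([glu_id, phe_id]), radius=6.0)
    rtags = assign_pharmacophore_types(pocket)

    def vdw_coul(p):
        from .mc import intermolecular_terms

        return intermolecular_terms(p, pocket, site, emodel)

    def grade_of(p) -> int:
        ks = {r.kind for r in detect_interactions(p, pocket, site, criteria, ltags, rtags)}
        if not ks:
            return 0
        if "salt_bridge" not in ks:
            return -1
        has_pi = bool(ks & {"pi_pi_parallel", "pi_pi_edge"})
        has_hb = bool(ks & {"hbond_weak", "hbond_strong"})
        if has_pi and has_hb:
            return 3
        if has_pi:
            return 2
        if has_hb:
            return -1
        return 1

    glu_t = _plant_target(pocket, glu_id)
    aro_t = _plant_target(pocket, phe_id)
    n_side = aro_t.normal * (1.0 if float(np.dot(aro_t.normal, -aro_t.point)) >= 0 else -1.0)
    p_ring = aro_t.point + 3.7 * n_side
    inward = -glu_t.point / np.linalg.norm(glu_t.point)

    # grade 2: tight salt bridge + genuinely attractive parallel stack
    p2 = vdw2 = coul2 = None
    work = ligand.copy()
    base_local = ligand.coords - ligand.atoms[n_idx].coords
    for _ in range(800):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        if np.dot(u, inward) < 0.2:
            continue
        anchor = glu_t.point + 2.95 * u
        axis_target = (p_ring - anchor) / np.linalg.norm(p_ring - anchor)
        ring_c = anchor + axis_len * axis_target
        if np.linalg.norm(ring_c - aro_t.point) > 4.4:
            continue
        rot0 = rotation_aligning(lig_axis, axis_target)
        for roll_deg in np.arange(0.0, 360.0, 10.0):
            roll = rotation_about_axis(axis_target, float(roll_deg))
            work.set_coords((roll * rot0).apply(base_local) + anchor)
            v, c = vdw_coul(work)
            if v > -2.0:  # need a real stacking reward, not a graze
                continue
            _, lig_n, _ = best_fit_plane(work.coords[ring_idx])
            if interplanar_angle(lig_n, aro_t.normal) > criteria.pi_parallel_max_angle:
                continue
            if grade_of(work) == 2:
                p2, vdw2, coul2 = work.copy(), v, c
                break
        if p2 is not None:
            break
    if p2 is None:
        return None

    # grade 3: smallest roll about the ligand axis that gains the H-bond
    # without disturbing the stack or the salt bridge energetics
    p3 = None
    own_axis = p2.coords[ring_idx].mean(axis=0) - p2.atoms[n_idx].coords
    pivot = p2.atoms[n_idx].coords.copy()
    for step in range(1, 72):
        for sign in (1.0, -1.0):
            rot = rotation_about_axis(own_axis, sign * 5.0 * step)
            cand = p2.copy()
            cand.set_coords(rot.apply(cand.coords - pivot) + pivot)
            v, c = vdw_coul(cand)
            if v > vdw2 + 0.7 or c > coul2 + 0.3:
                continue
            if grade_of(cand) == 3:
                p3 = cand
                break
        if p3 is not None:
            break
    if p3 is None:
        return None

    # grade 1: smallest swing of the ring away from Phe about the amine,
    # landing the ring in free space (little stray vdw either way)
    p1 = None
    away = p2.coords[ring_idx].mean(axis=0) - aro_t.point
    away /= np.linalg.norm(away)
    swing_axis = np.cross(own_axis, -away)
    if np.linalg.norm(swing_axis) < 1e-8:
        return None
    swing_axis /= np.linalg.norm(swing_axis)
    for ang in np.arange(15.0, 150.0, 5.0):
        for sign in (1.0, -1.0):
            rot = rotation_about_axis(swing_axis, float(sign * ang))
            cand = p2.copy()
            cand.set_coords(rot.apply(cand.coords - pivot) + pivot)
            v, _ = vdw_coul(cand)
            if not (-1.0 <= v <= 0.7):
                continue
            if grade_of(cand) == 1:
                p1 = cand
                break
        if p1 is not None:
            break
    if p1 is None:
        return None

    p0 = p1.translated(np.array([0.0, 0.0, 16.0]))
    if grade_of(p0) != 0:
        return None
    return [p0, p1, p2, p3], pocket, site


# ---------------------------------------------------------------------------
# MC starting systems


def make_mc_system(
    pocket: Structure | None = None,
    ligand: Structure | None = None,
    seed: int = 0,
) -> tuple[Structure, Structure, ActiveSite, tuple[MonitoredPair, ...]]:
    """A ligand posed in a small pocket with one planted salt bridge and
    one planted aromatic contact, ready for run_mc.

    Returns (pose, receptor, site, monitored_pairs); the monitored pairs
    track the cationic amine against the carboxylate oxygens and the
    ligand ring against the aromatic residue ring. Deterministic in seed.
    """
    if ligand is None:
        ligand = make_toy_ligand("mdma_like")
    feats = _ligand_feature_points(ligand)
    if feats["cation_idx"] is None or not feats["ring_idx"]:
        raise SpecError("make_mc_system needs a cationic, aromatic ligand")
    rng = np.random.default_rng(seed)

    def _fit(pk: Structure, n_samples: int = 400) -> tuple[float, Structure] | None:
        """Best bridging pose (clearance, conf) for a candidate pocket.

        Seeded randomized search over the amine approach direction, the
        salt-bridge distance and the ligand orientation, keeping the pi
        contact (<= 4.9 A) and maximizing steric clearance.
        """
        glu = next(r for r in pk.residue_ids() if r[2] in ("GLU", "ASP"))
        aro = next(r for r in pk.residue_ids() if r[2] in ("PHE", "TYR"))
        glu_t = _plant_target(pk, glu)
        aro_t = _plant_target(pk, aro)
        aro_c = aro_t.point
        # stacked approach point: offset from the ring centre along the
        # ring normal, on the side facing the pocket interior
        n_side = aro_t.normal * (1.0 if float(np.dot(aro_t.normal, -aro_c)) >= 0 else -1.0)
        p_ring = aro_c + 3.6 * n_side
        inward = -glu_t.point / np.linalg.norm(glu_t.point)
        local_rng = np.random.default_rng(seed)
        lig_axis = _axis_of(ligand, feats)
        axis_len = float(
            np.linalg.norm(
                ligand.coords[feats["ring_idx"]].mean(axis=0)
                - ligand.atoms[feats["cation_idx"]].coords
            )
        )
        best = None
        for _ in range(n_samples):
            u = local_rng.normal(size=3)
            u /= np.linalg.norm(u)
            if np.dot(u, inward) < 0.3:  # approach from inside the pocket
                continue
            anchor = glu_t.point + float(local_rng.uniform(2.8, 3.6)) * u
            # aim the amine->ring axis at the stacked approach point; the
            # ligand ring centroid then lands on that line at axis_len
            axis_target = (p_ring - anchor) / np.linalg.norm(p_ring - anchor)
            ring_c = anchor + axis_len * axis_target
            if np.linalg.norm(ring_c - aro_c) > 4.7:  # keep the pi contact
                continue
            rot0 = rotation_aligning(lig_axis, axis_target)
            for _r in range(8):
                roll = rotation_about_axis(axis_target, float(local_rng.uniform(0, 360)))
                conf = ligand.copy()
                conf.set_coords(
                    (roll * rot0).apply(
                        conf.coords - conf.atoms[feats["cation_idx"]].coords
                    )
                    + anchor
                )
                clearance = _min_dist(conf, pk)
                if best is None or clearance > best[0]:
                    best = (clearance, conf)
            if best is not None and best[0] >= 2.3:  # roomy enough
                break
        if best is None or best[0] < 1.8:
            return None
        return best

    if pocket is None:
        # scan the aromatic residue's azimuth for the roomiest bridge
        overall = None
        for az in (100.0, 110.0, 120.0, 130.0, 140.0):
            pk = make_toy_pocket(
                PocketSpec(
                    roster=(
                        ResiduePlacement("GLU", 494, radius=6.5, azimuth=0.0, z=0.0),
                        ResiduePlacement("PHE", 335, radius=7.5, azimuth=az, z=0.0),
                    ),
                    seed=seed,
                )
            )
            fit = _fit(pk)
            if fit is not None and (overall is None or fit[0] > overall[0]):
                overall = (fit[0], fit[1], pk)
        if overall is None:
            raise SpecError("could not fit a bridging pose in any candidate pocket")
        _, pose, pocket = overall
    else:
        fit = _fit(pocket)
        if fit is None:
            raise SpecError("could not fit a bridging pose in the given pocket")
        pose = fit[1]
    glu_id = next(rid for rid in pocket.residue_ids() if rid[2] in ("GLU", "ASP"))
    aro_id = next(rid for rid in pocket.residue_ids() if rid[2] in ("PHE", "TYR"))
    site = select_active_site(pocket, pose, radius=6.0)
    glu_os = [
        i
        for i in pocket.atoms_of_residue(glu_id)
        if pocket.atoms[i].name in _KEY_ATOMS[glu_id[2]]
    ]
    aro_ring = [
        i
        for i in pocket.atoms_of_residue(aro_id)
        if pocket.atoms[i].name in _KEY_ATOMS[aro_id[2]]
    ]
    pairs = (
        MonitoredPair(
            label=f"amine-{glu_id[2]}{glu_id[1]}",
            ligand_indices=(feats["cation_idx"],),
            receptor_indices=tuple(glu_os),
        ),
        MonitoredPair(
            label=f"ring-{aro_id[2]}{aro_id[1]}",
            ligand_indices=tuple(feats["ring_idx"]),
            receptor_indices=tuple(aro_ring),
        ),
    )
    return pose, pocket, site, pairs
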