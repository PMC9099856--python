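"""Typed noncovalent interaction detection and occurrence profiling.

Detects H-bonds (weak/strong), salt bridges, pi-pi (parallel/edge) and
cation-pi contacts between a ligand pose and the active-site residues of a
receptor, with explicit geometric criteria. Aromatic contacts use ring
centroid-to-centroid distances with a 5 A cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import angle_between, best_fit_plane, interplanar_angle
from .structures import (
    ActiveSite,
    InputError,
    PharmacophoreTag,
    ResidueId,
    Structure,
    assign_pharmacophore_types,
)

KINDS = ("hbond_weak", "hbond_strong", "salt_bridge", "pi_pi_parallel", "pi_pi_edge", "cation_pi")


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric windows for each interaction type (A / degrees)."""

    hbond_max_dist: float = 3.5
    hbond_min_angle: float = 120.0
    hbond_strong_dist: float = 3.0
    hbond_strong_angle: float = 150.0
    salt_bridge_max_dist: float = 4.0
    pi_centroid_max_dist: float = 5.0
    pi_parallel_max_angle: float = 30.0
    pi_edge_min_angle: float = 60.0
    cation_pi_max_dist: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "hbond_max_dist",
            "hbond_strong_dist",
            "salt_bridge_max_dist",
            "pi_centroid_max_dist",
            "cation_pi_max_dist",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hbond_strong_dist > self.hbond_max_dist:
            raise ValueError("strong H-bond distance must not exceed the weak cutoff")
        if self.hbond_strong_angle < self.hbond_min_angle:
            raise ValueError("strong H-bond angle must not be laxer than the weak one")


@dataclass(frozen=True)
class InteractionRecord:
    kind: str
    ligand_atoms: tuple[int, ...]
    receptor_atoms: tuple[int, ...]
    residue_id: ResidueId
    distance: float
    angle: float | None = None
    displaced: bool = False  # unclassified-pi reported as parallel, flagged


# ---------------------------------------------------------------------------
# feature extraction


@dataclass
class _Features:
    """Grouped pharmacophoric features of one structure."""

    cation_groups: list[tuple[tuple[int, ...], np.ndarray]] = field(default_factory=list)
    anion_atoms: list[int] = field(default_factory=list)
    donors: list[tuple[int, int | None]] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)
    rings: list[tuple[tuple[int, ...], np.ndarray, np.ndarray]] = field(default_factory=list)


def extract_features(
    s: Structure, tags: Sequence[PharmacophoreTag] | None = None
) -> _Features:
    """Group per-atom tags into interaction-ready features.

    Cation atoms of one residue form a single charged group whose centre is
    the mean of the tagged nitrogens (guanidinium centroid for Arg); anion
    atoms stay individual. Aromatic ring members are grouped back into the
    perceived rings, each with centroid and best-fit-plane normal.
    """
    if tags is None:
        tags = assign_pharmacophore_types(s)
    xyz = s.coords
    f = _Features()
    by_tag: dict[str, list[PharmacophoreTag]] = {}
    for t in tags:
        by_tag.setdefault(t.tag, []).append(t)
    # cation groups, one per residue
    cation_by_res: dict[ResidueId, list[int]] = {}
    for t in by_tag.get("cation", []):
        cation_by_res.setdefault(s.atoms[t.atom_index].residue_id, []).append(t.atom_index)
    for idxs in cation_by_res.values():
        idxs = tuple(sorted(idxs))
        f.cation_groups.append((idxs, xyz[list(idxs)].mean(axis=0)))
    f.anion_atoms = sorted(t.atom_index for t in by_tag.get("anion", []))
    f.donors = sorted(
        {(t.atom_index, t.h_index) for t in by_tag.get("hbond_donor", [])},
        key=lambda p: (p[0], -1 if p[1] is None else p[1]),
    )
    f.acceptors = sorted({t.atom_index for t in by_tag.get("hbond_acceptor", [])})
    aromatic = {t.atom_index for t in by_tag.get("aromatic_ring_member", [])}
    for ring in s.rings:
        if set(ring.indices) <= aromatic:
            pts = xyz[list(ring.indices)]
            centroid, normal, _ = best_fit_plane(pts)
            f.rings.append((tuple(ring.indices), centroid, normal))
    # receptor side-chain rings may not be in s.rings if bonds were not
    # perceived; group by residue as a fallback
    if not f.rings and aromatic:
        by_res: dict[ResidueId, list[int]] = {}
        for i in aromatic:
            by_res.setdefault(s.atoms[i].residue_id, []).append(i)
        for idxs in by_res.values():
            idxs = tuple(sorted(idxs))
            centroid, normal, _ = best_fit_plane(xyz[list(idxs)])
            f.rings.append((idxs, centroid, normal))
    return f


def _residue_rings(s: Structure, feats: _Features) -> list[tuple[tuple[int, ...], np.ndarray, np.ndarray]]:
    return feats.rings


# ---------------------------------------------------------------------------
# detection


def detect_interactions(
    pose: Structure,
    receptor: Structure,
    site: ActiveSite,
    criteria: InteractionCriteria = InteractionCriteria(),
    ligand_tags: Sequence[PharmacophoreTag] | None = None,
    receptor_tags: Sequence[PharmacophoreTag] | None = None,
) -> list[InteractionRecord]:
    """All typed ligand-receptor contacts within the active site.

    Every (ligand feature, receptor feature) pair inside its distance and
    angle window yields exactly one record. A salt bridge is reported in
    addition to an H-bond when both criteria hold. Records are sorted by
    (residue, kind, distance).
    """
    if ligand_tags is None:
        ligand_tags = assign_pharmacophore_types(pose)
    if receptor_tags is None:
        receptor_tags = assign_pharmacophore_types(receptor)
    if not ligand_tags:
        raise InputError("detect_interactions: ligand carries no pharmacophore tags")
    site_tags = [
        t for t in receptor_tags if receptor.atoms[t.atom_index].residue_id in site.residue_ids
    ]
    lf = extract_features(pose, ligand_tags)
    rf = extract_features(receptor, site_tags)
    lxyz, rxyz = pose.coords, receptor.coords
    records: list[InteractionRecord] = []

    def rid(atom_idx: int) -> ResidueId:
        return receptor.atoms[atom_idx].residue_id

    # H-bonds, both directions
    for (d, h), a in _pairs(lf.donors, rf.acceptors):
        rec = _hbond(lxyz, rxyz, d, h, a, criteria, rid(a), ligand_is_donor=True)
        if rec:
            records.append(rec)
    for (d, h), a in _pairs(rf.donors, lf.acceptors):
        rec = _hbond(rxyz, lxyz, d, h, a, criteria, rid(d), ligand_is_donor=False)
        if rec:
            records.append(rec)
    # salt bridges: cation group centre vs individual anion atom
    for (idxs, centre) in lf.cation_groups:
        for a in rf.anion_atoms:
            dist = float(np.linalg.norm(centre - rxyz[a]))
            if dist <= criteria.salt_bridge_max_dist:
                records.append(
                    InteractionRecord("salt_bridge", idxs, (a,), rid(a), dist)
                )
    for (idxs, centre) in rf.cation_groups:
        for a in lf.anion_atoms:
            dist = float(np.linalg.norm(centre - lxyz[a]))
            if dist <= criteria.salt_bridge_max_dist:
                records.append(
                    InteractionRecord("salt_bridge", (a,), idxs, rid(idxs[0]), dist)
                )
    # pi-pi
    for (li, lc, ln) in lf.rings:
        for (ri, rc, rn) in rf.rings:
            dist = float(np.linalg.norm(lc - rc))
            if dist > criteria.pi_centroid_max_dist:
                continue
            alpha = interplanar_angle(ln, rn)
            if alpha <= criteria.pi_parallel_max_angle:
                kind, displaced = "pi_pi_parallel", False
            elif alpha >= criteria.pi_edge_min_angle:
                kind, displaced = "pi_pi_edge", False
            else:
                kind, displaced = "pi_pi_parallel", True
            records.append(
                InteractionRecord(kind, li, ri, rid(ri[0]), dist, angle=alpha, displaced=displaced)
            )
    # cation-pi
    for (idxs, centre) in lf.cation_groups:
        for (ri, rc, _) in rf.rings:
            dist = float(np.linalg.norm(centre - rc))
            if dist <= criteria.cation_pi_max_dist:
                records.append(InteractionRecord("cation_pi", idxs, ri, rid(ri[0]), dist))
    for (idxs, centre) in rf.cation_groups:
        for (li, lc, _) in lf.rings:
            dist = float(np.linalg.norm(centre - lc))
            if dist <= criteria.cation_pi_max_dist:
                records.append(InteractionRecord("cation_pi", li, idxs, rid(idxs[0]), dist))
    records.sort(key=lambda r: (r.residue_id, r.kind, r.distance, r.ligand_atoms))
    return records


def _pairs(donors, acceptors):
    for dh in donors:
        for a in acceptors:
            yield dh, a


def _hbond(
    dxyz: np.ndarray,
    axyz: np.ndarray,
    d: int,
    h: int | None,
    a: int,
    c: InteractionCriteria,
    residue: ResidueId,
    ligand_is_donor: bool,
) -> InteractionRecord | None:
    dist = float(np.linalg.norm(dxyz[d] - axyz[a]))
    if dist > c.hbond_max_dist or dist < 1e-6:
        return None
    angle = None
    if h is not None:
        angle = angle_between(dxyz[d] - dxyz[h], axyz[a] - dxyz[h])
        if angle < c.hbond_min_angle:
            return None
    strong = dist <= c.hbond_strong_dist and (angle is None or angle >= c.hbond_strong_angle)
    kind = "hbond_strong" if strong else "hbond_weak"
    datoms = tuple(i for i in (d, h) if i is not None)
    if ligand_is_donor:
        return InteractionRecord(kind, datoms, (a,), residue, dist, angle)
    return InteractionRecord(kind, (a,), datoms, residue, dist, angle)


# ---------------------------------------------------------------------------
# profiling over ensembles


@dataclass
class ContactProfile:
    occurrence: dict[ResidueId, float]
    n_poses: int
    mode: str  # typed_only | any_contact

    def as_series(self) -> pd.Series:
        return pd.Series(self.occurrence, dtype=float).sort_index()


ANY_CONTACT_DIST = 4.0


def contact_profile(
    poses: Sequence[Structure],
    receptor: Structure,
    site: ActiveSite,
    criteria: InteractionCriteria = InteractionCriteria(),
    mode: str = "typed_only",
) -> ContactProfile:
    """Relative per-residue contact occurrence over a pose ensemble.

    ``occurrence(res)`` is the fraction of poses with at least one typed
    record (mode ``typed_only``) or any heavy-atom pair within 4.0 A
    (mode ``any_contact``) involving that residue.
    """
    if len(poses) == 0:
        raise InputError("contact_profile: empty ensemble")
    if mode not in ("typed_only", "any_contact"):
        raise InputError(f"unknown profile mode {mode!r}")
    receptor_tags = assign_pharmacophore_types(receptor)
    counts: dict[ResidueId, int] = {}
    for pose in poses:
        contacted: set[ResidueId] = set()
        if mode == "typed_only":
            recs = detect_interactions(pose, receptor, site, criteria, receptor_tags=receptor_tags)
            contacted = {r.residue_id for r in recs}
        else:
            pxyz = pose.coords[pose.heavy_indices()]
            for rid in site.residue_ids:
                idx = [
                    i
                    for i in receptor.atoms_of_residue(rid)
                    if not receptor.atoms[i].is_hydrogen
                ]
                rxyz = receptor.coords[idx]
                dmin = np.sqrt(
                    ((pxyz[:, None, :] - rxyz[None, :, :]) ** 2).sum(-1)
                ).min()
                if dmin <= ANY_CONTACT_DIST:
                    contacted.add(rid)
        for rid in contacted:
            counts[rid] = counts.get(rid, 0) + 1
    n = len(poses)
    return ContactProfile(
        occurrence={rid: c / n for rid, c in sorted(counts.items())}, n_poses=n, mode=mode
    )


def occurrence_table(records_per_pose: Iterable[Sequence[InteractionRecord]]) -> pd.DataFrame:
    """Counts of typed records partitioned by (residue, kind).

    Rows are residues, columns interaction kinds, values record counts
    summed over the ensemble; the grand total equals the number of records.
    """
    rows: dict[ResidueId, dict[str, int]] = {}
    for records in records_per_pose:
        for r in records:
            row = rows.setdefault(r.residue_id, {k: 0 for k in KINDS})
            row[r.kind] += 1
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    if df.empty:
        return pd.DataFrame(columns=list(KINDS), dtype=int)
    return df[list(KINDS)].sort_index()


# ---------------------------------------------------------------------------
# trajectory distance monitoring


@dataclass(frozen=True)
class MonitoredPair:
    """A ligand selection vs a receptor selection; multi-atom selections
    are tracked by their centroid (ring or charged-group centre)."""

    label: str
    ligand_indices: tuple[int, ...]
    receptor_indices: tuple[int, ...]


@dataclass
class DistanceSeries:
    label: str
    values: np.ndarray  # A, one per trajectory step


def monitor_pair_distances(traj, pairs: Sequence[MonitoredPair]) -> list[DistanceSeries]:
    """Centroid-to-centroid distance of each pair along an MC trajectory.

    ``traj`` is an :class:`~bindspace.mc.MCTrajectory`; one series per
    pair, with one value per recorded step.
    """
    rxyz = traj.receptor.coords
    out = []
    for p in pairs:
        if not p.ligand_indices or not p.receptor_indices:
            raise InputError(f"monitored pair {p.label!r}: empty selection")
        n_atoms = len(traj.snapshots[0]) if traj.snapshots else 0
        if max(p.ligand_indices) >= n_atoms or max(p.receptor_indices) >= len(rxyz):
            raise InputError(f"monitored pair {p.label!r}: index out of range")
        rc = rxyz[list(p.receptor_indices)].mean(axis=0)
        vals = [
            float(np.linalg.norm(snap.coords[list(p.ligand_indices)].mean(axis=0) - rc))
            for snap in traj.snapshots[1:]  # one per step, post-acceptance
        ]
        out.append(DistanceSeries(p.label, np.array(vals)))
    return out


def distance_series_frame(series: Sequence[DistanceSeries]) -> pd.DataFrame:
    """Tidy long-format table of monitored distances (step, pair, distance)."""
    rows = [
        {"step": k, "pair": s.label, "distance": float(v)}
        for s in series
        for k, v in enumerate(s.values)
    ]
    return pd.DataFrame(rows, columns=["step", "pair", "distance"])


def records_to_frame(records: Sequence[InteractionRecord]) -> pd.DataFrame:
    """Tidy DataFrame of interaction records (for CSV/JSON export)."""
    return pd.DataFrame(
        [
            {
                "kind": r.kind,
                "chain": r.residue_id[0],
                "resnum": r.residue_id[1],
                "resname": r.residue_id[2],
                "ligand_atoms": "+".join(map(str, r.ligand_atoms)),
                "receptor_atoms": "+".join(map(str, r.receptor_atoms)),
                "distance": round(r.distance, 4),
                "angle": np.nan if r.angle is None else round(r.angle, 2),
                "displaced": r.displaced,
            }
            for r in records
        ]
    )
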