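"""Electrostatic complementarity (EC) on the solvent-accessible surface.

The ligand SAS is sampled Shrake-Rupley style with a golden-spiral point
lattice; ligand and protein electrostatic potentials (point charges,
Coulomb) are evaluated at every surviving point; the local EC score

    EC(x) = 1 - |ESP_L + ESP_P| / max(|ESP_L|, |ESP_P|, k)

(with both ESPs first capped to +/-cap) is 1 for perfectly complementary
potentials and -1 for identical clashing ones. The global score is the
area-weighted mean over the ligand surface. Defaults k = 5, cap = 12 in
kcal/(mol e) — a declared unit convention for the point-charge ESP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import fibonacci_sphere
from .structures import EmptyStructureError, Structure

COULOMB_CONSTANT = 332.06  # kcal A / (mol e^2)
MIN_CHARGE_DISTANCE = 0.01  # A; closer charges contribute as if at this range


@dataclass(frozen=True)
class ECParams:
    k: float = 5.0  # denominator floor, ESP units
    cap: float = 12.0  # max ESP deviation from zero entering the score
    probe_radius: float = 1.4  # A
    points_per_atom: int = 256
    dielectric: float = 1.0  # relative permittivity for the surface ESP

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.cap < self.k:
            raise ValueError("cap must be at least k")


@dataclass
class SurfaceField:
    """Area-weighted SAS point cloud with per-point ESP and EC values."""

    positions: np.ndarray  # (n, 3) A
    area_weights: np.ndarray  # (n,) A^2
    owner_atoms: np.ndarray  # (n,) atom index
    esp_ligand: np.ndarray | None = None
    esp_protein: np.ndarray | None = None
    local_ec: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def total_area(self) -> float:
        return float(self.area_weights.sum())

    def atom_area(self, n_atoms: int) -> np.ndarray:
        """Exposed SAS area per atom (A^2)."""
        return np.bincount(self.owner_atoms, weights=self.area_weights, minlength=n_atoms)

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.positions, columns=["x", "y", "z"])
        df["area"] = self.area_weights
        df["atom"] = self.owner_atoms
        for name, arr in (
            ("esp_ligand", self.esp_ligand),
            ("esp_protein", self.esp_protein),
            ("local_ec", self.local_ec),
        ):
            if arr is not None:
                df[name] = arr
        return df


@dataclass
class ECResult:
    global_ec: float
    total_area: float
    field: SurfaceField


def sample_sas(
    s: Structure,
    p: ECParams = ECParams(),
    occluders: Structure | None = None,
) -> SurfaceField:
    """Shrake-Rupley sampling of the solvent-accessible surface.

    Near-uniform points are placed on each atom's expanded sphere
    (r_vdw + probe); points inside any neighbour's expanded sphere are
    discarded. Each surviving point carries the area weight
    4 pi (r + probe)^2 / points_per_atom of its owner atom. With
    ``occluders`` given (e.g. the receptor around a bound pose), its atoms
    also bury surface points, yielding the in-complex SAS.
    """
    if len(s) == 0:
        raise EmptyStructureError("sample_sas: empty structure")
    unit = fibonacci_sphere(p.points_per_atom)
    centers = s.coords
    radii = np.array([a.vdw_radius for a in s.atoms]) + p.probe_radius
    occ_centers = centers
    occ_radii = radii
    if occluders is not None and len(occluders) > 0:
        occ_centers = np.vstack([centers, occluders.coords])
        occ_radii = np.concatenate(
            [radii, np.array([a.vdw_radius for a in occluders.atoms]) + p.probe_radius]
        )
    tree = cKDTree(occ_centers)
    positions, weights, owners = [], [], []
    max_r = float(occ_radii.max())
    for i in range(len(s)):
        pts = centers[i] + radii[i] * unit
        # candidate occluders: any sphere that could reach these points
        nbrs = [
            j
            for j in tree.query_ball_point(centers[i], radii[i] + max_r)
            if j != i
        ]
        keep = np.ones(len(pts), dtype=bool)
        for j in nbrs:
            keep &= ((pts - occ_centers[j]) ** 2).sum(-1) > occ_radii[j] ** 2 - 1e-12
        if keep.any():
            w = 4.0 * np.pi * radii[i] ** 2 / p.points_per_atom
            positions.append(pts[keep])
            weights.append(np.full(int(keep.sum()), w))
            owners.append(np.full(int(keep.sum()), i, dtype=int))
    if positions:
        return SurfaceField(
            positions=np.vstack(positions),
            area_weights=np.concatenate(weights),
            owner_atoms=np.concatenate(owners),
        )
    return SurfaceField(
        positions=np.zeros((0, 3)), area_weights=np.zeros(0), owner_atoms=np.zeros(0, int)
    )


def esp_from_charges(
    points: np.ndarray | SurfaceField,
    charges: tuple[np.ndarray, np.ndarray],
    p: ECParams = ECParams(),
) -> np.ndarray:
    """Point-charge ESP at each surface point, kcal/(mol e).

    ESP(x) = sum_i 332.06 q_i / (dielectric * |x - x_i|). The SAS offset
    keeps points away from nuclei; any charge closer than 0.01 A
    contributes as if at that distance (capped, to avoid the singularity).
    """
    pos = points.positions if isinstance(points, SurfaceField) else np.asarray(points, float)
    qpos, q = charges
    qpos = np.asarray(qpos, float).reshape(-1, 3)
    q = np.asarray(q, float)
    if not np.all(np.isfinite(q)):
        raise ValueError("charges must be finite")
    if len(q) == 0:
        return np.zeros(len(pos))
    d = np.sqrt(((pos[:, None, :] - qpos[None, :, :]) ** 2).sum(-1))
    d = np.maximum(d, MIN_CHARGE_DISTANCE)
    return COULOMB_CONSTANT / p.dielectric * (q[None, :] / d).sum(axis=1)


def structure_charges(s: Structure) -> tuple[np.ndarray, np.ndarray]:
    return s.coords, s.charges


def local_ec(esp_l: np.ndarray, esp_p: np.ndarray, p: ECParams = ECParams()) -> np.ndarray:
    """Per-point complementarity score, bounded in [-1, 1]."""
    el = np.clip(np.asarray(esp_l, float), -p.cap, p.cap)
    ep = np.clip(np.asarray(esp_p, float), -p.cap, p.cap)
    denom = np.maximum(np.maximum(np.abs(el), np.abs(ep)), p.k)
    return 1.0 - np.abs(el + ep) / denom


def ec_score(field: SurfaceField, p: ECParams = ECParams()) -> ECResult:
    """Global EC: area-weighted mean of the local score over the ligand SAS."""
    if field.esp_ligand is None or field.esp_protein is None:
        raise ValueError("ec_score: populate esp_ligand and esp_protein first")
    field.local_ec = local_ec(field.esp_ligand, field.esp_protein, p)
    w = field.area_weights
    total = float(w.sum())
    g = float((field.local_ec * w).sum() / total) if total > 0 else 0.0
    return ECResult(global_ec=g, total_area=total, field=field)


def compute_ec(
    ligand: Structure,
    receptor: Structure,
    p: ECParams = ECParams(),
) -> ECResult:
    """End-to-end EC of a bound pose: sample the ligand SAS, map both
    ESPs, score."""
    field = sample_sas(ligand, p)
    field.esp_ligand = esp_from_charges(field, structure_charges(ligand), p)
    field.esp_protein = esp_from_charges(field, structure_charges(receptor), p)
    return ec_score(field, p)


def write_point_cloud_pdb(field: SurfaceField, path: str) -> None:
    """PDB-like point cloud for visualization; B-factor = local EC."""
    lines = []
    ec = field.local_ec if field.local_ec is not None else np.zeros(len(field))
    for i, (pos, e) in enumerate(zip(field.positions, ec), start=1):
        lines.append(
            f"HETATM{i % 100000:>5d}  S   SUR P   1    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.00:6.2f}{e:6.2f}           S"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
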