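"""Metropolis Monte Carlo torsional search (Boltzmann jump protocol).

Each step applies a random torsional perturbation with an exact per-move
rms of 60 degrees (default), relaxes the ligand with 20 steepest-descent
minimization steps, and accepts or rejects the minimized conformer with
the Metropolis criterion at 1000 K (default). The receptor is held rigid.

The energy model is a minimal Lennard-Jones + distance-dependent-
dielectric Coulomb + 3-fold torsion potential; absolute energies are a
ranking device for the protocol, not literature-comparable values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import rotation_about_axis
from .interactions import MonitoredPair
from .structures import ActiveSite, InputError, Structure, list_rotatable_bonds

#: gas constant, kcal/(mol K)
GAS_CONSTANT = 1.987204e-3
#: Coulomb conversion constant, kcal A / (mol e^2)
COULOMB_CONSTANT = 332.06
#: pair distances below this are clamped (capped repulsion)
MIN_PAIR_DISTANCE = 0.1

# per-element Lennard-Jones well depth (kcal/mol) and rmin/2 (A)
DEFAULT_LJ = {
    "H": (0.020, 1.10),
    "C": (0.086, 1.70),
    "N": (0.170, 1.55),
    "O": (0.210, 1.52),
    "S": (0.250, 1.80),
    "P": (0.200, 1.80),
    "Na": (0.047, 1.36),
    "Cl": (0.265, 1.75),
    "F": (0.061, 1.47),
    "K": (0.087, 1.76),
    "Br": (0.320, 1.85),
    "I": (0.400, 1.98),
}


@dataclass(frozen=True)
class EnergyModel:
    lj_params: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_LJ))
    coulomb_constant: float = COULOMB_CONSTANT
    dielectric_factor: float = 4.0  # epsilon = factor * r (distance-dependent)
    torsion_barrier: float = 1.4  # kcal/mol, 3-fold
    nonbonded_cutoff: float = 10.0  # A


@dataclass(frozen=True)
class MCConfig:
    temperature: float = 1000.0  # K
    torsion_rms: float = 60.0  # degrees, exact per-move rms
    n_steps: int = 1000
    minimize_steps: int = 20
    seed: int = 42
    monitored_pairs: tuple[MonitoredPair, ...] = ()
    exact_rms: bool = True  # False: 60 deg is the normal draw width instead

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not (0 < self.torsion_rms <= 180):
            raise ValueError("torsion_rms must be in (0, 180] degrees")
        if self.n_steps < 0 or self.minimize_steps < 0:
            raise ValueError("step counts must be non-negative")


@dataclass
class MCStep:
    index: int
    proposed_energy: float  # after perturbation, before minimization
    post_min_energy: float
    accepted: bool
    torsion_deltas: np.ndarray  # degrees per rotatable bond


@dataclass
class MCTrajectory:
    steps: list[MCStep]
    snapshots: list[Structure]  # snapshots[0] = initial, [k] = after step k
    receptor: Structure
    config: MCConfig
    monitored: dict[str, list[float]] = field(default_factory=dict)
    initial_energy: float = 0.0

    @property
    def energies(self) -> np.ndarray:
        """Post-acceptance energy after each step."""
        out = []
        cur = self.initial_energy
        for st in self.steps:
            if st.accepted:
                cur = st.post_min_energy
            out.append(cur)
        return np.array(out, dtype=float)

    @property
    def acceptance_rate(self) -> float:
        if not self.steps:
            return 0.0
        return sum(s.accepted for s in self.steps) / len(self.steps)


@dataclass
class MinimizationResult:
    structure: Structure
    energies: list[float]  # energy after each iteration (index 0 = start)
    n_iterations: int

    @property
    def final_energy(self) -> float:
        return self.energies[-1]


# ---------------------------------------------------------------------------
# energy evaluation


def _lj_coulomb(
    xyz_a: np.ndarray,
    xyz_b: np.ndarray,
    q_a: np.ndarray,
    q_b: np.ndarray,
    eps_a: np.ndarray,
    eps_b: np.ndarray,
    rm_a: np.ndarray,
    rm_b: np.ndarray,
    m: EnergyModel,
    mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """Pairwise LJ and Coulomb sums between two atom sets (vectorized)."""
    d = np.sqrt(((xyz_a[:, None, :] - xyz_b[None, :, :]) ** 2).sum(-1))
    if (d < MIN_PAIR_DISTANCE).any() and (mask is None or (d[mask] < MIN_PAIR_DISTANCE).any()):
        warnings.warn("overlapping atoms: repulsion capped at 0.1 A", stacklevel=3)
    d = np.maximum(d, MIN_PAIR_DISTANCE)
    within = d <= m.nonbonded_cutoff
    if mask is not None:
        within &= mask
    eps = np.sqrt(eps_a[:, None] * eps_b[None, :])
    rm = rm_a[:, None] + rm_b[None, :]
    x6 = (rm / d) ** 6
    lj = eps * (x6 * x6 - 2.0 * x6)
    coul = m.coulomb_constant * q_a[:, None] * q_b[None, :] / (m.dielectric_factor * d * d)
    return float(lj[within].sum()), float(coul[within].sum())


def _params(s: Structure, m: EnergyModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    eps = np.array([m.lj_params[a.element][0] for a in s.atoms])
    rm = np.array([m.lj_params[a.element][1] for a in s.atoms])
    return s.charges, eps, rm


def _site_subset(receptor: Structure, site: ActiveSite) -> list[int]:
    return [i for i, a in enumerate(receptor.atoms) if a.residue_id in site.residue_ids]


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return float(np.degrees(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w))))


def _torsion_energy(lig: Structure, rotors: list[tuple[int, int]], m: EnergyModel) -> float:
    adj = lig.adjacency()
    e = 0.0
    xyz = lig.coords
    for i, j in rotors:
        nb_i = [k for k in adj[i] if k != j and not lig.atoms[k].is_hydrogen]
        nb_j = [k for k in adj[j] if k != i and not lig.atoms[k].is_hydrogen]
        if not nb_i or not nb_j:
            continue
        # average over every substituent pair: invariant to atom relabeling
        terms = [
            1.0 + np.cos(np.deg2rad(3.0 * _dihedral(xyz[a], xyz[i], xyz[j], xyz[b])))
            for a in nb_i
            for b in nb_j
        ]
        e += 0.5 * m.torsion_barrier * float(np.mean(terms))
    return e


_EXCLUSION_CACHE: dict[tuple, np.ndarray] = {}


def _exclusion_mask(lig: Structure) -> np.ndarray:
    """Intramolecular pair mask: True for graph distance >= 3 (1-4 and up).

    Cached on the bond topology — it is evaluated on every energy call
    and conformers of one ligand share it.
    """
    key = (len(lig), tuple(sorted(tuple(sorted(b)) for b in lig.bonds)))
    cached = _EXCLUSION_CACHE.get(key)
    if cached is not None:
        return cached
    import networkx as nx

    n = len(lig)
    g = lig.graph()
    mask = np.ones((n, n), dtype=bool)
    np.fill_diagonal(mask, False)
    lengths = dict(nx.all_pairs_shortest_path_length(g, cutoff=2))
    for i, dd in lengths.items():
        for j in dd:
            if j != i:
                mask[i, j] = False
    mask = np.triu(mask, 1)  # each pair once
    if len(_EXCLUSION_CACHE) > 64:
        _EXCLUSION_CACHE.clear()
    _EXCLUSION_CACHE[key] = mask
    return mask


def intermolecular_terms(
    ligand: Structure, receptor: Structure, site: ActiveSite, m: EnergyModel = EnergyModel()
) -> tuple[float, float]:
    """(LJ, Coulomb) sums between the ligand and the active-site atoms."""
    idx = _site_subset(receptor, site)
    if not idx:
        return 0.0, 0.0
    q_l, eps_l, rm_l = _params(ligand, m)
    q_r, eps_r, rm_r = _params(receptor, m)
    rxyz = receptor.coords[idx]
    return _lj_coulomb(
        ligand.coords, rxyz, q_l, q_r[idx], eps_l, eps_r[idx], rm_l, rm_r[idx], m
    )


def ligand_internal_energy(
    ligand: Structure, m: EnergyModel = EnergyModel(), rotors: list[tuple[int, int]] | None = None
) -> float:
    """Intramolecular nonbonded (1-4 and further) plus torsional energy."""
    if rotors is None:
        rotors = list_rotatable_bonds(ligand)
    q, eps, rm = _params(ligand, m)
    xyz = ligand.coords
    mask = _exclusion_mask(ligand)
    lj, coul = _lj_coulomb(xyz, xyz, q, q, eps, eps, rm, rm, m, mask=mask)
    return lj + coul + _torsion_energy(ligand, rotors, m)


def system_energy(
    ligand: Structure,
    receptor: Structure,
    site: ActiveSite,
    m: EnergyModel = EnergyModel(),
) -> float:
    """Total interaction + ligand internal energy (kcal/mol). Pure function."""
    lj, coul = intermolecular_terms(ligand, receptor, site, m)
    return lj + coul + ligand_internal_energy(ligand, m)


# ---------------------------------------------------------------------------
# torsional moves


def _split_fragment(s: Structure, i: int, j: int) -> list[int]:
    """Atoms of the smaller fragment when bond (i, j) is cut.

    Tie broken toward the fragment containing j. The returned fragment is
    the one that moves when the torsion is rotated.
    """
    g = s.graph()
    g.remove_edge(i, j)
    import networkx as nx

    comp_j = nx.node_connected_component(g, j)
    comp_i = nx.node_connected_component(g, i)
    if len(comp_j) <= len(comp_i):
        return sorted(comp_j)
    return sorted(comp_i)


def rotate_torsion(s: Structure, bond: tuple[int, int], angle_deg: float) -> Structure:
    """Return a copy with the smaller fragment rotated about the bond axis."""
    i, j = bond
    out = s.copy()
    frag = _split_fragment(s, i, j)
    xyz = out.coords
    axis = xyz[j] - xyz[i]
    rot = rotation_about_axis(axis, angle_deg)
    pivot = xyz[i]
    xyz[frag] = rot.apply(xyz[frag] - pivot) + pivot
    out.set_coords(xyz)
    return out


def perturb_torsions(
    conformer: Structure,
    rotors: list[tuple[int, int]],
    torsion_rms: float,
    rng: np.random.Generator,
    exact_rms: bool = True,
) -> tuple[Structure, np.ndarray]:
    """Random torsional perturbation with rms(deltas) == torsion_rms.

    Deltas are drawn from a zero-mean normal and rescaled so their rms is
    exactly ``torsion_rms`` (default); with ``exact_rms=False`` the normal
    width itself is ``torsion_rms``. Returns the new conformer and the
    per-rotor deltas (degrees).
    """
    if not rotors:
        warnings.warn("perturb_torsions: no rotatable bonds, returning input", stacklevel=2)
        return conformer.copy(), np.zeros(0)
    deltas = rng.standard_normal(len(rotors))
    while np.sqrt((deltas**2).mean()) < 1e-12:
        deltas = rng.standard_normal(len(rotors))
    if exact_rms:
        deltas = deltas * (torsion_rms / np.sqrt((deltas**2).mean()))
    else:
        deltas = deltas * torsion_rms
    out = conformer
    for bond, d in zip(rotors, deltas):
        out = rotate_torsion(out, bond, float(d))
    return out, deltas


# ---------------------------------------------------------------------------
# minimization (torsion-space steepest descent)


def minimize_steps(
    ligand: Structure,
    receptor: Structure | None,
    site: ActiveSite | None,
    m: EnergyModel = EnergyModel(),
    n: int = 20,
    rotors: list[tuple[int, int]] | None = None,
) -> MinimizationResult:
    """Exactly ``n`` steepest-descent iterations in torsion space.

    The ligand's internal geometry is rigid except for rotations about its
    rotatable bonds; the gradient is taken numerically and each iteration
    uses a backtracking line search, so the energy is non-increasing. With
    ``receptor=None`` the objective is the ligand internal energy alone.
    """
    if rotors is None:
        rotors = list_rotatable_bonds(ligand)

    def energy(s: Structure) -> float:
        if receptor is None or site is None:
            return ligand_internal_energy(s, m, rotors)
        return system_energy(s, receptor, site, m)

    current = ligand.copy()
    e_cur = energy(current)
    energies = [e_cur]
    if not rotors:
        return MinimizationResult(current, energies + [e_cur] * n, n)
    step_size = 10.0  # degrees along the normalized gradient
    h = 0.5  # finite-difference probe, degrees
    for _ in range(n):
        grad = np.zeros(len(rotors))
        for k, bond in enumerate(rotors):
            probe = rotate_torsion(current, bond, h)
            grad[k] = (energy(probe) - e_cur) / h
        gnorm = float(np.linalg.norm(grad))
        if gnorm < 1e-10:
            energies.append(e_cur)
            continue
        direction = -grad / gnorm
        alpha = step_size
        moved = False
        for _bt in range(6):
            trial = current
            for bond, d in zip(rotors, direction * alpha):
                trial = rotate_torsion(trial, bond, float(d))
            e_trial = energy(trial)
            if e_trial < e_cur:
                current, e_cur = trial, e_trial
                moved = True
                break
            alpha *= 0.5
        if moved:
            step_size = min(alpha * 1.5, 30.0)
        energies.append(e_cur)
    return MinimizationResult(current, energies, n)


# ---------------------------------------------------------------------------
# Metropolis


def metropolis_accept(
    delta_e: float, temperature: float, rng: np.random.Generator
) -> bool:
    """Accept downhill moves always; uphill with probability exp(-dE/RT)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return True
    return bool(rng.random() < np.exp(-delta_e / (GAS_CONSTANT * temperature)))


def run_mc(
    pose: Structure,
    receptor: Structure,
    site: ActiveSite,
    cfg: MCConfig = MCConfig(),
    m: EnergyModel = EnergyModel(),
) -> MCTrajectory:
    """Run the Boltzmann-jump MC protocol on a ligand in a rigid pocket.

    Each step: perturb torsions (exact 60 deg rms by default), minimize
    (20 steps), apply the Metropolis criterion to the post-minimization
    energy versus the current energy. Rejected proposals restore the
    previous conformer. Monitored pair distances are recorded after every
    step. Fully reproducible from the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    rotors = list_rotatable_bonds(pose)
    receptor_ref = receptor.coords.copy()
    current = pose.copy()
    e_cur = system_energy(current, receptor, site, m)
    traj = MCTrajectory(
        steps=[], snapshots=[current.copy()], receptor=receptor, config=cfg,
        monitored={p.label: [] for p in cfg.monitored_pairs},
        initial_energy=e_cur,
    )
    for k in range(cfg.n_steps):
        proposed, deltas = perturb_torsions(
            current, rotors, cfg.torsion_rms, rng, exact_rms=cfg.exact_rms
        )
        e_prop = system_energy(proposed, receptor, site, m)
        minres = minimize_steps(proposed, receptor, site, m, n=cfg.minimize_steps, rotors=rotors)
        e_new = minres.final_energy
        accepted = metropolis_accept(e_new - e_cur, cfg.temperature, rng)
        if accepted:
            current, e_cur = minres.structure, e_new
        traj.steps.append(
            MCStep(index=k, proposed_energy=e_prop, post_min_energy=e_new,
                   accepted=accepted, torsion_deltas=deltas)
        )
        traj.snapshots.append(current.copy())
        cxyz = current.coords
        for p in cfg.monitored_pairs:
            lc = cxyz[list(p.ligand_indices)].mean(axis=0)
            rc = receptor_ref[list(p.receptor_indices)].mean(axis=0)
            traj.monitored[p.label].append(float(np.linalg.norm(lc - rc)))
        if not np.array_equal(receptor.coords, receptor_ref):
            raise RuntimeError("receptor coordinates changed during MC (must stay rigid)")
    return traj
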