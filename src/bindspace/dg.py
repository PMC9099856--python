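"""Component-structured binding free-energy estimate.

Reproduces the *term inventory* of an empirical ΔG function — enthalpic
LJ/Coulomb, explicit H-bond rewards, Born-like polar desolvation, lost
H-bond penalties, nonpolar solvation from buried surface, ligand internal
strain, and an entropic penalty for frozen rotors — with declared default
coefficients. It ranks poses; it does not predict absolute affinities,
and no published calibration is reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ec import ECParams, sample_sas
from .interactions import InteractionCriteria, detect_interactions
from .mc import EnergyModel, intermolecular_terms, ligand_internal_energy, minimize_steps
from .structures import (
    ActiveSite,
    InputError,
    Structure,
    assign_pharmacophore_types,
    list_rotatable_bonds,
)


@dataclass(frozen=True)
class DGParams:
    """Coefficients of the estimator (kcal/mol unless noted)."""

    hbond_strong_reward: float = -1.0  # per strong H-bond
    hbond_weak_reward: float = -0.5  # per weak H-bond
    salt_bridge_reward: float = -1.0  # salt-bridge reinforcement, strong level
    born_constant: float = 166.0  # kcal A / (mol e^2); half of 332.06
    born_radius_offset: float = 0.5  # A added to the covalent radius
    # transfer screening (1/eps_interior - 1/eps_water): burial moves a
    # charge from water (~78.5) into the protein interface, not vacuum.
    # The effective interface dielectric of 20 follows empirical-scoring
    # practice (side-chain flexibility + retained interfacial water), so a
    # contact ion pair is net favourable while an uncompensated buried
    # charge is still penalized.
    born_screening: float = 1.0 / 20.0 - 1.0 / 78.5
    lost_hbond_penalty: float = 0.6  # per buried unsatisfied donor/acceptor
    buried_threshold: float = 0.5  # buried fraction counting as buried
    nonpolar_coefficient: float = -0.025  # kcal/(mol A^2) of buried SASA
    entropy_per_rotor: float = 0.65  # per frozen rotatable bond
    charged_atom_min_q: float = 0.25  # |q| above which an atom desolvates
    contact_distance: float = 4.5  # A; rotor-freezing contact criterion
    minimize_steps: int = 20  # for the internal-strain reference


@dataclass
class DGBreakdown:
    e_vdw: float
    e_coulomb: float
    e_hbond: float
    polar_desolvation: float  # >= 0
    lost_hbond_penalty: float  # >= 0
    nonpolar_solvation: float  # <= 0
    internal_strain: float  # >= 0
    entropy_penalty: float  # >= 0

    @property
    def total(self) -> float:
        return (
            self.e_vdw
            + self.e_coulomb
            + self.e_hbond
            + self.polar_desolvation
            + self.lost_hbond_penalty
            + self.nonpolar_solvation
            + self.internal_strain
            + self.entropy_penalty
        )

    def as_dict(self) -> dict[str, float]:
        d = {
            "e_vdw": self.e_vdw,
            "e_coulomb": self.e_coulomb,
            "e_hbond": self.e_hbond,
            "polar_desolvation": self.polar_desolvation,
            "lost_hbond_penalty": self.lost_hbond_penalty,
            "nonpolar_solvation": self.nonpolar_solvation,
            "internal_strain": self.internal_strain,
            "entropy_penalty": self.entropy_penalty,
        }
        d["total"] = self.total
        return d


def estimate_dg(
    pose: Structure,
    receptor: Structure,
    site: ActiveSite,
    params: DGParams = DGParams(),
    energy_model: EnergyModel = EnergyModel(),
    criteria: InteractionCriteria = InteractionCriteria(),
    ec_params: ECParams = ECParams(),
) -> DGBreakdown:
    """Estimate binding ΔG of a pose as a sum of named components.

    Pure function of its inputs. Burial is measured by comparing the
    per-atom ligand SAS free versus in complex.
    """
    if np.allclose(pose.charges, 0.0) and np.allclose(receptor.charges, 0.0):
        raise InputError("estimate_dg: no partial charges on either structure")
    tags = assign_pharmacophore_types(pose)
    e_vdw, e_coulomb = intermolecular_terms(pose, receptor, site, energy_model)

    records = detect_interactions(pose, receptor, site, criteria, ligand_tags=tags)
    e_hbond = 0.0
    hb_ligand_atoms: set[int] = set()
    for r in records:
        if r.kind == "hbond_strong":
            e_hbond += params.hbond_strong_reward
        elif r.kind == "hbond_weak":
            e_hbond += params.hbond_weak_reward
        elif r.kind == "salt_bridge":
            e_hbond += params.salt_bridge_reward
        if r.kind in ("hbond_strong", "hbond_weak"):
            hb_ligand_atoms.update(r.ligand_atoms)

    # burial from per-atom SAS, free vs in-complex
    free = sample_sas(pose, ec_params)
    site_atoms = [i for i, a in enumerate(receptor.atoms) if a.residue_id in site.residue_ids]
    context = Structure(atoms=[receptor.atoms[i] for i in site_atoms], role="receptor")
    bound = sample_sas(pose, ec_params, occluders=context)
    n = len(pose)
    area_free = free.atom_area(n)
    area_bound = bound.atom_area(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        buried_fraction = np.where(area_free > 0, 1.0 - area_bound / np.maximum(area_free, 1e-12), 0.0)
    buried_fraction = np.clip(buried_fraction, 0.0, 1.0)

    # Born-like polar desolvation of charged ligand atoms
    polar = 0.0
    for i, a in enumerate(pose.atoms):
        q = a.partial_charge
        if abs(q) < params.charged_atom_min_q:
            continue
        r_born = a.covalent_radius + params.born_radius_offset
        polar += (
            params.born_constant * params.born_screening * q * q * buried_fraction[i] / r_born
        )

    # buried donors/acceptors without an H-bond record
    lost = 0.0
    polar_sites = sorted(
        {t.atom_index for t in tags if t.tag in ("hbond_donor", "hbond_acceptor")}
    )
    for i in polar_sites:
        if buried_fraction[i] > params.buried_threshold and i not in hb_ligand_atoms:
            lost += params.lost_hbond_penalty

    buried_area = float(np.maximum(area_free - area_bound, 0.0).sum())
    nonpolar = params.nonpolar_coefficient * buried_area

    # internal strain: pose conformer vs its torsionally relaxed form
    e_conf = ligand_internal_energy(pose, energy_model)
    relaxed = minimize_steps(pose, None, None, energy_model, n=params.minimize_steps)
    strain = max(0.0, e_conf - relaxed.final_energy)

    # entropic freezing: rotors whose moving fragment contacts the receptor
    rotors = list_rotatable_bonds(pose)
    frozen = 0
    if site_atoms:
        rxyz = receptor.coords[site_atoms]
        from .mc import _split_fragment

        pxyz = pose.coords
        for bond in rotors:
            frag = [k for k in _split_fragment(pose, *bond) if not pose.atoms[k].is_hydrogen]
            if not frag:
                continue
            dmin = np.sqrt(((pxyz[frag][:, None, :] - rxyz[None, :, :]) ** 2).sum(-1)).min()
            if dmin <= params.contact_distance:
                frozen += 1
    entropy = params.entropy_per_rotor * frozen

    return DGBreakdown(
        e_vdw=e_vdw,
        e_coulomb=e_coulomb,
        e_hbond=e_hbond,
        polar_desolvation=polar,
        lost_hbond_penalty=lost,
        nonpolar_solvation=nonpolar,
        internal_strain=strain,
        entropy_penalty=entropy,
    )


def breakdown_table(breakdowns: list[DGBreakdown]) -> pd.DataFrame:
    """One row per pose, one column per component (CSV-ready)."""
    return pd.DataFrame([b.as_dict() for b in breakdowns])
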