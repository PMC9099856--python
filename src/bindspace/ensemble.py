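"""Ensemble binding-space parameterization of scored pose sets.

Implements the retention filter (top 80 poses by Gibbs free energy),
summary statistics of the score distribution (mean, SD, binned mode,
range), a sensitivity score relating score range to conformational
variability, binding-mode displacement (mean pairwise rmsd in the common
receptor frame), greedy leader clustering with a representative pose, and
orientation classification against reference poses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import angle_between, kabsch_rmsd
from .structures import InputError, Structure, assign_pharmacophore_types

DEFAULT_MAX_POSES = 80
MODE_BIN_WIDTH = 0.5  # kcal/mol, anchored at the minimum
DEFAULT_CLUSTER_THRESHOLD = 2.0  # A
DEFAULT_ORIENTATION_ANGLE = 40.0  # degrees

ORIENTATION_LABELS = ("serotonin_like", "escitalopram_like", "intermediate")


@dataclass
class LigandPose:
    conformer: Structure
    delta_g: float | None  # kcal/mol; more negative = more favourable
    source_state: str = ""
    site_label: str = ""  # S1 | S2 | intermediate


@dataclass
class PoseEnsemble:
    poses: list[LigandPose]
    ligand_name: str = ""

    def __len__(self) -> int:
        return len(self.poses)

    def __post_init__(self) -> None:
        counts = {len(p.conformer) for p in self.poses}
        if len(counts) > 1:
            raise InputError("all poses of an ensemble must share atom count/order")


@dataclass
class BindingSpaceSummary:
    n_poses: int
    mean_dg: float
    sd_dg: float | None
    mode_dg: float
    range_dg: float
    sensitivity_score: float | None
    mean_pairwise_rmsd: float | None
    per_state_counts: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_poses": self.n_poses,
            "mean_dg": self.mean_dg,
            "sd_dg": self.sd_dg,
            "mode_dg": self.mode_dg,
            "range_dg": self.range_dg,
            "sensitivity_score": self.sensitivity_score,
            "mean_pairwise_rmsd": self.mean_pairwise_rmsd,
            "per_state_counts": dict(self.per_state_counts),
            "sensitivity_formula": "range_dg / mean pairwise superposed rmsd",
            "mode_bin_width_kcal": MODE_BIN_WIDTH,
        }


@dataclass
class ClusterResult:
    labels: list[int]
    representative_index: int
    threshold: float
    algorithm: str = "greedy-leader (input order, non-superposed rmsd)"

    @property
    def n_clusters(self) -> int:
        return max(self.labels) + 1 if self.labels else 0


@dataclass
class OrientationLabel:
    label: str
    angle_to_refs: dict[str, float]


# ---------------------------------------------------------------------------


def filter_top_poses(poses: list[LigandPose], max_n: int = DEFAULT_MAX_POSES) -> PoseEnsemble:
    """Retain the ``max_n`` most favourable (lowest ΔG) poses, ΔG-ascending.

    Ties are broken by input order (stable sort). Every pose must carry a
    score.
    """
    for k, p in enumerate(poses):
        if p.delta_g is None or not math.isfinite(p.delta_g):
            raise InputError(f"pose {k} has no finite ΔG score")
    ranked = sorted(poses, key=lambda p: p.delta_g)  # python sort is stable
    return PoseEnsemble(poses=ranked[:max_n])


def pose_rmsd(a: LigandPose, b: LigandPose, superpose: bool = False) -> float:
    """Heavy-atom rmsd between two poses of the same ligand.

    Without superposition the rmsd is taken in the common receptor frame
    (binding-mode displacement); with ``superpose=True`` it is computed
    after optimal rigid alignment (intramolecular flexibility).
    """
    if len(a.conformer) != len(b.conformer):
        raise InputError("pose_rmsd: atom-count mismatch")
    idx = a.conformer.heavy_indices()
    pa = a.conformer.coords[idx]
    pb = b.conformer.coords[idx]
    if superpose:
        return kabsch_rmsd(pa, pb)
    return float(np.sqrt(((pa - pb) ** 2).sum() / len(pa)))


def _mean_pairwise(e: PoseEnsemble, superpose: bool) -> float | None:
    n = len(e)
    if n < 2:
        return None
    vals = [
        pose_rmsd(e.poses[i], e.poses[j], superpose=superpose)
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return float(np.mean(vals))


def binding_space_summary(e: PoseEnsemble) -> BindingSpaceSummary:
    """Parameterize the binding space of a scored ensemble.

    mode_dg is the centre of the most populated 0.5 kcal/mol bin anchored
    at the minimum ΔG (ties -> lowest bin). The sensitivity score is
    range_dg over the mean pairwise *superposed* rmsd (conformational
    variability); mean_pairwise_rmsd is the non-superposed binding-mode
    displacement.
    """
    if len(e) == 0:
        raise InputError("binding_space_summary: empty ensemble")
    dgs = np.array([p.delta_g for p in e.poses], dtype=float)
    n = len(dgs)
    lo = float(dgs.min())
    bins = np.floor((dgs - lo) / MODE_BIN_WIDTH + 1e-12).astype(int)
    best_bin = np.bincount(bins).argmax()
    mode = lo + (best_bin + 0.5) * MODE_BIN_WIDTH
    sd = float(np.std(dgs, ddof=1)) if n >= 2 else None
    conf_rmsd = _mean_pairwise(e, superpose=True)
    disp_rmsd = _mean_pairwise(e, superpose=False)
    rng = float(dgs.max() - lo)
    sensitivity = None
    if conf_rmsd is not None and conf_rmsd > 1e-12:
        sensitivity = rng / conf_rmsd
    counts: dict[str, int] = {}
    for p in e.poses:
        counts[p.source_state] = counts.get(p.source_state, 0) + 1
    return BindingSpaceSummary(
        n_poses=n,
        mean_dg=float(dgs.mean()),
        sd_dg=sd,
        mode_dg=float(mode),
        range_dg=rng,
        sensitivity_score=sensitivity,
        mean_pairwise_rmsd=disp_rmsd,
        per_state_counts=counts,
    )


def cluster_poses(e: PoseEnsemble, threshold: float = DEFAULT_CLUSTER_THRESHOLD) -> ClusterResult:
    """Greedy leader clustering on non-superposed rmsd, in input order.

    A pose joins the first cluster whose leader is within ``threshold``,
    otherwise founds a new cluster. The representative is the medoid
    (minimum summed rmsd) of the most populated cluster; ties go to the
    lower ΔG, then the lower index.
    """
    if len(e) == 0:
        raise InputError("cluster_poses: empty ensemble")
    leaders: list[int] = []
    labels: list[int] = []
    for i, p in enumerate(e.poses):
        assigned = None
        for ci, leader in enumerate(leaders):
            if pose_rmsd(e.poses[leader], p) <= threshold:
                assigned = ci
                break
        if assigned is None:
            leaders.append(i)
            assigned = len(leaders) - 1
        labels.append(assigned)
    sizes = np.bincount(labels)
    top = int(sizes.argmax())  # ties -> lowest cluster id
    members = [i for i, c in enumerate(labels) if c == top]
    best = None
    for i in members:
        summed = sum(pose_rmsd(e.poses[i], e.poses[j]) for j in members if j != i)
        dg = e.poses[i].delta_g if e.poses[i].delta_g is not None else math.inf
        key = (summed, dg, i)
        if best is None or key < best[0]:
            best = (key, i)
    return ClusterResult(labels=labels, representative_index=best[1], threshold=threshold)


# ---------------------------------------------------------------------------
# orientation classification


def ligand_axis(pose: LigandPose) -> np.ndarray:
    """Unit vector from the cationic amine N to the aromatic ring centroid."""
    s = pose.conformer
    tags = assign_pharmacophore_types(s)
    cations = sorted({t.atom_index for t in tags if t.tag == "cation"})
    aromatic = sorted({t.atom_index for t in tags if t.tag == "aromatic_ring_member"})
    if not cations or not aromatic:
        raise InputError("ligand has no cation or no aromatic ring: axis undefined")
    centroid = s.coords[aromatic].mean(axis=0)
    v = centroid - s.coords[cations[0]]
    return v / np.linalg.norm(v)


def classify_orientation(
    p: LigandPose,
    ref_a: LigandPose,
    ref_b: LigandPose,
    max_angle: float = DEFAULT_ORIENTATION_ANGLE,
) -> OrientationLabel:
    """Label a pose 5-HT-like (ref_a), escitalopram-like (ref_b) or
    intermediate by the angle between ligand axes.

    The label goes to the reference whose axis angle is within
    ``max_angle`` and is the smaller of the two; a pose matching neither
    is intermediate.
    """
    axis = ligand_axis(p)
    ang_a = angle_between(axis, ligand_axis(ref_a))
    ang_b = angle_between(axis, ligand_axis(ref_b))
    if ang_a <= max_angle and ang_a <= ang_b:
        label = "serotonin_like"
    elif ang_b <= max_angle:
        label = "escitalopram_like"
    else:
        label = "intermediate"
    return OrientationLabel(
        label=label, angle_to_refs={"serotonin_like": ang_a, "escitalopram_like": ang_b}
    )
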