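"""Docked-pose clustering and MD starting-structure selection.

Docking into a rigid protein template yields up to a few hundred ligand
poses per (ligand, template) pair. To seed a small number of independent MD
simulations, the poses are grouped by greedy nearest-neighbor clustering on
their pairwise heavy-atom RMSD matrix, clusters whose representative lies
outside the active site are discarded, and the central structures of the
(at most three) most populated surviving clusters become the MD starting
orientations, ranked I/II/III by cluster population.

RMSDs are computed without superposition by default: poses docked into one
template share a coordinate frame, and differences in binding position are
meaningful signal that superposition would erase. All lengths are in nm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PoseSet:
    """Heavy-atom coordinate sets of docked poses sharing one atom ordering.

    ``coords`` has shape (n_poses, n_atoms, 3), in nm. ``site_center`` /
    ``site_radius`` optionally define the active-site sphere used by the
    out-of-site filter.
    """

    ligand_id: str
    template_id: str
    coords: np.ndarray
    site_center: np.ndarray | None = None
    site_radius: float | None = None
    atoms: object = None  # optional biotite AtomArray template for PDB output

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError(
                f"coords must have shape (n_poses, n_atoms, 3), got "
                f"{self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("pose coordinates must be finite")
        if self.site_center is not None:
            self.site_center = np.asarray(self.site_center, dtype=float).reshape(3)

    @property
    def n_poses(self) -> int:
        return self.coords.shape[0]

    @property
    def atom_count(self) -> int:
        return self.coords.shape[1]


@dataclass
class Cluster:
    members: list[int]
    central: int

    @property
    def population(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    """Clusters sorted by population (descending) plus leftover poses."""

    clusters: list[Cluster]
    cutoff_used: float
    unclustered: list[int] = field(default_factory=list)


@dataclass
class SelectedPose:
    """One MD starting structure: cluster rank I/II/III and its coordinates."""

    rank: str
    pose_index: int
    population: int
    coords: np.ndarray


def pose_rmsd_matrix(poses: PoseSet, superimpose: bool = False) -> np.ndarray:
    """Symmetric matrix of pairwise heavy-atom RMSDs, nm.

    With ``superimpose=True`` each pair is optimally translated and rotated
    (Kabsch) before the deviation is measured; default is the shared docking
    frame with no fitting.
    """
    if poses.n_poses < 2:
        raise ValidationError("need at least 2 poses for an RMSD matrix")
    x = poses.coords
    n = poses.n_poses
    if not superimpose:
        # ||xi - xj||^2 summed over atoms, vectorized over pose pairs
        diff = x[:, None, :, :] - x[None, :, :, :]
        msd = np.mean(np.sum(diff * diff, axis=-1), axis=-1)
        return np.sqrt(msd)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _kabsch_rmsd(x[i], x[j])
    return mat


def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    u, _s, vt = np.linalg.svd(a0.T @ b0)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = a0 - b0 @ rot.T
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def nearest_neighbor_cluster(
    matrix: np.ndarray, cutoff: float, max_clusters: int = 5
) -> ClusterSet:
    """Greedy nearest-neighbor clustering of a pose-pose distance matrix.

    Repeatedly take the pose with the most unassigned neighbors within
    ``cutoff`` (ties broken by lowest pose index), form a cluster of it and
    those neighbors, remove them, and repeat — stopping after
    ``max_clusters`` clusters, with any remaining poses reported as
    unclustered. Populations are non-increasing by construction.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValidationError("empty distance matrix")
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValidationError(f"distance matrix must be square, got {matrix.shape}")
    if cutoff <= 0 or max_clusters < 1:
        raise ValidationError("cutoff must be > 0 and max_clusters >= 1")
    n = matrix.shape[0]
    neighbor = matrix <= cutoff  # includes self on the zero diagonal
    remaining = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while remaining.any() and len(clusters) < max_clusters:
        counts = (neighbor & remaining).sum(axis=1)
        counts[~remaining] = -1
        seed = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbor[seed] & remaining)
        clusters.append(
            Cluster(
                members=[int(m) for m in members],
                central=central_structure([int(m) for m in members], matrix),
            )
        )
        remaining[members] = False
    return ClusterSet(
        clusters=clusters,
        cutoff_used=float(cutoff),
        unclustered=[int(i) for i in np.flatnonzero(remaining)],
    )


def central_structure(members: list[int], matrix: np.ndarray) -> int:
    """Member with the smallest mean distance to the other members.

    A singleton's central structure is itself; ties go to the lowest index.
    """
    if not members:
        raise ValidationError("empty cluster")
    if len(members) == 1:
        return members[0]
    sub = np.asarray(matrix)[np.ix_(members, members)]
    mean_to_others = sub.sum(axis=1) / (len(members) - 1)
    return members[int(np.argmin(mean_to_others))]


def active_site_filter(
    poses: PoseSet,
    clusters: ClusterSet,
    site_center: np.ndarray | None = None,
    site_radius: float | None = None,
) -> tuple[list[Cluster], list[dict]]:
    """Discard clusters whose central structure lies outside the active site.

    A cluster is discarded when the geometric center of its central
    structure is farther than ``site_radius`` from ``site_center`` (both in
    nm, defaulting to the PoseSet's site definition). Returns the retained
    clusters and a log of discards with their distances.
    """
    center = site_center if site_center is not None else poses.site_center
    radius = site_radius if site_radius is not None else poses.site_radius
    if center is None or radius is None:
        raise ConfigError(
            "active-site filter requested without site_center/site_radius"
        )
    center = np.asarray(center, dtype=float).reshape(3)
    retained, discards = [], []
    for cluster in clusters.clusters:
        centroid = poses.coords[cluster.central].mean(axis=0)
        dist = float(np.linalg.norm(centroid - center))
        if dist > radius:
            discards.append(
                {
                    "central_index": cluster.central,
                    "population": cluster.population,
                    "distance_nm": dist,
                }
            )
            logger.info(
                "%s/%s: discarded cluster (central pose %d, %d members) at "
                "%.3f nm from site center (radius %.3f nm)",
                poses.ligand_id, poses.template_id, cluster.central,
                cluster.population, dist, radius,
            )
        else:
            retained.append(cluster)
    return retained, discards


POSE_RANKS = ("I", "II", "III")


def select_md_poses(
    poses: PoseSet,
    cutoff: float = 0.2,
    max_clusters: int = 5,
    max_selected: int = 3,
    use_site_filter: bool | None = None,
    superimpose: bool = False,
) -> tuple[list[SelectedPose], ClusterSet]:
    """Cluster, filter and pick ≤3 MD starting structures for one pose set.

    Runs nearest-neighbor clustering at ``cutoff`` (≤ ``max_clusters``
    clusters), applies the active-site filter when a site is defined (or
    explicitly requested), and returns the central structures of the most
    populated retained clusters tagged I/II/III. An empty selection is a
    warning, not an error.
    """
    if poses.n_poses == 1:
        sel = [SelectedPose("I", 0, 1, poses.coords[0].copy())]
        return sel, ClusterSet([Cluster([0], 0)], cutoff_used=cutoff)
    matrix = pose_rmsd_matrix(poses, superimpose=superimpose)
    clusters = nearest_neighbor_cluster(matrix, cutoff, max_clusters)
    if use_site_filter is None:
        use_site_filter = poses.site_center is not None and poses.site_radius is not None
    retained = clusters.clusters
    if use_site_filter:
        retained, _discards = active_site_filter(poses, clusters)
    if not retained:
        logger.warning(
            "%s/%s: no clusters retained after active-site filtering",
            poses.ligand_id, poses.template_id,
        )
        return [], clusters
    selected = [
        SelectedPose(
            rank=POSE_RANKS[i],
            pose_index=cluster.central,
            population=cluster.population,
            coords=poses.coords[cluster.central].copy(),
        )
        for i, cluster in enumerate(retained[:max_selected])
    ]
    return selected, clusters


# -- pose I/O ----------------------------------------------------------------

_ANGSTROM_PER_NM = 10.0


def read_poses_pdb(
    path: str | Path,
    ligand_id: str,
    template_id: str,
    heavy_only: bool = True,
    site_center: np.ndarray | None = None,
    site_radius: float | None = None,
) -> PoseSet:
    """Read docked poses from a multi-model PDB (MODEL/ENDMDL records).

    Coordinates are converted from Å to nm; hydrogens are dropped by
    default since docking protonation is unreliable.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if heavy_only:
        stack = stack[:, stack.element != "H"]
    template = stack[0]
    return PoseSet(
        ligand_id=ligand_id,
        template_id=template_id,
        coords=stack.coord / _ANGSTROM_PER_NM,
        site_center=site_center,
        site_radius=site_radius,
        atoms=template,
    )


def write_pose_pdb(poses: PoseSet, pose_index: int, path: str | Path) -> None:
    """Write one pose as a single-model PDB (requires a PDB-derived PoseSet)."""
    from biotite.structure.io.pdb import PDBFile

    if poses.atoms is None:
        raise ConfigError(
            "PoseSet has no atom template; only PDB-derived pose sets can be "
            "written back as PDB"
        )
    atoms = poses.atoms.copy()
    atoms.coord = poses.coords[pose_index] * _ANGSTROM_PER_NM
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_poses_csv(
    path: str | Path, ligand_id: str, template_id: str, **kwargs
) -> PoseSet:
    """Read poses from a flat CSV with columns ``pose_id,atom_index,x,y,z`` (nm)."""
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("pose_id", "atom_index", "x", "y", "z"):
        if col not in df.columns:
            raise ValidationError(f"{path}: pose CSV missing column {col!r}")
    coords = []
    for _pid, grp in df.groupby("pose_id", sort=True):
        grp = grp.sort_values("atom_index")
        coords.append(grp[["x", "y", "z"]].to_numpy(dtype=float))
    counts = {c.shape[0] for c in coords}
    if len(counts) > 1:
        raise ValidationError(f"{path}: poses differ in atom count: {sorted(counts)}")
    return PoseSet(
        ligand_id=ligand_id,
        template_id=template_id,
        coords=np.stack(coords),
        **kwargs,
    )
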