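"""Ensemble analyses: restraint satisfaction, modeled-matrix regeneration,
RMSD clustering and local spatial density."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from hic3d.errors import ValidationError
from hic3d.io import ContactMatrix, GenomeTrack
from hic3d.optimizer import Conformation
from hic3d.restraints import DecayCurve, RestraintSet, ScalingModel, distance_to_contact


@dataclass
class EnsembleSummary:
    n_models: int
    satisfaction_fraction: float
    ratio_hist_edges: np.ndarray  # histogram of simulated/target distance ratios
    ratio_hist_counts: np.ndarray

    def __post_init__(self):
        if not 0.0 <= self.satisfaction_fraction <= 1.0:
            raise ValidationError("satisfaction fraction outside [0, 1]")


@dataclass
class ClusterResult:
    rmsd_matrix: np.ndarray
    labels: np.ndarray
    representative: int


def satisfaction(ensemble, restraints: RestraintSet, lo: float = 0.5,
                 hi: float = 2.0, n_hist_bins: int = 50) -> EnsembleSummary:
    """Fraction of (model, pair) distances within ``[lo, hi] × target`` (inclusive)."""
    ensemble = list(ensemble)
    if not ensemble:
        raise ValidationError("empty ensemble")
    if restraints.n_restraints == 0:
        raise ValidationError("empty restraint set")
    n_ok = 0
    n_tot = 0
    ratios_all = []
    for conf in ensemble:
        d = conf.pairwise_distances(restraints.i, restraints.j)
        ratio = d / restraints.target
        n_ok += int(np.count_nonzero((ratio >= lo) & (ratio <= hi)))
        n_tot += len(ratio)
        ratios_all.append(ratio)
    ratios = np.concatenate(ratios_all)
    edges = np.geomspace(max(ratios.min(), 1e-3) / 2, ratios.max() * 2, n_hist_bins + 1)
    counts, edges = np.histogram(ratios, bins=edges)
    return EnsembleSummary(len(ensemble), n_ok / n_tot, edges, counts)


def inverse_map(ensemble, curve: DecayCurve, model: ScalingModel) -> ContactMatrix:
    """Modeled contact matrix: distances → contacts per model, averaged.

    Each pairwise distance is pushed through the inverse of the log-log
    contact/distance interpolation; entries are averaged across models. The
    diagonal is left at zero (it is never a restraint source).
    """
    ensemble = list(ensemble)
    if not ensemble:
        raise ValidationError("empty ensemble")
    bins = ensemble[0].bins
    n = bins.n_bins
    iu, ju = np.triu_indices(n, k=1)
    acc = np.zeros(len(iu))
    for conf in ensemble:
        d = conf.pairwise_distances(iu, ju)
        acc += distance_to_contact(np.maximum(d, 1e-12), curve, model)
    acc /= len(ensemble)
    C = np.zeros((n, n))
    C[iu, ju] = acc
    C[ju, iu] = acc
    return ContactMatrix(bins, C, validate=False)


def rmsd(a: Conformation, b: Conformation, allow_reflection: bool = False) -> float:
    """Minimal RMSD over translations and rotations (Kabsch superposition).

    With ``allow_reflection`` the minimum also runs over improper rotations,
    collapsing mirror-image pairs to zero.
    """
    if a.n_beads != b.n_beads:
        raise ValidationError("conformations have different bead counts")
    A = a.coords - a.coords.mean(axis=0)
    B = b.coords - b.coords.mean(axis=0)
    U, _, Vt = np.linalg.svd(A.T @ B)
    R = (U @ Vt).T
    if not allow_reflection and np.linalg.det(R) < 0:
        D = np.diag([1.0, 1.0, -1.0])
        R = (U @ D @ Vt).T
    residual = A @ R.T - B
    return float(np.sqrt((residual**2).sum(axis=1).mean()))


def rmsd_matrix(ensemble, allow_reflection: bool = True) -> np.ndarray:
    ensemble = list(ensemble)
    m = len(ensemble)
    M = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            M[i, j] = M[j, i] = rmsd(ensemble[i], ensemble[j], allow_reflection)
    return M


def cluster_ensemble(ensemble, n_clusters: int = 2,
                     allow_reflection: bool = True) -> ClusterResult:
    """Average-linkage clustering of the pairwise RMSD matrix.

    The representative is the member of the largest cluster with the lowest
    mean RMSD to its cluster mates.
    """
    ensemble = list(ensemble)
    m = len(ensemble)
    if m < 2:
        raise ValidationError("need at least 2 models to cluster")
    if n_clusters > m:
        raise ValidationError(f"n_clusters {n_clusters} > n_models {m}")
    M = rmsd_matrix(ensemble, allow_reflection)
    Z = linkage(squareform(M, checks=False), method="average")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    sizes = np.bincount(labels)
    biggest = int(np.argmax(sizes))
    members = np.nonzero(labels == biggest)[0]
    if len(members) == 1:
        rep = int(members[0])
    else:
        mean_rmsd = M[np.ix_(members, members)].sum(axis=1) / (len(members) - 1)
        rep = int(members[np.argmin(mean_rmsd)])
    return ClusterResult(M, labels, rep)


def local_density(conf: Conformation, radius_um: float) -> GenomeTrack:
    """Per-bead count of other beads within ``radius_um`` (Euclidean)."""
    if radius_um <= 0:
        raise ValidationError("radius must be positive")
    D = cdist(conf.coords, conf.coords)
    counts = (D <= radius_um).sum(axis=1) - 1  # exclude self
    return GenomeTrack(conf.bins, counts.astype(float), name="local_density")


def default_density_radius(restraints: RestraintSet, factor: float = 5.0) -> float:
    """Default probe radius: ``factor`` × mean bonded distance."""
    return factor * float(restraints.d_eq.mean())
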