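"""Ensemble-comparison statistics.

Everything needed to compare a generated or reconstructed ensemble with a
reference one: index-matched and one-against-all RMSD distributions,
pooled backbone dihedral distributions and their Jensen-Shannon
divergences (natural log), radius-of-gyration distributions, the MSE
between average CA distance maps, a joint PCA embedding of flattened
distance maps, and k-medoids clustering on the pairwise RMSD matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import jensenshannon
from sklearn.decomposition import PCA

from .ensemble import Ensemble
from .geometry import backbone_dihedrals, ca_distance_map, kabsch_rmsd, radius_of_gyration

__all__ = [
    "pairwise_rmsd",
    "one_against_all_rmsd",
    "js_divergence",
    "dihedral_distributions",
    "rg_values",
    "mean_distance_map",
    "mean_distance_map_mse",
    "pca_embed",
    "cluster_by_rmsd",
    "wrap_omega",
    "MetricsReport",
    "compare_ensembles",
]


def pairwise_rmsd(a: Ensemble, b: Ensemble) -> np.ndarray:
    """Kabsch RMSD of index-matched members (requires equal sizes, one sequence)."""
    if len(a) != len(b):
        raise ValueError("ensembles must have equal sizes for index-matched RMSD")
    if a.sequence != b.sequence:
        raise ValueError("ensembles must share one sequence")
    return np.array(
        [kabsch_rmsd(x.atoms(), y.atoms()) for x, y in zip(a, b)]
    )


def one_against_all_rmsd(
    ensemble: Ensemble, max_pairs: int | None = None, seed=None
) -> np.ndarray:
    """Flat list of each-vs-every-other RMSDs (both directions counted).

    When the number of unordered pairs exceeds ``max_pairs`` a seeded
    uniform subsample of pairs is used instead.
    """
    n = len(ensemble)
    if n < 2:
        raise ValueError("need at least 2 conformations")
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[p] for p in keep]
    atoms = [c.atoms() for c in ensemble]
    values = np.array([kabsch_rmsd(atoms[i], atoms[j]) for i, j in pairs])
    return np.concatenate([values, values])  # i->j and j->i


def js_divergence(samples_a, samples_b, bins: int = 50) -> float:
    """Jensen-Shannon divergence (nats) of two samples over a shared histogram.

    Histograms share the common min..max support with equal-width bins.
    Two identical constant samples have zero-width support and return 0 by
    convention.  The value is bounded by ln 2.
    """
    a = np.asarray(samples_a, dtype=np.float64).ravel()
    b = np.asarray(samples_b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    p, _ = np.histogram(a, bins=edges)
    q, _ = np.histogram(b, bins=edges)
    return float(jensenshannon(p, q, base=np.e) ** 2)


def wrap_omega(omega_degrees) -> np.ndarray:
    """Map omega torsions from (-180, 180] to (0, 360], centered on trans (180°).

    The trans peak sits at ±180°, which an unwrapped histogram splits into
    two edge bins; re-centering removes that artifact before binning.
    """
    return np.mod(np.asarray(omega_degrees, dtype=np.float64), 360.0)


def dihedral_distributions(ensemble: Ensemble) -> dict[str, np.ndarray]:
    """Pooled phi/psi/omega samples across all members, n*(L-1) values each."""
    pools = {"phi": [], "psi": [], "omega": []}
    for conf in ensemble:
        tables = backbone_dihedrals(conf)
        for key in pools:
            pools[key].append(tables[key])
    return {k: np.concatenate(v) for k, v in pools.items()}


def rg_values(ensemble: Ensemble) -> np.ndarray:
    """Radius of gyration of every member, Å."""
    return np.array([radius_of_gyration(c) for c in ensemble])


def mean_distance_map(ensemble: Ensemble) -> np.ndarray:
    """Average CA distance map over the ensemble, (L, L) Å."""
    return np.mean([ca_distance_map(c) for c in ensemble], axis=0)


def mean_distance_map_mse(a: Ensemble, b: Ensemble) -> float:
    """Mean squared difference of the two average distance maps, Å²."""
    if a.sequence != b.sequence:
        raise ValueError("ensembles must share one sequence")
    return float(np.mean((mean_distance_map(a) - mean_distance_map(b)) ** 2))


def _distance_features(ensemble: Ensemble) -> np.ndarray:
    """Strict upper triangle of each member's CA distance map, flattened."""
    L = ensemble.n_residues
    iu = np.triu_indices(L, k=1)
    return np.stack([ca_distance_map(c)[iu] for c in ensemble])


def pca_embed(
    ensembles: list[Ensemble], components: int = 2
) -> tuple[list[np.ndarray], np.ndarray]:
    """Joint PCA of flattened distance maps across all input ensembles.

    The PCA is fitted on the concatenation (centered, not scaled) so that
    every ensemble shares one set of axes; returns per-ensemble score
    arrays and the explained-variance fractions.
    """
    seq = ensembles[0].sequence
    if any(e.sequence != seq for e in ensembles):
        raise ValueError("all ensembles must share one sequence")
    features = [_distance_features(e) for e in ensembles]
    stacked = np.concatenate(features)
    if stacked.shape[0] < components:
        raise ValueError("fewer samples than requested components")
    pca = PCA(n_components=components)
    scores = pca.fit_transform(stacked)
    out, offset = [], 0
    for f in features:
        out.append(scores[offset:offset + f.shape[0]])
        offset += f.shape[0]
    return out, pca.explained_variance_ratio_


def cluster_by_rmsd(
    ensemble: Ensemble, n_clusters: int = 3, seed=None, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """K-medoids on the full pairwise Kabsch RMSD matrix.

    Seeded medoid initialization followed by Voronoi iteration (assign to
    the nearest medoid; re-pick each medoid as the member minimizing total
    within-cluster RMSD).  Clusters are reported by descending size;
    returns (assignments, medoid indices).
    """
    n = len(ensemble)
    if n < n_clusters:
        raise ValueError("ensemble smaller than the requested cluster count")
    atoms = [c.atoms() for c in ensemble]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = kabsch_rmsd(atoms[i], atoms[j])

    # k-medoids++ style seeding: subsequent medoids drawn proportional to the
    # squared distance from the nearest already-chosen medoid
    rng = np.random.default_rng(seed)
    medoids = [int(rng.integers(n))]
    while len(medoids) < n_clusters:
        d2 = dist[:, medoids].min(axis=1) ** 2
        total = d2.sum()
        if total == 0:
            remaining = [i for i in range(n) if i not in medoids]
            medoids.append(remaining[0])
            continue
        medoids.append(int(rng.choice(n, p=d2 / total)))
    medoids = np.array(medoids)
    for _ in range(max_iter):
        assign = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(n_clusters):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    assign = np.argmin(dist[:, medoids], axis=1)
    # report clusters by descending size (ties by original cluster index)
    sizes = np.bincount(assign, minlength=n_clusters)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(n_clusters, dtype=int)
    relabel[order] = np.arange(n_clusters)
    return relabel[assign], medoids[order]


@dataclass
class MetricsReport:
    """Bundle of the standard reference-vs-candidate comparison statistics."""

    pairwise_rmsd: np.ndarray | None
    one_against_all_rmsd: np.ndarray
    dihedrals_reference: dict
    dihedrals_candidate: dict
    js_values: dict
    rg_reference: np.ndarray
    rg_candidate: np.ndarray
    mean_distance_map_mse: float
    pca_coordinates: list
    pca_explained_variance: np.ndarray
    cluster_assignments: np.ndarray
    cluster_medoids: np.ndarray

    def summary(self) -> dict:
        """Scalar summary suitable for JSON serialization."""
        out = {
            "n_reference": len(self.rg_reference),
            "n_candidate": len(self.rg_candidate),
            "mean_distance_map_mse": self.mean_distance_map_mse,
            "rg_mean_reference": float(np.mean(self.rg_reference)),
            "rg_mean_candidate": float(np.mean(self.rg_candidate)),
            **{f"js_{k}": v for k, v in self.js_values.items()},
        }
        if self.pairwise_rmsd is not None:
            out["mean_pairwise_rmsd"] = float(np.mean(self.pairwise_rmsd))
        out["mean_one_against_all_rmsd"] = float(np.mean(self.one_against_all_rmsd))
        return out


def compare_ensembles(
    reference: Ensemble,
    candidate: Ensemble,
    *,
    bins: int = 50,
    n_clusters: int = 3,
    max_pairs: int | None = 20000,
    seed: int = 0,
) -> MetricsReport:
    """Compute the full comparison suite of ``candidate`` against ``reference``.

    Index-matched RMSD is included only when the two ensembles have equal
    sizes (i.e. the candidate is a reconstruction of the reference).
    """
    matched = pairwise_rmsd(reference, candidate) if len(reference) == len(candidate) else None
    dihed_ref = dihedral_distributions(reference)
    dihed_cand = dihedral_distributions(candidate)
    rg_ref = rg_values(reference)
    rg_cand = rg_values(candidate)
    js = {
        "phi": js_divergence(dihed_ref["phi"], dihed_cand["phi"], bins=bins),
        "psi": js_divergence(dihed_ref["psi"], dihed_cand["psi"], bins=bins),
        "omega": js_divergence(
            wrap_omega(dihed_ref["omega"]), wrap_omega(dihed_cand["omega"]), bins=bins
        ),
        "rg": js_divergence(rg_ref, rg_cand, bins=bins),
    }
    coords, evr = pca_embed([reference, candidate])
    n_clust = min(n_clusters, len(candidate))
    assignments, medoids = cluster_by_rmsd(candidate, n_clusters=n_clust, seed=seed)
    return MetricsReport(
        pairwise_rmsd=matched,
        one_against_all_rmsd=one_against_all_rmsd(candidate, max_pairs=max_pairs, seed=seed),
        dihedrals_reference=dihed_ref,
        dihedrals_candidate=dihed_cand,
        js_values=js,
        rg_reference=rg_ref,
        rg_candidate=rg_cand,
        mean_distance_map_mse=mean_distance_map_mse(reference, candidate),
        pca_coordinates=coords,
        pca_explained_variance=evr,
        cluster_assignments=assignments,
        cluster_medoids=medoids,
    )
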