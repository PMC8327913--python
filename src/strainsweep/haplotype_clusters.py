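"""Clustering SNVs into perfectly linked haplotypes from trajectory shape.

When SNV densities are too low for read clouds to connect sites, SNVs
riding on the same haplotype can still be recognized because their
frequency trajectories move together (up to a polarization flip).  For a
pair of SNVs i, j the dissimilarity

    d_ij(+/-) = (1/T) * sum_t 2 (D_i + D_j) (f_i - f_j(+/-))^2
                / [ (f_i + f_j(+/-)) (2 - f_i - f_j(+/-)) ]

compares the two trajectories under the two possible polarizations of j
(f_j(-) = 1 - f_j); under pure binomial noise with equal true
frequencies each timepoint's term has expectation about 2, so the
clustering threshold d* = 3.5 sits above the null mean.  UPGMA is run on
d_ij = min(d_ij+, d_ij-), flat clusters are cut at d*, member SNVs are
oriented along a minimum spanning tree, and the cluster trajectory is the
pooled (depth-summed) frequency of the oriented members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as hc_linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, minimum_spanning_tree

__all__ = [
    "DissimilarityPair",
    "ClusterTrajectory",
    "pairwise_dissimilarity",
    "dissimilarity_matrix",
    "cluster_snvs",
    "repolarize_cluster",
]

#: placeholder distance for pairs with no shared informative timepoints
_UNDEFINED_DISTANCE = 1e9


@dataclass
class DissimilarityPair:
    snv_i: int
    snv_j: int
    d_plus: float
    d_minus: float
    n_timepoints: int
    orientation: str  # 'same' | 'flipped'

    @property
    def d(self) -> float:
        return min(self.d_plus, self.d_minus)


def _dissimilarity_terms(fi, fj, Di, Dj) -> np.ndarray:
    num = 2.0 * (Di + Dj) * (fi - fj) ** 2
    den = (fi + fj) * (2.0 - fi - fj)
    out = np.zeros_like(num)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def pairwise_dissimilarity(f_i, f_j, D_i, D_j) -> DissimilarityPair:
    """Evaluate d_ij+ and d_ij- over the shared non-missing timepoints.

    Missing observations (NaN frequency at either SNV) are excluded from
    both the sum and T; a pair with no shared timepoints is undefined and
    raises ``ValueError``.
    """
    fi = np.asarray(f_i, dtype=float)
    fj = np.asarray(f_j, dtype=float)
    Di = np.asarray(D_i, dtype=float)
    Dj = np.asarray(D_j, dtype=float)
    shared = ~(np.isnan(fi) | np.isnan(fj))
    T = int(shared.sum())
    if T == 0:
        raise ValueError("no shared timepoints; pair dissimilarity undefined")
    fi, Di, Dj = fi[shared], Di[shared], Dj[shared]
    fj = fj[shared]
    d_plus = float(_dissimilarity_terms(fi, fj, Di, Dj).sum() / T)
    d_minus = float(_dissimilarity_terms(fi, 1.0 - fj, Di, Dj).sum() / T)
    return DissimilarityPair(
        snv_i=-1, snv_j=-1, d_plus=d_plus, d_minus=d_minus, n_timepoints=T,
        orientation="same" if d_plus <= d_minus else "flipped",
    )


def dissimilarity_matrix(freqs: pd.DataFrame, depths: pd.DataFrame):
    """All-pairs d+ and d- matrices (NaN-aware, vectorized).

    Returns (d_plus, d_minus, n_shared) as dense (n x n) arrays.
    """
    f = freqs.to_numpy(dtype=float)
    D = depths.to_numpy(dtype=float)
    n, T = f.shape
    obs = ~np.isnan(f)
    f0 = np.nan_to_num(f)

    d_plus = np.zeros((n, n))
    d_minus = np.zeros((n, n))
    for variant, target in ((f0, d_plus), (1.0 - f0, d_minus)):
        for i in range(n):
            fi, Di = f0[i], D[i]
            shared = obs[i][None, :] & obs
            terms = _dissimilarity_terms(
                np.broadcast_to(fi, variant.shape), variant,
                np.broadcast_to(Di, variant.shape), D,
            )
            terms = np.where(shared, terms, 0.0)
            target[i] = terms.sum(axis=1)
    n_shared = (obs.astype(int) @ obs.astype(int).T).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_plus = np.where(n_shared > 0, d_plus / n_shared, _UNDEFINED_DISTANCE)
        d_minus = np.where(n_shared > 0, d_minus / n_shared, _UNDEFINED_DISTANCE)
    np.fill_diagonal(d_plus, 0.0)
    np.fill_diagonal(d_minus, _UNDEFINED_DISTANCE)
    return d_plus, d_minus, n_shared


@dataclass
class ClusterTrajectory:
    """A set of co-clustered, consistently polarized SNVs with a pooled
    average frequency trajectory."""

    members: list
    flipped: dict = field(default_factory=dict)   # snv_id -> bool
    A: pd.Series | None = None                    # pooled oriented alt counts
    D: pd.Series | None = None
    frequency: pd.Series | None = None
    orientation_conflicts: int = 0


def cluster_snvs(
    freqs: pd.DataFrame,
    depths: pd.DataFrame,
    d_star: float = 3.5,
    positions: pd.Series | None = None,
    counts_A: pd.DataFrame | None = None,
) -> list[ClusterTrajectory]:
    """UPGMA clustering of SNVs on d_ij = min(d_ij+, d_ij-), cut at d*.

    ``freqs``/``depths`` are SNV x timepoint; frequencies are NaN where
    the depth filter failed.  Singleton SNVs form singleton clusters.
    When ``counts_A`` (alt counts) is given, pooled cluster counts and the
    average frequency trajectory are computed via
    :func:`repolarize_cluster`.
    """
    ids = list(freqs.index)
    if len(ids) == 0:
        return []
    if len(ids) == 1:
        labels = np.array([1])
        d_plus = d_minus = np.zeros((1, 1))
    else:
        d_plus, d_minus, _ = dissimilarity_matrix(freqs, depths)
        d = np.minimum(d_plus, d_minus)
        d = np.minimum(d, d.T)  # enforce exact symmetry
        iu = np.triu_indices(len(ids), k=1)
        Z = hc_linkage(d[iu], method="average")
        labels = fcluster(Z, t=d_star, criterion="distance")

    clusters = []
    for lab in np.unique(labels):
        members = [ids[i] for i in np.flatnonzero(labels == lab)]
        clusters.append(
            repolarize_cluster(
                members, freqs, depths,
                d_plus=pd.DataFrame(d_plus, index=ids, columns=ids),
                d_minus=pd.DataFrame(d_minus, index=ids, columns=ids),
                positions=positions, counts_A=counts_A,
            )
        )
    clusters.sort(key=lambda c: (-len(c.members), str(c.members[0])))
    return clusters


def repolarize_cluster(
    members: list,
    freqs: pd.DataFrame,
    depths: pd.DataFrame,
    d_plus: pd.DataFrame,
    d_minus: pd.DataFrame,
    positions: pd.Series | None = None,
    counts_A: pd.DataFrame | None = None,
) -> ClusterTrajectory:
    """Orient a cluster's members and pool their counts.

    Orientations are propagated from an anchor SNV (lowest genomic
    coordinate, falling back on table order) along the minimum spanning
    tree of the d matrix: an edge with d- < d+ flips the orientation
    across it; exact ties keep the anchor's orientation and are logged as
    conflicts.  After orientation, pooled counts A^c_t and D^c_t are the
    sums of oriented alternate counts and depths, and the cluster is
    globally polarized so its first non-missing frequency is <= 0.5.
    """
    if len(members) == 0:
        raise ValueError("empty cluster")
    sub_plus = d_plus.loc[members, members].to_numpy()
    sub_minus = d_minus.loc[members, members].to_numpy()
    d = np.minimum(sub_plus, sub_minus)

    if positions is not None:
        anchor = int(np.argmin([positions.get(m, np.inf) for m in members]))
    else:
        anchor = 0

    flipped = {m: False for m in members}
    conflicts = 0
    if len(members) > 1:
        # strictly positive weights so the MST keeps zero-distance edges
        mst = minimum_spanning_tree(csr_matrix(d + 1e-12))
        adj = (mst + mst.T).tocsr()
        order, predecessors = breadth_first_order(adj, anchor, directed=False)
        for node in order:
            pred = predecessors[node]
            if pred < 0:
                continue
            dp, dm = sub_plus[pred, node], sub_minus[pred, node]
            if dm < dp:
                rel_flip = True
            elif dp < dm:
                rel_flip = False
            else:
                rel_flip = False
                conflicts += 1
            flipped[members[node]] = flipped[members[pred]] ^ rel_flip

    if counts_A is not None:
        A = counts_A.loc[members].to_numpy(dtype=float)
        D = depths.loc[members].to_numpy(dtype=float)
        miss = np.isnan(freqs.loc[members].to_numpy(dtype=float))
        flip_vec = np.array([flipped[m] for m in members])[:, None]
        A_or = np.where(flip_vec, D - A, A)
        A_or = np.where(miss, 0.0, A_or)
        D_eff = np.where(miss, 0.0, D)
        Ac = A_or.sum(axis=0)
        Dc = D_eff.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            fc = np.where(Dc > 0, Ac / Dc, np.nan)
        first = np.flatnonzero(Dc > 0)
        if len(first) and fc[first[0]] > 0.5:
            flipped = {m: not v for m, v in flipped.items()}
            Ac = Dc - Ac
            fc = np.where(Dc > 0, 1.0 - fc, np.nan)
        cols = freqs.columns
        return ClusterTrajectory(
            members=members, flipped=flipped,
            A=pd.Series(Ac, index=cols), D=pd.Series(Dc, index=cols),
            frequency=pd.Series(fc, index=cols),
            orientation_conflicts=conflicts,
        )
    return ClusterTrajectory(members=members, flipped=flipped,
                             orientation_conflicts=conflicts)
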