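"""Genetic linkage between SNV pairs from read-cloud sharing.

Two SNVs on the same DNA fragment end up in the same read cloud, but so
do SNVs from unrelated fragments that happen to share a droplet
("impurity").  Sharing is therefore tested against the impurity null
model (see :mod:`strainsweep.read_clouds`): the chance that sites i and j
co-occur in cloud mu is p_i p_j F(D_mu).  Pairs with significantly
elevated sharing are then classified by the four-gamete logic: each of
the four allelic combinations is tested against its own impurity
expectation, and the number of significant cells maps to a two-, three-
or four-haplotype call.  Three or fewer haplotypes are consistent with
clonal descent; all four indicate a possible recombination event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import poisson
from statsmodels.stats.multitest import multipletests

from .read_clouds import ImpurityModel, ReadCloudSet

__all__ = [
    "SharingTable",
    "LdCall",
    "shared_cloud_counts",
    "test_pair_sharing",
    "classify_ld",
    "classify_pairs",
    "sharing_by_distance",
    "poisson_binomial_tail",
    "LD_DISTANCE_BINS",
]

#: conventional coordinate-distance categories for LD summaries (bp)
LD_DISTANCE_BINS = (0.0, 200.0, 2000.0, np.inf)

_CELLS = [("ref", "ref"), ("ref", "alt"), ("alt", "ref"), ("alt", "alt")]


@dataclass
class SharingTable:
    """Shared-read-cloud counts for one SNV pair.

    ``cells`` is a 2x2 array indexed [allele_i][allele_j] with 0=ref,
    1=alt, counting clouds by their majority allele at each site (clouds
    tied at either site are dropped from the cells but still counted in
    ``total_shared``).  ``rate_i``/``rate_j`` are per-cloud detection
    rates of each site, and ``allele_rates_*`` the same split by allele —
    the inputs of the impurity null.
    """

    snv_i: int
    snv_j: int
    distance: float | None
    total_shared: int
    cells: np.ndarray
    rate_i: float = 0.0
    rate_j: float = 0.0
    allele_rates_i: np.ndarray = field(default_factory=lambda: np.zeros(2))
    allele_rates_j: np.ndarray = field(default_factory=lambda: np.zeros(2))


@dataclass
class LdCall:
    snv_i: int
    snv_j: int
    distance: float | None
    sharing_p: float
    sharing_p_bonferroni: float
    cell_p: np.ndarray
    n_significant_cells: int
    category: str
    four_haplotype_p: float
    q_value: float = np.nan


def _site_cloud_alleles(cloud_set: ReadCloudSet, snv_id: int) -> pd.Series:
    """Majority allele per cloud at one site ('ref', 'alt', or 'tie')."""
    codes, _ = cloud_set.cloud_index()
    mask = cloud_set.reads["snv_id"].to_numpy() == snv_id
    sub = pd.DataFrame(
        {"cloud": codes[mask], "alt": (cloud_set.reads["allele"].to_numpy()[mask] == "alt")}
    )
    g = sub.groupby("cloud")["alt"]
    n_alt = g.sum()
    n_tot = g.size()
    out = pd.Series("tie", index=n_alt.index, dtype=object)
    out[n_alt * 2 > n_tot] = "alt"
    out[n_alt * 2 < n_tot] = "ref"
    return out


def shared_cloud_counts(snv_i: int, snv_j: int, cloud_set: ReadCloudSet,
                        panel: pd.DataFrame) -> SharingTable:
    """Count clouds covering both SNVs and tabulate allele combinations.

    A cloud contributes to the cell given by its majority allele at each
    site; clouds tied at either site are dropped from the cells.  The
    coordinate distance is defined only when the SNVs share a contig
    (``None`` otherwise — the pair is still countable).
    """
    ai = _site_cloud_alleles(cloud_set, snv_i)
    aj = _site_cloud_alleles(cloud_set, snv_j)
    shared = ai.index.intersection(aj.index)
    cells = np.zeros((2, 2), dtype=int)
    for cloud in shared:
        x, y = ai[cloud], aj[cloud]
        if x == "tie" or y == "tie":
            continue
        cells[int(x == "alt"), int(y == "alt")] += 1

    ri, rj = panel.loc[snv_i], panel.loc[snv_j]
    if ri["contig"] == rj["contig"] and ri["species"] == rj["species"]:
        distance = float(abs(int(ri["pos"]) - int(rj["pos"])))
    else:
        distance = None

    n = cloud_set.n_clouds
    return SharingTable(
        snv_i=snv_i,
        snv_j=snv_j,
        distance=distance,
        total_shared=int(len(shared)),
        cells=cells,
        rate_i=len(ai) / n,
        rate_j=len(aj) / n,
        allele_rates_i=np.array([(ai == "ref").sum(), (ai == "alt").sum()]) / n,
        allele_rates_j=np.array([(aj == "ref").sum(), (aj == "alt").sum()]) / n,
    )


def poisson_binomial_tail(probs, observed: int, exact_max: int = 20) -> float:
    """Upper tail P(X >= observed) for X a sum of independent Bernoullis.

    Exact by dynamic programming when at most ``exact_max`` probabilities
    are given; otherwise a Poisson approximation with lambda = sum(probs),
    which is accurate for many small per-cloud probabilities.
    """
    probs = np.asarray(probs, dtype=float)
    if observed <= 0:
        return 1.0
    if len(probs) <= exact_max:
        dist = np.zeros(len(probs) + 1)
        dist[0] = 1.0
        for p in probs:
            dist[1:] = dist[1:] * (1 - p) + dist[:-1] * p
            dist[0] *= 1 - p
        return float(min(1.0, dist[min(observed, len(probs)):].sum()))
    return float(poisson.sf(observed - 1, probs.sum()))


def test_pair_sharing(table: SharingTable, model: ImpurityModel) -> float:
    """P-value for the pair's total shared-cloud count under impurity."""
    if model.sum_F <= 0 and model.n_clouds == 0:
        raise ValueError("impurity model is not fitted")
    if model.cloud_D is not None and model.n_clouds <= 20:
        probs = model.per_cloud_probabilities(table.rate_i, table.rate_j)
        return poisson_binomial_tail(probs, table.total_shared)
    lam = model.expected_sharing(table.rate_i, table.rate_j)
    if table.total_shared == 0:
        return 1.0
    return float(poisson.sf(table.total_shared - 1, lam))


def classify_ld(table: SharingTable, model: ImpurityModel, alpha: float = 0.05) -> LdCall:
    """Four-gamete classification of one screened SNV pair.

    Each allele-combination cell is tested against its impurity
    expectation (Poisson upper tail at the cell's expected count); the
    number of significant cells maps to the two/three/four-haplotype
    categories.  The four-haplotype p-value is the largest of the four
    cell p-values (all four cells must be elevated).
    """
    cell_p = np.ones((2, 2))
    for a in (0, 1):
        for b in (0, 1):
            lam = model.expected_sharing(table.allele_rates_i[a], table.allele_rates_j[b])
            obs = int(table.cells[a, b])
            cell_p[a, b] = 1.0 if obs == 0 else float(poisson.sf(obs - 1, lam))
    n_sig = int((cell_p < alpha).sum())
    category = {4: "four_haplotypes", 3: "three_haplotypes"}.get(n_sig, "two_haplotypes")
    return LdCall(
        snv_i=table.snv_i,
        snv_j=table.snv_j,
        distance=table.distance,
        sharing_p=np.nan,
        sharing_p_bonferroni=np.nan,
        cell_p=cell_p,
        n_significant_cells=n_sig,
        category=category,
        four_haplotype_p=float(cell_p.max()),
    )


def _site_incidence(cloud_set: ReadCloudSet, snv_ids: np.ndarray):
    """Sparse cloud incidence by majority allele for a set of sites.

    Returns (M_any, M_ref, M_alt): boolean CSR matrices of shape
    (n_sites, n_clouds).
    """
    codes, n_clouds = cloud_set.cloud_index()
    reads = cloud_set.reads
    mask = reads["snv_id"].isin(snv_ids).to_numpy()
    site_index = pd.Index(snv_ids)
    rows = site_index.get_indexer(reads["snv_id"].to_numpy()[mask])
    cols = codes[mask]
    is_alt = (reads["allele"].to_numpy()[mask] == "alt").astype(int)

    shape = (len(snv_ids), n_clouds)
    n_alt = sparse.coo_matrix((is_alt, (rows, cols)), shape=shape).tocsr()
    n_tot = sparse.coo_matrix((np.ones_like(is_alt), (rows, cols)), shape=shape).tocsr()
    any_ = (n_tot > 0).astype(np.int64)
    # majority calls: alt iff 2*n_alt > n_tot, ref iff 2*n_alt < n_tot
    diff = (2 * n_alt - n_tot).tocsr()
    alt = (diff > 0).astype(np.int64)
    ref = (diff < 0).astype(np.int64)
    return any_, ref, alt


def classify_pairs(
    panel: pd.DataFrame,
    cloud_set: ReadCloudSet,
    model: ImpurityModel,
    min_shared: int = 12,
    screen_alpha: float = 0.1,
    alpha: float = 0.05,
    maf_min: float = 0.1,
) -> pd.DataFrame:
    """Screen and classify all same-species SNV pairs of a panel.

    Pipeline: (1) keep SNVs whose minor-allele frequency among read
    clouds exceeds ``maf_min``; (2) keep pairs with at least
    ``min_shared`` shared clouds across all timepoints; (3) screen with
    the impurity sharing test at Bonferroni-corrected p < ``screen_alpha``;
    (4) classify surviving pairs by the four-gamete cell tests and attach
    Benjamini-Hochberg q-values to the four-haplotype calls.
    """
    snv_ids = panel.index.to_numpy()
    m_any, m_ref, m_alt = _site_incidence(cloud_set, snv_ids)
    n = cloud_set.n_clouds
    site_clouds = np.asarray(m_any.sum(axis=1)).ravel()
    ref_clouds = np.asarray(m_ref.sum(axis=1)).ravel()
    alt_clouds = np.asarray(m_alt.sum(axis=1)).ravel()

    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt_clouds / np.maximum(ref_clouds + alt_clouds, 1)
    keep = (np.minimum(freq, 1 - freq) > maf_min) & (site_clouds > 0)

    shared = (m_any @ m_any.T).toarray()
    species = panel["species"].to_numpy()
    same_sp = species[:, None] == species[None, :]
    iu, ju = np.triu_indices(len(snv_ids), k=1)
    ok = keep[iu] & keep[ju] & same_sp[iu, ju] & (shared[iu, ju] >= min_shared)
    iu, ju = iu[ok], ju[ok]
    if len(iu) == 0:
        return pd.DataFrame(
            columns=["snv_i", "snv_j", "distance", "total_shared", "sharing_p",
                     "sharing_p_bonferroni", "category", "four_haplotype_p", "q_value"]
        )

    n_pairs = len(iu)
    lam = site_clouds[iu] / n * site_clouds[ju] / n * model.sum_F
    sharing_p = poisson.sf(shared[iu, ju] - 1, lam)
    p_bonf = np.minimum(sharing_p * n_pairs, 1.0)
    screened = p_bonf < screen_alpha

    cell_counts = {}
    for a, mi in (("ref", m_ref), ("alt", m_alt)):
        for b, mj in (("ref", m_ref), ("alt", m_alt)):
            cell_counts[(a, b)] = (mi @ mj.T).toarray()[iu, ju]
    rates = {"ref": ref_clouds / n, "alt": alt_clouds / n}

    cell_ps = np.ones((n_pairs, 4))
    for k, (a, b) in enumerate(_CELLS):
        lam_cell = rates[a][iu] * rates[b][ju] * model.sum_F
        obs = cell_counts[(a, b)]
        pk = poisson.sf(obs - 1, lam_cell)
        pk[obs == 0] = 1.0
        cell_ps[:, k] = pk

    n_sig = (cell_ps < alpha).sum(axis=1)
    category = np.where(n_sig >= 4, "four_haplotypes",
                        np.where(n_sig == 3, "three_haplotypes", "two_haplotypes"))
    four_p = cell_ps.max(axis=1)

    pos = panel["pos"].to_numpy()
    contig = panel["contig"].to_numpy()
    dist = np.where(contig[iu] == contig[ju], np.abs(pos[iu] - pos[ju]).astype(float), np.nan)

    out = pd.DataFrame(
        {
            "snv_i": snv_ids[iu],
            "snv_j": snv_ids[ju],
            "distance": dist,
            "total_shared": shared[iu, ju],
            "sharing_p": sharing_p,
            "sharing_p_bonferroni": p_bonf,
            "category": np.where(screened, category, "not_classified"),
            "four_haplotype_p": np.where(screened, four_p, np.nan),
            "q_value": np.nan,
        }
    )
    if screened.any():
        _, q, _, _ = multipletests(four_p[screened], method="fdr_bh")
        out.loc[screened, "q_value"] = q
    return out


def sharing_by_distance(
    panel: pd.DataFrame,
    cloud_set: ReadCloudSet,
    bins=None,
) -> pd.DataFrame:
    """Fraction of same-contig SNV pairs sharing at least one cloud, by
    coordinate distance bin.

    ``bins`` defaults to log-spaced edges; pass
    :data:`LD_DISTANCE_BINS` for the <200 bp / 200 bp-2 kb / >2 kb
    categories.  A single-SNV input yields an empty table.
    """
    snv_ids = panel.index.to_numpy()
    if len(snv_ids) < 2:
        return pd.DataFrame(columns=["bin_low", "bin_high", "n_pairs", "fraction_sharing"])
    m_any, _, _ = _site_incidence(cloud_set, snv_ids)
    shared = (m_any @ m_any.T).toarray()
    iu, ju = np.triu_indices(len(snv_ids), k=1)
    contig = panel["contig"].to_numpy()
    species = panel["species"].to_numpy()
    ok = (contig[iu] == contig[ju]) & (species[iu] == species[ju])
    iu, ju = iu[ok], ju[ok]
    pos = panel["pos"].to_numpy()
    dist = np.abs(pos[iu] - pos[ju]).astype(float)
    has_sharing = shared[iu, ju] > 0

    if bins is None:
        lo = max(dist.min(), 1.0)
        bins = np.geomspace(lo, dist.max() + 1, 9)
        bins = np.concatenate([[0.0], bins[1:]])
    bins = np.asarray(bins, dtype=float)
    idx = np.clip(np.digitize(dist, bins) - 1, 0, len(bins) - 2)
    rows = []
    for b in range(len(bins) - 1):
        mask = idx == b
        if not mask.any():
            continue
        rows.append(
            {
                "bin_low": bins[b],
                "bin_high": bins[b + 1],
                "n_pairs": int(mask.sum()),
                "fraction_sharing": float(has_sharing[mask].mean()),
            }
        )
    return pd.DataFrame(rows)
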