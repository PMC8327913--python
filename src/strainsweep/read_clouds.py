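"""Read-cloud ingestion and the read-cloud impurity null model.

A "read cloud" is the set of reads sharing one droplet barcode in a
linked-read library.  In complex metagenomes a single droplet typically
captures fragments from several species, so read-cloud co-occurrence of
two loci is only weak evidence of physical linkage.  This module provides

* barcode error correction (merging barcodes one edit away from a larger
  cloud),
* the per-cloud effective species number S_mu (root of detected richness
  times inverse Simpson index),
* the cloud-size spectrum used to visualize impurity, and
* an empirical impurity null model: the chance that two sites i, j
  co-occur in cloud mu is modelled as P_{i,j,mu} = p_i p_j F(D_mu), where
  p are per-cloud detection rates and F is a tabulated, non-decreasing
  function of the cloud's read count, fitted from between-species
  co-occurrence (assumed to be dominated by impurity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReadCloudSet",
    "ImpurityModel",
    "UndefinedStatisticError",
    "correct_barcodes",
    "effective_species_number",
    "cloud_size_spectrum",
    "fit_impurity_model",
]


class UndefinedStatisticError(ValueError):
    """A statistic is undefined on the given input (e.g. no species-assigned reads)."""


_READ_COLUMNS = ["timepoint", "barcode", "species", "contig", "pos", "allele"]
_OPTIONAL_COLUMNS = {"snv_id": -1, "gene": "", "fragment": -1}


class ReadCloudSet:
    """Barcode-keyed collection of mapped read records across timepoints.

    Backed by a single DataFrame with one row per read: ``timepoint,
    barcode, species, contig, pos, allele`` plus optional ``snv_id, gene,
    fragment`` columns.  A cloud is identified by (timepoint, barcode);
    its size D_mu is the number of read records it contains.
    """

    def __init__(self, reads: pd.DataFrame):
        missing = [c for c in _READ_COLUMNS if c not in reads.columns]
        if missing:
            raise ValueError(f"read table is missing columns: {missing}")
        reads = reads.copy()
        for col, default in _OPTIONAL_COLUMNS.items():
            if col not in reads.columns:
                reads[col] = default
        if len(reads) and (reads["pos"] < 0).any():
            raise ValueError("positions must be non-negative")
        reads["snv_id"] = reads["snv_id"].fillna(-1).astype(int)
        reads["allele"] = reads["allele"].fillna("")
        self.reads = reads.reset_index(drop=True)
        self._cloud_codes: np.ndarray | None = None
        self._n_clouds: int | None = None

    def __len__(self) -> int:
        return len(self.reads)

    def cloud_index(self) -> tuple[np.ndarray, int]:
        """Integer cloud id per read row, and the number of clouds."""
        if self._cloud_codes is None:
            key = self.reads["timepoint"].astype(str) + "\t" + self.reads["barcode"].astype(str)
            codes, uniq = pd.factorize(key, sort=True)
            self._cloud_codes = codes
            self._n_clouds = len(uniq)
        return self._cloud_codes, self._n_clouds

    @property
    def n_clouds(self) -> int:
        return self.cloud_index()[1]

    def cloud_sizes(self) -> np.ndarray:
        """Read count D_mu per cloud (indexed by the integer cloud id)."""
        codes, n = self.cloud_index()
        return np.bincount(codes, minlength=n)

    def species_per_cloud(self) -> pd.DataFrame:
        """Unique (cloud, species) detections with read counts."""
        codes, _ = self.cloud_index()
        df = pd.DataFrame({"cloud": codes, "species": self.reads["species"].to_numpy()})
        return df.groupby(["cloud", "species"], sort=True).size().rename("n_reads").reset_index()

    # ---- I/O -----------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.reads.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReadCloudSet":
        return cls(pd.read_csv(path, sep="\t", dtype={"barcode": str, "allele": str},
                               keep_default_na=False, na_values=[]))

    @classmethod
    def from_sam(cls, path, barcode_tag: str = "BX", timepoint: float = 0.0,
                 species_sep: str = "|") -> "ReadCloudSet":
        """Read barcoded alignments from a SAM/BAM file.

        The species is taken from the reference name prefix up to
        ``species_sep`` (the full reference name if absent); allele calls
        are not available from alignments alone and are left empty.
        """
        import pysam

        rows = []
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or not rec.has_tag(barcode_tag):
                    continue
                ref = rec.reference_name or ""
                species, _, contig = ref.partition(species_sep)
                rows.append(
                    (timepoint, rec.get_tag(barcode_tag), species, contig or ref,
                     rec.reference_start + 1, "")
                )
        return cls(pd.DataFrame(rows, columns=_READ_COLUMNS))


# ---------------------------------------------------------------------------
# barcode error correction
# ---------------------------------------------------------------------------

def _deletion_signatures(barcode: str):
    yield barcode
    for i in range(len(barcode)):
        yield barcode[:i] + barcode[i + 1 :]


def _within_edit_one(a: str, b: str) -> bool:
    import edlib

    return edlib.align(a, b, task="distance", k=1)["editDistance"] != -1


def correct_barcodes(raw_records: pd.DataFrame) -> ReadCloudSet:
    """Merge barcodes within edit distance 1 of a larger cloud's barcode.

    Barcodes are processed in order of decreasing read count (ties broken
    lexicographically); each barcode may merge into the largest already
    accepted cloud within one edit (substitution, insertion or deletion),
    so merges never chain.  An empty input yields an empty set.
    """
    if len(raw_records) == 0:
        return ReadCloudSet(pd.DataFrame(columns=_READ_COLUMNS))

    pieces = []
    for tp, sub in raw_records.groupby("timepoint", sort=True):
        counts = sub["barcode"].value_counts()
        order = sorted(counts.index, key=lambda b: (-counts[b], b))
        sig_map: dict[str, list[str]] = {}
        target: dict[str, str] = {}
        for bc in order:
            candidates = set()
            for sig in _deletion_signatures(bc):
                candidates.update(sig_map.get(sig, ()))
            best = None
            for cand in candidates:
                if counts[cand] <= counts[bc]:
                    continue
                if not _within_edit_one(bc, cand):
                    continue
                if best is None or (counts[cand], ) > (counts[best], ) or (
                    counts[cand] == counts[best] and cand < best
                ):
                    best = cand
            if best is not None:
                target[bc] = best
            else:
                target[bc] = bc
                for sig in _deletion_signatures(bc):
                    sig_map.setdefault(sig, []).append(bc)
        sub = sub.copy()
        sub["barcode"] = sub["barcode"].map(target)
        pieces.append(sub)
    return ReadCloudSet(pd.concat(pieces, ignore_index=True))


# ---------------------------------------------------------------------------
# per-cloud composition statistics
# ---------------------------------------------------------------------------

def effective_species_number(counts, root: bool = True) -> float:
    """Effective number of species detected in one read cloud.

    ``counts`` are per-species read counts r_{mu,s}.  The statistic is
    sqrt( k / sum_s (r_s / R)^2 ) with k the number of species having at
    least one read — the geometric mean of detected richness and the
    inverse Simpson index — so a uniform k-species cloud scores exactly k.
    ``root=False`` returns the un-rooted ratio for sensitivity checks.
    """
    r = np.asarray(counts, dtype=float)
    r = r[r > 0]
    if r.size == 0:
        raise UndefinedStatisticError("cloud has no species-assigned reads")
    p = r / r.sum()
    ratio = len(r) / np.sum(p**2)
    return float(np.sqrt(ratio)) if root else float(ratio)


def _log_bins(values: np.ndarray, min_per_bin: int, max_bins: int = 15) -> np.ndarray:
    """Logarithmic bin edges over positive ints, greedily merged so every
    bin holds at least ``min_per_bin`` values."""
    lo, hi = values.min(), values.max()
    if lo == hi:
        return np.array([lo, hi + 1])
    edges = np.unique(np.geomspace(lo, hi + 1, max_bins + 1).round().astype(int))
    counts, _ = np.histogram(values, bins=edges)
    keep = [edges[0]]
    acc = 0
    for c, e in zip(counts, edges[1:]):
        acc += c
        if acc >= min_per_bin:
            keep.append(e)
            acc = 0
    if keep[-1] != edges[-1]:
        if len(keep) > 1:
            keep[-1] = edges[-1]
        else:
            keep.append(edges[-1])
    return np.asarray(keep)


def cloud_size_spectrum(cloud_set: ReadCloudSet, min_per_bin: int = 50) -> pd.DataFrame:
    """Binned cloud-size summary: total read pairs and median S_mu per bin.

    Clouds are binned by their total read count; empty bins are omitted.
    """
    if len(cloud_set) == 0:
        raise ValueError("empty read cloud set")
    D = cloud_set.cloud_sizes()
    spc = cloud_set.species_per_cloud()
    grouped = spc.groupby("cloud")["n_reads"]
    k = grouped.size().reindex(np.arange(len(D)), fill_value=0).to_numpy()
    sumsq = spc.assign(sq=spc["n_reads"].astype(float) ** 2).groupby("cloud")["sq"].sum()
    sumsq = sumsq.reindex(np.arange(len(D)), fill_value=0.0).to_numpy()
    tot = grouped.sum().reindex(np.arange(len(D)), fill_value=0).to_numpy().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        s_mu = np.sqrt(k / (sumsq / tot**2))

    edges = _log_bins(D, min_per_bin)
    idx = np.clip(np.digitize(D, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        rows.append(
            {
                "bin_low": int(edges[b]),
                "bin_high": int(edges[b + 1]),
                "n_clouds": int(mask.sum()),
                "total_read_pairs": int(D[mask].sum()),
                "median_s": float(np.median(s_mu[mask])),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# impurity null model
# ---------------------------------------------------------------------------

def _pava_nondecreasing(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators: closest non-decreasing sequence."""
    y = y.astype(float).copy()
    w = w.astype(float).copy()
    blocks = [[i] for i in range(len(y))]
    vals = list(y)
    wts = list(w)
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1] + 1e-15:
            tot = wts[i] + wts[i + 1]
            vals[i] = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / tot
            wts[i] = tot
            blocks[i].extend(blocks[i + 1])
            del vals[i + 1], wts[i + 1], blocks[i + 1]
            if i > 0:
                i -= 1
        else:
            i += 1
    out = np.empty_like(y)
    for val, idxs in zip(vals, blocks):
        out[idxs] = val
    return out


@dataclass
class ImpurityModel:
    """Fitted read-cloud impurity null model.

    ``species_weights`` holds the per-timepoint read-share simplex p_s;
    ``detection_rates`` the pooled per-cloud detection rate of each
    species (fraction of clouds containing at least one of its reads).
    ``F`` is tabulated on cloud-size bins and non-decreasing; the null
    co-occurrence probability for two features with per-cloud detection
    rates c_i, c_j in a cloud of size D is c_i * c_j * F(D).
    """

    species_weights: pd.DataFrame
    detection_rates: pd.Series
    bin_centers: np.ndarray
    bin_F: np.ndarray
    n_clouds: int
    cloud_D: np.ndarray | None = None
    sum_F: float = 0.0

    def F(self, D) -> np.ndarray:
        """Interpolated F(D): linear between bin centers in log D,
        constant beyond the outermost bins."""
        logd = np.log(np.maximum(np.asarray(D, dtype=float), 1.0))
        return np.interp(logd, np.log(self.bin_centers), self.bin_F)

    def expected_sharing(self, rate_i: float, rate_j: float) -> float:
        """Expected chance co-occurrence count over all clouds."""
        return float(rate_i * rate_j * self.sum_F)

    def per_cloud_probabilities(self, rate_i: float, rate_j: float) -> np.ndarray:
        if self.cloud_D is None:
            raise ValueError("per-cloud sizes not retained in this model")
        return np.clip(rate_i * rate_j * self.F(self.cloud_D), 0.0, 1.0)

    # ---- serialization --------------------------------------------------
    def to_json(self, path) -> None:
        obj = {
            "species_weights": {
                str(tp): {s: float(v) for s, v in row.items()}
                for tp, row in self.species_weights.iterrows()
            },
            "detection_rates": {s: float(v) for s, v in self.detection_rates.items()},
            "bin_centers": self.bin_centers.tolist(),
            "bin_F": self.bin_F.tolist(),
            "n_clouds": int(self.n_clouds),
            "sum_F": float(self.sum_F),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ImpurityModel":
        with open(path) as fh:
            obj = json.load(fh)
        weights = pd.DataFrame.from_dict(obj["species_weights"], orient="index").sort_index()
        return cls(
            species_weights=weights,
            detection_rates=pd.Series(obj["detection_rates"]).sort_index(),
            bin_centers=np.asarray(obj["bin_centers"], dtype=float),
            bin_F=np.asarray(obj["bin_F"], dtype=float),
            n_clouds=int(obj["n_clouds"]),
            cloud_D=None,
            sum_F=float(obj["sum_F"]),
        )


def fit_impurity_model(cloud_set: ReadCloudSet, min_clouds_per_bin: int = 50) -> ImpurityModel:
    """Fit the impurity null model from between-species cloud sharing.

    The scale function F(D) is the observed number of distinct species
    pairs per cloud in each cloud-size bin, divided by the expected number
    from independent per-cloud species detection rates (sum over pairs of
    c_s c_s'), then monotonized (non-decreasing in D) by weighted PAVA.
    Under a fragment-per-droplet process this makes F(D) approximately
    E[n(n-1) | D] / E[n]^2 for n fragments per cloud, so the same F
    calibrates per-site co-occurrence tests.  Species read-share weights
    p_s are retained per timepoint.  Requires at least two species.
    """
    spc = cloud_set.species_per_cloud()
    species = sorted(spc["species"].unique())
    if len(species) < 2:
        raise UndefinedStatisticError("impurity model requires at least two species")

    n_clouds = cloud_set.n_clouds
    D = cloud_set.cloud_sizes()

    # per-timepoint read-share simplex
    shares = (
        cloud_set.reads.groupby(["timepoint", "species"]).size().unstack(fill_value=0).astype(float)
    )
    shares = shares.div(shares.sum(axis=1), axis=0)

    # pooled per-cloud detection rates
    det = spc.groupby("species")["cloud"].nunique().reindex(species).astype(float) / n_clouds
    c = det.to_numpy()
    denom = (c.sum() ** 2 - np.sum(c**2)) / 2.0
    if denom <= 0:
        raise UndefinedStatisticError("degenerate species detection rates")

    k_per_cloud = spc.groupby("cloud").size().reindex(np.arange(n_clouds), fill_value=0).to_numpy()
    pairs_obs = k_per_cloud * (k_per_cloud - 1) / 2.0

    edges = _log_bins(D, min_clouds_per_bin)
    idx = np.clip(np.digitize(D, edges) - 1, 0, len(edges) - 2)
    centers, F_raw, weights = [], [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        centers.append(np.exp(np.mean(np.log(np.maximum(D[mask], 1)))))
        F_raw.append(pairs_obs[mask].mean() / denom)
        weights.append(mask.sum())
    centers = np.asarray(centers)
    F_fit = _pava_nondecreasing(np.asarray(F_raw), np.asarray(weights, dtype=float))

    model = ImpurityModel(
        species_weights=shares,
        detection_rates=det,
        bin_centers=centers,
        bin_F=F_fit,
        n_clouds=n_clouds,
        cloud_D=D,
    )
    model.sum_F = float(model.F(D).sum())
    return model
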