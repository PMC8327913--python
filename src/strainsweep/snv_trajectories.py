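"""Allele-frequency trajectories, sweep detection, and diversity summaries.

Allele frequencies are plug-in estimates f = A/D from unique read-cloud
counts.  SNVs are polarized against a reference cohort so that the
"reference" allele is the cohort consensus.  A "SNV difference" (a full
or partial sweep) is an allele moving from below 20% to above 70%
frequency between two sampled timepoints; the set of such candidates is
tested against a binomial sampling-noise null that yields an ensemble
p-value and false discovery rate.  Backbone confirmation checks, via
read-cloud sharing with core genes, that a sweeping SNV really belongs to
the species it was mapped to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import binom, poisson

from .read_clouds import ReadCloudSet

__all__ = [
    "AlleleCountTable",
    "SnvDifferenceSet",
    "estimate_frequencies",
    "flip_snvs",
    "polarize_by_cohort",
    "apply_inclusion_rule",
    "intermediate_diversity",
    "detect_snv_differences",
    "confirm_backbone",
    "jensen_shannon_distance",
]

_PANEL_COLUMNS = ["species", "contig", "pos", "ref", "alt", "degeneracy", "prev_ref", "prev_alt"]


class AlleleCountTable:
    """Per-SNV, per-timepoint unique read-cloud counts.

    ``panel`` describes the SNVs (rows indexed by snv_id with at least
    the columns species/contig/pos/ref/alt/degeneracy/prev_ref/prev_alt);
    ``A`` and ``D`` are aligned DataFrames (SNV x timepoint) of
    alternate-supporting and total unique read clouds.  Timepoint columns
    are strictly increasing sampling days.
    """

    def __init__(self, panel: pd.DataFrame, A: pd.DataFrame, D: pd.DataFrame):
        missing = [c for c in _PANEL_COLUMNS if c not in panel.columns]
        if missing:
            raise ValueError(f"panel is missing columns: {missing}")
        if not (A.index.equals(panel.index) and D.index.equals(panel.index)):
            raise ValueError("A and D must be indexed like the panel")
        if not A.columns.equals(D.columns):
            raise ValueError("A and D must share timepoint columns")
        t = np.asarray(A.columns, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if ((A.to_numpy() < 0) | (A.to_numpy() > D.to_numpy())).any():
            raise ValueError("require 0 <= A <= D")
        self.panel = panel
        self.A = A.astype(int)
        self.D = D.astype(int)

    @property
    def timepoints(self) -> np.ndarray:
        return np.asarray(self.A.columns, dtype=float)

    def subset(self, ids) -> "AlleleCountTable":
        return AlleleCountTable(self.panel.loc[ids], self.A.loc[ids], self.D.loc[ids])

    # ---- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        df = self.panel.copy()
        for t in self.A.columns:
            df[f"A:{t}"] = self.A[t]
            df[f"D:{t}"] = self.D[t]
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "AlleleCountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        a_cols = sorted([c for c in df.columns if c.startswith("A:")], key=lambda c: float(c[2:]))
        d_cols = sorted([c for c in df.columns if c.startswith("D:")], key=lambda c: float(c[2:]))
        times = [float(c[2:]) for c in a_cols]
        A = df[a_cols].copy()
        D = df[d_cols].copy()
        A.columns = times
        D.columns = times
        panel = df.drop(columns=a_cols + d_cols)
        return cls(panel, A, D)

    def to_vcf(self, path) -> None:
        """VCF-flavored export: one sample column per timepoint carrying
        AD-style (ref,alt) unique-cloud counts."""
        times = list(self.A.columns)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
                     '"Unique read clouds per allele">\n')
            samples = "\t".join(f"t{t:g}" for t in times)
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tFORMAT\t{samples}\n")
            for snv_id, row in self.panel.iterrows():
                ads = [
                    f"{int(self.D.loc[snv_id, t] - self.A.loc[snv_id, t])},"
                    f"{int(self.A.loc[snv_id, t])}"
                    for t in times
                ]
                fh.write(
                    f"{row['species']}|{row['contig']}\t{int(row['pos'])}\t{snv_id}\t"
                    f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tAD\t" + "\t".join(ads) + "\n"
                )


def estimate_frequencies(counts: AlleleCountTable, min_depth: int = 10) -> pd.DataFrame:
    """Plug-in frequencies f = A/D; timepoints with D < min_depth are NaN."""
    A = counts.A.to_numpy(dtype=float)
    D = counts.D.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(D >= min_depth, A / D, np.nan)
    return pd.DataFrame(f, index=counts.A.index, columns=counts.A.columns)


def flip_snvs(counts: AlleleCountTable, mask: pd.Series) -> AlleleCountTable:
    """Swap ref/alt for the masked SNVs (A <- D - A, prevalences and
    allele labels exchanged).  Applying the same flip twice is the
    identity."""
    panel = counts.panel.copy()
    A = counts.A.copy()
    m = mask.reindex(panel.index).fillna(False).astype(bool)
    panel.loc[m, ["ref", "alt"]] = panel.loc[m, ["alt", "ref"]].to_numpy()
    panel.loc[m, ["prev_ref", "prev_alt"]] = panel.loc[m, ["prev_alt", "prev_ref"]].to_numpy()
    A.loc[m] = counts.D.loc[m] - counts.A.loc[m]
    return AlleleCountTable(panel, A, counts.D.copy())


def polarize_by_cohort(counts: AlleleCountTable) -> tuple[AlleleCountTable, pd.DataFrame]:
    """Repolarize so the reference allele is the cohort-consensus allele.

    SNVs whose alternate allele has the majority cohort prevalence are
    flipped.  Exact ties (prevalence 0.5 each) and SNVs with missing
    prevalence are left as-is and flagged.  Returns the repolarized table
    and a per-SNV record (flipped / tie / missing_prevalence).  The
    operation is idempotent.
    """
    panel = counts.panel
    prev_ref = panel["prev_ref"].to_numpy(dtype=float)
    prev_alt = panel["prev_alt"].to_numpy(dtype=float)
    missing = np.isnan(prev_ref) | np.isnan(prev_alt)
    tie = (~missing) & (prev_alt == prev_ref)
    flip = (~missing) & (prev_alt > prev_ref)
    record = pd.DataFrame(
        {"flipped": flip, "tie": tie, "missing_prevalence": missing}, index=panel.index
    )
    return flip_snvs(counts, pd.Series(flip, index=panel.index)), record


def apply_inclusion_rule(counts: AlleleCountTable, min_freq: float = 0.1,
                         min_depth: int = 10) -> AlleleCountTable:
    """Keep SNVs whose alternate allele reaches ``min_freq`` in at least
    one timepoint with adequate depth."""
    f = estimate_frequencies(counts, min_depth)
    keep = (f >= min_freq).any(axis=1)
    return counts.subset(keep[keep].index)


def intermediate_diversity(frequencies: pd.DataFrame, core_sites: int) -> pd.Series:
    """Fraction of core-genome sites at intermediate frequency, 0.2 < f < 0.8
    (strict inequalities), per timepoint."""
    if core_sites <= 0:
        raise ValueError("core_sites must be positive")
    f = frequencies.to_numpy(dtype=float)
    inter = (f > 0.2) & (f < 0.8)
    return pd.Series(inter.sum(axis=0) / core_sites, index=frequencies.columns)


@dataclass
class SnvDifferenceSet:
    """SNV differences between one ordered pair of timepoints."""

    t1: float
    t2: float
    flagged: pd.DataFrame          # snv_id index; f1, f2, null_probability
    n_tested: int
    expected: float                 # ensemble expected candidate count
    observed: int
    pvalue: float
    fdr: float                      # expected / observed
    declared: bool


_F0_GRID = np.arange(0.01, 1.0, 0.01)


def _null_candidate_probability(D1: np.ndarray, D2: np.ndarray) -> np.ndarray:
    """Per-SNV probability of satisfying the 0.2/0.7 criterion under a
    constant true frequency, maximized over f0 on a 0.01-step grid.

    The criterion is two-sided in allele space (either allele may be the
    minor one that rises), so the null is
    P(A1/D1 <= 0.2) P(A2/D2 >= 0.7) + P(A1/D1 >= 0.8) P(A2/D2 <= 0.3)
    under independent binomial sampling at the two depths; maximizing
    over f0 gives a conservative ensemble expectation.
    """
    D1 = np.asarray(D1)
    D2 = np.asarray(D2)
    k1 = np.floor(0.2 * D1 + 1e-9)[:, None]
    k2 = np.ceil(0.7 * D2 - 1e-9)[:, None]
    d1 = D1[:, None]
    d2 = D2[:, None]
    f0 = _F0_GRID[None, :]
    up = binom.cdf(k1, d1, f0) * binom.sf(k2 - 1, d2, f0)
    down = binom.sf(d1 - k1 - 1, d1, f0) * binom.cdf(d2 - k2, d2, f0)
    return (up + down).max(axis=1)


def detect_snv_differences(
    counts: AlleleCountTable,
    t1: float,
    t2: float,
    alpha: float = 0.05,
    fdr: float = 0.1,
    min_depth: int = 10,
) -> SnvDifferenceSet:
    """Detect SNV differences (sweeps) between two timepoints.

    Candidates are SNVs whose minor allele at t1 transitions from below
    20% to above 70% frequency at t2 (strict inequalities): either the
    alternate allele rises (f1 < 0.2, f2 > 0.7) or the reference allele
    does (f1 > 0.8, f2 < 0.3).  The observed candidate count is compared
    with its expectation under binomial sampling noise; the ensemble
    p-value is the Poisson upper tail at that expectation.  All
    candidates are declared SNV differences iff p < ``alpha`` and
    expected/observed < ``fdr``.  The flagged table reports the rising
    allele and its frequencies.
    """
    if t2 <= t1:
        raise ValueError("t2 must be later than t1")
    cols = counts.A.columns
    if t1 not in cols or t2 not in cols:
        raise ValueError("both timepoints must be sampled")

    D1 = counts.D[t1].to_numpy()
    D2 = counts.D[t2].to_numpy()
    tested = (D1 >= min_depth) & (D2 >= min_depth)
    A1 = counts.A[t1].to_numpy()[tested]
    A2 = counts.A[t2].to_numpy()[tested]
    d1 = D1[tested]
    d2 = D2[tested]
    ids = counts.panel.index[tested]

    f1 = A1 / d1
    f2 = A2 / d2
    up = (f1 < 0.2) & (f2 > 0.7)
    down = (f1 > 0.8) & (f2 < 0.3)
    cand = up | down
    null_p = _null_candidate_probability(d1, d2)
    expected = float(null_p.sum())
    observed = int(cand.sum())
    pvalue = float(poisson.sf(observed - 1, expected)) if observed > 0 else 1.0
    fdr_value = expected / observed if observed > 0 else np.inf
    declared = bool(observed > 0 and pvalue < alpha and fdr_value < fdr)

    rising = np.where(up, "alt", "ref")
    f1_rising = np.where(up, f1, 1.0 - f1)
    f2_rising = np.where(up, f2, 1.0 - f2)
    flagged = pd.DataFrame(
        {
            "rising_allele": rising[cand],
            "f1": f1_rising[cand],
            "f2": f2_rising[cand],
            "null_probability": null_p[cand],
        },
        index=ids[cand],
    )
    return SnvDifferenceSet(
        t1=float(t1), t2=float(t2), flagged=flagged, n_tested=int(tested.sum()),
        expected=expected, observed=observed, pvalue=pvalue,
        fdr=float(fdr_value), declared=declared,
    )


def confirm_backbone(
    snv_id: int,
    cloud_set: ReadCloudSet,
    core_genes: pd.DataFrame,
    panel: pd.DataFrame,
    min_shared_clouds: int = 3,
) -> str:
    """Confirm that a SNV is linked to its inferred species backbone.

    For each allele, core genes sharing at least ``min_shared_clouds``
    distinct read clouds with reads carrying that allele are collected.
    Positive: both alleles have more than two thirds of these frequently
    shared genes from the SNV's own species.  Negative: either allele has
    more than a third from another species.  Unconfirmed otherwise (e.g.
    an allele with no frequently shared genes).

    ``core_genes`` maps gene id to species (columns ``gene``, ``species``).
    """
    reads = cloud_set.reads
    codes, _ = cloud_set.cloud_index()
    gene_species = core_genes.set_index("gene")["species"]
    own_species = panel.loc[snv_id, "species"]

    at_site = reads["snv_id"].to_numpy() == snv_id
    fractions = []
    any_negative = False
    for allele in ("ref", "alt"):
        allele_clouds = np.unique(codes[at_site & (reads["allele"].to_numpy() == allele)])
        if len(allele_clouds) == 0:
            fractions.append(None)
            continue
        in_clouds = np.isin(codes, allele_clouds) & ~at_site
        sub = pd.DataFrame({"gene": reads["gene"].to_numpy()[in_clouds],
                            "cloud": codes[in_clouds]})
        sub = sub[sub["gene"].isin(gene_species.index)]
        n_clouds_per_gene = sub.groupby("gene")["cloud"].nunique()
        frequent = n_clouds_per_gene[n_clouds_per_gene >= min_shared_clouds]
        if len(frequent) == 0:
            fractions.append(None)
            continue
        own = (gene_species.loc[frequent.index] == own_species).mean()
        fractions.append(float(own))
        if own < 2.0 / 3.0:
            any_negative = True

    if any_negative:
        return "negative"
    if all(f is not None and f > 2.0 / 3.0 for f in fractions):
        return "positive"
    return "unconfirmed"


def jensen_shannon_distance(p, q) -> float:
    """Jensen-Shannon distance (square root of the divergence, base-2
    logarithms) between two relative-abundance vectors on the same
    species set.  0 for identical vectors, 1 for disjoint support."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("vectors must be on the same species set")
    return float(jensenshannon(p, q, base=2))
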