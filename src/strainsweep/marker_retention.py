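"""Private marker SNV retention and replacement-vs-modification calls.

A "private marker" is an allele at high frequency in the focal host whose
cohort prevalence is exactly zero — a fingerprint of the resident strain.
If a sweep replaces the resident strain with a distantly related one, the
private markers are disrupted (the temporally variable SNVs include sites
whose private reference allele loses its majority); if the sweep is an
evolutionary modification of the resident strain, the markers ride along
and are preserved.  The sweeping SNV set's dN/dS (from 1D/4D codon
degeneracy classes) provides a second line of evidence: values well below
1 indicate alleles that evolved under purifying selection between hosts
rather than within this one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MarkerClassification",
    "identify_private_markers",
    "classify_markers",
    "dn_ds",
    "classify_event",
]


@dataclass
class MarkerClassification:
    species: str
    n_preserved: int
    n_disrupted: int
    n_unclassified: int
    labels: pd.Series          # per-marker: preserved | disrupted | unclassified
    dn_ds: float | None = None
    event: str | None = None


def identify_private_markers(panel: pd.DataFrame) -> pd.DataFrame:
    """SNVs whose alternate-or-reference allele has cohort prevalence
    exactly zero, with the private allele identified.

    Returns the subset of the panel with an extra ``private_allele``
    column ('ref' or 'alt').
    """
    prev_ref = panel["prev_ref"].to_numpy(dtype=float)
    prev_alt = panel["prev_alt"].to_numpy(dtype=float)
    is_private = (prev_ref == 0.0) | (prev_alt == 0.0)
    out = panel.loc[is_private].copy()
    out["private_allele"] = np.where(out["prev_alt"].to_numpy() == 0.0, "alt", "ref")
    return out


def classify_markers(
    markers: pd.DataFrame,
    frequencies: pd.DataFrame,
    temporally_variable,
    high_freq: float = 0.8,
    high_fraction: float = 0.8,
    floor_freq: float = 0.5,
) -> MarkerClassification:
    """Classify private markers as preserved or disrupted.

    Preserved: the private allele stays above ``high_freq`` in at least
    ``high_fraction`` of the non-missing timepoints and never drops below
    ``floor_freq``.  Disrupted: the SNV is temporally variable and its
    private allele is the ancestral (reference-polarized) one — the
    allele displaced by the sweep, so the resident strain's fingerprint
    was lost.  ``temporally_variable`` is either a mapping snv_id ->
    rising allele ('ref'/'alt'), in which case the private allele must
    differ from the rising one, or a plain collection of snv_ids, in
    which case the rising allele is taken to be the alternate.  Markers
    matching neither rule — or with no non-missing timepoints — are
    unclassified.  ``frequencies`` are alternate-allele frequencies
    (NaN = missing).
    """
    if isinstance(temporally_variable, dict):
        rising = dict(temporally_variable)
    else:
        rising = {snv_id: "alt" for snv_id in temporally_variable}
    labels = {}
    for snv_id, row in markers.iterrows():
        f_alt = frequencies.loc[snv_id].to_numpy(dtype=float)
        f_priv = f_alt if row["private_allele"] == "alt" else 1.0 - f_alt
        obs = f_priv[~np.isnan(f_priv)]
        preserved = (
            len(obs) > 0
            and (obs > high_freq).mean() >= high_fraction
            and obs.min() >= floor_freq
        )
        disrupted = snv_id in rising and row["private_allele"] != rising[snv_id]
        if preserved and disrupted:
            raise ValueError(f"marker {snv_id} satisfies both retention rules")
        if preserved:
            labels[snv_id] = "preserved"
        elif disrupted:
            labels[snv_id] = "disrupted"
        else:
            labels[snv_id] = "unclassified"
    labels = pd.Series(labels, dtype=object).reindex(markers.index, fill_value="unclassified")
    species = str(markers["species"].iloc[0]) if len(markers) else ""
    return MarkerClassification(
        species=species,
        n_preserved=int((labels == "preserved").sum()),
        n_disrupted=int((labels == "disrupted").sum()),
        n_unclassified=int((labels == "unclassified").sum()),
        labels=labels,
    )


def dn_ds(sweeping_panel: pd.DataFrame, site_totals: pd.Series | dict) -> float | None:
    """dN/dS of a sweeping SNV set from 1D/4D degeneracy classes.

    (1D changes / 1D site opportunities) / (4D changes / 4D site
    opportunities).  Twofold/threefold sites are excluded from both the
    numerator and the opportunities.  Undefined (None) when there are no
    4D changes; 0.0 when there are 4D changes but no 1D changes.
    """
    totals = pd.Series(site_totals)
    n1 = int((sweeping_panel["degeneracy"] == "1D").sum())
    n4 = int((sweeping_panel["degeneracy"] == "4D").sum())
    if n4 == 0:
        return None
    opp1 = float(totals.get("1D", 0))
    opp4 = float(totals.get("4D", 0))
    if opp1 <= 0 or opp4 <= 0:
        raise ValueError("need positive 1D and 4D site opportunity counts")
    return (n1 / opp1) / (n4 / opp4)


def classify_event(
    n_preserved: int,
    n_disrupted: int,
    n_snv_differences: int,
    dn_ds_value: float | None = None,
    median_initial_frequency: float | None = None,
    replacement_disrupted_fraction: float = 0.5,
    modification_disrupted_fraction: float = 0.1,
    replacement_min_snvs: int = 1000,
    modification_min_dnds: float = 1.0,
) -> str:
    """Label a species' sweep as replacement, modification or intermediate.

    Replacement: most markers disrupted and a genome-wide number of SNV
    differences.  Modification: markers essentially intact, few SNVs, and
    a dN/dS not indicative of between-host divergence (>= 1, or undefined
    as happens for small nonsynonymous clusters).  Everything else —
    including marker-preserving sweeps whose low dN/dS points at imported
    haplotypes — is intermediate.  Thresholds are heuristics distilled
    from exemplar events and are fully configurable.
    """
    classified = n_preserved + n_disrupted
    if classified == 0:
        return "intermediate"
    frac = n_disrupted / classified
    if frac > replacement_disrupted_fraction and n_snv_differences >= replacement_min_snvs:
        return "replacement"
    dnds_ok = dn_ds_value is None or dn_ds_value >= modification_min_dnds
    if frac < modification_disrupted_fraction and n_snv_differences < replacement_min_snvs and dnds_ok:
        return "modification"
    return "intermediate"
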