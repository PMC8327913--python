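"""Synthetic longitudinal linked-read metagenome generator.

Every input the analysis pipeline consumes can be produced here with the
statistical structure the downstream methods assume: a species community
with heavy-tailed abundances and an antibiotic perturbation window, a
two-strain SNV panel with shared/private alleles and cohort prevalences,
latent haplotype frequency trajectories under time-varying selection and
drift, binomial sequencing noise, and barcoded read clouds whose
"impurity" (fragments from several species per droplet) mirrors what is
seen in real linked-read gut metagenomes.  Ground-truth labels (strain of
origin, fragment of origin, latent frequencies) are kept alongside every
dataset so that recovery tests can score the inference modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "CommunityConfig",
    "StrainPanelConfig",
    "WrightFisherParams",
    "CloudConfig",
    "simulate_community",
    "simulate_strain_trajectory",
    "simulate_allele_counts",
    "simulate_strain_panel",
    "simulate_read_clouds",
]

_BASES = np.array(list("ACGT"))


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class CommunityConfig:
    """Parameters of the synthetic species community.

    Abundances follow a lognormal law (baseline log10-abundances are
    normal with standard deviation ``abundance_sigma``), which gives the
    steep rank-abundance curves typical of gut communities.  A
    perturbation window models an antibiotic course: affected species are
    shifted by a per-species log10 fold effect inside the window and relax
    back exponentially (timescale ``recovery_days``) afterwards.
    """

    n_species: int
    timepoints: Sequence[float]
    abundance_sigma: float = 1.5
    perturbation_window: tuple[float, float] | None = None
    perturbation_effects: Mapping[int, float] = field(default_factory=dict)
    recovery_days: float = 21.0
    noise_sigma: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_species <= 0:
            raise ValueError("n_species must be positive")
        if len(self.timepoints) == 0:
            raise ValueError("timepoints must be non-empty")
        t = np.asarray(self.timepoints, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.perturbation_window is not None:
            lo, hi = self.perturbation_window
            if not (t[0] <= lo <= hi <= t[-1]):
                raise ValueError("perturbation window must lie within the sampling span")
        if self.abundance_sigma < 0 or self.noise_sigma < 0 or self.recovery_days <= 0:
            raise ValueError("scale parameters must be positive")


def _window_weight(t: np.ndarray, window: tuple[float, float] | None, recovery: float) -> np.ndarray:
    """Perturbation weight: 0 before, 1 inside, exponential relaxation after."""
    if window is None:
        return np.zeros_like(t)
    lo, hi = window
    w = np.zeros_like(t, dtype=float)
    inside = (t >= lo) & (t <= hi)
    after = t > hi
    w[inside] = 1.0
    w[after] = np.exp(-(t[after] - hi) / recovery)
    return w


def simulate_community(config: CommunityConfig, normalize: bool = True) -> pd.DataFrame:
    """Simulate a species-by-timepoint relative abundance table.

    Returns a DataFrame indexed by species id with one column per
    timepoint.  With ``normalize=True`` (default) each column sums to 1.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.timepoints, dtype=float)
    S, T = config.n_species, len(t)

    base = rng.normal(0.0, config.abundance_sigma, size=S)  # log10 baseline
    w = _window_weight(t, config.perturbation_window, config.recovery_days)
    effects = np.zeros(S)
    for idx, eff in config.perturbation_effects.items():
        effects[int(idx)] = eff

    log10_a = base[:, None] + effects[:, None] * w[None, :]
    if config.noise_sigma > 0:
        log10_a = log10_a + rng.normal(0.0, config.noise_sigma, size=(S, T))
    a = 10.0 ** log10_a
    if normalize:
        a = a / a.sum(axis=0, keepdims=True)
    species = [f"species_{i:03d}" for i in range(S)]
    return pd.DataFrame(a, index=species, columns=t)


@dataclass
class WrightFisherParams:
    """Wright-Fisher diffusion parameters for a haplotype frequency.

    df = s_e(tau) f(1-f) dtau + sqrt(f(1-f)/N_e(tau)) dW

    ``s_schedule`` and ``ne_schedule`` are piecewise-constant schedules
    given as (start_day, value) pairs; a value applies from its start day
    until the next breakpoint.  ``N_e`` may be ``np.inf`` (no drift).
    Time is measured in days throughout.
    """

    f0: float
    s_schedule: Sequence[tuple[float, float]] = ((0.0, 0.0),)
    ne_schedule: Sequence[tuple[float, float]] = ((0.0, np.inf),)
    dt_sim: float = 0.1

    def validate(self, sample_times: np.ndarray) -> None:
        if not (0.0 <= self.f0 <= 1.0):
            raise ValueError("f0 must lie in [0, 1]")
        if self.dt_sim <= 0:
            raise ValueError("dt_sim must be positive")
        gaps = np.diff(sample_times)
        if len(gaps) and self.dt_sim > gaps.min():
            raise ValueError("dt_sim must not exceed the smallest inter-sample gap")
        for _, ne in self.ne_schedule:
            if not ne > 0:
                raise ValueError("N_e must be positive")

    def s_at(self, t: float) -> float:
        return _schedule_value(self.s_schedule, t)

    def ne_at(self, t: float) -> float:
        return _schedule_value(self.ne_schedule, t)


def _schedule_value(schedule: Sequence[tuple[float, float]], t: float) -> float:
    val = schedule[0][1]
    for start, v in schedule:
        if t >= start:
            val = v
        else:
            break
    return val


def simulate_strain_trajectory(
    params: WrightFisherParams,
    sample_times: Sequence[float],
    seed=None,
    n_reps: int = 1,
) -> np.ndarray:
    """Integrate the Wright-Fisher diffusion and report f at sample times.

    The deterministic (selection) part is advanced exactly in logit space
    within each sub-step; the drift noise is then added Euler-Maruyama
    style and the state clipped to [0, 1].  A frequency of exactly 0 or 1
    at a full step is absorbing (no mutation).  With 1/N_e = 0 the output
    is the exact logistic solution.  Returns shape (T,) for ``n_reps=1``,
    else (n_reps, T).
    """
    times = np.asarray(sample_times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("sample_times must be strictly increasing")
    params.validate(times)
    rng = _as_rng(seed)

    f = np.full(n_reps, float(params.f0))
    out = np.empty((n_reps, len(times)))
    out[:, 0] = f
    for k in range(len(times) - 1):
        t0, t1 = times[k], times[k + 1]
        n_sub = max(1, int(np.ceil((t1 - t0) / params.dt_sim - 1e-12)))
        h = (t1 - t0) / n_sub
        for j in range(n_sub):
            tau = t0 + j * h
            s = params.s_at(tau)
            ne = params.ne_at(tau)
            interior = (f > 0.0) & (f < 1.0)
            if s != 0.0 and interior.any():
                f = np.where(interior, expit(logit(np.clip(f, 1e-300, 1.0)) + s * h), f)
            if np.isfinite(ne) and interior.any():
                noise = rng.standard_normal(n_reps) * np.sqrt(np.clip(f * (1 - f), 0, None) * h / ne)
                f = np.where(interior, np.clip(f + noise, 0.0, 1.0), f)
        out[:, k + 1] = f
    return out[0] if n_reps == 1 else out


def simulate_allele_counts(trajectory, depths, seed=None) -> np.ndarray:
    """Binomial read-cloud sampling layer: A ~ Binomial(D, f).

    ``trajectory`` and ``depths`` broadcast against each other; the result
    has the broadcast shape.  Latent frequencies outside [0, 1] and
    negative depths are errors.
    """
    f = np.asarray(trajectory, dtype=float)
    D = np.asarray(depths)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("trajectory values must lie in [0, 1]")
    if np.any(D < 0):
        raise ValueError("depths must be non-negative")
    rng = _as_rng(seed)
    f_b, D_b = np.broadcast_arrays(f, D)
    return rng.binomial(D_b.astype(int), f_b)


@dataclass
class StrainPanelConfig:
    """Two-strain SNV panel layout.

    ``n_snvs`` distinguishing SNVs separate the resident strain (carries
    the reference allele) from the competing strain (carries the
    alternate); ``n_shared_between_strains`` additional SNVs carry the
    alternate allele on both strains.  ``strain_divergence`` (SNVs per bp)
    sets the genome length over which sites are scattered.  Each strain
    receives ``private_marker_count`` sites whose strain-specific allele
    has cohort prevalence exactly 0.  Cohort prevalences of the remaining
    alternate alleles follow a Beta law.
    """

    n_snvs: int
    n_shared_between_strains: int = 0
    strain_divergence: float = 1e-3
    private_marker_count: int = 0
    cohort_prevalence_law: tuple[float, float] = (0.5, 2.0)
    degeneracy_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"1D": 0.7, "4D": 0.3}
    )

    def validate(self) -> None:
        if self.n_snvs <= 0:
            raise ValueError("n_snvs must be positive")
        if self.strain_divergence <= 0:
            raise ValueError("strain_divergence must be positive")
        if abs(sum(self.degeneracy_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("degeneracy fractions must sum to 1")
        if 2 * self.private_marker_count > self.n_snvs:
            raise ValueError("too many private markers for the panel size")


def simulate_strain_panel(
    config: StrainPanelConfig,
    seed=None,
    species: str = "species_000",
    contig: str = "contig_0",
) -> pd.DataFrame:
    """Build a two-strain SNV panel with ground-truth strain alleles.

    Columns: species, contig, pos, ref, alt, degeneracy, prev_ref,
    prev_alt, strain1_alt, strain2_alt (bools: does that strain carry the
    alternate allele).  Index is the SNV id.
    """
    config.validate()
    rng = _as_rng(seed)
    n_total = config.n_snvs + config.n_shared_between_strains
    genome_length = max(int(np.ceil(n_total / config.strain_divergence)), n_total * 2)
    pos = np.sort(rng.choice(genome_length, size=n_total, replace=False)) + 1

    ref_idx = rng.integers(0, 4, n_total)
    alt_idx = (ref_idx + rng.integers(1, 4, n_total)) % 4

    classes = list(config.degeneracy_fractions)
    probs = np.array([config.degeneracy_fractions[c] for c in classes], dtype=float)
    degeneracy = rng.choice(classes, size=n_total, p=probs / probs.sum())

    a, b = config.cohort_prevalence_law
    prev_alt = rng.beta(a, b, n_total)
    prev_ref = 1.0 - prev_alt

    strain1_alt = np.zeros(n_total, dtype=bool)
    strain2_alt = np.zeros(n_total, dtype=bool)
    strain2_alt[: config.n_snvs] = True                  # distinguishing sites
    strain1_alt[config.n_snvs:] = True                   # shared alternate alleles
    strain2_alt[config.n_snvs:] = True

    # Private markers: strain 1's allele (reference) unseen in the cohort
    # at the first block of distinguishing sites; strain 2's allele
    # (alternate) unseen at the second block.
    m = config.private_marker_count
    prev_ref[:m] = 0.0
    prev_alt[:m] = rng.uniform(0.3, 1.0, m)
    prev_alt[m : 2 * m] = 0.0
    prev_ref[m : 2 * m] = rng.uniform(0.3, 1.0, m)

    panel = pd.DataFrame(
        {
            "species": species,
            "contig": contig,
            "pos": pos,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "degeneracy": degeneracy,
            "prev_ref": prev_ref,
            "prev_alt": prev_alt,
            "strain1_alt": strain1_alt,
            "strain2_alt": strain2_alt,
        }
    )
    panel.index.name = "snv_id"
    return panel


@dataclass
class CloudConfig:
    """Read-cloud (droplet) generator parameters.

    Fragments per cloud are 1 + Poisson(mean_fragments - 1); fragment
    lengths are exponential with the given scale (~10 kb, matching HMW
    extraction); each fragment contributes 1 + Poisson(reads_per_fragment
    - 1) background reads at uniform positions plus one read at every SNV
    position it spans, so SNV co-occurrence inside one fragment is exact
    while impurity sharing only arises through multi-fragment clouds.
    """

    n_clouds: int = 1000
    mean_fragments: float = 7.0
    fragment_length: float = 10_000.0
    reads_per_fragment: float = 10.0
    read_length: int = 150
    genome_length: int = 100_000
    gene_length: int = 1000
    min_fragment_length: float = 300.0

    def validate(self) -> None:
        if self.fragment_length <= 0:
            raise ValueError("fragment length must be positive")
        if self.n_clouds <= 0 or self.mean_fragments < 1 or self.reads_per_fragment < 1:
            raise ValueError("invalid cloud configuration")


def simulate_read_clouds(
    community: pd.DataFrame,
    snv_panel: pd.DataFrame,
    cloud_config: CloudConfig,
    seed=None,
    strain2_freq: pd.DataFrame | None = None,
):
    """Simulate barcoded read clouds for every timepoint of a community.

    ``community`` is a species-by-timepoint abundance table (columns are
    sampling days).  ``snv_panel`` carries per-species SNVs with
    ground-truth strain alleles (see :func:`simulate_strain_panel`);
    ``strain2_freq`` gives the frequency of strain 2 per species (rows)
    and timepoint (columns); species absent from it are pure strain 1.

    Returns a :class:`~strainsweep.read_clouds.ReadCloudSet` whose reads
    retain the ground-truth fragment id.
    """
    from .read_clouds import ReadCloudSet

    cloud_config.validate()
    rng = _as_rng(seed)
    species_names = list(community.index)
    sp_codes = pd.Index(species_names)
    G = cloud_config.genome_length

    # per-species sorted SNV positions for interval lookups
    snv_pos: dict[str, np.ndarray] = {}
    snv_ids: dict[str, np.ndarray] = {}
    snv_alt1: dict[str, np.ndarray] = {}
    snv_alt2: dict[str, np.ndarray] = {}
    for sp, sub in snv_panel.groupby("species", sort=True):
        sub = sub.sort_values("pos")
        snv_pos[sp] = sub["pos"].to_numpy(dtype=float)
        snv_ids[sp] = sub.index.to_numpy()
        snv_alt1[sp] = sub["strain1_alt"].to_numpy(dtype=bool)
        snv_alt2[sp] = sub["strain2_alt"].to_numpy(dtype=bool)

    frames = []
    frag_offset = 0
    for t in community.columns:
        abund = community[t].to_numpy(dtype=float)
        abund = abund / abund.sum()
        n_frag = 1 + rng.poisson(cloud_config.mean_fragments - 1.0, cloud_config.n_clouds)
        cloud_of_frag = np.repeat(np.arange(cloud_config.n_clouds), n_frag)
        nf = len(cloud_of_frag)
        sp_of_frag = rng.choice(len(species_names), size=nf, p=abund)
        length = np.clip(
            rng.exponential(cloud_config.fragment_length, nf),
            cloud_config.min_fragment_length,
            G - 1,
        )
        start = rng.uniform(0, G - length)
        n_reads = 1 + rng.poisson(cloud_config.reads_per_fragment - 1.0, nf)

        strain2 = np.zeros(nf, dtype=bool)
        if strain2_freq is not None:
            for sp_name in strain2_freq.index:
                if sp_name not in sp_codes:
                    continue
                si = sp_codes.get_loc(sp_name)
                mask = sp_of_frag == si
                if mask.any():
                    f2 = float(strain2_freq.loc[sp_name, t])
                    strain2[mask] = rng.random(mask.sum()) < f2

        barcodes = np.array([f"BC{i:07d}" for i in range(cloud_config.n_clouds)])
        frag_ids = frag_offset + np.arange(nf)
        frag_offset += nf

        # background reads: uniform positions within fragments
        read_frag = np.repeat(np.arange(nf), n_reads)
        span = np.maximum(length - cloud_config.read_length, 1.0)
        rpos = (start[read_frag] + rng.uniform(0, span[read_frag])).astype(int)
        bg = pd.DataFrame(
            {
                "timepoint": float(t),
                "barcode": barcodes[cloud_of_frag[read_frag]],
                "species": np.asarray(species_names, dtype=object)[sp_of_frag[read_frag]],
                "contig": "contig_0",
                "pos": rpos,
                "snv_id": -1,
                "allele": "",
                "gene": rpos // cloud_config.gene_length,
                "fragment": frag_ids[read_frag],
            }
        )
        frames.append(bg)

        # one read per SNV spanned by each fragment
        for sp_name in snv_pos:
            if sp_name not in sp_codes:
                continue
            si = sp_codes.get_loc(sp_name)
            fmask = np.flatnonzero(sp_of_frag == si)
            if len(fmask) == 0:
                continue
            ppos = snv_pos[sp_name]
            lo = np.searchsorted(ppos, start[fmask])
            hi = np.searchsorted(ppos, start[fmask] + length[fmask])
            counts = hi - lo
            keep = counts > 0
            if not keep.any():
                continue
            fsel = fmask[keep]
            lo, counts = lo[keep], counts[keep]
            snv_idx = np.concatenate([np.arange(l, l + c) for l, c in zip(lo, counts)])
            frag_rep = np.repeat(fsel, counts)
            has_alt = np.where(
                strain2[frag_rep], snv_alt2[sp_name][snv_idx], snv_alt1[sp_name][snv_idx]
            )
            pos_read = ppos[snv_idx].astype(int)
            frames.append(
                pd.DataFrame(
                    {
                        "timepoint": float(t),
                        "barcode": barcodes[cloud_of_frag[frag_rep]],
                        "species": sp_name,
                        "contig": "contig_0",
                        "pos": pos_read,
                        "snv_id": snv_ids[sp_name][snv_idx],
                        "allele": np.where(has_alt, "alt", "ref"),
                        "gene": pos_read // cloud_config.gene_length,
                        "fragment": frag_ids[frag_rep],
                    }
                )
            )

    reads = pd.concat(frames, ignore_index=True)
    reads["gene"] = reads["species"].astype(str) + "|g" + reads["gene"].astype(str)
    return ReadCloudSet(reads)
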