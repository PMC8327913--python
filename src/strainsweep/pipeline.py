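"""End-to-end orchestration of the synthetic study and analysis stages.

``run_pipeline`` executes simulate -> impurity -> snvdiff -> linkage ->
cluster -> drift -> markers -> report, passing data between stages
through TSV/JSON files in the output directory and recording a manifest
(stage, parameters, seed, output hashes).  Reruns with an identical
configuration and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import haplotype_clusters, linkage, marker_retention, read_clouds, selection_drift
from . import snv_trajectories as snv
from . import synthetic

__all__ = ["RunConfig", "run_pipeline", "summarize_report", "STAGES"]

STAGES = ["simulate", "impurity", "snvdiff", "linkage", "cluster", "drift", "markers", "report"]


@dataclass
class RunConfig:
    """Configuration of a full synthetic-study run.

    Defaults emulate the study design the analysis targets: ~19 roughly
    weekly samples over 5 months, a two-week antibiotic window, a
    lognormal 50-species community, and a focal species carrying two
    strains whose minority haplotype sweeps during treatment and
    partially reverts afterwards.
    """

    outdir: str = "strainsweep_run"
    seed: int = 0
    # community
    n_species: int = 50
    timepoints: list = field(default_factory=lambda: [float(7 * i) for i in range(19)])
    abundance_sigma: float = 1.5
    antibiotic_window: list = field(default_factory=lambda: [35.0, 49.0])
    perturbation_effects: dict = field(default_factory=lambda: {1: -2.0, 2: -1.0})
    # strain panel (focal species)
    n_snvs: int = 60
    n_shared_between_strains: int = 5
    private_marker_count: int = 10
    strain_divergence: float = 1e-3
    # strain dynamics (Wright-Fisher, per day)
    f0: float = 0.05
    s_before: float = 0.0
    s_during: float = 0.5
    s_after: float = -0.05
    ne_per_day: float = 1000.0
    dt_sim: float = 0.5
    # sequencing depth and read clouds
    total_coverage: int = 2000
    n_clouds: int = 800
    mean_fragments: float = 7.0
    fragment_length: float = 10000.0
    reads_per_fragment: float = 8.0
    genome_length: int = 100000
    gene_length: int = 1000
    # analysis parameters
    min_depth: int = 10
    d_star: float = 3.5
    min_shared_clouds: int = 12
    screen_alpha: float = 0.1
    alpha: float = 0.05
    fdr: float = 0.1
    maf_min: float = 0.1
    bootstrap_reps: int = 100
    core_sites: int = 100000
    skip: list = field(default_factory=list)

    # ---- YAML round trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**data)
        if "perturbation_effects" in data:
            cfg.perturbation_effects = {int(k): float(v) for k, v in
                                        data["perturbation_effects"].items()}
        return cfg

    def validate(self) -> None:
        if not self.timepoints or len(self.timepoints) < 2:
            raise ValueError("need at least two timepoints")
        lo, hi = self.antibiotic_window
        if not (self.timepoints[0] <= lo <= hi <= self.timepoints[-1]):
            raise ValueError("antibiotic window must lie within the sampling span")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: RunConfig):
        self.entries: dict = {}
        self.config = dataclasses.asdict(config)

    def record(self, stage: str, outputs: list[Path], params: dict, seed: int) -> None:
        self.entries[stage] = {
            "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
            "params": params,
            "seed": seed,
        }

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "stages": self.entries}, fh,
                      indent=1, sort_keys=True)


def _stage_seed(config: RunConfig, index: int) -> int:
    return int(np.random.SeedSequence(config.seed).generate_state(index + 1)[index] % (2**31))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path, seed: int) -> list[Path]:
    ss = np.random.SeedSequence(seed)
    s_comm, s_panel, s_traj, s_counts, s_clouds = [
        np.random.default_rng(c) for c in ss.spawn(5)
    ]

    comm_cfg = synthetic.CommunityConfig(
        n_species=config.n_species,
        timepoints=config.timepoints,
        abundance_sigma=config.abundance_sigma,
        perturbation_window=tuple(config.antibiotic_window),
        perturbation_effects=config.perturbation_effects,
        seed=seed,
    )
    abundances = synthetic.simulate_community(comm_cfg)
    # the focal species is the most abundant at baseline
    focal = abundances[abundances.columns[0]].idxmax()

    panel_cfg = synthetic.StrainPanelConfig(
        n_snvs=config.n_snvs,
        n_shared_between_strains=config.n_shared_between_strains,
        strain_divergence=config.strain_divergence,
        private_marker_count=config.private_marker_count,
    )
    panel = synthetic.simulate_strain_panel(panel_cfg, seed=s_panel, species=focal)

    lo, hi = config.antibiotic_window
    wf = synthetic.WrightFisherParams(
        f0=config.f0,
        s_schedule=((config.timepoints[0], config.s_before), (lo, config.s_during),
                    (hi, config.s_after)),
        ne_schedule=((config.timepoints[0], config.ne_per_day),),
        dt_sim=config.dt_sim,
    )
    f2 = synthetic.simulate_strain_trajectory(wf, config.timepoints, seed=s_traj)

    # per-SNV alternate-allele frequency given the strain mixture
    s1 = panel["strain1_alt"].to_numpy()[:, None]
    s2 = panel["strain2_alt"].to_numpy()[:, None]
    f_alt = s1 * (1 - f2)[None, :] + s2 * f2[None, :]

    depth = np.maximum(
        np.round(abundances.loc[focal].to_numpy() * config.total_coverage), 0
    ).astype(int)
    depths = np.broadcast_to(depth, f_alt.shape)
    A = synthetic.simulate_allele_counts(f_alt, depths, seed=s_counts)
    counts = snv.AlleleCountTable(
        panel,
        pd.DataFrame(A, index=panel.index, columns=config.timepoints),
        pd.DataFrame(np.array(depths), index=panel.index, columns=config.timepoints),
    )

    cloud_cfg = synthetic.CloudConfig(
        n_clouds=config.n_clouds,
        mean_fragments=config.mean_fragments,
        fragment_length=config.fragment_length,
        reads_per_fragment=config.reads_per_fragment,
        genome_length=config.genome_length,
        gene_length=config.gene_length,
    )
    strain2_freq = pd.DataFrame([f2], index=[focal], columns=config.timepoints)
    clouds = synthetic.simulate_read_clouds(
        abundances, panel, cloud_cfg, seed=s_clouds, strain2_freq=strain2_freq
    )

    genes = []
    for sp in abundances.index:
        for g in range(config.genome_length // config.gene_length):
            genes.append({"gene": f"{sp}|g{g}", "species": sp})
    core_genes = pd.DataFrame(genes)

    paths = {
        "abundances.tsv": lambda p: abundances.to_csv(p, sep="\t"),
        "counts.tsv": lambda p: counts.to_tsv(p),
        "clouds.tsv": lambda p: clouds.to_tsv(p),
        "core_genes.tsv": lambda p: core_genes.to_csv(p, sep="\t", index=False),
        "truth.json": lambda p: Path(p).write_text(
            json.dumps(
                {"focal_species": focal, "strain2_frequency": f2.tolist(),
                 "timepoints": list(map(float, config.timepoints))},
                indent=1, sort_keys=True)
        ),
    }
    written = []
    for name, writer in paths.items():
        p = out / name
        writer(p)
        written.append(p)
    return written


def _stage_impurity(config: RunConfig, out: Path) -> list[Path]:
    clouds = read_clouds.ReadCloudSet.from_tsv(out / "clouds.tsv")
    model = read_clouds.fit_impurity_model(clouds)
    model.to_json(out / "impurity.json")
    spectrum = read_clouds.cloud_size_spectrum(clouds)
    spectrum.to_csv(out / "cloud_spectrum.tsv", sep="\t", index=False)
    return [out / "impurity.json", out / "cloud_spectrum.tsv"]


def _stage_snvdiff(config: RunConfig, out: Path) -> list[Path]:
    counts = snv.AlleleCountTable.from_tsv(out / "counts.tsv")
    counts, polarization = snv.polarize_by_cohort(counts)
    counts = snv.apply_inclusion_rule(counts, min_depth=config.min_depth)
    freqs = snv.estimate_frequencies(counts, config.min_depth)
    counts.to_tsv(out / "counts_polarized.tsv")

    t0 = counts.timepoints[0]
    rows = []
    flagged_union: dict = {}
    for t in counts.timepoints[1:]:
        res = snv.detect_snv_differences(counts, t0, t, alpha=config.alpha,
                                         fdr=config.fdr, min_depth=config.min_depth)
        for snv_id, r in res.flagged.iterrows():
            rows.append({"snv_id": snv_id, "t1": res.t1, "t2": res.t2,
                         "rising_allele": r["rising_allele"],
                         "f1": r["f1"], "f2": r["f2"], "declared": res.declared,
                         "ensemble_p": res.pvalue, "ensemble_fdr": res.fdr})
            if res.declared:
                flagged_union.setdefault(snv_id, r["rising_allele"])
    diffs = pd.DataFrame(rows, columns=["snv_id", "t1", "t2", "rising_allele",
                                        "f1", "f2", "declared", "ensemble_p",
                                        "ensemble_fdr"])
    diffs.to_csv(out / "snv_differences.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"snv_id": sorted(flagged_union),
         "rising_allele": [flagged_union[k] for k in sorted(flagged_union)]}
    ).to_csv(out / "temporally_variable.tsv", sep="\t", index=False)

    div = snv.intermediate_diversity(freqs, config.core_sites)
    div.rename("diversity").to_csv(out / "diversity.tsv", sep="\t")

    abundances = pd.read_csv(out / "abundances.tsv", sep="\t", index_col=0)
    base = abundances.iloc[:, 0].to_numpy()
    jsd = pd.Series(
        {float(c): snv.jensen_shannon_distance(abundances[c].to_numpy(), base)
         for c in abundances.columns}, name="jsd")
    jsd.to_csv(out / "jsd.tsv", sep="\t")
    return [out / p for p in ["counts_polarized.tsv", "snv_differences.tsv",
                              "temporally_variable.tsv", "diversity.tsv", "jsd.tsv"]]


def _stage_linkage(config: RunConfig, out: Path) -> list[Path]:
    clouds = read_clouds.ReadCloudSet.from_tsv(out / "clouds.tsv")
    model = read_clouds.fit_impurity_model(clouds)
    counts = snv.AlleleCountTable.from_tsv(out / "counts_polarized.tsv")
    calls = linkage.classify_pairs(
        counts.panel, clouds, model, min_shared=config.min_shared_clouds,
        screen_alpha=config.screen_alpha, alpha=config.alpha, maf_min=config.maf_min)
    calls.to_csv(out / "ld_calls.tsv", sep="\t", index=False)
    curve = linkage.sharing_by_distance(counts.panel, clouds)
    curve.to_csv(out / "sharing_by_distance.tsv", sep="\t", index=False)
    return [out / "ld_calls.tsv", out / "sharing_by_distance.tsv"]


def _stage_cluster(config: RunConfig, out: Path) -> list[Path]:
    counts = snv.AlleleCountTable.from_tsv(out / "counts_polarized.tsv")
    variable = pd.read_csv(out / "temporally_variable.tsv", sep="\t")["snv_id"].tolist()
    members_rows, traj_rows = [], []
    if variable:
        sub = counts.subset(variable)
        freqs = snv.estimate_frequencies(sub, config.min_depth)
        clusters = haplotype_clusters.cluster_snvs(
            freqs, sub.D, d_star=config.d_star,
            positions=sub.panel["pos"], counts_A=sub.A)
        for cid, cl in enumerate(clusters):
            for m in cl.members:
                members_rows.append({"snv_id": m, "cluster": cid,
                                     "flipped": bool(cl.flipped[m])})
            for t, a, d in zip(counts.timepoints, cl.A, cl.D):
                traj_rows.append({"cluster": cid, "timepoint": t,
                                  "A": a, "D": d})
    pd.DataFrame(members_rows, columns=["snv_id", "cluster", "flipped"]).to_csv(
        out / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame(traj_rows, columns=["cluster", "timepoint", "A", "D"]).to_csv(
        out / "cluster_trajectories.tsv", sep="\t", index=False)
    return [out / "clusters.tsv", out / "cluster_trajectories.tsv"]


def _stage_drift(config: RunConfig, out: Path, seed: int) -> list[Path]:
    traj = pd.read_csv(out / "cluster_trajectories.tsv", sep="\t")
    grid = selection_drift.FrequencyGrid()
    fits = {}
    sel_rows = []
    for k, (cid, sub) in enumerate(traj.groupby("cluster")):
        sub = sub.sort_values("timepoint")
        times = sub["timepoint"].to_numpy(dtype=float)
        A = np.round(sub["A"].to_numpy(dtype=float)).astype(int)
        D = np.round(sub["D"].to_numpy(dtype=float)).astype(int)
        A = np.minimum(A, D)
        fit = selection_drift.fit_drift(A, D, times, grid=grid)
        fit.pvalue = selection_drift.bootstrap_pvalue(
            A, D, times, fit, reps=config.bootstrap_reps, seed=seed + k, grid=grid)
        pw = selection_drift.fit_piecewise(A, D, times, config.antibiotic_window,
                                           grid=grid)
        fit.epoch_boundaries = pw.epoch_boundaries
        fit.epoch_ne = pw.epoch_ne
        fits[str(cid)] = fit.to_dict()
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(D > 0, A / np.maximum(D, 1), np.nan)
        for i in range(1, len(times)):
            if D[i - 1] <= 0 or D[i] <= 0:
                continue
            s = selection_drift.plugin_selection(
                f[i - 1], f[i], times[i] - times[i - 1],
                depth_prev=D[i - 1], depth_curr=D[i])
            sel_rows.append({"cluster": cid, "t1": times[i - 1], "t2": times[i],
                             "s_per_day": s})
    with open(out / "drift_fits.json", "w") as fh:
        json.dump(fits, fh, indent=1, sort_keys=True)
    pd.DataFrame(sel_rows, columns=["cluster", "t1", "t2", "s_per_day"]).to_csv(
        out / "selection.tsv", sep="\t", index=False)
    return [out / "drift_fits.json", out / "selection.tsv"]


def _stage_markers(config: RunConfig, out: Path) -> list[Path]:
    counts = snv.AlleleCountTable.from_tsv(out / "counts_polarized.tsv")
    var_df = pd.read_csv(out / "temporally_variable.tsv", sep="\t")
    variable = dict(zip(var_df["snv_id"], var_df["rising_allele"]))
    freqs = snv.estimate_frequencies(counts, config.min_depth)

    rows = []
    events = {}
    for species, panel_sp in counts.panel.groupby("species"):
        markers = marker_retention.identify_private_markers(panel_sp)
        var_sp = {v: a for v, a in variable.items() if v in panel_sp.index}
        if len(markers):
            cls = marker_retention.classify_markers(markers, freqs, var_sp)
        else:
            cls = marker_retention.MarkerClassification(
                species=species, n_preserved=0, n_disrupted=0, n_unclassified=0,
                labels=pd.Series(dtype=object))
        for snv_id, label in cls.labels.items():
            rows.append({"species": species, "snv_id": snv_id, "label": label})
        site_totals = panel_sp["degeneracy"].value_counts()
        dnds = (marker_retention.dn_ds(panel_sp.loc[list(var_sp)], site_totals)
                if var_sp else None)
        events[species] = {
            "n_preserved": cls.n_preserved,
            "n_disrupted": cls.n_disrupted,
            "n_unclassified": cls.n_unclassified,
            "n_snv_differences": len(var_sp),
            "dn_ds": dnds,
            "event": marker_retention.classify_event(
                cls.n_preserved, cls.n_disrupted, len(var_sp), dnds),
        }
    pd.DataFrame(rows, columns=["species", "snv_id", "label"]).to_csv(
        out / "markers.tsv", sep="\t", index=False)
    with open(out / "events.json", "w") as fh:
        json.dump(events, fh, indent=1, sort_keys=True)
    return [out / "markers.tsv", out / "events.json"]


def _stage_report(config: RunConfig, out: Path) -> list[Path]:
    summary = summarize_report(out, config)
    summary.to_csv(out / "summary.tsv", sep="\t")
    return [out / "summary.tsv"]


def summarize_report(outdir, config: RunConfig | None = None) -> pd.DataFrame:
    """Per-species summary across stage outputs.

    Columns: number of SNV differences, median and interquartile range of
    their initial frequencies, fraction retained at the final timepoint
    (f > 0.7), final-timepoint diversity, and the event label.
    """
    out = Path(outdir)
    config = config or RunConfig()
    counts = snv.AlleleCountTable.from_tsv(out / "counts_polarized.tsv")
    freqs = snv.estimate_frequencies(counts, config.min_depth)
    var_df = pd.read_csv(out / "temporally_variable.tsv", sep="\t")
    variable = dict(zip(var_df["snv_id"], var_df["rising_allele"]))
    events = {}
    if (out / "events.json").exists():
        events = json.loads((out / "events.json").read_text())

    t_first, t_last = counts.timepoints[0], counts.timepoints[-1]
    rows = []
    for species, panel_sp in counts.panel.groupby("species"):
        var_sp = [v for v in variable if v in panel_sp.index]
        if var_sp:
            flip = np.array([variable[v] == "ref" for v in var_sp])
            f1 = np.where(flip, 1 - freqs.loc[var_sp, t_first], freqs.loc[var_sp, t_first])
            f_end = np.where(flip, 1 - freqs.loc[var_sp, t_last], freqs.loc[var_sp, t_last])
            f1 = pd.Series(f1)
            med = float(f1.median())
            iqr = float(f1.quantile(0.75) - f1.quantile(0.25))
            retained = float(np.nanmean(f_end > 0.7))
        else:
            med = iqr = retained = 0.0
        rows.append({
            "species": species,
            "n_polymorphic": int(len(panel_sp)),
            "n_snv_differences": len(var_sp),
            "median_initial_frequency": med,
            "iqr_initial_frequency": iqr,
            "fraction_retained": retained,
            "event": events.get(species, {}).get("event", "none"),
        })
    return pd.DataFrame(rows).set_index("species")


def run_pipeline(config: RunConfig) -> Path:
    """Run all (non-skipped) stages and write a manifest; returns outdir."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    params = dataclasses.asdict(config)

    runners = {
        "simulate": lambda s: _stage_simulate(config, out, s),
        "impurity": lambda s: _stage_impurity(config, out),
        "snvdiff": lambda s: _stage_snvdiff(config, out),
        "linkage": lambda s: _stage_linkage(config, out),
        "cluster": lambda s: _stage_cluster(config, out),
        "drift": lambda s: _stage_drift(config, out, s),
        "markers": lambda s: _stage_markers(config, out),
        "report": lambda s: _stage_report(config, out),
    }
    for i, stage in enumerate(STAGES):
        if stage in config.skip:
            continue
        seed = _stage_seed(config, i)
        try:
            outputs = runners[stage](seed)
        except FileNotFoundError as exc:
            raise RuntimeError(f"stage '{stage}' is missing an input: {exc}") from exc
        manifest.record(stage, outputs, params, seed)
    manifest.write(out / "manifest.json")
    return out
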