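"""End-to-end pipeline: simulate/load -> normalize -> assemble ->
cluster -> consensus -> statistics -> report tables.

This module glues the stages together behind a single configuration
object and also houses the robustness sweep that compares the
consensus method's gate-placement variability against traditional
sequential gating (the headline robustness comparison).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .consensus import (
    ConsensusPopulations,
    anchor_and_merge,
    build_coassociation,
    consensus_partition,
)
from .errors import ParameterError
from .gating import GatingCriteria, gating_variation_study
from .highdim import density_peak_cluster, graph_community_cluster, som_cluster
from .io_model import (
    DatasetVariant,
    EventMatrix,
    SampleMeta,
    StudySet,
    TransformSpec,
    apply_transform,
    read_events,
    write_events_csv,
)
from .popstats import control_adjusted_tx, population_table
from .synthetic import reference_design, generate_study

#: low / default / high parameter presets for the clustering suite
PARAM_LEVELS = {
    "low": {"som_grid": (8, 8), "k_meta": 5, "graph_k": 15, "dp_k": 15},
    "default": {"som_grid": (10, 10), "k_meta": 7, "graph_k": 30, "dp_k": 30},
    "high": {"som_grid": (12, 12), "k_meta": 9, "graph_k": 45, "dp_k": 45},
}


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # synthetic | directory
    data_dir: str = ""
    out_dir: str = "cytoconsensus_out"
    seed: int = 42
    # synthetic design
    events_bead: int = 5000
    events_unlabeled: int = 20000
    events_labeled: int = 20000
    separation: str = "well_separated"
    mrc_fraction: float = 0.0
    batch_gain: float = 0.4
    batch_offset: float = 20.0
    # processing
    cofactor: float = 150.0
    normalize: bool = True
    peak_statistic: str = "median"
    gating_retentions: tuple[float, ...] = (0.995, 0.999, 1.0)
    level: str = "default"
    coassoc_subsample: int = 5000
    consensus_cut: float = 0.5
    anchor_fraction: float = 0.9
    similarity_threshold: float = 3.0
    b_requested: int = 100
    null_reps: int = 200
    embeddings: bool = True
    embed_max_events: int = 4000

    def validate(self) -> None:
        if self.mode not in ("synthetic", "directory"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.mode == "directory" and not os.path.isdir(self.data_dir):
            raise ParameterError(f"data_dir {self.data_dir!r} does not exist")
        if self.level not in PARAM_LEVELS:
            raise ParameterError(f"level must be one of {sorted(PARAM_LEVELS)}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str) -> PipelineConfig:
    """Parse a flat ``key = value`` config file."""
    cfg = PipelineConfig()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParameterError(f"bad config line: {raw.rstrip()}")
            key, value = (x.strip() for x in line.split("=", 1))
            if not hasattr(cfg, key):
                raise ParameterError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, value.lower() in ("1", "true", "yes", "on"))
            elif isinstance(current, int):
                setattr(cfg, key, int(value))
            elif isinstance(current, float):
                setattr(cfg, key, float(value))
            elif isinstance(current, tuple):
                setattr(cfg, key, tuple(float(v) for v in value.split(",")))
            else:
                setattr(cfg, key, value)
    cfg.validate()
    return cfg


def write_study(study: StudySet, out_dir: str, format: str = "csv") -> None:
    """Write one events file per sample plus a metadata table."""
    from .io_model import write_events_fcs

    if format not in ("csv", "fcs"):
        raise ParameterError(f"unknown study format {format!r}")
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for meta, m in study.samples:
        fname = f"{meta.sample_id}.{format}"
        if format == "csv":
            write_events_csv(os.path.join(out_dir, fname), m)
        else:
            write_events_fcs(os.path.join(out_dir, fname), m)
        rows.append({"sample_id": meta.sample_id,
                     "sample_type": meta.sample_type.value,
                     "stain_channel": meta.stain_channel or "",
                     "day": meta.day,
                     "passage": "" if meta.passage is None else meta.passage,
                     "file": fname})
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "metadata.csv"), index=False)


def load_study(data_dir: str) -> StudySet:
    meta_path = os.path.join(data_dir, "metadata.csv")
    if not os.path.isfile(meta_path):
        raise ParameterError(f"{data_dir}: missing metadata.csv")
    table = pd.read_csv(meta_path, keep_default_na=False)
    samples = []
    for _, row in table.iterrows():
        fname = str(row["file"])
        fmt = "fcs" if fname.lower().endswith(".fcs") else "csv"
        m = read_events(os.path.join(data_dir, fname), format=fmt)
        meta = SampleMeta(
            sample_id=str(row["sample_id"]),
            sample_type=str(row["sample_type"]),
            stain_channel=str(row["stain_channel"]) or None,
            day=int(row["day"]),
            passage=int(row["passage"]) if str(row["passage"]) != "" else None)
        samples.append((meta, m))
    return StudySet(samples)


def make_study(cfg: PipelineConfig) -> StudySet:
    if cfg.mode == "directory":
        return load_study(cfg.data_dir)
    design = reference_design(
        mrc_fraction=cfg.mrc_fraction, separation=cfg.separation,
        events_per_sample={"bead": cfg.events_bead,
                           "unlabeled": cfg.events_unlabeled,
                           "labeled": cfg.events_labeled},
        batch_gain=cfg.batch_gain, batch_offset=cfg.batch_offset)
    return generate_study(design, seed=cfg.seed)


def cluster_suite(m: EventMatrix, level: str = "default", seed: int = 0) -> list:
    """Run the three clusterers at one parameter level."""
    p = PARAM_LEVELS[level]
    return [
        som_cluster(m, grid=p["som_grid"], k_meta=p["k_meta"], seed=seed),
        graph_community_cluster(m, k_neighbors=p["graph_k"], seed=seed),
        density_peak_cluster(m, k_neighbors=p["dp_k"]),
    ]


def consensus_stage(
    m: EventMatrix,
    meta: pd.DataFrame,
    clusterings: list,
    cut: float = 0.5,
    coassoc_subsample: int = 5000,
    anchor_fraction: float = 0.9,
    similarity_threshold: float = 3.0,
    b_requested: int = 100,
    null_reps: int = 200,
    seed: int = 0,
) -> ConsensusPopulations:
    coassoc = build_coassociation(clusterings, subsample=coassoc_subsample, seed=seed)
    labels = consensus_partition(coassoc, cut=cut, m=m)
    return anchor_and_merge(
        m, labels, meta, anchor_fraction=anchor_fraction,
        similarity_threshold=similarity_threshold, B_requested=b_requested,
        null_reps=null_reps, seed=seed)


def run_consensus(
    study: StudySet,
    seed: int = 0,
    variant: DatasetVariant | None = None,
    level: str = "default",
    cut: float = 0.5,
    cofactor: float = 150.0,
    normalize: bool = True,
    coassoc_subsample: int = 5000,
    anchor_fraction: float = 0.9,
    similarity_threshold: float = 3.0,
    b_requested: int = 100,
    null_reps: int = 200,
    cd45_threshold: float | None = None,
) -> tuple[ConsensusPopulations, EventMatrix, pd.DataFrame]:
    """Normalize, transform, assemble one variant, cluster, and build the
    consensus populations. Returns (populations, transformed matrix, meta)."""
    from .io_model import assemble_dataset
    from .normalization import normalize_study

    if normalize:
        study, _ = normalize_study(study)
    variant = variant or DatasetVariant(include_beads="all", cells="all")
    pooled, meta = assemble_dataset(study, variant,
                                    cd45_threshold=cd45_threshold, seed=seed)
    t = apply_transform(pooled, TransformSpec(cofactor=cofactor))
    clusterings = cluster_suite(t, level=level, seed=seed)
    pops = consensus_stage(
        t, meta, clusterings, cut=cut, coassoc_subsample=coassoc_subsample,
        anchor_fraction=anchor_fraction, similarity_threshold=similarity_threshold,
        b_requested=b_requested, null_reps=null_reps, seed=seed)
    return pops, t, meta


def labeled_population_counts(pops: ConsensusPopulations) -> pd.Series:
    """Event counts of the labeled-cell populations, largest first."""
    sel = np.array([pops.roles.get(name) == "labeled_population"
                    for name in pops.labels])
    return pd.Series(pops.labels[sel]).value_counts()


def robustness_sweep(
    study: StudySet,
    levels: tuple[str, ...] = ("low", "default", "high"),
    cuts: tuple[float, ...] = (0.4, 0.5, 0.6),
    seed: int = 0,
    normalize: bool = True,
    coassoc_subsample: int = 3000,
    b_requested: int = 50,
    null_reps: int = 100,
) -> pd.DataFrame:
    """Consensus labeled-population counts over parameter level x cut.

    Clusterings are computed once per level and re-cut, mirroring a user
    re-running the consensus stage under different settings. Counts are
    matched across runs by descending-size rank (runs may produce
    different population namings), padded with zeros.
    """
    from .io_model import assemble_dataset
    from .normalization import normalize_study

    if normalize:
        study, _ = normalize_study(study)
    pooled, meta = assemble_dataset(
        study, DatasetVariant(include_beads="all", cells="all"), seed=seed)
    t = apply_transform(pooled, TransformSpec())
    runs = {}
    for level in levels:
        clusterings = cluster_suite(t, level=level, seed=seed)
        coassoc = build_coassociation(clusterings, subsample=coassoc_subsample,
                                      seed=seed)
        for cut in cuts:
            labels = consensus_partition(coassoc, cut=cut, m=t)
            pops = anchor_and_merge(t, labels, meta, B_requested=b_requested,
                                    null_reps=null_reps, seed=seed)
            counts = labeled_population_counts(pops)
            runs[f"{level}_cut{cut}"] = counts.to_numpy()
    width = max(len(v) for v in runs.values())
    padded = {k: np.r_[v, np.zeros(width - len(v))] for k, v in runs.items()}
    return pd.DataFrame(padded, index=[f"rank_{i + 1}" for i in range(width)])


def sweep_mean_cv(sweep: pd.DataFrame) -> float:
    """Mean CV (%) of labeled-population counts due to cut placement.

    Mirrors the robustness comparison's structure: within each parameter
    level, the CV of rank-matched counts across cut perturbations (the
    formalized stand-in for a user re-placing gates), averaged over
    levels and populations.
    """
    levels = sorted({c.rsplit("_cut", 1)[0] for c in sweep.columns})
    cvs = []
    for level in levels:
        cols = [c for c in sweep.columns if c.rsplit("_cut", 1)[0] == level]
        block = sweep[cols]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        cvs.append(100.0 * sd[mean > 0] / mean[mean > 0])
    return float(pd.concat(cvs).mean())


def traditional_mean_cv(study: StudySet,
                        retentions: tuple[float, ...] = (0.995, 0.999, 1.0),
                        normalize: bool = True) -> float:
    from .normalization import normalize_study

    if normalize:
        study, _ = normalize_study(study)
    res = gating_variation_study(
        study, [GatingCriteria(retention=r) for r in retentions])
    return res.mean_cv_percent


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Outputs (CSV unless noted): normalization model report, traditional
    gating variation table, consensus labels + audit (JSON) for the
    all-cells and CD45-negative variants, per-channel control-adjusted
    T(x) tables, marker-positivity phenotype calls, and the
    population-by-passage table (CSV + aligned text).
    """
    from .gating import quantile_gate
    from .io_model import SampleType
    from .normalization import normalize_study

    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    stamp = {"config_hash": cfg.hash(), "seed": cfg.seed}

    study = make_study(cfg)
    if cfg.normalize:
        study, norm_report = normalize_study(study, statistic=cfg.peak_statistic)
        norm_report.to_csv(os.path.join(cfg.out_dir, "normalization_report.csv"),
                           index=False)

    var = gating_variation_study(
        study, [GatingCriteria(retention=r) for r in cfg.gating_retentions])
    gate_tab = var.counts.copy()
    gate_tab["cv_percent"] = var.cv_percent
    gate_tab.to_csv(os.path.join(cfg.out_dir, "gating_variation.csv"))

    unl = [m.channel("CD45") for _, m in study.select(SampleType.unlabeled_cells)]
    cd45_cut = quantile_gate(unl, retention=0.999, channel="CD45").cutoff

    results = {}
    variants = {
        "all_cells": (DatasetVariant(include_beads="all", cells="all"), None),
        "cd45neg_cells": (DatasetVariant(include_beads="all",
                                         cells="gated_cd45neg",
                                         drop_cd45_channel=True), cd45_cut),
    }
    for name, (variant, thr) in variants.items():
        pops, t, meta = run_consensus(
            study, seed=cfg.seed, variant=variant, level=cfg.level,
            cut=cfg.consensus_cut, cofactor=cfg.cofactor, normalize=False,
            coassoc_subsample=cfg.coassoc_subsample,
            anchor_fraction=cfg.anchor_fraction,
            similarity_threshold=cfg.similarity_threshold,
            b_requested=cfg.b_requested, null_reps=cfg.null_reps,
            cd45_threshold=thr)
        out = meta.copy()
        out["population"] = pops.labels
        out.to_csv(os.path.join(cfg.out_dir, f"consensus_labels_{name}.csv"),
                   index=False)
        with open(os.path.join(cfg.out_dir, f"consensus_audit_{name}.json"), "w") as fh:
            json.dump({**stamp, "audit": pops.audit}, fh, indent=1, default=str)
        results[name] = (pops, t, meta)

    pops, t, meta = results["all_cells"]
    stats_rows = []
    lab_sel = (meta["sample_type"] == "labeled_cells").to_numpy()
    unl_by_day = {int(d): t.values[(meta["sample_type"] == "unlabeled_cells").to_numpy()
                                   & (meta["day"] == d).to_numpy()]
                  for d in sorted(meta["day"].unique())}
    for ch_i, ch in enumerate(t.panel.channels):
        pops_ch = {name: t.values[(pops.labels == name) & lab_sel, ch_i]
                   for name in pops.roles
                   if pops.roles[name] == "labeled_population"
                   and ((pops.labels == name) & lab_sel).sum() >= 30}
        controls = {}
        for stain in sorted(x for x in meta["stain_channel"].unique() if x):
            sel = (meta["stain_channel"] == stain).to_numpy()
            controls[f"beads_{stain}"] = {
                int(d): t.values[sel & (meta["day"] == d).to_numpy(), ch_i]
                for d in sorted(meta["day"].unique())}
        adj = control_adjusted_tx(
            pops_ch, {d: v[:, ch_i] for d, v in unl_by_day.items()},
            controls, channel=ch, B_requested=cfg.b_requested,
            null_reps=cfg.null_reps)
        for name, tx in adj.population_tx.items():
            stats_rows.append({"channel": ch, "population": name, "tx": tx,
                               "control_level": adj.control_variability,
                               "adjusted": adj.adjusted[name],
                               "significant": adj.significant[name],
                               "excluded_controls": ",".join(adj.excluded_controls)})
    pd.DataFrame(stats_rows).to_csv(
        os.path.join(cfg.out_dir, "tx_per_channel.csv"), index=False)

    # overall (all-channel) day-to-day T(x) per control, with bin counts
    from .popstats import tx_compare

    overall_rows = []
    days = sorted(meta["day"].unique())[:2]
    controls_all = {"unlabeled_cells":
                    (meta["sample_type"] == "unlabeled_cells").to_numpy()}
    for stain in sorted(x for x in meta["stain_channel"].unique() if x):
        controls_all[f"beads_{stain}"] = (meta["stain_channel"] == stain).to_numpy()
    for name, sel in controls_all.items():
        byday = [t.values[sel & (meta["day"] == d).to_numpy()] for d in days]
        r = tx_compare(byday[0], byday[1], B_requested=cfg.b_requested * 10,
                       null_reps=cfg.null_reps)
        overall_rows.append({"control": name, "tx": r.tx, "bins": r.B,
                             "events_day1": r.n_control,
                             "events_day2": r.n_test})
    pd.DataFrame(overall_rows).to_csv(
        os.path.join(cfg.out_dir, "tx_overall_controls.csv"), index=False)

    # marker positivity -> phenotype per labeled population
    from .io_model import EventMatrix as _EM
    from .popstats import marker_positivity

    unl_em = {d: _EM(v, t.panel, t.scale) for d, v in unl_by_day.items()}
    ctl_em = {}
    for stain in sorted(x for x in meta["stain_channel"].unique() if x):
        sel = (meta["stain_channel"] == stain).to_numpy()
        ctl_em[f"beads_{stain}"] = {
            int(d): _EM(t.values[sel & (meta["day"] == d).to_numpy()],
                        t.panel, t.scale)
            for d in days}
    pheno_rows = []
    for name, role in pops.roles.items():
        if role != "labeled_population":
            continue
        sel = (pops.labels == name) & lab_sel
        if sel.sum() < 30:
            continue
        call = marker_positivity(_EM(t.values[sel], t.panel, t.scale),
                                 unl_em, ctl_em,
                                 B_requested=cfg.b_requested,
                                 null_reps=cfg.null_reps)
        pheno_rows.append({"population": name, "phenotype": call.phenotype,
                           **{f"{ch}_positive": call.positive[ch]
                              for ch in t.panel.channels}})
    pd.DataFrame(pheno_rows).to_csv(
        os.path.join(cfg.out_dir, "phenotypes.csv"), index=False)

    if cfg.embeddings:
        from .consensus import ConsensusPopulations, cross_embedding_consistency
        from .highdim import embed_suite

        rng = np.random.default_rng(cfg.seed)
        n = t.n_events
        sub = np.sort(rng.choice(n, size=min(cfg.embed_max_events, n),
                                 replace=False))
        emb = embed_suite(t.take(sub), algorithms=("tsne", "umap"),
                          seed=cfg.seed)
        sub_pops = ConsensusPopulations(labels=pops.labels[sub],
                                        roles=pops.roles)
        scores = cross_embedding_consistency(sub_pops, emb)
        pd.Series(scores, name="island_consistency").rename_axis(
            "population").to_csv(
            os.path.join(cfg.out_dir, "embedding_consistency.csv"))

    lab_mask = lab_sel & np.array(
        [pops.roles.get(name) == "labeled_population" for name in pops.labels])
    table = population_table(pops.labels[lab_mask],
                             meta["passage"].to_numpy()[lab_mask])
    table.table.to_csv(os.path.join(cfg.out_dir, "population_table.csv"),
                       index=False)
    with open(os.path.join(cfg.out_dir, "population_table.txt"), "w") as fh:
        fh.write(table.to_text() + "\n")
    with open(os.path.join(cfg.out_dir, "run.json"), "w") as fh:
        json.dump({**stamp, "n_populations": len(pops.roles),
                   "mean_gating_cv_percent": var.mean_cv_percent}, fh, indent=1)
    return {"populations": pops, "population_table": table,
            "gating_variation": var, "config_hash": cfg.hash()}
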