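"""End-to-end orchestration: simulate/load -> secretome -> reporter array
-> network -> integration, with one master seed and a single run report.

Every stage writes its tabular output under the run directory, and the
report records only numbers traceable to those files.  Identical config +
seed yields byte-identical outputs (no timestamps in the report).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._seeds import substream_int
from .cluster import cluster_profiles
from .moderated import ModeratedActivityModel
from .network import (InteractionNetwork, identify_candidates, overlap_enrichment,
                      predict_downstream_tfs)
from .secretome import (SpectralCountMatrix, assemble_candidate_pool, compute_nsaf,
                        differential_abundance, partition_identifications,
                        secretome_stats_table)
from .simulate import (ConfigError, GroundTruth, NetworkSimConfig, PlantedCluster,
                       SecretomeSimConfig, StudySimConfig, TracerSimConfig,
                       simulate_study)
from .tracer import ReporterPlateSet, background_filter, normalize_activity, remove_outliers

__all__ = ["PipelineConfig", "RunReport", "validate_config", "load_config", "run_pipeline"]

log = logging.getLogger("secretracer")


@dataclass
class StageParams:
    """All tunable stage parameters with their documented defaults."""

    alpha_secr: float = 0.10        # secretome t-test level ("90% significance")
    lfc_threshold: float = 1.5      # |log2FC| cut for the significant flag
    test_scale: str = "log"         # t-test on log2(NSAF+eps) or raw NSAF
    min_detect_reps: int = 1        # replicates with Spc>0 to call detected
    target: str = "diseased"
    reference: str = "healthy"
    treated: str = "treated"
    control: str = "control"
    alpha_bg: float = 0.05          # below-background filter level
    alpha_out: float = 0.003        # replicate outlier level
    alpha_adj: float = 0.05         # BH-adjusted activity call level
    prior_proportion: float = 0.01  # assumed DE proportion for the B statistic
    moderate: bool = True
    k_min: int = 1
    k_max: int = 10
    n_starts: int = 50
    n_perm: int = 100
    expansion_depth: int = 1
    max_signaling_hops: int = 1
    universe: str = "panel"         # Fisher universe: reporter panel | network tfs

    _BOUNDS = {
        "alpha_secr": (0.0, 1.0), "alpha_bg": (0.0, 1.0), "alpha_out": (0.0, 1.0),
        "alpha_adj": (0.0, 1.0), "prior_proportion": (0.0, 1.0),
        "lfc_threshold": (0.0, float("inf")),
    }

    def validate(self) -> None:
        for name, (lo, hi) in self._BOUNDS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigError(f"{name}={v} outside [{lo}, {hi}]")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ConfigError(f"need 1 <= k_min <= k_max, got [{self.k_min}, {self.k_max}]")
        if self.n_starts < 1 or self.n_perm < 1:
            raise ConfigError("n_starts and n_perm must be >= 1")
        if self.min_detect_reps < 1:
            raise ConfigError("min_detect_reps must be >= 1")
        if self.expansion_depth < 0 or self.max_signaling_hops < 0:
            raise ConfigError("expansion_depth and max_signaling_hops must be >= 0")
        if self.universe not in ("panel", "network"):
            raise ConfigError(f"universe must be 'panel' or 'network', got {self.universe!r}")
        if self.test_scale not in ("log", "linear"):
            raise ConfigError(f"test_scale must be 'log' or 'linear', got {self.test_scale!r}")


@dataclass
class InputPaths:
    counts_tsv: str | None = None
    annotation_tsv: str | None = None
    plates_csv: str | None = None
    edges_tsv: str | None = None
    nodes_tsv: str | None = None
    ground_truth_json: str | None = None


@dataclass
class PipelineConfig:
    simulate: StudySimConfig | None = field(default_factory=StudySimConfig)
    inputs: InputPaths = field(default_factory=InputPaths)
    params: StageParams = field(default_factory=StageParams)
    seed: int = 0
    outdir: str = "secretracer_run"

    def config_hash(self) -> str:
        # hash the scientific configuration, not file locations
        doc = _as_plain(self)
        doc.pop("outdir", None)
        doc.pop("inputs", None)
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in obj.__dict__.items()}
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, set):
        return sorted(obj)
    return obj


def _build(cls, doc: dict, where: str, strict: bool):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(doc) - names
    if unknown:
        msg = f"unknown key(s) in {where}: {sorted(unknown)}"
        if strict:
            raise ConfigError(msg)
        log.warning(msg)
        doc = {k: v for k, v in doc.items() if k in names}
    return cls(**doc)


def validate_config(doc: dict | PipelineConfig | None, strict: bool = True) -> PipelineConfig:
    """Fill defaults, check ranges, and return an effective config.

    An empty document yields the full default config.  Unknown keys raise
    in strict mode and warn otherwise.
    """
    if isinstance(doc, PipelineConfig):
        cfg = doc
    else:
        doc = dict(doc or {})
        sim_doc = doc.pop("simulate", {})
        inputs_doc = doc.pop("inputs", {})
        params_doc = doc.pop("params", {})
        top = _build(PipelineConfig, doc, "pipeline", strict)
        if sim_doc is None:
            top.simulate = None
        else:
            sim_doc = dict(sim_doc)
            sec = _build(SecretomeSimConfig, sim_doc.pop("secretome", {}), "simulate.secretome", strict)
            tra_doc = dict(sim_doc.pop("tracer", {}))
            if "planted_clusters" in tra_doc:
                tra_doc["planted_clusters"] = [
                    pc if isinstance(pc, PlantedCluster) else PlantedCluster(**pc)
                    for pc in tra_doc["planted_clusters"]
                ]
            tra = _build(TracerSimConfig, tra_doc, "simulate.tracer", strict)
            net_doc = dict(sim_doc.pop("network", {}))
            if "planted_chains" in net_doc:
                net_doc["planted_chains"] = [tuple(c) for c in net_doc["planted_chains"]]
            net = _build(NetworkSimConfig, net_doc, "simulate.network", strict)
            top.simulate = _build(
                StudySimConfig,
                {**sim_doc, "secretome": sec, "tracer": tra, "network": net},
                "simulate", strict)
        top.inputs = _build(InputPaths, dict(inputs_doc or {}), "inputs", strict)
        top.params = _build(StageParams, dict(params_doc or {}), "params", strict)
        cfg = top

    cfg.params.validate()
    if cfg.simulate is not None:
        cfg.simulate.seed = cfg.seed
        cfg.simulate.secretome.target = cfg.params.target
        cfg.simulate.secretome.reference = cfg.params.reference
        cfg.simulate.tracer.treated = cfg.params.treated
        cfg.simulate.tracer.control = cfg.params.control
        cfg.simulate.validate()
        cfg.simulate.secretome.validate()
        cfg.simulate.tracer.validate()
        cfg.simulate.network.validate()
    else:
        need = ("counts_tsv", "annotation_tsv", "plates_csv", "edges_tsv", "nodes_tsv")
        missing = [k for k in need if getattr(cfg.inputs, k) is None]
        if missing:
            raise ConfigError(f"no simulation configured and inputs missing: {missing}")
    return cfg


def load_config(path, strict: bool = True) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return validate_config(doc, strict=strict)


@dataclass
class RunReport:
    """Headline numbers of one pipeline run, all traceable to stage files."""

    config_hash: str
    seed: int
    version: str
    n_detected: int
    n_shared: int
    n_exclusive_target: int
    n_exclusive_reference: int
    n_significant: int
    pool_size: int
    n_pool_shared: int
    n_pool_exclusive: int
    n_reporters: int
    n_active_reporters: int
    d0: float
    s0_sq: float
    chosen_k: int
    top_cluster_size: int
    n_predicted_tfs: int
    overlap: int
    fisher_p: float
    n_candidates: int
    top_candidate: str | None
    recovery: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    def summary(self) -> str:
        r = self
        lines = [
            "secreted-factor discovery run",
            "=" * 42,
            f"config {r.config_hash}  seed {r.seed}  secretracer {r.version}",
            "",
            "secretome:",
            f"  detected proteins          {r.n_detected}",
            f"  shared / target-only / ref-only  {r.n_shared} / "
            f"{r.n_exclusive_target} / {r.n_exclusive_reference}",
            f"  significant (t + fold cut) {r.n_significant}",
            f"  candidate pool             {r.pool_size} "
            f"({r.n_pool_shared} shared + {r.n_pool_exclusive} exclusive)",
            "reporter array:",
            f"  reporters                  {r.n_reporters}",
            f"  active (BH p < alpha)      {r.n_active_reporters}",
            f"  variance prior d0, s0^2    {r.d0:.4g}, {r.s0_sq:.4g}",
            f"  clusters (chosen k)        {r.chosen_k}; top cluster {r.top_cluster_size} reporters",
            "network:",
            f"  predicted downstream TFs   {r.n_predicted_tfs}",
            f"  overlap with top cluster   {r.overlap} (Fisher p = {r.fisher_p:.3g})",
            f"  candidate ligands          {r.n_candidates}; top: {r.top_candidate}",
        ]
        if r.recovery:
            lines.append("ground-truth recovery:")
            for k, v in sorted(r.recovery.items()):
                lines.append(f"  {k:26s} {v}")
        return "\n".join(lines)


def _load_inputs(cfg: PipelineConfig):
    p = cfg.inputs
    scm = SpectralCountMatrix.from_tsv(p.counts_tsv)
    annot = pd.read_csv(p.annotation_tsv, sep="\t").set_index("protein_id")["secreted"]
    plates = ReporterPlateSet.from_csv(p.plates_csv)
    net = InteractionNetwork.from_tsv(p.edges_tsv, p.nodes_tsv)
    truth = GroundTruth.from_json(p.ground_truth_json) if p.ground_truth_json else None
    return scm, annot, plates, net, truth


def run_pipeline(cfg: PipelineConfig | dict | None = None, strict: bool = True) -> RunReport:
    """Execute all stages in order and write outputs + report to outdir."""
    cfg = validate_config(cfg if cfg is not None else {}, strict=strict)
    pp = cfg.params
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    try:
        stage = "simulate"
        if cfg.simulate is not None:
            log.info("simulating study inputs (seed %d)", cfg.seed)
            scm, annot, plates, net, truth = simulate_study(cfg.simulate)
            scm.to_tsv(out / "counts.tsv")
            annot.rename("secreted").rename_axis("protein_id").reset_index().to_csv(
                out / "annotation.tsv", sep="\t", index=False)
            plates.to_csv(out / "plates.csv")
            net.to_tsv(out / "edges.tsv", out / "nodes.tsv")
            truth.to_json(out / "ground_truth.json")
        else:
            log.info("loading study inputs")
            scm, annot, plates, net, truth = _load_inputs(cfg)

        stage = "secretome"
        nsaf = compute_nsaf(scm)
        part = partition_identifications(scm, min_detect_reps=pp.min_detect_reps)
        stats_tab = differential_abundance(
            nsaf, scm, part, pp.target, pp.reference,
            alpha=pp.alpha_secr, lfc_threshold=pp.lfc_threshold, scale=pp.test_scale)
        pool = assemble_candidate_pool(part, annot, pp.target, stats_tab)
        full_tab = secretome_stats_table(scm, nsaf, part, stats_tab, annot, pool)
        full_tab.reset_index().to_csv(out / "secretome_stats.tsv", sep="\t", index=False)
        log.info("secretome: %d detected, pool %d", len(part.detected), len(pool))

        stage = "tracer"
        filtered = background_filter(plates, alpha_bg=pp.alpha_bg)
        profiles = normalize_activity(filtered, pp.treated, pp.control)
        profiles = remove_outliers(profiles, alpha_out=pp.alpha_out)
        profiles.to_tsv(out / "activity.tsv")
        results = ModeratedActivityModel(
            profiles, moderate=pp.moderate, prior_proportion=pp.prior_proportion
        ).fit(alpha_adj=pp.alpha_adj)
        results.to_tsv(out / "reporter_stats.tsv")
        clust = cluster_profiles(
            profiles, k_range=range(pp.k_min, pp.k_max + 1),
            n_starts=pp.n_starts, n_perm=pp.n_perm,
            seed=substream_int(cfg.seed, "pipeline-cluster"))
        clust.assignments().reset_index().to_csv(out / "clusters.tsv", sep="\t", index=False)
        with open(out / "cluster_curves.json", "w") as fh:
            json.dump(clust.curves_dict(), fh, indent=2, sort_keys=True)
        log.info("tracer: %d active reporters, k=%d", len(results.active_reporters), clust.k)

        stage = "network"
        ligand_nodes = net.nodes_of_type("ligand")
        ligands = sorted(pool.ids & ligand_nodes)
        ltf = predict_downstream_tfs(
            net, ligands, expansion_depth=pp.expansion_depth,
            max_signaling_hops=pp.max_signaling_hops)
        ltf.to_tsv(out / "ligand_tf_map.tsv")
        universe = set(clust.labels.index) if pp.universe == "panel" else net.nodes_of_type("tf")
        top_members = set(clust.top_cluster_members()) & universe
        enr = overlap_enrichment(ltf.all_predicted_tfs(), top_members, universe)
        with open(out / "enrichment.json", "w") as fh:
            json.dump(enr.to_dict(), fh, indent=2, sort_keys=True)

        stage = "integrate"
        evidence = pool.table.copy()
        evidence["mean_nsaf"] = full_tab[f"mean_nsaf_{pp.target}"].reindex(evidence.index)
        candidates = identify_candidates(ltf, enr.overlap_tfs, evidence)
        candidates.reset_index().to_csv(out / "candidates.tsv", sep="\t", index=False)

        recovery: dict = {}
        if truth is not None:
            if truth.planted_up_proteins:
                rec = truth.planted_up_proteins & pool.ids
                recovery["pool_sensitivity"] = round(len(rec) / len(truth.planted_up_proteins), 4)
            if truth.planted_active_reporters:
                act = set(results.active_reporters)
                recovery["active_sensitivity"] = round(
                    len(truth.planted_active_reporters & act)
                    / len(truth.planted_active_reporters), 4)
            if truth.planted_cluster_count:
                recovery["planted_k"] = truth.planted_cluster_count
                recovery["k_recovered"] = bool(clust.k == truth.planted_cluster_count)
            if truth.planted_chains:
                planted_ligands = [c[0] for c in truth.planted_chains]
                ranks = [int(candidates.loc[l, "rank"]) if l in candidates.index else None
                         for l in planted_ligands]
                recovery["planted_ligand_ranks"] = ranks

        report = RunReport(
            config_hash=cfg.config_hash(), seed=cfg.seed, version=__version__,
            n_detected=len(part.detected), n_shared=len(part.shared),
            n_exclusive_target=len(part.exclusive[pp.target]),
            n_exclusive_reference=len(part.exclusive[pp.reference]),
            n_significant=int(stats_tab["significant"].sum()),
            pool_size=len(pool),
            n_pool_shared=int((pool.table["provenance"] == "shared").sum()),
            n_pool_exclusive=int((pool.table["provenance"] == "exclusive").sum()),
            n_reporters=len(clust.labels), n_active_reporters=len(results.active_reporters),
            d0=results.d0, s0_sq=results.s0_sq,
            chosen_k=clust.k, top_cluster_size=len(clust.top_cluster_members()),
            n_predicted_tfs=len(ltf.all_predicted_tfs()),
            overlap=enr.overlap, fisher_p=enr.pvalue,
            n_candidates=len(candidates),
            top_candidate=candidates.index[0] if len(candidates) else None,
            recovery=recovery,
        )
        report.to_json(out / "report.json")
        (out / "summary.txt").write_text(report.summary() + "\n")
        log.info("done: %d candidates, top %s", report.n_candidates, report.top_candidate)
        return report
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
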