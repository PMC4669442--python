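"""Synthetic study generators with planted ground truth.

Three generators emulate the three inputs of the secreted-factor
discovery pipeline, each a pure function of its config (including seed):

* ``simulate_secretome`` — negative-binomial spectral counts over two
  conditions (diseased/healthy conditioned media) with replicates,
  lognormal protein lengths, a secreted-annotation column, planted
  up-regulated secreted proteins, and structurally condition-exclusive
  proteins (all-zero counts in exactly one condition).
* ``simulate_tracer`` — reporter-plate luminescence time courses with
  non-infected background wells, TA basal-promoter control wells, and
  planted temporally coherent reporter clusters (ramp / pulse / flat /
  decline profiles) under multiplicative lognormal noise.
* ``simulate_network`` — a random typed ligand/receptor/signaling/tf
  graph with admissible edge types only, plus planted
  ligand -> receptor -> tf chains.

``simulate_study`` wires the three together so that ligand node ids are
secreted protein ids and tf node ids are reporter names, planting chains
from up-regulated secreted proteins to active reporters of the most
active planted cluster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._seeds import substream
from .network import InteractionNetwork
from .secretome import SpectralCountMatrix
from .tracer import ReporterPlateSet

__all__ = [
    "ConfigError",
    "SecretomeSimConfig",
    "TracerSimConfig",
    "PlantedCluster",
    "NetworkSimConfig",
    "StudySimConfig",
    "GroundTruth",
    "simulate_secretome",
    "simulate_tracer",
    "simulate_network",
    "simulate_study",
]

PROFILE_SHAPES = ("ramp", "pulse", "flat", "decline")


class ConfigError(ValueError):
    """Raised when a simulation config violates one of its invariants."""


# ---------------------------------------------------------------------------
# configs


@dataclass
class SecretomeSimConfig:
    """Defaults mirror the study scale: three replicates of conditioned
    media per condition, ~615 detected proteins of which 101/139 are
    exclusive to the diseased/healthy condition, ~30% secreted."""

    n_proteins: int = 615
    n_replicates: int = 3
    frac_secreted: float = 0.30
    n_planted_up: int = 10
    planted_log2fc: float = 2.0
    n_exclusive_diseased: int = 101
    n_exclusive_healthy: int = 139
    mean_count: float = 50.0
    dispersion: float = 0.1
    length_log_mean: float = 6.0
    length_log_sd: float = 0.6
    seed: int = 0
    target: str = "diseased"
    reference: str = "healthy"

    def validate(self) -> None:
        for name in ("n_proteins", "n_replicates", "n_planted_up",
                     "n_exclusive_diseased", "n_exclusive_healthy"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.frac_secreted <= 1.0:
            raise ConfigError("frac_secreted must be in [0, 1]")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2 for downstream testing")
        if self.n_planted_up > self.frac_secreted * self.n_proteins:
            raise ConfigError("n_planted_up exceeds the number of secreted proteins")
        n_special = (self.n_planted_up + self.n_exclusive_diseased + self.n_exclusive_healthy)
        if n_special > self.n_proteins:
            raise ConfigError("planted + exclusive proteins exceed n_proteins")
        if self.mean_count <= 0 or self.dispersion <= 0:
            raise ConfigError("mean_count and dispersion must be positive")


@dataclass
class PlantedCluster:
    """A set of reporter indices sharing one temporal profile."""

    members: tuple[int, ...]
    shape: str
    amplitude: float

    def __post_init__(self) -> None:
        self.members = tuple(int(m) for m in self.members)
        if self.shape not in PROFILE_SHAPES:
            raise ConfigError(f"unknown profile shape {self.shape!r}; use one of {PROFILE_SHAPES}")
        if not np.isfinite(self.amplitude):
            raise ConfigError("cluster amplitude must be finite")


def _default_planted_clusters() -> list[PlantedCluster]:
    # 35 of 52 reporters active across four temporally distinct clusters,
    # most-active first; remaining 17 reporters stay at baseline.
    return [
        PlantedCluster(tuple(range(0, 10)), "ramp", 2.0),
        PlantedCluster(tuple(range(10, 19)), "pulse", 1.5),
        PlantedCluster(tuple(range(19, 27)), "decline", 1.0),
        PlantedCluster(tuple(range(27, 35)), "flat", 0.5),
    ]


@dataclass
class TracerSimConfig:
    """Defaults mirror the assay layout: 52 reporters, 5 reads at 2-hour
    spacing over 8 hours, 4 replicate wells per reporter/condition."""

    n_reporters: int = 52
    n_timepoints: int = 5
    timepoint_spacing: float = 2.0
    n_replicates: int = 4
    n_background_wells: int = 4
    n_ta_wells: int = 4
    planted_clusters: list[PlantedCluster] = field(default_factory=_default_planted_clusters)
    noise_log_sd: float = 0.15
    background_level: float = 100.0
    ta_level: float = 10000.0
    basal_log_sd: float = 0.5
    n_plates: int = 1
    seed: int = 0
    treated: str = "treated"
    control: str = "control"

    def validate(self) -> None:
        if self.n_timepoints < 2:
            raise ConfigError("n_timepoints must be >= 2")
        if self.n_reporters < 1 or self.n_replicates < 1 or self.n_plates < 1:
            raise ConfigError("n_reporters, n_replicates and n_plates must be >= 1")
        if self.n_background_wells < 1:
            raise ConfigError(
                "n_background_wells must be >= 1: without background wells the "
                "downstream background filter is impossible")
        if self.n_ta_wells < 1:
            raise ConfigError("n_ta_wells must be >= 1 (TA normalization impossible)")
        seen: set[int] = set()
        for pc in self.planted_clusters:
            if not all(0 <= m < self.n_reporters for m in pc.members):
                raise ConfigError(f"cluster members out of range: {pc.members}")
            if seen & set(pc.members):
                raise ConfigError("planted cluster memberships must be disjoint")
            seen |= set(pc.members)
        if self.noise_log_sd < 0 or self.background_level <= 0 or self.ta_level <= 0:
            raise ConfigError("noise_log_sd >= 0 and positive flux levels required")


@dataclass
class NetworkSimConfig:
    """Sparse random typed graph; admissible edges are ligand->receptor,
    receptor->signaling, receptor->tf, signaling->tf and tf->tf."""

    n_ligands: int = 40
    n_receptors: int = 30
    n_signaling: int = 20
    n_tfs: int = 52
    edge_density: float = 0.003
    planted_chains: list[tuple[str, str, str]] = field(default_factory=list)
    ligand_ids: list[str] | None = None
    receptor_ids: list[str] | None = None
    signaling_ids: list[str] | None = None
    tf_ids: list[str] | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_ligands", "n_receptors", "n_signaling", "n_tfs"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ConfigError("edge_density must be in [0, 1]")
        for ids, n, name in (
            (self.ligand_ids, self.n_ligands, "ligand_ids"),
            (self.receptor_ids, self.n_receptors, "receptor_ids"),
            (self.signaling_ids, self.n_signaling, "signaling_ids"),
            (self.tf_ids, self.n_tfs, "tf_ids"),
        ):
            if ids is not None and len(ids) != n:
                raise ConfigError(f"{name} length must equal its node count ({n})")


@dataclass
class GroundTruth:
    """Planted structure common to all generators."""

    planted_up_proteins: set[str] = field(default_factory=set)
    planted_active_reporters: set[str] = field(default_factory=set)
    planted_cluster_count: int = 0
    planted_chains: list[tuple[str, str, str]] = field(default_factory=list)
    exclusive_proteins: dict[str, list[str]] = field(default_factory=dict)

    def merged_with(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            planted_up_proteins=self.planted_up_proteins | other.planted_up_proteins,
            planted_active_reporters=(self.planted_active_reporters
                                      | other.planted_active_reporters),
            planted_cluster_count=max(self.planted_cluster_count, other.planted_cluster_count),
            planted_chains=self.planted_chains + other.planted_chains,
            exclusive_proteins={**self.exclusive_proteins, **other.exclusive_proteins},
        )

    def to_json(self, path) -> None:
        doc = {
            "planted_up_proteins": sorted(self.planted_up_proteins),
            "planted_active_reporters": sorted(self.planted_active_reporters),
            "planted_cluster_count": self.planted_cluster_count,
            "planted_chains": [list(c) for c in self.planted_chains],
            "exclusive_proteins": {k: sorted(v) for k, v in self.exclusive_proteins.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            planted_up_proteins=set(doc["planted_up_proteins"]),
            planted_active_reporters=set(doc["planted_active_reporters"]),
            planted_cluster_count=int(doc["planted_cluster_count"]),
            planted_chains=[tuple(c) for c in doc["planted_chains"]],
            exclusive_proteins={k: list(v) for k, v in doc.get("exclusive_proteins", {}).items()},
        )


# ---------------------------------------------------------------------------
# generators


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2."""
    shape = 1.0 / dispersion
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p)


def simulate_secretome(cfg: SecretomeSimConfig):
    """Spectral-count matrix + secreted annotation + ground truth.

    Per-protein baseline abundance varies lognormally around
    ``mean_count`` (normalized so the marginal mean is preserved);
    planted-up secreted proteins have their diseased-condition mean scaled
    by ``2**planted_log2fc``; exclusive proteins are structurally zero in
    the other condition.
    """
    cfg.validate()
    rng = substream(cfg.seed, "secretome")
    n = cfg.n_proteins
    ids = np.array([f"P{i:04d}" for i in range(n)])
    lengths = np.maximum(
        1, np.round(rng.lognormal(cfg.length_log_mean, cfg.length_log_sd, size=n))
    ).astype(int)

    n_secreted = int(round(cfg.frac_secreted * n))
    secreted_idx = rng.choice(n, size=n_secreted, replace=False)
    secreted = np.zeros(n, dtype=int)
    secreted[secreted_idx] = 1

    # planted-up proteins are secreted and shared; exclusives are drawn
    # from the remainder so categories stay disjoint
    planted_idx = rng.choice(secreted_idx, size=cfg.n_planted_up, replace=False)
    remaining = np.setdiff1d(np.arange(n), planted_idx, assume_unique=False)
    excl = rng.choice(remaining, size=cfg.n_exclusive_diseased + cfg.n_exclusive_healthy,
                      replace=False)
    excl_d = excl[:cfg.n_exclusive_diseased]
    excl_h = excl[cfg.n_exclusive_diseased:]

    sigma = 0.5  # per-protein abundance spread (log scale), mean-preserving
    base_mu = cfg.mean_count * rng.lognormal(-sigma**2 / 2.0, sigma, size=n)

    mu = {cfg.reference: base_mu.copy(), cfg.target: base_mu.copy()}
    mu[cfg.target][planted_idx] *= 2.0**cfg.planted_log2fc

    cols, data = [], {}
    for cond in (cfg.target, cfg.reference):
        for r in range(1, cfg.n_replicates + 1):
            col = f"{cond}_{r}"
            cols.append(col)
            counts = _nb_draw(rng, mu[cond], cfg.dispersion)
            data[col] = counts
    counts = pd.DataFrame(data, index=pd.Index(ids, name="protein_id"), columns=cols)
    counts.loc[ids[excl_d], [c for c in cols if c.startswith(cfg.reference)]] = 0
    counts.loc[ids[excl_h], [c for c in cols if c.startswith(cfg.target)]] = 0
    # exclusives must be detectable in their own condition
    own = {cfg.target: excl_d, cfg.reference: excl_h}
    for cond, idx in own.items():
        own_cols = [c for c in cols if c.startswith(cond)]
        sub = counts.loc[ids[idx], own_cols]
        dead = sub.sum(axis=1) == 0
        if dead.any():
            counts.loc[sub.index[dead], own_cols[0]] = 1

    scm = SpectralCountMatrix(
        counts=counts,
        lengths=pd.Series(lengths, index=counts.index, name="length"),
        conditions={c: c.rsplit("_", 1)[0] for c in cols},
    )
    annotation = pd.Series(secreted, index=counts.index, name="secreted")
    truth = GroundTruth(
        planted_up_proteins=set(ids[planted_idx]),
        exclusive_proteins={cfg.target: list(ids[excl_d]), cfg.reference: list(ids[excl_h])},
    )
    return scm, annotation, truth


def profile_value(shape: str, amplitude: float, t: float, t_max: float) -> float:
    """Log2 treated/control offset of a planted profile at time t."""
    frac = t / t_max if t_max > 0 else 0.0
    if shape == "ramp":
        return amplitude * frac
    if shape == "decline":
        return amplitude * (1.0 - frac)
    if shape == "pulse":
        return amplitude * (1.0 - abs(2.0 * frac - 1.0))
    return amplitude  # flat


def simulate_tracer(cfg: TracerSimConfig):
    """Reporter plates with background and TA wells + ground truth.

    Reporter wells sit at a reporter-specific basal level around
    ``ta_level``; treated wells are additionally scaled by
    ``2**profile(t)``.  All wells carry multiplicative lognormal noise of
    ``noise_log_sd`` log2 units.
    """
    cfg.validate()
    rng = substream(cfg.seed, "tracer")
    times = np.arange(cfg.n_timepoints) * cfg.timepoint_spacing
    t_max = times[-1] if times[-1] > 0 else 1.0
    reporters = [f"TF{i + 1:02d}" for i in range(cfg.n_reporters)]

    shape_of = {}
    for pc in cfg.planted_clusters:
        for m in pc.members:
            shape_of[m] = (pc.shape, pc.amplitude)

    rows = []
    noise = lambda size: 2.0 ** rng.normal(0.0, cfg.noise_log_sd, size=size)
    for plate_i in range(1, cfg.n_plates + 1):
        plate = f"plate{plate_i}"
        well_counter = 0

        def well() -> str:
            nonlocal well_counter
            well_counter += 1
            return f"W{well_counter:04d}"

        basal = cfg.ta_level * 2.0 ** rng.normal(0.0, cfg.basal_log_sd, size=cfg.n_reporters)
        for t in times:
            for b in range(1, cfg.n_background_wells + 1):
                rows.append((plate, well(), "none", "background", t, b,
                             cfg.background_level * noise(None)))
            for cond in (cfg.treated, cfg.control):
                for r in range(1, cfg.n_ta_wells + 1):
                    rows.append((plate, well(), "TA", cond, t, r, cfg.ta_level * noise(None)))
                for gi, rep in enumerate(reporters):
                    shape, amp = shape_of.get(gi, ("flat", 0.0))
                    offset = profile_value(shape, amp, t, t_max) if cond == cfg.treated else 0.0
                    for r in range(1, cfg.n_replicates + 1):
                        rows.append((plate, well(), rep, cond, t, r,
                                     basal[gi] * 2.0**offset * noise(None)))
    data = pd.DataFrame(
        rows, columns=["plate", "well", "reporter", "condition", "time_h", "replicate", "flux"]
    )
    plates = ReporterPlateSet(data=data, ta_reporter="TA", background_condition="background")

    active = {reporters[m] for pc in cfg.planted_clusters if pc.amplitude != 0
              for m in pc.members}
    n_unassigned = cfg.n_reporters - len(shape_of)
    truth = GroundTruth(
        planted_active_reporters=active,
        planted_cluster_count=len(cfg.planted_clusters) + (1 if n_unassigned else 0),
    )
    return plates, truth


_ADMISSIBLE = (
    ("ligand", "receptor"),
    ("receptor", "signaling"),
    ("receptor", "tf"),
    ("signaling", "tf"),
    ("tf", "tf"),
)


def simulate_network(cfg: NetworkSimConfig) -> InteractionNetwork:
    """Random typed directed graph with planted ligand->receptor->tf chains."""
    cfg.validate()
    rng = substream(cfg.seed, "network")
    groups = {
        "ligand": cfg.ligand_ids or [f"L{i:03d}" for i in range(cfg.n_ligands)],
        "receptor": cfg.receptor_ids or [f"R{i:03d}" for i in range(cfg.n_receptors)],
        "signaling": cfg.signaling_ids or [f"S{i:03d}" for i in range(cfg.n_signaling)],
        "tf": cfg.tf_ids or [f"T{i:03d}" for i in range(cfg.n_tfs)],
    }
    node_types = {n: t for t, nodes in groups.items() for n in nodes}
    if len(node_types) != sum(len(v) for v in groups.values()):
        raise ConfigError("node ids must be unique across types")

    edges: list[tuple[str, str]] = []
    for src_t, dst_t in _ADMISSIBLE:
        src_nodes, dst_nodes = groups[src_t], groups[dst_t]
        if not src_nodes or not dst_nodes:
            continue
        draw = rng.random((len(src_nodes), len(dst_nodes)))
        for i, u in enumerate(src_nodes):
            for j, v in enumerate(dst_nodes):
                if u == v:
                    continue
                if draw[i, j] < cfg.edge_density:
                    edges.append((u, v))

    for lig, rec, tf in cfg.planted_chains:
        for node, want in ((lig, "ligand"), (rec, "receptor"), (tf, "tf")):
            if node_types.get(node) != want:
                raise ConfigError(
                    f"planted chain ({lig}, {rec}, {tf}): {node!r} is not a {want} node")
        edges.append((lig, rec))
        edges.append((rec, tf))

    return InteractionNetwork.from_edges(sorted(set(edges)), node_types)


# ---------------------------------------------------------------------------
# coordinated study


@dataclass
class StudySimConfig:
    """One coherent synthetic study: the network's ligand nodes are the
    secreted proteins and its tf nodes are the reporter panel, with
    ``n_planted_chains`` chains from planted up-regulated proteins to
    members of the most active planted reporter cluster."""

    secretome: SecretomeSimConfig = field(default_factory=SecretomeSimConfig)
    tracer: TracerSimConfig = field(default_factory=TracerSimConfig)
    network: NetworkSimConfig = field(default_factory=NetworkSimConfig)
    n_planted_chains: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_planted_chains < 0:
            raise ConfigError("n_planted_chains must be >= 0")
        if self.n_planted_chains > self.secretome.n_planted_up:
            raise ConfigError("n_planted_chains exceeds the planted up-regulated proteins")
        first = self.tracer.planted_clusters[0] if self.tracer.planted_clusters else None
        if self.n_planted_chains and (first is None or first.amplitude == 0):
            raise ConfigError("planted chains need an active first planted cluster")


def simulate_study(cfg: StudySimConfig):
    """Generate the three coordinated inputs and merged ground truth."""
    cfg.validate()
    rng = substream(cfg.seed, "study")
    sec_cfg = SecretomeSimConfig(**{**asdict(cfg.secretome), "seed": cfg.seed})
    tra_cfg = TracerSimConfig(**{
        **{k: v for k, v in cfg.tracer.__dict__.items() if k != "planted_clusters"},
        "planted_clusters": cfg.tracer.planted_clusters, "seed": cfg.seed})
    scm, annotation, sec_truth = simulate_secretome(sec_cfg)
    plates, tra_truth = simulate_tracer(tra_cfg)

    ligand_ids = sorted(annotation.index[annotation == 1])
    reporters = sorted({r for r in plates.assay_wells["reporter"].unique() if r != "TA"})
    net_cfg = NetworkSimConfig(**{**asdict(cfg.network), "seed": cfg.seed})
    net_cfg.n_ligands = len(ligand_ids)
    net_cfg.ligand_ids = ligand_ids
    net_cfg.n_tfs = len(reporters)
    net_cfg.tf_ids = reporters
    net_cfg.receptor_ids = None
    net_cfg.signaling_ids = None

    # chains: planted-up secreted proteins -> random receptors -> members
    # of the most active planted cluster
    chains: list[tuple[str, str, str]] = []
    if cfg.n_planted_chains:
        top = cfg.tracer.planted_clusters[0]
        top_tfs = [f"TF{m + 1:02d}" for m in top.members]
        up = sorted(sec_truth.planted_up_proteins)
        receptors = [f"R{i:03d}" for i in range(net_cfg.n_receptors)]
        if not receptors:
            raise ConfigError("planted chains require at least one receptor node")
        lig_pick = rng.choice(len(up), size=cfg.n_planted_chains, replace=False)
        for i, li in enumerate(lig_pick):
            rec = receptors[int(rng.integers(len(receptors)))]
            tf = top_tfs[i % len(top_tfs)]
            chains.append((up[int(li)], rec, tf))
    net_cfg.planted_chains = chains

    net = simulate_network(net_cfg)
    truth = sec_truth.merged_with(tra_truth)
    truth.planted_chains = chains
    return scm, annotation, plates, net, truth
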