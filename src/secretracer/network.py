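"""Ligand -> receptor -> TF traversal and overlap enrichment.

A typed directed interaction network (node types: ligand, receptor,
signaling, tf) is traversed to predict, for each candidate ligand, the
transcription factors downstream of its receptors: a ligand's *core* TFs
are tf-type nodes reachable from its direct receptor successors through at
most one signaling intermediate, and the set is then expanded by up to
``expansion_depth`` additional directed edges.  The predicted TF set is
tested for overlap enrichment against the most-active reporter cluster
with a one-sided Fisher exact (hypergeometric tail) test, and ligands
reaching overlap TFs are ranked into a candidate table using secretome
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InteractionNetwork",
    "LigandTFMap",
    "EnrichmentResult",
    "predict_downstream_tfs",
    "overlap_enrichment",
    "identify_candidates",
]

NODE_TYPES = ("ligand", "receptor", "signaling", "tf")


class NetworkError(ValueError):
    """Raised for malformed networks or mistyped queries."""


class InteractionNetwork:
    """Typed directed graph of molecular interactions."""

    def __init__(self, graph: nx.DiGraph):
        for node, data in graph.nodes(data=True):
            t = data.get("type")
            if t not in NODE_TYPES:
                raise NetworkError(f"node {node!r} has invalid type {t!r}")
        if any(u == v for u, v in graph.edges):
            raise NetworkError("self-loops are not allowed")
        self.graph = graph

    @classmethod
    def from_edges(cls, edges, node_types: dict[str, str]) -> "InteractionNetwork":
        g = nx.DiGraph()
        for node, t in node_types.items():
            g.add_node(node, type=t)
        for u, v in edges:
            if u not in g or v not in g:
                missing = [x for x in (u, v) if x not in g]
                raise NetworkError(f"edge ({u}, {v}) references unknown node(s) {missing}")
            g.add_edge(u, v)
        return cls(g)

    @classmethod
    def from_tsv(cls, edge_path, node_path, symmetrize: bool = False) -> "InteractionNetwork":
        nodes = pd.read_csv(node_path, sep="\t")
        edges = pd.read_csv(edge_path, sep="\t")
        pairs = list(edges[["source", "target"]].itertuples(index=False, name=None))
        if symmetrize:
            pairs += [(v, u) for u, v in pairs if u != v]
        return cls.from_edges(pairs, dict(zip(nodes["id"], nodes["type"])))

    @classmethod
    def from_sif(cls, sif_path, node_path, symmetrize: bool = False) -> "InteractionNetwork":
        """Three-column SIF dialect: source <tab> interaction <tab> target."""
        nodes = pd.read_csv(node_path, sep="\t")
        sif = pd.read_csv(sif_path, sep="\t", header=None, names=["source", "interaction", "target"])
        pairs = list(sif[["source", "target"]].itertuples(index=False, name=None))
        if symmetrize:
            pairs += [(v, u) for u, v in pairs if u != v]
        return cls.from_edges(pairs, dict(zip(nodes["id"], nodes["type"])))

    def to_tsv(self, edge_path, node_path) -> None:
        pd.DataFrame(sorted(self.graph.edges), columns=["source", "target"]).to_csv(
            edge_path, sep="\t", index=False)
        pd.DataFrame(
            sorted((n, d["type"]) for n, d in self.graph.nodes(data=True)),
            columns=["id", "type"],
        ).to_csv(node_path, sep="\t", index=False)

    def nodes_of_type(self, t: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["type"] == t}

    def node_type(self, n: str) -> str:
        return self.graph.nodes[n]["type"]


@dataclass
class LigandTFMap:
    """Per-ligand receptors and downstream TF sets at a fixed depth."""

    expansion_depth: int
    receptors: dict[str, set[str]] = field(repr=False)
    core_tfs: dict[str, set[str]] = field(repr=False)
    tfs: dict[str, set[str]] = field(repr=False)

    @property
    def ligands(self) -> list[str]:
        return sorted(self.receptors)

    def all_predicted_tfs(self) -> set[str]:
        out: set[str] = set()
        for s in self.tfs.values():
            out |= s
        return out

    def to_tsv(self, path) -> None:
        rows = [
            (lig, ";".join(sorted(self.receptors[lig])), ";".join(sorted(self.tfs[lig])))
            for lig in self.ligands
        ]
        pd.DataFrame(rows, columns=["ligand", "receptors", "downstream_tfs"]).to_csv(
            path, sep="\t", index=False)


def predict_downstream_tfs(
    net: InteractionNetwork,
    ligands,
    expansion_depth: int = 1,
    max_signaling_hops: int = 1,
) -> LigandTFMap:
    """TFs downstream of each ligand's receptors.

    Core TFs are reachable from a ligand's receptor successors through at
    most ``max_signaling_hops`` signaling nodes; the expanded set adds TFs
    within ``expansion_depth`` further directed edges from the core TFs or
    the signaling intermediates on core paths.
    """
    g = net.graph
    ligands = sorted(ligands)
    bad = [l for l in ligands if l not in g or net.node_type(l) != "ligand"]
    if bad:
        raise NetworkError(f"not ligand nodes in the network: {bad}")

    receptors: dict[str, set[str]] = {}
    core: dict[str, set[str]] = {}
    expanded: dict[str, set[str]] = {}
    for lig in ligands:
        recs = {v for v in g.successors(lig) if net.node_type(v) == "receptor"}
        core_tfs: set[str] = set()
        intermediates: set[str] = set()
        # BFS from receptors through <= max_signaling_hops signaling nodes
        frontier = set(recs)
        for hop in range(max_signaling_hops + 1):
            nxt: set[str] = set()
            for u in frontier:
                for v in g.successors(u):
                    t = net.node_type(v)
                    if t == "tf":
                        core_tfs.add(v)
                    elif t == "signaling" and hop < max_signaling_hops and v not in intermediates:
                        nxt.add(v)
            intermediates |= nxt
            frontier = nxt
            if not frontier:
                break
        # expansion: up to expansion_depth extra edges from core TFs or
        # their signaling intermediates, collecting tf-type nodes reached
        tfs = set(core_tfs)
        frontier = core_tfs | intermediates
        seen = set(frontier)
        for _ in range(expansion_depth):
            nxt = set()
            for u in frontier:
                for v in g.successors(u):
                    if v not in seen:
                        nxt.add(v)
                        if net.node_type(v) == "tf":
                            tfs.add(v)
            seen |= nxt
            frontier = nxt
            if not frontier:
                break
        receptors[lig] = recs
        core[lig] = core_tfs
        expanded[lig] = tfs
    return LigandTFMap(expansion_depth=expansion_depth, receptors=receptors,
                       core_tfs=core, tfs=expanded)


@dataclass
class EnrichmentResult:
    """One-sided Fisher exact overlap test of two TF sets in a universe."""

    universe_size: int   # N
    top_cluster_size: int  # K
    predicted_in_universe: int  # n
    overlap: int  # x
    pvalue: float
    overlap_tfs: set[str] = field(default_factory=set, repr=False)

    def to_dict(self) -> dict:
        return {
            "universe_size": self.universe_size,
            "top_cluster_size": self.top_cluster_size,
            "predicted_in_universe": self.predicted_in_universe,
            "overlap": self.overlap,
            "pvalue": self.pvalue,
            "overlap_tfs": sorted(self.overlap_tfs),
        }


def overlap_enrichment(predicted, top_cluster, universe) -> EnrichmentResult:
    """P(X >= x) for the overlap of predicted TFs with the top cluster.

    Hypergeometric upper tail with N = |universe|, K = |top_cluster|,
    n = |predicted ∩ universe|, x = |predicted ∩ top_cluster|.  The
    predicted set is intersected with the universe internally; the top
    cluster must already lie within it.
    """
    universe = set(universe)
    if not universe:
        raise NetworkError("empty universe for enrichment test")
    top_cluster = set(top_cluster)
    if not top_cluster <= universe:
        raise NetworkError("top cluster not contained in the universe")
    predicted = set(predicted) & universe
    overlap = predicted & top_cluster
    x, big_n, big_k, n = len(overlap), len(universe), len(top_cluster), len(predicted)
    p = float(stats.hypergeom.sf(x - 1, big_n, big_k, n))
    return EnrichmentResult(
        universe_size=big_n, top_cluster_size=big_k, predicted_in_universe=n,
        overlap=x, pvalue=min(p, 1.0), overlap_tfs=overlap,
    )


def identify_candidates(
    ltf_map: LigandTFMap,
    overlap_tfs,
    secretome_evidence: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rank ligands that reach overlap TFs into a candidate table.

    ``secretome_evidence`` (optional) is indexed by protein id with
    columns ``provenance`` (shared | exclusive), ``log2fc`` and
    ``mean_nsaf``.  Ranking: descending overlap-TF count; then exclusive
    proteins (effectively infinite fold change) ahead of shared, exclusives
    ordered by mean NSAF and shared by log2 fold change, both descending;
    lexical id as the final tie-break.
    """
    overlap_tfs = set(overlap_tfs)
    rows = []
    for lig in ltf_map.ligands:
        hits = ltf_map.tfs[lig] & overlap_tfs
        if not hits:
            continue
        provenance, lfc, nsaf = "", np.nan, np.nan
        if secretome_evidence is not None and lig in secretome_evidence.index:
            rec = secretome_evidence.loc[lig]
            provenance = rec.get("provenance", "")
            lfc = float(rec.get("log2fc", np.nan))
            nsaf = float(rec.get("mean_nsaf", np.nan))
        exclusive = provenance == "exclusive"
        score = nsaf if exclusive else lfc
        if not np.isfinite(score):
            score = -np.inf
        rows.append({
            "ligand": lig,
            "n_overlap_tfs": len(hits),
            "overlap_tfs": ";".join(sorted(hits)),
            "receptors": ";".join(sorted(ltf_map.receptors[lig])),
            "provenance": provenance,
            "log2fc": lfc,
            "mean_nsaf": nsaf,
            "_excl": 0 if exclusive else 1,
            "_score": score,
        })
    if not rows:
        cols = ["ligand", "n_overlap_tfs", "overlap_tfs", "receptors", "provenance",
                "log2fc", "mean_nsaf", "rank"]
        return pd.DataFrame(columns=cols).set_index("ligand")
    tab = pd.DataFrame(rows)
    tab = tab.sort_values(
        by=["n_overlap_tfs", "_excl", "_score", "ligand"],
        ascending=[False, True, False, True],
        kind="stable",
    ).drop(columns=["_excl", "_score"])
    tab["rank"] = np.arange(1, len(tab) + 1)
    return tab.set_index("ligand")
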