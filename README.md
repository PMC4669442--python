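# secretracer

Identify **functional secreted factors** by connecting three data streams:

1. **Secretome differential abundance** — label-free spectral counting of
   conditioned-media proteomes from a diseased and a healthy source,
   quantified as normalized spectral abundance factors (NSAF),
   partitioned into shared and condition-exclusive identifications, and
   gated on a secreted-protein annotation to form a candidate pool.
2. **Transcription-factor reporter arrays** — a panel of luciferase
   reporters (one per TF response element) read as photon flux over a
   time course in treated vs control media, reduced to normalized log2
   fold-change profiles, tested with empirical-Bayes moderated t/F
   statistics, and clustered into temporal activation groups with a
   permutation-null choice of the cluster number.
3. **Ligand–receptor–TF networks** — a typed directed interaction graph
   traversed from each candidate ligand through its receptors to
   downstream TFs, whose overlap with the most active reporter cluster is
   scored by a one-sided Fisher exact test; ligands reaching overlap TFs
   are ranked into the final candidate table.

The package is aimed at systems-biology analysts who have (or want to
simulate) these three inputs and need a reproducible, tested pipeline
from raw tables to ranked candidates. A synthetic-study generator with
planted ground truth (up-regulated secreted proteins, temporally coherent
active reporter clusters, ligand→receptor→TF chains) makes every stage
testable without any external download.

## The statistics at the core

**NSAF.** For protein *i* with spectral count `Spc_i` and length `L_i`
in one sample,

```
NSAF_i = (Spc_i / L_i) / Σ_j (Spc_j / L_j)
```

so each sample's NSAF column sums to 1. Shared proteins are tested by a
two-sided Welch t-test on log2(NSAF + ε) with ε = half the smallest
nonzero NSAF, flagged significant at p < 0.10 and |log2FC| ≥ 1.5.

**Moderated t.** Per reporter *g*, a cell-means model by timepoint gives
coefficients β_gt and a pooled residual variance s²_g on d_g df. A
scaled inverse-chi-square prior (d₀, s₀²) is fitted by moment matching on
log s²_g (digamma/trigamma inversion); the posterior variance
`s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)` yields moderated statistics
`t̃_gt = β_gt / (s̃_g/√n_gt)` on d₀ + d_g df, a per-reporter moderated F
(mean of t̃² over timepoints), and a log-odds of differential activity.
P-values are Benjamini-Hochberg adjusted across reporters within each
timepoint; a reporter is *active* if its minimum adjusted p < 0.05.

**Cluster number.** For each k, SSE(k) is the best-of-random-starts
k-means within-cluster sum of squares; SSE_perm(k) is its mean over
datasets whose timepoint columns are independently shuffled across
reporters. The chosen k maximizes the gap SSE_perm(k) − SSE(k).

**Overlap enrichment.** With universe N (the assayed reporter panel by
default), top-cluster size K, predicted set size n, and overlap x, the
enrichment p-value is the hypergeometric upper tail P(X ≥ x).

## Worked example

```sh
secretracer all --seed 1 --out run1
cat run1/summary.txt
```

prints (numbers produced by this exact command):

```
secreted-factor discovery run
==========================================
config 1390d837f2ea9949  seed 1  secretracer 0.1.0

secretome:
  detected proteins          615
  shared / target-only / ref-only  375 / 101 / 139
  significant (t + fold cut) 10
  candidate pool             148 (116 shared + 32 exclusive)
reporter array:
  reporters                  52
  active (BH p < alpha)      46
  variance prior d0, s0^2    7.808, 0.01149
  clusters (chosen k)        4; top cluster 10 reporters
network:
  predicted downstream TFs   3
  overlap with top cluster   2 (Fisher p = 0.091)
  candidate ligands          3; top: P0018
ground-truth recovery:
  active_sensitivity         1.0
  k_recovered                False
  planted_k                  5
  planted_ligand_ranks       [1]
  pool_sensitivity           1.0
```

Reading it: of 615 simulated proteins, 375 are detected in both media
and 101 only in the diseased medium; annotation-gating yields a pool of
148 candidate secreted factors (the planted up-regulated ones among
them). On the 52-reporter array, 46 reporters show significant activity
at some timepoint; profiles fall into 4 temporal clusters and the most
active cluster holds 10 reporters (the weakest planted cluster is, by
design, too faint to separate from baseline, hence `k_recovered: False`
against the 5 planted groups). Traversing the network from the pool
ligands reaches 3 TFs, 2 of which sit in that top cluster (Fisher
p ≈ 0.09 against the 52-reporter universe), and the top-ranked candidate
ligand `P0018` is the planted chain's ligand. Per-stage tables
(`secretome_stats.tsv`, `reporter_stats.tsv`, `clusters.tsv`,
`candidates.tsv`, …) and `report.json` land in `run1/`.

The same run is available as a library:

```python
from secretracer import run_pipeline, validate_config
report = run_pipeline(validate_config({"seed": 1, "outdir": "run1"}))
print(report.summary())
```

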