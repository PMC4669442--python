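# Methods

This note documents the models, the numerical choices, and what the
synthetic studies do and do not establish. Notation: two media
conditions are called *target* (default `diseased`) and *reference*
(default `healthy`); the reporter-array conditions are *treated* and
*control*.

## Secretome stage

**Quantification.** Spectral counts are length-normalized into NSAF per
sample: `NSAF_i = (Spc_i/L_i) / Σ_j (Spc_j/L_j)`. A sample whose counts
are all zero has no normalizer and is rejected by name. Proteins with
zero counts get NSAF 0, so each column sums to exactly 1; the ratio is
invariant to any common scaling of a sample's counts.

**Detection and partition.** A protein is *detected* in a condition if
its count is nonzero in at least `min_detect_reps` replicates (default
1: any nonzero count, since peptide-level evidence thresholds are
applied upstream of this pipeline). Detected proteins split into
*shared* (both conditions) and *exclusive* (exactly one); exclusives are
treated as a separate category rather than as extreme fold changes, so
they carry no log2FC.

**Differential abundance.** Shared proteins are tested by a two-sided
Welch t-test on `log2(NSAF + ε)` replicate values, with
`ε = ½·min(nonzero NSAF)` guarding zeros while perturbing the scale as
little as possible. The log scale is the default because NSAF values
span orders of magnitude; `test_scale="linear"` switches to raw NSAF.
`log2FC = log2(mean_target + ε) − log2(mean_reference + ε)`; a protein
is flagged significant at `p < α_secr = 0.10` **and**
`|log2FC| ≥ θ_lfc = 1.5`. No multiplicity correction is applied in this
arm (BH belongs to the reporter arm); the permissive α is deliberate
since the flag annotates rather than gates.

**Candidate pool.** The pool for the target condition is
annotation-gated, not fold-change-gated: all shared secreted proteins
plus all target-exclusive secreted proteins. Proteins missing from the
annotation count as non-secreted. Differential flags are attached as
evidence.

## Reporter-array stage

**Background filter.** The background is estimated from non-infected
wells per (plate, timepoint) stratum — background wells carry the
condition label `background` in the plate CSV and therefore cannot be
matched to a treatment, so the stratum is shared across conditions. On
log2 flux, a well is retained iff it strictly exceeds the one-sided
upper prediction bound `m_bg + t_{1−α_bg, n−1}·s_bg·√(1+1/n)`
(α_bg = 0.05), i.e. it must look unlike one more background draw. Fewer
than two background wells in a stratum leave the SD undefined and raise
an error.

**Normalization.** Per well, `a = log2(flux) − mean(log2 TA flux)` over
the same (plate, condition, timepoint) stratum; the TA reporter (basal
promoter, no TF binding elements) absorbs nonspecific promoter activity
and any plate gain factor — multiplying a plate's fluxes by a constant
changes nothing downstream. Per reporter and timepoint,
`y_r = a_treated,r − mean(a_control)`: the treated replicate structure
is kept so the variance model sees real replication, while the control
enters as a mean (pairing of wells across conditions is not defined by
the plate layout).

**Outliers.** Within each (reporter, timepoint) replicate group, a value
is removed when its *leave-one-out* z-score — mean and SD of the other
replicates — has a two-sided normal tail below α_out = 0.003; if the
other replicates are identical, any deviating value is removed.
Decisions are taken on the original groups and applied in one pass, so
symmetric extremes can mask each other; groups of one or two values are
never touched. The leave-one-out form is what makes a single gross
outlier among otherwise-identical replicates detectable at all (an
inclusive z-score is bounded by (n−1)/√n and can never reach the 0.003
cutoff for small n). The flip side is that for n = 4 the statistic is
heavy-tailed relative to the normal reference, so the realized null
removal rate (~10 %) exceeds the nominal α; with the larger replicate
numbers of a multi-array experiment the rule approaches its nominal
level.

**Moderated statistics.** Per reporter, the model is cell-means by
timepoint: β_gt is the replicate mean and the residual variance s²_g
pools across timepoints with d_g = Σ_t(n_gt − 1) df — the simplest model
yielding a coefficient and squared error per timepoint. The
empirical-Bayes prior (d₀, s₀²) is fitted by moment matching on
log s²_g: with `e_g = log s²_g − ψ(d_g/2) + log(d_g/2)`, solve
`ψ'(d₀/2) = var(e) − mean(ψ'(d_g/2))` for d₀ (bracketed root-finding on
the strictly decreasing trigamma) and set
`s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2))`. Non-positive excess
dispersion gives d₀ = ∞ (complete pooling); degenerate all-zero data
disable shrinkage. Moderated t uses the posterior variance on d₀ + d_g
df; the moderated F is the mean of t̃² across timepoints; the log-odds
(B) statistic uses a normal prior on true effects whose variance is
estimated per timepoint from the top `prior_proportion/2` fraction of
|t̃| (proportion 0.01, prior SD clamped to [0.1, 4] on the coefficient
scale). BH adjustment runs across reporters within each timepoint, and
a reporter is *active* when its minimum adjusted p over timepoints is
below α_adj = 0.05 (significance at at least one timepoint). On
complete data this entire stage reproduces the reference R
implementation of variance moderation (limma) to ~1e-14, which one test
verifies directly through `Rscript`.

A caveat the synthetic studies expose: TA normalization subtracts a
*stratum-level* TA mean, so its estimation noise is shared by every
reporter at that (plate, timepoint) and the per-timepoint tests read it
as reporter-specific signal. With a single plate and 4 TA wells this
makes the activity calls anti-conservative (at default noise most
reporters are called active at some timepoint); sensitivity for truly
active reporters is unaffected. Real multi-array designs (the assay is
typically run as ~6 replicate arrays) shrink this term.

**Clustering.** Features are reporter-mean profiles (missing cells
imputed with the reporter's own temporal mean); k-means with Euclidean
distance, best of `n_starts = 50` random starts per k. The null model
permutes each timepoint column independently across reporters —
preserving every timepoint's marginal distribution while destroying
temporal coherence — and `SSE_perm(k)` averages `n_perm = 100` such
datasets. The chosen k maximizes the *raw* gap `SSE_perm(k) − SSE(k)`
(a log-SSE variant would change tie geometry; the raw difference is the
plain reading of "difference of sum-of-square errors" and is what is
implemented), smallest k on ties. Since column permutation preserves
the total sum of squares exactly, gap(1) ≡ 0 and k = 1 is chosen only
when no k beats zero. Clusters are ranked 1…k by descending mean member
activity. The raw gap is conservative: it merges planted groups whose
profile distance is small relative to the null's SSE decline, so only
well-separated temporal families count as recoverable clusters.

## Network stage

Nodes are typed ligand / receptor / signaling / tf; edges are directed
(undirected sources can be symmetrized at load time). For each ligand:
receptors are its direct successors of receptor type; *core* TFs are
tf-type nodes reachable from those receptors through at most
`max_signaling_hops = 1` signaling intermediates (keeping "direct
receptor → downstream TF" tight); the final set adds TFs within
`expansion_depth = 1` further directed edges from the core TFs or the
signaling intermediates on core paths. Both depths are parameters
because curated-database expansion semantics vary. The predicted TF set
grows monotonically in depth and in edges.

Enrichment of the predicted set against the most active cluster is the
hypergeometric upper tail; the default universe is the assayed reporter
panel (the only TFs whose activity was actually measured), switchable to
all tf-type network nodes. Candidate ligands — those reaching at least
one overlap TF — are ranked by descending overlap-TF count, then by
evidence strength: condition-exclusive proteins first (detection only in
the target medium is effectively an unbounded fold change), exclusives
ordered by mean target NSAF and shared proteins by log2FC, with lexical
id as the final deterministic tie-break.

## Synthetic studies

The generators are pure functions of (config, seed); all randomness
derives from one master seed through named CRC32 substreams, so stages
rerun in isolation reproduce the pipeline.

**Secretome.** Defaults mirror the study scale: 615 proteins, 3
replicates per condition, 101/139 structurally condition-exclusive
proteins (all-zero counts in the other condition, not merely low — the
analysis treats exclusivity as categorical), ~30 % secreted, 10 planted
up-regulated secreted proteins at log2FC 2. Counts are negative
binomial with mean 50 and dispersion 0.1 (var = μ + 0.1 μ²,
overdispersion typical of spectral counting); per-protein baseline
abundance varies lognormally (σ = 0.5 in log, mean-preserving); lengths
are lognormal (median ~400 aa). Not emulated: peptide-level sampling,
shared peptides, abundance-dependent detection — so the detection step
here only exercises the set arithmetic, not missingness mechanisms.

**Reporter array.** Defaults mirror the assay layout: 52 reporters, 5
reads at 2-hour spacing (0–8 h), 4 replicate wells per
reporter/condition, 4 background and 4 TA wells per timepoint, one
plate. Noise is multiplicative lognormal (0.15 log2 units), required
positive by the downstream log transform; no spatial plate artifacts.
Planted profiles come from four parametric families (ramp, pulse, flat,
decline). The default planted structure follows the most-to-least
active gradient of a real screen — amplitudes 2 / 1.5 / 1 / 0.5 over
35 of 52 reporters — which deliberately includes a weakest cluster that
is *not* separable from baseline, so the default-config chosen k (4) is
smaller than the planted count (5); recovery tests for the cluster
number instead use fully separated amplitude-2 structures (ramp up,
decline, ramp down), where it is a fair target.

**Network.** Admissible random edges are ligand→receptor,
receptor→signaling, receptor→tf, signaling→tf, tf→tf, each present with
probability `edge_density = 0.003`. The density default keeps the
expected number of spurious ligand→panel-TF connections per study well
below one (≈ 30·d receptors per ligand × ≈ 62·d TFs per receptor across
~180 ligand nodes), the regime of a sparse curated interaction map;
planted chains add their two edges explicitly. The coordinated study
generator names ligand nodes after the secreted proteins and tf nodes
after the reporter panel, and plants chains from up-regulated proteins
to members of the most active cluster.

## Problem sizes in the test suite

The acceptance-style tests scale the studies to keep the suite fast
while leaving the effects far above noise: cluster-number recovery uses
24 reporters, k ∈ 1…6, 20 starts, 30 permutations over 20 seeds;
secretome recovery uses 400 proteins over 50 seeds; the end-to-end
planted-chain study runs the full default generators with k ∈ 1…8, 30
starts, 40 permutations over 20 seeds. The numbers of starts and
permutations are analysis knobs, not study conditions; the gap curves
stabilize well below these values for data of this size.

## Known limitations

- The Welch-test scale (log vs linear NSAF) and the zero-handling ε are
  conventions; both are isolated behind config switches.
- The activity call inherits the TA-stratum correlation discussed above;
  treat per-reporter *active* flags from single-plate data as liberal.
- Fisher enrichment assumes the predicted TF set is exchangeable within
  the universe; with a panel universe of 52, power is limited and the
  test is reported as evidence, not as a gate.
- Condition-exclusive candidates carry no fold change and are ranked by
  abundance; their placement ahead of shared candidates on overlap ties
  is a convention, recorded in the candidate table's `provenance`
  column.
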