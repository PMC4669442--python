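"""Secretome differential abundance from spectral counts.

Label-free quantification by spectral counting: a protein's abundance in a
sample is proxied by its number of peptide-spectrum matches (Spc).  Because
longer proteins yield more tryptic peptides, counts are length-normalized
into normalized spectral abundance factors,

    NSAF_i = (Spc_i / L_i) / sum_j (Spc_j / L_j)

per sample, so each sample's NSAF values sum to one.  Identifications are
partitioned into shared and condition-exclusive sets; shared proteins are
tested for differential abundance (Welch t-test on log2 NSAF, fold-change
threshold), and the candidate secreted-factor pool for the target condition
is assembled by gating on the secreted annotation: all shared secreted
proteins plus all target-exclusive secreted proteins.  Differential flags
annotate pool members but do not gate membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpectralCountMatrix",
    "IdentificationPartition",
    "compute_nsaf",
    "partition_identifications",
    "differential_abundance",
    "assemble_candidate_pool",
    "secretome_stats_table",
]


class SecretomeError(ValueError):
    """Raised for malformed spectral-count inputs."""


@dataclass
class SpectralCountMatrix:
    """Integer spectral counts per protein per sample.

    Parameters
    ----------
    counts : DataFrame
        Proteins (index) x samples (columns), non-negative integers.
    lengths : Series
        Protein length in amino acids, indexed like ``counts``.
    conditions : mapping
        Sample name -> condition label (exactly two conditions).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise SecretomeError(f"duplicate protein ids: {dupes[:5]}")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()].tolist()
            raise SecretomeError(f"missing lengths for proteins: {missing[:5]}")
        if (self.lengths <= 0).any():
            raise SecretomeError("protein lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise SecretomeError("spectral counts must be non-negative")
        unknown = set(self.counts.columns) - set(self.conditions)
        if unknown:
            raise SecretomeError(f"samples without condition label: {sorted(unknown)}")

    @property
    def condition_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns:
            c = self.conditions[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]

    # --- I/O: TSV with columns protein_id, length, <condition>_<replicate> ---

    def to_tsv(self, path) -> None:
        out = pd.DataFrame({"protein_id": self.counts.index, "length": self.lengths.to_numpy()})
        out = pd.concat([out.set_index(self.counts.index), self.counts], axis=1)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SpectralCountMatrix":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index("protein_id")
        lengths = df.pop("length")
        conditions = {s: s.rsplit("_", 1)[0] for s in df.columns}
        return cls(counts=df, lengths=lengths, conditions=conditions)


@dataclass
class IdentificationPartition:
    """Detected proteins split into shared and condition-exclusive sets."""

    shared: set[str]
    exclusive: dict[str, set[str]]  # condition -> ids detected only there
    min_detect_reps: int = 1

    @property
    def detected(self) -> set[str]:
        out = set(self.shared)
        for ids in self.exclusive.values():
            out |= ids
        return out

    def sizes(self) -> dict[str, int]:
        d = {"shared": len(self.shared), "detected": len(self.detected)}
        for cond, ids in self.exclusive.items():
            d[f"exclusive_{cond}"] = len(ids)
        return d


def compute_nsaf(scm: SpectralCountMatrix) -> pd.DataFrame:
    """Normalized spectral abundance factors, per sample.

    Each sample column of the result sums to 1 over all proteins (proteins
    with zero counts contribute zero).  A sample with no nonzero count has
    an undefined normalizer and raises an error naming the sample.
    """
    spc_over_l = scm.counts.div(scm.lengths, axis=0)
    totals = spc_over_l.sum(axis=0)
    dead = totals.index[totals == 0].tolist()
    if dead:
        raise SecretomeError(
            f"sample(s) with all-zero spectral counts, NSAF undefined: {dead}"
        )
    return spc_over_l.div(totals, axis=1)


def partition_identifications(
    scm: SpectralCountMatrix, min_detect_reps: int = 1
) -> IdentificationPartition:
    """Partition detected proteins into shared / exclusive-to-one-condition.

    A protein is detected in a condition iff its count is nonzero in at
    least ``min_detect_reps`` replicates of that condition.  Proteins
    detected in neither condition are excluded entirely.
    """
    conds = scm.condition_names
    if len(conds) != 2:
        raise SecretomeError(f"exactly two conditions required, got {conds}")
    detected = {}
    for c in conds:
        cols = scm.samples_for(c)
        n_nonzero = (scm.counts[cols] > 0).sum(axis=1)
        detected[c] = set(scm.counts.index[n_nonzero >= min_detect_reps])
    shared = detected[conds[0]] & detected[conds[1]]
    exclusive = {
        conds[0]: detected[conds[0]] - detected[conds[1]],
        conds[1]: detected[conds[1]] - detected[conds[0]],
    }
    return IdentificationPartition(shared=shared, exclusive=exclusive, min_detect_reps=min_detect_reps)


def differential_abundance(
    nsaf: pd.DataFrame,
    scm: SpectralCountMatrix,
    part: IdentificationPartition,
    target: str,
    reference: str,
    alpha: float = 0.10,
    lfc_threshold: float = 1.5,
    scale: str = "log",
) -> pd.DataFrame:
    """Welch t-test and log2 fold change for shared proteins.

    Fold change is log2(mean NSAF target + eps) - log2(mean NSAF reference
    + eps) with eps = half the smallest nonzero NSAF in the matrix.  The
    two-sided Welch test runs on log2(NSAF + eps) replicate values by
    default (``scale='log'``); ``scale='linear'`` tests raw NSAF instead.
    A protein is flagged significant iff p < alpha and |log2FC| >=
    lfc_threshold.
    """
    t_cols = scm.samples_for(target)
    r_cols = scm.samples_for(reference)
    if len(t_cols) < 2 or len(r_cols) < 2:
        raise SecretomeError("need >=2 replicates per condition for the t-test")
    if scale not in ("log", "linear"):
        raise SecretomeError(f"unknown test scale {scale!r}")

    nonzero = nsaf.to_numpy()[nsaf.to_numpy() > 0]
    eps = 0.5 * nonzero.min() if nonzero.size else 1.0

    shared = sorted(part.shared)
    sub = nsaf.loc[shared]
    mean_t = sub[t_cols].mean(axis=1)
    mean_r = sub[r_cols].mean(axis=1)
    log2fc = np.log2(mean_t + eps) - np.log2(mean_r + eps)

    if scale == "log":
        xt = np.log2(sub[t_cols].to_numpy() + eps)
        xr = np.log2(sub[r_cols].to_numpy() + eps)
    else:
        xt = sub[t_cols].to_numpy()
        xr = sub[r_cols].to_numpy()
    with warnings.catch_warnings():
        # zero-variance groups trigger a precision warning; their NaN p is
        # mapped to 1 below (identical groups are by definition unchanged)
        warnings.filterwarnings("ignore", message="Precision loss")
        p = stats.ttest_ind(xt, xr, axis=1, equal_var=False).pvalue
    p = np.where(np.isnan(p), 1.0, p)

    out = pd.DataFrame(
        {
            "mean_nsaf_target": mean_t,
            "mean_nsaf_reference": mean_r,
            "log2fc": log2fc,
            "pvalue": p,
        },
        index=pd.Index(shared, name="protein_id"),
    )
    out["significant"] = (out["pvalue"] < alpha) & (out["log2fc"].abs() >= lfc_threshold)
    return out


@dataclass
class CandidatePool:
    """Annotation-gated candidate secreted factors for the target condition."""

    target: str
    table: pd.DataFrame = field(repr=False)  # index protein_id; provenance, log2fc

    @property
    def ids(self) -> set[str]:
        return set(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def assemble_candidate_pool(
    part: IdentificationPartition,
    annotation: pd.Series,
    target: str,
    stats_table: pd.DataFrame | None = None,
) -> CandidatePool:
    """Pool = shared secreted proteins + target-exclusive secreted proteins.

    ``annotation`` maps protein id -> {0,1}; proteins missing from the
    annotation are treated as non-secreted (with a warning via pandas
    reindex fill).  Fold-change and significance flags from
    ``stats_table`` are attached for shared members but never gate
    membership; exclusive members carry no fold change.
    """
    if target not in part.exclusive:
        raise SecretomeError(f"unknown target condition {target!r}")
    annot = annotation.reindex(sorted(part.detected)).fillna(0).astype(int)

    shared_secr = sorted(p for p in part.shared if annot.get(p, 0) == 1)
    excl_secr = sorted(p for p in part.exclusive[target] if annot.get(p, 0) == 1)

    rows = []
    for p in shared_secr:
        lfc = np.nan
        sig = False
        if stats_table is not None and p in stats_table.index:
            lfc = float(stats_table.loc[p, "log2fc"])
            sig = bool(stats_table.loc[p, "significant"])
        rows.append((p, "shared", lfc, sig))
    for p in excl_secr:
        rows.append((p, "exclusive", np.nan, False))
    table = pd.DataFrame(
        rows, columns=["protein_id", "provenance", "log2fc", "significant"]
    ).set_index("protein_id")
    return CandidatePool(target=target, table=table)


def secretome_stats_table(
    scm: SpectralCountMatrix,
    nsaf: pd.DataFrame,
    part: IdentificationPartition,
    stats_table: pd.DataFrame,
    annotation: pd.Series,
    pool: CandidatePool,
) -> pd.DataFrame:
    """Per-protein summary across all detected proteins, for export."""
    ids = sorted(part.detected)
    cls = pd.Series("shared", index=ids)
    for cond, excl in part.exclusive.items():
        cls[cls.index.isin(excl)] = f"exclusive_{cond}"
    out = pd.DataFrame(index=pd.Index(ids, name="protein_id"))
    out["length"] = scm.lengths.reindex(ids)
    for cond in scm.condition_names:
        out[f"mean_nsaf_{cond}"] = nsaf[scm.samples_for(cond)].mean(axis=1).reindex(ids)
    out["log2fc"] = stats_table["log2fc"].reindex(ids)
    out["pvalue"] = stats_table["pvalue"].reindex(ids)
    sig = pd.Series(False, index=out.index)
    common = stats_table.index.intersection(out.index)
    sig.loc[common] = stats_table.loc[common, "significant"].astype(bool)
    out["significant"] = sig
    out["partition"] = cls
    out["secreted"] = annotation.reindex(ids).fillna(0).astype(int)
    out["in_pool"] = out.index.isin(pool.ids)
    return out
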