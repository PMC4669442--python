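"""Reporter-array luminescence reduction.

A transcriptional activity cell array reads a panel of luciferase reporters
(one per transcription factor response element) as photon flux over a time
course, in a treated and a control condition, alongside two kinds of
control wells per plate: non-infected *background* wells (no reporter;
capture substrate autoluminescence) and *TA* wells (basal promoter with no
TF binding elements; capture nonspecific promoter activity).

Reduction proceeds in three steps, each recording what it removed:

1. ``background_filter`` — drop wells whose log2 flux is not above the
   plate/timepoint background, using a one-sided prediction-interval
   exceedance test on the background wells' log2 flux.
2. ``normalize_activity`` — per-well TA normalization on the log2 scale,
   then treated-replicate minus control-mean to give a replicate-level
   normalized log2 fold change y[g, t, r] per reporter g, timepoint t,
   replicate r.  TA normalization cancels plate gain changes.
3. ``remove_outliers`` — within each (reporter, timepoint) replicate group,
   remove values extreme under a normal model of the *other* replicates
   (leave-one-out z, two-sided tail below ``alpha_out``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReporterPlateSet",
    "ActivityProfileSet",
    "background_filter",
    "normalize_activity",
    "remove_outliers",
]

PLATE_COLUMNS = ["plate", "well", "reporter", "condition", "time_h", "replicate", "flux"]


class TracerError(ValueError):
    """Raised for malformed plate data or impossible strata."""


@dataclass
class ReporterPlateSet:
    """Long-format plate records with designated TA and background markers.

    ``data`` columns: plate, well, reporter, condition, time_h, replicate,
    flux.  Rows with ``condition == background_condition`` are non-infected
    wells; rows with ``reporter == ta_reporter`` are basal-promoter control
    wells.
    """

    data: pd.DataFrame = field(repr=False)
    ta_reporter: str = "TA"
    background_condition: str = "background"

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise TracerError(f"plate table missing columns: {missing}")
        if (self.data["flux"] <= 0).any():
            raise TracerError("photon flux must be positive")
        self.data = self.data.reset_index(drop=True)

    @property
    def background(self) -> pd.DataFrame:
        return self.data[self.data["condition"] == self.background_condition]

    @property
    def assay_wells(self) -> pd.DataFrame:
        return self.data[self.data["condition"] != self.background_condition]

    @property
    def reporters(self) -> list[str]:
        r = self.assay_wells["reporter"].unique().tolist()
        return sorted(x for x in r if x != self.ta_reporter)

    def to_csv(self, path) -> None:
        self.data[PLATE_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kw) -> "ReporterPlateSet":
        return cls(data=pd.read_csv(path), **kw)


@dataclass
class ActivityProfileSet:
    """Replicate-level normalized log2 fold change per reporter/timepoint.

    ``values`` columns: reporter, time_h, replicate, y.  ``removed``
    records every cell dropped along the way with its reason
    (below_background | outlier).
    """

    values: pd.DataFrame = field(repr=False)
    removed: pd.DataFrame = field(repr=False)

    @property
    def reporters(self) -> list[str]:
        return sorted(self.values["reporter"].unique())

    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(self.values["time_h"].unique())

    def mean_profiles(self) -> pd.DataFrame:
        """Reporter x timepoint matrix of replicate-mean activity."""
        return self.values.pivot_table(index="reporter", columns="time_h", values="y", aggfunc="mean")

    def to_tsv(self, path) -> None:
        kept = self.values.assign(retained=True, reason="")
        gone = self.removed.assign(retained=False)
        cols = ["reporter", "time_h", "replicate", "y", "retained", "reason"]
        out = kept if gone.empty else pd.concat([kept, gone], ignore_index=True)
        for c in cols:
            if c not in out.columns:
                out[c] = np.nan
        out[cols].sort_values(["reporter", "time_h", "replicate"]).to_csv(path, sep="\t", index=False)


def _background_thresholds(plates: ReporterPlateSet, alpha_bg: float) -> pd.DataFrame:
    """Per (plate, time) one-sided prediction-interval bound on log2 flux."""
    bg = plates.background
    if bg.empty:
        raise TracerError("no background wells present; background filter impossible")
    rows = []
    for (plate, time), grp in bg.groupby(["plate", "time_h"]):
        n = len(grp)
        if n < 2:
            raise TracerError(
                f"stratum (plate={plate}, time={time}) has {n} background well(s); "
                "need >=2 for a background SD"
            )
        logf = np.log2(grp["flux"].to_numpy())
        mean, sd = logf.mean(), logf.std(ddof=1)
        tq = stats.t.ppf(1.0 - alpha_bg, n - 1)
        rows.append((plate, time, mean + tq * sd * np.sqrt(1.0 + 1.0 / n)))
    return pd.DataFrame(rows, columns=["plate", "time_h", "threshold"])


def background_filter(plates: ReporterPlateSet, alpha_bg: float = 0.05) -> ReporterPlateSet:
    """Remove assay wells not above the plate/timepoint background.

    A well is retained iff its log2 flux strictly exceeds
    ``bg_mean + t(1-alpha, n-1) * bg_sd * sqrt(1 + 1/n)`` computed on the
    log2 flux of that stratum's background wells (an upper prediction bound
    for one new background draw).  Removals are recorded on the result's
    ``data`` attribute under ``plates.removed`` with reason
    ``below_background``.
    """
    thr = _background_thresholds(plates, alpha_bg)
    assay = plates.assay_wells.merge(thr, on=["plate", "time_h"], how="left", validate="m:1")
    if assay["threshold"].isna().any():
        bad = assay.loc[assay["threshold"].isna(), ["plate", "time_h"]].drop_duplicates()
        raise TracerError(f"no background wells for strata:\n{bad}")
    keep = np.log2(assay["flux"].to_numpy()) > assay["threshold"].to_numpy()
    removed = assay.loc[~keep, PLATE_COLUMNS].assign(reason="below_background")
    kept = pd.concat(
        [assay.loc[keep, PLATE_COLUMNS], plates.background[PLATE_COLUMNS]], ignore_index=True
    )
    out = ReporterPlateSet(
        data=kept, ta_reporter=plates.ta_reporter, background_condition=plates.background_condition
    )
    out.removed = removed.reset_index(drop=True)  # type: ignore[attr-defined]
    return out


def normalize_activity(
    plates: ReporterPlateSet, treated: str, control: str
) -> ActivityProfileSet:
    """TA-normalize and fold-change against the control condition.

    Per well, a = log2(flux) - mean(log2 flux of TA wells in the same
    (plate, condition, time) stratum).  Per reporter and timepoint,
    y[r] = a_treated[r] - mean_r(a_control); the treated replicate
    structure is carried forward so downstream moderation sees
    replicate-level variance.
    """
    assay = plates.assay_wells
    ta = assay[assay["reporter"] == plates.ta_reporter]
    rep = assay[assay["reporter"] != plates.ta_reporter].copy()
    if rep.empty:
        raise TracerError("no reporter wells after filtering")

    ta_mean = (
        ta.assign(logf=np.log2(ta["flux"]))
        .groupby(["plate", "condition", "time_h"])["logf"]
        .mean()
        .rename("ta_logf")
        .reset_index()
    )
    rep = rep.merge(ta_mean, on=["plate", "condition", "time_h"], how="left", validate="m:1")
    if rep["ta_logf"].isna().any():
        bad = rep.loc[rep["ta_logf"].isna(), ["plate", "condition", "time_h"]].drop_duplicates()
        raise TracerError(f"no retained TA well in strata:\n{bad}")
    rep["a"] = np.log2(rep["flux"]) - rep["ta_logf"]

    tr = rep[rep["condition"] == treated]
    ct = rep[rep["condition"] == control]
    if tr.empty or ct.empty:
        raise TracerError(f"conditions {treated!r}/{control!r} not both present")
    ct_mean = (
        ct.groupby(["reporter", "time_h"])["a"].mean().rename("a_control").reset_index()
    )
    y = tr.merge(ct_mean, on=["reporter", "time_h"], how="left", validate="m:1")
    # (g, t) cells with no retained control replicate are marked missing
    missing = y["a_control"].isna()
    y["y"] = y["a"] - y["a_control"]
    values = y.loc[~missing, ["reporter", "time_h", "replicate", "y"]].reset_index(drop=True)
    removed = getattr(plates, "removed", pd.DataFrame(columns=PLATE_COLUMNS + ["reason"]))
    removed = removed.reindex(columns=list(removed.columns))
    return ActivityProfileSet(values=values, removed=removed)


def remove_outliers(profiles: ActivityProfileSet, alpha_out: float = 0.003) -> ActivityProfileSet:
    """Single-pass leave-one-out outlier removal within replicate groups.

    For each value in a (reporter, timepoint) group of size >= 3, compute
    the z-score against the mean and SD of the *other* replicates and
    remove the value when its two-sided normal tail probability is below
    ``alpha_out``.  If the other replicates are identical (SD = 0) any
    deviating value is removed.  Decisions are made on the original groups
    and applied at once (one pass); groups of size <= 2 are never touched.
    """
    vals = profiles.values.reset_index(drop=True)
    drop_labels: list[int] = []
    zcut = stats.norm.isf(alpha_out / 2.0)
    for _, idx in vals.groupby(["reporter", "time_h"]).groups.items():
        y = vals.loc[idx, "y"].to_numpy()
        n = len(y)
        if n < 3:
            continue
        for j in range(n):
            rest = np.delete(y, j)
            mu, sd = rest.mean(), rest.std(ddof=1)
            if sd == 0:
                extreme = y[j] != mu
            else:
                extreme = abs(y[j] - mu) / sd > zcut
            if extreme:
                drop_labels.append(idx[j])
    drop = vals.index.isin(drop_labels)
    removed_now = vals.loc[drop, ["reporter", "time_h", "replicate", "y"]].assign(reason="outlier")
    if profiles.removed.empty:
        removed = removed_now.reset_index(drop=True)
    else:
        removed = pd.concat([profiles.removed, removed_now], ignore_index=True)
    return ActivityProfileSet(values=vals.loc[~drop].reset_index(drop=True), removed=removed)
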