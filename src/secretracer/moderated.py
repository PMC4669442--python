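"""Empirical-Bayes moderated statistics for reporter time-courses.

With only a few replicates per reporter, per-reporter variance estimates
are unstable and ordinary t-statistics misbehave.  The empirical-Bayes
remedy treats the per-reporter residual variances s_g^2 (d_g df) as draws
from a scaled inverse-chi-square prior with parameters (d0, s0^2),
estimated by moment matching on log s_g^2:

    e_g    = log s_g^2 - digamma(d_g/2) + log(d_g/2)
    var(e) - mean(trigamma(d_g/2)) = trigamma(d0/2)        (solve for d0)
    s0^2   = exp(mean(e) + digamma(d0/2) - log(d0/2))

The posterior variance s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g) shrinks
each reporter toward the prior, and the moderated t

    t~[g,t] = beta[g,t] / (s~_g / sqrt(n[g,t]))

follows a t distribution on d0 + d_g df under the null.  The per-reporter
moderated F is the mean of t~^2 over timepoints, and the log-odds of
differential activity (B statistic) uses a normal prior on true effects
whose variance is estimated from the top fraction of |t~|.

The model here is cell-means by timepoint: beta[g,t] is the replicate mean
of the normalized log2 fold change, and s_g^2 pools residuals across
timepoints within a reporter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

__all__ = ["ModeratedActivityModel", "ModeratedActivityResults", "trigamma_inverse", "fit_f_dist"]

_LARGE_DF = 1e12  # stands in for an infinite-df prior


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0.

    trigamma is strictly decreasing on (0, inf) with range (0, inf), so the
    root is unique; solved by bracketed root-finding.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:  # trigamma(x) ~ 1/x^2 as x -> 0
        return 1.0 / np.sqrt(y)
    if y < 1e-6:  # trigamma(x) ~ 1/x as x -> inf
        return 1.0 / y
    f = lambda x: float(special.polygamma(1, x)) - y
    return float(optimize.brentq(f, 1e-8, 1e8, xtol=1e-12, rtol=1e-14))


def fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled-F prior to observed variances.

    Returns (d0, s0_sq); d0 is inf when the log-variances are no more
    dispersed than sampling alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need >=2 positive residual variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    emean = e.mean()
    evar = np.sum((e - emean) ** 2) / (len(e) - 1)
    evar -= np.mean(special.polygamma(1, df[ok] / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def _tmixture(tstat: np.ndarray, std_unscaled: np.ndarray, df: np.ndarray,
              proportion: float, v0_lim: tuple[float, float] | None = None) -> float:
    """Estimate the prior variance of true effects from the top |t| values."""
    tstat = np.abs(np.asarray(tstat, dtype=float))
    std_unscaled = np.asarray(std_unscaled, dtype=float)
    df = np.asarray(df, dtype=float)
    n = len(tstat)
    ntarget = int(np.ceil(proportion / 2.0 * n))
    if ntarget < 1:
        return np.nan
    p = max(ntarget / n, proportion)
    max_df = df.max()
    low = df < max_df
    if low.any():
        log_tail = stats.t.logsf(tstat[low], df[low])
        tstat = tstat.copy()
        tstat[low] = stats.t.isf(np.exp(log_tail), max_df)
    order = np.argsort(-tstat)[:ntarget]
    tt = tstat[order]
    v1 = std_unscaled[order] ** 2
    r = np.arange(1, ntarget + 1)
    p0 = 2.0 * stats.t.sf(tt, max_df)
    ptarget = ((r - 0.5) / n - (1.0 - p) * p0) / p
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if pos.any():
        qtarget = stats.t.isf(ptarget[pos] / 2.0, max_df)
        v0[pos] = v1[pos] * ((tt[pos] / qtarget) ** 2 - 1.0)
    if v0_lim is not None:
        v0 = np.clip(v0, *v0_lim)
    return float(v0.mean())


class ModeratedActivityModel:
    """Cell-means linear model per reporter with variance moderation.

    Parameters
    ----------
    profiles : ActivityProfileSet or DataFrame
        Replicate-level normalized log2 fold changes with columns
        reporter, time_h, replicate, y.
    moderate : bool
        When False the prior is forced off (d0 = 0) and the statistics
        reduce to ordinary t-tests on the pooled per-reporter variance.
    prior_proportion : float
        Assumed proportion of truly differentially active reporters, used
        only by the log-odds (B) statistic.
    """

    def __init__(self, profiles, moderate: bool = True, prior_proportion: float = 0.01):
        if isinstance(profiles, pd.DataFrame):
            values = profiles
        elif isinstance(getattr(profiles, "values", None), pd.DataFrame):
            values = profiles.values
        else:
            raise TypeError("profiles must be an ActivityProfileSet or a DataFrame")
        self.data = values[["reporter", "time_h", "replicate", "y"]].copy()
        self.moderate = moderate
        self.prior_proportion = prior_proportion

    def fit(self, alpha_adj: float = 0.05) -> "ModeratedActivityResults":
        d = self.data
        reporters = sorted(d["reporter"].unique())
        if len(reporters) < 3:
            raise ValueError("fewer than 3 reporters; variance prior not estimable")

        grp = d.groupby(["reporter", "time_h"])["y"]
        beta = grp.mean()
        nrep = grp.size()
        rss = grp.apply(lambda y: float(((y - y.mean()) ** 2).sum()))

        per_rep = pd.DataFrame({"rss": rss, "n": nrep}).reset_index()
        agg = per_rep.groupby("reporter").agg(rss=("rss", "sum"), n=("n", "sum"),
                                              ncell=("time_h", "size"))
        df_resid = (agg["n"] - agg["ncell"]).astype(float)
        if (df_resid <= 0).all():
            raise ValueError("zero residual df for every reporter; replicates required")
        s2 = np.where(df_resid > 0, agg["rss"] / df_resid.replace(0, np.nan), np.nan)
        s2 = pd.Series(s2, index=agg.index)

        n_pos = int(((s2 > 0) & (df_resid > 0)).sum())
        if self.moderate and n_pos >= 2:
            d0, s0_sq = fit_f_dist(s2.dropna().to_numpy(), df_resid[s2.notna()].to_numpy())
        else:
            # degenerate (near-constant) data: no estimable prior, no shrinkage
            d0, s0_sq = 0.0, 0.0
        d0_eff = min(d0, _LARGE_DF)
        post = (d0_eff * s0_sq + df_resid * s2.fillna(0.0)) / (d0_eff + df_resid)
        df_total = d0_eff + df_resid

        table = pd.DataFrame({"beta": beta, "n": nrep}).reset_index()
        table = table.merge(post.rename("s2_post"), left_on="reporter", right_index=True)
        table = table.merge(df_total.rename("df_total"), left_on="reporter", right_index=True)
        se = np.sqrt(table["s2_post"] / table["n"])
        with np.errstate(divide="ignore", invalid="ignore"):
            table["t_mod"] = np.where(se > 0, table["beta"] / se, 0.0)
        table["pvalue"] = 2.0 * stats.t.sf(np.abs(table["t_mod"]), table["df_total"])

        # BH family: reporters within each timepoint
        table["p_adj"] = np.nan
        for t, idx in table.groupby("time_h").groups.items():
            table.loc[idx, "p_adj"] = multipletests(table.loc[idx, "pvalue"], method="fdr_bh")[1]

        f_mod = table.groupby("reporter")["t_mod"].apply(lambda t: float((t**2).mean()))
        k = table.groupby("reporter")["t_mod"].size().astype(float)
        f_p = stats.f.sf(f_mod, k, df_total.reindex(f_mod.index))

        table["lods"] = self._lods(table, d0_eff, s0_sq)

        active = table.groupby("reporter")["p_adj"].min() < alpha_adj
        per_reporter = pd.DataFrame({
            "s2": s2, "df_resid": df_resid, "s2_post": post, "f_mod": f_mod,
            "f_pvalue": pd.Series(f_p, index=f_mod.index), "active": active,
        })
        return ModeratedActivityResults(
            model=self, d0=float(d0), s0_sq=float(s0_sq), table=table,
            per_reporter=per_reporter, alpha_adj=alpha_adj,
        )

    def _lods(self, table: pd.DataFrame, d0_eff: float, s0_sq: float) -> np.ndarray:
        """Log-odds of differential activity (B statistic), per table row."""
        prop = self.prior_proportion
        su = 1.0 / np.sqrt(table["n"].to_numpy(dtype=float))  # unscaled coefficient SD
        tstat = table["t_mod"].to_numpy(dtype=float)
        dft = table["df_total"].to_numpy(dtype=float)
        lods = np.full(len(table), np.log(prop / (1.0 - prop)))
        # prior variance of true effects estimated per timepoint column
        for _, idx in table.groupby("time_h").groups.items():
            pos = table.index.get_indexer(idx)
            if s0_sq > 0:
                v0_lim = (0.1**2 / s0_sq, 4.0**2 / s0_sq)
                v0 = _tmixture(tstat[pos], su[pos], dft[pos], prop, v0_lim)
            else:
                v0 = 0.0
            if not np.isfinite(v0) or v0 <= 0:
                continue
            r = (su[pos] ** 2 + v0) / su[pos] ** 2
            t2 = tstat[pos] ** 2
            d = dft[pos]
            kernel = np.where(
                d > 1e6,
                t2 * (1.0 - 1.0 / r) / 2.0,
                (1.0 + d) / 2.0 * np.log((t2 + d) / (t2 / r + d)),
            )
            lods[pos] = np.log(prop / (1.0 - prop)) - np.log(r) / 2.0 + kernel
        return lods


@dataclass
class ModeratedActivityResults:
    """Estimates, moderated statistics and activity calls.

    Attributes
    ----------
    d0, s0_sq : float
        Prior degrees of freedom and prior variance of the shrinkage
        target (d0 may be inf when variances are homogeneous).
    table : DataFrame
        Per (reporter, time_h): beta, n, t_mod, pvalue, p_adj, lods.
    per_reporter : DataFrame
        s2, df_resid, s2_post, f_mod, f_pvalue, active.
    """

    model: ModeratedActivityModel
    d0: float
    s0_sq: float
    table: pd.DataFrame = field(repr=False)
    per_reporter: pd.DataFrame = field(repr=False)
    alpha_adj: float = 0.05

    @property
    def active_reporters(self) -> list[str]:
        act = self.per_reporter["active"]
        return sorted(act.index[act])

    def summary(self) -> str:
        lines = [
            "Moderated reporter-activity statistics",
            "=" * 44,
            f"reporters: {len(self.per_reporter)}   cells: {len(self.table)}",
            f"prior df d0: {self.d0:.4g}   prior variance s0^2: {self.s0_sq:.4g}",
            f"active (min BH-adjusted p < {self.alpha_adj:g}): {len(self.active_reporters)}",
            "",
            self.per_reporter.round(4).to_string(),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        t = self.table.merge(
            self.per_reporter[["f_mod", "f_pvalue", "active"]], left_on="reporter",
            right_index=True,
        )
        t.sort_values(["reporter", "time_h"]).to_csv(path, sep="\t", index=False)
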