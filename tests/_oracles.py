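"""Independent straight-line reference computations used only by tests.

Each oracle recomputes a quantity by a different route than the package
(explicit formulas, exact enumeration, bracketed inversion) so that
agreement is evidence, not tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, special


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch two-sided t-test from the textbook formulas: (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * (1.0 - special.stdtr(df, abs(t)))
    return t, df, p


def normal_two_sided_p(z: float) -> float:
    """2 * P(Z > |z|) via the complementary error function."""
    return math.erfc(abs(z) / math.sqrt(2.0))


def t_upper_quantile(alpha: float, df: int) -> float:
    """t such that P(T_df > t) = alpha, by bracketed inversion of the CDF."""
    return optimize.brentq(lambda t: special.stdtr(df, t) - (1.0 - alpha), -500, 500,
                           xtol=1e-13)


def hypergeom_upper_tail(x: int, N: int, K: int, n: int) -> float:
    """P(X >= x) for X ~ Hypergeom(N, K, n) by exact integer enumeration."""
    denom = math.comb(N, n)
    total = 0
    for j in range(max(x, 0, K + n - N), min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, written from scratch."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def trigamma_inverse_newton(y: float, n_iter: int = 100) -> float:
    """Solve trigamma(x) = y by damped Newton iteration (independent of the
    package's bracketed solver)."""
    x = 0.5 + 1.0 / y
    for _ in range(n_iter):
        tri = float(special.polygamma(1, x))
        deriv = float(special.polygamma(2, x))
        step = tri * (1.0 - tri / y) / deriv
        x += step
        if abs(step) < 1e-14 * max(x, 1.0):
            break
    return x


def moderated_oracle(values):
    """Straight-line moderated statistics on a long table.

    ``values``: DataFrame with reporter, time_h, replicate, y.  Returns a
    dict with d0, s0_sq and a row-per-(reporter, time) table of
    (beta, t_mod, pvalue, p_adj), mirroring the moment-matching recipe but
    written linearly with explicit loops.
    """
    reporters = sorted(values["reporter"].unique())
    times = sorted(values["time_h"].unique())

    beta, nrep, s2, dfr = {}, {}, {}, {}
    for g in reporters:
        rss = 0.0
        df = 0
        for t in times:
            y = values[(values["reporter"] == g) & (values["time_h"] == t)]["y"].to_numpy()
            if len(y) == 0:
                continue
            beta[(g, t)] = y.mean()
            nrep[(g, t)] = len(y)
            rss += float(((y - y.mean()) ** 2).sum())
            df += len(y) - 1
        s2[g] = rss / df if df > 0 else np.nan
        dfr[g] = df

    es = []
    for g in reporters:
        if dfr[g] > 0 and s2[g] > 0:
            es.append(math.log(s2[g]) - float(special.digamma(dfr[g] / 2.0))
                      + math.log(dfr[g] / 2.0))
    es = np.array(es)
    emean = es.mean()
    evar = float(((es - emean) ** 2).sum() / (len(es) - 1))
    evar -= float(np.mean([special.polygamma(1, dfr[g] / 2.0)
                           for g in reporters if dfr[g] > 0 and s2[g] > 0]))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse_newton(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0, s0_sq = math.inf, math.exp(emean)

    rows = []
    for g in reporters:
        post = (d0 * s0_sq + dfr[g] * s2[g]) / (d0 + dfr[g]) if math.isfinite(d0) else s0_sq
        for t in times:
            if (g, t) not in beta:
                continue
            tm = beta[(g, t)] / math.sqrt(post / nrep[(g, t)])
            dft = d0 + dfr[g]
            p = 2.0 * (1.0 - special.stdtr(dft, abs(tm))) if math.isfinite(dft) else \
                normal_two_sided_p(tm)
            rows.append((g, t, beta[(g, t)], tm, p))

    # BH within each timepoint across reporters
    out = {}
    for t in times:
        sub = [(g, tt, b, tm, p) for (g, tt, b, tm, p) in rows if tt == t]
        adj = bh_adjust([p for (*_, p) in sub])
        for (g, tt, b, tm, p), a in zip(sub, adj):
            out[(g, tt)] = {"beta": b, "t_mod": tm, "pvalue": p, "p_adj": a}
    return {"d0": d0, "s0_sq": s0_sq, "cells": out}
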