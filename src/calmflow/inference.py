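"""Inferential statistics for the airflow analysis.

Rank tests follow the conventions of interactive stats packages: the
rank-sum Z uses the tie-corrected normal approximation without continuity
correction; the one-sample signed-rank statistic is reported as the centred
rank sum S = sum(sign * rank) with exact enumeration of the 2^n sign
patterns for n <= 12.  The condition x session ANOVA is the fixed-effects
model ``response ~ condition + session + condition:session + participant``
(additive participant block) with every F tested against the residual mean
square, so the error degrees of freedom are
``N - 1 - (a-1) - (b-1) - (a-1)(b-1) - (n-1)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class StatResult:
    """Outcome of one statistical test."""

    test: str
    statistic_name: str            # one of Z, W, F, t, r, S
    value: float
    p_value: float
    df: tuple[int, ...] | None = None
    sided: str = "two-sided"
    n: tuple[int, ...] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    def to_row(self) -> dict:
        df1 = self.df[0] if self.df else None
        df2 = self.df[1] if self.df and len(self.df) > 1 else None
        return {"test": self.test, "statistic": self.statistic_name,
                "value": self.value, "df1": df1, "df2": df2,
                "p": self.p_value, "sided": self.sided,
                "n": "x".join(map(str, self.n)) if self.n else None}


def _check_sample(x, name="sample"):
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def wilcoxon_ranksum(x, y, sided: str = "two-sided") -> StatResult:
    """Wilcoxon rank-sum (Mann-Whitney) test via the normal approximation.

    Midranks are used for ties; the variance is tie-corrected; no
    continuity correction is applied.  Z is signed by x's rank sum relative
    to its null expectation.
    """
    x, y = _check_sample(x, "x"), _check_sample(y, "y")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = ranks[:n1].sum()
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts)
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        raise ValueError("degenerate rank variance (all pooled values tied)")
    z = (w - mean_w) / math.sqrt(var_w)
    if sided == "two-sided":
        p = 2.0 * sps.norm.sf(abs(z))
    elif sided == "greater":
        p = sps.norm.sf(z)
    elif sided == "less":
        p = sps.norm.cdf(z)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return StatResult("wilcoxon_ranksum", "Z", z, min(p, 1.0),
                      sided=sided, n=(n1, n2), extra={"rank_sum_x": w})


def _exact_signed_rank_p(ranks: np.ndarray, s_obs: float,
                         alternative: str) -> float:
    """Exact p for the centred signed-rank sum by enumerating sign patterns."""
    n = len(ranks)
    totals = np.zeros(1)
    for r in ranks:  # distribution of sum(+-r) by convolution over signs
        totals = np.concatenate([totals + r, totals - r])
    if alternative == "greater":
        return float(np.mean(totals >= s_obs - 1e-12))
    if alternative == "less":
        return float(np.mean(totals <= s_obs + 1e-12))
    return float(min(1.0, 2.0 * min(np.mean(totals >= s_obs - 1e-12),
                                    np.mean(totals <= s_obs + 1e-12))))


def wilcoxon_signedrank_one_sample(x, mu0: float = 0.0,
                                   alternative: str = "greater",
                                   exact_max_n: int = 12) -> StatResult:
    """One-sample signed-rank test of location against ``mu0``.

    The reported statistic is the centred rank sum S = sum(sign(d) * rank)
    over non-zero differences d = x - mu0 (midranks of |d| for ties).  For
    n <= ``exact_max_n`` the p-value is exact by enumeration of all sign
    patterns; otherwise the normal approximation Z = S / sqrt(sum rank^2)
    is used.  ``alternative`` refers to the location of x relative to mu0.
    """
    x = _check_sample(x)
    d = x - mu0
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all observations equal mu0")
    ranks = sps.rankdata(np.abs(d))
    s = float(np.sum(np.sign(d) * ranks))
    z = s / math.sqrt(float(np.sum(ranks ** 2)))
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, s, alternative)
        method = "exact"
    else:
        if alternative == "greater":
            p = sps.norm.sf(z)
        elif alternative == "less":
            p = sps.norm.cdf(z)
        else:
            p = 2.0 * sps.norm.sf(abs(z))
        method = "normal"
    return StatResult("wilcoxon_signedrank", "S", s, min(p, 1.0),
                      sided=alternative, n=(n,),
                      extra={"z": z, "method": method})


def anova_condition_session(table: pd.DataFrame, response: str = "value_uV",
                            ) -> dict[str, StatResult]:
    """Two-way condition x session ANOVA with an additive participant block.

    ``table`` must hold a complete crossed design: every
    (participant, condition, session) cell exactly once.  Sums of squares
    come from the balanced-design decomposition (equivalent to OLS on
    condition + session + interaction + participant); each F is tested
    against the residual mean square.  Returns StatResults keyed
    'condition', 'session', 'interaction'.
    """
    df = table[["participant", "condition", "session", response]].copy()
    parts = df["participant"].unique()
    conds = df["condition"].unique()
    sessions = df["session"].unique()
    a, b, n = len(conds), len(sessions), len(parts)
    if a < 2 or b < 2 or n < 2:
        raise ValueError("need >= 2 levels of condition, session, participant")
    counts = df.groupby(["participant", "condition", "session"]).size()
    if len(counts) != a * b * n or (counts != 1).any():
        expected = set(itertools.product(parts, conds, sessions))
        missing = sorted(expected - set(counts.index), key=str)
        raise ValueError(f"unbalanced design; missing/duplicated cells, "
                         f"e.g. {missing[:5]}")
    y = df[response].to_numpy(dtype=float)
    gm = y.mean()

    def group_ss(cols):
        g = df.groupby(cols, sort=True)[response].mean()
        k = df.groupby(cols, sort=True).size()
        return float((k * (g - gm) ** 2).sum()), g

    ss_c, _ = group_ss("condition")
    ss_s, _ = group_ss("session")
    ss_p, _ = group_ss("participant")
    cell = df.groupby(["condition", "session"])[response].mean().unstack()
    yc = df.groupby("condition")[response].mean()
    ys = df.groupby("session")[response].mean()
    ss_i = n * float(((cell.sub(yc, axis=0).sub(ys, axis=1) + gm) ** 2)
                     .to_numpy().sum())
    ss_tot = float(((y - gm) ** 2).sum())
    ss_res = ss_tot - ss_c - ss_s - ss_i - ss_p
    n_obs = a * b * n
    df_res = n_obs - 1 - (a - 1) - (b - 1) - (a - 1) * (b - 1) - (n - 1)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_res = max(ss_res, 0.0) / df_res

    def f_result(name, ss, df1):
        if ms_res == 0:
            raise ValueError("zero residual mean square")
        f = (ss / df1) / ms_res
        p = float(sps.f.sf(f, df1, df_res))
        return StatResult(f"anova_{name}", "F", f, p, df=(df1, df_res),
                          n=(n,), extra={"ss": ss, "ms_resid": ms_res})

    return {"condition": f_result("condition", ss_c, a - 1),
            "session": f_result("session", ss_s, b - 1),
            "interaction": f_result("interaction", ss_i, (a - 1) * (b - 1))}


def pearson_correlation(x, y) -> StatResult:
    """Pearson r with the two-sided t-based p-value."""
    x, y = _check_sample(x, "x"), _check_sample(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        t, p = math.inf * math.copysign(1, r), 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return StatResult("pearson", "r", r, min(p, 1.0), df=(n - 2,), n=(n,),
                      extra={"t": t})


def paired_ttest(first, last, sided: str = "two-sided",
                 mode: str = "paired") -> StatResult:
    """t comparison of two matched samples (default last vs first, paired).

    ``mode='paired'`` tests the mean of (last - first) with df = n - 1;
    ``mode='pooled'`` is the two-sample equal-variance t with df = 2n - 2
    (both conventions appear in reports of within-subject skin-temperature
    comparisons).
    """
    first, last = _check_sample(first, "first"), _check_sample(last, "last")
    if len(first) != len(last):
        raise ValueError("samples must have equal length")
    n = len(first)
    if n < 2:
        raise ValueError("need n >= 2")
    if mode == "paired":
        d = last - first
        sd = d.std(ddof=1)
        if np.all(d == 0):  # no change at all: t is 0 by convention
            t, sd = 0.0, 1.0
        elif sd == 0:
            raise ValueError("zero-variance paired differences")
        else:
            t = d.mean() / (sd / math.sqrt(n))
        df_ = n - 1
    elif mode == "pooled":
        s2 = (first.var(ddof=1) + last.var(ddof=1)) / 2.0
        if s2 == 0:
            raise ValueError("zero pooled variance")
        t = (last.mean() - first.mean()) / math.sqrt(s2 * 2.0 / n)
        df_ = 2 * n - 2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if sided == "two-sided":
        p = 2.0 * float(sps.t.sf(abs(t), df_))
    elif sided == "greater":
        p = float(sps.t.sf(t, df_))
    elif sided == "less":
        p = float(sps.t.cdf(t, df_))
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return StatResult("paired_t" if mode == "paired" else "pooled_t", "t",
                      float(t), min(p, 1.0), df=(df_,), n=(n,))


def two_point_slope(differential_table: pd.DataFrame,
                    comfort_table: pd.DataFrame,
                    scale: str = "PPD",
                    orientation: str = "ac_minus_rs") -> pd.DataFrame:
    """Per participant-session slope of EEG change against a comfort scale.

    NOTE: this index is a reconstruction (its original definition is not
    published); the frame's ``attrs['definition']`` records that.

    For each (participant, session, channel, band) present under both
    conditions, slope = (Y_AC - Y_RS) / (X_AC - X_RS) where Y is the
    differential band amplitude and X the session's scale value (PMV or
    PPD) under each condition.  Rows with X_AC == X_RS are omitted with a
    logged reason.  ``comfort_table`` needs columns participant, condition,
    session, value.
    """
    if scale not in ("PMV", "PPD"):
        raise ValueError("scale must be 'PMV' or 'PPD'")
    if orientation not in ("ac_minus_rs", "rs_minus_ac"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sgn = 1.0 if orientation == "ac_minus_rs" else -1.0
    xkey = ["participant", "session"]
    xs = comfort_table.pivot_table(index=xkey, columns="condition",
                                   values="value", aggfunc="first")
    ys = differential_table.pivot_table(
        index=xkey + ["channel", "band"], columns="condition",
        values="value_uV", aggfunc="first")
    rows, skipped = [], []
    for (pid, sess, ch, band), row in ys.iterrows():
        if not {"AC", "RS"}.issubset(row.dropna().index):
            skipped.append(((pid, sess, ch, band), "missing condition"))
            continue
        try:
            xac, xrs = xs.loc[(pid, sess), "AC"], xs.loc[(pid, sess), "RS"]
        except KeyError:
            skipped.append(((pid, sess, ch, band), "missing scale value"))
            continue
        dx = xac - xrs
        if dx == 0 or not np.isfinite(dx):
            skipped.append(((pid, sess, ch, band), "zero scale difference"))
            continue
        slope = sgn * (row["AC"] - row["RS"]) / (sgn * dx)
        rows.append((pid, sess, scale, band, ch, float(slope)))
    out = pd.DataFrame(rows, columns=["participant", "session", "scale",
                                      "band", "channel", "slope"])
    out.attrs["definition"] = ("reconstructed two-point slope: "
                               "(Y_AC - Y_RS) / (X_AC - X_RS) per "
                               "participant-session")
    out.attrs["orientation"] = orientation
    out.attrs["skipped"] = skipped
    return out


def slope_tests_by_session(slopes: pd.DataFrame,
                           alternative: str = "greater"
                           ) -> dict[int, StatResult]:
    """One-sample one-sided signed-rank test of the slopes against zero,
    per session (sessions after the baseline)."""
    out = {}
    for sess, grp in slopes.groupby("session"):
        vals = grp["slope"].to_numpy()
        if len(vals) == 0 or np.all(vals == 0):
            continue
        out[int(sess)] = wilcoxon_signedrank_one_sample(
            vals, 0.0, alternative=alternative)
    return out
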