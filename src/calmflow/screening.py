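"""Two-stage cohort screening: jackknife Mahalanobis candidates, then rules.

Stage one computes, for each participant's feature vector, the Mahalanobis
distance to the mean/covariance estimated with that participant left out
(the jackknifed distance).  Under multivariate normality the squared
leave-one-out distance follows a scaled F distribution,

    d_i^2  ~  p (m^2 - 1) / (m (m - p)) * F_{p, m-p},    m = n - 1,

which yields the alpha-level upper control limit (UCL) on the distance
scale.  Participants above the UCL are outlier *candidates* only.

Stage two applies the study's hard exclusion rules (seasonal bounds on the
per-session delta-band mean amplitude and on the differential task duration)
and pass-through experimenter-error flags.  A participant is excluded when
they are a candidate confirmed by at least one rule violation, or carry an
experimenter-error flag; rules alone may also be applied when no candidate
stage was run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

#: seasonal exclusion thresholds
DELTA_AMPLITUDE_LIMIT_UV = {"cooling": 6.0, "heating": 60.0}
#: differential task duration (TTL) bound: (comparison, seconds)
TTL_DIFFERENTIAL_LIMIT_S = {"cooling": ("lt", -15.0), "heating": ("gt", 95.0)}


@dataclass
class OutlierReport:
    """Per-participant screening outcome.

    ``table`` has one row per participant with columns distance, ucl,
    candidate, rules (list of violated rule names), experimenter_error,
    decision ('retain'/'exclude').
    """

    table: pd.DataFrame
    alpha: float = 0.05
    ucl: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.table)

    @property
    def n_retained(self) -> int:
        return int((self.table["decision"] == "retain").sum())

    @property
    def retained(self) -> list:
        return self.table.index[self.table["decision"] == "retain"].tolist()

    @property
    def excluded(self) -> list:
        return self.table.index[self.table["decision"] == "exclude"].tolist()

    def to_json_dict(self) -> dict:
        rows = {}
        for pid, row in self.table.iterrows():
            rows[str(pid)] = {
                "distance": None if pd.isna(row.get("distance", np.nan))
                else float(row["distance"]),
                "candidate": bool(row.get("candidate", False)),
                "rules": list(row.get("rules", []) or []),
                "experimenter_error": bool(row.get("experimenter_error",
                                                   False)),
                "decision": str(row["decision"]),
            }
        return {"alpha": self.alpha,
                "ucl": None if self.ucl is None else float(self.ucl),
                "n_input": self.n_input, "n_retained": self.n_retained,
                "participants": rows, **self.meta}

    def log_lines(self) -> list[str]:
        lines = [f"screening: n_input={self.n_input} "
                 f"n_retained={self.n_retained} "
                 f"alpha={self.alpha} ucl={self.ucl}"]
        for pid, row in self.table.iterrows():
            why = []
            if row.get("candidate", False):
                why.append(f"distance {row['distance']:.2f} > UCL")
            why += list(row.get("rules", []) or [])
            if row.get("experimenter_error", False):
                why.append("experimenter error")
            lines.append(f"  {pid}: {row['decision']}"
                         + (f" ({'; '.join(why)})" if why else ""))
        return lines


def jackknife_ucl(n: int, p: int, alpha: float = 0.05) -> float:
    """Alpha-level UCL for jackknifed Mahalanobis distances at (n, p)."""
    m = n - 1
    if m <= p:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    scale = p * (m * m - 1) / (m * (m - p))
    return float(np.sqrt(scale * sps.f.ppf(1.0 - alpha, p, m - p)))


def jackknife_mahalanobis(data, alpha: float = 0.05,
                          labels=None) -> OutlierReport:
    """Leave-one-out Mahalanobis distances and alpha-level candidates.

    ``data`` is an (n, p) matrix, one row per participant.  Distances are
    computed against the mean and (unbiased) covariance of the other n - 1
    rows, via a Sherman-Morrison downdate of the full-sample covariance.
    Candidates are rows whose distance exceeds the UCL.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in data")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    const_cols = [j for j in range(p) if np.ptp(x[:, j]) == 0]
    if const_cols:
        raise ValueError(f"constant columns {const_cols} make the "
                         "covariance singular")
    xbar = x.mean(axis=0)
    v = x - xbar
    s = np.cov(x, rowvar=False, ddof=1).reshape(p, p)
    try:
        q = np.einsum("ij,ij->i", v, np.linalg.solve(s, v.T).T)  # full d^2
    except np.linalg.LinAlgError:
        raise ValueError("singular full-sample covariance") from None
    # leave-one-out: d_i^2 = c^2 (n-2) (q/(n-1)) / (1 - c q/(n-1)), c=n/(n-1)
    c = n / (n - 1.0)
    denom = 1.0 - c * q / (n - 1.0)
    if np.any(denom <= 1e-12):
        bad = np.nonzero(denom <= 1e-12)[0]
        raise ValueError(f"singular leave-one-out covariance for rows "
                         f"{bad.tolist()}")
    d2 = c * c * (n - 2.0) * (q / (n - 1.0)) / denom
    d = np.sqrt(d2)
    ucl = jackknife_ucl(n, p, alpha)
    idx = list(labels) if labels is not None else list(range(n))
    table = pd.DataFrame({
        "distance": d,
        "ucl": ucl,
        "candidate": d > ucl,
        "rules": [[] for _ in range(n)],
        "experimenter_error": False,
        "decision": np.where(d > ucl, "candidate", "retain"),
    }, index=pd.Index(idx, name="participant"))
    return OutlierReport(table=table, alpha=alpha, ucl=ucl,
                         meta={"n": n, "p": p})


def _delta_rule_violations(band_table: pd.DataFrame, season: str) -> dict:
    limit = DELTA_AMPLITUDE_LIMIT_UV[season]
    delta = band_table[band_table["band"] == "delta"]
    # per-session mean over channels, any condition
    per_session = (delta.groupby(["participant", "condition", "session"])
                   ["value_uV"].mean())
    out: dict = {}
    for (pid, cond, sess), val in per_session.items():
        if val > limit:
            out.setdefault(pid, []).append(
                f"delta band mean {val:.2f} uV > {limit} uV "
                f"({cond}, session {sess})")
    return out


def _ttl_rule_violations(ttl_table: pd.DataFrame, season: str) -> dict:
    op, bound = TTL_DIFFERENTIAL_LIMIT_S[season]
    out: dict = {}
    rows = ttl_table[ttl_table["session"] > 1]
    for _, row in rows.iterrows():
        v = row["ttl_differential_s"]
        hit = v < bound if op == "lt" else v > bound
        if hit:
            sign = "<" if op == "lt" else ">"
            out.setdefault(row["participant"], []).append(
                f"differential TTL {v:.1f} s {sign} {bound} s "
                f"({row['condition']}, session {int(row['session'])})")
    return out


def apply_exclusion_rules(band_table: pd.DataFrame | None,
                          ttl_table: pd.DataFrame | None,
                          season: str,
                          candidates: OutlierReport | None = None,
                          experimenter_errors=(),
                          participants=None) -> OutlierReport:
    """Rule-based exclusion stage, optionally gated on candidate flags.

    ``ttl_table`` needs columns participant, condition, session,
    ttl_differential_s (change of total task duration from the guided first
    session).  When ``candidates`` is given (from
    :func:`jackknife_mahalanobis`), exclusion requires candidate AND a rule
    violation, or an experimenter-error flag; without it, a rule violation
    alone excludes.
    """
    if season not in DELTA_AMPLITUDE_LIMIT_UV:
        raise ValueError(f"unknown season {season!r}")
    if band_table is None and ttl_table is None:
        raise ValueError("no measurement tables provided")
    violations: dict = {}
    if band_table is not None:
        for pid, msgs in _delta_rule_violations(band_table, season).items():
            violations.setdefault(pid, []).extend(msgs)
    if ttl_table is not None:
        for pid, msgs in _ttl_rule_violations(ttl_table, season).items():
            violations.setdefault(pid, []).extend(msgs)

    if participants is None:
        pool: list = []
        for t in (band_table, ttl_table):
            if t is not None:
                pool.extend(t["participant"].unique().tolist())
        participants = sorted(set(pool), key=str)
    errors = set(experimenter_errors)

    rows = []
    for pid in participants:
        rules = violations.get(pid, [])
        is_candidate = True
        dist = np.nan
        if candidates is not None:
            if pid in candidates.table.index:
                is_candidate = bool(candidates.table.loc[pid, "candidate"])
                dist = float(candidates.table.loc[pid, "distance"])
            else:
                is_candidate = False
        exclude = (pid in errors) or (bool(rules) and is_candidate)
        rows.append({"participant": pid, "distance": dist,
                     "candidate": candidates is not None and is_candidate,
                     "rules": rules,
                     "experimenter_error": pid in errors,
                     "decision": "exclude" if exclude else "retain"})
    table = pd.DataFrame(rows).set_index("participant")
    alpha = candidates.alpha if candidates is not None else 0.05
    ucl = candidates.ucl if candidates is not None else None
    return OutlierReport(table=table, alpha=alpha, ucl=ucl,
                         meta={"season": season,
                               "gated_on_candidates": candidates is not None})
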