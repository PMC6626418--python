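"""Kaplan-Meier estimation and Mantel-Haenszel (log-rank) comparison of
cluster cohorts.

The estimators are written out directly (rather than wrapped from a survival
library) so the tie convention — events precede censorings at equal times —
and the most-disparate-pair reporting are exactly as specified; library
implementations serve as independent cross-checks in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Product-limit curve: survival defined at the distinct event times."""

    event_times: np.ndarray  # ascending, distinct times with >= 1 event
    survival: np.ndarray  # S(t) at each event time, non-increasing
    at_risk: np.ndarray  # risk-set size just before each event time
    n_events: np.ndarray  # events at each event time
    n_samples: int
    median: float  # smallest event time with S(t) <= 0.5, else max observed time
    median_is_lower_bound: bool  # True when the curve never reaches 0.5

    @property
    def median_label(self) -> str:
        if self.median_is_lower_bound:
            return f"> {self.median:g}"
        return f"{self.median:g}"


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    group_sizes: tuple[int, ...]


def _validate(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape or time.ndim != 1:
        raise ValueError("time and event must be 1-D arrays of equal length")
    if len(time) == 0:
        raise ValueError("need at least one record")
    if np.any(time < 0):
        raise ValueError("negative survival time")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    return time, event


def km_estimate(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    At tied times, events are processed before censorings (censored samples
    remain in the risk set for events at their own time).
    """
    time, event = _validate(time, event)
    n = len(time)
    event_times = np.unique(time[event == 1])
    surv = np.empty(len(event_times))
    at_risk = np.empty(len(event_times), dtype=int)
    n_events = np.empty(len(event_times), dtype=int)
    s = 1.0
    for i, t in enumerate(event_times):
        r = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        s *= 1.0 - d / r
        surv[i] = s
        at_risk[i] = r
        n_events[i] = d
    max_time = float(time.max())
    below = np.nonzero(surv <= 0.5)[0] if len(surv) else np.array([], dtype=int)
    if below.size:
        median, lower_bound = float(event_times[below[0]]), False
    else:
        median, lower_bound = max_time, True
    return KMCurve(
        event_times=event_times,
        survival=surv,
        at_risk=at_risk,
        n_events=n_events,
        n_samples=n,
        median=median,
        median_is_lower_bound=lower_bound,
    )


def logrank_k(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> LogRankResult:
    """K-group Mantel-Haenszel log-rank test.

    Builds the hypergeometric observed-minus-expected table at each distinct
    event time; the statistic is quadratic in O-E with the usual covariance.
    """
    time, event = _validate(time, event)
    group = np.asarray(group)
    if group.shape != time.shape:
        raise ValueError("group length mismatch")
    groups = np.unique(group)
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    if event.sum() == 0:
        raise ValueError("log-rank test undefined with zero events")

    gidx = np.searchsorted(groups, group)
    event_times = np.unique(time[event == 1])
    oe = np.zeros(k)
    cov = np.zeros((k, k))
    for t in event_times:
        at_risk = time >= t
        n_t = int(at_risk.sum())
        d_t = int(np.sum((time == t) & (event == 1)))
        n_j = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_j = np.bincount(
            gidx[(time == t) & (event == 1)], minlength=k
        ).astype(float)
        e_j = d_t * n_j / n_t
        oe += d_j - e_j
        if n_t > 1:
            frac = n_j / n_t
            v = d_t * (n_t - d_t) / (n_t - 1)
            cov += v * (np.diag(frac) - np.outer(frac, frac))

    # statistic uses the first k-1 groups (the covariance matrix is singular)
    sub = slice(0, k - 1)
    cov_sub = cov[sub, sub]
    try:
        chi2 = float(oe[sub] @ np.linalg.solve(cov_sub, oe[sub]))
    except np.linalg.LinAlgError:
        chi2 = float(oe[sub] @ np.linalg.pinv(cov_sub) @ oe[sub])
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    sizes = tuple(int(np.sum(group == g)) for g in groups)
    return LogRankResult(chi_square=chi2, df=df, p_value=p, group_sizes=sizes)


def logrank(
    time_a: np.ndarray,
    event_a: np.ndarray,
    time_b: np.ndarray,
    event_b: np.ndarray,
) -> LogRankResult:
    """Two-group Mantel-Haenszel log-rank test (chi-square with 1 df)."""
    time_a, event_a = _validate(time_a, event_a)
    time_b, event_b = _validate(time_b, event_b)
    time = np.concatenate([time_a, time_b])
    event = np.concatenate([event_a, event_b])
    group = np.concatenate([np.zeros(len(time_a), dtype=int), np.ones(len(time_b), dtype=int)])
    return logrank_k(time, event, group)


@dataclass
class ClusterSurvivalReport:
    curves: dict[int, KMCurve]
    medians: dict[int, str]
    pairwise: list[dict]  # cluster_a, cluster_b, chi_square, p_value, p_bonferroni
    overall: LogRankResult | None
    headline_p: float | None  # minimum unadjusted pairwise p ("most disparate pair")
    headline_pair: tuple[int, int] | None
    n_dropped_missing: int = 0
    excluded_clusters: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "medians": {str(k): v for k, v in self.medians.items()},
            "pairwise": self.pairwise,
            "overall": None
            if self.overall is None
            else {
                "chi_square": self.overall.chi_square,
                "df": self.overall.df,
                "p_value": self.overall.p_value,
            },
            "headline_p": self.headline_p,
            "headline_pair": list(self.headline_pair) if self.headline_pair else None,
            "n_dropped_missing": self.n_dropped_missing,
            "excluded_clusters": self.excluded_clusters,
        }


def compare_clusters(
    labels_by_sample: dict[str, int],
    pheno,
    *,
    min_group_size: int = 5,
) -> ClusterSurvivalReport:
    """Per-cluster KM curves plus pairwise and overall log-rank comparisons.

    The headline p-value is the minimum unadjusted pairwise p (the most
    disparate pair of curves); a Bonferroni-adjusted value accompanies every
    pair because that minimum is anti-conservative.
    """
    pheno_ids = set(pheno.sample_ids)
    labeled = {s: l for s, l in labels_by_sample.items() if s in pheno_ids}
    n_dropped = len(labels_by_sample) - len(labeled)
    if n_dropped:
        logger.warning("dropped %d labeled samples without survival data", n_dropped)
    if not labeled:
        raise ValueError("no labeled samples with survival data")

    idx = {s: i for i, s in enumerate(pheno.sample_ids)}
    clusters = sorted(set(labeled.values()))
    arrays: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    excluded: list[int] = []
    for c in clusters:
        members = [s for s, l in labeled.items() if l == c]
        if len(members) < min_group_size:
            logger.warning("cluster %d has %d samples (< %d); excluded", c, len(members), min_group_size)
            excluded.append(c)
            continue
        take = [idx[s] for s in members]
        arrays[c] = (pheno.os_time[take], pheno.os_event[take])

    curves = {c: km_estimate(t, e) for c, (t, e) in arrays.items()}
    medians = {c: curve.median_label for c, curve in curves.items()}

    kept = sorted(arrays)
    pairwise: list[dict] = []
    overall = None
    headline_p = None
    headline_pair = None
    if len(kept) >= 2:
        n_pairs = len(kept) * (len(kept) - 1) // 2
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                ta, ea = arrays[a]
                tb, eb = arrays[b]
                if ea.sum() + eb.sum() == 0:
                    logger.warning("pair (%d, %d) has zero events; skipped", a, b)
                    continue
                res = logrank(ta, ea, tb, eb)
                pairwise.append(
                    {
                        "cluster_a": a,
                        "cluster_b": b,
                        "chi_square": res.chi_square,
                        "p_value": res.p_value,
                        "p_bonferroni": min(1.0, res.p_value * n_pairs),
                    }
                )
        time = np.concatenate([arrays[c][0] for c in kept])
        event = np.concatenate([arrays[c][1] for c in kept])
        group = np.concatenate([np.full(len(arrays[c][0]), c) for c in kept])
        if event.sum() > 0:
            overall = logrank_k(time, event, group)
        if pairwise:
            best = min(pairwise, key=lambda r: r["p_value"])
            headline_p = best["p_value"]
            headline_pair = (best["cluster_a"], best["cluster_b"])

    return ClusterSurvivalReport(
        curves=curves,
        medians=medians,
        pairwise=pairwise,
        overall=overall,
        headline_p=headline_p,
        headline_pair=headline_pair,
        n_dropped_missing=n_dropped,
        excluded_clusters=excluded,
    )
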