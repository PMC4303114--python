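"""Xenograft time-to-event endpoints from tumor-volume trajectories.

Tumor volume from caliper diameters is ``vol = width^2 x length / 2``.
Two endpoints are derived relative to the volume at randomization (day 0):

* **TTR** (time to tumor regression): first measurement day with volume at
  or below half the baseline.
* **TTP** (time to tumor progression): first measurement day with volume
  at or above twice the baseline.

Subjects never crossing within the follow-up horizon are censored at their
last observation or at the horizon, whichever is earlier.  Event timing is
the first measurement at/after the true crossing -- tumors are measured on
a weekly-style grid, so only grid times are observable and no interpolation
is attempted.  Animals harvested early (e.g. at the 1,000 mm^3 stop rule)
simply contribute a truncated series: progression is an event if doubling
occurred by harvest, otherwise the subject is censored at harvest.

Arms are compared with the Kaplan-Meier estimator (median = first time the
survival curve reaches 0.5 or below, "not achieved" if it never does; 95%
CI by the log-log transform) and the Gehan-Breslow generalized Wilcoxon
two-sample test, which weights early differences more heavily than the
log-rank test -- appropriate when regression happens early if at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from lifelines.utils import median_survival_times

from .errors import InputError

__all__ = [
    "TumorTrajectory",
    "EndpointTable",
    "KMResult",
    "GehanResult",
    "volume",
    "endpoint",
    "endpoint_table",
    "km_fit",
    "gehan_wilcoxon",
    "response_fraction",
]


def volume(width: float, length: float) -> float:
    """Tumor volume (mm^3) from caliper width and length (mm): w^2 * l / 2."""
    if width <= 0 or length <= 0:
        raise InputError("width and length must be positive")
    return width**2 * length / 2.0


@dataclass
class TumorTrajectory:
    """One subject's tumor-volume time series since randomization.

    ``days`` must be non-decreasing and include day 0; ``volumes`` (mm^3)
    must be positive.  The day-0 volume is the randomization baseline that
    the TTR/TTP thresholds refer to.
    """

    subject: str
    arm: str
    days: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if len(self.days) == 0:
            raise InputError(f"{self.subject}: empty trajectory")
        if len(self.days) != len(self.volumes):
            raise InputError(f"{self.subject}: days/volumes length mismatch")
        if np.any(np.diff(self.days) < 0):
            raise InputError(f"{self.subject}: days must be non-decreasing")
        if self.days[0] != 0:
            raise InputError(f"{self.subject}: day 0 baseline required")
        if np.any(self.volumes <= 0):
            raise InputError(f"{self.subject}: volumes must be positive")

    @classmethod
    def from_diameters(
        cls, subject: str, arm: str, days, widths, lengths
    ) -> "TumorTrajectory":
        """Build a trajectory from caliper width/length series."""
        vols = [volume(w, l) for w, l in zip(widths, lengths, strict=True)]
        return cls(subject=subject, arm=arm, days=days, volumes=np.array(vols))

    @property
    def baseline(self) -> float:
        return float(self.volumes[0])


@dataclass
class EndpointTable:
    """Per-subject event times for one endpoint.

    ``df`` columns: ``subject``, ``arm``, ``time`` (days), ``event``
    (1 = crossed the threshold, 0 = censored).
    """

    df: pd.DataFrame
    kind: str       # "TTR" or "TTP"
    horizon: float

    def __post_init__(self) -> None:
        if len(self.df) == 0:
            raise InputError("empty endpoint table")
        if (self.df["time"] > self.horizon).any():
            raise InputError("event/censoring times exceed the horizon")

    def arm_table(self, arm: str) -> "EndpointTable":
        sub = self.df[self.df["arm"] == arm]
        if len(sub) == 0:
            raise InputError(f"no subjects in arm {arm!r}")
        return EndpointTable(sub.reset_index(drop=True), self.kind, self.horizon)


def endpoint(
    traj: TumorTrajectory, kind: str, horizon: float = 470.0
) -> tuple[float, int]:
    """Event time and indicator for one trajectory.

    TTR: first day with volume <= 0.5 x baseline; TTP: first day with
    volume >= 2 x baseline.  Only measurements up to ``horizon`` count; a
    subject never crossing is censored at min(last observation, horizon).
    """
    if kind not in ("TTR", "TTP"):
        raise InputError(f"unknown endpoint kind {kind!r}")
    in_window = traj.days <= horizon
    days = traj.days[in_window]
    vols = traj.volumes[in_window]
    if len(days) == 0:
        raise InputError(f"{traj.subject}: no measurements within horizon")
    if kind == "TTR":
        crossed = vols <= 0.5 * traj.baseline
    else:
        crossed = vols >= 2.0 * traj.baseline
    idx = np.flatnonzero(crossed)
    if len(idx) > 0:
        return float(days[idx[0]]), 1
    return float(min(days[-1], horizon)), 0


def endpoint_table(
    trajectories: list[TumorTrajectory], kind: str, horizon: float = 470.0
) -> EndpointTable:
    """Derive per-subject event times for a batch of trajectories."""
    if not trajectories:
        raise InputError("no trajectories given")
    rows = []
    for traj in trajectories:
        time, event = endpoint(traj, kind, horizon)
        rows.append(
            {"subject": traj.subject, "arm": traj.arm, "time": time, "event": event}
        )
    return EndpointTable(pd.DataFrame(rows), kind=kind, horizon=horizon)


@dataclass
class KMResult:
    """Kaplan-Meier fit summary: median (inf = not achieved) with 95% CI."""

    median: float
    ci_lower: float
    ci_upper: float
    survival: pd.DataFrame      # index: time; column "S"
    n_subjects: int
    n_events: int

    @property
    def median_achieved(self) -> bool:
        return math.isfinite(self.median)

    @staticmethod
    def _fmt(x: float) -> str:
        return "NA" if not math.isfinite(x) else f"{x:g}"

    def format_median(self) -> str:
        """Table-style ``median (lower-upper)`` with NA for not-achieved."""
        return (
            f"{self._fmt(self.median)} "
            f"({self._fmt(self.ci_lower)}-{self._fmt(self.ci_upper)})"
        )


def km_fit(table: EndpointTable) -> KMResult:
    """Product-limit estimate of the endpoint distribution.

    The median is the first time the survival curve is at or below 0.5,
    reported as ``inf`` ("not achieved") when the curve never reaches it.
    The 95% CI of the median comes from inverting the log-log
    (exponential-Greenwood) confidence band.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(table.df["time"], table.df["event"])
    ci = median_survival_times(kmf.confidence_interval_)
    lower, upper = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    surv = kmf.survival_function_.rename(columns=lambda _: "S")
    return KMResult(
        median=float(kmf.median_survival_time_),
        ci_lower=lower,
        ci_upper=upper,
        survival=surv,
        n_subjects=len(table.df),
        n_events=int(table.df["event"].sum()),
    )


@dataclass
class GehanResult:
    """Gehan-Breslow generalized Wilcoxon test: chi-square (1 df) and p."""

    statistic: float
    p: float


def gehan_scores(times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Gehan score of each observation against the pooled sample.

    U_i counts the observations that observation i definitely outlives
    minus those that definitely outlive it; pairs whose ordering is
    ambiguous under censoring (or tied events) contribute 0.  A censored
    time is treated as surviving beyond an event at the same time.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    ti, tj = t[:, None], t[None, :]
    di, dj = d[:, None], d[None, :]
    greater = (dj == 1) & ((ti > tj) | ((ti == tj) & (di == 0)))
    less = (di == 1) & ((tj > ti) | ((tj == ti) & (dj == 0)))
    return (greater.sum(axis=1) - less.sum(axis=1)).astype(float)


def gehan_wilcoxon(table_a: EndpointTable, table_b: EndpointTable) -> GehanResult:
    """Two-sample Gehan generalized Wilcoxon test (permutation variance).

    The statistic is W = sum of arm A's Gehan scores; its variance under
    the conditional permutation null is n1*n2 * sum(U^2) / (N*(N-1)), and
    W^2/Var is referred to chi-square with 1 df.  Asymptotically
    equivalent to the Wilcoxon-weighted log-rank test; identical arms give
    statistic 0 and p = 1.
    """
    for tab, name in ((table_a, "A"), (table_b, "B")):
        if len(tab.df) == 0:
            raise InputError(f"arm {name} has no subjects")
    n1, n2 = len(table_a.df), len(table_b.df)
    times = np.concatenate([table_a.df["time"], table_b.df["time"]])
    events = np.concatenate([table_a.df["event"], table_b.df["event"]])
    scores = gehan_scores(times, events)
    w = scores[:n1].sum()
    n = n1 + n2
    var = n1 * n2 / (n * (n - 1)) * (scores**2).sum()
    if var == 0:  # degenerate: no between-subject ordering information
        return GehanResult(statistic=0.0, p=1.0)
    chi2 = w**2 / var
    return GehanResult(statistic=float(chi2), p=float(stats.chi2.sf(chi2, 1)))


def response_fraction(table: EndpointTable) -> float:
    """Percent of subjects with an event within the horizon."""
    return 100.0 * float(table.df["event"].sum()) / len(table.df)


def arm_summary(
    trajectories: list[TumorTrajectory],
    horizon: float = 470.0,
    compare: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-arm endpoint summary in the style of a xenograft results table.

    For every arm: n, TR% (fraction regressing), median TTR with 95% CI,
    TP% within the horizon (fraction progressing), median TTP with CI.
    ``compare`` lists arm pairs to test with the generalized Wilcoxon; the
    p-values are attached to the first arm of each pair.
    """
    ttr = endpoint_table(trajectories, "TTR", horizon)
    ttp = endpoint_table(trajectories, "TTP", horizon)
    arms = list(dict.fromkeys(t.arm for t in trajectories))
    rows = []
    for arm in arms:
        a_ttr, a_ttp = ttr.arm_table(arm), ttp.arm_table(arm)
        km_ttr, km_ttp = km_fit(a_ttr), km_fit(a_ttp)
        rows.append(
            {
                "arm": arm,
                "n": km_ttr.n_subjects,
                "TR_pct": response_fraction(a_ttr),
                "TTR_median": km_ttr.format_median(),
                "TP_pct": response_fraction(a_ttp),
                "TTP_median": km_ttp.format_median(),
                "p_TTR": np.nan,
                "p_TTP": np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("arm")
    for arm_a, arm_b in compare or []:
        out.loc[arm_a, "p_TTR"] = gehan_wilcoxon(
            ttr.arm_table(arm_a), ttr.arm_table(arm_b)
        ).p
        out.loc[arm_a, "p_TTP"] = gehan_wilcoxon(
            ttp.arm_table(arm_a), ttp.arm_table(arm_b)
        ).p
    return out.reset_index()
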