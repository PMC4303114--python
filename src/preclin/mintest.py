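"""Min test (intersection-union test) for two-drug dose matrices.

A combination is declared superior only if it beats BOTH of its
constituent single-agent doses.  Following Laska & Meisner, each
combination cell is compared to the single-agent cells at the same doses
with two one-tailed two-sample t tests (alternative: the combination has
lower relative growth, i.e. more inhibition); the Min-test p-value is the
maximum of the two one-tailed p-values.  This controls the test's level
without any multiplicity correction across the two comparisons: the null
("no better than the best single agent") is an intersection-union null and
its least-favorable configuration is combination mean equal to the better
single agent's mean.

Calls:  p_min <= alpha (default 0.05) -> ``enhanced``;  because the
p-values are one-tailed, p_min >= 1 - alpha (default 0.95) indicates the
combination is *worse* than at least one single agent -> ``attenuated``;
anything between -> ``neither``.  A matrix is summarized as the percentage
of its both-doses-positive cells called enhanced or attenuated.  No
correction is applied across the cells of a matrix.

The t tests are pooled-variance (Student) by default -- the classical
Min-test presentation, stable at quadruplicate sample sizes -- with Welch
available via a flag.  Tests operate on relative-growth replicates, never
on display-scaled inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InputError, InsufficientReplicatesError, StructuralError
from .growth import GrowthMatrix

__all__ = [
    "MinTestResult",
    "MatrixSummary",
    "one_tailed_t",
    "min_test",
    "analyze_matrix",
    "summarize_matrix",
    "pairwise_bonferroni",
]


def one_tailed_t(combo_reps, single_reps, welch: bool = False) -> float:
    """One-tailed two-sample t test p-value: combination growth < single.

    Pooled-variance (Student) t with n1 + n2 - 2 df by default; Welch with
    Satterthwaite df when ``welch`` is set.  Small p means the combination
    grew *less* (was more inhibited) than the single agent; p near 1 means
    it grew more.  Degenerate zero-variance cases resolve by the sign of
    the mean difference, with equal means giving the no-evidence p = 0.5.
    """
    x = np.asarray(combo_reps, dtype=float)
    y = np.asarray(single_reps, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise InsufficientReplicatesError(
            f"need >=2 replicates per group, got {n1} and {n2}"
        )
    m1, m2 = x.mean(), y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if welch:
        a, b = v1 / n1, v2 / n2
        se2 = a + b
        if se2 == 0:
            return 0.5 if m1 == m2 else (0.0 if m1 < m2 else 1.0)
        # Satterthwaite df, written with normalised ratios so extreme
        # variance scales cannot underflow
        fa, fb = a / se2, b / se2
        df = 1.0 / (fa**2 / (n1 - 1) + fb**2 / (n2 - 1))
        se = np.sqrt(se2)
    else:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        if sp2 == 0:
            return 0.5 if m1 == m2 else (0.0 if m1 < m2 else 1.0)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    return float(stats.t.cdf(t, df))


@dataclass(frozen=True)
class MinTestResult:
    """Min-test outcome for one combination cell."""

    dose_a: float
    dose_b: float
    p_vs_a: float   # one-tailed p against single-agent A at dose_a
    p_vs_b: float   # one-tailed p against single-agent B at dose_b
    p_min: float    # max of the two (the Min-test p-value)
    call: str       # "enhanced" | "attenuated" | "neither"


def min_test(
    combo_reps,
    single_a_reps,
    single_b_reps,
    dose_a: float,
    dose_b: float,
    alpha: float = 0.05,
    attenuation: float = 0.95,
    welch: bool = False,
) -> MinTestResult:
    """Min test of one combination against both matched single agents.

    ``p_min`` is the maximum of the two one-tailed p-values; the call is
    ``enhanced`` when p_min <= ``alpha``, ``attenuated`` when p_min >=
    ``attenuation``, else ``neither``.
    """
    if not 0 < alpha < 1 or not 0 < attenuation < 1:
        raise InputError("alpha and attenuation thresholds must be in (0, 1)")
    p_a = one_tailed_t(combo_reps, single_a_reps, welch=welch)
    p_b = one_tailed_t(combo_reps, single_b_reps, welch=welch)
    p_min = max(p_a, p_b)
    if p_min <= alpha:
        call = "enhanced"
    elif p_min >= attenuation:
        call = "attenuated"
    else:
        call = "neither"
    return MinTestResult(
        dose_a=dose_a, dose_b=dose_b, p_vs_a=p_a, p_vs_b=p_b, p_min=p_min, call=call
    )


def analyze_matrix(
    g: GrowthMatrix,
    alpha: float = 0.05,
    attenuation: float = 0.95,
    welch: bool = False,
) -> list[MinTestResult]:
    """Min test for every both-doses-positive cell of a growth matrix.

    Each combination (a, b) is tested against the single-agent cells
    (a, 0) and (0, b); a missing single-agent cell is a structural error
    naming the dose.
    """
    reps = g.replicates
    cells = sorted(
        set(zip(reps["drugA_dose"], reps["drugB_dose"])),
        key=lambda c: (c[0], c[1]),
    )
    have = set(cells)
    results = []
    for a, b in cells:
        if a == 0 or b == 0:
            continue
        if (a, 0.0) not in have:
            raise StructuralError(f"missing single-agent A cell at doseA={a}")
        if (0.0, b) not in have:
            raise StructuralError(f"missing single-agent B cell at doseB={b}")
        results.append(
            min_test(
                g.cell_growth(a, b),
                g.cell_growth(a, 0.0),
                g.cell_growth(0.0, b),
                dose_a=a,
                dose_b=b,
                alpha=alpha,
                attenuation=attenuation,
                welch=welch,
            )
        )
    return results


@dataclass
class MatrixSummary:
    """Percentage of enhanced / attenuated calls among combination cells."""

    n_combinations: int
    pct_enhanced: float
    pct_attenuated: float
    results: list[MinTestResult] = field(repr=False)


def summarize_matrix(results: list[MinTestResult]) -> MatrixSummary:
    """Summarize one matrix's Min-test results as call percentages.

    ``results`` must contain each both-doses-positive cell exactly once
    (duplicated cells are rejected); percentages are over those cells only.
    """
    if not results:
        raise StructuralError("no combination cells to summarize")
    seen = set()
    for r in results:
        key = (r.dose_a, r.dose_b)
        if key in seen:
            raise StructuralError(f"duplicate combination cell {key}")
        if r.dose_a == 0 or r.dose_b == 0:
            raise StructuralError(f"single-agent cell {key} in combination results")
        seen.add(key)
    n = len(results)
    n_enh = sum(r.call == "enhanced" for r in results)
    n_att = sum(r.call == "attenuated" for r in results)
    return MatrixSummary(
        n_combinations=n,
        pct_enhanced=100.0 * n_enh / n,
        pct_attenuated=100.0 * n_att / n,
        results=list(results),
    )


def pairwise_bonferroni(
    groups: dict[str, "np.ndarray"],
    comparisons: list[tuple[str, str]],
    welch: bool = False,
) -> list[dict]:
    """Bonferroni-adjusted two-sided pairwise t tests.

    Each requested pair is compared with a two-sided pooled-variance
    (or Welch) t test; raw p-values are multiplied by the number of
    requested comparisons and capped at 1.
    """
    if len(groups) < 2:
        raise InputError("need at least two groups")
    for name, vals in groups.items():
        if len(np.asarray(vals)) < 2:
            raise InsufficientReplicatesError(f"group {name!r} has <2 replicates")
    m = len(comparisons)
    out = []
    for g1, g2 in comparisons:
        for name in (g1, g2):
            if name not in groups:
                raise InputError(f"unknown group name {name!r}")
        res = stats.ttest_ind(
            np.asarray(groups[g1], dtype=float),
            np.asarray(groups[g2], dtype=float),
            equal_var=not welch,
        )
        p_raw = float(res.pvalue)
        out.append(
            {
                "group1": g1,
                "group2": g2,
                "p_raw": p_raw,
                "p_adj": min(1.0, p_raw * m),
            }
        )
    return out
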