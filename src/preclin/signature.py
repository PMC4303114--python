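"""Differential gene-signature derivation and scoring statistics.

A two-group expression contrast yields an up/down gene signature by
per-gene two-sample t tests with Benjamini-Hochberg control at FDR < 0.05
(a deliberate gene-level stand-in for isoform-resolution RNA-seq
differential calling; declared in output metadata).  Three statistics then
relate signatures to samples and to each other:

* **Sample t score** -- the t statistic of the Pearson correlation between
  a sample's expression over the signature genes and the signature's
  +1/-1 up/down pattern; high positive scores mean the sample looks like
  the signature-defining perturbation.
* **Signature similarity** -- Pearson correlation between two per-gene
  differential patterns over their shared genes, reported as a t statistic
  with n - 2 df and a two-sided p.
* **Fisher enrichment** -- one-sided (over-representation) Fisher exact
  test of a query set against a target set within a gene universe,
  reported as a signed two-sided z score:
  ``z = sign(observed - expected overlap) x Phi^-1(1 - p/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, InputError

__all__ = [
    "Signature",
    "SignatureScore",
    "SimilarityResult",
    "EnrichmentResult",
    "derive_signature",
    "score_sample",
    "score_samples",
    "signature_similarity",
    "fisher_enrichment",
]

#: finite stand-in for an infinite t at |r| = 1 (keeps tabular output finite)
T_SATURATION = 1e6


@dataclass(frozen=True)
class Signature:
    """Up/down gene sets with optional per-gene selection statistics.

    ``stats`` (when present) is a per-gene table with columns ``t``, ``p``,
    ``fdr`` and ``delta`` (group-2 minus group-1 mean).  Up and down sets
    are disjoint; an empty signature is representable (a null contrast
    selects nothing) but cannot be scored against.
    """

    name: str
    up_genes: frozenset[str]
    down_genes: frozenset[str]
    stats: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.up_genes & self.down_genes:
            raise InputError("up and down gene sets overlap")

    @property
    def genes(self) -> frozenset[str]:
        return self.up_genes | self.down_genes

    def pattern(self) -> pd.Series:
        """+1 for up genes, -1 for down genes."""
        if not self.genes:
            raise InputError(f"signature {self.name!r} is empty")
        return pd.Series(
            {g: 1.0 for g in sorted(self.up_genes)}
            | {g: -1.0 for g in sorted(self.down_genes)}
        )


def derive_signature(
    expr: pd.DataFrame,
    groups: pd.Series,
    fdr_threshold: float = 0.05,
    name: str = "signature",
) -> Signature:
    """Select differentially expressed genes at BH-adjusted p < threshold.

    ``expr`` is genes x samples; ``groups`` maps each sample column to one
    of exactly two labels (group order = order of first appearance).
    Per-gene two-sample t tests (pooled variance) are corrected by
    Benjamini-Hochberg; selected genes split into up/down by the sign of
    the group-2 minus group-1 mean difference.
    """
    if not 0 < fdr_threshold < 1:
        raise ConfigError("fdr_threshold must be in (0, 1)")
    groups = pd.Series(groups)
    if not groups.index.isin(expr.columns).all():
        groups = pd.Series(np.asarray(groups), index=expr.columns)
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise InputError(f"need exactly two group labels, got {levels}")
    cols1 = groups.index[groups == levels[0]]
    cols2 = groups.index[groups == levels[1]]
    if len(cols1) < 2 or len(cols2) < 2:
        raise InputError("need at least 2 samples per group")
    x1 = expr[cols1].to_numpy()
    x2 = expr[cols2].to_numpy()
    t, p = stats.ttest_ind(x2, x1, axis=1, equal_var=True)
    p = np.nan_to_num(p, nan=1.0)  # zero-variance genes carry no evidence
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    delta = x2.mean(axis=1) - x1.mean(axis=1)
    table = pd.DataFrame(
        {"t": t, "p": p, "fdr": fdr, "delta": delta}, index=expr.index
    )
    selected = table["fdr"] < fdr_threshold
    up = frozenset(table.index[selected & (table["delta"] > 0)])
    down = frozenset(table.index[selected & (table["delta"] < 0)])
    return Signature(name=name, up_genes=up, down_genes=down, stats=table)


@dataclass(frozen=True)
class SignatureScore:
    """Signature t score of one sample."""

    sample: str
    t: float
    r: float
    n: int          # signature genes used
    saturated: bool = False     # |r| = 1; t reported as the capped sentinel


def _correlation_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Pearson r between x and y and its t statistic with n - 2 df."""
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise InputError("zero variance; correlation undefined")
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    one_minus_r2 = 1.0 - r * r
    if one_minus_r2 <= 1e-15:
        return r, np.copysign(T_SATURATION, r), True
    t = r * np.sqrt((n - 2) / one_minus_r2)
    return r, float(t), False


def score_sample(sample: pd.Series, sig: Signature) -> SignatureScore:
    """t score of one expression profile against a signature pattern.

    The sample's expression over the signature genes is correlated with
    the +1/-1 pattern; the score is ``t = r * sqrt(n - 2) / sqrt(1 - r^2)``.
    Invariant to additive shifts and positive rescaling of the sample.
    Requires >= 3 signature genes present in the sample's gene space.
    """
    pattern = sig.pattern()
    shared = pattern.index.intersection(sample.index)
    if len(shared) < 3:
        raise InputError(
            f"only {len(shared)} signature genes present in sample; need >=3"
        )
    r, t, sat = _correlation_t(
        sample[shared].to_numpy(dtype=float), pattern[shared].to_numpy()
    )
    return SignatureScore(
        sample=str(sample.name), t=t, r=r, n=len(shared), saturated=sat
    )


def score_samples(
    expr: pd.DataFrame, sig: Signature, center_genes: bool = False
) -> pd.DataFrame:
    """Score every column of an expression matrix against a signature.

    ``center_genes`` subtracts each gene's cohort median first, scoring
    samples relative to the cohort rather than on absolute expression.
    """
    mat = expr.sub(expr.median(axis=1), axis=0) if center_genes else expr
    rows = [score_sample(mat[c], sig) for c in mat.columns]
    return pd.DataFrame(
        [
            {"sample": s.sample, "t": s.t, "r": s.r, "n": s.n,
             "saturated": s.saturated}
            for s in rows
        ]
    ).set_index("sample")


@dataclass(frozen=True)
class SimilarityResult:
    """Global similarity of two differential gene patterns."""

    t: float
    r: float
    n: int          # shared genes
    p: float        # two-sided, from Student t with n - 2 df
    saturated: bool = False


def signature_similarity(
    delta_a: pd.Series, sig_b: "Signature | pd.Series"
) -> SimilarityResult:
    """Pearson similarity of two per-gene differential patterns as a t score.

    ``delta_a`` holds per-gene differential values (e.g. t statistics or
    mean differences) of one contrast; ``sig_b`` is either a second
    per-gene pattern or a :class:`Signature`, in which case its +1/-1
    pattern is used.  Symmetric in its arguments; anti-correlated patterns
    give negative t.
    """
    pattern_b = sig_b.pattern() if isinstance(sig_b, Signature) else sig_b
    shared = delta_a.index.intersection(pattern_b.index)
    if len(shared) < 3:
        raise InputError(f"only {len(shared)} shared genes; need >=3")
    r, t, sat = _correlation_t(
        delta_a[shared].to_numpy(dtype=float),
        pattern_b[shared].to_numpy(dtype=float),
    )
    n = len(shared)
    p = 0.0 if sat else 2.0 * float(stats.t.sf(abs(t), n - 2))
    return SimilarityResult(t=t, r=r, n=n, p=p, saturated=sat)


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher exact over-representation of a query set in a target set."""

    overlap: int
    n_query: int
    n_target: int
    n_universe: int
    expected: float     # overlap expected under independence
    p_one_sided: float  # hypergeometric upper tail P(X >= overlap)
    z: float            # signed two-sided z: sign(obs - exp) * Phi^-1(1 - p/2)


def fisher_enrichment(
    query: Iterable[str], target: Iterable[str], universe: Iterable[str]
) -> EnrichmentResult:
    """One-sided Fisher exact enrichment, reported as a two-sided z score.

    The p-value is the hypergeometric upper tail P(overlap >= observed)
    for drawing ``|query|`` genes from the universe with ``|target|``
    successes.  The z score maps p through the standard normal quantile
    with the half-p two-sided convention, signed by whether the observed
    overlap exceeds its expectation; z = 0 when overlap equals expectation
    or when no enrichment signal is possible (p = 1).
    """
    query, target, universe = set(query), set(target), set(universe)
    if len(universe) < 4:
        raise InputError("universe must contain at least 4 genes")
    if not query <= universe:
        raise InputError("query is not a subset of the universe")
    if not target <= universe:
        raise InputError("target is not a subset of the universe")
    k = len(query & target)
    M, K, n = len(universe), len(target), len(query)
    p = float(stats.hypergeom.sf(k - 1, M, K, n))
    p = min(p, 1.0)
    expected = n * K / M
    if k == expected or p >= 1.0:
        z = 0.0
    else:
        z = float(np.copysign(stats.norm.isf(p / 2.0), k - expected))
    return EnrichmentResult(
        overlap=k,
        n_query=n,
        n_target=K,
        n_universe=M,
        expected=expected,
        p_one_sided=p,
        z=z,
    )
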