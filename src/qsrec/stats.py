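"""Validation statistics computable from printed summary numbers.

Intervention studies of this kind rarely publish raw per-child data;
what they print are group sizes, means and standard deviations, count
tables and agreement indices.  This module implements the machinery
needed to reproduce (and check) such numbers exactly:

* one-way ANOVA reconstructed from group summaries, with partial eta
  squared and SPSS-style observed power,
* chi-square goodness of fit over category counts,
* Fleiss' kappa for agreement among more than two judges, with the
  classical Fleiss and Altman interpretation bands,
* paired t with a mean-difference/SD-of-differences effect size,
* Bonferroni adjustment,
* entrance->exit emotion-valence transition tables.

All statistics are computed at full precision; round for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.stats
from statsmodels.stats import inter_rater

from .errors import DomainError, SchemaError

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "ChiSquareResult",
    "KappaResult",
    "PairedTResult",
    "TransitionSummary",
    "anova_from_summary",
    "chi_square_gof",
    "fleiss_kappa",
    "paired_t",
    "bonferroni",
    "transition_summary",
]

VALENCES = ("positive", "negative", "neutral")


@dataclass(frozen=True)
class GroupSummary:
    """One group's size, mean, and sample standard deviation (divisor n-1)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DomainError(f"group n must be >= 2, got {self.n}")
        if self.sd < 0:
            raise DomainError(f"sd must be non-negative, got {self.sd}")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    eta2p: float
    p: float
    observed_power: float


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    fleiss_band: str
    altman_band: str


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    d: float
    p: float


def anova_from_summary(
    groups: Sequence[GroupSummary | tuple[int, float, float]], alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA from per-group (n, mean, sd) summaries.

    Between/within sums of squares are reconstructed exactly from the
    summaries; partial eta squared is SSb/(SSb+SSw).  Observed power is
    the SPSS convention: the upper-tail probability, at the alpha-level
    critical value of the central F, of the noncentral F with
    noncentrality F * df_between.
    """
    gs = [g if isinstance(g, GroupSummary) else GroupSummary(*g) for g in groups]
    if len(gs) < 2:
        raise DomainError("need at least two groups")
    n = np.array([g.n for g in gs], dtype=float)
    m = np.array([g.mean for g in gs], dtype=float)
    s = np.array([g.sd for g in gs], dtype=float)
    N = n.sum()
    k = len(gs)
    grand = float((n * m).sum() / N)
    ssb = float((n * (m - grand) ** 2).sum())
    ssw = float(((n - 1) * s**2).sum())
    df_b, df_w = k - 1, int(N - k)
    if ssw == 0.0:
        if ssb == 0.0:
            raise DomainError("F undefined: zero between- and within-group variation")
        F = np.inf
    else:
        F = (ssb / df_b) / (ssw / df_w)
    eta2p = ssb / (ssb + ssw) if (ssb + ssw) > 0 else 0.0
    p = float(scipy.stats.f.sf(F, df_b, df_w))
    crit = scipy.stats.f.ppf(1 - alpha, df_b, df_w)
    power = float(scipy.stats.ncf.sf(crit, df_b, df_w, F * df_b))
    return AnovaResult(
        F=float(F), df_between=df_b, df_within=df_w, eta2p=float(eta2p), p=p,
        observed_power=power,
    )


def chi_square_gof(
    observed: Sequence[float], expected: Sequence[float] | None = None
) -> ChiSquareResult:
    """Chi-square goodness of fit; uniform expectation by default.

    ``expected`` may be counts or proportions; it is rescaled to the
    observed total.  No continuity correction.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or len(obs) == 0:
        raise DomainError("observed must be a non-empty 1-d sequence")
    if expected is None:
        exp = np.full_like(obs, obs.sum() / len(obs))
    else:
        exp = np.asarray(expected, dtype=float)
        if len(exp) != len(obs):
            raise DomainError("observed and expected lengths differ")
        if np.any(exp <= 0):
            raise DomainError("expected cells must all be positive")
        exp = exp * (obs.sum() / exp.sum())
    df = len(obs) - 1
    if df == 0:
        raise DomainError("p undefined with a single category (df = 0)")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return ChiSquareResult(chi2=chi2, df=df, p=float(scipy.stats.chi2.sf(chi2, df)))


def _fleiss_band(kappa: float) -> str:
    # Fleiss (1981): < 0.40 poor, 0.40-0.75 intermediate to good, > 0.75 excellent
    if kappa > 0.75:
        return "excellent"
    if kappa >= 0.40:
        return "intermediate-good"
    return "poor"


def _altman_band(kappa: float) -> str:
    # Altman (1991): <=0.20 poor, 0.21-0.40 fair, 0.41-0.60 moderate,
    # 0.61-0.80 good, 0.81-1.00 very good
    if kappa > 0.80:
        return "very good"
    if kappa > 0.60:
        return "good"
    if kappa > 0.40:
        return "moderate"
    if kappa > 0.20:
        return "fair"
    return "poor"


def fleiss_kappa(
    ratings: Sequence[Sequence[int]], raters_per_subject: int | None = None
) -> KappaResult:
    """Fleiss' kappa over a subjects x categories count matrix.

    Each row gives how many of the n raters assigned that subject to
    each category; every row must sum to the same n >= 2.
    """
    mat = np.asarray(ratings, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise SchemaError("ratings must be a 2-d matrix with >= 2 subjects")
    row_sums = mat.sum(axis=1)
    n = raters_per_subject if raters_per_subject is not None else int(row_sums[0])
    if n < 2:
        raise SchemaError("need at least 2 raters per subject")
    if not np.allclose(row_sums, n):
        raise SchemaError(f"every row must sum to {n} raters, got {row_sums.tolist()}")
    p_cat = mat.sum(axis=0) / mat.sum()
    p_e = float((p_cat**2).sum())
    if abs(1.0 - p_e) < 1e-12:
        raise DomainError("kappa undefined: expected agreement is 1")
    kappa = float(inter_rater.fleiss_kappa(mat, method="fleiss"))
    return KappaResult(kappa=kappa, fleiss_band=_fleiss_band(kappa),
                       altman_band=_altman_band(kappa))


def paired_t(before: Sequence[float], after: Sequence[float]) -> PairedTResult:
    """Paired t test; effect size d = mean(diff) / sd(diff)."""
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape or b.ndim != 1 or len(b) < 2:
        raise DomainError("before/after must be equal-length 1-d sequences, n >= 2")
    diff = b - a
    sd = diff.std(ddof=1)
    if sd == 0.0:
        raise DomainError("t undefined: zero-variance differences")
    n = len(diff)
    t = float(diff.mean() / (sd / np.sqrt(n)))
    d = float(diff.mean() / sd)
    p = float(2 * scipy.stats.t.sf(abs(t), n - 1))
    return PairedTResult(t=t, df=n - 1, d=d, p=p)


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni adjustment: p' = min(1, m*p) with m the family size."""
    ps = list(p_values)
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise DomainError("p-values must lie in [0, 1]")
    m = len(ps)
    return [min(1.0, m * p) for p in ps]


@dataclass(frozen=True)
class TransitionSummary:
    """Counts and row percentages over (entrance, exit) valence pairs."""

    counts: Mapping[str, Mapping[str, int]]
    row_percentages: Mapping[str, Mapping[str, float] | None]

    def count(self, entrance: str, exit: str) -> int:
        return self.counts[entrance][exit]


def transition_summary(pairs: Iterable[tuple[str, str]]) -> TransitionSummary:
    """Tabulate entrance->exit valence transitions with row percentages.

    Rows with zero observations have ``None`` percentages (undefined).
    """
    counts = {r: {c: 0 for c in VALENCES} for r in VALENCES}
    for entrance, exit_ in pairs:
        if entrance not in VALENCES or exit_ not in VALENCES:
            raise DomainError(f"unknown valence in pair ({entrance!r}, {exit_!r})")
        counts[entrance][exit_] += 1
    percentages: dict[str, dict[str, float] | None] = {}
    for row in VALENCES:
        total = sum(counts[row].values())
        if total == 0:
            percentages[row] = None
        else:
            percentages[row] = {c: 100.0 * counts[row][c] / total for c in VALENCES}
    return TransitionSummary(counts=counts, row_percentages=percentages)
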