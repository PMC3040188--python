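"""Second-stage individual-genotyping statistics.

Candidate SNPs promoted from a pooled scan are validated on individually
genotyped cases and controls with the classical toolkit: an exact
Hardy-Weinberg equilibrium test as genotyping QC, two-sided Fisher exact
tests on allelic (2x2) and genotypic (2x3 or collapsed 2x2) tables, and
cross-product odds ratios with Woolf 95% confidence intervals.  A helper
reconstructs 2x2 tables from printed group sizes and percentage (or sex
ratio) summaries, so published contingency statistics can be recomputed
from the numbers a paper actually shows.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io import ValidationError

__all__ = [
    "AssociationResult",
    "HweResult",
    "hwe_test",
    "fisher_association",
    "genotype_association",
    "table_from_rates",
    "table_from_ratio",
]

GENOTYPE_MODELS = ("genotypic-2df", "dominant", "recessive")


@dataclass(frozen=True)
class AssociationResult:
    test: str
    model: str
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    method: str
    continuity_corrected: bool = False


@dataclass(frozen=True)
class HweResult:
    p_value: float
    statistic: float | None
    method: str


def _as_table(table, shape: tuple[int, int]) -> np.ndarray:
    arr = np.asarray(table)
    if arr.shape != shape:
        raise ValidationError(f"expected a {shape[0]}x{shape[1]} table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValidationError("counts must be non-negative")
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValidationError("counts must be integers")
    return arr.astype(np.int64)


# ---------------------------------------------------------------------------
# Hardy-Weinberg


def hwe_test(genotype_counts, method: str = "exact") -> HweResult:
    """Hardy-Weinberg test from (AA, Aa, aa) counts.

    ``exact`` (default) is the conditional exact test: given the allele
    counts, the p-value sums the probabilities of all heterozygote counts
    whose probability does not exceed the observed one.  ``chisq`` is the
    1-df goodness-of-fit variant against the p^2 : 2pq : q^2 expectation.
    """
    counts = np.asarray(genotype_counts)
    if counts.shape != (3,):
        raise ValidationError("genotype_counts must be (AA, Aa, aa)")
    if np.any(counts < 0) or not np.all(np.equal(np.mod(counts, 1), 0)):
        raise ValidationError("genotype counts must be non-negative integers")
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValidationError("total genotype count must be >= 1")
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    if method == "chisq":
        p = na / (2 * n)
        expected = np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)]) * n
        if np.any(expected == 0):
            return HweResult(1.0, 0.0, "chisq")
        stat = float(((counts - expected) ** 2 / expected).sum())
        return HweResult(float(stats.chi2.sf(stat, df=1)), stat, "chisq")
    if method != "exact":
        raise ValidationError("method must be 'exact' or 'chisq'")
    hets = np.arange(na % 2, min(na, nb) + 1, 2)
    log_const = gammaln(na + 1) + gammaln(nb + 1) - gammaln(2 * n + 1) + gammaln(n + 1)
    log_probs = (
        log_const
        + hets * math.log(2)
        - gammaln((na - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((nb - hets) / 2 + 1)
    )
    probs = np.exp(log_probs)
    probs /= probs.sum()
    p_obs = probs[hets == n_ab][0]
    p_value = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return HweResult(min(1.0, p_value), None, "exact")


# ---------------------------------------------------------------------------
# Fisher tests and odds ratios


def _woolf_ci(a, b, c, d, alpha=0.05) -> tuple[float, float, bool]:
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    return math.exp(log_or - z * se), math.exp(log_or + z * se), corrected


def fisher_association(table, or_method: str = "sample") -> AssociationResult:
    """Two-sided Fisher exact test on a 2x2 table with OR and 95% CI.

    The odds ratio is the sample cross-product (a*d)/(b*c) with a Woolf
    confidence interval (Haldane 0.5 correction when a cell is zero,
    flagged via ``continuity_corrected``); ``or_method='conditional'``
    substitutes the exact conditional maximum-likelihood OR and interval.
    """
    t = _as_table(table, (2, 2))
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("degenerate table: empty margin")
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    a, b, c, d = t.ravel()
    if or_method == "conditional":
        res = stats.contingency.odds_ratio(t, kind="conditional")
        ci = res.confidence_interval(0.95)
        return AssociationResult(
            "fisher", "allelic", p, float(res.statistic), float(ci.low), float(ci.high),
            "exact conditional MLE OR",
        )
    if or_method != "sample":
        raise ValidationError("or_method must be 'sample' or 'conditional'")
    if min(b, c) == 0 and min(a, d) == 0:
        oratio = math.nan
    elif b == 0 or c == 0:
        oratio = math.inf
    else:
        oratio = (a * d) / (b * c)
    lo, hi, corrected = _woolf_ci(a, b, c, d)
    return AssociationResult(
        "fisher", "allelic", p, float(oratio), lo, hi, "cross-product OR, Woolf CI",
        continuity_corrected=corrected,
    )


def _freeman_halton_2x3(t: np.ndarray) -> float:
    """Exact two-sided p for a 2x3 table by enumeration over fixed margins."""
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    log_const = (
        gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)
    )

    def log_prob(a, b, c):
        d, e, f = cols[0] - a, cols[1] - b, cols[2] - c
        cells = np.array([a, b, c, d, e, f])
        return log_const - gammaln(cells + 1).sum()

    obs = log_prob(*t[0])
    total = 0.0
    r0 = int(rows[0])
    for a in range(min(r0, int(cols[0])) + 1):
        for b in range(min(r0 - a, int(cols[1])) + 1):
            c = r0 - a - b
            if c > cols[2]:
                continue
            lp = log_prob(a, b, c)
            if lp <= obs + 1e-10:
                total += math.exp(lp)
    return min(1.0, total)


def genotype_association(
    table, model: str, exact_limit: int = 500
) -> AssociationResult:
    """Association test on a 2x3 genotype table (columns AA, Aa, aa).

    ``dominant`` collapses to carriers of the a allele (Aa+aa vs AA),
    ``recessive`` to aa vs AA+Aa; both reduce to :func:`fisher_association`.
    ``genotypic-2df`` runs the Fisher-Freeman-Halton exact test for totals
    up to ``exact_limit`` and a 2-df chi-squared otherwise (method reported).
    """
    t = _as_table(table, (2, 3))
    if model == "dominant":
        collapsed = np.column_stack([t[:, 1] + t[:, 2], t[:, 0]])
        res = fisher_association(collapsed)
        return AssociationResult(res.test, "dominant", res.p_value, res.odds_ratio,
                                 res.ci_low, res.ci_high, res.method, res.continuity_corrected)
    if model == "recessive":
        collapsed = np.column_stack([t[:, 2], t[:, 0] + t[:, 1]])
        res = fisher_association(collapsed)
        return AssociationResult(res.test, "recessive", res.p_value, res.odds_ratio,
                                 res.ci_low, res.ci_high, res.method, res.continuity_corrected)
    if model != "genotypic-2df":
        raise ValidationError(f"unknown model {model!r}; choose from {GENOTYPE_MODELS}")
    if np.any(t.sum(axis=1) == 0):
        raise ValidationError("degenerate table: empty row margin")
    nonzero_cols = t.sum(axis=0) > 0
    tt = t[:, nonzero_cols]
    if tt.shape[1] < 2:
        return AssociationResult("freeman-halton", "genotypic-2df", 1.0, math.nan,
                                 math.nan, math.nan, "single informative column")
    if t.sum() <= exact_limit:
        if tt.shape[1] == 2:
            p = float(stats.fisher_exact(tt, alternative="two-sided")[1])
            method = "exact (collapsed to 2x2)"
        else:
            p = _freeman_halton_2x3(tt)
            method = "Freeman-Halton enumeration"
        return AssociationResult("freeman-halton", "genotypic-2df", p, math.nan,
                                 math.nan, math.nan, method)
    stat, p, dof, _ = stats.chi2_contingency(tt, correction=False)
    return AssociationResult("chi2", "genotypic-2df", float(p), math.nan,
                             math.nan, math.nan, f"chi-squared ({dof} df)")


# ---------------------------------------------------------------------------
# Reconstructing tables from printed summaries


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def table_from_rates(n1: int, n2: int, pct1: float, pct2: float) -> pd.DataFrame:
    """2x2 table from group sizes and printed positive percentages.

    Positives are ``round(n * pct / 100)`` to the nearest integer (half away
    from zero); rows are the two groups, columns positive/negative.
    """
    for pct in (pct1, pct2):
        if not (0.0 <= pct <= 100.0):
            raise ValidationError("percentages must lie in [0, 100]")
    if n1 < 0 or n2 < 0:
        raise ValidationError("group sizes must be non-negative")
    pos1 = _round_half_away(n1 * pct1 / 100.0)
    pos2 = _round_half_away(n2 * pct2 / 100.0)
    return pd.DataFrame(
        [[pos1, n1 - pos1], [pos2, n2 - pos2]],
        index=["group1", "group2"],
        columns=["positive", "negative"],
    )


def table_from_ratio(n1: int, n2: int, ratio1: float, ratio2: float) -> pd.DataFrame:
    """2x2 table from group sizes and printed positive/negative ratios.

    Solves m / f = ratio with m + f = n, i.e. positives =
    ``round(n * r / (1 + r))`` (half away from zero).
    """
    if ratio1 < 0 or ratio2 < 0:
        raise ValidationError("ratios must be non-negative")
    pos1 = _round_half_away(n1 * ratio1 / (1.0 + ratio1))
    pos2 = _round_half_away(n2 * ratio2 / (1.0 + ratio2))
    return pd.DataFrame(
        [[pos1, n1 - pos1], [pos2, n2 - pos2]],
        index=["group1", "group2"],
        columns=["positive", "negative"],
    )
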