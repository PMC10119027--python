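"""Statistical primitives shared by the analysis modules.

Thin, well-specified wrappers around scipy/statsmodels: two-sided Fisher's
exact test on 2x2 tables, sample odds ratio with a Woolf (logit) confidence
interval, Benjamini-Hochberg FDR, and one-way ANOVA with Tukey-Kramer HSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd


def _as_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("contingency table cells must be non-negative")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.all(t == np.floor(t)):
            raise ValueError("contingency table cells must be integers")
        t = t.astype(np.int64)
    return t


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Uses the point-probability rule: the p-value sums hypergeometric
    probabilities of all tables with the observed margins whose point
    probability does not exceed the observed table's.
    """
    t = _as_table(table)
    if t.sum() == 0:
        raise ValueError("all-zero contingency table")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return float(min(p, 1.0))


def odds_ratio_ci(table, level: float = 0.95) -> tuple[float, float, float]:
    """Sample odds ratio (ad)/(bc) with a Woolf (logit) confidence interval.

    When any cell is zero, the Haldane-Anscombe correction (+0.5 on every
    cell) is applied to both the estimate and the interval, keeping the
    estimate finite.

    Returns (odds_ratio, ci_low, ci_high).
    """
    t = _as_table(table).astype(float)
    if np.any(t == 0):
        t = t + 0.5
    a, b, c, d = t.ravel()
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.5 + level / 2)
    lo = float(np.exp(np.log(or_) - z * se))
    hi = float(np.exp(np.log(or_) + z * se))
    return float(or_), lo, hi


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group1, group2, meandiff, p_adj
    dropped_groups: tuple[str, ...] = ()


def anova_tukey(groups: dict[str, "np.ndarray"]) -> AnovaTukeyResult:
    """One-way ANOVA followed by Tukey-Kramer HSD pairwise comparisons.

    Groups with fewer than two observations are dropped with a warning.
    Degenerate input (zero within-group variance everywhere) is handled:
    equal means report F=0, p=1; unequal means report p=0.
    """
    kept = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    dropped = tuple(k for k, v in kept.items() if v.size < 2)
    if dropped:
        warnings.warn(f"dropping groups with <2 members: {dropped}")
        kept = {k: v for k, v in kept.items() if v.size >= 2}
    if len(kept) < 2:
        raise ValueError("need at least two groups with >=2 values each")

    labels = sorted(kept)
    arrays = [kept[k] for k in labels]
    within_ss = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    grand = np.concatenate(arrays).mean()
    between_ss = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)

    if within_ss == 0.0:
        if between_ss == 0.0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = np.inf, 0.0
        pairs = []
        for i, g1 in enumerate(labels):
            for g2 in labels[i + 1:]:
                diff = kept[g2].mean() - kept[g1].mean()
                pairs.append((g1, g2, diff, 1.0 if diff == 0 else 0.0))
        pairwise = pd.DataFrame(pairs, columns=["group1", "group2", "meandiff", "p_adj"])
        return AnovaTukeyResult(f_stat, p, pairwise, dropped)

    f_stat, p = sps.f_oneway(*arrays)
    values = np.concatenate(arrays)
    tags = np.concatenate([np.full(kept[k].size, k, dtype=object) for k in labels])
    res = pairwise_tukeyhsd(values, tags)
    pairwise = pd.DataFrame(
        {
            "group1": [labels[i] for i, _ in _pair_indices(len(labels))],
            "group2": [labels[j] for _, j in _pair_indices(len(labels))],
            "meandiff": res.meandiffs,
            "p_adj": res.pvalues,
        }
    )
    return AnovaTukeyResult(float(f_stat), float(p), pairwise, dropped)


def _pair_indices(k: int):
    return [(i, j) for i in range(k) for j in range(i + 1, k)]
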