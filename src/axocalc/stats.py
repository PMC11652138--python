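"""Two-group comparisons with a normality gate, as used for transport data.

Each group is screened with Shapiro–Wilk (alpha = 0.05 by default); if
both pass, an unpaired two-sided Student t test is used, otherwise a
two-sided Mann–Whitney U test (exact null distribution for small
tie-free samples, normal approximation with continuity and tie
correction otherwise). Significance labelling uses the conventional
strict thresholds p < 0.05 (*), p < 0.01 (**), p < 0.001 (***).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ComparisonResult

__all__ = [
    "compare_groups",
    "mann_whitney_u",
    "significance_stars",
    "binned_mean_sem",
]

#: Largest n_a * n_b for which the exact U null distribution is used.
EXACT_U_LIMIT = 400


def significance_stars(p: float) -> str:
    """Star label for a p-value; thresholds are strict inequalities."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test: (U statistic, p-value).

    Uses the exact null distribution when the samples are small
    (n_a * n_b <= 400) and tie-free, and the normal approximation with
    continuity and tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = (
        "exact" if (a.size * b.size <= EXACT_U_LIMIT and not has_ties)
        else "asymptotic"
    )
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:
        return False  # degenerate: constant sample is not treatable as normal
    return sps.shapiro(x).pvalue >= alpha


def compare_groups(
    a, b, normality_alpha: float = 0.05
) -> ComparisonResult:
    """Compare two independent samples with the normality-gated test choice.

    Requires n >= 3 per group. Group means are reported with the n-1
    (sample) standard deviation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError(
            f"need >= 3 observations per group (got {a.size}, {b.size})"
        )
    norm_a = _is_normal(a, normality_alpha)
    norm_b = _is_normal(b, normality_alpha)
    if norm_a and norm_b:
        res = sps.ttest_ind(a, b, equal_var=True)
        test, stat, p = "t", float(res.statistic), min(float(res.pvalue), 1.0)
    else:
        stat, p = mann_whitney_u(a, b)
        test = "mannwhitneyu"
    return ComparisonResult(
        n_a=int(a.size), n_b=int(b.size), test=test, statistic=stat,
        p_value=p, mean_a=float(a.mean()), mean_b=float(b.mean()),
        std_a=float(a.std(ddof=1)), std_b=float(b.std(ddof=1)),
        normal_a=norm_a, normal_b=norm_b, stars=significance_stars(p),
    )


def binned_mean_sem(groups) -> pd.DataFrame:
    """Per-bin mean with SEM = SD(n-1)/sqrt(n) for binned parameter traces.

    ``groups`` is a sequence of per-bin value arrays (or a mapping of bin
    label to values). Bins with fewer than two values get SEM 0 and are
    flagged; empty bins get NaN and are flagged, not fatal.
    """
    if isinstance(groups, dict):
        labels = list(groups.keys())
        values = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        values = [np.asarray(v, dtype=float) for v in groups]
        labels = list(range(len(values)))
    rows = []
    for lab, v in zip(labels, values):
        n = v.size
        if n == 0:
            rows.append((lab, 0, np.nan, np.nan, True))
        elif n == 1:
            rows.append((lab, 1, float(v[0]), 0.0, True))
        else:
            rows.append(
                (lab, n, float(v.mean()),
                 float(v.std(ddof=1) / np.sqrt(n)), False)
            )
    return pd.DataFrame(
        rows, columns=["bin", "n", "mean", "sem", "flagged"]
    )
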