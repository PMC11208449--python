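"""Validation and comparison statistics.

* Lin's concordance correlation coefficient (CCC) with McBride's grading
  (>0.99 excellent, >0.95 good, >0.90 moderate, otherwise poor; boundary
  values fall to the lower grade).
* Exact two-sided Wilcoxon signed-rank test by full enumeration of the
  2^n sign assignments (midranks for tied |differences|, zeros dropped).
* Bonferroni-adjusted significance threshold (0.05 / 3 -> 0.0167).
* Cohort comparison tables: median (IQR) per condition and exact p-values
  against the preoperative state for each osteotomy translation distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CccResult",
    "PairedComparison",
    "lin_ccc",
    "mcbride_grade",
    "wilcoxon_signed_rank",
    "bonferroni_alpha",
    "cohort_compare",
]


@dataclass(frozen=True)
class CccResult:
    ccc: float
    grade: str


@dataclass(frozen=True)
class PairedComparison:
    parameter: str
    pre: np.ndarray
    post: np.ndarray
    p_value: float
    significant: bool


def mcbride_grade(ccc: float) -> str:
    """McBride agreement grade of a concordance coefficient."""
    if not -1.0 <= ccc <= 1.0:
        raise ValueError(f"CCC must lie in [-1, 1], got {ccc}")
    if ccc > 0.99:
        return "excellent"
    if ccc > 0.95:
        return "good"
    if ccc > 0.90:
        return "moderate"
    return "poor"


def lin_ccc(x, y, *, sample_moments: bool = False) -> CccResult:
    """Lin's concordance correlation coefficient between paired vectors.

    Uses population (divide-by-n) moments per Lin's original estimator;
    ``sample_moments=True`` switches to n-1 denominators.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D vectors, n >= 2")
    ddof = 1 if sample_moments else 0
    sx2 = x.var(ddof=ddof)
    sy2 = y.var(ddof=ddof)
    if sx2 + sy2 == 0.0:
        raise ValueError("CCC undefined: both vectors are constant")
    n = len(x)
    sxy = ((x - x.mean()) * (y - y.mean())).sum() / (n - ddof)
    ccc = 2.0 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)
    return CccResult(ccc=float(ccc), grade=mcbride_grade(float(ccc)))


def _signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All 2^n values of W+ = sum of ranks of positive differences."""
    n = len(ranks)
    if n > 25:
        raise ValueError("exact enumeration limited to n <= 25")
    values = np.zeros(1)
    for r in ranks:                     # convolution over sign choices
        values = np.concatenate([values, values + r])
    return values


def wilcoxon_signed_rank(pre, post, *, mode: str = "exact") -> float:
    """Exact two-sided Wilcoxon signed-rank p-value for paired samples.

    Differences ``post - pre`` equal to zero are dropped before ranking
    (classic treatment); tied magnitudes receive midranks.  The two-sided
    p-value doubles the smaller tail of the exact permutation distribution
    of W+ over all 2^n sign assignments (capped at 1).

    Returns ``nan`` when every difference is zero (test undefined).
    """
    if mode != "exact":
        raise ValueError("only exact mode is implemented")
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired vectors must have equal length")
    d = post - pre
    d = d[d != 0.0]
    if len(d) == 0:
        return float("nan")
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    dist = _signed_rank_distribution(ranks)
    m = len(dist)
    lo = np.count_nonzero(dist <= w_obs + 1e-9) / m
    hi = np.count_nonzero(dist >= w_obs - 1e-9) / m
    return float(min(1.0, 2.0 * min(lo, hi)))


def bonferroni_alpha(alpha: float = 0.05, m: int = 3) -> float:
    """Bonferroni-adjusted per-comparison threshold, rounded to 4 decimals."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return round(alpha / m, 4)


def _iqr_text(v: np.ndarray, decimals: int) -> str:
    q1, q3 = np.percentile(v, [25, 75])
    f = f"{{:.{decimals}f}}"
    return f"{f.format(np.median(v))} ({f.format(q1)}–{f.format(q3)})"


def format_comparison_table(table: pd.DataFrame,
                            alpha_label: str = "0.0167") -> str:
    """Plain-text rendering of a :func:`cohort_compare` table.

    Median (IQR) columns per condition, three p-value columns, and a
    significance star on p-values below the Bonferroni-adjusted threshold.
    """
    lines = []
    pcols = [c for c in table.columns if c.startswith("p_vs_")]
    conds = [c for c in table.columns
             if not c.startswith(("p_vs_", "sig_vs_"))]
    header = ["parameter"] + conds + [c.replace("p_vs_", "vs. ")
                                      for c in pcols]
    widths = [max(24, len(h)) for h in header]
    lines.append("  ".join(h.ljust(w) for h, w in zip(header, widths)))
    for name, row in table.iterrows():
        cells = [str(name)]
        cells += [str(row[c]) for c in conds]
        for p in pcols:
            star = "*" if row.get(p.replace("p_", "sig_"), False) else ""
            cells.append(f"{row[p]:.3g}{star}")
        lines.append("  ".join(c.ljust(w) for c, w in zip(cells, widths)))
    lines.append(f"* significant at p < {alpha_label} "
                 "(Bonferroni-adjusted)")
    return "\n".join(lines)


def cohort_compare(
    cohort_pre: pd.DataFrame,
    cohort_post_by_distance: dict[float, pd.DataFrame],
    *,
    alpha: float = 0.05,
    decimals: int = 2,
) -> pd.DataFrame:
    """Compare a preoperative cohort against each osteotomy distance.

    ``cohort_pre`` and each entry of ``cohort_post_by_distance`` are
    (models x parameters) frames with identical columns and row order.
    Returns one row per parameter: median (IQR) per condition, the exact
    Wilcoxon p per distance, and significance at the Bonferroni-adjusted
    threshold over the number of distances.
    """
    distances = sorted(cohort_post_by_distance)
    thr = bonferroni_alpha(alpha, len(distances))
    rows = []
    for param in cohort_pre.columns:
        pre = cohort_pre[param].to_numpy(dtype=float)
        if len(pre) < 2:
            raise ValueError("need at least 2 paired models per comparison")
        row: dict[str, object] = {
            "parameter": param,
            "preoperative": _iqr_text(pre, decimals),
        }
        for d in distances:
            post_df = cohort_post_by_distance[d]
            if len(post_df) != len(pre):
                raise ValueError(
                    f"cohort length mismatch for distance {d}"
                )
            post = post_df[param].to_numpy(dtype=float)
            p = wilcoxon_signed_rank(pre, post)
            row[f"mdco{d:g}"] = _iqr_text(post, decimals)
            row[f"p_vs_{d:g}mm"] = np.round(p, 5)
            row[f"sig_vs_{d:g}mm"] = bool(p < thr) if np.isfinite(p) else False
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")
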