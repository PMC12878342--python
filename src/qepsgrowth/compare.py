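"""Two-group comparison of derived growth variables.

Test selection follows the classic rule: Student's t-test when both groups
pass Shapiro-Wilk normality at alpha 0.05, Mann-Whitney U otherwise.  The
standardized mean difference is Cohen's d with pooled SD and a Hedges-type
large-sample CI.  No multiplicity correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "compare_groups",
    "cohens_d",
    "summary_table",
    "describe_cell",
    "smd_forest_frame",
]

NORMALITY_ALPHA = 0.05
SIGNIFICANCE_ALPHA = 0.05


@dataclass
class GroupComparison:
    variable: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    median_a: float
    range_a: tuple[float, float]
    mean_b: float
    sd_b: float
    median_b: float
    range_b: tuple[float, float]
    test: str  # "t" | "mwu"
    p_value: float
    smd: float
    smd_ci: tuple[float, float]
    normal_a: bool
    normal_b: bool

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_ALPHA


def _is_normal(x: np.ndarray) -> bool:
    if np.ptp(x) == 0.0:  # constant sample: Shapiro undefined
        return False
    return stats.shapiro(x).pvalue > NORMALITY_ALPHA


def cohens_d(a: np.ndarray, b: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Pooled-SD standardized mean difference with 95% CI."""
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
        / (na + nb - 2)
    )
    if pooled == 0.0:
        return 0.0, (0.0, 0.0)
    d = (np.mean(a) - np.mean(b)) / pooled
    se = np.sqrt((na + nb) / (na * nb) + d**2 / (2 * (na + nb - 2)))
    return float(d), (float(d - 1.96 * se), float(d + 1.96 * se))


def compare_groups(
    a: pd.DataFrame,
    b: pd.DataFrame,
    variables: Sequence[str] | None = None,
    min_n: int = 3,
) -> list[GroupComparison]:
    """Compare each variable between two per-individual tables.

    Variables with fewer than ``min_n`` non-missing values in either group
    are skipped with a log entry.
    """
    if variables is None:
        variables = [
            c
            for c in a.columns
            if c in b.columns and pd.api.types.is_numeric_dtype(a[c])
        ]
    out: list[GroupComparison] = []
    for var in variables:
        xa = pd.to_numeric(a[var], errors="coerce").dropna().to_numpy(dtype=float)
        xb = pd.to_numeric(b[var], errors="coerce").dropna().to_numpy(dtype=float)
        if len(xa) < min_n or len(xb) < min_n:
            log.info(
                "skipping %s: %d vs %d non-missing values (need %d)",
                var, len(xa), len(xb), min_n,
            )
            continue
        normal_a, normal_b = _is_normal(xa), _is_normal(xb)
        if normal_a and normal_b:
            test = "t"
            p = float(stats.ttest_ind(xa, xb).pvalue)
        else:
            test = "mwu"
            p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        if np.isnan(p):  # zero-variance t-branch on identical samples
            p = 1.0
        d, ci = cohens_d(xa, xb)
        out.append(
            GroupComparison(
                variable=var,
                n_a=len(xa),
                n_b=len(xb),
                mean_a=float(np.mean(xa)),
                sd_a=float(np.std(xa, ddof=1)),
                median_a=float(np.median(xa)),
                range_a=(float(np.min(xa)), float(np.max(xa))),
                mean_b=float(np.mean(xb)),
                sd_b=float(np.std(xb, ddof=1)),
                median_b=float(np.median(xb)),
                range_b=(float(np.min(xb)), float(np.max(xb))),
                test=test,
                p_value=p,
                smd=d,
                smd_ci=ci,
                normal_a=normal_a,
                normal_b=normal_b,
            )
        )
    return out


def describe_cell(values) -> str:
    """mean ± SD, median (range) and n, formatted as one table cell."""
    x = np.asarray(values, dtype=float)
    mean, sd = np.mean(x), np.std(x, ddof=1) if len(x) > 1 else 0.0
    return (
        f"{mean:.1f} ± {sd:.1f}  {np.median(x):.1f} "
        f"({np.min(x):g}-{np.max(x):g})  n = {len(x)}"
    )


def _fmt_group(mean, sd, median, rng, n) -> str:
    return (
        f"{mean:.1f} ± {sd:.1f}  {median:.1f} "
        f"({rng[0]:.1f}-{rng[1]:.1f})  n = {n}"
    )


def summary_table(
    comparisons: Sequence[GroupComparison],
    label_a: str = "group_a",
    label_b: str = "group_b",
) -> pd.DataFrame:
    """Mean ± SD / median (range) / n per group with test and p-value."""
    rows = []
    for c in comparisons:
        rows.append(
            {
                "variable": c.variable,
                label_a: _fmt_group(c.mean_a, c.sd_a, c.median_a, c.range_a, c.n_a),
                label_b: _fmt_group(c.mean_b, c.sd_b, c.median_b, c.range_b, c.n_b),
                "test": c.test,
                "p_value": c.p_value,
                "smd": c.smd,
            }
        )
    return pd.DataFrame(
        rows, columns=["variable", label_a, label_b, "test", "p_value", "smd"]
    )


def smd_forest_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Plot data for a standardized-mean-difference forest display."""
    return pd.DataFrame(
        {
            "variable": [c.variable for c in comparisons],
            "smd": [c.smd for c in comparisons],
            "ci_low": [c.smd_ci[0] for c in comparisons],
            "ci_high": [c.smd_ci[1] for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
        }
    )


def render_text(table: pd.DataFrame) -> str:
    """Fixed-width text rendering of a summary table."""
    if table.empty:
        return "  ".join(table.columns)
    widths = {
        col: max(len(col), *(len(str(v)) for v in table[col])) for col in table.columns
    }
    lines = ["  ".join(col.ljust(widths[col]) for col in table.columns)]
    for _, row in table.iterrows():
        lines.append(
            "  ".join(
                (f"{v:.4g}" if isinstance(v, float) else str(v)).ljust(widths[c])
                for c, v in row.items()
            )
        )
    return "\n".join(lines)
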