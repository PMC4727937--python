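"""Seed viability statistics: exact binomial intervals and rescue tests."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SeedCount:
    """Plump/aborted seed counts for one line."""

    label: str
    n_plump: int
    n_aborted: int

    def __post_init__(self):
        if self.n_plump < 0 or self.n_aborted < 0:
            raise ValueError("seed counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_plump + self.n_aborted

    @property
    def proportion(self) -> float:
        if self.n_total == 0:
            raise ValueError("no seeds scored")
        return self.n_plump / self.n_total


def binomial_ci(count: SeedCount, confidence: float = 0.95) -> tuple[float, float, float]:
    """Clopper-Pearson exact interval for the plump-seed proportion.

    Returns ``(proportion, lower, upper)``.  The bounds are exactly 0 at
    k=0 and exactly 1 at k=n.
    """
    if count.n_total < 1:
        raise ValueError("need at least one scored seed")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    k, n = count.n_plump, count.n_total
    alpha = 1.0 - confidence
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return count.proportion, lower, upper


def rescue_test(line: SeedCount, control: SeedCount, n_comparisons: int = 1) -> float:
    """Bonferroni-adjusted one-sided exact binomial test against the control.

    The null proportion is the control's observed plump fraction treated as
    fixed; the alternative is "greater".  The raw p-value is multiplied by
    ``n_comparisons`` and capped at 1.
    """
    if control.n_total < 1:
        raise ValueError("control must have at least one scored seed")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    p0 = control.proportion
    p = stats.binomtest(line.n_plump, line.n_total, p0, alternative="greater").pvalue
    return min(1.0, float(p) * n_comparisons)


def cube_root_transform(proportions: Sequence[float]) -> np.ndarray:
    """Elementwise cube root; a variance-stabilising, order-preserving map."""
    x = np.asarray(proportions, dtype=float)
    if np.any(x < 0):
        raise ValueError("proportions must be non-negative")
    return np.power(x, 1.0 / 3.0)


def star_annotation(adjusted_p: float) -> str:
    """Significance stars: ``**`` below 0.001, ``*`` below 0.01."""
    if adjusted_p < 0.001:
        return "**"
    if adjusted_p < 0.01:
        return "*"
    return ""


def rescue_report(
    lines: Sequence[SeedCount],
    control: SeedCount,
    confidence: float = 0.95,
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Per-line proportions, exact CIs and adjusted rescue-test p-values."""
    m = n_comparisons if n_comparisons is not None else len(lines)
    rows = []
    for sc in lines:
        prop, lo, hi = binomial_ci(sc, confidence)
        raw = stats.binomtest(
            sc.n_plump, sc.n_total, control.proportion, alternative="greater"
        ).pvalue
        adj = min(1.0, float(raw) * m)
        rows.append(
            {
                "label": sc.label,
                "n_plump": sc.n_plump,
                "n_aborted": sc.n_aborted,
                "proportion": prop,
                "ci_lower": lo,
                "ci_upper": hi,
                "p_raw": float(raw),
                "p_adjusted": adj,
                "stars": star_annotation(adj),
            }
        )
    return pd.DataFrame(rows)
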