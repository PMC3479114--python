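"""Replicate aggregation and one-tailed two-sample comparisons.

Replicates are summarized as mean ± SEM (sample standard deviation over √n);
group contrasts use the pooled-variance (Student) two-sample t-test with a
directional alternative, classified as significant at p ≤ 0.05 and marginally
significant at 0.05 < p ≤ 0.10.  No multiple-testing correction is applied —
comparisons are reported per contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

__all__ = [
    "ComparisonReport",
    "replicate_stats",
    "one_tailed_t",
    "classify",
    "compare_groups",
]

SIGNIFICANT_P = 0.05
MARGINAL_P = 0.10
_MIN_P = 1e-300  # keep p in (0, 1] even for zero-variance separations


def replicate_stats(values) -> tuple[float, float, int]:
    """Mean, standard error of the mean (n−1 denominator), and n."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("replicate statistics need at least 2 values")
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(n))
    return mean, sem, n


def one_tailed_t(group_a, group_b, direction: str = "less") -> float:
    """One-tailed pooled-variance Student t-test p-value.

    ``direction`` is the alternative about ``group_a`` relative to
    ``group_b``: ``"less"`` tests mean_a < mean_b (e.g. mutant rupture force
    below wild type), ``"greater"`` the reverse.  Identical groups give
    p = 0.5; a degenerate zero-variance comparison with equal means gives
    p = 1.0 with a warning.
    """
    if direction not in ("less", "greater"):
        raise ValueError(f"direction must be 'less' or 'greater', got {direction!r}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            warnings.warn("zero pooled variance with equal means; p = 1 by convention")
            return 1.0
        return _MIN_P if (a.mean() < b.mean()) == (direction == "less") else 1.0
    res = sp_stats.ttest_ind(a, b, equal_var=True, alternative=direction)
    return float(min(max(res.pvalue, _MIN_P), 1.0))


def classify(p: float) -> str:
    """Significance class: ``significant`` (p ≤ 0.05), ``marginal``
    (0.05 < p ≤ 0.10), else ``ns``."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p-value outside (0, 1]: {p}")
    if p <= SIGNIFICANT_P:
        return "significant"
    if p <= MARGINAL_P:
        return "marginal"
    return "ns"


@dataclass
class ComparisonReport:
    """Two-group replicate comparison with directional significance."""

    label_a: str
    label_b: str
    values_a: list[float]
    values_b: list[float]
    direction: str = "less"
    mean_a: float = field(init=False)
    sem_a: float = field(init=False)
    mean_b: float = field(init=False)
    sem_b: float = field(init=False)
    p_value: float = field(init=False)
    significance: str = field(init=False)

    def __post_init__(self) -> None:
        self.mean_a, self.sem_a, _ = replicate_stats(self.values_a)
        self.mean_b, self.sem_b, _ = replicate_stats(self.values_b)
        self.p_value = one_tailed_t(self.values_a, self.values_b, self.direction)
        self.significance = classify(self.p_value)

    def to_dict(self) -> dict:
        return {
            "group_a": {
                "label": self.label_a,
                "values": list(map(float, self.values_a)),
                "mean": self.mean_a,
                "sem": self.sem_a,
                "n": len(self.values_a),
            },
            "group_b": {
                "label": self.label_b,
                "values": list(map(float, self.values_b)),
                "mean": self.mean_b,
                "sem": self.sem_b,
                "n": len(self.values_b),
            },
            "direction": self.direction,
            "p_value": self.p_value,
            "significance": self.significance,
        }


def compare_groups(
    values_a, values_b, label_a: str = "A", label_b: str = "B", direction: str = "less"
) -> ComparisonReport:
    return ComparisonReport(label_a, label_b, list(values_a), list(values_b), direction)
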