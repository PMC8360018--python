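"""Replicate statistics: pooled t-tests, Bonferroni correction, stars.

Triplicate simulations per condition give n = 3 samples per metric; each
non-reference condition is compared to the water reference with a
two-sided Student's (pooled-variance) t-test and the p-values of one
metric's family of comparisons are Bonferroni-corrected.  Significance
stars follow the adjusted p: * for p <= .05, ** for p <= .01, *** for
p <= .001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["ComparisonResult", "two_sample_t", "bonferroni", "stars",
           "compare_to_water"]


@dataclass
class ComparisonResult:
    condition: str
    metric: str
    mean_a: float
    mean_b: float
    t: float
    p_raw: float
    p_adjusted: float
    stars: str


def two_sample_t(sample_a, sample_b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided pooled-variance t-test (Welch via ``equal_var=False``)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    if equal_var and a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate: zero pooled variance
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means; p set to 0",
                      stacklevel=2)
        return np.inf if a.mean() > b.mean() else -np.inf, 0.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni-adjusted p-values: each multiplied by the family size,
    capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="bonferroni")[1]


def stars(p_adjusted: float) -> str:
    if p_adjusted <= 0.001:
        return "***"
    if p_adjusted <= 0.01:
        return "**"
    if p_adjusted <= 0.05:
        return "*"
    return "ns"


def compare_to_water(metric_tables: dict[str, dict[str, np.ndarray]],
                     reference: str = "water",
                     equal_var: bool = True) -> list[ComparisonResult]:
    """Compare every condition's replicate metrics against the reference.

    ``metric_tables`` maps condition -> {metric -> replicate values}.  The
    Bonferroni family is, per metric, the set of all non-reference
    conditions carrying that metric.
    """
    if reference not in metric_tables:
        raise ValueError(f"reference condition {reference!r} missing")
    ref = metric_tables[reference]
    metrics = sorted(ref)
    results: list[ComparisonResult] = []
    for metric in metrics:
        family = [c for c in sorted(metric_tables)
                  if c != reference and metric in metric_tables[c]]
        raw = []
        pairs = []
        for cond in family:
            a = np.asarray(metric_tables[cond][metric], dtype=float)
            b = np.asarray(ref[metric], dtype=float)
            if len(a) != len(b):
                raise ValueError(
                    f"{cond}/{metric}: replicate count differs from reference"
                )
            t, p = two_sample_t(a, b, equal_var=equal_var)
            raw.append(p)
            pairs.append((cond, a.mean(), b.mean(), t))
        adj = bonferroni(raw)
        for (cond, ma, mb, t), p_raw, p_adj in zip(pairs, raw, adj):
            results.append(
                ComparisonResult(cond, metric, float(ma), float(mb), t,
                                 float(p_raw), float(p_adj), stars(p_adj))
            )
    return results
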