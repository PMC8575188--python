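"""Nonparametric group comparisons across postnatal days.

The comparison protocol for a per-acinus quantity across the four assessed
days: an advisory Shapiro-Wilk normality screen per group, two-sided
Mann-Whitney U tests for all C(4,2) = 6 day pairs with a Šidák-corrected
per-comparison threshold, and a Kruskal-Wallis H omnibus test. Acini are
pooled across the animals of a day, which mirrors the published protocol;
note this treats acini from the same animal as independent observations
(pseudo-replication), a caveat inherited deliberately rather than "fixed".
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ComparisonReport",
    "sidak_threshold",
    "ranktest_pairwise",
    "normality_screen",
    "omnibus_independence",
    "compare_groups",
]

#: Group sizes at or below this use the exact U distribution (no ties), above
#: it the normal approximation with tie and continuity correction.
EXACT_SWITCH_N = 8


@dataclasses.dataclass
class ComparisonReport:
    """Full comparison of one quantity across day groups."""

    quantity: str
    group_names: list
    normality_p: dict
    pairwise_p: np.ndarray
    sidak_alpha: float
    omnibus_p: float

    @property
    def significant(self) -> np.ndarray:
        """Boolean matrix: pairwise p below the Šidák per-comparison threshold."""
        return self.pairwise_p < self.sidak_alpha

    def to_dict(self) -> dict:
        return {
            "quantity": self.quantity,
            "groups": list(map(str, self.group_names)),
            "normality_p": {str(k): v for k, v in self.normality_p.items()},
            "pairwise_p": self.pairwise_p.tolist(),
            "sidak_alpha": self.sidak_alpha,
            "omnibus_p": self.omnibus_p,
            "significant": self.significant.tolist(),
        }


def sidak_threshold(family_alpha: float, m: int) -> float:
    """Šidák per-comparison threshold 1 − (1 − α)^(1/m).

    Controls the family-wise error at ``family_alpha`` over ``m``
    independent comparisons; with α = 0.01 and the m = 6 day pairs this is
    0.00167 (5 d.p.).
    """
    if not (0 < family_alpha < 1):
        raise ValueError("family_alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - family_alpha) ** (1.0 / m)


def _mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact null enumeration when both groups are small (n ≤ 8) and tie-free;
    otherwise the normal approximation with tie and continuity correction.
    """
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= EXACT_SWITCH_N and len(y) <= EXACT_SWITCH_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


def ranktest_pairwise(groups: Mapping | Sequence[Sequence[float]]) -> np.ndarray:
    """Symmetric matrix of two-sided Mann-Whitney U p-values over all pairs.

    Diagonal entries are 1. Any empty group is an error; single-value
    groups are allowed but carry almost no power.
    """
    values = list(groups.values()) if isinstance(groups, Mapping) else list(groups)
    if len(values) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(list(g), dtype=float) for g in values]
    for i, a in enumerate(arrays):
        if a.size == 0:
            raise ValueError(f"group {i} is empty")
    k = len(arrays)
    p = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        p[i, j] = p[j, i] = _mannwhitney_p(arrays[i], arrays[j])
    return p


def normality_screen(groups: Mapping | Sequence[Sequence[float]]) -> dict:
    """Shapiro-Wilk p per group; advisory only, never gates the rank tests.

    Groups with fewer than 3 values cannot be tested and are flagged with
    ``None``.
    """
    items = groups.items() if isinstance(groups, Mapping) else enumerate(groups)
    out = {}
    for name, g in items:
        arr = np.asarray(list(g), dtype=float)
        if arr.size < 3 or arr.size > 5000:
            out[name] = None
        else:
            out[name] = float(stats.shapiro(arr).pvalue)
    return out


def omnibus_independence(groups: Mapping | Sequence[Sequence[float]]) -> float:
    """Kruskal-Wallis H-test p-value (tie-corrected, chi-square reference)."""
    values = list(groups.values()) if isinstance(groups, Mapping) else list(groups)
    if len(values) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(list(g), dtype=float) for g in values]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate input: all values identical")
    return float(stats.kruskal(*arrays).pvalue)


def compare_groups(
    groups: Mapping[object, Sequence[float]],
    quantity: str = "volume_mm3",
    family_alpha: float = 0.01,
) -> ComparisonReport:
    """Run the full comparison protocol on named groups (e.g. one per day)."""
    names = list(groups.keys())
    m = len(names) * (len(names) - 1) // 2
    return ComparisonReport(
        quantity=quantity,
        group_names=names,
        normality_p=normality_screen(groups),
        pairwise_p=ranktest_pairwise(groups),
        sidak_alpha=sidak_threshold(family_alpha, m),
        omnibus_p=omnibus_independence(groups),
    )
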