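"""Pairwise Wilcoxon rank-sum tables across conditions.

For every feature and every pair of conditions, a two-sided Wilcoxon
rank-sum (Mann-Whitney) test is run on the pooled window-level feature
values.  The exact null distribution is enumerated when both samples have
at most ``exact_max_n`` observations and no cross-sample ties; otherwise the
normal approximation with continuity and tie correction is used.  No
multiple-testing correction is applied by default (a Holm option is
provided).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import CONDITION_PAIRS, Condition

EXACT_MAX_N = 10


def rank_sum_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = EXACT_MAX_N) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if x.size <= exact_max_n and y.size <= exact_max_n and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def _pair_label(pair: Tuple[Condition, Condition]) -> str:
    return f"{pair[0].value}_vs_{pair[1].value}"


@dataclass
class PValueMatrix:
    """Feature x condition-pair p-values with significance flags."""

    p_values: pd.DataFrame  # rows: features, columns: pair labels
    alpha: float = 0.05

    def __post_init__(self) -> None:
        vals = self.p_values.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def significant(self) -> pd.DataFrame:
        """Boolean flags, True exactly where p < alpha (strict)."""
        return self.p_values < self.alpha


def pairwise_wilcoxon(
    table: pd.DataFrame,
    feature_cols: Optional[Sequence[str]] = None,
    condition_col: str = "condition",
    alpha: float = 0.05,
    pairs: Sequence[Tuple[Condition, Condition]] = CONDITION_PAIRS,
    holm: bool = False,
) -> PValueMatrix:
    """Wilcoxon rank-sum p-value for every feature x condition pair.

    ``table`` holds one row per analysis window with numeric feature columns
    and a condition label column.  With ``holm=True``, Holm step-down
    correction is applied across each feature's six pairs.
    """
    needed = {c for pair in pairs for c in pair}
    present = set(Condition(v) for v in table[condition_col].unique())
    missing = sorted(c.value for c in needed - present)
    if missing:
        raise ValueError(f"conditions absent from the table: {missing}")
    if feature_cols is None:
        feature_cols = [
            c for c in table.columns
            if c != condition_col and pd.api.types.is_numeric_dtype(table[c])
        ]

    groups = {
        c: table.loc[table[condition_col].map(lambda v: Condition(v) is c)]
        for c in needed
    }
    rows = {}
    for feat in feature_cols:
        ps = []
        for a, b in pairs:
            ps.append(rank_sum_p(groups[a][feat].to_numpy(),
                                 groups[b][feat].to_numpy()))
        if holm:
            ps = _holm(np.asarray(ps)).tolist()
        rows[feat] = ps
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[_pair_label(p) for p in pairs]
    )
    return PValueMatrix(p_values=df, alpha=alpha)


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty_like(p)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def significance_table(matrix: PValueMatrix) -> pd.DataFrame:
    """Rendered table: p-values formatted with a star where p < alpha."""
    def fmt(p: float) -> str:
        base = "<0.0001" if p < 1e-4 else f"{p:.4f}"
        return base + ("*" if p < matrix.alpha else "")

    return matrix.p_values.map(fmt)
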