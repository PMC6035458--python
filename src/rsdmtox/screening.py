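"""Representative feature sets: PCA scores and Mann-Whitney screening.

Features are z-scored before PCA (they span Gy, %, mm and unitless scales).
The Mann-Whitney screen reports raw, unadjusted p-values by default; a
Bonferroni / Benjamini-Hochberg option exists for users who want it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .features import feature_family

log = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    selected: list[str]
    p_values: pd.Series  # raw p per feature
    families: pd.Series  # DVP / texture / DGP per feature
    alpha: float

    def selected_table(self, table: pd.DataFrame) -> pd.DataFrame:
        return table[self.selected]


def _drop_constant(table: pd.DataFrame) -> pd.DataFrame:
    std = table.std(axis=0)
    constant = std[std == 0].index
    if len(constant):
        log.warning("dropping %d constant feature(s) before PCA",
                    len(constant))
        table = table.drop(columns=constant)
    return table


def pca_features(table: pd.DataFrame,
                 variance_threshold: float = 0.99) -> pd.DataFrame:
    """Scores of the smallest number of principal components whose
    cumulative explained variance exceeds the threshold."""
    if len(table) < 2:
        raise ValueError("need at least 2 patients")
    table = _drop_constant(table)
    z = (table - table.mean()) / table.std(ddof=1)
    pca = PCA()
    scores = pca.fit_transform(z.values)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n = int(np.searchsorted(cum, variance_threshold) + 1)
    n = min(n, scores.shape[1])
    return pd.DataFrame(scores[:, :n], index=table.index,
                        columns=[f"PC{i + 1}" for i in range(n)])


def mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when both groups have <= 10 samples and no ties;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(x) <= 10 and len(y) <= 10 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def mwu_screen(table: pd.DataFrame, labels: np.ndarray,
               alpha: float = 0.05, adjust: str | None = None) -> ScreenResult:
    """Select features whose two-group Mann-Whitney p-value < alpha.

    ``adjust``: None (default, raw p-values as reported), "bonferroni" or
    "bh" for users wanting multiplicity control.
    """
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n1, n0 = int((labels == 1).sum()), int((labels == 0).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("each class needs at least 2 patients")
    pvals = pd.Series({
        name: mann_whitney_p(table[name].values[labels == 1],
                             table[name].values[labels == 0])
        for name in table.columns
    })
    test_p = pvals
    if adjust == "bonferroni":
        test_p = np.minimum(pvals * len(pvals), 1.0)
    elif adjust == "bh":
        order = np.argsort(pvals.values)
        m = len(pvals)
        adj = np.empty(m)
        prev = 1.0
        for rank_from_top, i in enumerate(order[::-1]):
            k = m - rank_from_top
            prev = min(prev, pvals.values[i] * m / k)
            adj[i] = prev
        test_p = pd.Series(adj, index=pvals.index)
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    selected = [n for n in table.columns if test_p[n] < alpha]
    families = pd.Series({n: feature_family(n) if _known(n) else "other"
                          for n in table.columns})
    return ScreenResult(selected, pvals, families, alpha)


def _known(name: str) -> bool:
    try:
        feature_family(name)
        return True
    except KeyError:
        return False
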