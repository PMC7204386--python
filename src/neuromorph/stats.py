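"""Nonparametric group-difference screening.

Per feature: a Kruskal-Wallis omnibus test across the three diagnostic
classes (HC, MCI, AD), followed by pairwise two-sided Mann-Whitney U
post-hoc tests. Post-hoc tests are run unconditionally — the screening
table reports every pairwise column regardless of the omnibus outcome —
and significance flags use strict ``p < alpha`` with no multiple-testing
correction by default (Holm and Bonferroni available across the pairwise
family of each feature).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_ORDER",
    "kruskal_wallis",
    "mann_whitney",
    "significance_table",
    "screen_features",
    "FeatureMatrix",
]

CLASS_ORDER = ("HC", "MCI", "AD")
PAIRS = (("HC", "MCI"), ("HC", "AD"), ("MCI", "AD"))


@dataclass
class FeatureMatrix:
    """Numeric subjects-by-features matrix with aligned labels."""

    names: list[str]
    X: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.X.shape[1] != len(self.names):
            raise ValueError(
                f"{self.X.shape[1]} columns but {len(self.names)} feature names"
            )
        if self.X.shape[0] != len(self.labels):
            raise ValueError("row count does not match label count")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, feature_names=None,
                       label_column: str = "label") -> "FeatureMatrix":
        if feature_names is None:
            feature_names = [
                c for c in df.columns
                if c != label_column and pd.api.types.is_numeric_dtype(df[c])
            ]
        return cls(
            names=list(feature_names),
            X=df[list(feature_names)].to_numpy(dtype=float),
            labels=df[label_column].to_numpy(),
        )


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H on midranks with tie correction; chi-square p-value.

    Degenerate input where every pooled observation is identical returns
    (H=0, p=1) instead of raising.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < 1:
            raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact enumeration when the combined sample is small (n_a + n_b <= 12)
    and tie-free; otherwise the normal approximation with tie and
    continuity correction. Identical constant samples return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return float(a.size * b.size / 2.0), 1.0
    tie_free = np.unique(pooled).size == pooled.size
    if a.size + b.size <= 12 and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def significance_table(
    features: FeatureMatrix,
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Omnibus + pairwise screening table, one row per feature.

    Columns: H, p_omnibus, p_HC_MCI, p_HC_AD, p_MCI_AD and the matching
    boolean significance flags (strict ``p < alpha``). ``correction``
    applies Holm or Bonferroni across the three pairwise tests of each
    feature before flagging (p-values reported are the adjusted ones).
    """
    labels = features.labels
    present = set(np.unique(labels))
    if set(CLASS_ORDER) - present:
        raise ValueError(
            f"need all three classes {CLASS_ORDER}, got {sorted(present)}"
        )
    if correction not in (None, "none", "holm", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")

    rows = []
    for j, name in enumerate(features.names):
        col = features.X[:, j]
        by_class = {c: col[labels == c] for c in CLASS_ORDER}
        H, p_omni = kruskal_wallis([by_class[c] for c in CLASS_ORDER])
        p_pairs = []
        for ca, cb in PAIRS:
            _, p = mann_whitney(by_class[ca], by_class[cb])
            p_pairs.append(p)
        p_pairs = _adjust(p_pairs, correction)
        row = {"feature": name, "H": H, "p_omnibus": p_omni}
        for (ca, cb), p in zip(PAIRS, p_pairs):
            row[f"p_{ca}_{cb}"] = p
        row["sig_omnibus"] = p_omni < alpha
        for (ca, cb), p in zip(PAIRS, p_pairs):
            row[f"sig_{ca}_{cb}"] = p < alpha
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")


def _adjust(pvals: list[float], correction: str | None) -> list[float]:
    if correction in (None, "none"):
        return pvals
    m = len(pvals)
    if correction == "bonferroni":
        return [min(1.0, p * m) for p in pvals]
    # Holm step-down
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return list(adj)


def screen_features(
    table: pd.DataFrame,
    feature_groups: dict[str, list[str]],
    protected: tuple[str, ...] = ("image", "cognitive"),
) -> list[str]:
    """Drop whole feature groups with no significant omnibus member.

    ``feature_groups`` maps a group name (e.g. "plasma", "csf", "image") to
    its member feature names; a non-protected group is removed when none of
    its members reached omnibus significance. Protected groups (the image
    block and the cognitive surrogate) pass through regardless, matching
    the screening protocol where only biochemical blocks are candidates
    for removal. Returns retained feature names in table order.
    """
    missing = [
        f for names in feature_groups.values() for f in names if f not in table.index
    ]
    if missing:
        raise ValueError(f"features not present in table: {missing}")
    dropped_groups = []
    retained: set[str] = set()
    for group, names in feature_groups.items():
        if group in protected or any(bool(table.loc[f, "sig_omnibus"]) for f in names):
            retained.update(names)
        else:
            dropped_groups.append(group)
    if dropped_groups:
        logger.info("screen_features: dropped groups %s", dropped_groups)
    return [f for f in table.index if f in retained]


def table_to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Reshape a screening table of (structure, metric) features into the
    wide layout metric-columns x pairwise-comparison, one row per structure.

    Expects feature names of the form ``<METRIC>_<STRUCTURE>``; features
    not matching that pattern are skipped.
    """
    cells = {}
    for feat in table.index:
        if "_" not in feat:
            continue
        metric, structure = feat.split("_", 1)
        for ca, cb in PAIRS:
            cells.setdefault(structure, {})[f"{metric}:{ca}v{cb}"] = (
                "*" if bool(table.loc[feat, f"sig_{ca}_{cb}"]) else ""
            )
    return pd.DataFrame.from_dict(cells, orient="index").fillna("")
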