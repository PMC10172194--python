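"""Differential feature screening between tissue regions or clusters.

Per-feature unpaired two-tailed t-tests (Welch by default) between two spot
groups, raw-mean fold changes, Benjamini-Hochberg FDR control, and the
screening presets used across the study:

==================  =========================================
preset              rule
==================  =========================================
genes_enrichment    FC >= 2 and BH q < 0.05
genes_network       FC >= 2 and p < 0.05
metabolites_network FC >= 1.5
cluster_markers     log2FC > 1 and p < 0.01
==================  =========================================

Fold-change thresholds are inclusive (>=); p/q thresholds strict (<).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid import SpotFeatureTable

__all__ = [
    "MARKER_COLUMNS",
    "SCREEN_PRESETS",
    "differential_features",
    "adjust_bh",
    "screen_markers",
    "markers_per_group",
]

MARKER_COLUMNS = [
    "feature_id", "modality", "group", "reference", "mean_a", "mean_b",
    "fold_change", "log2_fc", "t_statistic", "p_value", "q_value", "n_a", "n_b",
]

# threshold keys: fc (inclusive >=), log2_fc (strict >), p / q (strict <)
SCREEN_PRESETS: dict[str, dict[str, float]] = {
    "genes_enrichment": {"fc": 2.0, "q": 0.05},
    "genes_network": {"fc": 2.0, "p": 0.05},
    "metabolites_network": {"fc": 1.5},
    "cluster_markers": {"log2_fc": 1.0, "p": 0.01},
}


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Sort p ascending, q_(i) = min_{j >= i} p_(j) * m / j capped at 1, mapped
    back to the input order.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty_like(p)
    q[order] = q_sorted
    return q


def _log2_eps(values: np.ndarray) -> np.ndarray:
    """Per-feature pseudo-value: half the smallest nonzero entry (column-wise)."""
    masked = np.where(values > 0, values, np.inf)
    col_min = masked.min(axis=0)
    eps = np.where(np.isfinite(col_min), col_min / 2.0, 0.0)
    return eps


def differential_features(
    table: SpotFeatureTable | pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    group_name: str = "group_a",
    reference_name: str = "group_b",
    test: str = "welch",
    fold_values: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Two-group differential test for every feature.

    ``group_a`` / ``group_b`` are row (spot) labels with at least two
    members each.  The t statistic and two-tailed p come from the unpaired
    t-test (Welch unequal-variance form by default, Student's optional);
    fold change is the ratio of raw group means; log2 fold change adds a
    per-feature pseudo-value (half the smallest nonzero value of the
    feature) to both means.  Features constant and equal across both groups
    get t = 0, p = 1 by convention.

    When the test runs on transformed values (e.g. log-normalized counts),
    pass the untransformed matrix as ``fold_values`` so fold changes stay on
    the expression scale while the test uses the transformed one.
    """
    if isinstance(table, SpotFeatureTable):
        frame, modalities = table.values, table.modalities
    else:
        frame = table
        modalities = pd.Series("feature", index=frame.columns)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need >= 2 members")
    if test not in ("welch", "student"):
        raise ValueError(f"unknown test {test!r}")
    a = frame.loc[list(group_a)].to_numpy(float)
    b = frame.loc[list(group_b)].to_numpy(float)
    fold_frame = frame if fold_values is None else fold_values[frame.columns]
    fa = fold_frame.loc[list(group_a)].to_numpy(float)
    fb = fold_frame.loc[list(group_b)].to_numpy(float)
    mean_a, mean_b = fa.mean(axis=0), fb.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_a / mean_b
    fc = np.where((mean_a == 0) & (mean_b == 0), 1.0, fc)
    eps = _log2_eps(fold_frame.to_numpy(float))
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_fc = np.log2(mean_a + eps) - np.log2(mean_b + eps)
    log2_fc = np.where((mean_a == 0) & (mean_b == 0), 0.0, log2_fc)
    res = stats.ttest_ind(a, b, axis=0, equal_var=(test == "student"))
    t = np.asarray(res.statistic, float)
    p = np.asarray(res.pvalue, float)
    degenerate = np.isnan(t)
    equal_means = np.isclose(a.mean(axis=0), b.mean(axis=0))
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate & equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, 0.0, p)
    out = pd.DataFrame(
        {
            "feature_id": frame.columns,
            "modality": modalities.loc[frame.columns].to_numpy(),
            "group": group_name,
            "reference": reference_name,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "log2_fc": log2_fc,
            "t_statistic": t,
            "p_value": p,
            "q_value": adjust_bh(p),
            "n_a": len(group_a),
            "n_b": len(group_b),
        }
    )
    return out[MARKER_COLUMNS]


def screen_markers(
    records: pd.DataFrame,
    rules: str | Mapping[str, float] = "genes_enrichment",
) -> pd.DataFrame:
    """Filter marker records by a named preset or an explicit threshold map.

    Supported threshold keys: ``fc`` (fold change, inclusive >=),
    ``log2_fc`` (strict >), ``p`` (strict <), ``q`` (strict <).
    """
    if isinstance(rules, str):
        if rules not in SCREEN_PRESETS:
            raise ValueError(f"invalid-argument: unknown preset {rules!r}")
        thresholds = SCREEN_PRESETS[rules]
    else:
        thresholds = dict(rules)
        unknown = set(thresholds) - {"fc", "log2_fc", "p", "q"}
        if unknown:
            raise ValueError(f"invalid-argument: unknown rule keys {sorted(unknown)}")
    mask = np.ones(len(records), bool)
    if "fc" in thresholds:
        mask &= records["fold_change"].to_numpy(float) >= thresholds["fc"]
    if "log2_fc" in thresholds:
        mask &= records["log2_fc"].to_numpy(float) > thresholds["log2_fc"]
    if "p" in thresholds:
        mask &= records["p_value"].to_numpy(float) < thresholds["p"]
    if "q" in thresholds:
        mask &= records["q_value"].to_numpy(float) < thresholds["q"]
    return records[mask].reset_index(drop=True)


def markers_per_group(
    table: SpotFeatureTable | pd.DataFrame,
    groups: pd.Series,
    rules: str | Mapping[str, float] = "cluster_markers",
    test: str = "welch",
    fold_values: pd.DataFrame | None = None,
) -> dict:
    """One-vs-rest differential screen for every group.

    Returns group -> screened marker DataFrame; groups with fewer than two
    members (or a rest of fewer than two) are skipped.
    """
    frame = table.values if isinstance(table, SpotFeatureTable) else table
    groups = groups.loc[frame.index]
    out: dict = {}
    for g in sorted(groups.unique(), key=str):
        in_g = groups.index[groups == g]
        rest = groups.index[groups != g]
        if len(in_g) < 2 or len(rest) < 2:
            continue
        rec = differential_features(
            table, in_g, rest, group_name=str(g), reference_name="rest",
            test=test, fold_values=fold_values,
        )
        out[g] = screen_markers(rec, rules)
    return out
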