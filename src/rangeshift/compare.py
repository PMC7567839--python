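"""Two-sided Wilcoxon rank-sum comparisons of shift metrics across groups.

Each distribution-shift metric (centroid shift, % range-size change,
northern / southern edge displacement) is compared between every
unordered pair of groups — either strongest-predictor groups or
life-history groups — with the two-sided Mann-Whitney / Wilcoxon
rank-sum test. Small tie-free samples (n1 + n2 <= 12) use the exact
null distribution; larger or tied samples use the normal approximation
with midranks, tie correction, and continuity correction, so p-values
are reproducible bit-for-bit.

Holm adjustment across the pairs of one (metric, grouping, season)
family is available but off by default.
"""
from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12

METRICS = ("shift_km", "pct_area_change", "d_north", "d_south")
GROUPINGS = ("strongest_predictor", "life_history")


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    Exact enumeration p-value when n1 + n2 <= 12 and there are no ties;
    otherwise the tie-corrected normal approximation with continuity
    correction. U is computed from midranks, so U + U_swapped = n1 * n2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test needs at least one value per sample")
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (no_ties and x.size + y.size <= EXACT_MAX_N) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _holm(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests
    if len(pvals) == 0:
        return pvals
    return multipletests(pvals, method="holm")[1]


def group_summaries(values: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Median / mean / IQR / n per group for one metric."""
    rows = []
    for g, v in values.items():
        v = np.asarray(v, dtype=float)
        q1, q3 = (np.percentile(v, [25, 75]) if v.size else (np.nan, np.nan))
        rows.append({"group": g, "n": v.size, "median": np.median(v) if v.size else np.nan,
                     "mean": v.mean() if v.size else np.nan, "q1": q1, "q3": q3})
    return pd.DataFrame(rows)


def pairwise_compare(metrics: pd.DataFrame, groups: Mapping[str, str],
                     metric: str, grouping: str = "life_history",
                     season: str | None = None,
                     adjust: str | None = None) -> pd.DataFrame:
    """All pairwise rank-sum tests of one metric between species groups.

    ``metrics`` is a range-metrics table (one row per species-season);
    ``groups`` maps species name to its group label (strongest predictor
    or life-history type). Rows with a missing metric are dropped.
    Groups with fewer than 3 members are tested anyway but flagged
    ``low_power``. ``adjust='holm'`` adds Holm-adjusted p-values across
    the tested pairs.
    """
    if adjust not in (None, "none", "holm"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    df = metrics if season is None else metrics[metrics["season"] == season]
    if metric not in df.columns:
        raise KeyError(f"metric {metric!r} not in metrics table")
    labels = df["species"].map(dict(groups))
    unknown = df.loc[labels.isna(), "species"].unique()
    if unknown.size:
        raise ValueError(f"species without a group label: {sorted(unknown)}")
    by_group: dict[str, np.ndarray] = {}
    for g in sorted(set(labels)):
        v = df.loc[labels == g, metric].dropna().to_numpy(dtype=float)
        if v.size:
            by_group[g] = v
    if len(by_group) < 2:
        raise ValueError("need at least two non-empty groups")

    rows = []
    for a, b in itertools.combinations(sorted(by_group), 2):
        u, p = rank_sum_test(by_group[a], by_group[b])
        n_a, n_b = len(by_group[a]), len(by_group[b])
        rows.append({"metric": metric, "grouping": grouping, "season": season,
                     "group_a": a, "group_b": b, "n_a": n_a, "n_b": n_b,
                     "U": u, "p": p, "low_power": min(n_a, n_b) < 3})
    out = pd.DataFrame(rows)
    if adjust == "holm":
        out["p_holm"] = _holm(out["p"].to_numpy())
    return out


def compare_all(metrics: pd.DataFrame, life_history: Mapping[str, str],
                strongest: Mapping[str, str] | pd.DataFrame | None = None,
                metrics_names: Sequence[str] = METRICS,
                adjust: str | None = None) -> pd.DataFrame:
    """Every metric x grouping x season pairwise comparison in one table.

    ``strongest`` may be the strongest-predictor table from the
    importance stage (columns species, season, strongest_predictor), in
    which case the per-season mapping is used for that season's tests.
    """
    frames = []
    for season in sorted(metrics["season"].unique()):
        groupings: list[tuple[str, Mapping[str, str]]] = [("life_history", life_history)]
        if strongest is not None:
            if isinstance(strongest, pd.DataFrame):
                sub = strongest[strongest["season"] == season].dropna(
                    subset=["strongest_predictor"])
                mapping = dict(zip(sub["species"], sub["strongest_predictor"]))
            else:
                mapping = dict(strongest)
            if mapping:
                groupings.append(("strongest_predictor", mapping))
        for grouping, mapping in groupings:
            season_df = metrics[metrics["season"] == season]
            usable = season_df[season_df["species"].isin(mapping)]
            if usable.empty:
                continue
            for name in metrics_names:
                if name not in usable.columns or usable[name].dropna().empty:
                    continue
                try:
                    frames.append(pairwise_compare(
                        usable, mapping, name, grouping, season, adjust))
                except ValueError as exc:
                    logger.info("compare_all: skipped %s/%s/%s (%s)",
                                season, grouping, name, exc)
    return (pd.concat(frames, ignore_index=True)
            if frames else pd.DataFrame(columns=["metric", "grouping", "season"]))
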