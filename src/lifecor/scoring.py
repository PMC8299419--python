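"""Per-feature longevity scoring.

A feature's longevity score is the Pearson product-moment correlation r
between its expression and strain median lifespan over the selected
strains.  Alongside r we report the slope of the univariate least-squares
regression of lifespan (days) on expression, so the effect is interpretable
in days per expression unit.  Vetting thresholds default to |r| >= 0.4
(longevity-correlating) and |r| >= 0.7 (top hit).

Features whose score is undefined — fewer than ``min_obs`` pairwise-complete
observations, or a constant vector — carry a NaN marker rather than a
silent zero, and never pass a threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import OmicsDataset
from .selection import SelectionPlan

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.4, 0.7)
DEFAULT_MIN_OBS = 6


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation, pairwise-complete.

    Returns NaN (the undefined-score marker) when fewer than 3 complete
    pairs remain or either vector is constant.
    """
    x, y = _pairwise_complete(x, y)
    if x.size < 3:
        return float("nan")
    xd = x - x.mean()
    yd = y - y.mean()
    sxx = float(xd @ xd)
    syy = float(yd @ yd)
    if sxx == 0.0 or syy == 0.0:
        return float("nan")
    return float((xd @ yd) / np.sqrt(sxx * syy))


def univariate_slope(expression, lifespan) -> float:
    """Least-squares slope of lifespan regressed on expression.

    Units: days of median lifespan per expression unit.  Same undefined
    policy as :func:`pearson_r` (NaN marker); a flat response gives 0.
    """
    x, y = _pairwise_complete(expression, lifespan)
    if x.size < 3:
        return float("nan")
    xd = x - x.mean()
    sxx = float(xd @ xd)
    if sxx == 0.0:
        return float("nan")
    return float((xd @ (y - y.mean())) / sxx)


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-tailed critical Pearson r at sample size ``n``.

    r_crit = t / sqrt(t^2 + n - 2) with t the two-tailed Student-t
    quantile at ``alpha`` on n - 2 degrees of freedom.  Provided as a
    diagnostic for threshold choice, not applied as a filter.
    """
    if n < 3:
        raise ValueError("critical_r requires n >= 3")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    t = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t / np.sqrt(t * t + n - 2))


def threshold_tag(threshold: float) -> str:
    """Compact digit tag for a threshold, e.g. 0.4 -> '04', 0.75 -> '075'."""
    return f"{threshold:g}".replace(".", "").ljust(2, "0")


def pass_column(threshold: float) -> str:
    """Column name for a vetting flag, e.g. 0.4 -> 'pass_04'."""
    return f"pass_{threshold_tag(threshold)}"


@dataclass
class ScoreTable:
    """Longevity scores for one dataset.

    ``scores`` is indexed by feature (or gene, after collapse) with columns
    ``r``, ``slope``, ``n_used`` and one boolean ``pass_XX`` flag per
    vetting threshold.  NaN in ``r`` marks an undefined score.
    """

    dataset_id: str
    scores: pd.DataFrame
    thresholds: tuple
    key: str = "feature"

    def measured(self) -> set:
        """Ids with a defined score (enter overlap/ranking denominators)."""
        return set(self.scores.index[self.scores["r"].notna()])

    def hits(self, threshold: float) -> set:
        """Ids whose |r| passes ``threshold``."""
        r = self.scores["r"]
        return set(self.scores.index[r.abs() >= threshold])

    def vetted(self, threshold: float) -> pd.DataFrame:
        """The rows passing ``threshold``, in stored order."""
        r = self.scores["r"]
        return self.scores[r.abs() >= threshold]

    def n_undefined(self) -> int:
        return int(self.scores["r"].isna().sum())


def score_dataset(
    dataset: OmicsDataset,
    plan: SelectionPlan,
    thresholds=DEFAULT_THRESHOLDS,
    min_obs: int = DEFAULT_MIN_OBS,
) -> ScoreTable:
    """Score every feature of ``dataset`` against median lifespan.

    Expression is mapped to the z-score scale first (so slopes share
    units across normalization conventions).  Per feature, strains with a
    missing value are dropped (pairwise-complete); features with fewer
    than ``min_obs`` observations, or constant expression, get the
    undefined marker.
    """
    strains = plan.selected_strains
    if not strains:
        raise ValueError("selection plan has no selected strains")
    zset = dataset.to_zscore()
    missing = [s for s in strains if s not in zset.values.columns]
    if missing:
        raise ValueError(
            f"selected strains absent from dataset {dataset.dataset_id}: {missing}"
        )
    X = zset.values[strains].to_numpy(dtype=float)          # features x strains
    L = plan.lifespans.reindex(strains).to_numpy(dtype=float)

    mask = ~np.isnan(X)
    n = mask.sum(axis=1)
    Xf = np.where(mask, X, 0.0)
    Lb = np.where(mask, L[None, :], 0.0)
    sx = Xf.sum(axis=1)
    sl = Lb.sum(axis=1)
    sxx = (Xf * Xf).sum(axis=1)
    sll = (Lb * Lb).sum(axis=1)
    sxl = (Xf * Lb).sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        cov_n = n * sxl - sx * sl
        var_x = n * sxx - sx * sx
        var_l = n * sll - sl * sl
        r = cov_n / np.sqrt(var_x * var_l)
        slope = cov_n / var_x

    # numerical guard: round-off can push |r| marginally past 1
    r = np.clip(r, -1.0, 1.0)

    defined = (n >= max(min_obs, 3)) & (var_x > 0) & (var_l > 0)
    r = np.where(defined, r, np.nan)
    slope = np.where(defined, slope, np.nan)

    n_undef = int((~defined).sum())
    if n_undef:
        logger.info(
            "dataset %s: %d feature(s) with undefined score "
            "(min_obs=%d or constant vector)",
            dataset.dataset_id, n_undef, min_obs,
        )

    out = pd.DataFrame(
        {"r": r, "slope": slope, "n_used": n.astype(int)},
        index=zset.values.index,
    )
    thresholds = tuple(sorted(thresholds))
    for th in thresholds:
        out[pass_column(th)] = np.abs(out["r"].to_numpy()) >= th
        out[pass_column(th)] = out[pass_column(th)].fillna(False)
    return ScoreTable(
        dataset_id=dataset.dataset_id, scores=out, thresholds=thresholds
    )


def top_k_features(table: ScoreTable, k: int) -> pd.DataFrame:
    """The ``k`` strongest defined scores, |r| descending, id ascending on ties."""
    if k <= 0:
        raise ValueError("k must be positive")
    defined = table.scores[table.scores["r"].notna()].copy()
    defined["_abs_r"] = defined["r"].abs()
    # stable two-key sort: id ascending, then |r| descending
    defined = defined.sort_index(kind="mergesort")
    defined = defined.sort_values("_abs_r", ascending=False, kind="mergesort")
    return defined.drop(columns="_abs_r").head(k)


def collapse_features_to_genes(
    table: ScoreTable, feature_gene_map: dict[str, str]
) -> ScoreTable:
    """Collapse a feature-level score table to gene level.

    Each gene keeps the score row of its feature with maximal |r| (sign
    retained); |r| ties go to the lexicographically smallest feature id.
    Unmapped features, and features with undefined scores, are dropped and
    counted in the log.  The original feature id is kept in a
    ``source_feature`` column.
    """
    scores = table.scores
    mapped_gene = pd.Series(
        [feature_gene_map.get(f) for f in scores.index], index=scores.index
    )
    n_unmapped = int(mapped_gene.isna().sum())
    n_undefined = int(scores["r"].isna().sum())
    if n_unmapped:
        logger.info(
            "dataset %s: %d feature(s) without a gene mapping dropped at collapse",
            table.dataset_id, n_unmapped,
        )
    if n_undefined:
        logger.info(
            "dataset %s: %d undefined-score feature(s) dropped at collapse",
            table.dataset_id, n_undefined,
        )
    work = scores[mapped_gene.notna() & scores["r"].notna()].copy()
    work["gene_id"] = mapped_gene[work.index]
    work["source_feature"] = work.index
    work["_abs_r"] = work["r"].abs()
    # sort so the winner per gene is first: |r| desc, feature id asc
    work = work.sort_values("source_feature", kind="mergesort")
    work = work.sort_values("_abs_r", ascending=False, kind="mergesort")
    collapsed = work.drop_duplicates(subset="gene_id", keep="first")
    collapsed = collapsed.set_index("gene_id").drop(columns="_abs_r")
    collapsed = collapsed.sort_index()
    return ScoreTable(
        dataset_id=table.dataset_id,
        scores=collapsed,
        thresholds=table.thresholds,
        key="gene",
    )
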