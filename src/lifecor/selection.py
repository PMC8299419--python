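"""Match dataset strains to lifespans and pick the extreme-lived tails.

Strain naming is inconsistent across public BXD exports ("BXD-1", "bxd 1",
"BXD1"); names are harmonised by lower-casing and stripping hyphens, spaces
and underscores before matching.  Matched strains are ranked shortest to
longest lived and, in the default tails design, the ``tail_size`` shortest-
and longest-lived strains are kept for scoring.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

from .io import OmicsDataset

logger = logging.getLogger(__name__)

_STRIP = re.compile(r"[\s\-_]+")


def normalize_strain_name(name: str) -> str:
    """Canonical form used for matching: lower-case, separators removed."""
    return _STRIP.sub("", str(name).strip().lower())


def match_strains(
    dataset: OmicsDataset,
    lifespans: pd.DataFrame,
    sex_policy: str = "match_sex",
) -> pd.DataFrame:
    """Match a dataset's strains to the lifespan table.

    Parameters
    ----------
    lifespans
        DataFrame with columns ``strain_id``, ``median_lifespan_days``,
        ``sex``.
    sex_policy
        ``match_sex``: only lifespan entries whose sex equals the dataset's
        declared sex (or ``combined``) are eligible; when several entries
        remain for a strain the exact-sex one wins.  ``any``: all entries
        eligible, exact sex still preferred.

    Returns
    -------
    DataFrame with columns ``strain_id`` (dataset spelling), ``norm_id``,
    ``median_lifespan_days``, ordered shortest to longest lived, lifespan
    ties broken by ``norm_id`` ascending.  Unmatched strains are dropped
    and logged.
    """
    if sex_policy not in ("match_sex", "any"):
        raise ValueError(f"unknown sex_policy {sex_policy!r}")
    table = lifespans.copy()
    if sex_policy == "match_sex":
        eligible = table["sex"].isin({dataset.sex, "combined"})
        table = table[eligible]
    # exact sex match outranks a combined entry for the same strain
    table = table.assign(
        norm_id=table["strain_id"].map(normalize_strain_name),
        _pref=(table["sex"] != dataset.sex).astype(int),
    )
    table = (
        table.sort_values(["norm_id", "_pref", "sex"])
        .drop_duplicates(subset="norm_id", keep="first")
        .set_index("norm_id")
    )

    rows = []
    dropped = []
    for strain in dataset.strain_ids:
        key = normalize_strain_name(strain)
        if key in table.index:
            rows.append(
                (strain, key, float(table.loc[key, "median_lifespan_days"]))
            )
        else:
            dropped.append(strain)
    for strain in dropped:
        logger.info(
            "dataset %s: strain %r has no lifespan entry; dropped",
            dataset.dataset_id, strain,
        )
    if not rows:
        raise ValueError(
            f"dataset {dataset.dataset_id}: no strains mappable to lifespan table"
        )
    matched = pd.DataFrame(
        rows, columns=["strain_id", "norm_id", "median_lifespan_days"]
    )
    matched = matched.sort_values(
        ["median_lifespan_days", "norm_id"], kind="mergesort"
    ).reset_index(drop=True)
    return matched


@dataclass
class SelectionPlan:
    """The strains entering the correlation, flagged short/long tail.

    ``frame`` columns: strain_id, norm_id, median_lifespan_days, rank
    (1 = shortest lived), selected (bool), tail ('short', 'long', 'mid',
    or 'all').
    """

    mode: str
    tail_size: int
    frame: pd.DataFrame

    @property
    def selected_strains(self) -> list[str]:
        return list(self.frame.loc[self.frame["selected"], "strain_id"])

    @property
    def lifespans(self) -> pd.Series:
        """Median lifespan (days) of the selected strains, strain-indexed."""
        sel = self.frame[self.frame["selected"]]
        return pd.Series(
            sel["median_lifespan_days"].to_numpy(), index=sel["strain_id"].to_numpy()
        )

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()


def select_extremes(
    matched: pd.DataFrame, mode: str = "tails", tail_size: int = 4
) -> SelectionPlan:
    """Select strains for scoring.

    ``tails`` keeps the ``tail_size`` shortest- and longest-lived strains;
    if fewer than ``2 * tail_size`` strains matched, every strain is kept
    (with a warning) — the fallback used for sparsely profiled tissues.
    ``all`` keeps every matched strain.
    """
    if matched.empty:
        raise ValueError("no matched strains to select from")
    if mode not in ("tails", "all"):
        raise ValueError(f"unknown selection mode {mode!r}")
    if tail_size < 1:
        raise ValueError("tail_size must be >= 1")

    frame = matched.copy().reset_index(drop=True)
    frame["rank"] = frame.index + 1
    n = len(frame)
    effective_mode = mode
    if mode == "tails" and n < 2 * tail_size:
        logger.warning(
            "only %d matched strains (< 2*tail_size=%d); using all strains",
            n, 2 * tail_size,
        )
        effective_mode = "all"
    if effective_mode == "all":
        frame["selected"] = True
        frame["tail"] = "all"
    else:
        tail = []
        for i in range(n):
            if i < tail_size:
                tail.append("short")
            elif i >= n - tail_size:
                tail.append("long")
            else:
                tail.append("mid")
        frame["tail"] = tail
        frame["selected"] = frame["tail"] != "mid"
    return SelectionPlan(mode=effective_mode, tail_size=tail_size, frame=frame)
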