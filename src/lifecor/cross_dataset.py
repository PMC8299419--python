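"""Merge vetted hit sets across datasets.

Three views of cross-dataset agreement:

* pairwise overlap fractions — Jaccard index of the two hit sets after
  restricting both to the genes measured in both datasets (the shared
  measured universe);
* a shared-gene ranking — per gene, the number of datasets where it is
  measured and passes the threshold (presence count), together with the
  mean |r| over those passing datasets;
* a signed correlation pattern matrix for the top-ranked genes, keeping
  per-dataset signs (the same gene may correlate positively with lifespan
  in one tissue and negatively in another).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import ScoreTable


@dataclass
class OverlapMatrix:
    """Pairwise hit-set overlap statistics at one threshold.

    All matrices are dataset x dataset DataFrames.  ``fraction`` is the
    Jaccard index |A∩B| / |A∪B| over the shared measured universe of each
    pair; NaN marks an undefined fraction (empty union).
    """

    threshold: float
    fraction: pd.DataFrame
    intersection: pd.DataFrame
    union: pd.DataFrame
    hit_sizes: pd.Series

    def to_long_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-pair form for TSV output."""
        ids = list(self.fraction.index)
        rows = []
        for a in ids:
            for b in ids:
                rows.append(
                    {
                        "dataset_a": a,
                        "dataset_b": b,
                        "intersection": int(self.intersection.loc[a, b]),
                        "union": int(self.union.loc[a, b]),
                        "jaccard": self.fraction.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def overlap_matrix(tables: list[ScoreTable], threshold: float) -> OverlapMatrix:
    """Pairwise Jaccard overlap of hit sets at ``threshold``.

    Hit sets of a pair are first restricted to genes measured in both
    datasets, so a gene absent from one platform never counts against the
    overlap.  Requires gene-level tables on a common id space.
    """
    if len(tables) < 2:
        raise ValueError("overlap requires at least two score tables")
    ids = [t.dataset_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError("dataset ids must be unique")
    measured = {t.dataset_id: t.measured() for t in tables}
    hits = {t.dataset_id: t.hits(threshold) for t in tables}

    frac = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    inter = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    union = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for a in ids:
        for b in ids:
            shared = measured[a] & measured[b]
            ha = hits[a] & shared
            hb = hits[b] & shared
            u = ha | hb
            i = ha & hb
            inter.loc[a, b] = len(i)
            union.loc[a, b] = len(u)
            frac.loc[a, b] = len(i) / len(u) if u else np.nan
    sizes = pd.Series({d: len(hits[d]) for d in ids}, name="hits")
    return OverlapMatrix(
        threshold=threshold, fraction=frac, intersection=inter,
        union=union, hit_sizes=sizes,
    )


def shared_gene_ranking(
    tables: list[ScoreTable], threshold: float
) -> pd.DataFrame:
    """Rank genes by presence across datasets, then mean |r|.

    Returns a DataFrame indexed by gene id with columns ``presence_count``
    (datasets where measured AND passing), ``n_measured`` (datasets where
    the gene has a defined score), ``mean_abs_r`` (mean |r| over passing
    datasets only; NaN when none pass) and one signed-r column
    ``r_<dataset_id>`` per dataset (NaN where unmeasured or failing).
    Sorted by presence_count desc, mean_abs_r desc, gene id asc.
    """
    if not tables:
        raise ValueError("need at least one score table")
    ids = [t.dataset_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError("dataset ids must be unique")

    all_genes = sorted(set().union(*(t.measured() for t in tables)))
    out = pd.DataFrame(index=pd.Index(all_genes, name="gene_id"))
    measured = pd.DataFrame(False, index=out.index, columns=ids)
    for t in tables:
        col = f"r_{t.dataset_id}"
        r = t.scores["r"].reindex(out.index)
        passing = r.abs() >= threshold
        out[col] = r.where(passing)
        measured[t.dataset_id] = r.notna()

    r_cols = [f"r_{d}" for d in ids]
    out.insert(0, "presence_count", out[r_cols].notna().sum(axis=1))
    out.insert(1, "n_measured", measured.sum(axis=1))
    out.insert(2, "mean_abs_r", out[r_cols].abs().mean(axis=1))

    out = out.sort_index(kind="mergesort")
    out = out.sort_values("mean_abs_r", ascending=False, kind="mergesort",
                          na_position="last")
    out = out.sort_values("presence_count", ascending=False, kind="mergesort")
    return out


def presence_histogram(ranking: pd.DataFrame, n_datasets: int) -> pd.Series:
    """Number of genes at each presence count, over the full 0..n range."""
    counts = ranking["presence_count"].value_counts()
    idx = pd.RangeIndex(0, n_datasets + 1, name="presence_count")
    return counts.reindex(idx, fill_value=0).astype(int).rename("n_genes")


def sign_pattern_matrix(ranking: pd.DataFrame, top_n: int) -> pd.DataFrame:
    """Signed per-dataset r for the ``top_n`` ranked genes.

    Entries are the signed correlation where the gene passes in that
    dataset and NaN (an explicit missing marker, never 0) where it is
    unmeasured or fails.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    r_cols = [c for c in ranking.columns if c.startswith("r_")]
    return ranking.head(top_n)[r_cols].copy()
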