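"""Gene-set over-representation analysis of longevity hit sets.

The statistic is the hypergeometric upper tail: with ``N`` genes in the
universe, ``K`` of them in a set and ``n`` in the hit list, the p-value is
P(X >= k) for the observed overlap k.  Benjamini–Hochberg adjustment is
applied over the tested sets; both raw and adjusted values are reported.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

DEFAULT_MIN_SET_SIZE = 5
DEFAULT_MAX_SET_SIZE = 500


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` hits in the set, ``K`` set members in the universe, ``n`` hits
    overall, ``N`` universe size.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid urn: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> pd.Series:
    """Benjamini–Hochberg step-up adjusted p-values (monotone in p rank)."""
    p = pd.Series(pvalues, dtype=float)
    if p.empty:
        return p
    _, adj, _, _ = multipletests(p.to_numpy(), method="fdr_bh")
    return pd.Series(adj, index=p.index)


def run_enrichment(
    hits,
    universe,
    collection: GeneSetCollection,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    max_set_size: int = DEFAULT_MAX_SET_SIZE,
) -> pd.DataFrame:
    """Test every gene set for over-representation in ``hits``.

    Each set is intersected with ``universe`` first; sets whose effective
    size falls outside [min_set_size, max_set_size] are skipped.  Returns a
    DataFrame with columns set_id, set_name, k, K, n, N, p_value, fdr,
    sorted by p-value then set id.

    Raises ``ValueError`` if the hit list is not contained in the universe.
    """
    hits = set(hits)
    universe = set(universe)
    offenders = sorted(hits - universe)
    if offenders:
        raise ValueError(f"hit genes absent from universe: {offenders[:20]}")
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")

    N = len(universe)
    n = len(hits)
    rows = []
    for gene_set in collection:
        members = gene_set.members & universe
        K = len(members)
        if not min_set_size <= K <= max_set_size:
            continue
        k = len(members & hits)
        rows.append(
            {
                "set_id": gene_set.set_id,
                "set_name": gene_set.set_name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": hypergeom_upper_tail(k, K, n, N),
            }
        )
    result = pd.DataFrame(
        rows, columns=["set_id", "set_name", "k", "K", "n", "N", "p_value"]
    )
    if result.empty:
        result["fdr"] = pd.Series(dtype=float)
        return result
    result["fdr"] = bh_adjust(result["p_value"]).to_numpy()
    result = result.sort_values(["p_value", "set_id"], kind="mergesort")
    return result.reset_index(drop=True)
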