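"""Over-representation analysis of discrete gene lists against GMT sets.

Given a fixed query list (e.g. genes up in one ETS stratum) and a
background universe, each gene set is scored by the upper-tail
hypergeometric probability of its observed overlap with the query, with
BH adjustment across the tested sets.  This is the defined computation
for unranked lists; running-sum enrichment statistics are out of scope.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .core import GeneSetCollection
from .de import bh_fdr


def hypergeom_test(k: int, K: int, n: int, M: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(M, K, n).

    ``M`` universe size, ``K`` set size in universe, ``n`` query size,
    ``k`` observed hits.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts: k={k} must lie in [0, min(K={K}, n={n})]")
    if K > M or n > M or K < 0 or n < 0:
        raise ValueError(f"inconsistent counts: K={K}, n={n} must lie in [0, M={M}]")
    return float(min(stats.hypergeom.sf(k - 1, M, K, n), 1.0))


def run_ora(query, universe, collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric ORA of ``query`` against every set in ``collection``.

    Sets are intersected with the universe first; sets empty after
    intersection are not tested.  Returns a table sorted by p with
    columns set_name, k, K, n, M, p, q (BH across tested sets).
    """
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    query = list(dict.fromkeys(query))
    outside = [g for g in query if g not in uni]
    if outside:
        raise ValueError(f"query gene(s) outside universe: {outside[:5]}")
    qset = set(query)
    M, n = len(uni), len(qset)

    rows = []
    for set_name, members in collection.sets.items():
        in_universe = uni.intersection(members)
        K = len(in_universe)
        if K == 0:
            continue
        k = len(qset & in_universe)
        rows.append((set_name, k, K, n, M, hypergeom_test(k, K, n, M)))
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    table = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "M", "p"])
    table["q"] = bh_fdr(table["p"].to_numpy())
    return table.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
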