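"""Over-representation and contingency statistics.

``hypergeometric_ora`` is the classical gene-set over-representation test:
for a query of ``n`` genes drawn from a universe of ``N`` with ``K`` genes
in a set, the p-value is the upper hypergeometric tail P(X >= overlap),
Benjamini–Hochberg adjusted across sets.  Set-size filtering defaults to
``min_set_size=1`` (no restriction beyond non-emptiness) and no upper bound.

``fisher_exact_2x2`` is Fisher's exact test computed by direct enumeration
of the hypergeometric support at fixed margins, with the one-sided tail
taken in the direction of the observed odds ratio and a choice between the
probability-mass and tail-doubling two-sided rules.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

__all__ = ["hypergeometric_ora", "fisher_exact_2x2", "bh_adjust", "hypergeom_upper_tail"]


def hypergeom_upper_tail(k: int, n_universe: int, n_set: int, n_query: int) -> float:
    """P(X >= k) for X ~ Hypergeom(universe, set size, draws)."""
    p = float(scipy.stats.hypergeom.sf(k - 1, n_universe, n_set, n_query))
    return min(p, 1.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def hypergeometric_ora(
    query,
    sets: GeneSetCollection,
    universe,
    min_set_size: int = 1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of *query* in each gene set.

    Sets are intersected with the universe first and retained when at least
    ``min_set_size`` genes remain; query genes outside the universe are
    dropped with a warning.  Rows are sorted by adjusted p then set name.
    """
    universe = set(map(str, universe))
    if not universe:
        raise ValueError("empty universe")
    query = set(map(str, query))
    outside = query - universe
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe were dropped")
        query &= universe
    n_universe, n_query = len(universe), len(query)
    rows = []
    for name in sorted(sets.sets):
        members = set(sets.sets[name]) & universe
        if len(members) < min_set_size:
            continue
        overlap = sorted(members & query)
        k = len(overlap)
        p = hypergeom_upper_tail(k, n_universe, len(members), n_query)
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": len(members),
                "query_size": n_query,
                "universe_size": n_universe,
                "p": min(p, 1.0),
                "genes": ",".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "set_name", "overlap", "set_size", "query_size",
                "universe_size", "p", "padj", "genes",
            ]
        )
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["p"])
    out = out.sort_values(["padj", "set_name"], kind="stable").reset_index(drop=True)
    return out[
        ["set_name", "overlap", "set_size", "query_size", "universe_size", "p", "padj", "genes"]
    ]


@dataclass
class FisherResult:
    odds_ratio: float  # sample odds ratio ad/bc; inf when bc == 0 and ad > 0
    p: float


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, sided: str = "one", two_sided_rule: str = "mass"
) -> FisherResult:
    """Fisher's exact test on the 2×2 table [[a, b], [c, d]].

    With margins fixed, the top-left count follows a hypergeometric
    distribution; the test enumerates that support directly.  ``sided="one"``
    takes the tail in the direction of the observed odds ratio (p = 1 when
    the sample odds ratio equals 1, i.e. no directional evidence);
    ``sided="two"`` sums the probabilities of all tables no more likely than
    the observed one (``two_sided_rule="mass"``, the convention of most
    software) or doubles the smaller tail capped at 1
    (``two_sided_rule="double"``).
    """
    counts = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in counts):
        raise ValueError("counts must be non-negative integers")
    a, b, c, d = map(int, counts)
    row1, row2, col1 = a + b, c + d, a + c
    n = a + b + c + d
    if row1 == 0 or row2 == 0 or col1 == 0 or (b + d) == 0:
        raise ValueError("a margin of the 2x2 table is zero")
    lo, hi = max(0, col1 - row2), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = scipy.stats.hypergeom.pmf(support, n, col1, row1)
    obs = a - lo
    if sided == "two":
        if two_sided_rule == "mass":
            p = float(pmf[pmf <= pmf[obs] + 1e-12].sum())
        elif two_sided_rule == "double":
            lower = float(pmf[: obs + 1].sum())
            upper = float(pmf[obs:].sum())
            p = min(1.0, 2.0 * min(lower, upper))
        else:
            raise ValueError(f"unknown two_sided_rule {two_sided_rule!r}")
    elif sided == "one":
        if a * d > b * c:  # enrichment in the top-left cell
            p = float(pmf[obs:].sum())
        elif a * d < b * c:
            p = float(pmf[: obs + 1].sum())
        else:
            p = 1.0
    else:
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = a * d / (b * c)
    return FisherResult(odds_ratio=odds, p=min(p, 1.0))
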