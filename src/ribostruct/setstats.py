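"""Gene-set overlap and term-enrichment statistics.

The Fisher exact test here is computed from exact big-integer
hypergeometric weights: the two-sided p-value sums, over the support of
the overlap count, every table whose (exact, unnormalized) probability is
at most that of the observed table — the minimum-likelihood convention —
so ties are resolved exactly rather than through a floating-point
tolerance. Term enrichment is the upper-tail hypergeometric test with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OverlapResult",
    "fisher_exact_2x2",
    "overlap_fisher",
    "enrich_terms",
    "rank_select",
    "term_list_overlap",
]


@dataclass
class OverlapResult:
    """2x2 overlap between two gene sets within a universe."""

    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    pct_of_a: float
    pct_of_b: float
    odds_ratio: float
    p_two_sided: float
    p_enrichment: float  # one-sided upper tail

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        a = self.n_overlap
        b = self.n_a - a
        c = self.n_b - a
        d = self.n_universe - self.n_a - self.n_b + a
        return ((a, b), (c, d))


def fisher_exact_2x2(a: int, b: int, c: int,
                     d: int) -> tuple[float, float, float]:
    """(two-sided p, upper-tail p, odds ratio) for table [[a, b], [c, d]].

    Probabilities are exact ratios of integer binomial sums, converted to
    float only at the end. The odds ratio is the sample ad/bc, with the
    Haldane 0.5 correction applied when any cell is zero.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be >= 0")
    n = a + b + c + d
    row = a + b
    col = a + c
    k_lo = max(0, row + col - n)
    k_hi = min(row, col)
    # unnormalized hypergeometric weights over the support of cell a
    weights = [comb(row, k) * comb(n - row, col - k)
               for k in range(k_lo, k_hi + 1)]
    total = comb(n, col)
    w_obs = weights[a - k_lo]
    two = sum(w for w in weights if w <= w_obs)
    upper = sum(weights[a - k_lo:])
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return two / total, upper / total, odds


def overlap_fisher(set_a: Iterable[str], set_b: Iterable[str],
                   universe: Iterable[str]) -> OverlapResult:
    """Fisher exact test of the overlap between two sets in a universe."""
    universe = set(universe)
    if len(universe) < 2:
        raise ValueError("universe must contain >= 2 genes")
    sa, sb = set(set_a), set(set_b)
    stray = sorted((sa | sb) - universe)
    if stray:
        raise ValueError(f"sets contain genes outside the universe: "
                         f"{stray[:5]}")
    n_overlap = len(sa & sb)
    a = n_overlap
    b = len(sa) - a
    c = len(sb) - a
    d = len(universe) - len(sa) - len(sb) + a
    p_two, p_up, odds = fisher_exact_2x2(a, b, c, d)
    return OverlapResult(
        n_universe=len(universe), n_a=len(sa), n_b=len(sb),
        n_overlap=n_overlap,
        pct_of_a=100.0 * n_overlap / len(sa) if sa else float("nan"),
        pct_of_b=100.0 * n_overlap / len(sb) if sb else float("nan"),
        odds_ratio=odds, p_two_sided=p_two, p_enrichment=p_up)


def enrich_terms(gene_set: Iterable[str],
                 term_map: Mapping[str, Iterable[str]],
                 universe: Iterable[str],
                 drop_empty: bool = False) -> pd.DataFrame:
    """Hypergeometric term enrichment of a gene set against a term map.

    Terms are intersected with the universe before testing; the p-value is
    the upper-tail hypergeometric probability of the observed overlap or
    more, and q is the Benjamini-Hochberg adjusted p across tested terms.
    Terms with zero overlap are reported with p = 1 unless ``drop_empty``.
    """
    universe = set(universe)
    gene_set = set(gene_set)
    stray = sorted(gene_set - universe)
    if stray:
        raise ValueError(f"gene set contains genes outside the universe: "
                         f"{stray[:5]}")
    n = len(universe)
    k_set = len(gene_set)
    rows = []
    for term, members in term_map.items():
        in_universe = set(members) & universe
        k_term = len(in_universe)
        if k_term == 0:
            continue
        k_both = len(in_universe & gene_set)
        if k_both == 0 and drop_empty:
            continue
        p = float(stats.hypergeom.sf(k_both - 1, n, k_term, k_set))
        rows.append({"term": term, "term_size": k_term,
                     "overlap": k_both, "p": min(p, 1.0)})
    result = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p"])
    if len(result):
        result["q"] = multipletests(result["p"], method="fdr_bh")[1]
        result = result.sort_values(["q", "p", "term"],
                                    ignore_index=True)
    else:
        result["q"] = pd.Series(dtype=float)
    return result


def rank_select(metric_by_gene: Mapping[str, float] | pd.Series,
                fraction: float = 0.30, side: str = "top") -> list[str]:
    """Top or bottom fraction of genes by a metric.

    Selects floor(fraction * n) genes after dropping missing metrics;
    ties are broken by ascending gene id. Returns the selected ids sorted
    by gene id.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if side not in ("top", "bottom"):
        raise ValueError("side must be 'top' or 'bottom'")
    metric = pd.Series(metric_by_gene, dtype=float).dropna()
    n_sel = int(np.floor(fraction * len(metric)))
    key = -metric if side == "top" else metric
    order = pd.DataFrame({"key": key, "gene": key.index.astype(str)})
    order = order.sort_values(["key", "gene"], kind="mergesort")
    return sorted(order["gene"].iloc[:n_sel])


def term_list_overlap(enrich_a: pd.DataFrame, enrich_b: pd.DataFrame,
                      q_cutoff: float = 0.05) -> tuple[float, list[str]]:
    """Jaccard index between the significant term lists of two enrichments.

    Terms pass at q <= q_cutoff. Two empty lists are identical, so their
    Jaccard index is 1.
    """
    ta = set(enrich_a.loc[enrich_a["q"] <= q_cutoff, "term"])
    tb = set(enrich_b.loc[enrich_b["q"] <= q_cutoff, "term"])
    union = ta | tb
    if not union:
        return 1.0, []
    shared = sorted(ta & tb)
    return len(ta & tb) / len(union), shared
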