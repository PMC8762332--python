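"""Windowed 5'UTR/CDS structure-score features and group comparisons.

Per-nucleotide structure propensity scores (PARS-style: higher = more
double-stranded) are summarized over a fixed set of named windows anchored
on the start codon, and window summaries are compared between gene sets
with an unpaired Student t test.

Coordinates are 1-based and signed: position -1 is the last 5'UTR
nucleotide, +1 the first CDS nucleotide (the A of the AUG); there is no
position 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WINDOWS",
    "TranscriptModel",
    "GroupComparison",
    "DegenerateVarianceError",
    "window_bounds",
    "cumulative_score",
    "mean_per_nt_5utr",
    "window_scores",
    "compare_groups",
    "feature_table",
]

#: CDS-anchored windows: name -> (first, last) CDS position, 1-based inclusive.
_CDS_WINDOWS = {
    "plus15": (1, 30),
    "plus30": (16, 45),
    "plus45": (31, 60),
    "plus60": (46, 75),
    "plus75": (61, 90),
}

#: All named windows, in report order.
WINDOWS = ("total5utr", "first30", "start30", "plus15", "plus30", "plus45",
           "plus60", "plus75")


class DegenerateVarianceError(ValueError):
    """Raised when a t test is requested on constant, unequal groups."""


@dataclass
class TranscriptModel:
    """A transcript with per-nucleotide structure scores.

    ``scores`` runs 5'->3' and covers the full 5'UTR followed by the first
    covered CDS nucleotides (at most ``cds_len``).
    """

    gene_id: str
    utr5_len: int
    cds_len: int
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.utr5_len < 0 or self.cds_len < 0:
            raise ValueError(f"{self.gene_id}: negative region length")
        if len(self.scores) < self.utr5_len:
            raise ValueError(
                f"{self.gene_id}: score track shorter than the 5'UTR "
                f"({len(self.scores)} < {self.utr5_len})")
        if len(self.scores) > self.utr5_len + self.cds_len:
            raise ValueError(
                f"{self.gene_id}: score track longer than 5'UTR + CDS")

    @property
    def covered_cds(self) -> int:
        """Number of CDS nucleotides with a score."""
        return len(self.scores) - self.utr5_len


@dataclass
class GroupComparison:
    """Unpaired two-group comparison of one feature."""

    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t: float
    p: float
    significant: bool
    degenerate: bool = False
    alpha: float = 0.05


def window_bounds(window_name: str, utr5_len: int,
                  covered_cds: int) -> tuple[int, int] | None:
    """Signed 1-based inclusive bounds of a named window, or ``None``.

    Windows that do not fully fit the available sequence are missing
    (``None``), never truncated: a truncated cumulative score would not be
    comparable across transcripts.
    """
    if utr5_len < 0 or covered_cds < 0:
        raise ValueError("region lengths must be >= 0")
    if window_name == "total5utr":
        return (-utr5_len, -1) if utr5_len > 0 else None
    if window_name == "first30":
        # first 30 5'UTR nucleotides counted from the cap
        return (-utr5_len, -utr5_len + 29) if utr5_len >= 30 else None
    if window_name == "start30":
        # 15 nt either side of the start codon: -15..-1 and +1..+15
        return (-15, 15) if utr5_len >= 15 and covered_cds >= 15 else None
    if window_name in _CDS_WINDOWS:
        lo, hi = _CDS_WINDOWS[window_name]
        return (lo, hi) if covered_cds >= hi else None
    raise ValueError(f"unknown window name: {window_name!r}")


def _position_index(pos: int, utr5_len: int) -> int:
    # signed position (no 0) -> index into the score track
    return utr5_len + pos if pos < 0 else utr5_len + pos - 1


def cumulative_score(model: TranscriptModel, window_name: str) -> float | None:
    """Sum of per-nucleotide scores over a named window; ``None`` if missing."""
    bounds = window_bounds(window_name, model.utr5_len, model.covered_cds)
    if bounds is None:
        return None
    lo, hi = bounds
    positions = [p for p in range(lo, hi + 1) if p != 0]
    # accumulate 5'->3' so the sum is reproducible position by position
    return float(sum(model.scores[_position_index(p, model.utr5_len)]
                     for p in positions))


def mean_per_nt_5utr(model: TranscriptModel) -> float | None:
    """Average per-nucleotide score over the full 5'UTR; ``None`` if empty."""
    total = cumulative_score(model, "total5utr")
    if total is None:
        return None
    return total / model.utr5_len


def window_scores(model: TranscriptModel) -> dict[str, float | None]:
    """All named window sums plus the 5'UTR per-nucleotide mean."""
    out: dict[str, float | None] = {w: cumulative_score(model, w)
                                    for w in WINDOWS}
    out["mean_5utr_per_nt"] = mean_per_nt_5utr(model)
    return out


def compare_groups(group_a: Iterable[float], group_b: Iterable[float],
                   alpha: float = 0.05, welch: bool = False) -> GroupComparison:
    """Two-sided unpaired t test between two collections of values.

    Missing values (NaN/None) are dropped first. The default is the
    pooled-variance Student form; ``welch=True`` uses the unequal-variance
    Welch form. Both groups constant and equal is reported as a degenerate
    comparison with t = 0, p = 1; constant but unequal groups raise
    :class:`DegenerateVarianceError` (an infinite t is not meaningful).
    """
    a = np.asarray([v for v in group_a if v is not None], dtype=float)
    b = np.asarray([v for v in group_b if v is not None], dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError(f"each group needs >= 2 values (got {na}, {nb})")
    ma, mb = float(a.mean()), float(b.mean())
    va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))

    if va == 0.0 and vb == 0.0:
        if math.isclose(ma, mb, rel_tol=1e-9, abs_tol=1e-12):
            return GroupComparison(ma, mb, na, nb, t=0.0, p=1.0,
                                   significant=False, degenerate=True,
                                   alpha=alpha)
        raise DegenerateVarianceError(
            "both groups constant with unequal means; t is unbounded")

    from scipy import stats

    if welch:
        se = math.sqrt(va / na + vb / nb)
        t = (ma - mb) / se
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    p = float(2.0 * stats.t.sf(abs(t), df))
    return GroupComparison(ma, mb, na, nb, t=float(t), p=p,
                           significant=p < alpha, alpha=alpha)


def feature_table(models: Sequence[TranscriptModel],
                  gene_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Per-set window summaries (long form).

    One row per set x feature, where feature is each named window, the
    5'UTR per-nucleotide mean, and the 5'UTR length. ``mean`` averages over
    the set's genes with that feature defined; ``n`` counts them. Genes
    whose window is missing never contribute to the mean.
    """
    by_id = {m.gene_id: m for m in models}
    features = list(WINDOWS) + ["mean_5utr_per_nt", "utr5_len"]
    rows = []
    for set_name, genes in gene_sets.items():
        genes = list(genes)
        if not genes:
            raise ValueError(f"gene set {set_name!r} is empty")
        unknown = [g for g in genes if g not in by_id]
        if unknown:
            raise KeyError(f"gene set {set_name!r} references unknown genes: "
                           f"{unknown[:5]}")
        per_gene = [window_scores(by_id[g]) | {"utr5_len": by_id[g].utr5_len}
                    for g in genes]
        for feat in features:
            vals = [pg[feat] for pg in per_gene if pg[feat] is not None]
            rows.append({
                "set": set_name,
                "feature": feat,
                "mean": float(np.mean(vals)) if vals else float("nan"),
                "n": len(vals),
            })
    return pd.DataFrame(rows, columns=["set", "feature", "mean", "n"])
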