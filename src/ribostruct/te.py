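"""Translational-efficiency analysis of paired Ribo-seq/RNA-seq counts.

Translation efficiency (TE) is the ratio of normalized ribosome-footprint
signal to normalized mRNA signal per gene. Contrasts compare two
strain x condition cells and report per-gene log2 fold-changes of RNA,
ribosome footprints, and TE; genes are classified into up/down sets at a
fold-change threshold tau (default 1.5, boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountExperiment",
    "ContrastResult",
    "GeneSet",
    "normalize",
    "compute_te",
    "contrast",
    "classify_sets",
    "correlate",
]

SAMPLE_COLUMNS = ("sample_id", "strain", "condition", "assay", "replicate")


@dataclass
class CountExperiment:
    """Genes x samples count matrix with factorial sample metadata.

    ``counts`` holds raw integer counts (genes as index, sample ids as
    columns); ``samples`` is the sample sheet with one row per column of
    ``counts``. ``size_factors`` and ``normalized`` are filled in by
    :func:`normalize`.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    size_factors: pd.Series | None = None
    normalized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if "sample_id" in self.samples.columns:
            self.samples = self.samples.set_index("sample_id")
        missing = [c for c in ("strain", "condition", "assay", "replicate")
                   if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if sorted(self.samples.index) != sorted(self.counts.columns):
            raise ValueError(
                "sample sheet must cover every count column exactly once")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be >= 0")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def sample_ids(self, strain: str | None = None,
                   condition: str | None = None,
                   assay: str | None = None) -> list[str]:
        """Sample ids matching the given factor levels."""
        sel = pd.Series(True, index=self.samples.index)
        for col, val in (("strain", strain), ("condition", condition),
                         ("assay", assay)):
            if val is not None:
                sel &= self.samples[col] == val
        return list(self.samples.index[sel])


def normalize(expt: CountExperiment,
              method: str = "median-of-ratios") -> CountExperiment:
    """Attach size factors and a normalized matrix.

    ``median-of-ratios`` (default): per-sample size factor is the median,
    over genes whose geometric mean across samples is nonzero, of
    count / geometric mean (the DESeq convention). ``cpm``: each column is
    scaled to sum to 1e6.
    """
    counts = expt.counts.astype(float)
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("every sample needs at least one nonzero gene")
    if method == "median-of-ratios":
        arr = counts.to_numpy()
        all_nonzero = (arr > 0).all(axis=1)
        if not all_nonzero.any():
            raise ValueError(
                "no gene is nonzero in every sample; median-of-ratios is "
                "undefined — use method='cpm'")
        logs = np.log(arr[all_nonzero])
        log_geomean = logs.mean(axis=1)
        sf = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    elif method == "cpm":
        sf = counts.sum(axis=0).to_numpy() / 1e6
    else:
        raise ValueError(f"unknown normalization method: {method!r}")
    size_factors = pd.Series(sf, index=counts.columns, name="size_factor")
    normalized = counts / size_factors
    return replace(expt, size_factors=size_factors, normalized=normalized)


def _cell_mean(expt: CountExperiment, strain: str, condition: str,
               assay: str) -> pd.Series:
    cols = expt.sample_ids(strain=strain, condition=condition, assay=assay)
    if not cols:
        raise ValueError(
            f"no samples for strain={strain!r}, condition={condition!r}, "
            f"assay={assay!r}")
    if expt.normalized is None:
        raise ValueError("experiment is not normalized; call normalize first")
    return expt.normalized[cols].mean(axis=1)


def _guarded_ratio(num: pd.Series, den: pd.Series,
                   pseudocount: float) -> pd.Series:
    """num/den with the pseudocount added to both only where a mean is zero.

    Adding the pseudocount unconditionally would make ratios depend on the
    overall normalized scale; restricting it to genes where it is actually
    needed keeps fold-changes exactly invariant to uniform rescaling of
    any library.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    needs = (num == 0) | (den == 0)
    out = pd.Series(np.nan, index=num.index)
    out[~needs] = num[~needs] / den[~needs]
    out[needs] = (num[needs] + pseudocount) / (den[needs] + pseudocount)
    return out


def compute_te(expt: CountExperiment, strain: str, condition: str,
               pseudocount: float = 0.5) -> pd.Series:
    """Per-gene TE: mean normalized Ribo over mean normalized RNA.

    The pseudocount guards genes where either replicate-mean is zero
    (TE = (m + c) / c when the RNA mean is zero); elsewhere the plain
    ratio is used.
    """
    ribo = _cell_mean(expt, strain, condition, "Ribo")
    rna = _cell_mean(expt, strain, condition, "RNA")
    te = _guarded_ratio(ribo, rna, pseudocount)
    te.name = f"TE_{strain}_{condition}"
    return te


@dataclass
class ContrastResult:
    """Per-gene log2 fold-changes for one cell-vs-cell contrast.

    ``table`` has columns log2fc_rna, log2fc_ribo, log2fc_te, measurable.
    The TE fold-change is the footprint fold-change minus the RNA
    fold-change (TE = Ribo/RNA), so log2fc_te = log2fc_ribo - log2fc_rna
    holds identically. Non-measurable genes carry NaN fold-changes.
    """

    label: str
    cell_a: tuple[str, str]
    cell_b: tuple[str, str]
    table: pd.DataFrame

    @property
    def measurable_genes(self) -> pd.Index:
        return self.table.index[self.table["measurable"]]


def contrast(expt: CountExperiment, cell_a: tuple[str, str],
             cell_b: tuple[str, str], label: str | None = None,
             pseudocount: float = 0.5, min_count: int = 10) -> ContrastResult:
    """log2 fold-changes of RNA, Ribo, and TE for cell_b vs cell_a.

    Cells are (strain, condition) pairs; fold-changes are ratios of
    replicate-mean normalized counts (pseudocount-guarded at zero means),
    b over a. A gene
    is measurable when its raw counts summed across replicates reach
    ``min_count`` in each of the four assay x cell combinations.
    """
    if label is None:
        label = f"{cell_b[0]}.{cell_b[1]}-vs-{cell_a[0]}.{cell_a[1]}"
    means = {}
    measurable = pd.Series(True, index=expt.gene_ids)
    for assay in ("RNA", "Ribo"):
        for tag, (strain, condition) in (("a", cell_a), ("b", cell_b)):
            means[assay, tag] = _cell_mean(expt, strain, condition, assay)
            cols = expt.sample_ids(strain=strain, condition=condition,
                                   assay=assay)
            measurable &= expt.counts[cols].sum(axis=1) >= min_count
    log2fc_rna = np.log2(_guarded_ratio(means["RNA", "b"], means["RNA", "a"],
                                        pseudocount))
    log2fc_ribo = np.log2(_guarded_ratio(means["Ribo", "b"],
                                         means["Ribo", "a"], pseudocount))
    table = pd.DataFrame({
        "log2fc_rna": log2fc_rna,
        "log2fc_ribo": log2fc_ribo,
        "log2fc_te": log2fc_ribo - log2fc_rna,
        "measurable": measurable,
    })
    table.loc[~measurable, ["log2fc_rna", "log2fc_ribo", "log2fc_te"]] = np.nan
    return ContrastResult(label=label, cell_a=cell_a, cell_b=cell_b,
                          table=table)


@dataclass
class GeneSet:
    """A direction x assay gene set from one contrast."""

    name: str
    direction: str  # "up" | "down"
    assay: str      # "rna" | "ribo" | "te"
    contrast_label: str
    genes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)


def classify_sets(result: ContrastResult,
                  tau: float = 1.5) -> dict[tuple[str, str], GeneSet]:
    """Up/down gene sets at fold-change threshold tau (boundary inclusive).

    Up: fold-change >= tau; down: fold-change <= 1/tau. Only measurable
    genes are classified. Keys are (assay, direction) pairs.
    """
    if tau <= 1:
        raise ValueError("tau must be > 1")
    cut = np.log2(tau)
    tol = 1e-12  # absorb float round-trip at the exact boundary
    sets: dict[tuple[str, str], GeneSet] = {}
    sub = result.table[result.table["measurable"]]
    for assay in ("rna", "ribo", "te"):
        lfc = sub[f"log2fc_{assay}"]
        for direction, mask in (("up", lfc >= cut - tol),
                                ("down", lfc <= -cut + tol)):
            name = f"{result.label}.{assay}.{direction}"
            sets[assay, direction] = GeneSet(
                name=name, direction=direction, assay=assay,
                contrast_label=result.label,
                genes=sorted(sub.index[mask]))
    return sets


def correlate(result_a: ContrastResult, result_b: ContrastResult,
              field: str = "te") -> tuple[float, int]:
    """Pearson r between two contrasts' log2 fold-changes.

    Computed over genes measurable in both contrasts; returns (r, n).
    """
    from scipy import stats

    col = f"log2fc_{field}"
    common = result_a.measurable_genes.intersection(result_b.measurable_genes)
    if len(common) < 3:
        raise ValueError("need >= 3 genes measurable in both contrasts")
    r = stats.pearsonr(result_a.table.loc[common, col],
                       result_b.table.loc[common, col]).statistic
    return float(r), len(common)
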