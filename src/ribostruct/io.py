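"""Plain-text readers and writers for the pipeline's tabular formats.

All tables are tab-separated. The annotation format stores each
transcript's per-nucleotide score track as a semicolon-delimited float
list (5'->3', 5'UTR then covered CDS). Term maps use the GMT convention:
term, description, then one gene per field.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .polysome import GradientTrace
from .structure import TranscriptModel
from .te import CountExperiment

__all__ = [
    "write_annotation", "read_annotation",
    "write_counts", "read_counts",
    "write_gmt", "read_gmt",
    "write_classes", "read_classes",
    "read_trace",
]


def write_annotation(models: Sequence[TranscriptModel],
                     path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tutr5_len\tcds_len\tscores\n")
        for m in models:
            scores = ";".join(format(s, ".6g") for s in m.scores)
            fh.write(f"{m.gene_id}\t{m.utr5_len}\t{m.cds_len}\t{scores}\n")


def read_annotation(path: str | Path) -> list[TranscriptModel]:
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    models = []
    for row in table.itertuples(index=False):
        scores = np.array([float(s) for s in str(row.scores).split(";")])
        models.append(TranscriptModel(gene_id=row.gene_id,
                                      utr5_len=int(row.utr5_len),
                                      cds_len=int(row.cds_len),
                                      scores=scores))
    return models


def write_counts(expt: CountExperiment, counts_path: str | Path,
                 samples_path: str | Path) -> None:
    expt.counts.to_csv(counts_path, sep="\t")
    expt.samples.reset_index().to_csv(samples_path, sep="\t", index=False)


def read_counts(counts_path: str | Path,
                samples_path: str | Path) -> CountExperiment:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t",
                          dtype={"sample_id": str, "strain": str,
                                 "condition": str, "assay": str})
    return CountExperiment(counts=counts, samples=samples)


def write_gmt(term_map: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term, genes in term_map.items():
            desc = (descriptions or {}).get(term, "na")
            fh.write("\t".join([term, desc, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    term_map: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            term_map[fields[0]] = [g for g in fields[2:] if g]
    return term_map


def write_classes(classes: pd.Series, path: str | Path) -> None:
    classes.rename("class").to_csv(path, sep="\t")


def read_classes(path: str | Path) -> pd.Series:
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return table["class"]


def read_trace(path: str | Path) -> GradientTrace:
    """Two-column TSV (position, a254), with or without a header line."""
    table = pd.read_csv(path, sep="\t", comment="#", header=None)
    if not np.issubdtype(np.asarray(table.iloc[0]).dtype, np.number):
        table = table.iloc[1:].astype(float)
    return GradientTrace(position=table.iloc[:, 0].to_numpy(float),
                         a254=table.iloc[:, 1].to_numpy(float))
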