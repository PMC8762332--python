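"""End-to-end orchestration: simulate or load, analyze, and report.

A run is driven by a :class:`PipelineConfig` (usually loaded from YAML)
that either points at input files (counts + sample sheet + annotation,
optionally a GMT term map and class labels) or contains a simulation
block. The report bundle is a directory of TSV tables plus a JSON
manifest carrying the seed, package versions, and a hash of the
configuration; a rerun with the same configuration and seed is
byte-identical.

Stage order follows the analysis narrative: contrasts and fold-change
sets, cross-contrast correlations and set overlaps, windowed structure
summaries with t statistics, term enrichment, and rank-based
stratification of structure metrics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rsio
from . import setstats
from .simulate import SimulationConfig, generate_annotation, generate_counts
from .structure import (DegenerateVarianceError, TranscriptModel,
                        compare_groups, cumulative_score, feature_table,
                        window_scores)
from .te import CountExperiment, ContrastResult, classify_sets, contrast, \
    correlate, normalize

__all__ = ["PipelineConfig", "Thresholds", "run_pipeline",
           "DEFAULT_CONTRASTS"]

#: (label, cell_a, cell_b): fold-changes are reported for cell_b over cell_a.
DEFAULT_CONTRASTS = (
    ("WT.urea-vs-WT.SD", ("WT", "SD"), ("WT", "urea")),
    ("ntd-del.urea-vs-ntd-del.SD", ("ntd-del", "SD"), ("ntd-del", "urea")),
    ("ntd-del.SD-vs-WT.SD", ("WT", "SD"), ("ntd-del", "SD")),
    ("ntd-del.urea-vs-WT.urea", ("WT", "urea"), ("ntd-del", "urea")),
)


@dataclass
class Thresholds:
    tau: float = 1.5
    pseudocount: float = 0.5
    min_count: int = 10
    fraction: float = 0.30
    q_cutoff: float = 0.05
    normalization: str = "median-of-ratios"

    def validate(self) -> None:
        if self.tau <= 1:
            raise ValueError("tau must be > 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must be in (0, 1)")
        if not 0 < self.q_cutoff <= 1:
            raise ValueError("q_cutoff must be in (0, 1]")


@dataclass
class PipelineConfig:
    """Full run configuration: exactly one of inputs or simulation."""

    outdir: str | Path = "ribostruct_out"
    seed: int = 0
    simulation: dict | None = None
    inputs: dict | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    contrasts: list[tuple[str, tuple[str, str], tuple[str, str]]] = field(
        default_factory=lambda: [tuple(c) for c in DEFAULT_CONTRASTS])

    def validate(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of 'simulation' and 'inputs' must be given")
        self.thresholds.validate()
        if self.inputs is not None:
            for key in ("counts", "samples", "annotation"):
                if key not in self.inputs:
                    raise ValueError(f"inputs block is missing {key!r}")
                if not Path(self.inputs[key]).exists():
                    raise FileNotFoundError(
                        f"input file not found: {self.inputs[key]}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        thresholds = Thresholds(**data.pop("thresholds", {}))
        contrasts = [
            (c["label"], tuple(c["a"]), tuple(c["b"]))
            for c in data.pop("contrasts", [])
        ] or [tuple(c) for c in DEFAULT_CONTRASTS]
        return cls(thresholds=thresholds, contrasts=contrasts, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def canonical(self) -> str:
        # outdir is a run location, not analysis configuration: the same
        # analysis written elsewhere must hash identically
        data = {
            "seed": self.seed,
            "simulation": self.simulation,
            "inputs": {k: str(v) for k, v in self.inputs.items()}
            if self.inputs else None,
            "thresholds": dataclasses.asdict(self.thresholds),
            "contrasts": [[label, list(a), list(b)]
                          for label, a, b in self.contrasts],
        }
        return json.dumps(data, sort_keys=True)


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _load_or_simulate(config: PipelineConfig):
    if config.simulation is not None:
        sim_dict = dict(config.simulation)
        sim_dict["seed"] = config.seed
        sim = SimulationConfig.from_dict(sim_dict)
        annotation = generate_annotation(sim)
        expt, truth = generate_counts(sim, annotation)
        return (annotation.models, annotation.classes, annotation.term_map,
                expt, truth)
    models = rsio.read_annotation(config.inputs["annotation"])
    expt = rsio.read_counts(config.inputs["counts"], config.inputs["samples"])
    term_map = (rsio.read_gmt(config.inputs["terms"])
                if config.inputs.get("terms") else None)
    classes = (rsio.read_classes(config.inputs["classes"])
               if config.inputs.get("classes") else None)
    return models, classes, term_map, expt, None


def _structure_summary(models: list[TranscriptModel],
                       gene_sets: dict[str, list[str]],
                       alpha: float = 0.05) -> pd.DataFrame:
    """feature_table plus t statistics of every set against 'all'."""
    table = feature_table(models, gene_sets)
    by_id = {m.gene_id: m for m in models}

    def _values(set_name: str, feat: str) -> list[float]:
        out = []
        for g in gene_sets[set_name]:
            m = by_id[g]
            if feat == "utr5_len":
                out.append(float(m.utr5_len))
            else:
                out.append(window_scores(m)[feat])
        return [v for v in out if v is not None]

    t_col, p_col, sig_col = [], [], []
    for row in table.itertuples(index=False):
        if row.set == "all":
            t_col.append(np.nan), p_col.append(np.nan), sig_col.append(False)
            continue
        try:
            cmp = compare_groups(_values(row.set, row.feature),
                                 _values("all", row.feature), alpha=alpha)
            t_col.append(cmp.t), p_col.append(cmp.p)
            sig_col.append(cmp.significant)
        except (ValueError, DegenerateVarianceError):
            t_col.append(np.nan), p_col.append(np.nan), sig_col.append(False)
    table["t_vs_all"] = t_col
    table["p_vs_all"] = p_col
    table["significant"] = sig_col
    return table


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns key results."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds

    models, classes, term_map, expt, truth = _load_or_simulate(config)

    if config.simulation is not None:
        rsio.write_annotation(models, outdir / "annotation.tsv")
        rsio.write_counts(expt, outdir / "counts.tsv", outdir / "samples.tsv")
        _write_tsv(truth, outdir / "truth.tsv")
        rsio.write_classes(classes, outdir / "classes.tsv")
        rsio.write_gmt(term_map, outdir / "terms.gmt")

    norm = normalize(expt, method=th.normalization)
    _write_tsv(norm.size_factors.to_frame(), outdir / "size_factors.tsv")

    # --- contrasts and fold-change gene sets -----------------------------
    results: dict[str, ContrastResult] = {}
    all_sets = {}
    for label, cell_a, cell_b in config.contrasts:
        res = contrast(norm, cell_a, cell_b, label=label,
                       pseudocount=th.pseudocount, min_count=th.min_count)
        results[label] = res
        _write_tsv(res.table, outdir / f"contrast_{label}.tsv")
        all_sets[label] = classify_sets(res, tau=th.tau)
    membership = pd.DataFrame(
        [{"set": gs.name, "contrast": gs.contrast_label, "assay": gs.assay,
          "direction": gs.direction, "gene_id": g}
         for sets in all_sets.values() for gs in sets.values()
         for g in gs.genes],
        columns=["set", "contrast", "assay", "direction", "gene_id"])
    _write_tsv(membership, outdir / "gene_sets.tsv", index=False)

    # --- cross-strain response correlations and overlaps -----------------
    corr_rows, overlap_rows = [], []
    if len(config.contrasts) >= 2:
        wt_label, mut_label = config.contrasts[0][0], config.contrasts[1][0]
        for assay in ("rna", "ribo", "te"):
            r, n = correlate(results[wt_label], results[mut_label], assay)
            corr_rows.append({"field": assay, "contrast_a": wt_label,
                              "contrast_b": mut_label, "pearson_r": r,
                              "n": n})
            universe = sorted(
                results[wt_label].measurable_genes.intersection(
                    results[mut_label].measurable_genes))
            set_a = [g for g in all_sets[wt_label][assay, "up"].genes
                     if g in set(universe)]
            set_b = [g for g in all_sets[mut_label][assay, "up"].genes
                     if g in set(universe)]
            ov = setstats.overlap_fisher(set_a, set_b, universe)
            overlap_rows.append({
                "assay": assay, "n_universe": ov.n_universe, "n_a": ov.n_a,
                "n_b": ov.n_b, "n_overlap": ov.n_overlap,
                "pct_of_a": ov.pct_of_a, "pct_of_b": ov.pct_of_b,
                "odds_ratio": ov.odds_ratio,
                "p_two_sided": ov.p_two_sided,
                "p_enrichment": ov.p_enrichment})
    _write_tsv(pd.DataFrame(corr_rows), outdir / "correlations.tsv",
               index=False)
    _write_tsv(pd.DataFrame(overlap_rows), outdir / "overlaps.tsv",
               index=False)

    # --- windowed structure summaries per TE set --------------------------
    known = {m.gene_id for m in models}
    struct_sets: dict[str, list[str]] = {"all": sorted(known)}
    for label, _, _ in config.contrasts[2:4]:
        if label not in all_sets:
            continue
        for direction in ("down", "up"):
            gs = all_sets[label]["te", direction]
            genes = [g for g in gs.genes if g in known]
            if genes:
                struct_sets[gs.name] = genes
    summary = _structure_summary(models, struct_sets)
    _write_tsv(summary, outdir / "window_summaries.tsv", index=False)

    # --- term enrichment --------------------------------------------------
    enrichments: dict[str, pd.DataFrame] = {}
    if term_map:
        for set_name, genes in struct_sets.items():
            if set_name == "all":
                continue
            label = next(lbl for lbl in results if set_name.startswith(lbl))
            universe = sorted(results[label].measurable_genes
                              .intersection(known))
            enr = setstats.enrich_terms(
                [g for g in genes if g in set(universe)], term_map, universe)
            enrichments[set_name] = enr
            _write_tsv(enr, outdir / f"enrichment_{set_name}.tsv",
                       index=False)

    # --- rank stratification on structure metrics -------------------------
    rank_rows = []
    if term_map:
        total5 = {m.gene_id: cumulative_score(m, "total5utr")
                  for m in models}
        lengths = {m.gene_id: float(m.utr5_len) for m in models}
        universe = sorted(g for g, v in total5.items() if v is not None)
        rank_enrich = {}
        for metric_name, metric in (("total5utr", total5),
                                    ("utr5_len", lengths)):
            usable = {g: v for g, v in metric.items()
                      if v is not None and g in set(universe)}
            for side in ("top", "bottom"):
                sel = setstats.rank_select(usable, fraction=th.fraction,
                                           side=side)
                rank_enrich[metric_name, side] = setstats.enrich_terms(
                    sel, term_map, universe)
        for key_a, enr_a in rank_enrich.items():
            for set_name, enr_b in enrichments.items():
                jac, shared = setstats.term_list_overlap(
                    enr_a, enr_b, q_cutoff=th.q_cutoff)
                rank_rows.append({
                    "rank_metric": key_a[0], "side": key_a[1],
                    "te_set": set_name, "jaccard": jac,
                    "shared_terms": ";".join(shared)})
    _write_tsv(pd.DataFrame(rank_rows), outdir / "rank_term_overlap.tsv",
               index=False)

    # --- manifest ---------------------------------------------------------
    import scipy

    from . import __version__
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            config.canonical().encode()).hexdigest(),
        "versions": {"ribostruct": __version__,
                     "numpy": np.__version__,
                     "scipy": scipy.__version__,
                     "pandas": pd.__version__},
        "outputs": sorted(p.name for p in outdir.iterdir()
                          if p.name != "manifest.json"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {"contrasts": results, "gene_sets": all_sets,
            "correlations": pd.DataFrame(corr_rows),
            "overlaps": pd.DataFrame(overlap_rows),
            "window_summaries": summary, "enrichments": enrichments,
            "truth": truth, "outdir": outdir}
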