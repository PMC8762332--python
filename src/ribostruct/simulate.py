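"""Synthetic factorial Ribo-seq/RNA-seq experiments with planted effects.

Emulates a 2 strain (WT, ntd-del) x 2 condition (SD, urea) x 2 assay
(RNA, Ribo) design with two biological replicates per cell — 16 libraries
— over a transcriptome in which each gene belongs to one of two classes:

* ``membrane-like``: longer, more structured 5'UTRs; translationally
  induced by urea in the WT strain;
* ``cytoplasmic-like``: shorter, less structured 5'UTRs; somewhat more
  CDS structure.

Per-nucleotide structure-score tracks (PARS-style, higher = more
double-stranded) cover the 5'UTR plus the first 90 CDS nucleotides. The
planted translational-efficiency model couples the mutant strain's TE to
5'UTR structure: in ``ntd-del``, log2 TE is penalized by
``beta_structure_te`` per standard deviation of cumulative 5'UTR score,
while membrane-like genes gain ``urea_te_boost_membrane_wt`` log2 units of
TE in WT urea samples only. Counts are negative binomial with variance
mu + dispersion * mu^2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import TranscriptModel, cumulative_score
from .te import CountExperiment

__all__ = [
    "CLASSES",
    "MEMBRANE",
    "CYTOPLASMIC",
    "ConfigError",
    "SimulationConfig",
    "Annotation",
    "generate_annotation",
    "generate_counts",
    "simulate_experiment",
]

MEMBRANE = "membrane-like"
CYTOPLASMIC = "cytoplasmic-like"
CLASSES = (MEMBRANE, CYTOPLASMIC)

STRAINS = ("WT", "ntd-del")
CONDITIONS = ("SD", "urea")
ASSAYS = ("RNA", "Ribo")

#: truth-table response columns, named like te.contrast default labels
RESPONSE_CONTRASTS = (
    ("WT.urea-vs-WT.SD", ("WT", "urea"), ("WT", "SD")),
    ("ntd-del.urea-vs-ntd-del.SD", ("ntd-del", "urea"), ("ntd-del", "SD")),
    ("ntd-del.SD-vs-WT.SD", ("ntd-del", "SD"), ("WT", "SD")),
    ("ntd-del.urea-vs-WT.urea", ("ntd-del", "urea"), ("WT", "urea")),
)


class ConfigError(ValueError):
    """A simulation-configuration field is invalid."""


def _default_utr_logmean() -> dict[str, float]:
    # exp() of these are ~90 nt (membrane-like) and ~50 nt (cytoplasmic-like)
    return {MEMBRANE: float(np.log(90.0)), CYTOPLASMIC: float(np.log(50.0))}


def _default_pars_5utr() -> dict[str, float]:
    return {MEMBRANE: 0.35, CYTOPLASMIC: -0.35}


def _default_pars_cds() -> dict[str, float]:
    return {MEMBRANE: 0.0, CYTOPLASMIC: 0.25}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults emulate a desk-scale version of the profiled yeast design:
    4000 measurable genes, two biological replicates per strain x
    condition, ~1e6 counted reads per library, and NB dispersion 0.1.
    """

    n_genes: int = 4000
    replicates: int = 2
    library_size: int = 1_000_000
    nb_dispersion: float = 0.1
    frac_membrane_like: float = 0.3
    utr_len_logmean_by_class: dict[str, float] = field(
        default_factory=_default_utr_logmean)
    utr_len_logsd: float = 0.6
    pars_mean_5utr_by_class: dict[str, float] = field(
        default_factory=_default_pars_5utr)
    pars_mean_cds_by_class: dict[str, float] = field(
        default_factory=_default_pars_cds)
    pars_sd: float = 1.0
    cds_len: int = 300
    covered_cds: int = 90
    abundance_logsd: float = 1.0
    te_log2_sd: float = 0.35
    beta_structure_te: float = 0.4
    urea_te_boost_membrane_wt: float = 1.0
    n_decoy_terms: int = 8
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "replicates", "library_size",
                     "nb_dispersion", "utr_len_logsd", "pars_sd",
                     "cds_len", "covered_cds"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not 0.0 <= self.frac_membrane_like <= 1.0:
            raise ConfigError("frac_membrane_like must be in [0, 1]")
        if self.cds_len < 90:
            raise ConfigError("cds_len must be >= 90")
        if self.covered_cds > self.cds_len:
            raise ConfigError("covered_cds must be <= cds_len")
        for name in ("utr_len_logmean_by_class", "pars_mean_5utr_by_class",
                     "pars_mean_cds_by_class"):
            mapping = getattr(self, name)
            if set(mapping) != set(CLASSES):
                raise ConfigError(f"{name} must give a value per class "
                                  f"{CLASSES}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(data) - known
        if stray:
            raise ConfigError(f"unknown simulation fields: {sorted(stray)}")
        return cls(**data)


@dataclass
class Annotation:
    """Generated transcript models, class labels, and a class term map."""

    models: list[TranscriptModel]
    classes: pd.Series  # gene_id -> class label
    term_map: dict[str, list[str]]  # class terms + random decoy terms

    def __len__(self) -> int:
        return len(self.models)

    @property
    def gene_ids(self) -> list[str]:
        return [m.gene_id for m in self.models]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, order-insensitive streams per stage
    return np.random.default_rng([config.seed, stream])


def generate_annotation(config: SimulationConfig) -> Annotation:
    """Draw transcript models with class-dependent 5'UTRs and score tracks.

    5'UTR lengths are log-normal by class (rounded, floor 1 nt); the CDS
    length is fixed; per-nucleotide scores are normal with class-specific
    means for 5'UTR versus CDS positions. The term map contains the two
    class terms plus random decoy terms.
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_genes
    width = len(str(n))
    gene_ids = [f"g{str(i).zfill(width)}" for i in range(1, n + 1)]
    is_membrane = rng.random(n) < config.frac_membrane_like
    classes = pd.Series(np.where(is_membrane, MEMBRANE, CYTOPLASMIC),
                        index=pd.Index(gene_ids, name="gene_id"),
                        name="class")
    mu = classes.map(config.utr_len_logmean_by_class).to_numpy(float)
    utr_lens = np.maximum(
        1, np.rint(np.exp(rng.normal(mu, config.utr_len_logsd)))).astype(int)
    covered = min(config.covered_cds, config.cds_len)
    models = []
    for gid, cls, utr_len in zip(gene_ids, classes, utr_lens):
        utr_scores = rng.normal(config.pars_mean_5utr_by_class[cls],
                                config.pars_sd, size=int(utr_len))
        cds_scores = rng.normal(config.pars_mean_cds_by_class[cls],
                                config.pars_sd, size=covered)
        models.append(TranscriptModel(
            gene_id=gid, utr5_len=int(utr_len), cds_len=config.cds_len,
            scores=np.concatenate([utr_scores, cds_scores])))
    term_map = {
        MEMBRANE: sorted(classes.index[classes == MEMBRANE]),
        CYTOPLASMIC: sorted(classes.index[classes == CYTOPLASMIC]),
    }
    for i in range(config.n_decoy_terms):
        size = int(rng.integers(max(2, n // 20), max(3, n // 5)))
        members = rng.choice(gene_ids, size=size, replace=False)
        term_map[f"decoy{i + 1:02d}"] = sorted(members)
    return Annotation(models=models, classes=classes, term_map=term_map)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    # NB with variance mean + dispersion * mean^2
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_counts(
        config: SimulationConfig,
        annotation: Annotation) -> tuple[CountExperiment, pd.DataFrame]:
    """Simulate the 16-library factorial experiment and its truth table.

    RNA counts are NB around abundance x library_size; Ribo counts are NB
    around the RNA mean times the cell's true TE. The truth table records
    each gene's class, true TE per strain x condition, and true log2 TE
    response for the four standard contrasts.
    """
    config.validate()
    if len(annotation) != config.n_genes:
        raise ValueError(
            f"annotation has {len(annotation)} genes but config.n_genes is "
            f"{config.n_genes}")
    rng = _rng(config, 1)
    n = config.n_genes
    gene_ids = annotation.gene_ids

    abundance = np.exp(rng.normal(0.0, config.abundance_logsd, size=n))
    rel_abundance = abundance / abundance.sum()

    utr_score = np.array([cumulative_score(m, "total5utr") or 0.0
                          for m in annotation.models])
    sd = utr_score.std()
    z_struct = (utr_score - utr_score.mean()) / sd if sd > 0 else \
        np.zeros(n)
    is_membrane = (annotation.classes == MEMBRANE).to_numpy()

    base_log2_te = rng.normal(0.0, config.te_log2_sd, size=n)
    log2_te = {}
    for strain in STRAINS:
        for condition in CONDITIONS:
            te = base_log2_te.copy()
            if strain == "ntd-del":
                te = te - config.beta_structure_te * z_struct
            if strain == "WT" and condition == "urea":
                te = te + config.urea_te_boost_membrane_wt * is_membrane
            log2_te[strain, condition] = te

    columns, rows = {}, []
    for strain in STRAINS:
        for condition in CONDITIONS:
            rna_mean = rel_abundance * config.library_size
            ribo_mean = rna_mean * 2.0 ** log2_te[strain, condition]
            for assay in ASSAYS:
                mean = rna_mean if assay == "RNA" else ribo_mean
                for rep in range(1, config.replicates + 1):
                    sample_id = f"{strain}_{condition}_{assay}_{rep}"
                    columns[sample_id] = _nb_draw(rng, mean,
                                                  config.nb_dispersion)
                    rows.append({"sample_id": sample_id, "strain": strain,
                                 "condition": condition, "assay": assay,
                                 "replicate": rep})
    counts = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    samples = pd.DataFrame(rows)
    expt = CountExperiment(counts=counts, samples=samples)

    truth = pd.DataFrame({"class": annotation.classes},
                         index=counts.index)
    for (strain, condition), te in log2_te.items():
        truth[f"te_{strain}_{condition}"] = 2.0 ** te
    for label, cell_b, cell_a in RESPONSE_CONTRASTS:
        truth[f"response_{label}"] = (log2_te[cell_b] - log2_te[cell_a])
    return expt, truth


def simulate_experiment(
        config: SimulationConfig
) -> tuple[Annotation, CountExperiment, pd.DataFrame]:
    """Convenience wrapper: annotation plus counts plus truth table."""
    annotation = generate_annotation(config)
    expt, truth = generate_counts(config, annotation)
    return annotation, expt, truth
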