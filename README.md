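# ribostruct

Analysis toolkit for asking how 5′UTR secondary structure shapes
translational efficiency, built around paired ribosome-profiling
(Ribo-seq) and RNA-seq experiments in a factorial strain × condition
design — the kind of study used to dissect translation-initiation factors
such as eIF4B, whose 40S-binding activity preferentially supports
translation of mRNAs with long, structured 5′UTRs.

It is aimed at computational biologists who have per-gene count matrices
(not reads) and want a reproducible, scriptable path from counts to the
standard readouts of such a study:

- **Translational efficiency (TE).** For each gene, TE = normalized
  Ribo-seq signal / normalized RNA-seq signal. Counts are normalized by
  median-of-ratios size factors (the DESeq convention) or CPM. A contrast
  between two strain × condition cells reports per-gene
  log₂FC(RNA), log₂FC(Ribo), and log₂FC(TE) = log₂FC(Ribo) − log₂FC(RNA),
  and classifies genes into up/down sets at a fold-change threshold
  τ (default 1.5, boundary inclusive).
- **5′UTR structure windows.** Per-nucleotide structure-propensity scores
  (PARS-style: higher = more double-stranded) are summed over named
  windows anchored on the start codon: the whole 5′UTR, the first 30 nt
  from the cap, 30 nt surrounding the start codon, and the CDS windows
  +1..+30, +16..+45, +31..+60, +46..+75, +61..+90. Windows that do not
  fully fit a transcript are missing, never truncated. Gene sets are
  compared with the unpaired Student *t* test.
- **Set statistics.** Fisher's exact test for set overlaps (two-sided by
  minimum-likelihood summation, computed with exact integer arithmetic),
  upper-tail hypergeometric term enrichment against GMT maps with
  Benjamini–Hochberg correction, and top/bottom-fraction rank
  stratification with term-list Jaccard comparison.
- **Polysome profiles.** Polysome:monosome (P:M) ratios by trapezoidal
  area under baseline-subtracted A254 traces over operator-chosen peak
  intervals, and percent-of-total protein distributions across gradient
  fractions.
- **Synthetic experiments.** A seeded generator emulating the full
  16-library design (2 strains × 2 conditions × 2 assays × 2 replicates)
  with negative-binomial counts and *planted* effects: a membrane-like
  gene class with longer, more structured 5′UTRs that is translationally
  induced by the stress condition in the wild type, and a mutant strain
  whose log₂ TE is penalized in proportion to standardized 5′UTR
  structure. The generator writes a truth table, class labels, and a GMT
  term map, so every downstream statistic can be validated against known
  ground truth.

## Worked example

```python
from ribostruct import (SimulationConfig, simulate_experiment, normalize,
                        contrast, classify_sets, correlate, overlap_fisher,
                        cumulative_score, compare_groups)

cfg = SimulationConfig(n_genes=2000, seed=42)
ann, expt, truth = simulate_experiment(cfg)
norm = normalize(expt)

wt = contrast(norm, ("WT", "SD"), ("WT", "urea"))
mut = contrast(norm, ("ntd-del", "SD"), ("ntd-del", "urea"))
r, n = correlate(wt, mut, "te")
print(f"TE urea-response correlation (WT vs mutant): r = {r:.3f}, n = {n}")

strain = contrast(norm, ("WT", "urea"), ("ntd-del", "urea"))
down = classify_sets(strain, tau=1.5)["te", "down"].genes
print(f"genes with >=1.5-fold decreased TE in the mutant (urea): {len(down)}")

scores = {m.gene_id: cumulative_score(m, "total5utr") for m in ann.models}
cmp = compare_groups([scores[g] for g in down], list(scores.values()))
print(f"mean total-5'UTR score, down set vs transcriptome: "
      f"{cmp.mean_a:.1f} vs {cmp.mean_b:.1f} (t = {cmp.t:.1f}, p = {cmp.p:.2e})")
```

prints

```
TE urea-response correlation (WT vs mutant): r = 0.015, n = 1999
genes with >=1.5-fold decreased TE in the mutant (urea): 605
mean total-5'UTR score, down set vs transcriptome: 30.4 vs -3.5 (t = 21.1, p = 2.51e-91)
```

Read: the wild-type and mutant urea responses are uncorrelated at the TE
level (the two strains reprogram translation differently), 605 genes lose
≥1.5-fold TE when the mutant faces urea, and that set carries far more
5′UTR structure than the transcriptome average — the generator's planted
structure dependence, recovered from counts alone.

## Command line

```sh
ribostruct simulate --seed 7 --n-genes 4000 --outdir sim/
ribostruct run --config config.yaml
ribostruct polysome --trace trace.tsv --mono 1 5 --poly 5 9
```

`ribostruct run` drives the whole pipeline from a YAML file, e.g.

```yaml
seed: 7
outdir: out
simulation:          # or an `inputs:` block with counts/samples/annotation
  n_genes: 4000
thresholds:
  tau: 1.5
  fraction: 0.30
```

and writes contrast tables, gene-set memberships, overlap and correlation
tables, window-score group summaries with *t* statistics, enrichment
tables, rank-stratification term overlaps, and a `manifest.json` with the
seed, versions, and configuration hash. A rerun with the same
configuration and seed is byte-identical.

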