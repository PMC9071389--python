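# bricdecay

Genome-wide RNA half-life estimation from BRIC-seq chase time courses, with
a ground-truth simulator and the comparative analyses used to study how RNA
stability shapes gene expression.

## The problem

BRIC-seq measures physiological RNA decay without blocking transcription:
all RNA is labeled with 5-bromouridine (BrU), the label is washed out, and
the labeled fraction is immunoprecipitated and sequenced at chase time
points (here 0, 1, 2, 4, 8, 12 and 16 h). Under first-order decay the
labeled abundance of gene *g* follows

    y_g(t) = a_g · exp(−b_g · t),        t½ = ln 2 / b_g

Estimating *b_g* from counts is complicated by three things this package
handles explicitly: lowly expressed genes and noisy low-count tails must be
filtered and masked; library composition drifts toward stable transcripts at
late time points; and labeling/pull-down chemistry introduces per-time-point
multiplicative distortions. The pipeline estimates per-time-point correction
factors from genes observed at all time points (fit each to an exponential,
collect predicted/observed coefficients, average per time point, iterate),
applies them, fits every gene by least squares, caps very stable transcripts
(t½ > 16 h or a non-positive rate) at 16 h, and averages replicates.

Around the core pipeline the package provides, as separate modules:

- `simdata` — a seeded simulator of BRIC-seq time courses with log-normal
  true half-lives, negative-binomial-like counts, injected distortions,
  paired perturbation conditions with coupled transcription/stability
  changes, paired ribo-seq/RNA-seq tables, tissue matrices and a minimal GTF.
- `annotation` — GTF parsing, union exon/CDS lengths, chromosome groups
  (X; autosomes = 2L+2R+3L+3R; chromosome 4 kept separate), housekeeping
  classification (expression > 6 in all 12 tissues).
- `normalize` — cpm, TPM, TMM factors (verified against edgeR), GeTMM,
  the > 0.2 GeTMM expressed threshold, and a median-of-ratios log2
  fold-change.
- `riboseq` — ribosome density as the ribo-seq/RNA-seq TPM ratio over union
  CDS length, with the standard coverage filters.
- `stats_compare` — equal-count binning, means with 95% confidence
  intervals, Mann–Whitney tests, sorted differential-stability curves, log2
  half-life ratio tables, and the differential-stability versus
  differential-expression analysis (gene-level Spearman coupling).

## Worked example

```python
import numpy as np
from scipy import stats
from bricdecay import (SimConfig, simulate_truth, simulate_bric_counts,
                       compute_half_lives)

config = SimConfig(n_genes=2000, depth_per_timepoint=2e6, dispersion=0.05,
                   distortion=(1, 1, 1, 0.9, 1.1, 0.8, 1.2), seed=0)
truth = simulate_truth(config)
counts = simulate_bric_counts(truth, config)
table, report = compute_half_lives(counts)

stage = report["conditions"]["S2"]["1"]
print(f"genes in: {stage['genes_in']}, kept: {stage['kept_after_filter']}, "
      f"fitted: {stage['fitted']}, capped at 16 h: {stage['capped16']}")
print("norm factors (rep 1):", np.round(stage["norm_factors"], 3))

est = table.set_index("gene_id")["half_life_h"]
true = truth.set_index("gene_id")["true_halflife_h"].loc[est.index]
rho = stats.spearmanr(true, est).statistic
rel = (est - true.clip(upper=16)).abs() / true.clip(upper=16)
print(f"merged half-lives: {len(est)}, median {est.median():.2f} h")
print(f"Spearman(true, estimated) = {rho:.3f}, "
      f"median relative error = {100 * rel.median():.1f}%")
```

prints

```
genes in: 2000, kept: 2000, fitted: 1919, capped at 16 h: 76
norm factors (rep 1): [1.008 0.995 0.973 1.058 0.861 1.159 0.765]
merged half-lives: 2000, median 3.76 h
Spearman(true, estimated) = 0.970, median relative error = 12.5%
```

The normalization factors move opposite to the injected distortion
(0.9, 1.1, 0.8, 1.2 at 4–16 h), the estimated ranking tracks the truth
(ρ = 0.97), and very stable transcripts pile up at the 16 h cap. The median
relative error of ~12% reflects the variance of the unweighted
exponential fit under 5% overdispersion — see `docs/methods.md` for why
this, and not normalization, is the accuracy floor.

The same pipeline is available from the shell:

```sh
bricdecay simulate --n-genes 2000 --seed 0 --out run/
bricdecay halflife --counts run/counts.tsv --out run/hl/
bricdecay analyze --halflife-a a.tsv --halflife-b b.tsv --counts run/counts.tsv --out run/cmp/
```

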