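# chromcouple

Integrative ChIP-seq/RNA-seq analysis of promoter H3K27me3 demethylation
and its coupling to gene expression.

When the catalytic fragment of the H3K27 demethylase JMJD3 (KDM6B) is
induced in pluripotent cells — e.g. with a Tet-On system, so that +Dox is
the demethylase-expressing condition and −Dox the control — repressive
H3K27me3 is erased specifically at promoters, and a subset of the affected
genes (many of them bivalent developmental genes) is transcriptionally
upregulated. `chromcouple` implements the computational side of that kind
of experiment as a tested, reusable pipeline:

- **Promoter occupancy.** Coverage tracks (bedGraph) are depth-normalized
  to a common library size and summarized per gene as the mean density
  over TSS ± 3 kb.
- **Chromatin-state classification.** In the uninduced condition a
  promoter is *Bivalent* when both H3K4me3 and H3K27me3 occupancy exceed a
  threshold (default 20, strict inequality), *K4me3*/*K27me3* when only
  one does, *NoMark* otherwise.
- **Demethylation calls.** Per promoter, FC = (occ₊ + ε)/(occ₋ + ε) for
  H3K27me3; a promoter is demethylated below 0.5 (strict) or 0.66
  (relaxed).
- **Expression filters.** Differential genes by fold change > 2 with an
  FPKM > 4 floor on the larger condition mean; a replicate-aware variant
  (fold change plus a two-sample z > 4 on log₂ FPKM) for cross-cell-type
  comparisons.
- **Coupling statistics.** A rank plot — all genes sorted by H3K27me3
  log₂ fold change, expression log₂ fold change averaged in a sliding
  window of 1000 genes — and the PAGE gene-set statistic

  z = (S̄ₘ − μ)·√m / σ,

  where S̄ₘ is the mean expression log₂ fold change over the m
  demethylated genes and μ, σ are the mean and standard deviation over
  all genes; p-values come from the standard normal tail.
- **Metagene profiles.** Gene-body-scaled average coverage from 3 kb
  upstream of the TSS to 3 kb downstream of the TES, normalized to the
  average density over [TES, TES + 6 kb].
- **Synthetic data.** A generator that plants chromatin states,
  demethylation events, and demethylation-coupled expression shifts with
  known ground truth, so every stage of the pipeline is verifiable at
  desk scale.

## Worked example

Run the whole pipeline on a simulated dataset (400 genes, 30% bivalent,
40% of bivalent promoters demethylated, +1 log₂ planted expression shift
for demethylated genes):

```sh
chromcouple run --simulate --outdir demo --seed 1
```

```
chromcouple pipeline summary
===========================

Promoter chromatin states (uninduced condition): K4me3=125, K27me3=89, Bivalent=116, NoMark=70
Of the 116 bivalent genes, 43 (37%) promoters were H3K27me3-demethylated (fold change < 0.5); at the relaxed threshold (fold change < 0.66) the number increased (43 genes, 37%).
Differential expression (+Dox/-Dox, FC > 2, FPKM > 4): 26 up, 0 down, 26 total.
PAGE (demethylated set vs expression log2FC): z = 14.37, p = 7.455e-47 (two-sided).
Recovery vs planted truth: state accuracy 1.000, demethylation sensitivity 1.000 / specificity 1.000, recovered delta 1.055.
```

Reading the output: 116 of 400 promoters are called bivalent and 43 of
them (37%) lose more than half their H3K27me3 after induction — close to
the planted 30% × 40% plan. The demethylated genes carry a mean expression
shift of ~1 log₂ unit (recovered delta 1.055 vs the planted 1.0), and the
PAGE z of 14.4 says that shift is far beyond what a random 43-gene set
would show. The `demo/` directory holds the per-stage tables
(`promoter_signal.tsv`, `calls.tsv`, `de.tsv`, `rankplot.tsv`, `page.txt`)
plus the simulated inputs themselves (`demo/simulated_inputs/`), which can
be fed back through the file-based subcommands (`promoter-signal`,
`classify`, `de`, `rankplot`, `page`).

The same stages are available as a library:

```python
from chromcouple import (SimParams, simulate_dataset, normalize_library,
                         promoter_signal_table, make_calls,
                         differential_genes, coupling_report)

bundle = simulate_dataset(SimParams(seed=1))
tracks = {k: normalize_library(t) for k, t in bundle.tracks.items()}
signal = promoter_signal_table(tracks, bundle.genes)
calls = make_calls(signal["H3K4me3_minus_dox"],
                   signal["H3K27me3_minus_dox"],
                   signal["H3K27me3_plus_dox"])
de = differential_genes(bundle.expression, "minus_dox", "plus_dox")
report = coupling_report(calls, de, window_size=100)
print(report.page_demethylated_set.z)   # 14.37...
```

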