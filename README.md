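# svccf

Cancer cell fraction (CCF) inference and subclonal clustering of **structural
variant (SV) breakpoints** from tumour whole-genome sequencing.

Tumours are mixtures of cell populations. For point mutations, estimating the
fraction of cancer cells carrying a variant from its allele frequency is
routine; for structural variants it is not, because reads at a rearrangement
junction are split across two breakends, duplications inflate the
reference-supporting read count, and the background copy number may itself be
subclonal. `svccf` addresses this end to end: it classifies and counts reads
at both breakends of each SV, corrects allele frequencies for purity, ploidy
and copy number, and clusters SVs into clonal and subclonal populations with
a Bayesian mixture model fitted by variational inference. It is aimed at
cancer-genomics analysts who have SV calls (VCF breakend records or breakend
pair tables), a coordinate-sorted BAM, and optionally an allele-specific
copy-number segmentation (Battenberg / ASCAT / consensus-style tables).

## The model

Each SV *j* contributes supporting read counts at its two breakends
*i* ∈ {1, 2}: `b_ij` supporting reads (split + spanning) out of depth
`d_ij = b_ij + o_ij`. Conditional on the CCF φ_k of the cluster the SV
belongs to, the ends are independently binomial,

    b_ij | d_ij ~ Binomial(d_ij, f_ijk),      f_ijk = w_ij φ_k + ε,

with the CCF-to-VAF weight determined by tumour purity *t*, the multiplicity
m_ij (mutated copies, estimated over a finite candidate set Ξ derived from
the background copy number) and the total tumour/normal copy numbers:

    w_ij = t (m_ij (1 − ε) − n_tot_t ε) / ((1 − t) n_tot_n + t n_tot_t).

Both breakends share one cluster assignment z_j. The posterior over cluster
CCFs (Gaussian prior), mixing weights (Dirichlet prior) and assignments is
approximated by coordinate-ascent variational inference; the number of
clusters is chosen by best evidence lower bound (ELBO) over K = 1..6 with 5
restarts, followed by quality control (drop empty clusters, drop clusters
under 1% of the data, merge clusters whose means are within 0.10).
Duplication-class SVs have their normal read counts scaled by
`AF_norm = 1 − t/n_p` before VAF computation. Per-variant CCFs are
`min(2, (VAF − ε)/w)`; variants with CCF < 0.7 are called subclonal.

## Worked example

Simulate a two-clone tumour (50 SVs fully clonal, 50 at CCF 0.4, purity
0.75, 100× depth) and recover its structure:

```python
from svccf import (SimConfig, simulate_counts, BreakpointMixture,
                   ModelConfig, annotations_from_dataset)

cfg = SimConfig(n_sv=(50, 50), clone_ccfs=(1.0, 0.4), purity=0.75,
                depth=100, seed=7)
dataset, truth = simulate_counts(cfg)
cn_lo, cn_hi = annotations_from_dataset(dataset)
model = BreakpointMixture(dataset, cfg.meta(), cn_lo=cn_lo, cn_hi=cn_hi,
                          config=ModelConfig(seed=7))
results = model.fit()
print(results.summary())
```

```
Dual-breakend binomial mixture fit
==========================================
variants: 100    purity: 0.75
clusters (post-QC): 2    ELBO: -649.524

 cluster   mean CCF       sd   weight      n
       0     0.3966   0.0096   0.5000     50
       1     0.9926   0.0129   0.5000     50
```

The fit recovers both populations: a clonal cluster at CCF ≈ 0.99 and a
subclonal cluster at ≈ 0.40, each holding its 50 SVs; the posterior standard
deviations (~0.01) reflect the binomial noise at this depth.
`results.variant_ccfs()` gives per-variant CCFs, cluster assignments and
multiplicities; `results.post_assign(...)` assigns further variants (e.g.
SNVs, or SVs that were filtered out) to these clusters with the cluster CCFs
frozen.

The same pipeline is available from the shell:

```sh
svccf simulate --config sim.yaml --out sim/
svccf cluster  --filtered sim/dataset.tsv --purity 0.75 --seed 7 --out run/
svccf stats    --run run/ --out stats.tsv
```

with `annotate`, `count`, `filter`, `postassign` and `evaluate` subcommands
covering BAM-backed read counting and benchmarking against a truth table.

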