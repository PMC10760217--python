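# expressbn

Bayesian-network analysis of case/control brain expression data with a
binary risk-genotype covariate.

## The problem

In late-onset Alzheimer's disease (LOAD) cohorts, the APOE E4 haplotype is
the dominant genetic risk factor, and the question of interest is which
transcripts act *with* or *against* that risk: which expression changes sit
directly next to the diagnosis in the dependency structure, and which only
look associated because they are downstream of something else.  Ordinary
differential expression and co-expression networks cannot separate direct
from transitive dependencies; a Bayesian network (BN) over discretized
expression plus the genotype can.

`expressbn` implements that analysis as a tested, reusable pipeline for
datasets shaped like the two brain-bank cohorts it was designed around
(a few hundred post-mortem samples, a binary diagnosis `DX`, a binary
carrier status `APOE_Genetic`, and thousands of covariate-adjusted
transcript measurements):

1. **Maximum-entropy discretization** — each transcript is cut into k = 3
   ordered bins (low / medium / high) by the tie-respecting contiguous
   partition maximizing the Shannon entropy of bin occupancy
   (equal-frequency for tie-free data).
2. **Mixed mutual information (MMI) ranking** — plug-in mutual information
   I(g; DX) in bits on the shared multinomial coding; the top k = 2000
   transcripts (plus the phenotype nodes) go forward.  The empirical MMI
   CDF places any named hit by explanatory weight.
3. **Hybrid structure learning** — a pairwise G-test at α = 0.01 prunes
   the search space to a candidate skeleton; greedy hill climbing over
   add/delete/reverse with 20 shuffled restarts minimizes the decomposable
   MDL score
   `Σ_{j,k} −N_jk log2(N_jk/N_j·) + (log2 N)/2 · q (r − 1)` (bits).
   Each retained edge carries a strength: the MDL improvement it
   contributes given the child's other parents.
4. **Markov views of DX** — the Markov neighborhood (adjacent nodes with
   edge strengths) and Markov blanket (parents ∪ children ∪ co-parents),
   plus undirected dependency-path tracing for hits that act through
   intermediates.
5. **CPT risk statistics** — two-level conditional probability trees
   P(DX=1 | APOE_Genetic, transcript bin) with raw counts, and
   high-vs-low odds ratios with Wald 95% CIs.
6. **Cross-cohort similarity** — Jaccard overlap of the two cohorts'
   MMI-thresholded transcript sets as a function of percentile cutoff,
   with exact hypergeometric tail p-values.
7. **Synthetic cohorts** — a generator planting known structure
   (genotype→DX logistic link calibrated to printed cohort margins,
   Gaussian class-shift signal transcripts, transcript chains, null
   transcripts) with ground truth for recovery testing.

## Worked example

```python
import expressbn as xbn
from expressbn.pipeline import PipelineConfig

cfg = xbn.kronos_like(seed=42, n_transcripts=200)   # 475 samples, 3 planted hits
ds, truth = xbn.generate(cfg)
res = xbn.run_pipeline(PipelineConfig(label="kronos-like", seed=42),
                       "demo_run", dataset=ds)
print(sorted(res.view.blanket))
print({k: round(v, 2) for k, v in sorted(res.view.neighborhood.items())})
```

prints

```
['APOE_Genetic', 'SIG_DX1', 'SIG_DX2', 'SIG_DX3', 'T0050']
{'APOE_Genetic': 65.72, 'SIG_DX1': 114.11, 'SIG_DX2': 112.86, 'SIG_DX3': 115.55, 'T0050': 2.16}
```

The learned blanket of `DX` contains the genotype and all three planted
hits; the genotype edge carries 65.7 bits of explanatory weight and each
planted transcript ~114 bits.  `T0050` is a null transcript that slipped
in with a borderline 2.2-bit edge — exactly the kind of weak edge the CPT
stage is there to scrutinize.  The chain transcript `SIG_CHAIN` is
correctly *absent* from the neighborhood but remains reachable:

```python
xbn.dependency_path(res.network, "DX", "SIG_CHAIN")
# ['DX', 'SIG_DX1', 'SIG_CHAIN']
```

The run directory holds `ranking.tsv`, `network.graphml`,
`markov_blanket.json`, one `cpt_<transcript>.json` per neighborhood hit
and a `manifest.json` with every hyper-parameter and seed.  The CPT for
the top hit stratifies risk exactly by counts; among carriers
(`APOE_Genetic = 1`, 200 samples) the case probability climbs from 0.31
in the low bin to 0.91 in the high bin, a high-vs-low odds ratio of 23.8
(95% CI 9.1–62.2).

The same analysis is available from the shell:

```bash
expressbn simulate --preset kronos-like --seed 42 --out sim/
expressbn run --expression sim/expression.tsv --phenotypes sim/phenotypes.tsv \
              --seed 42 --out demo_run/
expressbn run-split --expression sim/expression.tsv --phenotypes sim/phenotypes.tsv \
              --seed 42 --out split_run/        # carriers / non-carriers separately
```

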