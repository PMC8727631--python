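# sescope

Super-enhancer landscapes and their downstream statistics, as one tested
pipeline.

Cancer-subtype studies of regulatory chromatin repeatedly run the same
computational chain: call H3K27ac enrichment regions from binned ChIP
signal, drop promoters, separate **super-enhancers** (SEs) from typical
enhancers at the inflection of the ranked size curve, ask which SEs are
specific to one subtype (here: triple-negative breast cancer, TNBC,
versus non-TNBC), pair those SEs with subtype-upregulated genes within an
upstream window, and then quantify the consequences — stem-cell frequency
from limiting-dilution xenografts, survival separation at an optimally
selected expression cutpoint, and multivariate Cox regression. `sescope`
implements that chain end to end for analysts who want each step to be an
inspectable, unit-tested function rather than a stack of web tools, and
ships a synthetic-data generator with planted ground truth so the whole
pipeline can be validated without any controlled-access download.

## The models in brief

* **Segmentation** — bins of counts are binarized against a Poisson
  background (call bin enriched iff P(X ≥ c | Poisson(λ_bg)) ≤ 1e-4) and
  segmented by a two-state Bernoulli-emission HMM fitted with Baum–Welch;
  Viterbi runs of the enriched state become regions.
* **SE call** — enhancers ranked ascending by size, both axes rescaled to
  [0, 1], LOESS fitted; the cutoff is the fitted value where the curve
  first reaches slope 1, and every enhancer at or above it is a
  super-enhancer (the "hockey stick" construction).
* **Pairing** — an SE locus (merged across tracks at ≥ 50% reciprocal
  overlap, called super in ≥ 2 TNBC tracks and 0 non-TNBC tracks) is
  paired with gene *g* iff *g* is upregulated (log2FC > 0.5,
  Benjamini–Hochberg p < 0.05, moderated t) and the locus lies ≤ 500 kb
  strand-aware upstream of *g*'s TSS.
* **Limiting dilution** — single-hit model P(positive) = 1 − e^(−f·dose);
  maximum-likelihood f with Wald CI on log f; likelihood-ratio comparison
  between groups.
* **Survival** — Kaplan–Meier, one/two-sided log-rank, maximally selected
  log-rank cutpoint with a permutation p-value that accounts for the
  selection, and Newton–Raphson Cox regression (Breslow ties).

Details, defaults and design rationale: [docs/methods.md](docs/methods.md).

## Worked example

Generate a synthetic study (six tracks, planted enhancer landscape with
3 TNBC-specific super-enhancers and their target genes) and run the full
pipeline:

```bash
sescope simulate --outdir bundle --seed 42
sescope run-all --config pipeline.yaml     # paths to the bundle + seed 42
```

which prints the per-stage counts:

```json
{
  "enrichment_regions":     {"TNBC_1": 99, "TNBC_2": 100, "...": "..."},
  "enhancers_after_promoter_filter": {"TNBC_1": 94, "...": "..."},
  "super_enhancers":        {"TNBC_1": 5, "TNBC_2": 7, "...": "..."},
  "subtype_specific_ses": 3,
  "upregulated_genes": 3,
  "se_gene_pairs": 3
}
```

`run/pairs.tsv` then holds exactly the planted SE → gene pairs, e.g.

```
se_id   gene_id   distance
SE1     TARGET_1  51128
SE2     TARGET_2  52672
SE3     TARGET_3  61079
```

each distance being the strand-aware upstream gap in bp from the gene's
TSS to the nearest SE edge. The stemness and survival readouts of the
same bundle:

```bash
$ sescope lda --table bundle/lda.tsv
control: 1/3524 (95% CI 1/7639 - 1/1625)
knockout: 1/17341 (95% CI 1/69503 - 1/4327)
LRT chi2 = 4.757, p = 2.918e-02

$ sescope survival --table bundle/survival.tsv --perm 2000 --seed 42 --covariates age,grade
optimal cutpoint 5.344 (max statistic 5.414, permutation p 0.0004998)
Cox marker_high: HR 2.346 (95% CI 1.752-3.142)
Cox age: HR 1.009 (95% CI 0.995-1.023)
Cox grade: HR 0.973 (95% CI 0.823-1.149)
```

Read: the tumour-initiating cell frequency drops from ~1 in 3,500 cells
to ~1 in 17,000 on knockout (the bundle plants 1/2000 vs 1/20000; 18
injections per group give wide CIs, and the likelihood-ratio test still
separates the groups at p < 0.05). The survival table plants a hazard
step of e^0.7 ≈ 2 above a marker cutpoint of 5.35: the maximally selected
statistic recovers the cutpoint at 5.344 and the marker-high indicator
carries an adjusted hazard ratio of 2.35.

The same operations are available as library calls
(`sescope.fit_hmm`, `sescope.call_super_enhancers`, `sescope.fit_lda`,
`sescope.maxstat_cutpoint`, ...); the CLI is a thin wrapper.

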