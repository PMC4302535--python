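# riploop

RIP-seq comparative analysis for closed-loop translation complexes: paired
IP/Total enrichment testing, pairwise bait contrasts, binding-group
clustering, stoichiometric decomposition of a hub protein's binding profile,
and gene-set / covariate statistics over the resulting transcript groups.

## The scientific problem

RNA immunoprecipitation sequencing (RIP-seq) measures which transcripts
co-purify with a tagged RNA-binding protein ("bait").  In the motivating
system — the yeast closed-loop translation initiation complex — six baits are
profiled: the cap binder eIF4E, the scaffold isoforms eIF4G1/eIF4G2, the
poly(A) binder Pab1, and the translational repressors (4E-BPs) Caf20 and
Eap1.  Each bait is assayed in replicated pairs of an immunoprecipitate (IP)
library and a matched total-RNA (Total) library.  The questions are: which
transcripts does each bait enrich or avoid, do two baits bind the same
transcripts, which co-binding groups exist transcriptome-wide, and can the
hub protein's binding profile be explained as a weighted sum of its binding
partners' profiles — with the transcripts that escape that model pointing to
dedicated regulation (in the motivating data, the repressors' own mRNAs,
i.e. an autoregulatory circuit).

## Methods at the core

* **Per-bait enrichment** — for gene *g* and bait *f*, counts follow a
  negative-binomial log-linear model (variance μ + φμ²) with a log
  library-size offset, replicate-pair block effects and a fraction (IP vs
  Total) coefficient β_frac.  The reported enrichment is
  e(g, f) = β_frac / ln 2, the log2(IP/Total) ratio on the counts-per-million
  scale; significance is a 1-df likelihood-ratio test, with
  Benjamini–Hochberg FDR across genes.  Counts are CPM-scaled only — no
  cross-library normalization — so fold changes are subject to composition
  ("real estate") shifts, which the synthetic data generator reproduces.
* **Pairwise contrast** — a joint model over two baits with a
  fraction × bait interaction term; its coefficient is
  e(g, A) − e(g, B), tested by the same LRT machinery.
* **Binding groups** — transcripts significant (FDR < 0.01) in ≥ 1 bait and
  exceeding 20 reads in every Total library are clustered on their
  per-replicate log2(IP/Total) profiles with uncentered Pearson similarity
  (cosine; no mean-centering) and average linkage; the tree is cut and the
  clusters matched to four archetypal sign patterns (groups I–IV).
* **Stoichiometric decomposition** — OLS fit of
  e(·, hub) = β₀ + Σ_f β_f · e(·, f) over the four hub-partner baits;
  transcripts are ranked by externally studentized (jackknife) residuals,
  computed by the closed-form leave-one-out identity, and flagged by a
  Bonferroni-corrected t test.
* **Set statistics** — hypergeometric over/under-representation of
  annotation terms per group (one-sided Fisher tails), a two-sided Fisher
  exact cluster-vs-rest variant, chi-square heterogeneity across groups, and
  Wilcoxon rank-sum comparisons of per-gene covariates between groups.

A synthetic-data module generates the whole study design — paired NB count
libraries for six baits × three replicates with planted co-binding groups, a
planted linear hub relation, planted outlier transcripts and correlated
covariates — together with a machine-readable truth file, so every statistic
can be checked against known ground truth.

## Worked example

Simulate a 2,000-gene experiment and run the full chain:

```bash
cat > config.yaml <<EOF
out_dir: data
simulation:
  n_genes: 2000
  seed: 42
EOF
riploop --config config.yaml simulate

cat > run.yaml <<EOF
counts: data/counts.tsv
sample_sheet: data/sample_sheet.tsv
gene_sets: data/gene_sets.gmt
covariates: data/covariates.tsv
out_dir: results
EOF
riploop --config run.yaml run-all
```

`results/report.md` then contains, among other tables (values from this
exact run):

```
| pair | significant | over in A | over in B |
| eIF4G1 vs eIF4G2 | 0 | 0 | 0 |
| Pab1 vs Caf20 | 447 | 310 | 137 |
...
| group | transcripts |
| I | 574 |
| II | 107 |
| III | 216 |
| IV | 298 |
...
Top outlier transcripts by |jackknife residual|:
| G0613 | 5.18 | True |
| G0921 | 4.94 | True |
```

The two scaffold isoforms, generated with near-identical profiles, show zero
significantly different transcripts; the four planted binding groups are
recovered; and the two transcripts planted with a +3 log2 deviation from the
hub's stoichiometric relation (G0613, G0921 in `data/truth.json`) are
exactly the two flagged outliers — the synthetic analogue of discovering the
repressor mRNAs' autoregulation.  The fitted partner coefficients for the
hub are attenuated and mixed between the two collinear scaffold isoforms
(0.67/0.57 here), a known consequence of fitting on noisy, highly correlated
estimated profiles; fitting on true profiles recovers (1.0, 0.4, 0.2, −0.1)
to within ±0.02 (see `docs/methods.md`).

## Layout

```
src/riploop/
  io.py             count matrix / sample sheet / GMT / covariate containers + TSV I/O
  simulate.py       synthetic paired RIP-seq generator with planted truth
  glm.py            batched NB IRLS engine and likelihood-ratio tests
  enrichment.py     CPM, count filters, dispersion estimation, paired & interaction tests, BH
  clustering.py     uncentered Pearson, average linkage, tree cuts, group archetypes, heatmap
  stoichiometry.py  OLS decomposition, jackknife residuals, outlier flagging
  sets.py           hypergeometric / Fisher / chi-square / Wilcoxon statistics
  evaluation.py     simulation-based calibration & recovery scenarios
  pipeline.py       run-all orchestration, manifest, markdown report
  cli.py            riploop command-line interface
```
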