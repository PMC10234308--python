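# snoexpress

Most annotated vertebrate snoRNAs are never detected as expressed RNAs.
`snoexpress` is a reusable pipeline for asking *why*: it computes the
sequence, structure, and genomic-context features that govern small
nucleolar RNA (snoRNA) expression, labels expression status from
replicate abundance tables, classifies status with a stratified ensemble
protocol, and explains every prediction with Shapley-additive feature
attributions.

## What it computes

**Box score.** C/D box snoRNAs carry a C box (consensus `RUGAUGA`) in the
first 20 nt, a D box (`CUGA`) in the last 20 nt, and an internal C′/D′
pair chosen to minimize the summed Hamming distance (D′ upstream of C′,
both confined to the 21st…21st-to-last nucleotide). H/ACA box snoRNAs
carry an H box (`ANANNA`, exact match in structurally unpaired positions)
and a 3′-terminal `ACA` (exact, last 10 nt). The box score is

        score = Σ_motifs Hamming(observed, consensus),

with an unidentifiable motif contributing its full length — so the score
ranges over [0, 22] for C/D (7+4+7+4) and {0, 3, 6, 9} for H/ACA
snoRNAs. Low score = well-conserved motifs.

**Structure.** Global stability is the minimum free energy (MFE,
kcal/mol) of the snoRNA fold. The *terminal stem* is the duplex formed by
the 15-nt genomic flanks extended into the snoRNA body (C/D: 5 nt both
sides; H/ACA: 5 nt at the 5′ end, 3 nt at the 3′ end, sparing the ACA
box); co-folding the two strands gives the stem stability (MFE) and a
length score = intermolecularly paired nucleotides − nucleotides inside
gaps within the stem. Folding uses ViennaRNA (RNAfold/RNAcofold, default
parameters) behind a pluggable engine contract.

**Genomic context.** Host genes are same-strand overlapping genes; for
intronic snoRNAs the pipeline derives intron rank (from both ends),
intron length, distances to the flanking exons, and the distance from the
snoRNA 3′ end to the highest-probability branchpoint.

**Labels.** A gene is *expressed* iff its abundance exceeds 1 TPM in at
least one average tissue (mean over biological replicates); the same rule
applied to host genes yields the three-way host status
(expressed / not expressed / intergenic).

**Classification.** Features (≈33 columns after one-hot encoding with the
shared `intergenic` indicator kept once) are split into tuning / training
/ test sets (10% / 80% / 10%, stratified) ten times so that the ten test
sets partition the cohort; per iteration, logistic regression, SVM,
k-nearest neighbors, random forest, and gradient boosting are grid-search
tuned (stratified 3-fold), trained, and tested, with standardization fit
on training rows only. The final call per snoRNA is the majority vote of
logistic regression + SVM + random forest. Reduced top-4 models
(box score, global stability, stem stability, host expressed) support
cross-species transfer: species rows are scaled with the *human* training
statistics, after collapsing snoRNAs with identical top-4 feature tuples.

**Interpretation.** Per-feature Shapley values on each model's decision
score (closed form for linear models, exact coalition enumeration for
small models, seeded permutation sampling otherwise; additivity holds on
every row). Mean |SHAP| per (model, iteration) yields predictive ranks
(rank 1 = most predictive), aggregated across models and iterations.
Motif logos are summarized as position frequency matrices with cumulative
Shannon entropy.

A first-class synthetic-cohort generator (`snoexpress.synthetic_data`)
emits genome FASTA, GTF, branchpoints, replicate TPM tables, metadata,
and a truth manifest, with expression status drawn from a logistic model
on the four driver features *measured from the emitted files*.

## Worked example

```bash
snoexpress simulate --n 200 --seed 3 --outdir demo_cohort
snoexpress run --cohort demo_cohort --seed 5 --outdir demo_out
```

prints

```
wrote cohort of 200 snoRNAs to demo_cohort
n=200 accuracy=0.725 sensitivity=0.514 specificity=0.844 auc=0.781
```

meaning: of the 200 synthetic snoRNAs, each predicted exactly once across
the ten held-out test sets, 72.5% of ensemble calls match the true
status; 51% of truly expressed snoRNAs are recovered (sensitivity) and
84% of non-expressed ones are correctly rejected (specificity), with an
ensemble ROC AUC of 0.78 at this small cohort size (it rises to ~0.86 at
n = 2,000). `demo_out/aggregate_ranks.tsv` starts

```
feature                  median_rank  mean_rank  aggregate_rank
box_score                1.5          1.8        1
terminal_stem_stability  2            2.46667    2
```

i.e. the box score and terminal-stem stability — two of the planted
expression determinants — lead the attribution ranks, exactly what the
generator encoded. `demo_out/predictions.tsv` holds per-snoRNA,
per-model calls with confusion categories, and
`demo_out/feature_ranks.tsv` the full rank distribution.

## Layout

| module | role |
| --- | --- |
| `genome_io` | GTF/FASTA ingestion, host assignment, intron context, flanks |
| `motif_scoring` | C/D and H/ACA box search, box score |
| `structure_features` | global fold, terminal-stem co-fold, length score |
| `expression_labels` | TPM averaging and the >1 TPM labeling rule |
| `feature_assembly` | merging, one-hot encoding, standardization, redundancy filter |
| `predictor` | split plan, tuning/training/testing, ensemble, metrics, transfer |
| `interpretation` | Shapley attribution, rank aggregation, logos |
| `synthetic_data` | self-contained cohort generator with truth manifest |
| `pipeline` / `cli` | end-to-end orchestration and the `snoexpress` command |

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
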