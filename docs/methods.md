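# Methods

## Scope and data model

The package treats snoRNA expression as a binary phenotype (expressed /
not expressed, with *expressed* the positive class throughout) and asks
which intrinsic and contextual features predict it. All coordinates are
0-based half-open internally; GTF I/O converts to/from the 1-based
inclusive convention at the boundary. Genomes are read as DNA and
transcribed (T→U) before any motif or folding operation; sequences are
always 5′→3′ in the snoRNA's own orientation, so minus-strand loci are
reverse-complemented and their flanks swapped at extraction time.

## Motif search

Consensus sequences: C `RUGAUGA`, D `CUGA`, C′/D′ the same pair, H
`ANANNA`, ACA `ACA` (IUPAC: R = A/G, N = any). Search rules:

* **C** — first 20 nt only; minimum-Hamming candidate wins, ties to the
  offset nearest the 5′ end; more than 3 mismatches ⇒ no motif.
* **D** — last 20 nt only; ties to the offset nearest the 3′ end; more
  than 2 mismatches ⇒ no motif.
* **C′/D′** — both confined to positions 20…len−21; the pair minimizing
  Hamming(D′) + Hamming(C′) subject to D′ ending at or before C′ starting
  wins, ties broken lexicographically on (D′ offset, C′ offset). There is
  no mismatch cap: any admissible pair is reported, and only a region too
  short to hold the pair (< 11 nt, i.e. snoRNAs under 51 nt) yields
  not-found. The search runs in O(n) per sequence via a prefix-minimum
  over the D′ Hamming profile.
* **H** — exact matches only, scanned 5′→3′; a hit requires all six
  positions unpaired (`.`) in the MFE structure of the snoRNA. Without a
  structure the search falls back to positions 20…len−21 with a warning.
* **ACA** — exact matches only, within the last 10 nt; the 3′-most match
  wins (the canonical box sits 3 nt from the 3′ end).

A motif that cannot be identified contributes its full length to the box
score, which forces the score ranges: C/D ∈ [0, 22] = 7+4+7+4 and
H/ACA ∈ {0, 3, 6, 9}. Mismatch counting treats `N` in a sequence as a
mismatch to every specific consensus letter.

## Folding features

The default engine wraps the ViennaRNA bindings (`RNA.fold` /
`RNA.cofold`, default parameters, 37 °C); energies are kcal/mol and
deterministic for a fixed engine version. Tests that assert energy
magnitudes do so only through signs and coarse bounds, since magnitudes
are engine-version-dependent.

Terminal-stem strands: strand5 = upstream 15-nt flank + first 5 snoRNA
nt; strand3 = last 5 (C/D) or last 3 (H/ACA) snoRNA nt + downstream
15-nt flank. The asymmetric H/ACA extension spares the ACA box, which is
not expected to pair in the stem. Flanks truncated at chromosome edges
shorten the strands with a warning.

The stem length score counts nucleotides engaged in *intermolecular*
pairs (2 per pair; a `length_score_mode="pairs"` switch counts pairs
once) minus gap nucleotides: unpaired positions on either strand lying
strictly between that strand's outermost intermolecular pairs. Positions
absorbed in intramolecular pairs within the span are neither stem nor
gap, but their loops are unpaired and therefore count as gaps. Zero
intermolecular pairs scores 0. These conventions make the score
monotone-ish in stem length, which is all it is used for.

A maximum-complementarity fallback engine (Nussinov-style, pair weights
GC=3 / AU=2 / GU=1, pseudo-energy −Σweights/2) exists for environments
without ViennaRNA. It is explicitly non-thermodynamic and never used
when the default engine is importable.

## Labels

Expressed ⇔ abundance strictly greater than 1 TPM in at least one
average tissue (arithmetic mean over replicates). Host status is the same
rule applied to a host-level abundance table, which may come from an
independent study; a hosted snoRNA whose host is absent from that table
is treated as host-not-expressed (absence read as non-detection) with a
warning rather than an error.

## Feature assembly

Twelve numeric features (length, box score, two stabilities, stem length
score, six intron-context features, branchpoint distance) plus seven
categorical parents (snoRNA type, target, host biotype, host function,
host expression status, NMD susceptibility, promoter class). One-hot
encoding names each column after its category; the `intergenic`
indicator, produced by every host-related parent, is collapsed into one
shared column. The encoder is fit on the full cohort before splitting
(categories are closed-world); standardization — population variance,
binary columns included, zero-variance columns mapped to 0 — is fit
strictly after splitting, on training rows only, and reapplied unchanged
to tuning/test/cross-species rows.

Structurally missing intron features (intergenic or exon-overlapping
snoRNAs) are imputed as raw 0 before scaling (`impute="median"` is the
alternative); the intergenic indicator carries the distinction, so the
imputed value itself is uninformative.

Host genes with multiple isoforms: the transcript whose intron is the
smallest one fully containing the snoRNA is used, ties broken by
transcript id. Multiple overlapping hosts resolve to the smallest gene
fully containing the snoRNA (else smallest overlapping). Branchpoint
distance is the non-negative magnitude |bp − snoRNA 3′ end| to the
highest-probability branchpoint of the hosting intron, probability ties
to the nearer one.

## Classification protocol

Ten stratified shuffles into tuning/training/test = 10%/80%/10% whose
test sets partition the cohort, so each snoRNA is predicted exactly once
(stratification within ±1 per set; the protocol therefore needs at least
10 members per class). Grid search uses stratified 3-fold accuracy with
ties to the first declared grid point; the shipped grids are modest,
reproducible defaults (logistic C over 5 log-spaced values; SVM
{linear, RBF} × 3 C values; kNN k ∈ {3, 5, 11}; forest/boosting 3×3) and
make no claim of matching any previously used spaces. Cohorts whose 10%
tuning split cannot support 3-fold stratification (fewer than 3 minority
members, i.e. roughly n < 90) skip the search and use the first grid
point, with a warning — the smoke-scale degradation mode.

The ensemble is the majority vote of logistic regression, SVM, and
random forest; kNN and gradient boosting are trained and reported but
excluded from the vote by default because they overfit cohorts of this
shape (configurable). The ensemble ROC uses the unweighted mean of the
three members' positive-class probabilities — an extension beyond
per-model ROCs, labeled as such. SVM probabilities come from Platt
scaling (`SVC(probability=True)`), seeded for determinism.

Cross-species transfer trains a reduced model on the top-4 features
(box score, global stability, stem stability, host expressed) with a
10%/90% tuning/training split of the full source cohort (default seed
42), scales target-species rows with the *source training* statistics,
and reports the proportion predicted expressed; a utility computes the
Pearson correlation between per-species expressed proportion and
annotated snoRNA count. Species cohorts are first deduplicated on exact
top-4 tuples (large identical-copy families would otherwise bias
accuracy).

## Attribution

Shapley values are computed against a background of the model's own
training rows on the model's decision score — log-odds margin where a
`decision_function` exists (logistic, SVM), positive-class probability
otherwise. Three routes, all satisfying local accuracy (baseline + Σ
contributions = output, within 1e-6 or exactly):

* linear models: φⱼ = wⱼ(xⱼ − mean backgroundⱼ), exact;
* ≤ 8 features: full coalition enumeration over the background, exact;
* otherwise: permutation sampling — each sample draws one feature
  permutation and one background row shared across all rows, so the
  telescoping sum keeps additivity exact per matrix.

At protocol scale the attribution uses at most 100 test rows and 100
background rows per (model, iteration), seeded, with 16 permutation
samples — sufficient to order features whose effects differ by more than
sampling noise, and the scale at which the whole suite stays fast.
Predictive rank 1 = largest mean |contribution| (both classes pooled, as
the absolute value discards direction); ties break by feature name.
Aggregation across models and iterations orders features by median rank,
then mean rank, then name.

## Synthetic cohorts

The generator emulates what the analysis assumes about real cohorts:
host genes with 1–6 introns and realistic exon/intron sizes; snoRNAs
(C/D 60–120 nt, H/ACA 120–160 nt; configurable class mix, default 70%
C/D; 30% intergenic; both strands) with motifs planted at canonical
positions and degenerated by a truncated-geometric number of mutations;
flanks carrying an engineered complementary block (uniform 0–15 nt) that
tunes the terminal stem; branchpoints planted 18–44 nt upstream of the
3′ splice site (plus occasional lower-probability decoys); and replicate
TPM tables (7 tissues × 3 replicates) written so the >1 TPM rule
recovers the generated labels exactly (replicates are rescaled so their
mean equals the intended tissue mean; expressed genes get a >1 TPM
margin, non-expressed genes stay below 0.9).

Expression status is generated from features **measured by re-running
the pipeline on the emitted files**, never from planting intents, so
imperfect planting cannot decouple features from labels. The logistic
link uses class-relative drivers: box score and global stability enter
as z-scores within each snoRNA type, stem stability as a global z-score,
host expression as its 0/1 indicator. This choice makes snoRNA class
itself carry no label signal beyond the drivers — matching the
observation that both classes share the same expression determinants —
where a raw-scale link would have made the class indicators the dominant
"determinant". Coefficients default to β = (−0.8 box, +0.1 C/D / −0.3
H/ACA stability, −0.5 stem, +1.5 host) times a global gain of 2.5 chosen
so the cohort's Bayes-level discriminability sits near AUC 0.88,
comparable to real cohorts; the intercept is solved (Brent) so the
expected expressed fraction hits the configured target (default 0.35,
in the range observed across vertebrates); labels are then flipped at
the configured noise rate (default 5%). All of this is overridable in
`SyntheticConfig`, and a fixed seed yields byte-identical files.

Background screening: a planted C box mutated beyond the 3-mismatch cap
is guaranteed unidentifiable (the background — including
mutation-induced shifted near-copies — is resampled until the search
fails). The short D, ACA, and H motifs are left unscreened: they arise
by chance in any realistic background, exactly as degenerate motifs are
"found" in real annotations.

What passing tests do *not* show about real data: synthetic intergenic
sequence is uniform random (no repeats, no paralog families, no GC
structure); categorical metadata (target, host function, NMD, promoter
class) is label-independent noise, so its real predictive value is not
modeled; every locus sits on its own chromosome; and TPM magnitudes are
arbitrary lognormals — only the >1 TPM semantics matter.

## Known limitations and deliberate exclusions

* One known-red self-check: on the n=2000 recovery cohort the aggregate
  attribution ranks recover box score, host expression, and stem
  stability as the top 3, but global snoRNA stability lands outside the
  top 5. Its generative coefficient is several-fold weaker than the
  other drivers and sign-flipped between classes (which linear
  attribution attenuates), while the one-hot complements of
  host-expressed (host-not-expressed, intergenic) deterministically
  inherit the strong host signal and occupy the next ranks. The
  corresponding acceptance test is left failing rather than weakening
  the check or inflating the coefficient.
* Branchpoints are consumed, never predicted; no liftover, trans-spliced
  or circular transcripts; no suboptimal-structure ensembles, partition
  functions, or pseudoknots; no PWM/HMM motif models or target
  prediction; no neural models, calibration, or class-weight tuning;
  figures are emitted as plot-ready tables only.
* The Kolmogorov–Smirnov logo utility compares per-position nucleotide
  samples on a fixed ordinal encoding (A<C<G<U) — a coarse screen for
  composition shifts, not a calibrated categorical test.
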