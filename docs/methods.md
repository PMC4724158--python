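# Methods

This note records the models and procedures `mpminer` implements, the
choices made where the design was genuinely open, and what the synthetic
fixtures do and do not establish about real patent data.

## Declaration grammar and normalization

A melting-point declaration is matched by a scanner compiled from the
grammar

```
FromLiterature? MeltingPoint Qualifier? (Value|Range|MeasurementError) OutcomeQualifier?
```

with numerals, decimals and spelled-out cardinals (composed tens/hundreds
up to 999) accepted as values; `-`, `–`, `—` and `to` as range
separators; the qualifier vocabulary `{>, <, ≥, ≤, ~, about,
approximately, approx., ca.}`; and `lit.`/`literature` setting the
from-literature flag. All temperatures are converted to Celsius
(F → C via (F − 32)·5/9), measurement errors v ± e become the interval
[v − e, v + e], and single values are stored as degenerate intervals. A
declaration with no unit is read as Celsius, because unitless ranges are
ubiquitous in Celsius-normalized experimental text. The original text is
retained verbatim on every record.

**Repair before flagging.** Two range defects are mechanically
correctable and are repaired during parsing: a decimal comma in the upper
bound (`82-82,5`), and a truncated upper bound, which borrows the missing
leading digits of the lower bound so both bounds have the same digit
count and upper ≥ lower (`159-62` → 159–162, `160-2` → 160–162). If no
borrowing yields upper ≥ lower the values are left unchanged and the
inverted-range flag fires downstream. Remaining implausible values are
flagged, never dropped, with four rules: value > 500 °C, range wider than
50 °C (both strict inequalities), inverted range, and — added here as a
fourth rule because misprinted minus signs occur — any bound below
−273.15 °C.

Sublimation-labeled records are parsed and labeled but excluded from MP
model training by default, as are records bearing `<`/`>` qualifiers and
decomposition labels; each exclusion is reversible by flag.

## Association

Entity recognition is an input: documents arrive with entity spans and
(where resolved) SMILES. Headings partition a document into experimental
sections (leading headingless paragraphs form one anonymous section).
A mention inside a bracketed group that opens within W = 80 characters
after an entity's end binds explicitly to that entity (nearest preceding
entity wins if several qualify, with a warning). Otherwise a mention in
the final paragraph of a section binds implicitly to the section's target
compound — the last structure-bearing entity of the heading, else the
first structure-bearing entity of the section — reflecting that
characterization data closes a synthesis write-up whose product is named
in the heading. Explicit binding always takes precedence. W is
configurable; 80 characters comfortably covers "name (2.1 g, 85 %, m.p.
…)" parentheticals without crossing sentences in practice.

## Curation

The molecule key is the RDKit canonical SMILES of the structure as given;
mixtures (more than one connected component) are excluded outright rather
than desalted, and unparsable structures are counted separately.
Within a molecule, measurement midpoints are merged transitively
(single linkage) whenever they differ by ≤ ΔT = 1 °C, keeping each merged
cluster's first-seen record; midpoints rather than interval overlap are
compared because most records are narrow ranges. The survivors are the
molecule's distinct measurements, and the representative is the record
whose midpoint lies nearest their median (even counts use the mean of the
two central values; ties resolve to the lower temperature, then the
lexicographically earlier patent id) — deterministic, and preserving the
link to an actual originating patent. The drug-like subset keeps
midpoints in the closed interval [50, 250] °C.

## Experimental accuracy

Assuming two reports of the same molecule are independent draws with
standard deviation σ, their difference has variance 2σ², so
σ̂ = √(mean ΔT²/2) over all pairwise differences within each molecule's
distinct measurements (all pairs, not consecutive ones). This /√2
convention matters: it is what makes repeated-measurement differences an
estimate of *single-measurement* accuracy.

Deduplication removes pairs with ΔT ≤ 1 °C before the differences are
observed, biasing σ̂ upward. The correction replaces the counts of
integer bins 0 and 1 (bin b collects ΔT ∈ [b, b+1), valued at its center
b + 0.5) each with the mean count of bins 2 and 3, then recomputes σ from
the corrected histogram; if bins 2 and 3 are both empty the correction is
skipped with a warning. The temperature-binned curve sorts (pair-mean MP,
ΔT) pairs by temperature into adaptive bins of at least 50 pairs,
estimates σ per bin, optionally rescales the curve so its count-weighted
mean equals a reference σ, and by default excludes pairs with mean
MP < 0 °C, which in mined data are dominated by processing errors.

## Descriptors and unsupervised filtering

QNPR descriptors count every contiguous character substring of length
1–3 of the molecule's SMILES; a substring must occur in at least five
molecules of the dataset to become a column (membership is counted per
molecule, not per occurrence — the threshold is a vocabulary filter, and
this reading is configurable). The raw string is split character by
character, with no tokenization of two-letter elements; canonical SMILES
should be fixed upstream so descriptors are reproducible. The matrix is
stored sparsely with named columns; sparseness is reported as zero
entries per non-zero entry.

Unsupervised filtering first eliminates columns with two or fewer
non-zero values, then groups inter-correlated columns greedily in column
order: a column joins the first kept column whose pairwise R² exceeds
0.95, else is kept itself. Greedy assignment in a fixed order is
deterministic and avoids solving a graph-clustering problem whose answer
the downstream model is insensitive to. Two zero-variance columns are
treated as perfectly correlated; a zero-variance column never groups with
a varying one. No target information is consulted, so the filter
introduces no selection bias.

## Regression, consensus, outliers, classification

The regression learner is an RBF-kernel SVM with LibSVM-style parameters
(C, γ, ε); a grid search scores user-supplied (C, γ, ε) triples by
fivefold CV on a random fraction of the rows, breaking ties toward the
smallest C, then γ, then ε. Fivefold CV assigns rows to folds by a
seeded uniform permutation (no stratification); every row is predicted
exactly once out-of-fold, the CV RMSE's standard error comes from the
fold-to-fold spread, and the final model is refit on all rows. Interval
targets train on their midpoints.

Consensus members are typically models on different descriptor views
trained with shared folds so their out-of-fold predictions align.
Strategies: simple mean; RMSE-weighted mean Σwᵢyᵢ/Σwᵢ with wᵢ = 1/RMSEᵢ;
and a multiple-linear-regression stack fit on out-of-fold member
predictions. The weighted form is normalized by Σwᵢ, which reduces
exactly to the simple average for equal member accuracies — the
alternative normalization by √Σwᵢ² lacks that property and is available
behind a flag for comparison. The distance-to-model is the standard
deviation of member predictions per input (CONSENSUS-STD).

Outlier filtering assumes residuals are N(0, σ) with σ = model RMSE. For
a two-sided tail probability p, the threshold z solves 2(1 − Φ(z)) = p;
residuals beyond z·σ are flagged, N·p of them are expected by chance, and
SNR = observed/expected measures how much of the flagged set is real
error rather than Gaussian tail. Removal is worthwhile when SNR ≫ 1.

The decompose-vs-melt classifier uses stratified bagging: each of 64 bags
resamples the minority class with replacement to its own size m and
subsamples the majority without replacement to m, so every bag holds 2m
rows with equal class counts. Bags alternate between a kernel learner and
a decision tree (learners are pluggable). A row's score averages the
votes of bags that excluded it; rows present in every bag (possible for
minority rows) fall back to the all-bags average. Balanced accuracy is
the mean of per-class recalls.

## Enrichment and solubility

Feature incidence is binary per molecule (SMARTS predicates; the starter
set covers carboxylic and phosphonic acids, α-amino acids, primary
amines, tetrazoles and nitroso groups). For each feature the upper-tail
hypergeometric probability P(X ≥ k) of k carriers among n subset draws
from a population of N with K carriers is computed per direction of
interest, with the fold change (k/n)/(K/N) and Benjamini–Hochberg
q-values attached (raw p is always retained; the correction is a
precaution the hypergeometric analysis itself does not require).

The general solubility equation logS = 0.5 − 0.01(MP − 25) − logP turns a
melting-point RMSE of σ °C into exactly 0.01·σ log units of solubility
error; logP is an input, not modeled here.

## Synthetic data: what it emulates, what it does not

The corpus generator emits experimental sections in the canonical shape —
a heading naming the product, a synthesis paragraph with a distractor
reagent entity, and a characterization tail with the declaration either
bracketed after the product name or closing the section — and exercises
every grammar production (prefix forms, qualifiers, ranges, measurement
errors, spelled-out values, °F, literature flags, outcome labels). Typo
injection covers decimal commas, truncated and inverted ranges, missing
decimal points and tenfold misprints; injected ranges are kept within one
tens block of three-digit values so that truncation is unambiguously
repairable and an inverted print (equal digit counts) is unambiguously
not — mirroring which real defects are mechanically correctable. Ground
truth (interval, flags, target entity, provenance) is emitted alongside.

The QSPR generator draws molecules without replacement from an enumerated
family of ~6000 substituted benzenes, pyridines, thiophenes and alkanes.
The latent MP is linear in ring, nitrogen, oxygen and halogen counts and
heavy-atom count plus a mild ring×nitrogen interaction, centered at
155 °C with a spread of ~31 °C; observations add Gaussian noise
(default σ = 35 °C, the experimental reproducibility scale of mined
data), duplicates re-observe with fresh noise, outliers add ±5σ, and a
5.5 % decomposing minority is drawn preferentially among acid- and
amine-bearing structures with its latent value shifted by +55 °C
(matching the 210 vs 155 °C medians of real decomposing vs melting
records). Everything is deterministic given the seed.

What passing tests on these fixtures shows: the grammar, repair, flagging,
association, curation, accuracy, filtering, consensus and classification
machinery is correct against enumerable ground truth, and the statistical
estimators recover their generating parameters. What it does not show:
robustness to real patent OCR noise, prose variety beyond the canonical
templates, chemical-NER errors (entities are inputs here), or the
headline accuracies attainable on hundreds of thousands of real records
with large commercial descriptor suites — problem sizes here (up to 5000
molecules, three QNPR views) are chosen to characterize behavior, not to
reproduce production-scale error rates.

## Numerical choices and limitations

* Suspicious-value inequalities are strict (> 500 °C, width > 50 °C); the
  drug-like interval is closed on both ends.
* Median of an even number of distinct measurements is the mean of the
  two central values; representative ties break to the lower temperature,
  then the earlier patent id.
* σ estimation from a histogram values each bin at its center; the
  correction is skipped (with a warning) when its reference bins are
  empty.
* Distance-to-model uses the sample standard deviation (ddof = 1) of
  member predictions, 0 for a single member.
* Grid-search ties and all fold assignments are deterministic given the
  seed; seeds are mandatory wherever randomness exists.
* The scanner resolves ambiguity longest-first (measurement error before
  range before single value) and requires word boundaries around
  prefixes and outcome tokens; spelled-out numbers are limited to
  cardinals up to 999.
* Fold assignment is positional: permuting input rows permutes fold
  membership. Results are invariant to row order only in distribution,
  and exactly reproducible for a fixed row order and seed.
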