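# Methods

This note documents the statistical and algorithmic choices behind
filterlab: what each stage computes, the defaults and why, what the
synthetic corpora do and do not emulate, and the known limitations.

## Query semantics

The Ovid-dialect engine implements the smallest semantics that make the
bundled filters reproducible and auditable:

* **Tokenization.** Text is lowercased and split on every
  non-alphanumeric character. `.tw` searches title + abstract only
  (those are the only text fields the corpus model carries). A
  multi-word textword must occur as an adjacent token sequence;
  truncation (`prognos*`) is a prefix match on the final token and is
  the only wildcard. No stemming, no stopwording at query time, no
  hidden normalization. A consequence worth knowing: hyphenated
  compounds split, so `survival.tw` matches "disease-free-survival".
  Whether production Ovid behaves identically on such tokens is not
  asserted here.
* **MeSH explosion.** `exp Heading/` matches the heading or any tree
  descendant, where descent is exactly tree-number prefix extension
  (`N06.850.505` descends from `N06.850`). Heading comparison is
  case- and punctuation-insensitive ("Follow-Up Studies" ≡ "follow up
  studies"), which absorbs the hyphenation differences between PubMed
  and MeSH renderings of the same heading. With an empty tree,
  explosion degrades to exact match and a warning is logged once.
* **Line combinations** (`or/1–13`, `1 and 2`, `3 not 1`) operate on
  the per-line id sets; en-dashes are normalized to hyphens before
  parsing because published strategy tables typeset ranges with
  en-dashes. Line numbers must be consecutive from 1 and references
  must point backwards.
* The Haynes broad prognosis filter is shipped as a hand-translated
  AST (`[MeSH Terms]` → exploded, `[MeSH:noexp]` → non-exploded,
  `[Text Word]` → `.tw`); PubMed query syntax is deliberately not
  parsed, since the filter serves only as a fixed comparator.

## Term discovery

Candidate terms are unigrams and bigrams of title+abstract tokens,
with a bundled (configurable) English stopword list applied to unigrams
and bigram boundaries. Ranking is by positive-set **document**
frequency (ties: chi-square, then lexicographic): the 2×2 behind the
chi-square counts studies containing the term, not occurrences, because
the sampling unit of a reference set is the study. Both counts are
reported. The Pearson statistic (1 df, optional Yates correction) comes
from `scipy.stats.chi2_contingency`; degenerate margins (term in no or
every record overall) return χ² = 0, p = 1 by convention rather than an
error, since such terms carry no discrimination signal. Note that at
reference-set sizes (tens of positives) even real effects are usually
non-significant; the ranking is therefore descriptive, and the
screening of "methodological" from clinical content terms is left to
the expert panel.

## Panel aggregation

Ratings are 1–9 per (term, panelist, round). Only the final round
determines selection; earlier rounds are stored for audit, matching the
usual design where the last round is a moderated re-rating. The RAND
classification used: median 7–9 appropriate, 4–6 uncertain, 1–3
inappropriate; *disagreement* when at least ⌈f·n⌉ ratings fall in 1–3
**and** at least ⌈f·n⌉ in 7–9, with f = 1/3 by default — the standard
tertile generalization for panels larger than nine, and configurable
because published panels vary in the exact cutpoint. Disagreement
demotes a term to uncertain; a filter term must be appropriate without
disagreement. Raising any single rating can never demote an appropriate
term (median and the tertile counts move the right way), which the
property suite checks.

## Relative-recall evaluation

`evaluate_review` composes strategy application, 2×2 construction and
the five statistics. The construction enforces the relative-recall
premise — the reference set must lie inside the baseline result (the
replayed review search); violations are reported with the offending
ids, because sensitivity against a reference the baseline never
contained is meaningless. Precision and NNR are flagged undefined (NaN)
when the filter retrieves nothing, rather than 0, since 1/precision
would otherwise be meaningless.

**Back-derivation.** Published evaluations print (included n, retrieved
N, sensitivity, specificity) per review. Cells are reconstructed as
A = round(sens·n/100), C = n−A, D = round(spec·(N−n)/100), B = N−n−D,
rounding half away from zero. Display rounding for comparison with
printed tables: sensitivity/specificity/time-saved to the printed
precision (usually integer), precision to the number of decimals
printed in that row, NNR to the nearest integer **from the unrounded
precision**. This convention regenerates the large majority of the
bundled published rows exactly; the handful of cells where the
publication's own rounding chain differs (e.g. an NNR of 278 where the
back-derived precision gives 276, and one row whose printed precision
and NNR are mutually inconsistent) are carried in the fixtures with
both values and flagged per cell rather than silently adjusted. One
fixture row's specificity digit is typeset ambiguously in the source
table; the stored value (42) is the unique one under which the row's
own precision, NNR and time-saved are mutually consistent, and the
fixture records that reasoning.

## Pooling

Per-review proportions are pooled with a hand-written
DerSimonian–Laird chain on a variance-stabilized scale (cross-checked
in the tests against `statsmodels.stats.meta_analysis.combine_effects`
as an independent oracle):

* **Transform** (default `ft_dl`): Freeman–Tukey double arcsine,
  t = asin√(x/(n+1)) + asin√((x+1)/(n+1)), var = 1/(n+0.5) — the
  historical default of Stata's `metaprop`, and the transform of choice
  when several studies sit at 0% or 100%, as review-level sensitivities
  routinely do. `logit_dl` (0.5 continuity correction at the
  boundaries) is the alternative.
* **Heterogeneity**: DL moment estimator, τ² = max(0, (Q−(k−1))/c).
* **Back-transform**: Miller's inverse with the harmonic mean of the
  study sizes; the pooled value is clamped to the transform's domain
  [0, π] first, so extreme CI bounds map to 0/100 instead of wrapping.
  The 95% CI is the normal approximation on the transformed scale,
  back-transformed and clamped to [0, 100].
* k = 1 returns the study's own proportion and CI; τ² = 0.

Numerical caveats: the pooled estimate always lies within the range of
the study proportions (the back-transform is monotone on [0, π]), and
pooling is permutation-invariant. Duplicating every study leaves the
estimate unchanged only when study sizes are equal; with unequal sizes
the DL τ² — and hence the weighting — legitimately shifts, so no such
invariance is claimed in general. No REML/Paule–Mandel estimators and
no prediction intervals are provided.

## Synthetic corpora

`synthcorpus.generate` emulates the *structure* that the pipeline
consumes: records whose designated signal terms occur independently
with class-specific probabilities (p_relevant vs p_irrelevant), planted
as whole tokens into title (30%) or abstract, over a Zipf–Mandelbrot
background vocabulary (`w00000`, `w00001`, …) with Poisson abstract
lengths; MeSH signal headings analogously. Generation is fully
deterministic given the seed (byte-identical MEDLINE output).

Defaults mirror a mid-sized review baseline: 73 relevant records (the
combined reference-set size in the bundled fixtures) in a 1314-record
result; default signal terms are morphological variants of the
prognostic-factor filter's terms ("prognostic"/"prognosis" exercise the
`prognos*` truncation) with enrichment of the order seen for
methodological language (p_relevant 0.1–0.55 vs p_irrelevant
0.02–0.25). Because insertions are independent, an OR-filter's expected
sensitivity has the closed form 100·(1−∏(1−pᵢ)), which the end-to-end
tests verify to within binomial noise.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: correlated term occurrence (real
methodological terms co-occur), realistic token distributions inside
titles, indexing variability in MeSH assignment, journal/year
structure, and reference sets defined by human inclusion judgements
rather than by construction. Results on synthetic corpora validate the
machinery, not the filter's field performance.

Problem sizes in the test suite (hundreds to a few thousand records,
six pooled studies) are chosen to make every planted effect detectable
at tight tolerances while keeping the whole suite near-instant; the
published-row fixtures involve no simulation at all.

## Known limitations

* The query engine supports no proximity operators, floating
  subheadings, `.mp`, or nested parentheses; strategies using them must
  be rewritten as numbered lines.
* The bundled MeSH tree is a toy (22 headings); real explosion requires
  supplying a full heading→tree-number table.
* RIS support covers the common tag subset (TY/ID/TI/AB/KW/PY/ER) with
  keywords standing in for indexing terms.
* Back-derivation inherits the information loss of published rounding:
  cells are exact only up to ±0.5 of a printed percentage point, which
  is why a few recomputed NNR values differ by one unit from their
  printed counterparts.
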