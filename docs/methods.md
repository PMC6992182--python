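# Methods

## Data model

A *fatty-acid profile* is one species' vector of percent-of-total-fatty-acid
values over a panel of labelled acids (here the 26-acid GC-FID panel,
C14:0 … C22:6n-3). Values are stored exactly as reported — typically 2–3
significant figures — and profiles are never re-normalized to sum to 100,
because every downstream quantity is defined on the as-reported scale and
the identified total (82–96% in the packaged data) carries information
about unidentified peaks. Species metadata carry the trophic level (a
fishbase-style scalar, used as a point value; its published SD is stored
but not modelled) and the total lipid content in g per 100 g wet weight.

Labels are parsed as `C<carbons>:<double_bonds>[n-<series>]` with carbons
in 4–30, double bonds in 0–6 and the series in {3, 6, 7, 9}. Parsing
normalizes unicode dash variants, case and whitespace, and resolves
known-bad labels through a two-column alias table shipped as package data;
the packaged table's truncated `C20:5n-` resolves to EPA (`C20:5n-3`).
An alias table rather than fuzzy matching keeps the repair deterministic
and auditable.

### The C22:4 convention

One panel acid, C22:4, carries no series suffix. The C22:4 found in marine
fish is nearly always adrenic acid, n-6, and study-level n-6/n-3 ratios
only reproduce when it is counted as n-6; reported n-6 *ranges*, however,
are often computed over explicitly labelled acids only. Both readings are
first-class: the `default` convention counts C22:4 as n-6, the `strict`
convention counts only explicit labels. Every aggregation and index takes
the convention as a parameter; `default` is used everywhere unless stated.

## Aggregation

Class sums follow the double-bond rule (SFA 0, MUFA 1, PUFA ≥ 2); n-3/n-6
sums follow the convention above; EPA, DPA (C22:5n-3) and DHA are read
directly off the profile. All aggregates are plain sums, so summaries are
linear in the profile (doubling a profile doubles every class sum). The
EPA+DHA share is denominated by the n-3 sum, i.e. (EPA+DHA)/n-3, the
denomination under which the study's reported 53.1%–88.3% range reproduces;
when a profile has no n-3 mass the share is reported as absent, never 0.

Fat-content classes use the Ackman rule. The published phrasing ("2–4%",
"4–8%") leaves boundary sides open; here the intervals are [2, 4) and
[4, 8], with > 8 high fat — a choice that matters only for values exactly
on a boundary, which the packaged data do not contain.

## Indices

The five indices are computed exactly as defined in the README. Two
numerical points deserve note:

- **IT numerator.** Published renderings of the Ulbricht–Southgate IT
  formula frequently garble the bracketing; the canonical form with
  numerator (C14:0 + C16:0 + C18:0) is used, and is validated by the
  packaged-data reproductions (IT 0.73 for *Trichiurus lepturus*, panel
  mean 0.48).
- **IT is scale-dependent.** IT's denominator adds the dimensionless
  n-3/n-6 ratio to percent-scale terms, so IT — unlike the other four
  indices, which are ratios of linear forms and exactly invariant under
  uniform rescaling of a profile — is defined on the percent-of-total
  scale. Feeding IT fractions instead of percentages changes the result;
  inputs are therefore always percent.

Degenerate denominators (no n-3, no SFA, no n-6 for IT's trailing term,
zero C14:0+C16:0 for HH) raise an `UndefinedIndexError` naming the species
rather than returning a sentinel, so degenerate synthetic inputs cannot
silently contaminate summary tables.

Two published study values deliberately do **not** reproduce from the
published species means and are asserted at their recomputed values: the
IT minimum for *Trypauchen vagina* recomputes to ≈ 0.34 (reported 0.38),
and the trophic-level/PUFA correlation recomputes to r = −0.44, p = 0.041
(reported −0.42, 0.04). Both discrepancies are consistent with the
original computation having used unpublished individual-level (n = 10 per
species) data; the species-mean recomputation is the reproducible anchor.

## Statistics

Across-species summaries use the sample (n−1) SD. Pearson correlations
are computed over species (n = 22 in the packaged data) with the exact
two-sided t transform on n−2 degrees of freedom; zero variance in either
variable is an error, not r = 0. The ANOVA stage drops empty fat
categories, requires at least two non-empty ones, and reports the one-way
F with a Tukey HSD pairwise table (studentized-range adjusted p, α = 0.05,
computed only when every group has ≥ 2 members). With exactly two groups
the F statistic equals the squared pooled t statistic, which the tests use
as an independent check.

## Clustering

Species are clustered agglomeratively (SciPy) on Euclidean distance over
the five-index matrix. Because the indices live on different scales
(n-6/n-3 ≈ 0.1–0.5, HH ≈ 0.6–1.4), columns are z-scored (sample SD) by
default; the flag is recorded on the matrix and zero-variance columns are
an error under scaling. Linkage is `complete` by default with `average`
and `ward` exposed; SciPy's tie-breaking (lowest pair index first) makes
results bit-stable for a fixed row order, and the k-cut partition itself
is invariant to row order (tested). Cut groups are renumbered 1..k by
increasing composite quality — mean z of (HH, P/S) minus mean z of
(IA, IT, n-6/n-3) — so group k is always the nutritionally best. On the
packaged data the complete-linkage 4-group cut places the five most
favourable species (*Collichthys lucidus*, *Ilisha elongata*, *Trypauchen
vagina*, *Odontamblyopus rubicundus*, *Sillago sihama*) alone in group 4.
The exact linkage behind the original figure is unknown, so this
membership is checked as a one-of-the-linkages property, not per linkage.

## Synthetic data generator

The generator emulates the study design, not the chemistry: `n_species`
(default 22) species of `n_individuals` (default 10), trophic levels
uniform on [2.0, 4.5], lipid contents uniform on the observed
[0.5, 7.4] g/100 g, and class totals starting from the study means
(SFA 38.9, MUFA 31.1, PUFA 20.9). `pufa_tl_slope` (percent per
trophic-level unit) moves mass between PUFA and SFA as a linear function
of centred trophic level (MUFA and the identified total stay fixed);
`n6_tl_slope` moves the n-6 share within PUFA around its study value
(12.9% of PUFA). Class mass is spread over the 26-acid panel by fixed
within-class proportions estimated once from the study means (C16:0 ≈ 66%
of SFA, oleic + palmitoleic ≈ 75% of MUFA, DHA + EPA ≈ 72% of n-3) and
normalized at use. Noise is unit-mean multiplicative log-normal with CV
`within_species_cv` (default 0.10), applied per label — positive by
construction, no rejection sampling; the rare draw whose total would
breach the 100% compositional ceiling is rescaled to 99.9. Configs
implying negative class mass raise a config error. Everything derives
from `seed`; identical configs export byte-identical CSVs.

What the generator does *not* emulate: between-acid correlation beyond
class structure, lipid-content/fatty-acid coupling, phylogenetic
relatedness, seasonal or size covariates. Tests passing on synthetic data
therefore demonstrate correctness of the computational pipeline and its
statistical calibration (type-I error of the correlation stage ≈ 5% over
200 null seeds; sign recovery > 95% at slope −4, CV 0.05), not fidelity
of any biological claim.

## Problem sizes and determinism

Every packaged-data computation is a 22 × 26 table operation and runs in
well under a second. Simulation-based calibration tests use 200 replicate
seeds of 22-species datasets — a few seconds each. The pipeline is fully
deterministic: two runs on identical inputs produce byte-identical
artifacts, and the CLI seeds its only stochastic stage (simulation)
explicitly.

## Known limitations

- Species-mean inputs only: the individual-level (n = 10) raw data behind
  published tables are generally unavailable, so correlations and ANOVAs
  here have species as the unit of analysis.
- Area-percent only; no conversion to absolute concentration (mg/100 g).
- No cis/trans isomer distinction and no lipid-ontology mapping; labels
  are taken at shorthand face value.
- Trophic-level uncertainty is ignored (no errors-in-variables model).
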