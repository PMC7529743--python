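# Methods

`foodmine` re-implements a literature-mining workflow for food chemical
composition: retrieve bibliographic records for a food search term, screen
them down to papers likely to report chemical measurements, standardize and
aggregate the curated measurements into per-compound entries, compare the
result against reference food-composition databases, and map the recovered
chemical space with substructure embeddings annotated by health-association
counts. This note documents the models, the defaults and why they are set
where they are, and what the synthetic fixtures do and do not establish.

## Corpus screening

The vocabulary filter scans each entry's MeSH terms and abstract for terms
from three controlled vocabularies (biochemicals, foods, measurement
methodologies). Matching is case-insensitive and token-boundary-aware:
text is tokenized on non-word characters and a term matches only as a full
token (or contiguous token sequence for multi-word terms), so "clove" never
fires inside "cloverleaf". The default pass rule is

> at least one food term AND at least one chemical-or-method term,

searched over MeSH ∪ abstract. The original study's exact boolean and term
lists were published only as supplementary material; the packaged
vocabularies are reconstructions assembled for this package and the rule is
configurable (`MatchRule`). Precision is the filter's only job, which is
why substring matches are rejected outright.

The relevance classifier collapses the three-way curation label
(not useful / quantified / unquantified) to useful-vs-not, featurizes
title + abstract + MeSH as n-gram counts (range 1–2, minimum document
frequency 2), and fits an L2-regularized logistic regression. A linear
model on counts is robust at the scale this stage sees (hundreds of
labelled documents); the family is replaceable. The training split is
balanced with SMOTE before fitting: each synthetic minority point is
`x + u·(x_nn − x)` for a uniform `u` and one of the k = 5 nearest minority
neighbours, so every synthetic point lies on a segment between two real
minority samples and class counts come out exactly equal. SMOTE and the
n-gram vocabulary both see the training split only; metrics (f1 = 2PR/(P+R),
precision, recall for the useful class) are computed once on the untouched
test split (default 25%, stratified). All stochastic steps take explicit
seeds.

## Records

Quantified measurements are converted to mg per 100 g of food with exact
rational arithmetic (`fractions.Fraction`); the supported unit table is
mg/100 g, g/100 g, µg/g, mg/g, mg/kg, ppm (w/w, ≡ mg/kg), %, µg/100 g and
g/kg. A `Fraction` input round-trips bit-for-bit; float inputs incur only
the final binary rounding. Dry/fresh basis is recorded but never converted
— moisture data is generally not reported alongside the measurement, and
preparation steps such as roasting change real contents, so mixtures of
bases are flagged rather than reconciled.

Compound identity is a PubChem CID when the name resolves, otherwise the
conservatively normalized name (lowercase, whitespace collapsed; salt and
stereo suffixes kept to avoid false merges). The default resolver is a
packaged synonym table of 36 food chemicals (alliaceous sulfur compounds,
methylxanthines, flavonoids, phenolic and organic acids, amino acids,
biogenic amines, sugars, fatty acids) with their CIDs and SMILES; a live
PubChem client with an on-disk cache exists behind an explicit opt-in and
is never touched by tests. CID-first equality is deliberately not
transitive across resolved and unresolved keys, so `CompoundKey` is
unhashable by design and grouping goes through an explicit `identity()`
tuple (CID when present, else name).

Aggregation merges all records for one compound key in one food into a
single entry: arithmetic mean, minimum, maximum and sample variance
(n − 1 denominator, defined as 0 for a single record) over the quantified
records' standardized values, plus record and distinct-paper counts.
Compounds reported only in relative terms (e.g. chromatogram peak-area
percentages) keep an entry with absent statistics — they still count as
unquantified coverage. Mean-across-records is the default; a
paper-weighted alternative (mean of per-paper means) is a reasonable
variant that callers can build from the record stream, since records retain
their paper ids.

## Database comparison

Reference snapshots list a food's compounds per food variant, with optional
quantities. Variants are merged first ("Garlic" + "Soft-necked Garlic"): a
compound is quantified if any variant quantifies it, and quantities from
multiple variants are averaged. Coverage is set arithmetic on compound
identities: a mined quantified compound is *novel* iff it appears in no
reference source at all (the union rule), quantified or not. Paper
frequency ranks compounds by distinct papers reporting them, ties broken by
name.

Agreement with a gold-standard database is the coefficient of
determination of an ordinary least-squares fit of log10(mined mean) on
log10(gold value) — equivalently the squared Pearson correlation of the
log values, which makes it invariant to rescaling either axis. Compounds
with a zero gold value cannot be log-transformed and are excluded and
reported. A sample-descriptor filter drops pairs whose contributing
records *all* carry an excluded descriptor (the roasted-cocoa situation:
processing shifts amino-acid contents, so roasted-only entries are removed
rather than averaged in); partially tagged entries stay. Fewer than three
matched pairs is an error, not a number.

## Chemical embeddings

A molecule's "sentence" is the ordered list of Morgan (circular)
substructure identifiers: for each atom in canonical order, the environment
identifier at radii 0..r. Radius defaults to 1. The molecule is
re-canonicalized before fingerprinting, so any SMILES spelling of a
structure yields the same sentence. Atoms lacking an environment at some
radius (a lone heavy atom has no radius-1 environment) repeat their largest
available identifier, keeping the token count exactly
atom_count × (r + 1).

Token vectors are trained with skip-gram plus negative sampling (window 5,
5 negatives drawn from the unigram^0.75 distribution, linearly decaying
learning rate), implemented directly in numpy: the corpora this package
embeds are desk-scale (tens to hundreds of molecules), where a compact
single-threaded trainer is adequate and exactly reproducible given a seed.
The default dimension is 32 at library level (the pipeline uses 16); the
300 dimensions customary for corpus-scale chemical embeddings are
overparameterized here. A molecule's embedding is the sum of its token
vectors; unseen tokens share one UNK vector (the mean of trained vectors).
2-D reduction is t-SNE by default and PCA as an exactly deterministic
alternative — the pipeline default is PCA so reruns are byte-identical.
The health overlay attaches per-CID association counts (a curated
chemical–disease association extract) and database membership, and reports
per database the number and fraction of member chemicals with at least one
association.

## Synthetic fixtures

The generators are pure functions of a `FixtureSpec` (same seed →
byte-identical files) and plant ground truth for every stage. Defaults
mirror the study conditions the workflow targets:

| parameter | default | rationale |
|---|---|---|
| n_relevant / n_irrelevant | 27 / 73 | 27% of reviewed papers contained chemical-content data |
| full_text_rate | 0.72 | ~72% of filtered papers were retrievable via a full-text link |
| quantified_label_rate | 0.70 | ~70% of the mined information was quantified |
| n_compounds | 70 | desk-scale compound panel; 50 quantified + 20 unquantified |
| planted_overlap | (16, 10, 24) | 48% of quantified compounds novel, as in the garlic panel |
| noise_sigma_log | 0.3 | record scatter of ±0.3 decades reproduces the observed log-log spread |
| true content range | 10^−2–10^3 mg/100 g | log-uniform, matching the orders-of-magnitude spread of real panels |

Relevant abstracts plant one food, one chemical and one method term among
neutral filler words; irrelevant abstracts draw from a token pool disjoint
from both, diluted by `vocab_overlap` (each vocabulary category leaks in
independently, so some diluted entries can pass the filter). At
`vocab_overlap = 0` the corpus is exactly separable — by construction, so
filter precision/recall of 1.0 and classifier f1 of 1.0 on this fixture
validate the plumbing, not real-world screening accuracy. Real abstracts
share vocabulary across relevant and irrelevant papers, which is exactly
why the original study reports f1 well below 1. Likewise the fixture's
compound names resolve perfectly, whereas real curation leaves a tail of
unresolved names; the name-only key path is tested separately.

The snapshot generator realizes the planted
(shared-quantified, shared-unquantified, novel) partition exactly, adds
reference-only compounds, and splits the gold rows across two food variants
to exercise the merge. The funnel expected for the end-to-end run is
derived from the planted construction (which entries carry which terms,
which have links, which labels), never by running the filter inside the
generator.

## Numerical choices and degenerate inputs

- Unit conversion: exact rational factors; unknown units raise with the
  supported list; negative values are domain errors.
- Variance: sample variance (n − 1); 0 for a single record.
- R²: `scipy.stats.linregress` on log10 values; < 3 pairs raises.
- SMOTE: minority count ≤ k raises with advice to lower k; already
  balanced input is returned unchanged.
- Ranking: descending score, ties broken by entry id so reruns are stable.
- Empty corpus: the pipeline completes with an all-zero funnel; the
  classifier stage records why it was skipped instead of failing.
- Pipeline artifacts are JSON with sorted keys and CSVs written with
  round-trip float formatting, which is what makes rerun byte-identity
  checkable.

## Problem sizes

The default test and acceptance runs use corpora of 100–120 entries,
compound panels of 40–70 with up to ~10,000 records for the aggregation
oracle, 100 random coverage specs, 1000 Monte-Carlo resimulations for the
agreement envelope, and embedding corpora of 5–10 molecules at dimension
8–16. These sizes make every planted quantity exactly recoverable while
keeping a full run in tens of seconds on one CPU.

## Known limitations

- The packaged vocabularies and synonym table are small reconstructions;
  applying the package to a real corpus requires supplying fuller ones.
- No full-text retrieval or table extraction: measurements enter as
  curated CSV records, as in the original workflow's manual step.
- No moisture-basis conversion; mixed-basis entries are only flagged.
- Live PubMed/PubChem modes are best-effort and unexercised by the test
  suite; offline fixtures are the supported path.
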