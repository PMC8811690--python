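# Methods

## Pipeline

The unit of analysis is a *concept record*: a unique identifier, a preferred
name, a source-vocabulary code, and zero or more semantic-type labels.
Several query exports (JSON array or JSON-lines; configurable key mapping,
default `ui`/`name`/`rootSource`/`semanticTypes`) are merged in listed order
and deduplicated on the concept identifier alone, keeping the first
occurrence. Names and source codes are not part of the duplicate key:
overlapping keyword queries retrieve the same concept under the same
identifier, which is exactly the duplication the step removes. Deduplicated
records are partitioned by verbatim source-vocabulary code.

## Tokenization model

A *word* is a maximal run of letters or digits (`[A-Za-z0-9]+`), so hyphens,
slashes and parentheses split tokens ("Intensity-modulated" → two words).
Tokens are lowercased before counting — density measures vocabulary reuse,
not casing. Numeric tokens count as words by default because procedure-coding
names are rich in numerals and carry real lexical mass; the flag
`keep_numeric_tokens=False` drops them. Stop words are removed before every
count; the packaged list is the standard 179-entry English list, and both the
list (`stopwords: builtin:english | file:<path>`) and the token pattern are
config inputs whose provenance is written into every report header. No
stemming, lemmatization or spelling normalization is performed.

Concept lengths are counted on post-stop-word tokens, consistent with all
word counts being taken after stop-word removal (this is also what makes a
minimal length of 1 attainable for names like "Radiotherapy of the brain"
reduced to multi-word forms elsewhere).

## Per-vocabulary and corpus statistics

For one vocabulary: `total_words` = Σ concept lengths, `unique_words` =
|distinct tokens|, `lexical_density = unique_words / total_words` stored at
full precision. A vocabulary whose names are all stop words yields a
*degenerate* profile (`total_words = 0`, density `None`, a logged warning) —
never a silent 0/0. Length statistics are over per-concept lengths; the
median of an even count is the mean of the two central values (the packaged
reference table has 35 rows, so either convention agrees with it).

Corpus totals add per-vocabulary totals; corpus unique words are the size of
the union of per-vocabulary token sets, so
`max(per-vocab unique) ≤ corpus unique ≤ Σ per-vocab unique`. The propagation
index of a word counts vocabularies whose token set contains it; the number
of propagation entries equals the corpus unique-word count by construction,
and the entries are sorted by descending index, then alphabetically.

Concentration sums the `k` largest vocabulary sizes and reports their share
of all concepts. Semantic-type distributions count, by default, *every* label
a concept carries (percentages may then sum above 100); `mode="first"`
restricts to the first-listed label. Metadata summaries tabulate author
country category (US / international organization / AU / NL / UK / other),
free vs. restricted license, and update recency
(`last_update_year ≥ reference_year − window + 1`, window defaulting to 5
years with a configurable reference year; unknown years never count as
recent).

## Rounding

All rounding is half-up and applied only at report time: per-vocabulary
density to 1 decimal, corpus density to 2 decimals, concept shares to 2
decimals, metadata shares to integer percent, length columns to the nearest
integer. Integer-count ratios are formed in decimal arithmetic so values at
the rounding boundary (e.g. 16/35 → 46%) do not depend on float
representation. Raw counts are always written beside percentages.

A note on the density direction: the ratio is defined here as
unique/total, which keeps it in [0, 1] and matches every row of the packaged
reference table (e.g. 132/265 → 0.5; 406/1420 → 0.3; 175/50682 → 0.0).

## Synthetic corpus generator

The generator emulates the statistical shape of a licensed metathesaurus
extract without reproducing any licensed content:

* **Skewed vocabulary sizes.** The default (reference-shaped) spec has 35
  vocabularies whose concept counts replay the audited margins: top five
  5479/326/142/115/95 (94.59% of 6509), thirty small vocabularies summing to
  352, overall per-vocabulary median 5, range 1–5479. The thirty small
  counts and the 28 minority semantic-type counts (sum 387 beside the 6122
  procedure-typed concepts, 29 types in total) are not published
  individually; fixed values satisfying the published margins were chosen
  once and are part of the spec.
* **Names** are space-joined draws from a per-vocabulary pool of synthetic
  letter–digit tokens; pool sizes and length ranges in the default spec are
  taken from the reference table's unique-word and length columns. Content
  words are guaranteed absent from the stop list, so the injected stop-word
  rate (default 0.25 per content word) is the only source of stop-word mass
  and expected post-stop counts are exact. A corpus-level shared pool
  (default 40 words, drawn with probability 0.3) produces propagation
  indices above 1.
* **Duplicates.** `round(duplicate_fraction × n_unique)` uniformly chosen
  records are re-emitted verbatim (same id, same name) at random later
  stream positions — mirroring overlapping-query retrieval. The default
  fraction 58/6509 injects exactly 58, so a 6567-record export deduplicates
  to 6509.
* **Seed contract.** All randomness flows from `SyntheticSpec.seed` through
  a single `random.Random`; identical specs give identical corpora.
* **Ground truth** (per-vocabulary totals, uniques, lengths; duplicate and
  type counts) is bookkept during generation and serves as the oracle the
  measurement pipeline is tested against.

What the generator does **not** emulate: linguistically realistic clinical
names, natural word-frequency laws, multi-label semantic typing, or
correlations between a vocabulary's metadata and its lexical shape (the
synthetic metadata table is faithful only in its margins — 25/6/2/1/1
country counts, 16 free / 19 restricted, 20 of 35 recently updated, 29
distinct authors). Tests passing on synthetic corpora therefore demonstrate
correctness of the counting, deduplication and aggregation machinery, not
fidelity to any particular real extract, whose totals additionally depend on
the exact stop list and tokenizer of the tool that produced them.

## Problem sizes and verification

The test suite checks the pipeline against two independent oracles: a
brute-force recomputation (own inline tokenizer, naive nested-loop distinct
counting) on 200 randomized corpora of ≤10 vocabularies × ≤20 concepts, and
the generator's ground truth on the full reference-shaped corpus (6567
records). Summary statistics are additionally checked against the packaged
35-row reference table and the printed count arithmetic (density 1048/56219
→ 0.02; shares 6157/6509 → 94.59%, 6122/6509 → 94.05%, 25/35 → 71%,
16/35 → 46%, 20/35 → 57%). The whole suite runs in a few seconds on one CPU.

## Known limitations

* The exact stop-word list and tokenizer options of any given published
  audit are typically unstated, so absolute corpus totals are not
  bit-reproducible across toolkits; ratios and rank statistics are robust.
* Deduplication assumes identifier-level duplication; two distinct
  identifiers naming the same clinical notion are out of scope (no semantic
  similarity).
* The live-export adapter for terminology services is deliberately absent:
  inputs are files, and authentication/scraping is a non-goal.
* English-only: the stop list and the token pattern assume English ASCII
  content; accented characters split tokens under the default pattern.
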