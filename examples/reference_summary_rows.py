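"""Recompute the reference table's summary rows.

Loads the packaged 35-row vocabulary-properties table (word counts,
lexical density, concept-length statistics per source vocabulary) and
recomputes its Median / Minimal / Maximal rows, plus the corpus-level
density from the printed word totals.  The medians characterize the
typical vocabulary: ~25 words in total, 19 of them distinct (density
0.7), longest concept 8 words.
"""
from termlex import corpus_report, lexical_metrics, synthetic_data
from termlex._rounding import round_half_up

profiles = synthetic_data.reference_profiles()
summaries = corpus_report.summarize_profiles(profiles)

print(f"{len(profiles)} source vocabularies")
for column, s in summaries.items():
    print(f"  {column:16s} median {s.median:8g}   range {s.min:g}-{s.max:g}")

total = sum(p.total_words for p in profiles)
density = lexical_metrics.lexical_density(total, 1048)
print(f"\ncorpus: {total} words, 1048 unique -> density {round_half_up(density, 2)}")
# a corpus density near zero reflects one huge procedure-coding
# vocabulary recombining a 175-word pool into ~50k concept names
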