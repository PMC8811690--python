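"""Profile a small hand-written concept export.

Builds a six-concept JSON export spanning three vocabularies, runs
ingest (parse -> merge -> dedup -> group) and the lexical profiler, and
prints the per-vocabulary table.  Lexical density is distinct words /
total words after stop-word removal: 1.0 means no word is reused within
the vocabulary's names.
"""
import json

from termlex import corpus_report, ingest

EXPORT = json.dumps(
    [
        {"ui": "C1", "name": "Radiation therapy of brain", "rootSource": "MTH"},
        {"ui": "C2", "name": "Radiation therapy of spine", "rootSource": "MTH"},
        {"ui": "C3", "name": "Intensity-modulated radiation therapy", "rootSource": "NCI"},
        {"ui": "C4", "name": "Proton beam radiation therapy", "rootSource": "NCI"},
        {"ui": "C2", "name": "Radiation therapy of spine", "rootSource": "MTH"},
        {"ui": "C5", "name": "Radiotherapy", "rootSource": "MSH"},
    ]
)

export = ingest.parse_export(EXPORT, query_label="radiation therapy")
records = ingest.deduplicate(export)
print(f"{len(export.records)} records -> {len(records)} unique concepts")

groups = ingest.group_by_vocab(records)
profiles, corpus = corpus_report.build_corpus_profile(groups)
print(corpus_report.render_profile_table(profiles, corpus.column_summaries))

print("most propagated words (word, vocabularies containing it):")
for entry in corpus.propagation[:3]:
    print(f"  {entry.word}: {entry.n_vocabularies}")
# 'radiation' and 'therapy' appear in all vocabularies that reuse them;
# a propagation index of 1 marks a word unique to one vocabulary.
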