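"""Corpus-level aggregation and report writing.

Aggregates per-vocabulary lexical profiles into summary rows (median /
min / max per metric column), concept-concentration statistics,
semantic-type distributions and metadata tabulations, and renders a
vocabulary-properties table with its three summary rows.

Report rounding (half-up): word counts as integers, per-vocabulary
density to 1 decimal, corpus density to 2 decimals, length columns to
the nearest integer, concept shares to 2 decimals, metadata shares to
integer percent.  Full precision is kept internally; rounding happens
only at report time.
"""
from __future__ import annotations

import statistics
from collections import Counter
from pathlib import Path
from typing import Mapping, Sequence

from ._rounding import percent, round_half_up
from .lexical_metrics import (
    TokenizationConfig,
    build_profiles,
    corpus_lexical_totals,
    vocab_token_sets,
    word_propagation,
)
from .types import (
    COUNTRY_CATEGORIES,
    LICENSE_CLASSES,
    METRIC_COLUMNS,
    ColumnSummary,
    ConceptRecord,
    CorpusProfile,
    MetadataSummary,
    SemanticTypeCount,
    SemanticTypeDistribution,
    VocabularyMetadata,
    VocabularyProfile,
)


def summarize_profiles(
    profiles: Sequence[VocabularyProfile],
) -> dict[str, ColumnSummary]:
    """Median / min / max of each metric column across vocabularies.

    The median of an even number of values is the mean of the two
    central ones.  Degenerate profiles (density ``None``) are excluded
    from the density column only.
    """
    if not profiles:
        raise ValueError("summarize_profiles requires at least one profile")
    out: dict[str, ColumnSummary] = {}
    for column in METRIC_COLUMNS:
        values = [p.metric(column) for p in profiles]
        values = [v for v in values if v is not None]
        if not values:
            continue
        out[column] = ColumnSummary(
            median=float(statistics.median(values)),
            min=float(min(values)),
            max=float(max(values)),
        )
    return out


def concentration(
    concept_counts_by_vocab: Mapping[str, int], k: int
) -> tuple[int, float]:
    """Concepts held by the ``k`` largest vocabularies and their share.

    Returns ``(top_k_count, share_percent)`` with the share as a
    percentage of all concepts, half-up to 2 decimals.  ``k = 0`` yields
    ``(0, 0.0)``.
    """
    n = len(concept_counts_by_vocab)
    if k < 0 or k > n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if k == 0:
        return 0, 0.0
    sizes = sorted(concept_counts_by_vocab.values(), reverse=True)
    top = sum(sizes[:k])
    total = sum(sizes)
    return top, percent(top, total, ndigits=2)


def semantic_distribution(
    records: Sequence[ConceptRecord], mode: str = "all"
) -> SemanticTypeDistribution:
    """Distribution of semantic-type labels over deduplicated concepts.

    ``mode="all"`` (default) counts every label a concept carries, so
    percentages may sum above 100; ``mode="first"`` counts only the
    first-listed label.  Percentages are against the concept count,
    half-up to 2 decimals.  Entries are sorted by descending count, then
    label.
    """
    if mode not in ("all", "first"):
        raise ValueError(f"mode must be 'all' or 'first', got {mode!r}")
    counts: Counter[str] = Counter()
    for record in records:
        labels = record.semantic_types
        if mode == "first":
            labels = labels[:1]
        for label in labels:
            counts[label] += 1
    n = len(records)
    entries = [
        SemanticTypeCount(label=label, count=c, percent=percent(c, n, 2) if n else 0.0)
        for label, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return SemanticTypeDistribution(entries=entries, n_types=len(counts), n_concepts=n)


def summarize_metadata(
    meta: Sequence[VocabularyMetadata],
    reference_year: int,
    window: int = 5,
) -> MetadataSummary:
    """Counts and integer percentages over vocabulary metadata.

    A vocabulary counts as recently updated when
    ``last_update_year >= reference_year - window + 1`` (unknown years
    never do).  Percentages round half-up individually, with raw counts
    reported beside them so totals remain auditable.
    """
    if not meta:
        raise ValueError("summarize_metadata requires at least one record")
    n = len(meta)
    country_counts = {c: 0 for c in sorted(COUNTRY_CATEGORIES)}
    license_counts = {c: 0 for c in sorted(LICENSE_CLASSES)}
    n_recent = 0
    cutoff = reference_year - window + 1
    for m in meta:
        country_counts[m.country_category] += 1
        license_counts[m.license_class] += 1
        if m.last_update_year is not None and m.last_update_year >= cutoff:
            n_recent += 1
    return MetadataSummary(
        n_vocabularies=n,
        country_counts=country_counts,
        country_percents={c: percent(v, n) for c, v in country_counts.items()},
        license_counts=license_counts,
        license_percents={c: percent(v, n) for c, v in license_counts.items()},
        n_recent=n_recent,
        percent_recent=percent(n_recent, n),
        reference_year=reference_year,
        window=window,
    )


def build_corpus_profile(
    records_by_vocab: Mapping[str, Sequence[ConceptRecord]],
    config: TokenizationConfig | None = None,
) -> tuple[list[VocabularyProfile], CorpusProfile]:
    """Run the full lexical aggregation for a grouped, deduplicated corpus."""
    config = config or TokenizationConfig()
    profiles = build_profiles(records_by_vocab, config)
    total, unique = corpus_lexical_totals(records_by_vocab, config)
    propagation = word_propagation(vocab_token_sets(records_by_vocab, config))
    corpus = CorpusProfile(
        n_vocabularies=len(profiles),
        n_concepts=sum(len(g) for g in records_by_vocab.values()),
        corpus_total_words=total,
        corpus_unique_words=unique,
        corpus_density=(unique / total) if total else None,
        column_summaries=summarize_profiles(profiles),
        propagation=propagation,
        n_words_unique_to_one_vocab=sum(
            1 for e in propagation if e.n_vocabularies == 1
        ),
    )
    return profiles, corpus


# ---------------------------------------------------------------------------
# report rendering


_SEPARATORS = {"tsv": "\t", "csv": ","}

REPORT_COLUMNS = (
    "vocabulary",
    "total_words",
    "unique_words",
    "lexical_density",
    "avg_len",
    "median_len",
    "max_len",
    "min_len",
)


def _fmt_row(profile_values: Mapping[str, float | None]) -> list[str]:
    """Apply report rounding to one row of metric values."""
    density = profile_values["lexical_density"]
    return [
        str(int(round_half_up(profile_values["total_words"]))),
        str(int(round_half_up(profile_values["unique_words"]))),
        "NA" if density is None else f"{round_half_up(density, 1):.1f}",
        str(int(round_half_up(profile_values["avg_len"]))),
        str(int(round_half_up(profile_values["median_len"]))),
        str(int(round_half_up(profile_values["max_len"]))),
        str(int(round_half_up(profile_values["min_len"]))),
    ]


def render_profile_table(
    profiles: Sequence[VocabularyProfile],
    summaries: Mapping[str, ColumnSummary] | None = None,
    fmt: str = "tsv",
    config: TokenizationConfig | None = None,
) -> str:
    """Render the vocabulary-properties table as TSV/CSV/Markdown text.

    One data row per vocabulary followed by Median / Minimal / Maximal
    summary rows.  A header comment records the tokenization provenance.
    Output is deterministic: identical inputs give identical bytes.
    """
    if not profiles:
        raise ValueError("render_profile_table requires at least one profile")
    if summaries is None:
        summaries = summarize_profiles(profiles)
    config = config or TokenizationConfig()

    header_comment = (
        f"# tokenization: pattern={config.token_pattern!r} "
        f"lowercase={config.lowercase} numeric={config.keep_numeric_tokens} "
        f"stopwords={config.stopword_source} (n={len(config.stopwords)})"
    )
    rows: list[list[str]] = []
    for p in profiles:
        rows.append([p.source_vocab] + _fmt_row({c: p.metric(c) for c in METRIC_COLUMNS}))
    for label, attr in (("Median", "median"), ("Minimal", "min"), ("Maximal", "max")):
        values = {c: getattr(summaries[c], attr) for c in METRIC_COLUMNS}
        rows.append([label] + _fmt_row(values))

    if fmt in _SEPARATORS:
        sep = _SEPARATORS[fmt]
        lines = [header_comment, sep.join(REPORT_COLUMNS)]
        lines += [sep.join(r) for r in rows]
        return "\n".join(lines) + "\n"
    if fmt == "md":
        lines = [header_comment, "| " + " | ".join(REPORT_COLUMNS) + " |"]
        lines.append("|" + "|".join(" --- " for _ in REPORT_COLUMNS) + "|")
        lines += ["| " + " | ".join(r) + " |" for r in rows]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}; expected tsv, csv, or md")


def write_profile_report(
    profiles: Sequence[VocabularyProfile],
    corpus: CorpusProfile | None,
    path: str | Path,
    fmt: str = "tsv",
    config: TokenizationConfig | None = None,
) -> Path:
    """Write the rendered vocabulary-properties table to ``path``."""
    summaries = corpus.column_summaries if corpus is not None else None
    text = render_profile_table(profiles, summaries, fmt=fmt, config=config)
    path = Path(path)
    path.write_text(text, encoding="utf-8")
    return path


def write_propagation(entries, path: str | Path) -> Path:
    """Write the word-propagation table as TSV (word, n_vocabularies)."""
    lines = ["word\tn_vocabularies"]
    lines += [f"{e.word}\t{e.n_vocabularies}" for e in entries]
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_semantic_distribution(
    dist: SemanticTypeDistribution, path: str | Path
) -> Path:
    """Write the semantic-type distribution as TSV."""
    lines = ["semantic_type\tn_concepts\tpercent"]
    lines += [f"{e.label}\t{e.count}\t{e.percent:.2f}" for e in dist.entries]
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_metadata_summary(summary: MetadataSummary, path: str | Path) -> Path:
    """Write the metadata tabulation as TSV (counts beside percentages)."""
    lines = ["dimension\tcategory\tcount\tpercent"]
    for cat, count in summary.country_counts.items():
        lines.append(
            f"country\t{cat}\t{count}\t{summary.country_percents[cat]:.0f}"
        )
    for cat, count in summary.license_counts.items():
        lines.append(
            f"license\t{cat}\t{count}\t{summary.license_percents[cat]:.0f}"
        )
    lines.append(
        f"updated_within_{summary.window}y\tyes\t{summary.n_recent}\t"
        f"{summary.percent_recent:.0f}"
    )
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
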