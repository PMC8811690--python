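"""Core domain types.

A *concept* is a unit of meaning with a unique identifier, a preferred
name, and a source vocabulary (the terminology that authored it, e.g.
SNOMED CT or ICD-10-PCS).  Concepts optionally carry one or more
semantic-type labels — high-level categories such as "Therapeutic or
Preventive Procedure".

A *vocabulary profile* holds the per-vocabulary lexical statistics
computed from concept names after tokenization and stop-word removal:
total word count, distinct word count, lexical density (distinct/total),
and concept-length statistics in words.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

#: Valid author-country categories for vocabulary metadata.
COUNTRY_CATEGORIES = frozenset({"US", "international_org", "AU", "NL", "UK", "other"})

#: Valid license classes: free (no use restriction) vs restricted.
LICENSE_CLASSES = frozenset({"free", "restricted"})

#: The seven per-vocabulary metric columns, in report order.
METRIC_COLUMNS = (
    "total_words",
    "unique_words",
    "lexical_density",
    "avg_len",
    "median_len",
    "max_len",
    "min_len",
)


@dataclass(frozen=True)
class ConceptRecord:
    """One terminology concept.

    Attributes
    ----------
    concept_id:
        Opaque identifier, unique within a deduplicated collection.
    name:
        The preferred name string (non-empty).
    source_vocab:
        Code of the vocabulary that authored the concept (non-empty).
    semantic_types:
        Zero or more semantic-type labels.
    """

    concept_id: str
    name: str
    source_vocab: str
    semantic_types: tuple[str, ...] = ()


@dataclass
class ConceptExport:
    """An ordered list of concept records as retrieved by one query.

    Duplicates are permitted; record order is preserved from the input.
    ``query_label`` is a provenance tag for the search term that produced
    the export.
    """

    records: list[ConceptRecord]
    query_label: str = ""

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.records)


@dataclass(frozen=True)
class VocabularyMetadata:
    """Provenance metadata for one source vocabulary.

    ``last_update_year`` is ``None`` when unknown.
    """

    source_vocab: str
    author: str
    country_category: str
    license_class: str
    last_update_year: Optional[int] = None

    def __post_init__(self) -> None:
        if self.country_category not in COUNTRY_CATEGORIES:
            raise ValueError(
                f"unknown country_category {self.country_category!r}; "
                f"expected one of {sorted(COUNTRY_CATEGORIES)}"
            )
        if self.license_class not in LICENSE_CLASSES:
            raise ValueError(
                f"unknown license_class {self.license_class!r}; "
                f"expected one of {sorted(LICENSE_CLASSES)}"
            )


@dataclass(frozen=True)
class VocabularyProfile:
    """Per-vocabulary lexical metrics.

    ``lexical_density`` is ``unique_words / total_words`` stored at full
    precision, or ``None`` for a degenerate vocabulary whose names are all
    empty after stop-word removal.  ``n_concepts`` may be ``None`` for
    profiles taken from published tables that do not print concept counts.
    """

    source_vocab: str
    total_words: int
    unique_words: int
    lexical_density: Optional[float]
    avg_len: float
    median_len: float
    max_len: int
    min_len: int
    n_concepts: Optional[int] = None

    def metric(self, column: str) -> Optional[float]:
        """Return one of the seven metric column values by name."""
        if column not in METRIC_COLUMNS:
            raise KeyError(column)
        return getattr(self, column)


@dataclass(frozen=True)
class PropagationEntry:
    """How widely one word propagates: the number of distinct source
    vocabularies whose (post-stop-word) token set contains it."""

    word: str
    n_vocabularies: int


@dataclass(frozen=True)
class ColumnSummary:
    """Median / min / max of one metric column across vocabularies."""

    median: float
    min: float
    max: float


@dataclass
class CorpusProfile:
    """Corpus-level aggregation over all vocabulary profiles."""

    n_vocabularies: int
    n_concepts: int
    corpus_total_words: int
    corpus_unique_words: int
    corpus_density: Optional[float]
    column_summaries: dict[str, ColumnSummary]
    propagation: list[PropagationEntry] = field(default_factory=list)
    n_words_unique_to_one_vocab: int = 0


@dataclass(frozen=True)
class SemanticTypeCount:
    """One semantic-type label with its concept count and percentage."""

    label: str
    count: int
    percent: float


@dataclass
class SemanticTypeDistribution:
    """Distribution of semantic-type labels over a deduplicated corpus.

    A concept carrying multiple labels increments each, so percentages
    (computed against ``n_concepts``) may sum above 100.
    """

    entries: list[SemanticTypeCount]
    n_types: int
    n_concepts: int


@dataclass
class MetadataSummary:
    """Counts and integer percentages over vocabulary metadata.

    Country categories and license classes each partition the
    vocabularies, so their counts sum to ``n_vocabularies``.  ``n_recent``
    counts vocabularies updated within the recency window
    ``[reference_year - window + 1, reference_year]``.
    """

    n_vocabularies: int
    country_counts: dict[str, int]
    country_percents: dict[str, float]
    license_counts: dict[str, int]
    license_percents: dict[str, float]
    n_recent: int
    percent_recent: float
    reference_year: int
    window: int
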