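"""Seeded synthetic concept corpora with known ground truth.

Licensed terminology extracts cannot be redistributed, so every pipeline
stage is exercised on generated corpora instead.  The generator emulates
the statistical shape of a real multi-vocabulary concept extract:

* a highly skewed concept-count distribution across vocabularies (a
  procedure-coding system can hold more than 80% of all concepts),
* concept names assembled from small per-vocabulary word pools with
  heavy word reuse (low lexical density) or no reuse (density 1.0),
* interspersed stop words at a configurable rate,
* a small fraction of duplicate records re-emitted under already-used
  concept identifiers, mirroring retrieval by overlapping queries,
* optional sharing of words across vocabularies through a corpus-level
  shared pool (this is what gives propagation indices above 1).

Content words are synthetic letter–digit hybrids guaranteed absent from
the stop list, so the injected stop-word rate is the only source of
stop-word mass and expected post-stop counts are exact.  All randomness
flows from ``SyntheticSpec.seed`` through a single ``random.Random``
generator: identical specs produce identical corpora.

``GroundTruth`` carries the exact per-vocabulary lexical statistics
implied by the generated names, computed during generation; it is the
oracle the analysis pipeline is checked against.
"""
from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, field, replace
from random import Random
from typing import Optional, Sequence

from .types import ConceptExport, ConceptRecord, VocabularyMetadata, VocabularyProfile

#: Stop words interspersed into generated names (all on the built-in list).
STOPWORD_FILLERS = ("of", "the", "in", "with", "for", "and", "to", "on")

#: Semantic-type label most procedure-heavy vocabularies carry.
PROCEDURE_TYPE = "Therapeutic or Preventive Procedure"


@dataclass(frozen=True)
class VocabularyBlock:
    """Generator parameters for one synthetic vocabulary.

    ``stopword_rate`` is the per-content-word probability of inserting a
    stop word after it, so the expected number of injected stop words in
    a name is ``rate × content length``.  With
    ``sample_without_replacement`` each name draws distinct pool words
    (requires ``word_pool_size >= length_max``), which forces density 1.0
    for a single-concept vocabulary.  ``shared_word_rate`` is the
    probability that a content word is drawn from the corpus-level shared
    pool instead of the vocabulary's own pool.
    """

    code: str
    n_concepts: int
    word_pool_size: int
    length_min: int
    length_max: int
    length_weights: Optional[tuple[float, ...]] = None
    stopword_rate: float = 0.0
    sample_without_replacement: bool = False
    shared_word_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_concepts < 1:
            raise ValueError("n_concepts must be >= 1")
        if self.word_pool_size < 1:
            raise ValueError("word_pool_size must be >= 1")
        if not 1 <= self.length_min <= self.length_max:
            raise ValueError("need 1 <= length_min <= length_max")
        if not 0.0 <= self.stopword_rate < 1.0:
            raise ValueError("stopword_rate must be in [0, 1)")
        if not 0.0 <= self.shared_word_rate <= 1.0:
            raise ValueError("shared_word_rate must be in [0, 1]")
        if self.length_weights is not None:
            n_lengths = self.length_max - self.length_min + 1
            if len(self.length_weights) != n_lengths:
                raise ValueError(
                    f"length_weights needs {n_lengths} entries, "
                    f"got {len(self.length_weights)}"
                )
        if self.sample_without_replacement and self.word_pool_size < self.length_max:
            raise ValueError(
                "sampling without replacement requires word_pool_size >= length_max"
            )


@dataclass(frozen=True)
class MetadataModel:
    """Sampling weights for synthetic vocabulary metadata."""

    country_weights: dict[str, float] = field(
        default_factory=lambda: {
            "US": 0.71,
            "international_org": 0.17,
            "AU": 0.06,
            "NL": 0.03,
            "UK": 0.03,
        }
    )
    free_prob: float = 0.46
    year_min: int = 2000
    year_max: int = 2020
    unknown_year_prob: float = 0.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Full corpus-generation recipe.

    ``duplicate_fraction`` re-emits ``round(fraction × n_unique)``
    verbatim copies of already-generated records at random later stream
    positions.  ``semantic_type_plan`` assigns exact per-label concept
    counts (must sum to the unique concept count); otherwise each concept
    draws one label from ``semantic_type_weights``.
    """

    seed: int
    vocabularies: tuple[VocabularyBlock, ...]
    duplicate_fraction: float = 0.0
    shared_pool_size: int = 0
    metadata_model: MetadataModel = field(default_factory=MetadataModel)
    semantic_type_plan: Optional[dict[str, int]] = None
    semantic_type_weights: dict[str, float] = field(
        default_factory=lambda: {PROCEDURE_TYPE: 1.0}
    )

    def __post_init__(self) -> None:
        if not self.vocabularies:
            raise ValueError("spec needs at least one vocabulary block")
        if not 0.0 <= self.duplicate_fraction < 1.0:
            raise ValueError("duplicate_fraction must be in [0, 1)")
        codes = [b.code for b in self.vocabularies]
        if len(set(codes)) != len(codes):
            raise ValueError("vocabulary codes must be distinct")
        if self.semantic_type_plan is not None:
            n_unique = sum(b.n_concepts for b in self.vocabularies)
            planned = sum(self.semantic_type_plan.values())
            if planned != n_unique:
                raise ValueError(
                    f"semantic_type_plan sums to {planned}, corpus has {n_unique}"
                )


@dataclass
class GroundTruth:
    """Exact statistics of a generated corpus, kept during generation."""

    profiles: dict[str, VocabularyProfile]
    concept_counts: dict[str, int]
    n_unique: int
    n_records: int
    n_duplicates: int
    semantic_type_counts: dict[str, int]


def _word_pool(code: str, size: int) -> list[str]:
    prefix = re.sub(r"[^a-z0-9]", "", code.lower()) or "v"
    return [f"{prefix}w{i}" for i in range(size)]


def _shared_pool(size: int) -> list[str]:
    return [f"sharedw{i}" for i in range(size)]


def generate_vocabulary(
    block: VocabularyBlock,
    rng: Random,
    id_start: int = 0,
    shared_pool: Sequence[str] = (),
) -> tuple[list[ConceptRecord], VocabularyProfile]:
    """Generate one vocabulary's concepts plus its exact lexical profile.

    Draws flow from the supplied seed stream ``rng``; calling with an
    identically seeded generator reproduces the records byte-for-byte.
    The returned profile is bookkeeping computed from the drawn content
    words, not a re-tokenization.
    """
    pool = _word_pool(block.code, block.word_pool_size)
    lengths = list(range(block.length_min, block.length_max + 1))
    records: list[ConceptRecord] = []
    seen_words: set[str] = set()
    content_lengths: list[int] = []

    for i in range(block.n_concepts):
        if block.length_weights is not None:
            n_words = rng.choices(lengths, weights=block.length_weights, k=1)[0]
        else:
            n_words = rng.randint(block.length_min, block.length_max)
        if block.sample_without_replacement:
            words = rng.sample(pool, n_words)
        else:
            words = []
            for _ in range(n_words):
                if shared_pool and rng.random() < block.shared_word_rate:
                    words.append(rng.choice(shared_pool))
                else:
                    words.append(rng.choice(pool))
        parts: list[str] = []
        for w in words:
            parts.append(w)
            if block.stopword_rate and rng.random() < block.stopword_rate:
                parts.append(rng.choice(STOPWORD_FILLERS))
        name = " ".join(parts)
        name = name[0].upper() + name[1:]
        records.append(
            ConceptRecord(
                concept_id=f"C{id_start + i:07d}",
                name=name,
                source_vocab=block.code,
            )
        )
        seen_words.update(words)
        content_lengths.append(n_words)

    total = sum(content_lengths)
    profile = VocabularyProfile(
        source_vocab=block.code,
        n_concepts=block.n_concepts,
        total_words=total,
        unique_words=len(seen_words),
        lexical_density=len(seen_words) / total if total else None,
        avg_len=statistics.fmean(content_lengths),
        median_len=float(statistics.median(content_lengths)),
        max_len=max(content_lengths),
        min_len=min(content_lengths),
    )
    return records, profile


def _assign_semantic_types(
    records: list[ConceptRecord], spec: SyntheticSpec, rng: Random
) -> tuple[list[ConceptRecord], dict[str, int]]:
    if spec.semantic_type_plan is not None:
        labels: list[str] = []
        for label, count in spec.semantic_type_plan.items():
            labels.extend([label] * count)
        rng.shuffle(labels)
    else:
        pool = list(spec.semantic_type_weights)
        weights = [spec.semantic_type_weights[p] for p in pool]
        labels = rng.choices(pool, weights=weights, k=len(records))
    counts: dict[str, int] = {}
    labeled = []
    for record, label in zip(records, labels):
        labeled.append(replace(record, semantic_types=(label,)))
        counts[label] = counts.get(label, 0) + 1
    return labeled, counts


def _generate_metadata(
    codes: Sequence[str], model: MetadataModel, rng: Random
) -> list[VocabularyMetadata]:
    countries = list(model.country_weights)
    weights = [model.country_weights[c] for c in countries]
    out = []
    for i, code in enumerate(codes):
        year: Optional[int]
        if model.unknown_year_prob and rng.random() < model.unknown_year_prob:
            year = None
        else:
            year = rng.randint(model.year_min, model.year_max)
        out.append(
            VocabularyMetadata(
                source_vocab=code,
                author=f"Synthetic author {i + 1:02d}",
                country_category=rng.choices(countries, weights=weights, k=1)[0],
                license_class="free" if rng.random() < model.free_prob else "restricted",
                last_update_year=year,
            )
        )
    return out


def generate_corpus(
    spec: SyntheticSpec,
) -> tuple[ConceptExport, list[VocabularyMetadata], GroundTruth]:
    """Generate a full synthetic concept export with exact ground truth.

    Vocabularies are generated in listed order; duplicates are then
    uniformly chosen earlier records re-emitted verbatim (same id, same
    name) at a random later stream position, so deduplication recovers
    exactly the unique records.
    """
    rng = Random(spec.seed)
    shared = _shared_pool(spec.shared_pool_size)

    records: list[ConceptRecord] = []
    profiles: dict[str, VocabularyProfile] = {}
    concept_counts: dict[str, int] = {}
    for block in spec.vocabularies:
        vocab_records, profile = generate_vocabulary(
            block, rng, id_start=len(records), shared_pool=shared
        )
        records.extend(vocab_records)
        profiles[block.code] = profile
        concept_counts[block.code] = block.n_concepts

    records, type_counts = _assign_semantic_types(records, spec, rng)
    n_unique = len(records)

    n_dup = round(spec.duplicate_fraction * n_unique)
    stream = list(records)
    for _ in range(n_dup):
        j = rng.randrange(len(stream))
        stream.insert(rng.randrange(j + 1, len(stream) + 1), stream[j])

    metadata = _generate_metadata(
        [b.code for b in spec.vocabularies], spec.metadata_model, rng
    )
    truth = GroundTruth(
        profiles=profiles,
        concept_counts=concept_counts,
        n_unique=n_unique,
        n_records=len(stream),
        n_duplicates=n_dup,
        semantic_type_counts=type_counts,
    )
    return ConceptExport(records=stream, query_label="synthetic"), metadata, truth


# ---------------------------------------------------------------------------
# packaged reference data and the default corpus shape


#: Published per-vocabulary lexical metrics for the 35 source vocabularies
#: holding radiation-therapy concepts in a large biomedical metathesaurus:
#: (code, total words, unique words, density, avg len, median len, max, min).
_REFERENCE_ROWS: tuple[tuple[str, int, int, float, float, float, int, int], ...] = (
    ("ATC", 5, 5, 1.0, 5, 5, 5, 5),
    ("CCS", 3, 3, 1.0, 3, 3, 3, 3),
    ("CHV", 3, 3, 1.0, 3, 3, 3, 3),
    ("ICD10AMAE", 12, 12, 1.0, 6, 6, 7, 5),
    ("ICD9CM", 7, 7, 1.0, 4, 4, 5, 2),
    ("MTHICD9", 9, 9, 1.0, 9, 9, 9, 9),
    ("NANDA-I", 4, 4, 1.0, 4, 4, 4, 4),
    ("NCI_CPTAC", 3, 3, 1.0, 3, 3, 3, 3),
    ("SNM", 7, 7, 1.0, 7, 7, 7, 7),
    ("PCDS", 9, 8, 0.9, 9, 9, 9, 9),
    ("NIC", 34, 30, 0.9, 11, 8, 18, 8),
    ("ICD10CM", 9, 7, 0.8, 5, 5, 5, 4),
    ("ALT", 25, 19, 0.8, 8, 8, 14, 3),
    ("ICD-10", 25, 19, 0.8, 6, 5, 14, 2),
    ("CCPSS", 7, 5, 0.7, 4, 4, 4, 3),
    ("ICNP", 6, 4, 0.7, 3, 3, 3, 3),
    ("PDQ", 27, 18, 0.7, 5, 6, 8, 3),
    ("ICD10AM", 29, 19, 0.7, 6, 6, 7, 4),
    ("ICPC2ICD10ENG", 19, 12, 0.6, 3, 2, 5, 2),
    ("MSH", 52, 32, 0.6, 3, 3, 4, 2),
    ("SPN", 24, 14, 0.6, 5, 5, 6, 4),
    ("CSP", 7, 4, 0.6, 4, 4, 4, 3),
    ("HCPCS", 97, 54, 0.6, 14, 13, 22, 10),
    ("SNMI", 71, 36, 0.5, 6, 7, 8, 5),
    ("MTH", 265, 132, 0.5, 4, 4, 23, 1),
    ("HL7V3.0", 46, 20, 0.4, 7, 6, 10, 4),
    ("NCI", 279, 115, 0.4, 4, 4, 14, 1),
    ("RCD", 61, 22, 0.4, 4, 3, 5, 3),
    ("MEDCIN", 488, 175, 0.4, 5, 5, 10, 2),
    ("UMD", 312, 97, 0.3, 5, 5, 9, 2),
    ("SNOMEDCT_US", 1420, 406, 0.3, 4, 4, 10, 2),
    ("LNC", 365, 96, 0.3, 8, 8, 19, 2),
    ("MDR", 409, 84, 0.2, 4, 4, 8, 2),
    ("CPT", 1398, 228, 0.2, 10, 9, 28, 3),
    ("ICD10PCS", 50682, 175, 0.0, 9, 9, 15, 2),
)

#: Concept counts of the five largest vocabularies in the same extract.
_TOP5_COUNTS: dict[str, int] = {
    "ICD10PCS": 5479,
    "SNOMEDCT_US": 326,
    "CPT": 142,
    "MDR": 115,
    "MEDCIN": 95,
}

#: Concept counts of the remaining 30 vocabularies (sum 352, corpus
#: median concept count 5, range 1-5479), assigned in reference-row order.
_SMALL_COUNTS = (
    76, 50, 40, 30, 25, 20, 15, 12, 10, 8, 6, 5, 5, 5, 5,
    5, 5, 4, 4, 3, 3, 3, 2, 2, 2, 2, 2, 1, 1, 1,
)

#: Concept counts per label for the 28 minority semantic types (sum 387).
_MINOR_TYPE_COUNTS = (
    60, 45, 38, 30, 27, 24, 21, 18, 16, 14, 12, 11, 10, 9,
    8, 7, 6, 6, 5, 4, 4, 3, 3, 2, 1, 1, 1, 1,
)

_MINOR_TYPE_LABELS = (
    "Medical Device",
    "Intellectual Product",
    "Health Care Activity",
    "Diagnostic Procedure",
    "Finding",
    "Disease or Syndrome",
    "Neoplastic Process",
    "Injury or Poisoning",
    "Pharmacologic Substance",
    "Biomedical Occupation or Discipline",
    "Organization",
    "Professional or Occupational Group",
    "Quantitative Concept",
    "Qualitative Concept",
    "Functional Concept",
    "Spatial Concept",
    "Temporal Concept",
    "Idea or Concept",
    "Activity",
    "Research Activity",
    "Laboratory Procedure",
    "Body Location or Region",
    "Body Part, Organ, or Organ Component",
    "Clinical Attribute",
    "Conceptual Entity",
    "Occupational Activity",
    "Phenomenon or Process",
    "Manufactured Object",
)


def reference_profiles() -> list[VocabularyProfile]:
    """The packaged 35-row vocabulary-properties reference table.

    Values are as printed in the source report (densities at 1 decimal,
    lengths at integer precision); per-vocabulary concept counts are not
    part of the table, so ``n_concepts`` is ``None``.
    """
    return [
        VocabularyProfile(
            source_vocab=code,
            total_words=total,
            unique_words=unique,
            lexical_density=density,
            avg_len=float(avg),
            median_len=float(median),
            max_len=max_len,
            min_len=min_len,
            n_concepts=None,
        )
        for code, total, unique, density, avg, median, max_len, min_len in _REFERENCE_ROWS
    ]


def reference_concept_counts() -> dict[str, int]:
    """Per-vocabulary concept counts of the reference corpus (sum 6509)."""
    counts = dict(_TOP5_COUNTS)
    small_iter = iter(_SMALL_COUNTS)
    for row in _REFERENCE_ROWS:
        if row[0] not in counts:
            counts[row[0]] = next(small_iter)
    return counts


def reference_corpus_spec(seed: int = 0) -> SyntheticSpec:
    """The default, reference-shaped corpus specification.

    35 vocabularies whose concept counts replay the observed skew (one
    procedure-coding vocabulary holding 84% of 6509 concepts, top five
    holding 94.59%), word pools and name-length ranges sized from the
    reference table, a duplicate fraction of 58/6509 so a merged export
    of 6567 records deduplicates to 6509, and a semantic-type plan in
    which 6122 of 6509 concepts (94.05%) are procedure-typed among 29
    types in total.
    """
    counts = reference_concept_counts()
    blocks = tuple(
        VocabularyBlock(
            code=code,
            n_concepts=counts[code],
            word_pool_size=unique,
            length_min=min_len,
            length_max=max_len,
            stopword_rate=0.25,
            shared_word_rate=0.3,
        )
        for code, _total, unique, _d, _a, _m, max_len, min_len in _REFERENCE_ROWS
    )
    plan = {PROCEDURE_TYPE: 6122}
    plan.update(dict(zip(_MINOR_TYPE_LABELS, _MINOR_TYPE_COUNTS)))
    return SyntheticSpec(
        seed=seed,
        vocabularies=blocks,
        duplicate_fraction=58 / 6509,
        shared_pool_size=40,
        semantic_type_plan=plan,
    )


def reference_metadata(reference_year: int = 2020) -> list[VocabularyMetadata]:
    """Synthetic metadata table with the observed marginal counts.

    Which vocabulary carries which attribute is synthetic; only the
    margins are faithful to the audited corpus: 25 US-registered authors,
    6 international organizations, 2 Australian, 1 Dutch and 1 British;
    16 vocabularies free of use restrictions and 19 restricted; 20 of 35
    updated within the five years before ``reference_year``; 29 distinct
    authors (one authoring four vocabularies, three authoring two each).
    """
    codes = [row[0] for row in _REFERENCE_ROWS]
    countries = ["US"] * 25 + ["international_org"] * 6 + ["AU"] * 2 + ["NL", "UK"]
    # 29 distinct authors over 35 vocabularies: 4 + 2 + 2 + 2 + 25 singles.
    authors = (
        ["Synthetic author 01"] * 4
        + ["Synthetic author 02"] * 2
        + ["Synthetic author 03"] * 2
        + ["Synthetic author 04"] * 2
        + [f"Synthetic author {i:02d}" for i in range(5, 30)]
    )
    out = []
    for i, code in enumerate(codes):
        recent = i < 20
        year = reference_year - (i % 5) if recent else reference_year - 6 - (i % 4)
        out.append(
            VocabularyMetadata(
                source_vocab=code,
                author=authors[i],
                country_category=countries[i],
                license_class="free" if i % 2 == 0 and i < 32 else "restricted",
                last_update_year=year,
            )
        )
    return out
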