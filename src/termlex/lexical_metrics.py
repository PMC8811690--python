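"""Tokenization, stop-word removal, and per-vocabulary lexical statistics.

The unit of analysis is the concept *name*.  Names are split into word
tokens (maximal runs of letters or digits by default, so hyphens,
slashes and parentheses all split), lowercased, and filtered against an
English stop-word list.  From the surviving tokens each vocabulary gets:

* ``total_words`` — tokens summed over all its concept names,
* ``unique_words`` — distinct tokens,
* ``lexical_density`` — ``unique_words / total_words``, a type–token
  ratio in [0, 1]: 1.0 means no word is ever reused; values near 0 mean
  a small word pool combinatorially recombined into many names,
* concept-length statistics (average, median, max, min) in words.

The *word propagation index* of a word is the number of vocabularies
whose token set contains it — a corpus-level measure of how widely a
word is shared across terminologies.
"""
from __future__ import annotations

import logging
import re
import statistics
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .errors import UndefinedDensityError
from .types import ConceptRecord, PropagationEntry, VocabularyProfile

logger = logging.getLogger(__name__)

#: Default token pattern: maximal runs of ASCII letters or digits.
DEFAULT_TOKEN_PATTERN = r"[A-Za-z0-9]+"

_NUMERIC = re.compile(r"[0-9]+\Z")


def builtin_stopwords() -> frozenset[str]:
    """The packaged English stop-word list (lowercase)."""
    text = (
        resources.files("termlex").joinpath("data/stopwords_en.txt").read_text("utf-8")
    )
    return frozenset(load_stopwords_text(text))


def load_stopwords_text(text: str) -> set[str]:
    """Parse a stop-word file: one word per line, ``#`` comments."""
    words = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line.lower())
    return words


@dataclass(frozen=True)
class TokenizationConfig:
    """How concept names are turned into countable words.

    Parameters
    ----------
    lowercase:
        Fold case before counting, so "Radiation" and "radiation" are the
        same word (density measures reuse, not casing).
    token_pattern:
        Regex whose non-overlapping matches are the tokens.
    stopwords:
        Lowercase words removed before any counting.  Defaults to the
        packaged English list.
    keep_numeric_tokens:
        Whether all-digit tokens count as words.  On by default: numerals
        are pervasive in procedure-coding names and carry lexical mass.
    stopword_source:
        Provenance string written into report headers.
    """

    lowercase: bool = True
    token_pattern: str = DEFAULT_TOKEN_PATTERN
    stopwords: frozenset[str] = field(default_factory=builtin_stopwords)
    keep_numeric_tokens: bool = True
    stopword_source: str = "builtin:english"

    def __post_init__(self) -> None:
        for word in self.stopwords:
            if word != word.lower():
                raise ValueError(f"stop-word entry not lowercase: {word!r}")
        object.__setattr__(self, "_regex", re.compile(self.token_pattern))

    @classmethod
    def from_dict(cls, cfg: Mapping[str, object]) -> "TokenizationConfig":
        """Build a config from a YAML-style mapping.

        ``stopwords`` may be ``builtin:english`` or ``file:<path>``.
        """
        kwargs: dict = {}
        if "lowercase" in cfg:
            kwargs["lowercase"] = bool(cfg["lowercase"])
        if "token_pattern" in cfg:
            kwargs["token_pattern"] = str(cfg["token_pattern"])
        if "keep_numeric_tokens" in cfg:
            kwargs["keep_numeric_tokens"] = bool(cfg["keep_numeric_tokens"])
        spec = str(cfg.get("stopwords", "builtin:english"))
        if spec == "builtin:english":
            kwargs["stopwords"] = builtin_stopwords()
        elif spec.startswith("file:"):
            path = spec[len("file:"):]
            with open(path, encoding="utf-8") as fh:
                kwargs["stopwords"] = frozenset(load_stopwords_text(fh.read()))
        else:
            raise ValueError(f"unknown stopwords source {spec!r}")
        kwargs["stopword_source"] = spec
        return cls(**kwargs)


def tokenize(name: str, config: TokenizationConfig | None = None) -> list[str]:
    """Split a concept name into word tokens (stop words NOT yet removed)."""
    config = config or _default_config()
    tokens = config._regex.findall(name)  # type: ignore[attr-defined]
    if config.lowercase:
        tokens = [t.lower() for t in tokens]
    if not config.keep_numeric_tokens:
        tokens = [t for t in tokens if not _NUMERIC.match(t)]
    return tokens


def remove_stopwords(
    tokens: Sequence[str], config: TokenizationConfig | None = None
) -> list[str]:
    """Drop stop-list members, preserving order of the rest."""
    config = config or _default_config()
    return [t for t in tokens if t not in config.stopwords]


def content_tokens(name: str, config: TokenizationConfig | None = None) -> list[str]:
    """Tokenize then remove stop words — the tokens all metrics count."""
    return remove_stopwords(tokenize(name, config), config)


def concept_length(name: str, config: TokenizationConfig | None = None) -> int:
    """Length of a concept name in post-stop-word tokens."""
    return len(content_tokens(name, config))


def lexical_density(total_words: int, unique_words: int) -> float:
    """Type–token ratio ``unique_words / total_words`` at full precision."""
    if total_words == 0:
        raise UndefinedDensityError("lexical density undefined for 0 total words")
    if not 0 <= unique_words <= total_words:
        raise ValueError(
            f"unique_words={unique_words} outside [0, total_words={total_words}]"
        )
    return unique_words / total_words


def vocab_profile(
    concepts: Sequence[ConceptRecord], config: TokenizationConfig | None = None
) -> VocabularyProfile:
    """Lexical profile of one vocabulary's concepts.

    All concepts must share one ``source_vocab``.  A vocabulary whose
    names are all empty after stop-word removal yields a degenerate
    profile with ``total_words = 0`` and ``lexical_density = None``
    (never a silent 0/0); a warning is logged.
    """
    if not concepts:
        raise ValueError("vocab_profile requires at least one concept")
    vocabs = {c.source_vocab for c in concepts}
    if len(vocabs) != 1:
        raise ValueError(f"concepts span multiple vocabularies: {sorted(vocabs)}")
    (code,) = vocabs

    config = config or _default_config()
    lengths: list[int] = []
    seen: set[str] = set()
    total = 0
    for concept in concepts:
        toks = content_tokens(concept.name, config)
        lengths.append(len(toks))
        total += len(toks)
        seen.update(toks)

    if total == 0:
        logger.warning(
            "vocabulary %s is degenerate: all names empty after stop-word removal",
            code,
        )
        density: float | None = None
    else:
        density = lexical_density(total, len(seen))

    return VocabularyProfile(
        source_vocab=code,
        n_concepts=len(concepts),
        total_words=total,
        unique_words=len(seen),
        lexical_density=density,
        avg_len=statistics.fmean(lengths),
        median_len=float(statistics.median(lengths)),
        max_len=max(lengths),
        min_len=min(lengths),
    )


def build_profiles(
    records_by_vocab: Mapping[str, Sequence[ConceptRecord]],
    config: TokenizationConfig | None = None,
) -> list[VocabularyProfile]:
    """Profile every vocabulary of a grouped corpus, in mapping order."""
    return [vocab_profile(group, config) for group in records_by_vocab.values()]


def vocab_token_sets(
    records_by_vocab: Mapping[str, Sequence[ConceptRecord]],
    config: TokenizationConfig | None = None,
) -> dict[str, set[str]]:
    """Distinct post-stop-word token set of each vocabulary."""
    config = config or _default_config()
    out: dict[str, set[str]] = {}
    for code, group in records_by_vocab.items():
        toks: set[str] = set()
        for concept in group:
            toks.update(content_tokens(concept.name, config))
        out[code] = toks
    return out


def word_propagation(
    tokens_by_vocab: Mapping[str, Iterable[str]]
) -> list[PropagationEntry]:
    """Propagation index of every corpus word.

    Sorted by descending vocabulary count, then alphabetically, so the
    most widely shared words head the table.
    """
    if not tokens_by_vocab:
        raise ValueError("word_propagation requires at least one vocabulary")
    counts: Counter[str] = Counter()
    for toks in tokens_by_vocab.values():
        counts.update(set(toks))
    entries = [PropagationEntry(word=w, n_vocabularies=n) for w, n in counts.items()]
    entries.sort(key=lambda e: (-e.n_vocabularies, e.word))
    return entries


def corpus_lexical_totals(
    records_by_vocab: Mapping[str, Sequence[ConceptRecord]],
    config: TokenizationConfig | None = None,
) -> tuple[int, int]:
    """Corpus-wide ``(total_words, unique_words)``.

    Totals add across vocabularies; uniques are the size of the union of
    per-vocabulary token sets (a word shared by several vocabularies is
    one corpus word).
    """
    if not records_by_vocab:
        raise ValueError("corpus_lexical_totals requires at least one vocabulary")
    config = config or _default_config()
    total = 0
    union: set[str] = set()
    for group in records_by_vocab.values():
        for concept in group:
            toks = content_tokens(concept.name, config)
            total += len(toks)
            union.update(toks)
    return total, len(union)


_DEFAULT_CONFIG: TokenizationConfig | None = None


def _default_config() -> TokenizationConfig:
    global _DEFAULT_CONFIG
    if _DEFAULT_CONFIG is None:
        _DEFAULT_CONFIG = TokenizationConfig()
    return _DEFAULT_CONFIG
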