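"""Brute-force reference implementations used only by tests.

Everything here recomputes lexical statistics from first principles with
naive loops and its own inline tokenizer, independent of the library's
code paths, so pipeline results can be checked against an oracle that
shares no implementation with them.
"""
from __future__ import annotations

import re

_WORD = re.compile(r"[A-Za-z0-9]+")


def naive_tokens(name: str, stopwords: frozenset[str]) -> list[str]:
    toks = [t.lower() for t in _WORD.findall(name)]
    return [t for t in toks if t not in stopwords]


def naive_unique(tokens: list[str]) -> int:
    """Distinct-token count by naive nested scan (no sets)."""
    distinct: list[str] = []
    for tok in tokens:
        found = False
        for seen in distinct:
            if seen == tok:
                found = True
                break
        if not found:
            distinct.append(tok)
    return len(distinct)


def naive_median(values: list[float]) -> float:
    ordered = sorted(values)
    n = len(ordered)
    if n % 2 == 1:
        return float(ordered[n // 2])
    return (ordered[n // 2 - 1] + ordered[n // 2]) / 2


def naive_profile(names: list[str], stopwords: frozenset[str]) -> dict:
    """Per-vocabulary statistics recomputed name by name."""
    per_name = [naive_tokens(n, stopwords) for n in names]
    lengths = [len(t) for t in per_name]
    flat: list[str] = []
    for toks in per_name:
        flat.extend(toks)
    total = len(flat)
    unique = naive_unique(flat)
    return {
        "total_words": total,
        "unique_words": unique,
        "lexical_density": unique / total if total else None,
        "avg_len": sum(lengths) / len(lengths),
        "median_len": naive_median([float(x) for x in lengths]),
        "max_len": max(lengths),
        "min_len": min(lengths),
    }


def naive_propagation(names_by_vocab: dict[str, list[str]], stopwords: frozenset[str]) -> dict[str, int]:
    """word -> number of vocabularies containing it, by nested scans."""
    counts: dict[str, int] = {}
    for names in names_by_vocab.values():
        vocab_words: list[str] = []
        for name in names:
            for tok in naive_tokens(name, stopwords):
                if tok not in vocab_words:
                    vocab_words.append(tok)
        for tok in vocab_words:
            counts[tok] = counts.get(tok, 0) + 1
    return counts
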