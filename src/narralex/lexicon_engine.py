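"""Tokenization and dictionary-based linguistic feature extraction.

Features follow the word-count paradigm: every category score is the
percentage of tokens in the narrative that match the category's word list,
relative to the total token count.  Emotional tone (positive/negative) is
additionally negation-adjusted: an emotion token preceded by a negation
("not good") within a short same-sentence window is excluded from the tone
numerator, because a naive dictionary match would score it with inverted
valence.

The Analytic / Clout / Authentic summary scores are documented surrogate
composites of the basic category percentages.  The proprietary program's
regression weights are unpublished; the surrogates preserve the documented
direction of each ingredient (e.g. Clout rises with we/you-words and falls
with I-words) with coefficients that are configuration, not constants of
nature.  Every output carries the label "surrogate, not proprietary LIWC".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .corpus_io import CorpusTable

__all__ = [
    "Lexicon", "TokenStream", "FeatureVector", "LexiconParseError",
    "EmptyStreamError", "tokenize", "load_lexicon", "default_lexicon",
    "match_categories", "category_percent", "find_negated_emotions",
    "adjusted_tone", "pronoun_percents", "summary_scores",
    "compute_features", "features_frame", "PRONOUN_CLASSES",
    "SUMMARY_LABEL", "DEFAULT_NEGATION_WINDOW",
]

SUMMARY_LABEL = "surrogate, not proprietary LIWC"
DEFAULT_NEGATION_WINDOW = 3

_TOKEN_RE = re.compile(r"[^\W_]+(?:'[^\W_]+)*", re.UNICODE)
_SENTENCE_SPLIT_RE = re.compile(r"(?<=[.!?])[\"')\]]*\s+")

#: built-in specific-pronoun classes (percent of total tokens each)
PRONOUN_CLASSES: dict[str, frozenset[str]] = {
    "I": frozenset({"i", "me", "my", "mine", "myself"}),
    "we": frozenset({"we", "us", "our", "ours", "ourselves"}),
    "you": frozenset({"you", "your", "yours", "yourself", "yourselves"}),
    "she_he": frozenset(
        {"she", "her", "hers", "herself", "he", "him", "his", "himself"}
    ),
    "they": frozenset({"they", "them", "their", "theirs", "themselves"}),
}

#: categories the summary-score surrogates require
SUMMARY_REQUIRED = (
    "article", "prep", "ppron", "ipron", "auxverb", "conj", "adverb",
    "negations", "exclusive",
)

#: default surrogate coefficients; override via summary_scores(coefficients=...)
DEFAULT_SUMMARY_COEFFICIENTS: dict[str, dict[str, float]] = {
    "analytic": {
        "_intercept": 30.0,
        "article": 1.0, "prep": 1.0,
        "ppron": -1.0, "ipron": -1.0, "auxverb": -1.0,
        "conj": -1.0, "adverb": -1.0, "negations": -1.0,
    },
    "clout": {
        "_intercept": 50.0,
        "we": 4.0, "you": 2.0, "I": -3.0, "negations": -2.0,
    },
    "authentic": {
        "_intercept": 40.0,
        "I": 4.0, "exclusive": 2.0, "she_he": -3.0,
    },
}


class LexiconParseError(ValueError):
    """Malformed dictionary file."""


class EmptyStreamError(ValueError):
    """Feature requested on a zero-token stream; caller must skip the narrative."""


@dataclass(frozen=True)
class TokenStream:
    """Lowercase tokens with per-token sentence indices."""

    tokens: tuple[str, ...]
    sentence_index: tuple[int, ...]
    narrative_id: str = ""

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Lexicon:
    """Named categories mapping to word patterns.

    A pattern is either a literal word or a stem ending in ``*`` which
    matches any token it prefixes ("friend*" matches "friend", "friends",
    "friendship").  A token may belong to several categories.
    """

    categories: dict[str, frozenset[str]]
    name: str = "unnamed"
    version: str = "0"
    _literals: dict[str, frozenset[str]] = field(init=False, repr=False)
    _stems: list[str] = field(init=False, repr=False)
    _stem_cats: dict[str, frozenset[str]] = field(init=False, repr=False)
    _cache: dict[str, frozenset[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for cat, patterns in self.categories.items():
            for p in patterns:
                if not p or p == "*":
                    raise LexiconParseError(f"category {cat!r}: empty pattern")
                if "*" in p[:-1]:
                    raise LexiconParseError(
                        f"category {cat!r}: '*' only allowed as final char: {p!r}"
                    )
                if p != p.lower():
                    raise LexiconParseError(
                        f"category {cat!r}: pattern not lowercase: {p!r}"
                    )
        literals: dict[str, set[str]] = {}
        stem_cats: dict[str, set[str]] = {}
        for cat, patterns in self.categories.items():
            for p in patterns:
                if p.endswith("*"):
                    stem_cats.setdefault(p[:-1], set()).add(cat)
                else:
                    literals.setdefault(p, set()).add(cat)
        self._literals = {w: frozenset(c) for w, c in literals.items()}
        self._stems = sorted(stem_cats)
        self._stem_cats = {s: frozenset(c) for s, c in stem_cats.items()}
        self._max_stem_len = max((len(s) for s in self._stems), default=0)
        self._cache = {}

    def lookup(self, token: str) -> frozenset[str]:
        """All categories whose patterns match *token* (lowercase)."""
        hit = self._cache.get(token)
        if hit is not None:
            return hit
        cats = set(self._literals.get(token, ()))
        # every matching stem is a prefix of the token; walk prefixes
        for k in range(1, min(len(token), self._max_stem_len) + 1):
            hit_cats = self._stem_cats.get(token[:k])
            if hit_cats:
                cats |= hit_cats
        result = frozenset(cats)
        if len(self._cache) < 200_000:
            self._cache[token] = result
        return result


def tokenize(text: str, narrative_id: str = "") -> TokenStream:
    """Split text into lowercase tokens and sentence indices.

    A token is a maximal run of letters/digits with internal apostrophes
    kept ("don't"); hyphens split tokens.  Sentences end at ``. ! ?``
    followed by whitespace (closing quotes/brackets allowed in between).
    """
    tokens: list[str] = []
    sent_idx: list[int] = []
    for i, sentence in enumerate(_SENTENCE_SPLIT_RE.split(text)):
        for match in _TOKEN_RE.finditer(sentence.lower()):
            tokens.append(match.group())
            sent_idx.append(i)
    # renumber to consecutive 0-based indices over non-empty sentences
    remap: dict[int, int] = {}
    for s in sent_idx:
        if s not in remap:
            remap[s] = len(remap)
    return TokenStream(
        tokens=tuple(tokens),
        sentence_index=tuple(remap[s] for s in sent_idx),
        narrative_id=narrative_id,
    )


def _parse_dic(lines: list[str], name: str) -> dict[str, set[str]]:
    """Parse the open percent-delimited dictionary dialect."""
    if not lines or lines[0].strip() != "%":
        raise LexiconParseError(f"{name}: line 1: expected '%' header")
    index_to_cat: dict[str, str] = {}
    i = 1
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if line == "%":
            break
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise LexiconParseError(
                f"{name}: line {i}: expected '<index> <category>', got {line!r}"
            )
        index_to_cat[parts[0]] = parts[1]
    else:
        raise LexiconParseError(f"{name}: missing closing '%' of header block")

    categories: dict[str, set[str]] = {c: set() for c in index_to_cat.values()}
    for lineno in range(i, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        parts = line.split()
        word, refs = parts[0].lower(), parts[1:]
        if not refs:
            raise LexiconParseError(
                f"{name}: line {lineno + 1}: word {word!r} has no category index"
            )
        for ref in refs:
            if ref not in index_to_cat:
                raise LexiconParseError(
                    f"{name}: line {lineno + 1}: unknown category index {ref!r}"
                )
            categories[index_to_cat[ref]].add(word)
    empty = sorted(c for c, words in categories.items() if not words)
    if empty:
        raise LexiconParseError(f"{name}: empty categories: {empty}")
    return categories


def load_lexicon(path) -> Lexicon:
    """Load a category dictionary.

    Accepts the open percent-delimited dialect (``%`` header block mapping
    numeric indices to category names, then ``word  index...`` lines) or a
    two-column TSV ``pattern<TAB>category``.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    stripped = [ln for ln in lines if ln.strip()]
    if stripped and stripped[0].strip() == "%":
        categories = _parse_dic(lines, path.name)
    else:
        categories = {}
        for lineno, line in enumerate(lines, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise LexiconParseError(
                    f"{path.name}: line {lineno}: expected 'pattern<TAB>category'"
                )
            pattern, cat = parts[0].strip().lower(), parts[1].strip()
            if not pattern or not cat:
                raise LexiconParseError(
                    f"{path.name}: line {lineno}: empty pattern or category"
                )
            categories.setdefault(cat, set()).add(pattern)
    return Lexicon(
        categories={c: frozenset(w) for c, w in categories.items()},
        name=path.stem,
        version="file",
    )


def default_lexicon() -> Lexicon:
    """The small open lexicon packaged with narralex."""
    return load_lexicon(Path(__file__).parent / "data" / "default.dic")


def match_categories(token: str, lexicon: Lexicon) -> frozenset[str]:
    """All categories matching *token*; stems and literals both count."""
    return lexicon.lookup(token)


def category_percent(stream: TokenStream, lexicon: Lexicon, category: str) -> float:
    """100 x (tokens matching *category*) / (total tokens)."""
    if len(stream) == 0:
        raise EmptyStreamError(stream.narrative_id or "<unnamed>")
    hits = sum(1 for tok in stream.tokens if category in lexicon.lookup(tok))
    return 100.0 * hits / len(stream)


def find_negated_emotions(
    stream: TokenStream,
    lexicon: Lexicon,
    window: int = DEFAULT_NEGATION_WINDOW,
) -> list[tuple[int, str]]:
    """Locate emotion tokens in the scope of a preceding negation.

    An emotion token (pos_tone or neg_tone) is negated iff a negations-token
    occurs at most *window* positions before it within the same sentence.
    Returns (token position, emotion category) pairs; a token matching both
    tones yields two pairs.
    """
    for cat in ("pos_tone", "neg_tone", "negations"):
        if cat not in lexicon.categories:
            raise KeyError(f"lexicon lacks required category {cat!r}")
    out: list[tuple[int, str]] = []
    neg_positions: list[int] = []
    for pos, (tok, sent) in enumerate(zip(stream.tokens, stream.sentence_index)):
        cats = lexicon.lookup(tok)
        if "negations" in cats:
            neg_positions.append(pos)
        emo = cats & {"pos_tone", "neg_tone"}
        if emo:
            for npos in reversed(neg_positions):
                if pos - npos > window:
                    break
                if stream.sentence_index[npos] == sent and npos < pos:
                    for cat in sorted(emo):
                        out.append((pos, cat))
                    break
    return out


def adjusted_tone(
    stream: TokenStream,
    lexicon: Lexicon,
    window: int = DEFAULT_NEGATION_WINDOW,
) -> tuple[float, float]:
    """Positive and negative tone percentages with negated occurrences removed.

    Negated emotion tokens are dropped from the numerator only; the
    denominator stays the total token count.
    """
    if len(stream) == 0:
        raise EmptyStreamError(stream.narrative_id or "<unnamed>")
    negated = find_negated_emotions(stream, lexicon, window)
    excl = {"pos_tone": set(), "neg_tone": set()}
    for pos, cat in negated:
        excl[cat].add(pos)
    counts = {"pos_tone": 0, "neg_tone": 0}
    for pos, tok in enumerate(stream.tokens):
        cats = lexicon.lookup(tok)
        for cat in ("pos_tone", "neg_tone"):
            if cat in cats and pos not in excl[cat]:
                counts[cat] += 1
    n = len(stream)
    return 100.0 * counts["pos_tone"] / n, 100.0 * counts["neg_tone"] / n


def pronoun_percents(stream: TokenStream) -> dict[str, float]:
    """Percent of total tokens in each built-in specific-pronoun class."""
    if len(stream) == 0:
        raise EmptyStreamError(stream.narrative_id or "<unnamed>")
    counts = dict.fromkeys(PRONOUN_CLASSES, 0)
    for tok in stream.tokens:
        for cls, words in PRONOUN_CLASSES.items():
            if tok in words:
                counts[cls] += 1
    n = len(stream)
    return {cls: 100.0 * c / n for cls, c in counts.items()}


def _clamp(x: float) -> float:
    return min(100.0, max(0.0, x))


def summary_scores(
    percents: Mapping[str, float],
    coefficients: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> tuple[float, float, float]:
    """Surrogate (analytic, clout, authentic) composites, each clamped to [0, 100].

    *percents* must contain the function-word category percentages
    (article, prep, ppron, ipron, auxverb, conj, adverb, negations,
    exclusive) and the specific-pronoun percentages (I, we, you, she_he).
    """
    coefs = coefficients or DEFAULT_SUMMARY_COEFFICIENTS
    needed = set()
    for comp in coefs.values():
        needed |= {k for k in comp if k != "_intercept"}
    missing = sorted(k for k in needed if k not in percents)
    if missing:
        raise KeyError(f"summary_scores: missing category percentages: {missing}")
    out = []
    for name in ("analytic", "clout", "authentic"):
        comp = coefs[name]
        val = comp.get("_intercept", 0.0) + sum(
            w * percents[k] for k, w in comp.items() if k != "_intercept"
        )
        out.append(_clamp(val))
    return tuple(out)  # type: ignore[return-value]


@dataclass(frozen=True)
class FeatureVector:
    """Per-narrative linguistic profile."""

    narrative_id: str
    word_count: int
    category_percent: dict[str, float]
    pronoun_percent: dict[str, float]
    analytic: float
    clout: float
    authentic: float
    negation_case_count: int
    summary_label: str = SUMMARY_LABEL


def compute_features(
    stream: TokenStream,
    lexicon: Lexicon,
    window: int = DEFAULT_NEGATION_WINDOW,
    coefficients: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> FeatureVector:
    """All features for one narrative (tone already negation-adjusted)."""
    if len(stream) == 0:
        raise EmptyStreamError(stream.narrative_id or "<unnamed>")
    n = len(stream)
    counts: dict[str, int] = dict.fromkeys(lexicon.categories, 0)
    pron_counts = dict.fromkeys(PRONOUN_CLASSES, 0)
    total_pron = 0
    for tok in stream.tokens:
        cats = lexicon.lookup(tok)
        for cat in cats:
            counts[cat] += 1
        if "ppron" in cats or "ipron" in cats:
            total_pron += 1
        for cls, words in PRONOUN_CLASSES.items():
            if tok in words:
                pron_counts[cls] += 1

    category_pct = {cat: 100.0 * c / n for cat, c in counts.items()}
    category_pct["total_pronouns"] = 100.0 * total_pron / n
    pron_pct = {cls: 100.0 * c / n for cls, c in pron_counts.items()}

    negated = find_negated_emotions(stream, lexicon, window)
    pos_adj, neg_adj = adjusted_tone(stream, lexicon, window)
    category_pct["pos_tone"] = pos_adj
    category_pct["neg_tone"] = neg_adj

    analytic, clout, authentic = summary_scores(
        {**category_pct, **pron_pct}, coefficients
    )
    return FeatureVector(
        narrative_id=stream.narrative_id,
        word_count=n,
        category_percent=category_pct,
        pronoun_percent=pron_pct,
        analytic=analytic,
        clout=clout,
        authentic=authentic,
        negation_case_count=len(negated),
    )


def features_frame(
    corpus: CorpusTable,
    lexicon: Optional[Lexicon] = None,
    window: int = DEFAULT_NEGATION_WINDOW,
) -> pd.DataFrame:
    """One feature row per narrative (empty narratives are skipped with a note).

    Columns: narrative_id, account_type, interpersonal_difficulties,
    word_count, every lexicon category percentage, total_pronouns, the five
    specific-pronoun percentages (pron_I .. pron_they), analytic, clout,
    authentic, negation_case_count.
    """
    lex = lexicon or default_lexicon()
    rows = []
    for rec in corpus.records:
        stream = tokenize(rec.text, rec.narrative_id)
        if len(stream) == 0:
            continue
        fv = compute_features(stream, lex, window)
        row: dict[str, object] = {
            "narrative_id": rec.narrative_id,
            "account_type": rec.account_type,
            "interpersonal_difficulties": rec.interpersonal_difficulties,
            "word_count": fv.word_count,
        }
        row.update(fv.category_percent)
        row.update({f"pron_{k}": v for k, v in fv.pronoun_percent.items()})
        row["analytic"] = fv.analytic
        row["clout"] = fv.clout
        row["authentic"] = fv.authentic
        row["negation_case_count"] = fv.negation_case_count
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["summary_label"] = SUMMARY_LABEL
    return df
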