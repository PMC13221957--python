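"""Synthetic narrative corpora with known ground truth.

The study corpus (journal essays) cannot be redistributed, so every pipeline
stage is exercised on generated corpora that emulate its statistical
structure: per-group token-emission rates for the dictionary categories,
log-normally dispersed narrative lengths, negated-emotion insertions,
multi-rater binary codings with controllable agreement, and vocabularies
with planted semantic clusters joined by a single designated bridge word.

The emission model is deliberately word-salad: linguistic realism is a
non-goal.  Each narrative draws a length L from a log-normal, draws its own
per-category emission rates around the group means (a Gaussian
narrative-level dispersion), emits round(rate x L) tokens per category from
category-specific word pools plus neutral filler, shuffles them into
sentences of 8-15 tokens, and finally inserts a negation token immediately
before each emotion token with probability ``negation_rate``.  Because the
narrative-level dispersion dominates the within-narrative sampling noise,
a planted standardized effect d between two groups is realized by shifting
one group's mean rate by d x dispersion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .corpus_io import CorpusTable, NarrativeRecord, RaterCodingTable
from .lexicon_engine import default_lexicon

__all__ = [
    "SyntheticSpec", "BridgePlan", "RaterPlan", "SpecError",
    "generate_corpus", "generate_bridge_corpus", "generate_rater_codes",
    "generate_true_labels", "filler_vocabulary",
    "DEFAULT_N_PER_GROUP", "DEFAULT_LENGTHS", "DEFAULT_CATEGORY_RATES",
    "EMISSION_POOLS",
]


class SpecError(ValueError):
    """Infeasible or inconsistent generator specification."""


#: study-shaped group sizes: 133 first-person accounts (56 coded with
#: interpersonal difficulties, 77 without) and 44 third-person accounts
DEFAULT_N_PER_GROUP: dict[str, int] = {"FPA_ID": 56, "FPA_noID": 77, "TPA": 44}

#: per-group narrative length (token count): mean and SD of the log-normal,
#: mirroring the reported word-count distributions
DEFAULT_LENGTHS: dict[str, tuple[float, float]] = {
    "FPA_ID": (4064.05, 4580.68),
    "FPA_noID": (2021.91, 1170.98),
    "TPA": (2669.73, 1629.20),
}

#: disjoint word pools the generator emits from, one per controlled category;
#: every pool word matches exactly its own category in the packaged lexicon
EMISSION_POOLS: dict[str, tuple[str, ...]] = {
    "pos_tone": ("good", "happy", "hope", "glad", "nice", "calm", "proud"),
    "neg_tone": ("bad", "sad", "afraid", "angry", "awful", "scared", "worse"),
    "social": ("friends", "people", "family", "doctor", "talked", "together"),
    "article": ("a", "an", "the"),
    "prep": ("of", "in", "for", "with", "on", "at", "from"),
    "ipron": ("it", "this", "that", "these", "those", "something"),
    "auxverb": ("is", "was", "were", "be", "have", "had", "did"),
    "conj": ("and", "because", "while", "although", "if"),
    "adverb": ("very", "really", "too", "also", "again", "often"),
    "negations": ("not", "no", "never", "none"),
    "exclusive": ("except",),  # "without" also matches prep; keep pools disjoint
    "I": ("i", "me", "my", "myself"),
    "we": ("we", "us", "our"),
    "you": ("you", "your", "yours"),
    "she_he": ("she", "her", "he", "him", "his"),
    "they": ("they", "them", "their"),
}

#: per-group mean emission rates (probability per token), informed by the
#: reported group profiles: first-person accounts are I-heavy and
#: social-light, third-person accounts she/he- and social-heavy, and the
#: interpersonal-difficulties group is more negative and less positive
DEFAULT_CATEGORY_RATES: dict[str, dict[str, float]] = {
    "FPA_ID": {
        "pos_tone": 0.0242, "neg_tone": 0.0253, "social": 0.0836,
        "I": 0.0922, "we": 0.0037, "you": 0.0032, "she_he": 0.0084,
        "they": 0.0074, "ipron": 0.0590,
        "article": 0.055, "prep": 0.115, "auxverb": 0.085,
        "conj": 0.055, "adverb": 0.050, "negations": 0.006, "exclusive": 0.004,
    },
    "FPA_noID": {
        "pos_tone": 0.0282, "neg_tone": 0.0217, "social": 0.0840,
        "I": 0.0802, "we": 0.0035, "you": 0.0044, "she_he": 0.0065,
        "they": 0.0076, "ipron": 0.0590,
        "article": 0.060, "prep": 0.115, "auxverb": 0.085,
        "conj": 0.055, "adverb": 0.050, "negations": 0.006, "exclusive": 0.004,
    },
    "TPA": {
        "pos_tone": 0.0259, "neg_tone": 0.0236, "social": 0.1463,
        "I": 0.0430, "we": 0.0114, "you": 0.0026, "she_he": 0.0445,
        "they": 0.0072, "ipron": 0.0580,
        "article": 0.065, "prep": 0.115, "auxverb": 0.085,
        "conj": 0.055, "adverb": 0.045, "negations": 0.005, "exclusive": 0.004,
    },
}

DEFAULT_RATE_DISPERSION = 0.01  # narrative-level SD of each emission rate

_NEGATION_INSERT = "not"
_SENT_MIN, _SENT_MAX = 8, 15


@dataclass(frozen=True)
class BridgePlan:
    """Two semantic clusters joined by a single designated bridge word."""

    cluster_a: tuple[str, ...] = (
        "voices", "hearing", "whisper", "echo", "shouting", "murmur",
        "sounds", "night",
    )
    cluster_b: tuple[str, ...] = (
        "hospital", "medication", "recovery", "treatment", "ward",
        "therapy", "clinic", "discharge",
    )
    bridge: str = "symptoms"
    leak: float = 0.0
    n_sentences: int = 200
    words_per_sentence: tuple[int, int] = (4, 8)
    bridge_inclusion: float = 0.4

    def __post_init__(self) -> None:
        if not 0 <= self.leak < 1:
            raise SpecError("leak probability must lie in [0, 1)")
        if self.bridge in self.cluster_a or self.bridge in self.cluster_b:
            raise SpecError("bridge word must belong to neither cluster")
        if set(self.cluster_a) & set(self.cluster_b):
            raise SpecError("clusters must be disjoint")


@dataclass(frozen=True)
class RaterPlan:
    """Independent raters reporting a binary code with a fixed accuracy."""

    n_raters: int = 3
    accuracy: float = 0.9
    base_rate: float = 56 / 133  # share of coded-positive items

    def __post_init__(self) -> None:
        if not 0.5 <= self.accuracy <= 1.0:
            raise SpecError("rater accuracy must lie in [0.5, 1]")
        if self.n_raters < 2:
            raise SpecError("need at least 2 raters")


@dataclass
class SyntheticSpec:
    """Everything the corpus generator needs, with study-shaped defaults."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_GROUP))
    length_distribution: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LENGTHS))
    category_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(r) for g, r in
                                 DEFAULT_CATEGORY_RATES.items()})
    rate_dispersion: float = DEFAULT_RATE_DISPERSION
    negation_rate: float = 0.05
    planted_effects: dict[str, tuple[str, str, float]] = field(
        default_factory=dict)  # variable -> (boosted group, reference group, d)
    bridge_plan: BridgePlan = field(default_factory=BridgePlan)
    rater_plan: RaterPlan = field(default_factory=RaterPlan)
    seed: int = 0

    def effective_rates(self) -> dict[str, dict[str, float]]:
        """Group mean rates after applying the planted standardized effects."""
        rates = {g: dict(r) for g, r in self.category_rates.items()}
        for var, (hi, lo, d) in self.planted_effects.items():
            for g in (hi, lo):
                if g not in rates:
                    raise SpecError(f"planted effect on unknown group {g!r}")
                if var not in rates[g]:
                    raise SpecError(f"planted effect on unknown variable {var!r}")
            rates[hi][var] = rates[hi][var] + d * self.rate_dispersion
        for g, r in rates.items():
            total = sum(r.values())
            if total > 1.0:
                raise SpecError(
                    f"group {g!r}: emission rates sum to {total:.3f} > 1"
                )
            if any(v < 0 for v in r.values()):
                raise SpecError(f"group {g!r}: negative emission rate")
        return rates


_FILLER_CACHE: Optional[tuple[str, ...]] = None


def filler_vocabulary(n: int = 500) -> tuple[str, ...]:
    """A closed list of *n* neutral pseudo-words.

    Built deterministically from syllable products and filtered so no word
    matches any category of the packaged lexicon (literal or stem) or the
    packaged stopword list: filler tokens leave every category percentage
    untouched.
    """
    global _FILLER_CACHE
    if _FILLER_CACHE is not None and len(_FILLER_CACHE) >= n:
        return _FILLER_CACHE[:n]
    from .word_network import load_stopwords

    lexicon = default_lexicon()
    stop = load_stopwords()
    onsets = ("b", "d", "g", "k", "l", "m", "p", "r", "t", "z")
    nuclei = ("a", "e", "i", "o", "u")
    codas = ("rn", "lt", "nd", "sk", "mp", "rp", "nt", "lk", "rt", "ld")
    words = []
    for onset, vowel, coda, vowel2 in itertools.product(
            onsets, nuclei, codas, nuclei):
        word = f"{onset}{vowel}{coda}{vowel2}x"
        if word in stop or lexicon.lookup(word):
            continue
        words.append(word)
        if len(words) == n:
            break
    if len(words) < n:
        raise SpecError(f"could not build {n} filler words")
    _FILLER_CACHE = tuple(words)
    return _FILLER_CACHE


def _narrative_rng(seed: int, counter: int) -> np.random.Generator:
    # counter-derived substream: corpora stay stable under count changes
    return np.random.default_rng([seed, counter])


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _emit_narrative(
    rng: np.random.Generator,
    length: int,
    rates: dict[str, float],
    dispersion: float,
    negation_rate: float,
    filler: Sequence[str],
) -> tuple[str, dict[str, float]]:
    """One narrative's text plus its realized per-category emission rates."""
    realized: dict[str, float] = {}
    tokens: list[str] = []
    for cat, rate in rates.items():
        q = float(np.clip(rate + rng.normal(0.0, dispersion), 0.0, 0.9))
        count = int(round(q * length))
        realized[cat] = count / length
        pool = EMISSION_POOLS[cat]
        tokens.extend(pool[i] for i in rng.integers(0, len(pool), count))
    n_filler = length - len(tokens)
    if n_filler < 0:
        raise SpecError("emission rates leave no room for filler vocabulary")
    tokens.extend(filler[i] for i in rng.integers(0, len(filler), n_filler))
    perm = rng.permutation(len(tokens))
    tokens = [tokens[i] for i in perm]

    emotion_words = set(EMISSION_POOLS["pos_tone"]) | set(EMISSION_POOLS["neg_tone"])
    sentences: list[list[str]] = []
    i = 0
    while i < len(tokens):
        k = int(rng.integers(_SENT_MIN, _SENT_MAX + 1))
        sentence = tokens[i:i + k]
        i += k
        out: list[str] = []
        for tok in sentence:
            if tok in emotion_words and rng.random() < negation_rate:
                out.append(_NEGATION_INSERT)
            out.append(tok)
        sentences.append(out)
    text = ". ".join(" ".join(s) for s in sentences) + "."
    return text, realized


def generate_corpus(spec: SyntheticSpec) -> tuple[CorpusTable, dict]:
    """Generate a corpus honoring the spec; returns (corpus, ground truth).

    Deterministic for a fixed seed.  Ground truth records the effective
    per-group mean rates, each narrative's realized rates, and the planted
    standardized effects.
    """
    rates = spec.effective_rates()
    filler = filler_vocabulary()
    records: list[NarrativeRecord] = []
    truth_narratives: dict[str, dict] = {}
    counter = 0
    for group in sorted(spec.n_per_group):
        n = spec.n_per_group[group]
        if group not in rates:
            raise SpecError(f"no category rates for group {group!r}")
        mean, sd = spec.length_distribution.get(group, (2000.0, 1200.0))
        mu, sigma = _lognormal_params(mean, sd)
        account = "TPA" if group == "TPA" else "FPA"
        flag = None if group == "TPA" else group == "FPA_ID"
        for j in range(n):
            rng = _narrative_rng(spec.seed, counter)
            length = max(_SENT_MAX * 2, int(round(rng.lognormal(mu, sigma))))
            text, realized = _emit_narrative(
                rng, length, rates[group], spec.rate_dispersion,
                spec.negation_rate, filler,
            )
            nid = f"{group}-{j:03d}"
            records.append(
                NarrativeRecord(
                    narrative_id=nid,
                    author_id=f"author-{counter:04d}",
                    text=text,
                    account_type=account,
                    interpersonal_difficulties=flag,
                    publication_order=0,
                )
            )
            truth_narratives[nid] = {"group": group, "length": length,
                                     "realized_rates": realized}
            counter += 1
    truth = {
        "effective_rates": rates,
        "planted_effects": dict(spec.planted_effects),
        "rate_dispersion": spec.rate_dispersion,
        "negation_rate": spec.negation_rate,
        "narratives": truth_narratives,
        "seed": spec.seed,
    }
    return CorpusTable(records=records, provenance="synthetic"), truth


def generate_bridge_corpus(spec: SyntheticSpec) -> CorpusTable:
    """A corpus whose co-occurrence graph has a planted bridge word.

    Each sentence draws its words from cluster A or cluster B (never both,
    except with the leak probability, which adds one word from the opposite
    cluster).  The bridge word is inserted into sentences of both clusters,
    so with zero leak every inter-cluster shortest path passes through it.
    """
    plan = spec.bridge_plan
    rng = _narrative_rng(spec.seed, 0)
    lo, hi = plan.words_per_sentence
    clusters = (list(plan.cluster_a), list(plan.cluster_b))
    sentences: list[str] = []
    for _ in range(plan.n_sentences):
        side = int(rng.random() < 0.5)
        pool = clusters[side]
        k = min(len(pool), int(rng.integers(lo, hi + 1)))
        words = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
        if rng.random() < plan.bridge_inclusion:
            words.insert(int(rng.integers(0, len(words) + 1)), plan.bridge)
        if plan.leak > 0 and rng.random() < plan.leak:
            other = clusters[1 - side]
            words.append(other[int(rng.integers(0, len(other)))])
        sentences.append(" ".join(words))
    text = ". ".join(sentences) + "."
    record = NarrativeRecord(
        narrative_id="bridge-000",
        author_id="bridge-author",
        text=text,
        account_type="FPA",
        interpersonal_difficulties=True,
    )
    return CorpusTable(records=[record], provenance="synthetic bridge corpus")


def generate_true_labels(n_items: int, plan: RaterPlan, seed: int) -> np.ndarray:
    """Ground-truth binary codes at the plan's base rate (deterministic)."""
    rng = _narrative_rng(seed, 1)
    return (rng.random(n_items) < plan.base_rate).astype(float)


def generate_rater_codes(
    true_labels: Sequence[bool],
    rater_plan: RaterPlan,
    seed: int,
) -> RaterCodingTable:
    """Each rater independently reports the true label with the stated accuracy."""
    labels = np.asarray(true_labels, dtype=float)
    rng = _narrative_rng(seed, 2)
    n, r = labels.size, rater_plan.n_raters
    correct = rng.random((n, r)) < rater_plan.accuracy
    codes = np.where(correct, labels[:, None], 1.0 - labels[:, None])
    return RaterCodingTable(
        item_ids=[f"item-{i:04d}" for i in range(n)],
        rater_ids=[f"rater-{j}" for j in range(r)],
        codes=codes,
    )
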