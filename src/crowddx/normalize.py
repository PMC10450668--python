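"""Deterministic normalization of free-text diagnoses.

Free-text diagnoses ("Anaemias of the kidneys", "OSA—obstructive sleep
apnea") are reduced to lowercase word-token *sets* so that two strings can
be compared by exact token-set equality or Jaccard similarity.  The cascade
is: lowercase, strip punctuation (hyphens and dashes act as separators),
tokenize, drop stop words, map British to US spelling, singularize, and
deduplicate.  Every step is rule-based and deterministic, so the same input
always yields the same token set, and normalization is idempotent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

__all__ = [
    "NormalizedTerm",
    "Normalizer",
    "default_normalizer",
    "normalize",
    "jaccard",
]

# Characters that act as token separators (hyphens, dashes, slashes and
# general punctuation).  Periods and apostrophes are *removed* instead, so
# that "O.S.A." collapses to the single token "osa" and "Kaposi's" to
# "kaposi".
_SEPARATORS = re.compile(r"[-–—−/\\,;:()\[\]{}!?\"«»+*&%$#@~`|<>=]+")
_POSSESSIVE = re.compile(r"[’']s\b")
_REMOVED = re.compile(r"[.’'^_]+")
_TOKEN = re.compile(r"[a-z0-9]+")

# Nouns that end in "s" but are singular / invariant in clinical usage;
# the suffix rules must leave them alone.
_INVARIANT = frozenset(
    {
        "feces",
        "faeces",
        "herpes",
        "diabetes",
        "scabies",
        "rabies",
        "ascites",
        "measles",
        "mumps",
        "pertussis",
        "series",
        "species",
    }
)


def _load_stopwords() -> frozenset[str]:
    text = resources.files("crowddx.data").joinpath("stopwords.txt").read_text()
    return frozenset(
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def _load_spelling_map() -> dict[str, str]:
    text = resources.files("crowddx.data").joinpath("british_american.tsv").read_text()
    table: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        brit, us = line.split("\t")
        table[brit.strip()] = us.strip()
    return table


def singularize(token: str) -> str:
    """Rule-based English singularization of a single lowercase token.

    Tokens of three characters or fewer are exempt, which protects
    acronyms such as "osa" from being mangled, as are Latin/Greek endings
    common in medicine (-us, -is, -ss) and a short invariant-noun list.
    """
    if len(token) <= 3 or token in _INVARIANT:
        return token
    if token.endswith(("ss", "us", "is")):
        return token
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith("oses"):
        return token[:-2] + "is"  # diagnoses -> diagnosis, stenoses -> stenosis
    if token.endswith("es") and token[:-2].endswith(("s", "x", "z", "ch", "sh")):
        return token[:-2]
    if token.endswith("s"):
        return token[:-1]
    return token


@dataclass(frozen=True)
class NormalizedTerm:
    """A raw string together with its normalized token set."""

    original: str
    tokens: frozenset[str] = field(default_factory=frozenset)

    def __bool__(self) -> bool:
        return bool(self.tokens)


class Normalizer:
    """Configurable normalization cascade.

    Parameters
    ----------
    stopwords:
        Words dropped after tokenization.  Defaults to the bundled minimal
        list (articles, prepositions, conjunctions).
    spelling_map:
        Token-level British->US lookup.  Applied before *and* after
        singularization so that plural British forms ("anaemias") still
        reach their US spelling.
    """

    def __init__(
        self,
        stopwords: frozenset[str] | None = None,
        spelling_map: dict[str, str] | None = None,
    ) -> None:
        self.stopwords = _load_stopwords() if stopwords is None else frozenset(stopwords)
        self.spelling_map = _load_spelling_map() if spelling_map is None else dict(spelling_map)

    @classmethod
    def from_files(cls, stopword_path: str | Path | None = None,
                   spelling_path: str | Path | None = None) -> "Normalizer":
        stop = None
        if stopword_path is not None:
            stop = frozenset(
                w.strip() for w in Path(stopword_path).read_text().splitlines()
                if w.strip() and not w.startswith("#")
            )
        spell = None
        if spelling_path is not None:
            spell = {}
            for line in Path(spelling_path).read_text().splitlines():
                if not line.strip() or line.startswith("#"):
                    continue
                brit, us = line.split("\t")
                spell[brit.strip()] = us.strip()
        return cls(stopwords=stop, spelling_map=spell)

    def _map_token(self, token: str) -> str:
        token = self.spelling_map.get(token, token)
        token = singularize(token)
        return self.spelling_map.get(token, token)

    def __call__(self, text: str) -> NormalizedTerm:
        lowered = text.lower()
        lowered = _POSSESSIVE.sub("", lowered)
        lowered = _SEPARATORS.sub(" ", lowered)
        lowered = _REMOVED.sub("", lowered)
        tokens = frozenset(
            self._map_token(tok)
            for tok in _TOKEN.findall(lowered)
            if tok not in self.stopwords
        )
        # a mapped/singularized form could itself be a stop word; it is not
        # with the bundled tables, but guard anyway
        tokens = frozenset(t for t in tokens if t and t not in self.stopwords)
        return NormalizedTerm(original=text, tokens=tokens)


@lru_cache(maxsize=1)
def default_normalizer() -> Normalizer:
    return Normalizer()


def normalize(text: str) -> NormalizedTerm:
    """Normalize ``text`` with the default (bundled) stop words and spelling map."""
    return default_normalizer()(text)


def jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """Token-set Jaccard similarity |a∩b| / |a∪b|.

    Two empty sets are identical by convention (1.0); exactly one empty
    set gives 0.0.
    """
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / (len(a) + len(b) - inter)
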