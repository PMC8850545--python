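"""Word lists defining the index, the comparison index and control series.

The Absolute Thinking Index (ATI) is built from a fixed dictionary of
absolutist words — terms that express totality without nuance ("absolutely",
"all", "never") and whose elevated usage is a linguistic marker of
depression. This module packages that dictionary (19 English terms, with
French and Japanese translation files alongside), the 19-word mental-health
symptom comparison list, and a pool of neutral words from which random-word
control lexicons are drawn for counterfactual analyses.

Lexicons are plain-text files, UTF-8, one term per line; ``#`` starts a
comment; an optional ``term<TAB>variant1,variant2`` form attaches
orthographic variants. All operations are pure: no call mutates its input.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Lexicon",
    "LexiconError",
    "LexiconNotPackagedError",
    "load_lexicon",
    "read_lexicon_file",
    "expand_accent_variants",
    "generate_control_lexicon",
    "load_control_pool",
]

ROLES = ("absolutist", "control", "symptom")

#: (language, role) -> packaged resource file
_PACKAGED = {
    ("en", "absolutist"): "absolutist_en.txt",
    ("fr", "absolutist"): "absolutist_fr.txt",
    ("ja", "absolutist"): "absolutist_ja.txt",
    ("en", "symptom"): "symptom_en.txt",
}

#: packaged dictionary sizes that are part of the published design
_EXPECTED_COUNTS = {("en", "absolutist"): 19, ("en", "symptom"): 19}


class LexiconError(ValueError):
    """Invalid lexicon contents or arguments."""


class LexiconNotPackagedError(LexiconError):
    """No packaged word list exists for the requested (language, role)."""


@dataclass(frozen=True)
class Lexicon:
    """An ordered word list with a role tag and optional variant spellings.

    Parameters
    ----------
    language : str
        ISO-639-1 code ("en", "fr", "ja", ...).
    role : str
        One of ``absolutist`` (index dictionary), ``symptom`` (comparison
        index) or ``control`` (random-word synthetic-control series).
    terms : tuple of str
        Ordered, unique (after lowercase/strip) non-empty query terms.
    variant_map : mapping
        term -> tuple of orthographic variants; every key must be a term.
    """

    language: str
    role: str
    terms: tuple[str, ...]
    variant_map: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise LexiconError(f"unknown lexicon role {self.role!r}")
        if not self.terms:
            raise LexiconError("lexicon has no terms")
        cleaned = [t.strip() for t in self.terms]
        if any(not t for t in cleaned):
            raise LexiconError("lexicon contains an empty term")
        keys = [t.lower() for t in cleaned]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise LexiconError(f"duplicate terms after normalization: {dupes}")
        object.__setattr__(self, "terms", tuple(cleaned))
        vmap = {k: tuple(v) for k, v in dict(self.variant_map).items()}
        unknown = set(vmap) - set(self.terms)
        if unknown:
            raise LexiconError(f"variant_map keys not in terms: {sorted(unknown)}")
        object.__setattr__(self, "variant_map", vmap)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)


def _strip_diacritics(term: str) -> str:
    """Remove combining marks via Unicode canonical (NFD) decomposition."""
    decomposed = unicodedata.normalize("NFD", term)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return unicodedata.normalize("NFC", stripped)


def _parse_lexicon_lines(lines, language: str, role: str) -> Lexicon:
    terms: list[str] = []
    variant_map: dict[str, tuple[str, ...]] = {}
    for raw in lines:
        line = raw.split("#", 1)[0].rstrip("\n").strip()
        if not line:
            continue
        if "\t" in line:
            term, _, variants = line.partition("\t")
            term = term.strip()
            vlist = tuple(v.strip() for v in variants.split(",") if v.strip())
            if vlist:
                variant_map[term] = vlist
        else:
            term = line
        terms.append(term)
    if not terms:
        raise LexiconError(f"lexicon file for ({language}, {role}) has no terms")
    return Lexicon(language=language, role=role, terms=tuple(terms),
                   variant_map=variant_map)


def read_lexicon_file(path: str | Path, language: str, role: str) -> Lexicon:
    """Read a lexicon from a plain-text file (one term per line)."""
    text = Path(path).read_text(encoding="utf-8")
    return _parse_lexicon_lines(text.splitlines(), language, role)


def load_lexicon(language: str, role: str) -> Lexicon:
    """Return the packaged word list for ``(language, role)``.

    Deterministic with stable term order. Raises
    :class:`LexiconNotPackagedError` when no list is packaged for the pair.
    """
    try:
        fname = _PACKAGED[(language, role)]
    except KeyError:
        raise LexiconNotPackagedError(
            f"lexicon not packaged for language={language!r}, role={role!r}"
        ) from None
    text = resources.files("atikit.data").joinpath(fname).read_text("utf-8")
    lex = _parse_lexicon_lines(text.splitlines(), language, role)
    expected = _EXPECTED_COUNTS.get((language, role))
    if expected is not None and len(lex) != expected:
        raise LexiconError(
            f"packaged ({language}, {role}) list has {len(lex)} terms, "
            f"expected {expected}"
        )
    return lex


def expand_accent_variants(lexicon: Lexicon) -> Lexicon:
    """Add the diacritic-stripped spelling of every accented term.

    Search users often omit accents to type faster, so each accented
    dictionary term is also queried in its accent-free spelling; both forms
    enter the extraction plan as separate series (19 terms become 21 for the
    French dictionary). Terms without diacritics pass through unchanged and
    the operation is idempotent.
    """
    terms = list(lexicon.terms)
    variant_map = {k: list(v) for k, v in lexicon.variant_map.items()}
    existing = {t.lower() for t in terms}
    for term in lexicon.terms:
        bare = _strip_diacritics(term)
        if bare != term and bare.lower() not in existing:
            terms.append(bare)
            existing.add(bare.lower())
            variant_map.setdefault(term, [])
            if bare not in variant_map[term]:
                variant_map[term].append(bare)
    return Lexicon(
        language=lexicon.language,
        role=lexicon.role,
        terms=tuple(terms),
        variant_map={k: tuple(v) for k, v in variant_map.items()},
    )


def load_control_pool(language: str = "en") -> tuple[str, ...]:
    """Return the packaged neutral-word pool for control lexicons."""
    if language != "en":
        raise LexiconNotPackagedError(
            f"control pool not packaged for language={language!r}"
        )
    text = resources.files("atikit.data").joinpath("control_pool_en.txt")
    lex = _parse_lexicon_lines(text.read_text("utf-8").splitlines(),
                               language, "control")
    return lex.terms


def generate_control_lexicon(
    n_words: int,
    seed: int,
    pool: Sequence[str] | None = None,
    language: str = "en",
) -> Lexicon:
    """Draw ``n_words`` distinct neutral words for synthetic-control series.

    Sampling is without replacement and deterministic for a fixed seed. The
    pool must be diacritic-free so the same control words can be matched
    across languages.
    """
    if pool is None:
        pool = load_control_pool(language)
    pool = tuple(pool)
    if n_words <= 0:
        raise LexiconError("n_words must be positive")
    if len(pool) < n_words:
        raise LexiconError(
            f"pool of {len(pool)} words is too small for n_words={n_words}"
        )
    accented = [w for w in pool if _strip_diacritics(w) != w]
    if accented:
        raise LexiconError(f"control pool contains diacritics: {accented}")
    rng = np.random.default_rng(seed)
    chosen = tuple(pool[i] for i in rng.choice(len(pool), n_words, replace=False))
    return Lexicon(language=language, role="control", terms=chosen)
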