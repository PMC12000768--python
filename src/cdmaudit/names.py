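"""Raw-name normalization for fidelity comparison.

A raw lab/medication name is split into two parallel token sets:

* ``ingredient_tokens`` — the substance/component-bearing words, used when
  comparing a name against the ingredients of its assigned drug code or the
  component of its lab code;
* ``attribute_tokens`` — dose numbers, units, dose-form and route words,
  used to judge whether a code's granularity (ingredient vs clinical drug vs
  branded drug) is supported by the name.

Normalization case-folds, replaces punctuation with spaces, routes numeric
tokens and configured stop tokens (units/forms/routes) into the attribute
set, and keeps everything else as ingredient tokens.  Two names that differ
only in case or punctuation share a ``key`` and are treated as the same raw
name; any other difference (e.g. "GLUCOSE [METER]" vs
"GLUCOSE [POINT-OF-CARE]") keeps them distinct.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import FrozenSet, Iterable

__all__ = ["NormalizedName", "NameNormalizer", "normalize_name", "DEFAULT_STOP_TOKENS"]

#: Units, dose-form and route words that describe how a drug is given rather
#: than what it is.  Kept (with numerals) in the attribute token set.
DEFAULT_STOP_TOKENS: frozenset[str] = frozenset(
    {
        # units
        "mg", "mcg", "ug", "g", "kg", "ml", "l", "dl", "meq", "mmol", "units",
        "unit", "iu", "hr", "ea", "pct",
        # dose forms
        "tablet", "tab", "tabs", "capsule", "cap", "caps", "solution", "soln",
        "suspension", "syrup", "cream", "ointment", "gel", "patch", "spray",
        "injection", "injectable", "infusion", "syringe", "vial", "drops",
        "powder", "lotion", "suppository", "inhaler", "aerosol",
        # routes / administration words
        "oral", "orally", "iv", "im", "sc", "subcutaneous", "intravenous",
        "topical", "ophthalmic", "otic", "nasal", "rectal", "inhalation",
        "er", "xr", "sr", "dr", "release", "extended", "delayed",
        # connective filler
        "in", "of", "per", "with", "and", "no",
    }
)

_NUMERIC_RE = re.compile(r"^\d+(\.\d+)?$")
_PUNCT_RE = re.compile(r"[^0-9a-z]+")


@dataclass(frozen=True)
class NormalizedName:
    original: str
    key: str  # case/punctuation-normalized form, order-preserving
    ingredient_tokens: FrozenSet[str]
    attribute_tokens: FrozenSet[str]

    @property
    def all_tokens(self) -> frozenset[str]:
        return self.ingredient_tokens | self.attribute_tokens

    @property
    def is_empty(self) -> bool:
        return not self.key


class NameNormalizer:
    """Caching normalizer with a configurable stop-token list."""

    def __init__(self, stop_tokens: Iterable[str] | None = None):
        self.stop_tokens = frozenset(
            t.lower() for t in (stop_tokens if stop_tokens is not None else DEFAULT_STOP_TOKENS)
        )
        self._cache: dict[str, NormalizedName] = {}

    def __call__(self, raw: str | None) -> NormalizedName:
        raw = "" if raw is None else str(raw)
        hit = self._cache.get(raw)
        if hit is not None:
            return hit
        lowered = raw.casefold()
        tokens = [t for t in _PUNCT_RE.split(lowered) if t]
        ingredient: set[str] = set()
        attribute: set[str] = set()
        for tok in tokens:
            if _NUMERIC_RE.match(tok):
                attribute.add(tok)
            elif tok in self.stop_tokens:
                attribute.add(tok)
            else:
                ingredient.add(tok)
        result = NormalizedName(
            original=raw,
            key=" ".join(tokens),
            ingredient_tokens=frozenset(ingredient),
            attribute_tokens=frozenset(attribute),
        )
        if len(self._cache) < 500_000:
            self._cache[raw] = result
        return result


_DEFAULT = NameNormalizer()


def normalize_name(raw: str | None) -> NormalizedName:
    """Normalize with the default stop-token list (module-level cache)."""
    return _DEFAULT(raw)
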