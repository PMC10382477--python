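"""Drug-name dictionaries: canonical names and their generic/brand synonyms.

FAERS DRUGNAME strings are free text — brand names, salts, doses and
formulation suffixes ("SERTRALINE HCL 50MG TAB"). A ``DrugDictionary``
maps such verbatim strings to a canonical generic name by looking for
any synonym as a whole-word token sequence inside the normalised
verbatim string. Word-boundary matching (not raw substring) matters:
the CITALOPRAM synonym must not fire inside ESCITALOPRAM.

Two curated dictionaries ship with the package: the six marketed SSRIs
and a statin class list (used for the co-medication sensitivity
analysis). Users can load their own from a tab-separated file, one
``CANONICAL<TAB>SYNONYM`` pair per line, '#' comments allowed.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DrugDictionary",
    "AmbiguousDrugNameError",
    "normalize_drug_name",
    "load_ssri_dictionary",
    "load_statin_dictionary",
    "UNMATCHED",
]

UNMATCHED = None  # sentinel: lookup is total, unmatched names map to None

_PUNCT = re.compile(r"[^A-Z0-9]+")


def normalize_drug_name(s: str) -> str:
    """Uppercase, strip punctuation to spaces, collapse whitespace."""
    return _PUNCT.sub(" ", str(s).upper()).strip()


class AmbiguousDrugNameError(ValueError):
    """A verbatim name matched synonyms of two or more canonical drugs."""


class DrugDictionary:
    """Canonical name -> synonym set, with total whole-word lookup."""

    def __init__(self, synonyms: Mapping[str, Iterable[str]]):
        self._synonyms: dict[str, frozenset[str]] = {}
        seen: dict[str, str] = {}
        patterns = []
        for canonical, syns in synonyms.items():
            norm = frozenset(normalize_drug_name(s) for s in [canonical, *syns] if str(s).strip())
            for s in norm:
                if s in seen and seen[s] != canonical:
                    raise ValueError(
                        f"synonym {s!r} is claimed by both {seen[s]!r} and {canonical!r}"
                    )
                seen[s] = canonical
            self._synonyms[canonical] = norm
            alt = "|".join(re.escape(s) for s in sorted(norm, key=len, reverse=True))
            patterns.append((canonical, re.compile(rf"(?<![A-Z0-9])(?:{alt})(?![A-Z0-9])")))
        self._patterns = patterns
        self._cache: dict[str, str | None] = {}

    @property
    def canonical_names(self) -> tuple[str, ...]:
        return tuple(self._synonyms)

    def synonyms(self, canonical: str) -> frozenset[str]:
        return self._synonyms[canonical]

    @classmethod
    def from_file(cls, path: str | Path) -> "DrugDictionary":
        """Load from a CANONICAL<TAB>SYNONYM file ('#' starts a comment)."""
        mapping: dict[str, list[str]] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected CANONICAL<TAB>SYNONYM, got {line!r}")
            canonical, synonym = parts[0].strip().lower(), parts[1].strip()
            mapping.setdefault(canonical, []).append(synonym)
        if not mapping:
            raise ValueError(f"{path}: empty drug dictionary")
        return cls(mapping)

    def match(self, verbatim: str) -> str | None:
        """Canonical name whose synonym occurs in the verbatim string, or
        None. Raises AmbiguousDrugNameError when two canonicals match."""
        norm = normalize_drug_name(verbatim)
        if norm in self._cache:
            return self._cache[norm]
        hits = [canonical for canonical, pat in self._patterns if pat.search(norm)]
        if len(hits) > 1:
            raise AmbiguousDrugNameError(
                f"{verbatim!r} matches multiple dictionary drugs: {', '.join(hits)}"
            )
        result = hits[0] if hits else UNMATCHED
        self._cache[norm] = result
        return result

    def match_series(self, verbatim: pd.Series) -> pd.Series:
        """Vectorised match over a DRUGNAME column (unique-value cached)."""
        uniques = verbatim.dropna().unique()
        table = {u: self.match(u) for u in uniques}
        return verbatim.map(table)


def _load_bundled(name: str) -> DrugDictionary:
    with resources.as_file(resources.files("faerspv.data") / name) as p:
        return DrugDictionary.from_file(p)


def load_ssri_dictionary() -> DrugDictionary:
    """The six marketed SSRIs with their major brand names."""
    return _load_bundled("ssri_synonyms.tsv")


def load_statin_dictionary() -> DrugDictionary:
    """HMG-CoA reductase inhibitors, for co-medication exclusion."""
    return _load_bundled("statin_synonyms.tsv")
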