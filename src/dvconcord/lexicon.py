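"""Mental-illness term lexicon, code crosswalks, and ICD-10 level-1 roll-up.

The analysis aggregates every diagnosis and every text-mined mention to a
closed set of first-level ICD-10 mental-illness groups (e.g. "Mood (affective)
disorders") before comparing the two record systems.  Three shipped,
user-replaceable files define that mapping:

* ``lexicon.csv`` — surface forms appearing in police narratives, each with an
  ICD-10 code (or a reserved special-category token) and a 3-level grouping;
* ``crosswalk.csv`` — one-to-one ICD-9/SNOMED-CT → ICD-10 conversions for
  emergency-department codes (ICD-10 inputs pass through unchanged);
* ``level1_map.csv`` — ICD-10 code ranges and special tokens mapped onto the
  level-1 group labels.

Categories without an ICD-10 chapter-V home (psychotropic medication groups,
unspecified substance abuse, drug-induced disorder, prescription-drug abuse,
unspecified mental illness) are modelled as reserved uppercase tokens that act
as their own level-1 groups.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Scheme",
    "LexiconEntry",
    "Lexicon",
    "Crosswalk",
    "Hierarchy",
    "LEVEL1_GROUPS",
    "GROUP_LABELS",
    "load_lexicon",
    "load_crosswalk",
    "load_hierarchy",
    "default_lexicon",
    "default_crosswalk",
    "default_hierarchy",
    "lookup_term",
    "convert_code",
    "roll_up",
]


class Scheme(str, Enum):
    """Diagnosis coding scheme of a hospital record."""

    ICD10 = "ICD10"
    ICD9 = "ICD9"
    SNOMED = "SNOMED"


#: Short handles for the closed level-1 group set.  The long labels are the
#: strings used throughout file output; the short keys are a convenience for
#: configuration (e.g. synthetic-cohort group weights).
GROUP_LABELS: dict[str, str] = {
    "physiological": "Mental disorders due to known physiological conditions",
    "substance_use": "Mental and behavioral disorders due to psychoactive substance use",
    "psychotic": "Schizophrenia, schizotypal, delusional, and other nonmood psychotic disorders",
    "mood": "Mood (affective) disorders",
    "anxiety": "Anxiety, dissociative, stress related, somatoform, and other nonpsychotic mental disorders",
    "behavioral_syndromes": "Behavioral syndromes associated with physiological disturbances and physical factors",
    "personality": "Disorders of adult personality and behavior",
    "intellectual": "Intellectual disability",
    "developmental": "Pervasive and specific developmental disorders",
    "childhood": "Behavioral and emotional disorders with onset usually occurring in childhood and adolescence",
    "unspecified": "Unspecified mental disorder",
    "self_harm": "Intentional self-harm",
    "symptoms_signs": "Symptoms and signs involving cognition, perception, emotional state, and behavior",
    "substance_abuse": "Substance abuse",
    "drug_induced": "Unspecified drug-induced disorders",
    "rx_abuse": "Drug prescription abuse",
    "tbi": "Traumatic brain injury",
    "injury_unspec": "Injury of unspecified body region",
    "degenerative": "Other degenerative diseases of the nervous system",
    "atrophies": "Systematic atrophies primarily affecting the central nervous system",
    "nervous_system": "Diseases of the nervous system",
    "chromosomal": "Chromosomal abnormalities, not elsewhere classified",
    "med_antidepressant": "Medications: antidepressants",
    "med_antipsychotic": "Medications (antipsychotics)",
    "med_anxiolytic": "Medications for anxiety",
    "med_neuroleptic": "Medications (neuroleptics)",
}

#: The closed level-1 group set, in canonical reporting order.
LEVEL1_GROUPS: tuple[str, ...] = tuple(GROUP_LABELS.values())


@dataclass(frozen=True)
class LexiconEntry:
    """One dictionary row: a lowercase surface form with its 3-level grouping."""

    surface_form: str
    canonical: str
    icd10_code: str
    level1_group: str
    level2_group: str
    level3_label: str


_TOKEN_RE = re.compile(r"^[A-Z][A-Z0-9_]+$")
_CODE_RE = re.compile(r"^([A-Z])(\d{2})(?:\.\d+)?$")


def _code_key(code: str) -> Optional[tuple[str, int]]:
    """Parse an ICD-10 code like ``F20.0`` into a sortable (letter, number) key."""
    m = _CODE_RE.match(code.strip().upper())
    if not m:
        return None
    return m.group(1), int(m.group(2))


class Hierarchy:
    """ICD-10 level-1 roll-up: code ranges plus special-category tokens."""

    def __init__(self, ranges: list[tuple[str, str, str]], tokens: dict[str, str]):
        parsed = []
        for start, end, group in ranges:
            ks, ke = _code_key(start), _code_key(end)
            if ks is None or ke is None:
                raise ValueError(f"bad ICD-10 range bound: {start!r}..{end!r}")
            if group not in set(LEVEL1_GROUPS):
                raise ValueError(f"unknown level1 group in hierarchy: {group!r}")
            parsed.append((ks, ke, group))
        # Narrow ranges take precedence over broad fallbacks (e.g. G30-G32
        # before the G00-G99 catch-all).
        parsed.sort(key=lambda r: r[1][1] - r[0][1])
        self._ranges = parsed
        for tok, group in tokens.items():
            if group not in set(LEVEL1_GROUPS):
                raise ValueError(f"unknown level1 group for token {tok!r}: {group!r}")
        self._tokens = dict(tokens)

    def roll_up(self, icd10_code: str) -> Optional[str]:
        """Map an ICD-10 code or special token to its level-1 group.

        Returns ``None`` for unknown codes (the "unmappable" flag).
        """
        code = icd10_code.strip()
        if _TOKEN_RE.match(code) and code in self._tokens:
            return self._tokens[code]
        key = _code_key(code)
        if key is None:
            return None
        letter, num = key
        for (ls, ns), (le, ne), group in self._ranges:
            if ls == letter == le and ns <= num <= ne:
                return group
        return None


class Lexicon:
    """Case-folded surface-form index over :class:`LexiconEntry` rows."""

    def __init__(self, entries: Iterable[LexiconEntry]):
        self._entries: dict[str, LexiconEntry] = {}
        for e in entries:
            key = e.surface_form.casefold().strip()
            if key in self._entries:
                raise ValueError(f"duplicate surface form in lexicon: {e.surface_form!r}")
            if e.level1_group not in set(LEVEL1_GROUPS):
                raise ValueError(
                    f"unknown level1 group {e.level1_group!r} for surface {e.surface_form!r}"
                )
            self._entries[key] = e

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def lookup(self, surface: str) -> Optional[LexiconEntry]:
        return self._entries.get(surface.casefold().strip())

    def surface_forms(self) -> list[str]:
        """All surface forms, longest first (for longest-match-first scanning)."""
        return sorted(self._entries, key=len, reverse=True)

    def entries_for_group(self, level1_group: str) -> list[LexiconEntry]:
        return [e for e in self._entries.values() if e.level1_group == level1_group]

    @property
    def groups(self) -> set[str]:
        return {e.level1_group for e in self._entries.values()}


class Crosswalk:
    """Deterministic (raw_code, scheme) → ICD-10 mapping for non-ICD-10 codes."""

    def __init__(self, rows: Iterable[tuple[str, Scheme, str]]):
        self._map: dict[tuple[Scheme, str], str] = {}
        for raw, scheme, icd10 in rows:
            scheme = Scheme(scheme)
            key = (scheme, raw.strip())
            if key in self._map and self._map[key] != icd10:
                raise ValueError(
                    f"conflicting crosswalk rows for {raw!r} ({scheme.value}): "
                    f"{self._map[key]!r} vs {icd10!r}"
                )
            self._map[key] = icd10.strip()

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    def convert(self, raw_code: str, scheme: Union[Scheme, str]) -> Optional[str]:
        """Return the single mapped ICD-10 code, or ``None`` when unmappable.

        ICD-10 inputs pass through unchanged (identity mapping).
        """
        scheme = Scheme(scheme)
        if scheme is Scheme.ICD10:
            return raw_code.strip()
        return self._map.get((scheme, raw_code.strip()))


def load_lexicon(path: Union[str, Path]) -> Lexicon:
    """Load a lexicon CSV (``surface_form,canonical,icd10_code,level1,level2,level3``).

    Duplicate surface forms (after case-folding) and unknown level-1 group
    labels are hard errors.  An empty file yields an empty lexicon with a
    warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["surface_form", "canonical", "icd10_code", "level1", "level2", "level3"]
    if list(df.columns) != expected:
        raise ValueError(f"lexicon header must be {expected}, got {list(df.columns)}")
    entries = [
        LexiconEntry(
            surface_form=r.surface_form.strip().lower(),
            canonical=r.canonical.strip(),
            icd10_code=r.icd10_code.strip(),
            level1_group=r.level1.strip(),
            level2_group=r.level2.strip(),
            level3_label=r.level3.strip(),
        )
        for r in df.itertuples()
    ]
    lex = Lexicon(entries)
    if len(lex) == 0:
        logger.warning("loaded an empty lexicon from %s", path)
    else:
        logger.info("loaded %d lexicon entries from %s", len(lex), path)
    return lex


def load_crosswalk(path: Union[str, Path]) -> Crosswalk:
    """Load a crosswalk CSV (``raw_code,scheme,icd10_code``)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["raw_code", "scheme", "icd10_code"]
    if list(df.columns) != expected:
        raise ValueError(f"crosswalk header must be {expected}, got {list(df.columns)}")
    return Crosswalk(
        (r.raw_code, Scheme(r.scheme), r.icd10_code) for r in df.itertuples()
    )


def load_hierarchy(path: Union[str, Path]) -> Hierarchy:
    """Load a level-1 map CSV (``kind,key_start,key_end,level1``)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    ranges, tokens = [], {}
    for r in df.itertuples():
        if r.kind == "range":
            ranges.append((r.key_start, r.key_end, r.level1))
        elif r.kind == "token":
            tokens[r.key_start] = r.level1
        else:
            raise ValueError(f"unknown hierarchy row kind: {r.kind!r}")
    return Hierarchy(ranges, tokens)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("dvconcord").joinpath("data", name)))


@lru_cache(maxsize=1)
def default_lexicon() -> Lexicon:
    return load_lexicon(_data_path("lexicon.csv"))


@lru_cache(maxsize=1)
def default_crosswalk() -> Crosswalk:
    return load_crosswalk(_data_path("crosswalk.csv"))


@lru_cache(maxsize=1)
def default_hierarchy() -> Hierarchy:
    return load_hierarchy(_data_path("level1_map.csv"))


# Thin functional wrappers mirroring the class methods.

def lookup_term(lexicon: Lexicon, surface: str) -> Optional[LexiconEntry]:
    """Case-insensitive exact-phrase lookup; ``None`` when absent."""
    return lexicon.lookup(surface)


def convert_code(
    crosswalk: Crosswalk, raw_code: str, scheme: Union[Scheme, str]
) -> Optional[str]:
    """Convert a raw diagnosis code to ICD-10; ``None`` flags an unmappable code."""
    return crosswalk.convert(raw_code, scheme)


def roll_up(hierarchy: Hierarchy, icd10_code: str) -> Optional[str]:
    """Roll an ICD-10 code (or special token) up to its level-1 group."""
    return hierarchy.roll_up(icd10_code)
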