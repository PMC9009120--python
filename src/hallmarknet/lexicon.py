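"""Dictionaries of aging hallmarks and age-related diseases, and sentence matching.

The mining pipeline rests on two controlled vocabularies: a hierarchical
taxonomy of the nine aging hallmarks (genomic instability, telomere
attrition, epigenetic alterations, loss of proteostasis, deregulated
nutrient sensing, mitochondrial dysfunction, cellular senescence, stem
cell exhaustion, altered intercellular communication) and a flat synonym
dictionary of age-related diseases (ARDs).  Every synonym of every
descendant taxonomy term is attributed to its root hallmark, so matching
a sentence yields root-level entity ids only.

Matching is deliberately simple and reproducible: sentences and synonyms
are lowercased, Unicode hyphens and en-dashes are normalised to ASCII
``-``, text is split into word tokens, and a synonym matches iff its
token sequence occurs contiguously in the sentence's token sequence.
There is no stemming and no fuzzy matching; a synonym never matches
inside a longer word.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "HALLMARK_IDS",
    "Taxonomy",
    "TaxonomyTerm",
    "DiseaseDictionary",
    "DiseaseEntry",
    "MentionRecord",
    "Matcher",
    "LexiconError",
    "load_taxonomy",
    "load_disease_dictionary",
    "packaged_taxonomy_path",
    "normalize_text",
    "tokenize",
    "match_sentence",
]

#: The nine canonical root hallmark identifiers.
HALLMARK_IDS = ("GI", "TA", "EA", "LOP", "DNS", "MD", "CS", "SCE", "AIC")


class LexiconError(ValueError):
    """Raised for malformed or inconsistent dictionary files."""


# Unicode hyphen (U+2010), non-breaking hyphen, figure dash, en dash -> ASCII hyphen
_DASHES = {0x2010: "-", 0x2011: "-", 0x2012: "-", 0x2013: "-"}
_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def normalize_text(text: str) -> str:
    """Lowercase and map Unicode hyphen variants to ASCII ``-``."""
    return text.lower().translate(_DASHES)


def tokenize(text: str) -> tuple[str, ...]:
    """Split normalised text into word tokens (letters/digits; underscores split)."""
    return tuple(_TOKEN_RE.findall(normalize_text(text)))


@dataclass(frozen=True)
class TaxonomyTerm:
    term_id: str
    label: str
    level: int
    parent_id: str | None
    root_hallmark: str
    synonyms: tuple[str, ...]


@dataclass(frozen=True)
class DiseaseEntry:
    ard_id: str
    name: str
    synonyms: tuple[str, ...]


@dataclass(frozen=True)
class MentionRecord:
    """One entity mention in one sentence (duplicates within a sentence collapse)."""

    doc_id: str
    sentence_index: int
    entity_id: str
    surface: str


class Taxonomy:
    """Validated hallmark taxonomy; synonyms roll up to the nine root hallmarks."""

    def __init__(self, terms: Iterable[TaxonomyTerm]):
        self.terms: list[TaxonomyTerm] = list(terms)
        self._by_id = {t.term_id: t for t in self.terms}
        self._validate()

    def _validate(self) -> None:
        if len(self._by_id) != len(self.terms):
            raise LexiconError("duplicate term ids in taxonomy")
        for t in self.terms:
            if t.level not in (1, 2, 3, 4):
                raise LexiconError(f"term {t.term_id!r}: level {t.level} not in 1..4")
            if t.root_hallmark not in HALLMARK_IDS:
                raise LexiconError(
                    f"term {t.term_id!r}: unknown root hallmark {t.root_hallmark!r}"
                )
            if not t.synonyms:
                raise LexiconError(f"term {t.term_id!r}: empty synonym list")
            if t.level == 1:
                if t.parent_id:
                    raise LexiconError(f"root term {t.term_id!r} must have no parent")
                if t.term_id != t.root_hallmark:
                    raise LexiconError(
                        f"root term id {t.term_id!r} must equal its hallmark id"
                    )
            else:
                parent = self._by_id.get(t.parent_id or "")
                if parent is None:
                    raise LexiconError(
                        f"term {t.term_id!r}: parent {t.parent_id!r} not found"
                    )
                if parent.level != t.level - 1:
                    raise LexiconError(
                        f"term {t.term_id!r} (level {t.level}) has parent at level "
                        f"{parent.level}; expected {t.level - 1}"
                    )
                if parent.root_hallmark != t.root_hallmark:
                    raise LexiconError(
                        f"term {t.term_id!r}: root differs from parent's root"
                    )

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def levels(self) -> set[int]:
        return {t.level for t in self.terms}

    def synonyms_by_root(self) -> dict[str, list[str]]:
        """All synonyms attributed to each root hallmark id."""
        out: dict[str, list[str]] = {h: [] for h in HALLMARK_IDS}
        for t in self.terms:
            out[t.root_hallmark].extend(t.synonyms)
        return out


class DiseaseDictionary:
    """ARD synonym dictionary; synonym collisions across ARDs are a load error."""

    def __init__(self, entries: Iterable[DiseaseEntry], excluded_ids: Iterable[str] = ()):
        all_entries = list(entries)
        ids = [e.ard_id for e in all_entries]
        if len(set(ids)) != len(ids):
            raise LexiconError("duplicate ARD ids in dictionary")
        self.excluded_ids: list[str] = list(excluded_ids)
        unknown = set(self.excluded_ids) - set(ids)
        if unknown:
            raise LexiconError(f"exclusions not in dictionary: {sorted(unknown)}")
        self.entries: list[DiseaseEntry] = [
            e for e in all_entries if e.ard_id not in set(self.excluded_ids)
        ]
        seen: dict[tuple[str, ...], str] = {}
        for e in self.entries:
            for syn in e.synonyms:
                key = tokenize(syn)
                if key in seen and seen[key] != e.ard_id:
                    raise LexiconError(
                        f"synonym {syn!r} maps to both {seen[key]!r} and {e.ard_id!r}"
                    )
                seen[key] = e.ard_id

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ard_ids(self) -> list[str]:
        return [e.ard_id for e in self.entries]

    def synonyms_by_id(self) -> dict[str, list[str]]:
        return {e.ard_id: list(e.synonyms) for e in self.entries}


class Matcher:
    """Token-sequence matcher from synonym dictionaries to root entity ids.

    Matching is case-insensitive and token-boundary safe: a synonym's
    token sequence must appear contiguously among the sentence's tokens,
    so e.g. ``ERK`` never matches inside ``BERKELEY``.  Overlapping
    synonyms all fire; deduplication happens at the entity level.
    """

    def __init__(self, synonym_map: Mapping[str, Iterable[str]]):
        # token-tuple -> set of entity ids
        self._index: dict[tuple[str, ...], set[str]] = {}
        self._max_len = 1
        for entity_id, synonyms in synonym_map.items():
            for syn in synonyms:
                toks = tokenize(syn)
                if not toks:
                    continue
                self._index.setdefault(toks, set()).add(entity_id)
                self._max_len = max(self._max_len, len(toks))
        self.entity_ids = sorted({e for s in self._index.values() for e in s})

    @classmethod
    def from_taxonomy(cls, taxonomy: Taxonomy) -> "Matcher":
        return cls(taxonomy.synonyms_by_root())

    @classmethod
    def from_dictionary(cls, dictionary: DiseaseDictionary) -> "Matcher":
        return cls(dictionary.synonyms_by_id())

    def match(self, sentence: str) -> set[str]:
        """Return the set of entity ids whose any synonym occurs in *sentence*."""
        tokens = tokenize(sentence)
        hits: set[str] = set()
        n = len(tokens)
        for i in range(n):
            upper = min(self._max_len, n - i)
            for length in range(1, upper + 1):
                entities = self._index.get(tokens[i : i + length])
                if entities:
                    hits.update(entities)
        return hits


def match_sentence(sentence: str, dictionary: Taxonomy | DiseaseDictionary | Matcher) -> set[str]:
    """Match one sentence against a taxonomy, disease dictionary, or prebuilt matcher.

    For repeated matching over a corpus build the :class:`Matcher` once
    and call :meth:`Matcher.match` directly.
    """
    if isinstance(dictionary, Matcher):
        return dictionary.match(sentence)
    if isinstance(dictionary, Taxonomy):
        return Matcher.from_taxonomy(dictionary).match(sentence)
    return Matcher.from_dictionary(dictionary).match(sentence)


def _split_synonyms(cell: str) -> tuple[str, ...]:
    return tuple(s.strip() for s in cell.split("|") if s.strip())


def load_taxonomy(path: str | Path | None = None) -> Taxonomy:
    """Load a hallmark taxonomy from delimited text.

    Columns (tab-separated, header row): ``term_id``, ``label``,
    ``level``, ``parent_id`` (empty for roots), ``root_hallmark``,
    ``synonyms`` (pipe-separated).  With no *path*, loads the packaged
    taxonomy (65 terms over four levels rooted in the nine hallmarks).
    """
    if path is None:
        path = packaged_taxonomy_path()
    terms = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("term_id"):
            raise LexiconError(f"{path}: missing header row")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise LexiconError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, got {len(fields)}"
                )
            term_id, label, level, parent_id, root, synonyms = fields
            try:
                level_i = int(level)
            except ValueError as exc:
                raise LexiconError(f"{path}:{lineno}: bad level {level!r}") from exc
            terms.append(
                TaxonomyTerm(
                    term_id=term_id,
                    label=label,
                    level=level_i,
                    parent_id=parent_id or None,
                    root_hallmark=root,
                    synonyms=_split_synonyms(synonyms),
                )
            )
    return Taxonomy(terms)


def load_disease_dictionary(
    path: str | Path, exclusions: Iterable[str] = ()
) -> DiseaseDictionary:
    """Load an ARD synonym dictionary from delimited text.

    Columns (tab-separated, header row): ``ard_id``, ``name``,
    ``synonyms`` (pipe-separated).  *exclusions* lists ARD ids removed
    before mining (diseases whose names do not mine well); they must be
    present in the file.
    """
    entries = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("ard_id"):
            raise LexiconError(f"{path}: missing header row")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise LexiconError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
                )
            ard_id, name, synonyms = fields
            entries.append(
                DiseaseEntry(ard_id=ard_id, name=name, synonyms=_split_synonyms(synonyms))
            )
    return DiseaseDictionary(entries, excluded_ids=list(exclusions))


def packaged_taxonomy_path() -> Path:
    """Path of the taxonomy file shipped with the package."""
    return Path(str(resources.files("hallmarknet").joinpath("data/hallmark_taxonomy.tsv")))
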