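"""Term dictionaries: loading, compilation, user extension.

A dictionary set binds, for one language, the concept term lists with their
negation lexicon and window, the numeric keyword markers, and the imaging
section vocabulary. Bundled sets exist for English and Italian; any YAML
file with the same schema can be loaded in their place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from .records import CONCEPT_FIELDS
from .textproc import tokenize


@dataclass
class TermDictionary:
    """Surface patterns for one extraction target."""

    concept_or_parameter: str
    terms: List[str]
    negators: List[str]
    window: int = 3
    token_terms: List[Tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"{self.concept_or_parameter}: empty term list")
        if self.window < 1:
            raise ValueError(f"{self.concept_or_parameter}: window must be >= 1")
        if not self.token_terms:
            self.token_terms = sorted(
                {tuple(t.text for t in tokenize(term)) for term in self.terms}
            )


@dataclass
class NumericSpec:
    parameter: str
    keywords: List[str]
    max_gap: int = 4
    compound_class: bool = False
    domain: Optional[Tuple[float, float]] = None
    token_keywords: List[Tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.token_keywords:
            self.token_keywords = sorted(
                {tuple(t.text for t in tokenize(k)) for k in self.keywords}
            )


@dataclass
class DiameterSpec:
    section_keywords: List[str]
    mm_units: List[str]
    cm_units: List[str]


@dataclass
class DictionarySet:
    language: str
    window: int
    negators: List[str]
    concepts: Dict[str, TermDictionary]
    numerics: Dict[str, NumericSpec]
    diameter: DiameterSpec

    def concept_dictionary(self, name: str) -> TermDictionary:
        return self.concepts[name]


def _from_mapping(data: dict) -> DictionarySet:
    window = int(data.get("window", 3))
    negators = [str(n).lower() for n in data["negators"]]
    concepts = {}
    for name, spec in data["concepts"].items():
        if name not in CONCEPT_FIELDS:
            raise ValueError(f"unknown concept in dictionary: {name}")
        concepts[name] = TermDictionary(
            concept_or_parameter=name,
            terms=list(spec["terms"]),
            negators=negators,
            window=int(spec.get("window", window)),
        )
    numerics = {}
    for name, spec in data["numerics"].items():
        domain = spec.get("domain")
        numerics[name] = NumericSpec(
            parameter=name,
            keywords=list(spec["keywords"]),
            max_gap=int(spec.get("max_gap", 4)),
            compound_class=bool(spec.get("compound_class", False)),
            domain=tuple(domain) if domain else None,
        )
    d = data["diameter"]
    diameter = DiameterSpec(
        section_keywords=[str(k).lower() for k in d["section_keywords"]],
        mm_units=[str(k).lower() for k in d["mm_units"]],
        cm_units=[str(k).lower() for k in d["cm_units"]],
    )
    return DictionarySet(
        language=str(data.get("language", "en")),
        window=window,
        negators=negators,
        concepts=concepts,
        numerics=numerics,
        diameter=diameter,
    )


def load_dictionary_file(path: Path) -> DictionarySet:
    with open(path, "r", encoding="utf-8") as fh:
        return _from_mapping(yaml.safe_load(fh))


def load_dictionaries(language: str = "en") -> DictionarySet:
    """Load one of the bundled dictionary sets ("en" or "it")."""
    name = f"lexicon_{language}.yaml"
    try:
        ref = resources.files("hepadecide").joinpath("data", name)
        text = ref.read_text(encoding="utf-8")
    except FileNotFoundError as exc:
        raise ValueError(f"no bundled dictionary for language {language!r}") from exc
    return _from_mapping(yaml.safe_load(text))
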