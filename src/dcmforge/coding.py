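"""Coded concepts and code registries.

Structured DICOM content replaces free text with *coded concepts*: tuples of
(code value, coding scheme designator, human-readable meaning, optional scheme
version) drawn from controlled terminologies such as SNOMED-CT (``SCT``), the
DICOM Controlled Terminology (``DCM``) and the Unified Code for Units of
Measure (``UCUM``).  This module provides the :class:`CodedConcept` atom used
throughout the package, its standard-defined equality semantics, small vetted
registries of frequently needed codes, and the "99"-prefix convention for
custom (site-defined) coding schemes.

Equality semantics
------------------
Two concepts are equal iff their code values and scheme designators match and,
*when both carry a scheme version*, the versions match as well.  A version on
only one operand acts as a disambiguator, not a discriminator, and is ignored.
The ``meaning`` field is display text and never participates in comparison;
a meaning mismatch between otherwise equal concepts emits a warning.
Designator comparison is case-sensitive (exact match).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterator, Optional

from pydicom.dataset import Dataset

from .errors import CodingError, RegistryLookupError

__all__ = [
    "CodedConcept",
    "CodeRegistry",
    "concepts_equal",
    "registry_lookup",
    "get_registry",
    "classify_scheme",
    "codes",
    "STANDARD_SCHEMES",
]

#: Designators of the coding schemes shipped with the package.
STANDARD_SCHEMES = frozenset({"SCT", "DCM", "UCUM", "RFC5646"})

_MAX_CODE_LEN = 16
_MAX_MEANING_LEN = 64


def _check_field(name: str, value: str, max_len: int) -> None:
    if not isinstance(value, str) or not value:
        raise CodingError(f"{name} must be a non-empty string")
    if len(value) > max_len:
        raise CodingError(f"{name} {value!r} exceeds {max_len} characters")
    if any(ord(c) < 0x20 or ord(c) == 0x7F for c in value):
        raise CodingError(f"{name} {value!r} contains control characters")


@dataclass(frozen=True, eq=False)
class CodedConcept:
    """A coded entry from a controlled terminology.

    Parameters
    ----------
    value:
        Code value, 1–16 characters, no control characters.
    scheme_designator:
        Designator of the coding scheme (e.g. ``"SCT"``), 1–16 characters.
    meaning:
        Human-readable meaning, 1–64 characters.  Display text only; never
        part of equality.
    scheme_version:
        Optional coding scheme version.
    """

    value: str
    scheme_designator: str
    meaning: str
    scheme_version: Optional[str] = None

    def __post_init__(self) -> None:
        _check_field("value", self.value, _MAX_CODE_LEN)
        _check_field("scheme_designator", self.scheme_designator, _MAX_CODE_LEN)
        _check_field("meaning", self.meaning, _MAX_MEANING_LEN)
        if self.scheme_version is not None:
            _check_field("scheme_version", self.scheme_version, _MAX_CODE_LEN)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CodedConcept):
            return NotImplemented
        return concepts_equal(self, other)

    def __ne__(self, other: object) -> bool:
        result = self.__eq__(other)
        return NotImplemented if result is NotImplemented else not result

    def __hash__(self) -> int:
        # Version is excluded: concepts differing only by version hash alike,
        # which keeps hashing consistent with the equality relation.
        return hash((self.value, self.scheme_designator))

    def to_dataset(self) -> Dataset:
        """Serialize to the DICOM code-sequence item attributes."""
        ds = Dataset()
        ds.CodeValue = self.value
        ds.CodingSchemeDesignator = self.scheme_designator
        ds.CodeMeaning = self.meaning
        if self.scheme_version is not None:
            ds.CodingSchemeVersion = self.scheme_version
        return ds

    @classmethod
    def from_dataset(cls, ds: Dataset) -> "CodedConcept":
        """Read a concept back from a code-sequence item."""
        return cls(
            value=str(ds.CodeValue),
            scheme_designator=str(ds.CodingSchemeDesignator),
            meaning=str(ds.CodeMeaning),
            scheme_version=(
                str(ds.CodingSchemeVersion)
                if "CodingSchemeVersion" in ds
                else None
            ),
        )


def concepts_equal(a: CodedConcept, b: CodedConcept) -> bool:
    """Standard-defined equality of two coded concepts.

    True iff code values and scheme designators match and the scheme versions
    match whenever both are present.  ``meaning`` never participates; a
    mismatch in meaning between equal codes raises a ``UserWarning`` because
    it usually indicates a transcription slip upstream.
    """
    if a.value != b.value or a.scheme_designator != b.scheme_designator:
        return False
    if a.scheme_version is not None and b.scheme_version is not None:
        if a.scheme_version != b.scheme_version:
            return False
    if a.meaning != b.meaning:
        warnings.warn(
            f"concepts ({a.value}, {a.scheme_designator}) compare equal but "
            f"carry different meanings: {a.meaning!r} vs {b.meaning!r}",
            UserWarning,
            stacklevel=2,
        )
    return True


class CodeRegistry:
    """A keyword-indexed collection of concepts from one coding scheme."""

    def __init__(self, scheme_designator: str):
        self.scheme_designator = scheme_designator
        self._entries: Dict[str, CodedConcept] = {}

    def add(self, keyword: str, concept: CodedConcept) -> None:
        if concept.scheme_designator != self.scheme_designator:
            raise CodingError(
                f"concept scheme {concept.scheme_designator!r} does not match "
                f"registry {self.scheme_designator!r}"
            )
        if keyword in self._entries:
            raise CodingError(
                f"duplicate keyword {keyword!r} in registry "
                f"{self.scheme_designator!r}"
            )
        self._entries[keyword] = concept

    def __getattr__(self, keyword: str) -> CodedConcept:
        if keyword.startswith("_"):
            raise AttributeError(keyword)
        try:
            return self._entries[keyword]
        except KeyError:
            raise RegistryLookupError(self.scheme_designator, keyword) from None

    def __getitem__(self, keyword: str) -> CodedConcept:
        return self.__getattr__(keyword)

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def keywords(self):
        return list(self._entries)


def _load_registries() -> Dict[str, CodeRegistry]:
    registries: Dict[str, CodeRegistry] = {}
    path = resources.files("dcmforge.data").joinpath("codes.csv")
    with path.open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            reg = registries.setdefault(
                row["registry"], CodeRegistry(row["registry"])
            )
            reg.add(
                row["keyword"],
                CodedConcept(
                    value=row["value"],
                    scheme_designator=row["designator"],
                    meaning=row["meaning"],
                ),
            )
    return registries


class _CodeNamespace:
    """Attribute access to the shipped registries, e.g. ``codes.SCT.Tumor``."""

    def __init__(self) -> None:
        self._registries = _load_registries()

    def __getattr__(self, scheme: str) -> CodeRegistry:
        if scheme.startswith("_"):
            raise AttributeError(scheme)
        try:
            return self._registries[scheme]
        except KeyError:
            raise RegistryLookupError("<registries>", scheme) from None

    def registries(self) -> Dict[str, CodeRegistry]:
        return dict(self._registries)


#: Shipped code registries, loaded from ``data/codes.csv`` at import time.
codes = _CodeNamespace()


def get_registry(scheme: str) -> CodeRegistry:
    """Return the shipped registry for ``scheme`` (e.g. ``"SCT"``)."""
    return getattr(codes, scheme)


def registry_lookup(scheme: str, keyword: str) -> CodedConcept:
    """Look up a concept by registry id and keyword.

    Raises
    ------
    RegistryLookupError
        If the registry exists but the keyword does not (the error names the
        registry), or if the registry itself is unknown.
    """
    return get_registry(scheme)[keyword]


def classify_scheme(designator: str) -> str:
    """Classify a coding scheme designator.

    Returns ``"custom"`` for designators following the site-defined scheme
    convention — a ``"99"`` prefix followed by at least one identifying
    character — ``"standard"`` for schemes shipped with the package, and
    ``"unknown"`` otherwise.
    """
    if not isinstance(designator, str) or not designator:
        raise CodingError("designator must be a non-empty string")
    if designator.startswith("99") and len(designator) > 2:
        return "custom"
    if designator in STANDARD_SCHEMES:
        return "standard"
    return "unknown"
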