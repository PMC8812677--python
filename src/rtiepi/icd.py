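"""ICD-10 code-set compilation and diagnosis matching.

The analysis hinges on deciding whether a health-care contact is
"RTI-relevant": whether any of its registered ICD-10 diagnoses falls in a
configured set of respiratory-tract-infection codes.  The set is given as a
list of code-or-range strings (``"J00-J06"``, ``"J20"``, ``"R06.0"``,
``"ZV100"``) and compiled once into a prefix matcher.

Matching semantics (standard claims-data practice):

* codes are normalised by uppercasing and stripping dots, so ``"J06.9"``
  and ``"J069"`` are equivalent;
* a listed code covers itself and all of its subdivisions (``J20`` covers
  ``J20.9``); a four-character entry such as ``R06.0`` covers ``R06.0`` and
  deeper subdivisions but not its siblings (``R06.1`` does not match);
* a range like ``J00-J06`` expands to every three-character code it spans,
  each matched with the same prefix semantics;
* national-extension codes (``ZV100``) are matched as literal prefixes with
  no validity check against the WHO classification.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "DEFAULT_RTI_CODES",
    "CodeSetError",
    "CompiledCodeSet",
    "normalize_code",
    "compile_code_set",
    "is_rti_relevant",
]

#: Default RTI-relevant diagnosis set: acute upper respiratory infections,
#: influenza/pneumonia, acute bronchitis, unspecified acute lower respiratory
#: infection, cough, dyspnea, fever, unspecified corona-/viral infections,
#: otitis media and mastoiditis, COVID-19, and the Swedish ICD-10-SE
#: coronavirus-related care code.
DEFAULT_RTI_CODES: tuple[str, ...] = (
    "J00-J06",
    "J10-J18",
    "J20",
    "J22",
    "R05",
    "R06.0",
    "R50",
    "B34.2",
    "B39",
    "B99",
    "H65-H70",
    "U07.1",
    "U07.2",
    "ZV100",
)


class CodeSetError(ValueError):
    """A code-set entry could not be parsed."""


_CODE_RE = re.compile(r"^[A-Z][A-Z0-9]{2,6}$")
_RANGE_RE = re.compile(r"^([A-Z])(\d{2})-([A-Z])(\d{2})$")


def normalize_code(code: str) -> str:
    """Uppercase and strip dots/whitespace from an ICD-10 code string."""
    return code.replace(".", "").replace(" ", "").upper()


@dataclass(frozen=True)
class CompiledCodeSet:
    """Deterministic, normalised form of a code-set specification.

    ``prefixes`` match a diagnosis if the diagnosis starts with the prefix
    (descendant expansion); ``exact`` codes match only themselves.  The
    default configuration uses prefixes exclusively.
    """

    prefixes: frozenset[str]
    exact: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        # group prefixes by length so matching is a few set lookups
        by_len: dict[int, frozenset[str]] = {}
        for n in {len(p) for p in self.prefixes}:
            by_len[n] = frozenset(p for p in self.prefixes if len(p) == n)
        object.__setattr__(self, "_by_len", by_len)

    def matches(self, code: str) -> bool:
        """True if ``code`` (any dialect) equals or descends from the set."""
        c = normalize_code(code)
        if not _CODE_RE.match(c):
            return False
        if c in self.exact:
            return True
        for n, prefixes in self._by_len.items():  # type: ignore[attr-defined]
            if len(c) >= n and c[:n] in prefixes:
                return True
        return False

    def __len__(self) -> int:
        return len(self.prefixes) + len(self.exact)


def _expand_range(entry: str, normalized: str) -> list[str]:
    m = _RANGE_RE.match(normalized)
    if m is None:
        raise CodeSetError(
            f"cannot parse code-range entry {entry!r}: expected e.g. 'J00-J06'"
        )
    left_letter, left_num, right_letter, right_num = m.groups()
    if left_letter != right_letter:
        raise CodeSetError(
            f"range entry {entry!r} mixes letter prefixes "
            f"({left_letter} vs {right_letter})"
        )
    lo, hi = int(left_num), int(right_num)
    if lo > hi:
        raise CodeSetError(f"range entry {entry!r} has start > end")
    return [f"{left_letter}{i:02d}" for i in range(lo, hi + 1)]


def compile_code_set(entries: Iterable[str]) -> CompiledCodeSet:
    """Compile code-or-range strings into a :class:`CompiledCodeSet`.

    Ranges are expanded inclusively to every three-character code they span;
    single codes become literal prefixes.  Raises :class:`CodeSetError` for
    malformed entries, naming the offending entry.
    """
    prefixes: set[str] = set()
    for entry in entries:
        norm = normalize_code(str(entry))
        if "-" in norm:
            prefixes.update(_expand_range(entry, norm))
        elif _CODE_RE.match(norm):
            prefixes.add(norm)
        else:
            raise CodeSetError(f"cannot parse code entry {entry!r}")
    return CompiledCodeSet(prefixes=frozenset(prefixes))


def is_rti_relevant(diagnoses: Sequence[str], codeset: CompiledCodeSet) -> bool:
    """True iff at least one registered diagnosis matches the code set.

    Empty, blank or unparseable diagnosis strings never match; a contact
    with no registered diagnosis is therefore never RTI-relevant.
    """
    return any(d and codeset.matches(d) for d in diagnoses)
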