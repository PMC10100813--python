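"""Trait combination types (TCTs) of dicot leaves.

A TCT encodes four binary architectural characters of a dicot leaf —
lobation (lobed / unlobed), margin (entire / toothed), primary venation
(pinnate / palmate) and secondary venation (looped / non-looped) — into one
of sixteen classes lettered ``A``–``P``.  Recording the TCT spectrum of a
fossil assemblage summarises its leaf-architectural diversity; individual
characters (e.g. the toothed-margin fraction) carry a climatic signal, and
certain letters track leaf economics (entire-margined, loop-veined leaves
are typically evergreen, toothed non-looped leaves deciduous).

Three assignment routes are supported:

* *specimen-based*: the four characters are read directly off the fossil;
* *taxonomy-based*: the letter implied by the fossil-species diagnosis;
* *combined*: specimen-based where possible, falling back to the taxonomy
  route when (only) the secondary venation is unreadable and the species
  diagnosis is unambiguous.

Secondary venation is the character most often lost to preservation, so an
8-class coarsening ("TCT classes", e.g. ``E/F``) that merges letters
differing only in that character is also provided.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "TraitQuartet",
    "TCTMap",
    "default_tct_map",
    "classify",
    "assign_combined",
    "tct_class",
    "tct_spectrum",
    "UNKNOWN",
]

UNKNOWN = "unknown"

LOBATION = ("unlobed", "lobed")
MARGIN = ("entire", "toothed")
PRIMARY = ("pinnate", "palmate")
SECONDARY = ("looped", "non-looped")

LETTERS = "ABCDEFGHIJKLMNOP"


@dataclass(frozen=True)
class TraitQuartet:
    """The four binary leaf-architecture characters of one leaf.

    Any character may be :data:`UNKNOWN`; classification then fails (first
    three characters) or falls back to class-level output (secondary
    venation only).
    """

    lobation: str = UNKNOWN
    margin: str = UNKNOWN
    primary_venation: str = UNKNOWN
    secondary_venation: str = UNKNOWN

    def __post_init__(self) -> None:
        for value, allowed in (
            (self.lobation, LOBATION),
            (self.margin, MARGIN),
            (self.primary_venation, PRIMARY),
            (self.secondary_venation, SECONDARY),
        ):
            if value != UNKNOWN and value not in allowed:
                raise ValueError(
                    f"invalid character state {value!r}; expected one of "
                    f"{allowed} or {UNKNOWN!r}"
                )

    @property
    def complete(self) -> bool:
        return UNKNOWN not in (
            self.lobation,
            self.margin,
            self.primary_venation,
            self.secondary_venation,
        )

    def as_tuple(self) -> tuple[str, str, str, str]:
        return (
            self.lobation,
            self.margin,
            self.primary_venation,
            self.secondary_venation,
        )


class TCTMap:
    """A total, injective mapping of the 16 character quartets to letters A–P.

    The letter table is data, not doctrine: the canonical published table is
    loadable from CSV, and :func:`default_tct_map` provides a nested
    enumeration that satisfies every anchor stated for the two Oligocene
    assemblages this package was written around (A = unlobed/entire/
    pinnate/looped, F = unlobed/toothed/pinnate/non-looped, P = lobed/
    toothed/palmate/non-looped, ...).
    """

    def __init__(self, table: Mapping[tuple[str, str, str, str], str]):
        if len(table) != 16:
            raise ValueError(f"TCT map must have 16 entries, got {len(table)}")
        letters = set(table.values())
        if letters != set(LETTERS):
            raise ValueError("TCT map must be a bijection onto letters A..P")
        self._forward = dict(table)
        self._inverse = {v: k for k, v in table.items()}

    def letter(self, quartet: TraitQuartet) -> str:
        return self._forward[quartet.as_tuple()]

    def quartet(self, letter: str) -> TraitQuartet:
        return TraitQuartet(*self._inverse[letter])

    def items(self):
        return self._forward.items()

    @classmethod
    def from_csv(cls, path) -> "TCTMap":
        """Load a map from CSV with columns
        lobation,margin,primary_venation,secondary_venation,letter."""
        table = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                key = (
                    row["lobation"].strip(),
                    row["margin"].strip(),
                    row["primary_venation"].strip(),
                    row["secondary_venation"].strip(),
                )
                table[key] = row["letter"].strip().upper()
        return cls(table)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["lobation", "margin", "primary_venation",
                 "secondary_venation", "letter"]
            )
            for key, letter in sorted(self._forward.items(),
                                      key=lambda kv: kv[1]):
                writer.writerow([*key, letter])


def default_tct_map() -> TCTMap:
    """The default letter table: nested enumeration of the quartets.

    Characters are ordered lobation -> margin -> primary -> secondary with
    state order (unlobed, lobed), (entire, toothed), (pinnate, palmate),
    (looped, non-looped); letters A..P follow that enumeration.  E.g.
    A = unlobed/entire/pinnate/looped and P = lobed/toothed/palmate/
    non-looped.
    """
    table = {}
    i = 0
    for lob in LOBATION:
        for mar in MARGIN:
            for pri in PRIMARY:
                for sec in SECONDARY:
                    table[(lob, mar, pri, sec)] = LETTERS[i]
                    i += 1
    return TCTMap(table)


def classify(quartet: TraitQuartet, tct_map: TCTMap | None = None) -> str | None:
    """Letter of a fully observed quartet, or ``None`` when unclassifiable.

    Any :data:`UNKNOWN` character makes the leaf unclassifiable at the
    16-type level; no state is ever guessed.  Unclassifiable is a value,
    not an exception — such specimens are excluded downstream.
    """
    if not quartet.complete:
        return None
    if tct_map is None:
        tct_map = default_tct_map()
    return tct_map.letter(quartet)


def assign_combined(
    quartet: TraitQuartet,
    diagnosis: Iterable[str] | None = None,
    tct_map: TCTMap | None = None,
) -> str | None:
    """Combined specimen- and taxonomy-based TCT assignment.

    Direct observation wins whenever all four characters are readable.
    Otherwise the fossil-species diagnosis is consulted: if it implies
    exactly one letter, that letter is used; an ambiguous (multi-letter)
    or absent diagnosis leaves the specimen unassigned.

    Parameters
    ----------
    quartet
        Characters observed on the specimen itself.
    diagnosis
        The set of letters compatible with the specimen's fossil-species
        diagnosis, or ``None`` when the species is indeterminate.
    """
    specimen_letter = classify(quartet, tct_map)
    if specimen_letter is not None:
        return specimen_letter
    if diagnosis is None:
        return None
    letters = {d.strip().upper() for d in diagnosis if d and d.strip()}
    if len(letters) == 1:
        return next(iter(letters))
    return None


def tct_class(letter: str, tct_map: TCTMap | None = None) -> str:
    """Coarsen a letter to its 8-class label ignoring secondary venation.

    Letters whose quartets differ only in secondary venation are merged
    and labelled with both letters in A..P order, e.g. ``"E/F"``.
    """
    if tct_map is None:
        tct_map = default_tct_map()
    q = tct_map.quartet(letter)
    partners = sorted(
        lt
        for quartet, lt in tct_map.items()
        if quartet[:3] == q.as_tuple()[:3]
    )
    return "/".join(partners)


def tct_spectrum(letters: Iterable[str | None]) -> "pandas.DataFrame":  # noqa: F821
    """Frequency table of TCT letters over a collection of assignments.

    ``None`` entries (unclassifiable specimens) are counted in the
    denominator of ``percent_total`` — matching how assemblage-level
    spectra are reported, with all scored leaves as the base — and excluded
    from ``percent_assigned``.  Both denominators are returned so either
    convention can be read off.
    """
    import pandas as pd

    letters = list(letters)
    n_total = len(letters)
    assigned = [lt for lt in letters if lt is not None]
    n_assigned = len(assigned)
    counts = pd.Series(assigned, dtype="object").value_counts().sort_index()
    frame = pd.DataFrame(
        {
            "count": counts,
            "percent_total": 100.0 * counts / n_total if n_total else 0.0,
            "percent_assigned": (
                100.0 * counts / n_assigned if n_assigned else 0.0
            ),
        }
    )
    frame.index.name = "tct"
    frame.attrs["n_total"] = n_total
    frame.attrs["n_assigned"] = n_assigned
    frame.attrs["n_unassigned"] = n_total - n_assigned
    return frame
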