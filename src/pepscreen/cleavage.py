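"""Declarative protease specificity rules and in silico digestion.

A protease is described by position patterns in Schechter-Berger
nomenclature: P4..P1 name the residues on the amino-terminal side of the
scissile bond and P1'..P4' those on the carboxy-terminal side; hydrolysis
occurs at the P1-P1' bond.  A cleavage site is reported at a between-residue
index ``i`` (0-based: the bond between ``seq[i-1]`` and ``seq[i]``) when at
least one site pattern matches there and no exception pattern does.  A
pattern position that falls outside the sequence is treated as a non-match,
which makes sequential digestion of fragments conservative: context lost at
a fragment terminus can never create a new site.

Digestion is exhaustive (every matching bond is cut, no missed cleavages),
so the fragments of one round tile the parent exactly.  Sequential
multi-enzyme digestion applies each enzyme in turn to every fragment of the
previous round, keeping coordinates relative to the original protein.
"""

from __future__ import annotations

import hashlib
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping, Sequence

import yaml

from .errors import InputError, SchemaError

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity / non-standard codes tolerated in input sequences.  They never
#: satisfy a constrained pattern position, so the default policy is
#: "never cleave at an ambiguous residue".
AMBIGUITY_CODES = "BXZU"

_ALPHABET = frozenset(STANDARD_RESIDUES)
_FULL_ALPHABET = frozenset(STANDARD_RESIDUES + AMBIGUITY_CODES)

#: Schechter-Berger label -> offset of the residue relative to the cleavage
#: index i (cleavage between seq[i-1] and seq[i]).  P1 is seq[i-1], P1' is
#: seq[i].
POSITION_OFFSETS: Mapping[str, int] = {
    "P4": -4, "P3": -3, "P2": -2, "P1": -1,
    "P1'": 0, "P2'": 1, "P3'": 2, "P4'": 3,
}


def _compile_pattern(positions: Mapping[str, frozenset[str]]) -> re.Pattern[str]:
    """Compile one position pattern to a zero-width regex.

    The regex matches at index ``i`` of a string iff every constrained
    position holds.  Fixed-width lookbehind/lookahead automatically fail
    near the termini, implementing the out-of-range-is-non-match rule.
    """
    offsets = {POSITION_OFFSETS[label]: allowed for label, allowed in positions.items()}
    behind = -min(min(offsets), 0)
    ahead = max(max(offsets) + 1, 0)
    parts = []
    if behind:
        body = "".join(
            "[%s]" % "".join(sorted(offsets[off])) if off in offsets else "."
            for off in range(-behind, 0)
        )
        parts.append("(?<=%s)" % body)
    if ahead:
        body = "".join(
            "[%s]" % "".join(sorted(offsets[off])) if off in offsets else "."
            for off in range(0, ahead)
        )
        parts.append("(?=%s)" % body)
    return re.compile("".join(parts))


def _parse_positions(raw: Mapping[str, str], context: str) -> dict[str, frozenset[str]]:
    positions: dict[str, frozenset[str]] = {}
    for label, residues in raw.items():
        if label not in POSITION_OFFSETS:
            raise SchemaError(f"{context}: unknown position label {label!r}")
        residues = str(residues).upper()
        bad = set(residues) - _ALPHABET
        if bad:
            raise SchemaError(
                f"{context}: residue letters {sorted(bad)} outside the standard alphabet"
            )
        if not residues:
            raise SchemaError(f"{context}: empty residue set at {label}")
        positions[label] = frozenset(residues)
    if not positions:
        raise SchemaError(f"{context}: pattern constrains no position")
    if "P1" not in positions and "P1'" not in positions:
        raise SchemaError(f"{context}: pattern must constrain P1 or P1'")
    return positions


@dataclass(frozen=True)
class CleavageRule:
    """Specificity of one protease: site patterns minus exception patterns."""

    site_patterns: tuple[Mapping[str, frozenset[str]], ...]
    exception_patterns: tuple[Mapping[str, frozenset[str]], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_site_rx", tuple(_compile_pattern(p) for p in self.site_patterns)
        )
        object.__setattr__(
            self, "_exc_rx", tuple(_compile_pattern(p) for p in self.exception_patterns)
        )

    @property
    def is_context_free(self) -> bool:
        """True when every pattern constrains only P1 and/or P1'.

        Context-free rules are idempotent under re-digestion: cutting a
        fragment again with the same enzyme changes nothing.
        """
        return all(
            set(p) <= {"P1", "P1'"}
            for p in (*self.site_patterns, *self.exception_patterns)
        )

    def sites(self, sequence: str) -> list[int]:
        found: set[int] = set()
        for rx in self._site_rx:  # type: ignore[attr-defined]
            found.update(m.start() for m in rx.finditer(sequence))
        n = len(sequence)
        out = []
        for i in sorted(found):
            if not 1 <= i <= n - 1:
                continue
            if any(rx.match(sequence, i) for rx in self._exc_rx):  # type: ignore[attr-defined]
                continue
            out.append(i)
        return out


@dataclass(frozen=True)
class Enzyme:
    """A named protease with its cleavage rule."""

    name: str
    rule: CleavageRule


@dataclass(frozen=True)
class PeptideFragment:
    """A digestion product located on its parent protein.

    Coordinates are 0-based half-open in the *original* parent sequence,
    also through sequential rounds; ``enzyme_chain`` lists the enzymes that
    produced it, in application order.
    """

    sequence: str
    parent: str
    start: int
    end: int
    enzyme_chain: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise InputError(
                f"invalid fragment coordinates {self.start}..{self.end} on {self.parent!r}"
            )
        if len(self.sequence) != self.end - self.start:
            raise InputError(
                f"fragment sequence length {len(self.sequence)} does not match "
                f"coordinates {self.start}..{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


def _validate_sequence(sequence: str, ambiguity: str) -> None:
    if not sequence:
        raise InputError("cannot digest an empty sequence")
    letters = set(sequence)
    unknown = letters - _FULL_ALPHABET
    if unknown:
        raise InputError(f"residues {sorted(unknown)} outside the supported alphabet")
    if ambiguity == "error":
        ambiguous = letters & set(AMBIGUITY_CODES)
        if ambiguous:
            raise InputError(
                f"ambiguous residues {sorted(ambiguous)} present and ambiguity policy is 'error'"
            )
    elif ambiguity != "never-cleave":
        raise InputError(f"unknown ambiguity policy {ambiguity!r}")


def find_cleavage_sites(sequence: str, enzyme: Enzyme, *, ambiguity: str = "never-cleave") -> list[int]:
    """Return the sorted between-residue cleavage indices of ``enzyme``.

    Site ``i`` means hydrolysis between ``sequence[i-1]`` and
    ``sequence[i]``; sites are strictly internal (``1 <= i <= len-1``).
    """
    sequence = sequence.upper()
    _validate_sequence(sequence, ambiguity)
    return enzyme.rule.sites(sequence)


def digest(
    sequence: str,
    enzyme: Enzyme,
    *,
    parent: str = "",
    offset: int = 0,
    chain: tuple[str, ...] = (),
    ambiguity: str = "never-cleave",
) -> list[PeptideFragment]:
    """Cut ``sequence`` at every site of ``enzyme``.

    The returned fragments tile ``[offset, offset + len(sequence))`` with no
    gaps or overlaps; an enzyme with no sites returns the whole sequence as
    a single fragment.
    """
    sequence = sequence.upper()
    sites = find_cleavage_sites(sequence, enzyme, ambiguity=ambiguity)
    bounds = [0, *sites, len(sequence)]
    new_chain = (*chain, enzyme.name)
    return [
        PeptideFragment(
            sequence=sequence[a:b],
            parent=parent,
            start=offset + a,
            end=offset + b,
            enzyme_chain=new_chain,
        )
        for a, b in zip(bounds, bounds[1:])
    ]


def sequential_digest(
    protein,
    combination: Sequence,
    library: "EnzymeLibrary | None" = None,
    *,
    ambiguity: str = "never-cleave",
) -> list[PeptideFragment]:
    """Digest with several enzymes applied one after another.

    ``protein`` may be a plain sequence string or any object with
    ``accession`` and ``sequence`` attributes.  ``combination`` holds enzyme
    names (resolved through ``library``) or :class:`Enzyme` objects.  The
    first enzyme sees the full protein; every later enzyme digests each
    fragment of the previous round independently, so pattern context is
    truncated at fragment termini.
    """
    if not combination:
        raise InputError("enzyme combination must contain at least one enzyme")
    accession = getattr(protein, "accession", "")
    sequence = getattr(protein, "sequence", protein)
    enzymes: list[Enzyme] = []
    for item in combination:
        if isinstance(item, Enzyme):
            enzymes.append(item)
        else:
            if library is None:
                raise InputError("a library is required to resolve enzyme names")
            enzymes.append(library[item])

    fragments = digest(sequence, enzymes[0], parent=accession, ambiguity=ambiguity)
    for enzyme in enzymes[1:]:
        fragments = [
            sub
            for frag in fragments
            for sub in digest(
                frag.sequence,
                enzyme,
                parent=accession,
                offset=frag.start,
                chain=frag.enzyme_chain,
                ambiguity=ambiguity,
            )
        ]
    return fragments


def length_filter(
    fragments: Iterable[PeptideFragment], min_len: int = 5, max_len: int = 30
) -> list[PeptideFragment]:
    """Keep fragments whose length lies in the inclusive ``[min_len, max_len]``."""
    if not 1 <= min_len <= max_len:
        raise InputError(f"invalid length bounds ({min_len}, {max_len})")
    return [f for f in fragments if min_len <= len(f) <= max_len]


class EnzymeLibrary:
    """A named, checksummed collection of enzymes loaded from a rule file."""

    def __init__(self, enzymes: Iterable[Enzyme], *, source: str = "<memory>", checksum: str = ""):
        self._enzymes: dict[str, Enzyme] = {}
        for enz in enzymes:
            if enz.name in self._enzymes:
                raise SchemaError(f"duplicate enzyme name {enz.name!r} in library")
            self._enzymes[enz.name] = enz
        if not self._enzymes:
            warnings.warn("enzyme library is empty", stacklevel=2)
        self.source = source
        self.checksum = checksum

    def __len__(self) -> int:
        return len(self._enzymes)

    def __iter__(self) -> Iterator[Enzyme]:
        return iter(self._enzymes.values())

    def __contains__(self, name: str) -> bool:
        return name in self._enzymes

    def __getitem__(self, name: str) -> Enzyme:
        try:
            return self._enzymes[name]
        except KeyError:
            raise InputError(f"unknown enzyme {name!r}") from None

    @property
    def names(self) -> list[str]:
        return list(self._enzymes)

    def subset(self, names: Sequence[str]) -> "EnzymeLibrary":
        return EnzymeLibrary(
            [self[n] for n in names], source=self.source, checksum=self.checksum
        )


def _enzyme_from_mapping(doc: Mapping, context: str) -> Enzyme:
    if not isinstance(doc, Mapping) or "name" not in doc:
        raise SchemaError(f"{context}: enzyme entry must be a mapping with a 'name'")
    name = str(doc["name"])
    sites = doc.get("sites") or []
    exceptions = doc.get("exceptions") or []
    if not isinstance(sites, list) or not isinstance(exceptions, list):
        raise SchemaError(f"{context}: 'sites' and 'exceptions' must be lists")
    rule = CleavageRule(
        site_patterns=tuple(
            _parse_positions(p, f"{name}: site pattern {i}") for i, p in enumerate(sites)
        ),
        exception_patterns=tuple(
            _parse_positions(p, f"{name}: exception pattern {i}")
            for i, p in enumerate(exceptions)
        ),
    )
    return Enzyme(name=name, rule=rule)


def parse_enzyme_library(path) -> EnzymeLibrary:
    """Load an enzyme library from a YAML rule file."""
    with open(path, "rb") as fh:
        raw = fh.read()
    checksum = hashlib.sha256(raw).hexdigest()
    doc = yaml.safe_load(raw) or {}
    entries = doc.get("enzymes") or []
    enzymes = [_enzyme_from_mapping(e, str(path)) for e in entries]
    return EnzymeLibrary(enzymes, source=str(path), checksum=checksum)


def bundled_library() -> EnzymeLibrary:
    """The 40-protease library shipped with the package."""
    ref = resources.files("pepscreen.data") / "enzymes.yaml"
    with resources.as_file(ref) as path:
        return parse_enzyme_library(path)
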