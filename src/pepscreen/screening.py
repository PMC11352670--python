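"""Exhaustive ordered enzyme-combination screening.

A depth-k combination is an ordered k-tuple of enzyme names in which
consecutive entries differ (the same enzyme applied twice in a row adds
nothing under exhaustive digestion).  Over a library of n enzymes there are
n * (n-1)^(k-1) such tuples: 1,560 ordered pairs and 60,840 ordered triples
for the bundled 40-enzyme library.  Each combination sequentially digests
every substrate, products are length-filtered and pooled across substrates,
deduplicated by sequence, and counted per bioactivity class via a
multi-label predictor; a peptide positive for several classes increments
each of them.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .cleavage import EnzymeLibrary
from .errors import InputError
from .predictors import BIOACTIVITY_CLASSES, BioactivityPredictor, predict_bioactivity


@dataclass(frozen=True, order=True)
class EnzymeCombination:
    """An ordered tuple of enzyme names; display name joins them with '_'."""

    enzymes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.enzymes) < 1:
            raise InputError("a combination needs at least one enzyme")
        for a, b in zip(self.enzymes, self.enzymes[1:]):
            if a == b:
                raise InputError(f"consecutive duplicate enzyme {a!r} in combination")

    @property
    def display_name(self) -> str:
        return "_".join(self.enzymes)


@dataclass(frozen=True)
class ScreenConfig:
    """Length bounds, class labels and dedupe behaviour of a screen."""

    min_len: int = 5
    max_len: int = 30
    classes: tuple[str, ...] = BIOACTIVITY_CLASSES
    dedupe: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.min_len <= self.max_len:
            raise InputError(f"invalid length bounds ({self.min_len}, {self.max_len})")
        if tuple(self.classes) != BIOACTIVITY_CLASSES:
            raise InputError(f"class labels are fixed to {BIOACTIVITY_CLASSES}")


def enumerate_combinations(library, k: int) -> list[EnzymeCombination]:
    """All ordered k-tuples with distinct consecutive entries.

    ``library`` is an :class:`EnzymeLibrary` or a sequence of names.
    Output is in lexicographic order of the name tuples, so enumeration is
    deterministic and independent of library insertion order.
    """
    if k < 1:
        raise InputError("combination depth k must be >= 1")
    names = sorted(library.names if isinstance(library, EnzymeLibrary) else library)
    if not names:
        raise InputError("cannot enumerate combinations over an empty library")

    def extend(prefix: tuple[str, ...]) -> Iterator[tuple[str, ...]]:
        if len(prefix) == k:
            yield prefix
            return
        for name in names:
            if prefix and prefix[-1] == name:
                continue
            yield from extend((*prefix, name))

    return [EnzymeCombination(t) for t in extend(())]


@dataclass
class ScreenResult:
    """Per-combination, per-class unique-peptide counts plus provenance."""

    counts: dict[str, dict[str, int]]            # display_name -> class -> count
    unique_peptides: dict[str, int]              # display_name -> unique peptide count
    combinations: list[EnzymeCombination]
    config: ScreenConfig
    provenance: dict

    def class_totals(self) -> dict[str, int]:
        """Unique peptides per class pooled over all combinations.

        This is a different convention from the per-combination counts: a
        peptide produced by several combinations is counted once here.
        """
        pooled: dict[str, set[str]] = {c: set() for c in self.config.classes}
        for combo, by_class in self._positives.items():
            for cls, seqs in by_class.items():
                pooled[cls].update(seqs)
        return {c: len(s) for c, s in pooled.items()}

    # populated by screen(); maps display_name -> class -> positive sequences
    _positives: dict[str, dict[str, set[str]]] = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"combination": combo, "class": cls, "count": cnt}
            for combo, by_class in sorted(self.counts.items())
            for cls, cnt in sorted(by_class.items())
        ]
        return pd.DataFrame(rows, columns=["combination", "class", "count"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_provenance(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")


class DigestCache:
    """Memoized fragment computation shared across combinations.

    Site finding is deterministic per (enzyme, sequence), so fragments can
    be cached: the first-round digest of a protein is identical for every
    combination starting with the same enzyme, and later rounds reuse
    digests of recurring fragment sequences.  Only peptide strings are
    produced here; :func:`pepscreen.cleavage.sequential_digest` remains the
    coordinate-tracking reference path and the two must agree (tested).
    """

    def __init__(self, library: EnzymeLibrary):
        self._library = library
        self._pieces: dict[tuple[str, str], tuple[str, ...]] = {}

    def pieces(self, sequence: str, enzyme_name: str) -> tuple[str, ...]:
        key = (enzyme_name, sequence)
        cached = self._pieces.get(key)
        if cached is None:
            sites = self._library[enzyme_name].rule.sites(sequence)
            cuts = [0, *sites, len(sequence)]
            cached = tuple(sequence[a:b] for a, b in zip(cuts, cuts[1:]))
            self._pieces[key] = cached
        return cached

    def sequential_pieces(self, sequence: str, names: Sequence[str]) -> list[str]:
        frags = [sequence]
        for name in names:
            frags = [p for f in frags for p in self.pieces(f, name)]
        return frags


def screen(
    proteins: Sequence,
    combinations: Sequence[EnzymeCombination],
    predictor: BioactivityPredictor,
    config: ScreenConfig = ScreenConfig(),
    *,
    library: EnzymeLibrary,
    seed: int | None = None,
    progress: bool = False,
) -> ScreenResult:
    """Digest, filter, predict and count for every combination.

    Predictions are memoized by peptide sequence, which is sound because
    the predictor contract requires purity; results are therefore
    independent of combination evaluation order.
    """
    if not combinations:
        raise InputError("no combinations to screen")
    iterator: Iterable[EnzymeCombination] = combinations
    if progress:
        from tqdm import tqdm

        iterator = tqdm(combinations, unit="combo", desc="screening")

    sequences = [str(getattr(p, "sequence", p)).upper() for p in proteins]
    digests = DigestCache(library)
    cache: dict[str, Mapping[str, bool]] = {}
    counts: dict[str, dict[str, int]] = {}
    unique: dict[str, int] = {}
    positives: dict[str, dict[str, set[str]]] = {}
    for combo in iterator:
        peptides: Iterable[str] = (
            pep
            for seq in sequences
            for pep in digests.sequential_pieces(seq, combo.enzymes)
            if config.min_len <= len(pep) <= config.max_len
        )
        pool = sorted(set(peptides)) if config.dedupe else sorted(peptides)
        todo = [p for p in set(pool) if p not in cache]
        if todo:
            for pred in predict_bioactivity(sorted(todo), predictor):
                cache[pred.sequence] = pred.calls
        by_class: dict[str, int] = {c: 0 for c in config.classes}
        pos: dict[str, set[str]] = {c: set() for c in config.classes}
        for pep in pool:
            calls = cache[pep]
            for cls in config.classes:
                if calls[cls]:
                    by_class[cls] += 1
                    pos[cls].add(pep)
        counts[combo.display_name] = by_class
        unique[combo.display_name] = len(set(pool))
        positives[combo.display_name] = pos

    provenance = {
        "library_source": library.source,
        "library_checksum": library.checksum,
        "library_size": len(library),
        "predictor": predictor.name,
        "predictor_version": predictor.version,
        "config": {
            "min_len": config.min_len,
            "max_len": config.max_len,
            "classes": list(config.classes),
            "dedupe": config.dedupe,
        },
        "n_proteins": len(proteins),
        "n_combinations": len(combinations),
        "seed": seed,
    }
    result = ScreenResult(
        counts=counts,
        unique_peptides=unique,
        combinations=list(combinations),
        config=config,
        provenance=provenance,
    )
    result._positives = positives
    return result


def best_combination_per_class(result: ScreenResult) -> dict[str, dict]:
    """The maximal-count combination for each class.

    Ties (including the all-zero degenerate case) break toward the
    lexicographically smallest enzyme-name tuple; an all-zero winner is
    flagged ``no_positives``.
    """
    if not result.counts:
        raise InputError("empty screen result")
    by_name = {c.display_name: c for c in result.combinations}
    out: dict[str, dict] = {}
    for cls in result.config.classes:
        best_combo = None
        best_count = -1
        for combo in sorted(result.combinations, key=lambda c: c.enzymes):
            cnt = result.counts[combo.display_name][cls]
            if cnt > best_count:
                best_combo, best_count = combo, cnt
        out[cls] = {
            "combination": best_combo,
            "count": best_count,
            "no_positives": best_count == 0,
        }
    return out


def format_best_combinations(best: Mapping[str, Mapping]) -> str:
    """Render per-class winners as 'CLS: Name_Name (n = count)' lines."""
    lines = []
    for cls in sorted(best):
        entry = best[cls]
        line = f"{cls}: {entry['combination'].display_name} (n = {entry['count']})"
        if entry.get("no_positives"):
            line += "  [no positives]"
        lines.append(line)
    return "\n".join(lines)


def compare_depths(
    proteins: Sequence,
    k_values: Sequence[int],
    *,
    library: EnzymeLibrary,
    config: ScreenConfig = ScreenConfig(),
    progress: bool = False,
) -> dict[int, dict]:
    """Unique length-passing peptide counts over all depth-k combinations.

    For each k this pools the unique peptide sequences obtainable from any
    k-combination, per protein and in total — the yield-versus-depth
    comparison that motivates stopping at two enzymes.
    """
    if not k_values:
        raise InputError("k_values must be non-empty")
    out: dict[int, dict] = {}
    for k in k_values:
        combos = enumerate_combinations(library, k)
        iterator: Iterable[EnzymeCombination] = combos
        if progress:
            from tqdm import tqdm

            iterator = tqdm(combos, unit="combo", desc=f"depth {k}")
        digests = DigestCache(library)
        per_protein: dict[str, set[str]] = {}
        for combo in iterator:
            for protein in proteins:
                acc = getattr(protein, "accession", "")
                seq = str(getattr(protein, "sequence", protein)).upper()
                bucket = per_protein.setdefault(acc, set())
                bucket.update(
                    pep
                    for pep in digests.sequential_pieces(seq, combo.enzymes)
                    if config.min_len <= len(pep) <= config.max_len
                )
        total = set().union(*per_protein.values()) if per_protein else set()
        out[k] = {
            "total": len(total),
            "per_protein": {acc: len(s) for acc, s in sorted(per_protein.items())},
        }
    return out
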