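"""Seeded synthetic fixtures shaped like the study inputs.

The generator emulates the structure (not the content) of the real inputs:
an expression table with one row per protein, three replicate intensity
columns and an annotation flag, plus a matching proteome FASTA, and mock
prediction tables so the whole pipeline runs offline.  Protein sequences
are drawn from Swiss-Prot average residue frequencies; abundances are
log-normal with multiplicative replicate noise, mimicking the dynamic
range of microarray intensities.  Everything is a pure function of the
seed: the same configuration always produces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cleavage import EnzymeLibrary, STANDARD_RESIDUES, bundled_library
from .errors import InputError
from .filtering import SafetyVerdict
from .predictors import BIOACTIVITY_CLASSES, SeededRandomPredictor, unit_float
from .screening import DigestCache
from .substrates import ProteinRecord

#: Swiss-Prot average amino-acid frequencies (per cent), used as the default
#: residue composition of synthetic proteins.
SWISSPROT_FREQUENCIES = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91,
    "L": 9.65, "K": 5.80, "M": 2.41, "F": 3.86, "P": 4.74,
    "S": 6.65, "T": 5.36, "W": 1.10, "Y": 2.92, "V": 6.86,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the fixture generator; defaults are study-shaped.

    Sixty expression rows with ~90% annotated leave headroom for a top-50
    annotated selection from a triplicate table; protein lengths follow a
    clipped normal around 300 residues, the scale of abundant metabolic
    proteins.
    """

    seed: int = 0
    n_proteins: int = 60
    length_mean: float = 300.0
    length_sd: float = 120.0
    length_min: int = 60
    length_max: int = 600
    composition: dict = field(default_factory=lambda: dict(SWISSPROT_FREQUENCIES))
    fraction_annotated: float = 0.9
    replicate_noise_sd: float = 0.05   # multiplicative, relative to the base intensity
    n_replicates: int = 3
    planted_motifs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise InputError("n_proteins must be >= 0")
        weights = np.array([self.composition.get(a, 0.0) for a in STANDARD_RESIDUES])
        if (weights < 0).any() or weights.sum() <= 0:
            raise InputError("composition weights must be non-negative with a positive sum")
        for motif in self.planted_motifs:
            if len(motif) > self.length_max:
                raise InputError(f"planted motif {motif!r} longer than length_max")
            if not set(motif) <= set(STANDARD_RESIDUES):
                raise InputError(f"planted motif {motif!r} has non-standard residues")


def generate_proteome(config: SyntheticConfig) -> list[ProteinRecord]:
    """Draw ``n_proteins`` random sequences; planted motifs are spliced in
    round-robin so each stated motif is guaranteed present."""
    rng = np.random.default_rng(config.seed)
    letters = np.array(list(STANDARD_RESIDUES))
    weights = np.array([config.composition.get(a, 0.0) for a in STANDARD_RESIDUES], dtype=float)
    weights = weights / weights.sum()
    records = []
    for i in range(config.n_proteins):
        length = int(
            np.clip(
                round(rng.normal(config.length_mean, config.length_sd)),
                config.length_min,
                config.length_max,
            )
        )
        seq = "".join(rng.choice(letters, size=length, p=weights))
        if config.planted_motifs:
            motif = config.planted_motifs[i % len(config.planted_motifs)]
            if len(motif) <= length:
                pos = int(rng.integers(0, length - len(motif) + 1))
                seq = seq[:pos] + motif + seq[pos + len(motif):]
        records.append(
            ProteinRecord(
                accession=f"SYN{i:04d}",
                sequence=seq,
                description="synthetic protein",
            )
        )
    return records


def generate_expression_table(config: SyntheticConfig, proteins) -> pd.DataFrame:
    """Log-normal base abundances with multiplicative replicate noise."""
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    rep_cols = [f"rep{i + 1}" for i in range(config.n_replicates)]
    for prot in proteins:
        base = float(rng.lognormal(mean=np.log(500.0), sigma=1.2))
        reps = base * (1.0 + rng.normal(0.0, config.replicate_noise_sd, config.n_replicates))
        reps = np.clip(reps, 0.0, None)
        annotated = bool(rng.random() < config.fraction_annotated)
        row = {"accession": prot.accession}
        row.update({c: round(float(v), 4) for c, v in zip(rep_cols, reps)})
        row["annotated"] = annotated
        rows.append(row)
    return pd.DataFrame(rows, columns=["accession", *rep_cols, "annotated"])


def enumerate_fixture_peptides(
    proteins,
    library: EnzymeLibrary | None = None,
    *,
    max_depth: int = 2,
    min_len: int = 1,
    max_len: int = 10**9,
) -> list[str]:
    """All unique peptides the fixture can yield at digestion depth <= 2.

    Uses the memoized digest cache so the union over all ordered pairs is
    computed as: every single-enzyme digest, then every fragment re-digested
    by every enzyme.  This is the coverage set a strict table-backed
    predictor must know about.
    """
    if library is None:
        library = bundled_library()
    if max_depth not in (1, 2):
        raise InputError("enumerate_fixture_peptides supports depth 1 or 2")
    digests = DigestCache(library)
    names = sorted(library.names)
    peptides: set[str] = set()
    round1: set[str] = set()
    for prot in proteins:
        seq = prot.sequence.upper()
        for name in names:
            round1.update(digests.pieces(seq, name))
    peptides.update(round1)
    if max_depth == 2:
        for frag in sorted(round1):
            for name in names:
                peptides.update(digests.pieces(frag, name))
    return sorted(p for p in peptides if min_len <= len(p) <= max_len)


def mock_bioactivity_table(peptides, seed: int, positive_rate: float = 0.05) -> pd.DataFrame:
    """Long-format score table (sequence, class, score, call) for a peptide set."""
    predictor = SeededRandomPredictor(seed, positive_rate)
    rows = []
    for pred in predictor.predict(sorted(set(peptides))):
        for cls in BIOACTIVITY_CLASSES:
            rows.append(
                {
                    "sequence": pred.sequence,
                    "class": cls,
                    "score": round(pred.scores[cls], 6),
                    "call": int(pred.calls[cls]),
                }
            )
    return pd.DataFrame(rows, columns=["sequence", "class", "score", "call"])


def mock_safety_verdict(sequence: str, seed: int) -> SafetyVerdict:
    """Deterministic per-sequence safety/stability verdict.

    Marginals: ~8% toxic; bitterness uniform on [0, 600] (so a realistic
    share exceeds the 333 cutoff); plasma half-life uniform on [0, 1600] s
    (about half pass the 800 s gate); intestinal half-life exponential with
    mean 2 s (most, not all, pass the 1 s gate).
    """
    return SafetyVerdict(
        sequence=sequence,
        toxic=unit_float(seed, "toxic", sequence) < 0.08,
        bitterness_score=round(600.0 * unit_float(seed, "bitter", sequence), 2),
        plasma_half_life_s=round(1600.0 * unit_float(seed, "plasma", sequence), 2),
        intestinal_half_life_s=round(
            -2.0 * float(np.log(1.0 - unit_float(seed, "gut", sequence))), 3
        ),
    )


def mock_safety_table(peptides, seed: int) -> pd.DataFrame:
    rows = []
    for pep in sorted(set(peptides)):
        v = mock_safety_verdict(pep, seed)
        rows.append(
            {
                "sequence": v.sequence,
                "toxic": int(v.toxic),
                "bitterness_score": v.bitterness_score,
                "plasma_half_life_s": v.plasma_half_life_s,
                "intestinal_half_life_s": v.intestinal_half_life_s,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sequence", "toxic", "bitterness_score",
            "plasma_half_life_s", "intestinal_half_life_s",
        ],
    )


def generate_fixture(
    config: SyntheticConfig,
    out_dir,
    *,
    library: EnzymeLibrary | None = None,
    score_tables: bool = True,
) -> dict[str, Path]:
    """Write the full fixture tree; deterministic for a given config.

    Produces ``proteome.fasta``, ``expression.tsv`` and, when
    ``score_tables`` is set, ``scores.tsv``/``safety.tsv`` covering every
    depth <= 2 peptide of the fixture under ``library`` so a strict
    table-backed predictor can never miss.
    """
    from .fastaio import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteins = generate_proteome(config)
    expression = generate_expression_table(config, proteins)

    paths = {
        "proteome": out / "proteome.fasta",
        "expression": out / "expression.tsv",
    }
    if proteins:
        write_fasta(proteins, paths["proteome"])
    else:
        paths["proteome"].write_text("")
    expression.to_csv(paths["expression"], sep="\t", index=False)

    if score_tables:
        peptides = enumerate_fixture_peptides(proteins, library, max_depth=2)
        paths["scores"] = out / "scores.tsv"
        paths["safety"] = out / "safety.tsv"
        mock_bioactivity_table(peptides, config.seed).to_csv(
            paths["scores"], sep="\t", index=False
        )
        mock_safety_table(peptides, config.seed).to_csv(
            paths["safety"], sep="\t", index=False
        )
    return paths
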