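"""FASTA reading/writing for substrates and digestion products.

Parsing is delegated to Biopython's SeqIO; the accession is the first
whitespace-delimited token of the header and the remainder is kept as the
description.  Lowercase sequences are uppercased with a warning, and
duplicate accessions are an error in strict mode.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cleavage import PeptideFragment
from .errors import InputError
from .substrates import ProteinRecord


def read_fasta(path, *, strict: bool = True) -> list[ProteinRecord]:
    """Load a multi-record FASTA into :class:`ProteinRecord` objects."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise InputError(f"record {rec.id!r} in {path} has an empty sequence")
        if seq != seq.upper():
            warnings.warn(f"record {rec.id!r}: lowercase residues uppercased", stacklevel=2)
            seq = seq.upper()
        if rec.id in seen:
            if strict:
                raise InputError(f"duplicate accession {rec.id!r} in {path}")
            continue
        seen.add(rec.id)
        description = rec.description[len(rec.id):].strip()
        records.append(ProteinRecord(accession=rec.id, sequence=seq, description=description))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path, *, width: int = 60) -> None:
    """Write protein records as wrapped FASTA."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def write_peptides_fasta(fragments: Sequence[PeptideFragment], path) -> None:
    """Write digestion products; headers carry parent, span and enzyme chain."""
    with open(path, "w") as fh:
        for frag in fragments:
            chain = "_".join(frag.enzyme_chain)
            fh.write(f">{frag.parent}|{frag.start}-{frag.end}|{chain}\n{frag.sequence}\n")


def fragments_to_frame(fragments: Sequence[PeptideFragment]) -> pd.DataFrame:
    """Tabulate fragments (sequence, parent, start, end, enzyme_chain)."""
    return pd.DataFrame(
        [
            {
                "sequence": f.sequence,
                "parent": f.parent,
                "start": f.start,
                "end": f.end,
                "enzyme_chain": "_".join(f.enzyme_chain),
            }
            for f in fragments
        ],
        columns=["sequence", "parent", "start", "end", "enzyme_chain"],
    )
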