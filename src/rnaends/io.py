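"""FASTA and dot-bracket I/O."""

from __future__ import annotations

import os
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequence import NucleotideSequence
from .structure import SecondaryStructure
from .thermo import EnsembleSample


def read_fasta(path: str | os.PathLike | TextIO) -> list[NucleotideSequence]:
    """Read a multi-record FASTA (wrapped lines fine; T is mapped to U)."""
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return [NucleotideSequence(rec.id, str(rec.seq)) for rec in records]


def write_fasta(seqs: Iterable[NucleotideSequence],
                path: str | os.PathLike | TextIO) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="")
               for s in seqs]
    SeqIO.write(records, path, "fasta")


def read_dotbracket(path: str | os.PathLike) -> list[SecondaryStructure]:
    """One dot-bracket structure per line; blank lines and '>' headers skipped."""
    structures = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith((">", "#")):
                continue
            structures.append(SecondaryStructure.from_dotbracket(line))
    if not structures:
        raise ValueError(f"no dot-bracket lines found in {path}")
    return structures


def write_dotbracket(structures: Iterable[SecondaryStructure],
                     path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in structures:
            fh.write(s.to_dotbracket() + "\n")


def write_sample_tsv(sample: EnsembleSample, energies: Iterable[float],
                     path: str | os.PathLike) -> None:
    """Per-structure TSV: index, energy (kcal/mol), dot-bracket."""
    with open(path, "w") as fh:
        fh.write("index\tenergy_kcal_mol\tstructure\n")
        for k, (structure, energy) in enumerate(
                zip(sample.structures, energies)):
            fh.write(f"{k}\t{energy:.4f}\t{structure.to_dotbracket()}\n")
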