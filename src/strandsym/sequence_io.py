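"""Sequence input/output, shuffled-composition controls, and synthetic fixtures.

The null model used throughout the package is the exact-composition shuffle:
a control sequence with precisely the same number of A, C, G and T (and hence
the same length) as its source, in seeded random order. Such controls retain
the mononucleotide spectrum — and therefore the mononucleotide symmetry
level — of the source exactly, while destroying any higher-order structure.

Synthetic fixtures come in two flavours: ``generate_symmetric`` builds a
sequence that is its own reverse complement (perfect strand symmetry at
every order), and ``generate_mixture`` blends a symmetric block with an
i.i.d. random block so that the strength of the symmetry signal can be tuned.
"""

from __future__ import annotations

import gzip
import textwrap
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

from .kmer_core import reverse_complement

__all__ = [
    "FastaParseError",
    "SequenceRecord",
    "GenomeAssembly",
    "ControlSet",
    "read_fasta",
    "write_fasta",
    "shuffle_control",
    "make_control_set",
    "generate_symmetric",
    "generate_mixture",
]

# DNA alphabet plus IUPAC ambiguity letters; U deliberately absent (DNA only)
_IUPAC = set("ACGTNRYSWKMBDHV")


class FastaParseError(ValueError):
    """Raised for structurally invalid FASTA input or non-IUPAC residues."""


@dataclass
class SequenceRecord:
    """One chromosome/contig: identifier plus uppercased residues."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if len(self.residues) < 1:
            raise FastaParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - _IUPAC
        if bad:
            raise FastaParseError(
                f"record {self.id!r}: non-IUPAC residue(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GenomeAssembly:
    """An identified, ordered set of sequence records with composition summaries."""

    genome_id: str
    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"genome {self.genome_id!r} has no records")

    @property
    def base_counts(self) -> dict[str, int]:
        counts = {"A": 0, "C": 0, "G": 0, "T": 0, "other": 0}
        for rec in self.records:
            for base in "ACGT":
                counts[base] += rec.residues.count(base)
        total = sum(len(r) for r in self.records)
        counts["other"] = total - sum(counts[b] for b in "ACGT")
        return counts

    @property
    def gc_content(self) -> float:
        """(C+G)/(A+C+G+T) over unambiguous bases, in [0, 1]."""
        c = self.base_counts
        denom = c["A"] + c["C"] + c["G"] + c["T"]
        if denom == 0:
            raise ValueError(f"genome {self.genome_id!r} has no unambiguous bases")
        return (c["C"] + c["G"]) / denom

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)


@dataclass
class ControlSet:
    """Exact-composition shuffled controls for one source genome."""

    source_genome_id: str
    controls: list[GenomeAssembly]
    seed: int

    @property
    def n_controls(self) -> int:
        return len(self.controls)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path, genome_id: str | None = None) -> GenomeAssembly:
    """Read a (possibly gzip-compressed, multi-record) FASTA file.

    Residues are uppercased and validated against the IUPAC DNA alphabet.
    Structural problems are reported with the offending line number;
    residue problems with the offending record and character.
    """
    path = Path(path)
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    stripped = [ln.strip() for ln in lines]
    nonblank = [(i, ln) for i, ln in enumerate(stripped, start=1) if ln]
    if not nonblank:
        raise FastaParseError(f"{path}: empty FASTA file")
    first_line_no, first = nonblank[0]
    if not first.startswith(">"):
        raise FastaParseError(
            f"{path}: line {first_line_no}: sequence data before first '>' header"
        )
    with _open_text(path) as fh:
        records = [
            SequenceRecord(id=rec.id, residues=str(rec.seq))
            for rec in SeqIO.parse(fh, "fasta")
        ]
    if not records:
        raise FastaParseError(f"{path}: no FASTA records parsed")
    return GenomeAssembly(genome_id=genome_id or path.name.split(".")[0], records=records)


def write_fasta(assembly: GenomeAssembly, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in assembly.records:
            fh.write(f">{rec.id}\n")
            fh.write(textwrap.fill(rec.residues, width=width) + "\n")


def shuffle_control(genome: GenomeAssembly, seed: int) -> GenomeAssembly:
    """Uniform seeded permutation of each record, independently per record.

    Preserves each record's residue multiset (including ambiguity letters)
    and length exactly; the same genome and seed reproduce the same control
    byte for byte.
    """
    rng = np.random.default_rng(seed)
    out = []
    for rec in genome.records:
        arr = np.frombuffer(rec.residues.encode("ascii"), dtype=np.uint8)
        shuffled = rng.permutation(arr)
        out.append(
            SequenceRecord(id=rec.id, residues=shuffled.tobytes().decode("ascii"))
        )
    return GenomeAssembly(genome_id=f"{genome.genome_id}|shuffled", records=out)


def make_control_set(genome: GenomeAssembly, n: int, seed: int) -> ControlSet:
    """Generate ``n`` shuffled controls from substream seeds ``seed + i``.

    One control suffices for paired group analysis; individual-genome
    analysis uses 30.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    controls = []
    for i in range(n):
        ctrl = shuffle_control(genome, seed + i)
        ctrl.genome_id = f"{genome.genome_id}|control_{i}"
        controls.append(ctrl)
    return ControlSet(source_genome_id=genome.genome_id, controls=controls, seed=seed)


def generate_symmetric(core: str, record_id: str = "symmetric") -> SequenceRecord:
    """Concatenate ``core`` with its reverse complement.

    The result equals its own reverse complement, so every k-mer occurs
    exactly as often as its reverse complement at every order — a perfect
    strand-symmetry fixture.
    """
    rc = reverse_complement(core)  # rejects ambiguity letters
    return SequenceRecord(id=record_id, residues=core + rc)


def _random_bases(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    draw = rng.choice(4, size=length, p=probs)
    return "".join("ACGT"[i] for i in draw)


def generate_mixture(
    length: int,
    symmetric_fraction: float,
    gc: float,
    seed: int,
    record_id: str | None = None,
) -> SequenceRecord:
    """Blend a self-reverse-complement block with an i.i.d. block.

    The symmetric block is built as ``s + revcomp(s)`` with
    ``len(s) ≈ symmetric_fraction * length / 2``; the remainder is i.i.d.
    with the stated GC fraction. The two blocks are concatenated in seeded
    random order, so the symmetry signal is global rather than positional.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    if not (0.0 <= symmetric_fraction <= 1.0):
        raise ValueError("symmetric_fraction must be in [0, 1]")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    half = int(round(symmetric_fraction * length / 2))
    core = _random_bases(rng, half, gc)
    sym_block = core + reverse_complement(core) if half else ""
    rand_block = _random_bases(rng, length - len(sym_block), gc)
    blocks = [sym_block, rand_block]
    order = rng.permutation(2)
    residues = "".join(blocks[i] for i in order if blocks[i])
    rid = record_id or f"mixture_f{symmetric_fraction:g}_seed{seed}"
    return SequenceRecord(id=rid, residues=residues)
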