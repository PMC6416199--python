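"""Overlapping k-mer counting and reverse-complement utilities.

Counts are kept as plain integers throughout: every downstream quantity
(symmetry indexes, arrangements, word symmetry distances) is invariant under
rescaling of the spectrum, so no conversion to relative frequencies is ever
needed. Counting is forward-strand only — strand symmetry is a property of
the k-mer spectrum *within* one strand, and collapsing onto canonical k-mers
would erase exactly the asymmetry signal being measured.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "KmerTable",
    "reverse_complement",
    "is_self_complementary",
    "count_kmers",
    "compile_tables",
    "word_to_code",
    "code_to_word",
    "rc_code_table",
]

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

# byte value -> 2-bit base code, 255 for anything that is not A/C/G/T
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENC[ord(_b)] = _i


def reverse_complement(word: str) -> str:
    """Reverse complement of a word over {A,C,G,T}.

    An involution: ``reverse_complement(reverse_complement(w)) == w``.
    Ambiguity letters are rejected — symmetry analysis is defined on the
    unambiguous alphabet only.
    """
    if not word or any(c not in _BASES for c in word):
        raise ValueError(f"word must be non-empty over ACGT, got {word!r}")
    return word.translate(_COMP)[::-1]


def is_self_complementary(word: str) -> bool:
    """True iff the word equals its own reverse complement.

    Only possible for even length; for even k exactly 4**(k//2) words are
    self-complementary.
    """
    return word == reverse_complement(word)


def word_to_code(word: str) -> int:
    """Base-4 integer code of a word (A=0, C=1, G=2, T=3, big-endian).

    Numeric code order equals lexicographic word order.
    """
    code = 0
    for c in word:
        i = _BASES.find(c)
        if i < 0:
            raise ValueError(f"invalid residue {c!r} in {word!r}")
        code = code * 4 + i
    return code


def code_to_word(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


@functools.lru_cache(maxsize=None)
def rc_code_table(k: int) -> np.ndarray:
    """Vector mapping every k-mer code to the code of its reverse complement."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = 4**k
    rc = np.zeros(n, dtype=np.int64)
    tmp = np.arange(n, dtype=np.int64)
    for i in range(k):
        digit = tmp & 3
        tmp >>= 2
        # digit i from the right is complemented and lands i-th from the left
        rc |= (3 - digit) << (2 * (k - 1 - i))
    return rc


@dataclass
class KmerTable:
    """Occurrence counts of overlapping k-mers, compiled over chromosomes.

    ``counts`` is sparse (absent word = 0); ``n_windows`` is the number of
    length-k windows scanned, ``n_valid`` the number actually counted
    (windows containing any non-ACGT letter are skipped).
    """

    k: int
    counts: dict[str, int] = field(default_factory=dict)
    n_windows: int = 0
    n_valid: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        total = sum(self.counts.values())
        if total != self.n_valid:
            raise ValueError(
                f"counts sum to {total} but n_valid={self.n_valid}"
            )
        if self.n_valid > self.n_windows:
            raise ValueError("n_valid cannot exceed n_windows")

    def dense(self) -> np.ndarray:
        """Counts over all 4**k codes in lexicographic word order."""
        arr = np.zeros(4**self.k, dtype=np.int64)
        for w, c in self.counts.items():
            arr[word_to_code(w)] = c
        return arr

    @classmethod
    def from_dense(cls, k: int, arr: np.ndarray, n_windows: int | None = None) -> "KmerTable":
        nz = np.nonzero(arr)[0]
        counts = {code_to_word(int(c), k): int(arr[c]) for c in nz}
        valid = int(arr.sum())
        return cls(k=k, counts=counts, n_windows=n_windows if n_windows is not None else valid, n_valid=valid)

    def to_tsv(self, path: str | Path) -> None:
        """Write the table as two-column TSV, words in lexicographic order."""
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\tn_valid={self.n_valid}\tn_windows={self.n_windows}\n")
            for w in sorted(self.counts):
                fh.write(f"{w}\t{self.counts[w]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerTable":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#k="):
                raise ValueError(f"{path}: missing '#k=' header")
            fields = dict(
                part.split("=", 1) for part in header.lstrip("#").split("\t")
            )
            counts: dict[str, int] = {}
            for line in fh:
                if not line.strip():
                    continue
                w, c = line.split("\t")
                counts[w] = int(c)
        return cls(
            k=int(fields["k"]),
            counts=counts,
            n_windows=int(fields.get("n_windows", fields["n_valid"])),
            n_valid=int(fields["n_valid"]),
        )


def count_kmers(record, k: int) -> KmerTable:
    """Count overlapping k-mers on the forward strand of one sequence record.

    Every window advanced by one position is examined (no wraparound);
    windows containing any non-ACGT letter contribute to ``n_windows`` but
    not to ``n_valid`` or the counts.

    ``record`` is anything with a ``residues`` string attribute, or a plain
    string.
    """
    residues = record if isinstance(record, str) else record.residues
    length = len(residues)
    if k < 1 or k > length:
        raise ValueError(f"k={k} out of range for sequence of length {length}")
    enc = _ENC[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    n_windows = length - k + 1
    bad = (enc == 255).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[k:] - cum[:-k]) == 0  # window [i, i+k) has no bad residue
    vals = np.zeros(n_windows, dtype=np.int64)
    e = enc.astype(np.int64)
    for i in range(k):
        vals = (vals << 2) | e[i : i + n_windows]
    sel = vals[valid]
    arr = np.bincount(sel, minlength=4**k) if sel.size else np.zeros(4**k, dtype=np.int64)
    table = KmerTable.from_dense(k, arr, n_windows=n_windows)
    return table


def compile_tables(tables: Iterable[KmerTable]) -> KmerTable:
    """Word-wise sum of per-chromosome tables of one order.

    Associative and commutative; a single table compiles to itself.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one table")
    k = tables[0].k
    if any(t.k != k for t in tables):
        raise ValueError("all tables must share the same k")
    counts: dict[str, int] = {}
    for t in tables:
        for w, c in t.counts.items():
            counts[w] = counts.get(w, 0) + c
    return KmerTable(
        k=k,
        counts=counts,
        n_windows=sum(t.n_windows for t in tables),
        n_valid=sum(t.n_valid for t in tables),
    )
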