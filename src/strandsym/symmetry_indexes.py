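"""Strand-symmetry indexes S1 and S2.

Both indexes compare the count f of every k-mer with the count f' of its
reverse complement, over all "eligible" ordered entries: words that differ
from their own reverse complement and whose pair is not entirely absent
(f = f' = 0). Self-complementary (palindromic) words carry no symmetry
information and are excluded.

    S1 = 1 - sum|f - f'| / sum(f + f')        (total-frequency weighting)
    S2 = 1 - (1/M) * sum(|f - f'| / (f + f')) (every pair weighted equally)

Each unordered complementary pair contributes two ordered entries (w, w')
and (w', w); the double counting cancels in both formulas, so M — the number
of ordered entries — is always even. Both indexes live in [0, 1]; 1 means
every eligible word matches its reverse complement exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kmer_core import KmerTable, compile_tables, count_kmers, rc_code_table
from .sequence_io import GenomeAssembly

__all__ = ["SymmetryIndexResult", "compute_indexes", "mono_s1"]


@dataclass
class SymmetryIndexResult:
    k: int
    s1: float
    s2: float
    m_pairs: int  # ordered entries used; two per unordered pair, hence even
    n_words_considered: int
    defined: bool = True


def compute_indexes(table: KmerTable) -> SymmetryIndexResult:
    """Evaluate S1 and S2 on one compiled k-mer table.

    If no eligible pair exists (all occurring words self-complementary, or
    an empty table) the result is flagged undefined and both indexes are
    NaN — never silently 0 or 1.
    """
    k = table.k
    n = 4**k
    f = table.dense()
    rc = rc_code_table(k)
    fp = f[rc]
    eligible = (np.arange(n, dtype=np.int64) != rc) & (f + fp > 0)
    m = int(eligible.sum())
    if m == 0:
        warnings.warn(
            f"no eligible complementary pairs at k={k}; symmetry indexes undefined",
            stacklevel=2,
        )
        return SymmetryIndexResult(
            k=k, s1=float("nan"), s2=float("nan"), m_pairs=0,
            n_words_considered=0, defined=False,
        )
    diff = np.abs(f - fp)[eligible].astype(np.float64)
    tot = (f + fp)[eligible].astype(np.float64)
    s1 = 1.0 - diff.sum() / tot.sum()
    s2 = 1.0 - float(np.mean(diff / tot))
    return SymmetryIndexResult(
        k=k, s1=float(s1), s2=float(s2), m_pairs=m, n_words_considered=m,
    )


def mono_s1(genome: GenomeAssembly) -> float:
    """Mononucleotide (k=1) S1 of a genome — the grouping covariate.

    Computed on the table compiled across all records.
    """
    tables = [count_kmers(rec, 1) for rec in genome.records]
    return compute_indexes(compile_tables(tables)).s1
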